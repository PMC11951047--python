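"""Simulation of metabolic defects on subpool models.

A defect removes the enzyme resources of one subpool — typically the main
(rank-1) reaction of an enzyme — by forcing its draw pseudoreaction to
zero, which by the capacity coupling v <= kcat·E also silences the
reaction.  Unlike a gene knockout, the enzyme's other subpools stay
available, so promiscuous (side) activities can absorb the freed pool and
compensate.

Workflows:

* single main-reaction blocks against a parsimonious wild-type reference
  whose subpool usages are held within a flexibility band (default 5%),
  with the blocked enzyme's subpools freed so redistribution can occur;
* pairwise main-reaction blocks (growth-impact screen, no band);
* pairwise side-subpool blocks at a chosen rank;
* classical double gene knockouts on the conventional GEM via boolean GPR
  evaluation, the comparison case in which side activities are lost too.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import CoralModel, StoichModel, ValidationError
from .lp import (
    ZERO_TOL,
    SolveResult,
    fba,
    ordering_rows_touching,
    pfba_subpools,
    scenario_overrides,
    solve_lp,
)

__all__ = [
    "WTReference",
    "DefectReport",
    "build_wt_reference",
    "block_main_single",
    "screen_single_blocks",
    "block_main_pairs",
    "block_side_pairs",
    "double_gene_knockout",
    "classify_redistribution",
]

logger = logging.getLogger(__name__)

#: usage bound granted to subpools unused in the wild type, so that
#: redistribution into them stays feasible under the band
WT_ZERO_EPS = 1e-8

#: growth above this threshold counts as non-lethal (1/h)
LETHAL_MU = 1e-6


@dataclass
class WTReference:
    """Parsimonious wild-type enzyme allocation (the P-of-reference state)."""

    mu: float
    band: float = 0.05
    subpool_usage: dict[str, float] = field(default_factory=dict)
    pool_usage: dict[str, float] = field(default_factory=dict)
    solution: SolveResult | None = None
    zero_eps: float = WT_ZERO_EPS

    def __post_init__(self) -> None:
        if not 0 <= self.band < 1:
            raise ValidationError(f"band fraction must be in [0, 1), got {self.band}")


@dataclass
class DefectReport:
    """Outcome of blocking one or more subpools (or genes)."""

    blocked: tuple[str, ...]
    enzymes: tuple[str, ...]
    status: str
    mu_del: float
    mu_wt: float
    #: mu_del / mu_wt (growth retained); the inverse is also provided
    growth_ratio: float
    #: subpool_id -> E_{s,j}/E_s of affected enzyme(s) after the block
    redistribution: dict[str, float] = field(default_factory=dict)
    #: subpool_id -> E_del - E_wt over all subpools (empty for pair screens)
    delta_usage: dict[str, float] = field(default_factory=dict)
    classification: str = ""
    #: both | one | neither enzyme promiscuous (pair screens)
    promiscuity: str = ""
    #: main subpool active in the WT reference (single-block screens)
    wt_main_used: bool = False

    @property
    def lethal(self) -> bool:
        return self.status != "optimal" or self.mu_del <= LETHAL_MU

    @property
    def growth_ratio_inverse(self) -> float:
        return self.mu_wt / self.mu_del if self.mu_del > 0 else math.inf


# ---------------------------------------------------------------------------
# wild-type reference and flexibility band
# ---------------------------------------------------------------------------

def build_wt_reference(
    model: CoralModel,
    mu: float,
    band: float = 0.05,
    underground: bool = True,
) -> WTReference:
    """Parsimonious subpool allocation at fixed growth (the WT state)."""
    sol = pfba_subpools(model, fixed_mu=mu, underground=underground)
    return WTReference(
        mu=mu,
        band=band,
        subpool_usage=dict(sol.subpool_usage),
        pool_usage=dict(sol.pool_usage),
        solution=sol,
    )


def band_overrides(
    model: CoralModel,
    wt: WTReference,
    freed_enzymes: Iterable[str] = (),
    band_mode: str = "subpool",
) -> dict[str, tuple[float, float]]:
    """Wild-type flexibility band as bound overrides.

    ``subpool`` mode bands every subpool draw within ±band of its WT value;
    ``pool`` mode bands only the per-enzyme pool supplies.  Subpools unused
    in the WT get [0, eps] so they stay off unless their enzyme is freed.
    Every subpool (and the supply) of a freed enzyme is unconstrained, which
    is what lets the blocked enzyme's pool redistribute.
    """
    if band_mode not in ("subpool", "pool"):
        raise ValidationError(f"unknown band mode {band_mode!r}")
    freed = set(freed_enzymes)
    lo_f, hi_f = 1.0 - wt.band, 1.0 + wt.band
    out: dict[str, tuple[float, float]] = {}
    for e, pools in model.registry.items():
        if e in freed:
            continue
        if band_mode == "pool":
            ewt = wt.pool_usage.get(e, 0.0)
            if ewt > ZERO_TOL:
                out[model.supply_id(e)] = (lo_f * ewt, hi_f * ewt)
            else:
                out[model.supply_id(e)] = (0.0, wt.zero_eps)
        else:
            for sp in pools:
                ewt = wt.subpool_usage.get(sp.subpool_id, 0.0)
                if ewt > ZERO_TOL:
                    out[sp.draw_id] = (lo_f * ewt, hi_f * ewt)
                else:
                    out[sp.draw_id] = (0.0, wt.zero_eps)
    return out


# ---------------------------------------------------------------------------
# single main-reaction blocks
# ---------------------------------------------------------------------------

def _solve_block(
    model: CoralModel,
    overrides: Mapping[str, tuple[float, float]],
    blocked_draws: Sequence[str],
    parsimonious: bool,
) -> SolveResult:
    """Maximise growth with the given subpool draws blocked.

    Ordering rows that reference a blocked draw are released — a blocked
    main would otherwise force every lower-ranked subpool to zero, and no
    redistribution could ever occur.  Optionally a second stage minimises
    the total draw at the achieved growth so the reported allocation is
    unique-ish and comparable across runs.
    """
    dropped = ordering_rows_touching(model, blocked_draws)
    sol = fba(model, bound_overrides=overrides, exclude_constraints=dropped)
    if not sol.ok or not parsimonious:
        return sol
    mu = sol.mu or 0.0
    slack = 1e-9 * max(1.0, abs(mu))
    second = dict(overrides)
    second[model.objective_id] = (mu - slack, mu)
    objective = {sp.draw_id: 1.0 for sp in model.subpools()}
    psol = solve_lp(
        model,
        objective,
        maximize=False,
        bound_overrides=second,
        exclude_constraints=dropped,
    )
    return psol if psol.ok else sol


def block_main_single(
    model: CoralModel,
    wt: WTReference,
    enzyme_id: str,
    band_mode: str = "subpool",
    parsimonious: bool = True,
    underground: bool = True,
) -> DefectReport:
    """Block one enzyme's main (rank-1) subpool against the WT reference.

    Growth is maximised with every other enzyme's usage held in the WT band
    while all subpools of the blocked enzyme are freed; infeasibility is
    reported as a lethal defect, not raised.
    """
    if enzyme_id not in model.registry:
        raise ValidationError(f"unknown enzyme {enzyme_id!r}")
    main = model.subpool(enzyme_id, 1)
    overrides = scenario_overrides(model, underground=underground)
    overrides.update(band_overrides(model, wt, freed_enzymes=[enzyme_id], band_mode=band_mode))
    overrides[main.draw_id] = (0.0, 0.0)

    sol = _solve_block(model, overrides, [main.draw_id], parsimonious)
    if not sol.ok:
        return DefectReport(
            blocked=(main.subpool_id,),
            enzymes=(enzyme_id,),
            status=sol.status,
            mu_del=0.0,
            mu_wt=wt.mu,
            growth_ratio=0.0,
            classification="lethal",
            wt_main_used=wt.subpool_usage.get(main.subpool_id, 0.0) > ZERO_TOL,
        )

    mu_del = sol.mu or 0.0
    pools = sorted(model.registry[enzyme_id], key=lambda s: s.rank)
    e_tot = sol.pool_usage.get(enzyme_id, 0.0)
    redistribution = {
        sp.subpool_id: (sol.subpool_usage[sp.subpool_id] / e_tot if e_tot > ZERO_TOL else 0.0)
        for sp in pools
    }
    delta = {
        sp.subpool_id: sol.subpool_usage[sp.subpool_id]
        - wt.subpool_usage.get(sp.subpool_id, 0.0)
        for sp in model.subpools()
    }
    report = DefectReport(
        blocked=(main.subpool_id,),
        enzymes=(enzyme_id,),
        status="optimal",
        mu_del=mu_del,
        mu_wt=wt.mu,
        growth_ratio=mu_del / wt.mu if wt.mu > 0 else math.inf,
        redistribution=redistribution,
        delta_usage=delta,
        wt_main_used=wt.subpool_usage.get(main.subpool_id, 0.0) > ZERO_TOL,
    )
    report.classification = classify_redistribution(model, wt, report, sol)
    return report


def classify_redistribution(
    model: CoralModel,
    wt: WTReference,
    report: DefectReport,
    sol: SolveResult,
) -> str:
    """Label how a blocked enzyme's pool redistributed among its subpools.

    ``direct_transfer``  — the rank-2 subpool absorbed the WT main usage
                           (same value within the flexibility band);
    ``majority_rank2``   — most of the pool went to rank 2, remainder spread;
    ``majority_deeper``  — most of the pool went to a rank > 2;
    ``none_to_rank2``    — nothing went to rank 2;
    ``mixed``            — anything else;
    ``no_sides``         — the enzyme has no side subpools;
    ``inactive``         — the main subpool was unused in the WT anyway.
    """
    if report.lethal:
        return "lethal"
    (enzyme_id,) = report.enzymes
    pools = sorted(model.registry[enzyme_id], key=lambda s: s.rank)
    main = pools[0]
    e1_wt = wt.subpool_usage.get(main.subpool_id, 0.0)
    if e1_wt <= ZERO_TOL:
        return "inactive"
    if len(pools) < 2:
        return "no_sides"
    rank2 = pools[1]
    e2_del = sol.subpool_usage.get(rank2.subpool_id, 0.0)
    if abs(e2_del - e1_wt) <= wt.band * e1_wt:
        return "direct_transfer"
    frac = report.redistribution
    f2 = frac.get(rank2.subpool_id, 0.0)
    if f2 > 0.5:
        return "majority_rank2"
    deeper = max((frac.get(sp.subpool_id, 0.0) for sp in pools[2:]), default=0.0)
    if deeper > 0.5:
        return "majority_deeper"
    if e2_del <= ZERO_TOL:
        return "none_to_rank2"
    return "mixed"


def screen_single_blocks(
    model: CoralModel,
    wt: WTReference,
    enzymes: Sequence[str] | None = None,
    band_mode: str = "subpool",
    underground: bool = True,
) -> list[DefectReport]:
    """Block every enzyme's main subpool in turn against the WT reference.

    The interesting subset — enzymes whose main subpool carried usage in the
    WT and whose block is non-lethal — is marked by
    ``report.wt_main_used and not report.lethal``.
    """
    targets = list(enzymes) if enzymes is not None else sorted(model.registry)
    reports = []
    for e in targets:
        reports.append(
            block_main_single(model, wt, e, band_mode=band_mode, underground=underground)
        )
    return reports


# ---------------------------------------------------------------------------
# pairwise blocks
# ---------------------------------------------------------------------------

def _promiscuity_label(model: CoralModel, e1: str, e2: str) -> str:
    n = sum(model.is_promiscuous(e) for e in (e1, e2))
    return {2: "both", 1: "one", 0: "neither"}[n]


def _pair_block(
    model: CoralModel,
    pairs: Iterable[tuple[str, str]],
    rank: int,
    mu_wt: float | None,
    underground: bool,
) -> list[DefectReport]:
    base_overrides = scenario_overrides(model, underground=underground)
    ref_cache: dict[frozenset, float] = {}

    def reference(released: list[str]) -> float:
        # blocking releases the touched ordering rows (a relaxation), so a
        # sound unblocked reference must be computed under the same release;
        # otherwise a block could appear to *increase* growth
        key = frozenset(released)
        if key not in ref_cache:
            base = fba(model, bound_overrides=base_overrides, exclude_constraints=released)
            if not base.ok:
                raise ValidationError(f"unblocked model is {base.status}")
            ref_cache[key] = base.mu or 0.0
        return ref_cache[key]

    reports = []
    for e1, e2 in pairs:
        sps = [model.subpool(e1, rank), model.subpool(e2, rank)]
        blocked_draws = [sp.draw_id for sp in sps]
        released = ordering_rows_touching(model, blocked_draws)
        mu_ref = mu_wt if mu_wt is not None else reference(released)
        overrides = scenario_overrides(
            model, underground=underground, blocks=blocked_draws
        )
        sol = fba(model, bound_overrides=overrides, exclude_constraints=released)
        mu_del = sol.mu or 0.0 if sol.ok else 0.0
        reports.append(
            DefectReport(
                blocked=tuple(sp.subpool_id for sp in sps),
                enzymes=(e1, e2),
                status=sol.status,
                mu_del=mu_del,
                mu_wt=mu_ref,
                growth_ratio=mu_del / mu_ref if mu_ref > 0 else math.inf,
                classification="lethal" if (not sol.ok or mu_del <= LETHAL_MU) else "viable",
                promiscuity=_promiscuity_label(model, e1, e2),
            )
        )
    return reports


def block_main_pairs(
    model: CoralModel,
    mu_wt: float | None = None,
    enzymes: Sequence[str] | None = None,
    underground: bool = True,
) -> list[DefectReport]:
    """Block every unordered pair of main (rank-1) subpools and maximise
    growth; no WT band is applied.  ``mu_wt`` is the reference growth rate
    for the ratio (the paper-style chemostat value, e.g. 0.1/h); when None,
    the model's own unblocked optimum is used.
    """
    targets = list(enzymes) if enzymes is not None else sorted(model.registry)
    pairs = list(itertools.combinations(targets, 2))
    return _pair_block(model, pairs, rank=1, mu_wt=mu_wt, underground=underground)


def block_side_pairs(
    model: CoralModel,
    rank: int,
    mu_wt: float | None = None,
    enzymes: Sequence[str] | None = None,
    underground: bool = True,
) -> list[DefectReport]:
    """Pairwise block of rank-k side subpools (k >= 2).

    Enzymes lacking a rank-k subpool are skipped (and logged).
    """
    if rank < 2:
        raise ValidationError("side-subpool blocks require rank >= 2")
    candidates = list(enzymes) if enzymes is not None else sorted(model.registry)
    eligible = []
    for e in candidates:
        if len(model.registry[e]) >= rank:
            eligible.append(e)
        else:
            logger.info("enzyme %s has no rank-%d subpool; skipped", e, rank)
    pairs = list(itertools.combinations(eligible, 2))
    return _pair_block(model, pairs, rank=rank, mu_wt=mu_wt, underground=underground)


def impacted_pairs(
    reports: Sequence[DefectReport], threshold: float = 0.01
) -> tuple[list[DefectReport], list[DefectReport]]:
    """Partition pair reports at the growth-impact threshold (default 1%):
    returns (impacted, unimpacted)."""
    impacted = [r for r in reports if r.mu_del < (1.0 - threshold) * r.mu_wt]
    rest = [r for r in reports if r not in impacted]
    return impacted, rest


# ---------------------------------------------------------------------------
# conventional double gene knockouts
# ---------------------------------------------------------------------------

def double_gene_knockout(
    gem: StoichModel,
    gene_pairs: Iterable[tuple[str, str]],
    underground: bool = True,
) -> list[DefectReport]:
    """Classical GPR-boolean double knockouts on the conventional GEM.

    For each gene pair, every reaction whose GPR evaluates false with both
    genes deleted has its bounds set to zero; growth is then maximised and
    compared with the unperturbed optimum.  Side activities of the encoded
    enzymes are lost together with the main one — the contrast case to
    subpool blocking.
    """
    from cobra.core.gene import GPR

    known = set(gem.genes)
    gprs = {
        rid: GPR.from_string(rxn.gpr)
        for rid, rxn in gem.reactions.items()
        if rxn.gpr
    }
    base_overrides = scenario_overrides(gem, underground=underground)
    base = fba(gem, bound_overrides=base_overrides)
    if not base.ok:
        raise ValidationError(f"unperturbed GEM is {base.status}")
    mu_wt = base.mu or 0.0

    reports = []
    for g1, g2 in gene_pairs:
        for g in (g1, g2):
            if g not in known:
                raise ValidationError(f"unknown gene {g!r}")
        ko = {g1, g2}
        overrides = dict(base_overrides)
        for rid, gpr in gprs.items():
            if not gpr.eval(knockouts=ko):
                overrides[rid] = (0.0, 0.0)
        sol = fba(gem, bound_overrides=overrides)
        mu_del = sol.mu or 0.0 if sol.ok else 0.0
        reports.append(
            DefectReport(
                blocked=(g1, g2),
                enzymes=(g1, g2),
                status=sol.status,
                mu_del=mu_del,
                mu_wt=mu_wt,
                growth_ratio=mu_del / mu_wt if mu_wt > 0 else math.inf,
                classification="lethal" if (not sol.ok or mu_del <= LETHAL_MU) else "viable",
            )
        )
    return reports
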