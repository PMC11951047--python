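"""Assembly and solution of the optimization problems on subpool models.

All analyses reduce to linear programs over the flux vector of the
(pseudo-)reaction network: steady state S·v = 0, flux bounds, the extra
kcat-ordering rows carried by the model, and scenario-specific bound
overrides (blocked subpools, chemostat growth fixing, underground
reactions switched off, wild-type usage bands).  Problems are solved with
the HiGHS engine through :func:`scipy.optimize.linprog`; the assembly is
solver-agnostic (plain sparse rows/columns/bounds).

Fluxes are mmol/gDW/h; subpool and pool usages are the fluxes of the draw
and supply pseudoreactions (mmol/gDW); growth is the flux of the objective
(biomass) reaction (1/h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import (
    CoralModel,
    LinearConstraint,
    StoichModel,
    ValidationError,
    build_s_matrix,
)

__all__ = [
    "SolveResult",
    "FVAResult",
    "solve_lp",
    "fba",
    "fva_flux",
    "fva_subpools",
    "pfba_subpools",
    "scenario_overrides",
    "ZERO_TOL",
    "RESIDUAL_TOL",
]

#: numerical zero for "carries flux" / "subpool is used" decisions
ZERO_TOL = 1e-8
#: residual tolerance reported solutions must satisfy
RESIDUAL_TOL = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class SolveResult:
    """Solution of one LP on a (subpool) model."""

    status: str
    objective: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    #: subpool_id -> E_{s,i} (mmol/gDW), coral-form models only
    subpool_usage: dict[str, float] = field(default_factory=dict)
    #: enzyme_id -> E_s (mmol/gDW)
    pool_usage: dict[str, float] = field(default_factory=dict)
    #: growth rate, flux of the model's objective reaction (1/h)
    mu: float | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    """Per-target [min, max] ranges under a shared constraint scenario."""

    minimum: dict[str, float] = field(default_factory=dict)
    maximum: dict[str, float] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)

    def range(self, target: str) -> float:
        return self.maximum[target] - self.minimum[target]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "minimum": pd.Series(self.minimum),
                "maximum": pd.Series(self.maximum),
                "status": pd.Series(self.status),
            }
        ).rename_axis("target")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _finite(x: float, lo: bool) -> float | None:
    if math.isinf(x):
        return None
    return x


def solve_lp(
    model: StoichModel,
    objective: Mapping[str, float],
    maximize: bool = True,
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
    extra_constraints: Sequence[LinearConstraint] = (),
    use_model_constraints: bool = True,
    exclude_constraints: Iterable[str] = (),
) -> SolveResult:
    """Solve min/max of a linear objective over the model's feasible set.

    ``bound_overrides`` maps reaction ids to replacement (lb, ub) pairs —
    the mechanism for blocking subpools, fixing growth, switching scenarios.
    Model-carried rows (kcat ordering) are included unless
    ``use_model_constraints`` is False; ``exclude_constraints`` drops named
    rows (used to release the ordering rows touching a blocked subpool,
    without which no resource could ever redistribute past the block).
    """
    S, met_index, rxn_index = build_s_matrix(model)
    n = len(rxn_index)
    c = np.zeros(n)
    for rid, coef in objective.items():
        if rid not in rxn_index:
            raise ValidationError(f"objective references unknown reaction {rid!r}")
        c[rxn_index[rid]] = coef
    if maximize:
        c = -c

    overrides = dict(bound_overrides or {})
    bounds = []
    for rid, rxn in model.reactions.items():
        lb, ub = overrides.get(rid, (rxn.lower_bound, rxn.upper_bound))
        if lb > ub:
            raise ValidationError(f"override for {rid!r} has lb {lb} > ub {ub}")
        bounds.append((_finite(lb, True), _finite(ub, False)))

    excluded = set(exclude_constraints)
    rows: list[LinearConstraint] = []
    if use_model_constraints and isinstance(model, CoralModel):
        rows.extend(c for c in model.constraints if c.name not in excluded)
    rows.extend(extra_constraints)

    eq_rows, eq_rhs, ub_rows, ub_rhs = [], [], [], []
    for con in rows:
        vec = sparse.lil_matrix((1, n))
        for rid, coef in con.coefficients.items():
            vec[0, rxn_index[rid]] = coef
        if con.sense == "==":
            eq_rows.append(vec)
            eq_rhs.append(con.rhs)
        else:
            ub_rows.append(vec)
            ub_rhs.append(con.rhs)

    A_eq = S if not eq_rows else sparse.vstack([S] + [r.tocsr() for r in eq_rows])
    b_eq = np.concatenate([np.zeros(S.shape[0]), np.asarray(eq_rhs)])
    A_ub = sparse.vstack([r.tocsr() for r in ub_rows]) if ub_rows else None
    b_ub = np.asarray(ub_rhs) if ub_rows else None

    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq.tocsr(),
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return SolveResult(status=status, objective=None)

    x = res.x
    fluxes = {rid: float(x[j]) for rid, j in rxn_index.items()}
    obj = float(-res.fun if maximize else res.fun)
    result = SolveResult(status="optimal", objective=obj, fluxes=fluxes)
    if model.objective_id in fluxes:
        result.mu = fluxes[model.objective_id]
    if isinstance(model, CoralModel):
        for e, pools in model.registry.items():
            sid = model.supply_id(e)
            if sid in fluxes:
                result.pool_usage[e] = fluxes[sid]
            if model.form == "coral":
                for sp in pools:
                    result.subpool_usage[sp.subpool_id] = fluxes[sp.draw_id]
    return result


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def scenario_overrides(
    model: StoichModel,
    underground: bool = True,
    fixed_mu: float | None = None,
    blocks: Iterable[str] = (),
    band: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, tuple[float, float]]:
    """Compose bound overrides for a simulation scenario.

    underground=False zeroes both bounds of every reaction tagged with
    underground provenance; ``fixed_mu`` pins the biomass reaction (the
    chemostat condition); ``blocks`` are reaction ids (typically subpool
    draws) forced to zero; ``band`` gives explicit (lb, ub) pairs, e.g. the
    wild-type flexibility band.
    """
    overrides: dict[str, tuple[float, float]] = {}
    if not underground:
        # derived copies (direction/GPR splits) inherit the underground tag
        for rxn in model.reactions.values():
            if rxn.provenance == "underground":
                overrides[rxn.id] = (0.0, 0.0)
        # switching underground off removes those catalytic activities
        # entirely: their subpool draws are zeroed too
        if isinstance(model, CoralModel) and model.form == "coral":
            for sp in model.subpools():
                if model.reactions[sp.reaction_id].provenance == "underground":
                    overrides[sp.draw_id] = (0.0, 0.0)
    if band:
        overrides.update({rid: (float(lo), float(hi)) for rid, (lo, hi) in band.items()})
    for rid in blocks:
        overrides[rid] = (0.0, 0.0)
    if fixed_mu is not None:
        if model.objective_id is None:
            raise ValidationError("cannot fix growth: model has no objective reaction")
        overrides[model.objective_id] = (fixed_mu, fixed_mu)
    return overrides


# ---------------------------------------------------------------------------
# named problems
# ---------------------------------------------------------------------------

def fba(
    model: StoichModel,
    objective: str | None = None,
    maximize: bool = True,
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
    exclude_constraints: Iterable[str] = (),
) -> SolveResult:
    """Flux balance analysis: optimise one reaction's flux (default: biomass)."""
    target = objective or model.objective_id
    if target is None:
        raise ValidationError("no objective reaction given or designated")
    return solve_lp(
        model,
        {target: 1.0},
        maximize=maximize,
        bound_overrides=bound_overrides,
        exclude_constraints=exclude_constraints,
    )


def ordering_rows_touching(model: CoralModel, draw_ids: Iterable[str]) -> list[str]:
    """Names of kcat-ordering rows that a block on the given draws must
    release.

    An inequality row kcat_lo·E_lo <= kcat_hi·E_hi only becomes a spurious
    zero-forcing constraint when the *higher-ranked* draw (negative
    coefficient) is blocked; rows where the blocked draw is on the lesser
    side are trivially satisfied and stay.  Equality (Vmax-equality) rows
    propagate a zero either way, so any touched row is released.
    """
    targets = set(draw_ids)
    out = []
    for c in model.constraints:
        if not c.name.startswith("order_"):
            continue
        touched = targets & set(c.coefficients)
        if not touched:
            continue
        if c.sense == "==" or any(c.coefficients[d] < 0 for d in touched):
            out.append(c.name)
    return out


def underground_exclusions(model: StoichModel, underground: bool) -> list[str]:
    """Ordering rows to release when underground activities are switched
    off (their zeroed draws would otherwise drag deeper ranks to zero)."""
    if underground or not isinstance(model, CoralModel) or model.form != "coral":
        return []
    draws = [
        sp.draw_id
        for sp in model.subpools()
        if model.reactions[sp.reaction_id].provenance == "underground"
    ]
    return ordering_rows_touching(model, draws)


def _fva(
    model: StoichModel,
    targets: Sequence[str],
    fixed_mu: float | None,
    underground: bool,
    extra_overrides: Mapping[str, tuple[float, float]] | None,
) -> FVAResult:
    overrides = scenario_overrides(model, underground=underground, fixed_mu=fixed_mu)
    if extra_overrides:
        overrides.update(extra_overrides)
    excluded = underground_exclusions(model, underground)
    out = FVAResult(scenario={"underground": underground, "fixed_mu": fixed_mu})
    for t in targets:
        if t not in model.reactions:
            raise ValidationError(f"FVA target {t!r} not in model")
        lo = solve_lp(model, {t: 1.0}, maximize=False, bound_overrides=overrides,
                      exclude_constraints=excluded)
        hi = solve_lp(model, {t: 1.0}, maximize=True, bound_overrides=overrides,
                      exclude_constraints=excluded)
        if lo.ok and hi.ok:
            out.minimum[t] = lo.objective
            out.maximum[t] = hi.objective
            out.status[t] = "optimal"
        else:
            out.minimum[t] = math.nan
            out.maximum[t] = math.nan
            out.status[t] = lo.status if not lo.ok else hi.status
    return out


def fva_flux(
    model: StoichModel,
    targets: Sequence[str] | None = None,
    fixed_mu: float | None = None,
    underground: bool = True,
    extra_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> FVAResult:
    """Flux variability analysis over reactions (default: all non-pseudo)."""
    if targets is None:
        targets = [r.id for r in model.reactions.values() if not r.is_pseudo]
    return _fva(model, list(targets), fixed_mu, underground, extra_overrides)


def fva_subpools(
    model: CoralModel,
    targets: Sequence[str] | None = None,
    fixed_mu: float | None = None,
    underground: bool = True,
    extra_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> FVAResult:
    """Variability of enzyme subpool usages (draw pseudoreactions)."""
    if model.form != "coral":
        raise ValidationError("subpool FVA requires a subpool-split model")
    if targets is None:
        targets = [sp.draw_id for sp in model.subpools()]
    return _fva(model, list(targets), fixed_mu, underground, extra_overrides)


def pfba_subpools(
    model: CoralModel,
    fixed_mu: float,
    underground: bool = True,
    extra_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> SolveResult:
    """Parsimonious enzyme allocation at fixed growth.

    Minimises the total subpool draw (equivalently, by pool conservation,
    the total enzyme pool usage) subject to the model constraints and the
    chemostat condition vbio = mu.  The result is the wild-type reference
    allocation for defect simulations.
    """
    if model.form != "coral":
        raise ValidationError("subpool pFBA requires a subpool-split model")
    overrides = scenario_overrides(model, underground=underground, fixed_mu=fixed_mu)
    if extra_overrides:
        overrides.update(extra_overrides)
    objective = {sp.draw_id: 1.0 for sp in model.subpools()}
    res = solve_lp(
        model,
        objective,
        maximize=False,
        bound_overrides=overrides,
        exclude_constraints=underground_exclusions(model, underground),
    )
    if not res.ok:
        raise ValidationError(
            f"growth rate {fixed_mu} is {res.status} on model {model.id!r}"
        )
    return res
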