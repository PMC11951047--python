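"""Synthetic toy GEMs with controlled promiscuity structure, and an
independent dense-LP oracle.

The generator emits small, viable linear-pathway models whose enzymes have
a prescribed promiscuity profile (number of catalysed reactions each),
log-uniform kcat spectra, optional isozyme/complex GPRs and optional
underground bypass reactions — the structural features the subpool
analyses assume — so every analysis can run deterministically from a seed
with no external model files.

:func:`oracle_solve` re-assembles each optimisation problem from the
subpool registry alone, with explicit inequality rows for the capacity
(v <= kcat·E) and kcat-ordering couplings instead of pseudometabolite
wiring, and serves as ground truth for the main solve path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .core import (
    CoralModel,
    EnzymeRecord,
    EnzymeTable,
    Metabolite,
    PoolConfig,
    Reaction,
    StoichModel,
    UndergroundReaction,
    UndergroundReactionSet,
    ValidationError,
)
from .lp import fba, scenario_overrides

__all__ = ["FixtureSpec", "make_fixture", "curated_fixture", "OracleSolution", "oracle_solve",
           "CURATED_FIXTURES"]

_INF = math.inf


# ---------------------------------------------------------------------------
# random fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Recipe for a synthetic pathway model.

    ``promiscuity_profile`` gives the number of catalysed reactions per
    enzyme, e.g. ``[1, 1, 3]`` — the third enzyme gets two side reactions
    on top of its pathway step.  Side reactions are pathway bypasses
    (productive) or demand-drained dead ends, in the given proportion.
    """

    n_steps: int = 4
    promiscuity_profile: Sequence[int] = (1, 2)
    kcat_range: tuple[float, float] = (1e2, 1e5)  # 1/h, log-uniform
    mw_range: tuple[float, float] = (20.0, 60.0)  # g/mmol
    productive_fraction: float = 0.7
    n_underground: int = 0
    and_fraction: float = 0.0
    or_fraction: float = 0.0
    uptake: float = 10.0  # mmol/gDW/h
    pool: PoolConfig = field(default_factory=PoolConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")
        if len(self.promiscuity_profile) > self.n_steps:
            raise ValidationError("more enzymes than pathway steps")
        if any(k < 1 for k in self.promiscuity_profile):
            raise ValidationError("promiscuity profile entries must be >= 1")


def make_fixture(
    spec: FixtureSpec,
) -> tuple[StoichModel, EnzymeTable, UndergroundReactionSet]:
    """Generate a viable toy GEM + enzyme table + underground set.

    Deterministic under the spec seed: two calls with equal specs produce
    identical objects (and byte-identical serializations).
    """
    rng = np.random.default_rng(spec.seed)
    model = StoichModel(id=f"fixture_seed{spec.seed}")
    n = spec.n_steps
    for i in range(n + 1):
        model.add_metabolite(Metabolite(id=f"M{i}", compartment="c"))

    model.add_reaction(
        Reaction(id="EX_M0", stoichiometry={"M0": -1.0},
                 lower_bound=-spec.uptake, upper_bound=0.0)
    )
    for i in range(1, n + 1):
        model.add_reaction(
            Reaction(id=f"R{i}", stoichiometry={f"M{i-1}": -1.0, f"M{i}": 1.0})
        )
    model.add_reaction(
        Reaction(id="BIOMASS", stoichiometry={f"M{n}": -1.0})
    )
    model.objective_id = "BIOMASS"

    table = EnzymeTable()
    lo, hi = math.log(spec.kcat_range[0]), math.log(spec.kcat_range[1])

    def draw_kcats(k: int) -> list[float]:
        vals = np.exp(rng.uniform(lo, hi, size=k))
        return sorted((float(v) for v in vals), reverse=True)

    dead_count = 0
    for idx, n_sub in enumerate(spec.promiscuity_profile):
        step = idx + 1
        enz_id = f"E{idx}"
        gene = f"g{idx}"
        mw = float(rng.uniform(*spec.mw_range))
        kcats = draw_kcats(n_sub)
        rec = EnzymeRecord(enz_id, (gene,), mw)
        # main activity: the pathway step, largest kcat
        rec.kcats[(f"R{step}", "fwd")] = kcats[0]
        main_rxn = model.reactions[f"R{step}"]
        main_rxn.gpr = gene

        for j, kcat in enumerate(kcats[1:], start=2):
            src = f"M{step-1}"
            if rng.random() < spec.productive_fraction:
                tgt = f"M{min(step + 1, n)}"  # bypass rejoining the chain
            else:
                dead_count += 1
                dmet = f"D{dead_count}"
                model.add_metabolite(Metabolite(id=dmet, compartment="c"))
                model.add_reaction(
                    Reaction(id=f"DM_{dmet}", stoichiometry={dmet: -1.0})
                )
                tgt = dmet
            side_id = f"S{idx}_{j}"
            model.add_reaction(
                Reaction(id=side_id, stoichiometry={src: -1.0, tgt: 1.0}, gpr=gene)
            )
            rec.kcats[(side_id, "fwd")] = kcat
        table.add(rec)

        # optional GPR complexity on the pathway step
        u = rng.random()
        if u < spec.and_fraction:
            partner_gene = f"gh{idx}"
            partner = EnzymeRecord(f"H{idx}", (partner_gene,), float(rng.uniform(*spec.mw_range)))
            partner.kcats[(f"R{step}", "fwd")] = kcats[0]
            table.add(partner)
            main_rxn.gpr = f"{gene} and {partner_gene}"
        elif u < spec.and_fraction + spec.or_fraction:
            iso_gene = f"go{idx}"
            iso = EnzymeRecord(f"O{idx}", (iso_gene,), float(rng.uniform(*spec.mw_range)))
            iso.kcats[(f"R{step}", "fwd")] = float(np.exp(rng.uniform(lo, hi)))
            table.add(iso)
            main_rxn.gpr = f"{gene} or {iso_gene}"

    und = UndergroundReactionSet()
    n_enz = len(spec.promiscuity_profile)
    for j in range(spec.n_underground):
        a = int(rng.integers(0, n))
        b = int(rng.integers(a + 1, n + 1))
        host = int(rng.integers(0, n_enz))
        uid = f"U{j+1}"
        gene = f"g{host}"
        und.reactions.append(
            UndergroundReaction(
                reaction_id=uid,
                stoichiometry={f"M{a}": -1.0, f"M{b}": 1.0},
                gpr=gene,
            )
        )
        # low kcat so underground activities rank behind native ones
        rec = table.records[f"E{host}"]
        floor = min(rec.kcats.values())
        rec.kcats[(uid, "fwd")] = floor * float(rng.uniform(0.05, 0.5))

    model.genes = sorted({g for rec in table.records.values() for g in rec.genes})
    model.validate()
    table.validate()
    sol = fba(model)
    if not sol.ok or (sol.mu or 0.0) <= 0:
        raise ValidationError(
            f"fixture spec (seed {spec.seed}) yields no productive biomass route"
        )
    return model, table, und


# ---------------------------------------------------------------------------
# curated motif fixtures
# ---------------------------------------------------------------------------

def _base_chain(mets: Sequence[str], uptake: float = 10.0) -> StoichModel:
    m = StoichModel(id="curated")
    for mid in mets:
        m.add_metabolite(Metabolite(id=mid, compartment="c"))
    m.add_reaction(
        Reaction(id=f"EX_{mets[0]}", stoichiometry={mets[0]: -1.0},
                 lower_bound=-uptake, upper_bound=0.0)
    )
    return m


def _finish(m: StoichModel, biomass_precursor: str, table: EnzymeTable):
    m.add_reaction(Reaction(id="BIOMASS", stoichiometry={biomass_precursor: -1.0}))
    m.objective_id = "BIOMASS"
    m.genes = sorted({g for rec in table.records.values() for g in rec.genes})
    m.validate()
    table.validate()
    return m, table, UndergroundReactionSet()


def _fx_direct_transfer():
    """One promiscuous enzyme whose side reaction is stoichiometrically
    identical to its main (tied kcat): blocking the main is growth-neutral
    and the rank-2 subpool absorbs the pool one-for-one."""
    m = _base_chain(["A", "B"])
    table = EnzymeTable()
    rec = EnzymeRecord("E_dt", ("g_dt",), 40.0)
    m.add_reaction(Reaction(id="Rmain", stoichiometry={"A": -1.0, "B": 1.0}, gpr="g_dt"))
    m.add_reaction(Reaction(id="Rside", stoichiometry={"A": -1.0, "B": 1.0}, gpr="g_dt"))
    rec.kcats[("Rmain", "fwd")] = 3600.0
    rec.kcats[("Rside", "fwd")] = 3600.0  # tied; lexicographic tie-break -> Rmain is rank 1
    table.add(rec)
    return _finish(m, "B", table)


def _fx_deep_rescuer():
    """Rank-2 side is a dead end, rank-3 side reproduces the main product:
    after blocking the main, the pool lands on rank 3 (class 'deeper')."""
    m = _base_chain(["A", "B", "Dd"])
    table = EnzymeTable()
    rec = EnzymeRecord("E_dr", ("g_dr",), 30.0)
    m.add_reaction(Reaction(id="Rmain", stoichiometry={"A": -1.0, "B": 1.0}, gpr="g_dr"))
    m.add_reaction(Reaction(id="Rdead", stoichiometry={"A": -1.0, "Dd": 1.0}, gpr="g_dr"))
    m.add_reaction(Reaction(id="Rresc", stoichiometry={"A": -1.0, "B": 1.0}, gpr="g_dr"))
    m.add_reaction(Reaction(id="DM_Dd", stoichiometry={"Dd": -1.0}))
    rec.kcats[("Rmain", "fwd")] = 7200.0
    rec.kcats[("Rdead", "fwd")] = 3600.0
    rec.kcats[("Rresc", "fwd")] = 1800.0
    table.add(rec)
    return _finish(m, "B", table)


def _fx_redundant_pair():
    """Two promiscuous enzymes on parallel routes, each with a side
    duplicate of its main: blocking both mains leaves growth unchanged."""
    m = _base_chain(["A", "B"])
    table = EnzymeTable()
    for tag in ("x", "y"):
        rec = EnzymeRecord(f"E_{tag}", (f"g_{tag}",), 25.0)
        m.add_reaction(
            Reaction(id=f"Rmain_{tag}", stoichiometry={"A": -1.0, "B": 1.0}, gpr=f"g_{tag}")
        )
        m.add_reaction(
            Reaction(id=f"Rside_{tag}", stoichiometry={"A": -1.0, "B": 1.0}, gpr=f"g_{tag}")
        )
        rec.kcats[(f"Rmain_{tag}", "fwd")] = 3600.0
        rec.kcats[(f"Rside_{tag}", "fwd")] = 3600.0
        table.add(rec)
    return _finish(m, "B", table)


def _fx_essential_pair():
    """Two non-promiscuous enzymes on consecutive essential steps:
    blocking both mains (or either) is lethal."""
    m = _base_chain(["A", "B", "C"])
    table = EnzymeTable()
    r1 = EnzymeRecord("E_a", ("g_a",), 35.0)
    r2 = EnzymeRecord("E_b", ("g_b",), 45.0)
    m.add_reaction(Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0}, gpr="g_a"))
    m.add_reaction(Reaction(id="R2", stoichiometry={"B": -1.0, "C": 1.0}, gpr="g_b"))
    r1.kcats[("R1", "fwd")] = 3600.0
    r2.kcats[("R2", "fwd")] = 3600.0
    table.add(r1)
    table.add(r2)
    return _finish(m, "C", table)


def _fx_and_complex():
    """A two-subunit complex on an essential step (GPR 'g_c1 and g_c2')."""
    m = _base_chain(["A", "B"])
    table = EnzymeTable()
    for g, e, mw in (("g_c1", "E_c1", 30.0), ("g_c2", "E_c2", 50.0)):
        rec = EnzymeRecord(e, (g,), mw)
        rec.kcats[("Rc", "fwd")] = 3600.0
        table.add(rec)
    m.add_reaction(Reaction(id="Rc", stoichiometry={"A": -1.0, "B": 1.0},
                            gpr="g_c1 and g_c2"))
    return _finish(m, "B", table)


def _fx_or_isozyme():
    """Two isozymes on one step (GPR 'g_i1 or g_i2'), different costs."""
    m = _base_chain(["A", "B"])
    table = EnzymeTable()
    for g, e, mw, kcat in (("g_i1", "E_i1", 20.0, 3600.0), ("g_i2", "E_i2", 60.0, 1800.0)):
        rec = EnzymeRecord(e, (g,), mw)
        rec.kcats[("Ri", "fwd")] = kcat
        table.add(rec)
    m.add_reaction(Reaction(id="Ri", stoichiometry={"A": -1.0, "B": 1.0},
                            gpr="g_i1 or g_i2"))
    return _finish(m, "B", table)


def _fx_tied_kcat():
    """Three subpools with kcats (90, 30, 30)/h: the tied pair's ranks are
    fixed by the lexicographic tie-break on reaction id."""
    m = _base_chain(["A", "B"])
    table = EnzymeTable()
    rec = EnzymeRecord("E_t", ("g_t",), 10.0)
    for rid, kcat in (("Rt1", 90.0), ("Rt2", 30.0), ("Rt3", 30.0)):
        m.add_reaction(Reaction(id=rid, stoichiometry={"A": -1.0, "B": 1.0}, gpr="g_t"))
        rec.kcats[(rid, "fwd")] = kcat
    table.add(rec)
    return _finish(m, "B", table)


CURATED_FIXTURES = {
    "direct_transfer": _fx_direct_transfer,
    "deep_rescuer": _fx_deep_rescuer,
    "redundant_pair": _fx_redundant_pair,
    "essential_pair": _fx_essential_pair,
    "and_complex": _fx_and_complex,
    "or_isozyme": _fx_or_isozyme,
    "tied_kcat": _fx_tied_kcat,
}


def curated_fixture(name: str) -> tuple[StoichModel, EnzymeTable, UndergroundReactionSet]:
    """Hand-built motif fixtures exercising each redistribution scenario."""
    try:
        return CURATED_FIXTURES[name]()
    except KeyError:
        raise ValidationError(
            f"unknown curated fixture {name!r}; available: {sorted(CURATED_FIXTURES)}"
        ) from None


# ---------------------------------------------------------------------------
# dense LP oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleSolution:
    status: str
    objective: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    subpool_usage: dict[str, float] = field(default_factory=dict)
    pool_usage: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


_ORACLE_MAX_COLUMNS = 500


def oracle_solve(
    model: CoralModel,
    objective: str | Mapping[str, float] = "fba",
    maximize: bool = True,
    fixed_mu: float | None = None,
    underground: bool = True,
    blocks: Sequence[str] = (),
    band: Mapping[str, tuple[float, float]] | None = None,
    ordering: bool | None = None,
) -> OracleSolution:
    """Ground-truth solve by independent dense assembly.

    Variables are the network reactions (non-pseudo), one usage variable
    per subpool and one per enzyme pool; capacity (v <= kcat·E), ordering,
    pool-conservation and mass-budget couplings are explicit dense rows
    built from the registry, never from pseudometabolite stoichiometry.

    ``objective``: "fba" (growth), "min_subpools" (total usage at fixed
    growth), or a {reaction_or_subpool_id: coefficient} map.  ``blocks``
    are subpool ids forced to zero (their ordering rows are released, as in
    the main path).  ``band`` maps subpool ids to (lb, ub) usage bounds.
    """
    if model.form != "coral":
        raise ValidationError("oracle expects a subpool-split model")
    rxns = [r for r in model.reactions.values() if not r.is_pseudo]
    sps = sorted(model.subpools(), key=lambda s: (s.enzyme_id, s.rank))
    enzymes = sorted(model.registry)
    n_v, n_sp, n_e = len(rxns), len(sps), len(enzymes)
    n_cols = n_v + n_sp + n_e
    if n_cols > _ORACLE_MAX_COLUMNS:
        raise ValidationError(
            f"oracle refuses {n_cols} columns (> {_ORACLE_MAX_COLUMNS}); "
            "it is a ground-truth path for small fixtures only"
        )
    v_idx = {r.id: i for i, r in enumerate(rxns)}
    sp_idx = {sp.subpool_id: n_v + i for i, sp in enumerate(sps)}
    e_idx = {e: n_v + n_sp + i for i, e in enumerate(enzymes)}

    # metabolite balance over network reactions (native + link metabolites)
    balance_mets = [
        mid for mid, met in model.metabolites.items() if met.kind in ("native", "link")
    ]
    m_idx = {mid: i for i, mid in enumerate(balance_mets)}
    A_eq = np.zeros((len(balance_mets) + n_e, n_cols))
    b_eq = np.zeros(A_eq.shape[0])
    for r in rxns:
        j = v_idx[r.id]
        for mid, coef in r.stoichiometry.items():
            if mid in m_idx:
                A_eq[m_idx[mid], j] += coef
    # pool conservation: sum_i E_{s,i} - E_s = 0
    for k, e in enumerate(enzymes):
        row = len(balance_mets) + k
        for sp in model.registry[e]:
            A_eq[row, sp_idx[sp.subpool_id]] = 1.0
        A_eq[row, e_idx[e]] = -1.0

    ub_rows: list[np.ndarray] = []
    ub_rhs: list[float] = []
    # capacity: v_j - kcat * E_{s,i} <= 0
    for sp in sps:
        row = np.zeros(n_cols)
        row[v_idx[sp.reaction_id]] = 1.0
        row[sp_idx[sp.subpool_id]] = -sp.kcat
        ub_rows.append(row)
        ub_rhs.append(0.0)
    # mass budget: sum MW_s * E_s <= E_tot
    row = np.zeros(n_cols)
    for e in enzymes:
        row[e_idx[e]] = model.registry[e][0].mw
    ub_rows.append(row)
    ub_rhs.append(model.pool_config.e_tot)
    # ordering rows, releasing those that touch a blocked subpool
    blocked = set(blocks)
    if not underground:
        # underground-off removes those activities: zero their usages too
        blocked |= {
            sp.subpool_id
            for sp in sps
            if model.reactions[sp.reaction_id].provenance == "underground"
        }
    use_ordering = (model.ordering_mode != "off") if ordering is None else ordering
    if use_ordering:
        mode = model.ordering_mode if model.ordering_mode != "off" else "chain"
        for e in enzymes:
            ordered = sorted(model.registry[e], key=lambda s: s.rank)
            if len(ordered) < 2:
                continue
            if mode in ("chain", "equality"):
                link_pairs = list(zip(ordered, ordered[1:]))
            else:
                link_pairs = [(ordered[0], sp) for sp in ordered[1:]]
            for hi_sp, lo_sp in link_pairs:
                # a blocked higher-ranked draw would force the lower one to
                # zero: release such rows (equality rows on any touch)
                if hi_sp.subpool_id in blocked or (
                    mode == "equality" and lo_sp.subpool_id in blocked
                ):
                    continue
                row = np.zeros(n_cols)
                row[sp_idx[lo_sp.subpool_id]] = lo_sp.kcat
                row[sp_idx[hi_sp.subpool_id]] = -hi_sp.kcat
                if mode == "equality":
                    A_eq = np.vstack([A_eq, row])
                    b_eq = np.append(b_eq, 0.0)
                else:
                    ub_rows.append(row)
                    ub_rhs.append(0.0)

    bounds: list[tuple[float | None, float | None]] = []
    flux_over = scenario_overrides(model, underground=underground, fixed_mu=fixed_mu)
    for r in rxns:
        lb, ub = flux_over.get(r.id, (r.lower_bound, r.upper_bound))
        bounds.append((None if math.isinf(lb) else lb, None if math.isinf(ub) else ub))
    band = band or {}
    for sp in sps:
        if sp.subpool_id in blocked:
            bounds.append((0.0, 0.0))
        elif sp.subpool_id in band:
            lo_b, hi_b = band[sp.subpool_id]
            bounds.append((lo_b, hi_b))
        else:
            bounds.append((0.0, None))
    bounds.extend([(0.0, None)] * n_e)

    c = np.zeros(n_cols)
    if objective == "fba":
        c[v_idx[model.objective_id]] = 1.0
    elif objective == "min_subpools":
        for sp in sps:
            c[sp_idx[sp.subpool_id]] = 1.0
        maximize = False
    else:
        for key, coef in objective.items():
            if key in v_idx:
                c[v_idx[key]] = coef
            elif key in sp_idx:
                c[sp_idx[key]] = coef
            else:
                raise ValidationError(f"oracle objective key {key!r} unknown")
    if maximize:
        c = -c

    res = linprog(
        c,
        A_ub=np.vstack(ub_rows),
        b_ub=np.asarray(ub_rhs),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    status = {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "failed")
    if status != "optimal":
        return OracleSolution(status=status, objective=None)
    x = res.x
    return OracleSolution(
        status="optimal",
        objective=float(-res.fun if maximize else res.fun),
        fluxes={r.id: float(x[v_idx[r.id]]) for r in rxns},
        subpool_usage={sp.subpool_id: float(x[sp_idx[sp.subpool_id]]) for sp in sps},
        pool_usage={e: float(x[e_idx[e]]) for e in enzymes},
    )
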