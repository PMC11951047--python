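"""Conversion of a conventional GEM + enzyme table into a subpool model.

The pipeline mirrors the GECKO family of protein-constrained models and then
refines it so every catalysed reaction owns a dedicated enzyme *subpool*:

1. :func:`split_reversible` — each catalysed reversible reaction becomes an
   irreversible forward/reverse pair (two distinct catalytic activities).
2. :func:`split_complex_gprs` — GPR simplification: OR branches (isozymes)
   become duplicate reactions; AND conjunctions (complexes) become chained
   partial reactions coupled 1:1 through linking pseudometabolites, each
   partial catalysed by a single enzyme.
3. :func:`build_ec_layer` — GECKO-form enzyme integration: one pool
   pseudometabolite per enzyme, consumed at 1/kcat per unit flux, supplied
   from a finite total protein pool at MW g/mmol.
4. :func:`split_subpools` — each enzyme's pool is split into per-reaction
   subpools, ranked by ascending MW/kcat (rank 1 = main reaction, the one
   with the largest kcat).
5. :func:`add_ordering_constraints` — linear rows enforcing
   kcat_{i+1}·E_{s,i+1} <= kcat_i·E_{s,i} along the rank chain, modelling
   prioritisation of enzyme resources by catalytic efficiency.

:func:`restructure` runs all five steps.
"""

from __future__ import annotations

import ast
import math
import warnings
from typing import Iterable

import sympy
from sympy.logic.boolalg import to_dnf

from .core import (
    PROT_POOL_EXCHANGE,
    PROT_POOL_MET,
    CoralModel,
    Direction,
    EnzymeTable,
    LinearConstraint,
    Metabolite,
    PoolConfig,
    Reaction,
    StoichModel,
    Subpool,
    ValidationError,
)

__all__ = [
    "split_reversible",
    "split_complex_gprs",
    "build_ec_layer",
    "split_subpools",
    "add_ordering_constraints",
    "restructure",
]

_INF = math.inf


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _gpr_genes(gpr: str) -> frozenset[str]:
    if not gpr:
        return frozenset()
    from cobra.core.gene import GPR

    return GPR.from_string(gpr).genes


def _is_catalyzed(rxn: Reaction, enz: EnzymeTable) -> bool:
    """True if some enzyme of the table is encoded in the reaction's GPR and
    carries a kcat for this reaction (either direction)."""
    g2e = enz.gene_to_enzyme()
    for g in _gpr_genes(rxn.gpr):
        e = g2e.get(g)
        if e is None:
            continue
        rec = enz.records[e]
        if (rxn.root_id, "fwd") in rec.kcats or (rxn.root_id, "rev") in rec.kcats:
            return True
    return False


# ---------------------------------------------------------------------------
# step 1: direction split
# ---------------------------------------------------------------------------

def split_reversible(model: StoichModel, enz: EnzymeTable) -> StoichModel:
    """Split every catalysed reversible reaction into fwd/rev irreversible
    halves.  The forward half keeps the reaction id; the reverse half gets
    the ``_REV`` suffix with negated stoichiometry.  Uncatalysed reactions
    (exchanges, spontaneous) are left untouched.
    """
    out = model.copy()
    split: dict[str, list[str]] = {}
    for rid in list(out.reactions):
        rxn = out.reactions[rid]
        if not _is_catalyzed(rxn, enz):
            continue
        if rxn.lower_bound >= 0:
            rxn.direction = rxn.direction or "fwd"
            continue
        rev = Reaction(
            id=f"{rid}_REV",
            stoichiometry={m: -c for m, c in rxn.stoichiometry.items()},
            lower_bound=0.0,
            upper_bound=-rxn.lower_bound,
            gpr=rxn.gpr,
            subsystem=rxn.subsystem,
            provenance=rxn.provenance,
            parent_id=rid,
            direction="rev",
        )
        rxn.lower_bound = 0.0
        rxn.direction = "fwd"
        out.add_reaction(rev)
        split[rid] = [rid, rev.id]
    if split:
        out.annotation.setdefault("reversible_split", {}).update(split)
    return out


# ---------------------------------------------------------------------------
# step 2: GPR simplification
# ---------------------------------------------------------------------------

def _gpr_to_dnf_branches(gpr: str) -> list[list[str]]:
    """DNF branches of a GPR as sorted gene-id lists, deterministically
    ordered.  Each branch is one sufficient gene combination (an isozyme or
    a complex)."""
    from cobra.core.gene import GPR

    tree = GPR.from_string(gpr)
    if tree.body is None:
        return []
    genes = sorted(tree.genes)
    sym = {g: sympy.Symbol(f"g{i}") for i, g in enumerate(genes)}
    back = {s: g for g, s in sym.items()}

    def conv(node) -> sympy.Expr:
        if isinstance(node, ast.BoolOp):
            parts = [conv(v) for v in node.values]
            return sympy.And(*parts) if isinstance(node.op, ast.And) else sympy.Or(*parts)
        if isinstance(node, ast.Name):
            return sym[node.id]
        raise ValidationError(f"unsupported GPR construct in {gpr!r}")

    dnf = to_dnf(conv(tree.body))
    terms = list(dnf.args) if isinstance(dnf, sympy.Or) else [dnf]
    branches = []
    for t in terms:
        atoms = list(t.args) if isinstance(t, sympy.And) else [t]
        branches.append(sorted(back[a] for a in atoms))
    branches.sort()
    return branches


def split_complex_gprs(model: StoichModel, enz: EnzymeTable) -> StoichModel:
    """Expand GPRs: one reaction copy per OR branch, and a chain of partial
    reactions (coupled by linking pseudometabolites) per AND complex, so
    each resulting reaction is catalysed by exactly one enzyme.

    Genes without an enzyme record (or without a kcat for the reaction)
    trigger a warning and contribute no protein cost.
    """
    out = model.copy()
    g2e = enz.gene_to_enzyme()
    gpr_split: dict[str, list[str]] = {}

    for rid in list(out.reactions):
        rxn = out.reactions[rid]
        if not rxn.gpr:
            continue
        root = rxn.root_id
        direction: Direction = rxn.direction or "fwd"

        branches = _gpr_to_dnf_branches(rxn.gpr)
        branch_enzymes: list[list[str]] = []
        for genes in branches:
            enzymes: list[str] = []
            for g in genes:
                e = g2e.get(g)
                if e is None:
                    warnings.warn(
                        f"reaction {rid!r}: gene {g!r} has no enzyme record; "
                        "no protein cost assigned for it"
                    )
                    continue
                if (root, direction) not in enz.records[e].kcats:
                    warnings.warn(
                        f"reaction {rid!r}: enzyme {e!r} has no kcat for "
                        f"({root!r}, {direction}); no protein cost assigned"
                    )
                    continue
                if e not in enzymes:
                    enzymes.append(e)
            branch_enzymes.append(enzymes)

        if all(not es for es in branch_enzymes):
            continue  # enzyme-free reaction, leave untouched

        substrates = {m: c for m, c in rxn.stoichiometry.items() if c < 0}
        products = {m: c for m, c in rxn.stoichiometry.items() if c > 0}
        new_ids: list[str] = []
        del out.reactions[rid]

        for k, (genes, enzymes) in enumerate(zip(branches, branch_enzymes), start=1):
            base = rid if k == 1 else f"{rid}_iso{k}"
            branch_gpr = " and ".join(genes)
            if len(enzymes) <= 1:
                r = rxn.copy()
                r.id = base
                r.gpr = branch_gpr
                r.catalyst = enzymes[0] if enzymes else None
                r.parent_id = root if base != root else rxn.parent_id
                r.direction = direction
                if k > 1:
                    r.provenance = "iso" if rxn.provenance == "native" else rxn.provenance
                out.add_reaction(r)
                new_ids.append(base)
            else:
                # chain of partial reactions, 1:1 linking metabolites
                m = len(enzymes)
                links = []
                for p in range(1, m):
                    lm = Metabolite(
                        id=f"pmet_link_{base}_{p}", compartment="pseudo", kind="link"
                    )
                    out.add_metabolite(lm)
                    links.append(lm.id)
                for p, e in enumerate(enzymes, start=1):
                    stoich: dict[str, float] = {}
                    if p == 1:
                        stoich.update(substrates)
                    else:
                        stoich[links[p - 2]] = -1.0
                    if p == m:
                        stoich.update(products)
                    else:
                        stoich[links[p - 1]] = 1.0
                    r = Reaction(
                        id=f"{base}_part{p}",
                        stoichiometry=stoich,
                        lower_bound=rxn.lower_bound,
                        upper_bound=rxn.upper_bound,
                        gpr=branch_gpr,
                        subsystem=rxn.subsystem,
                        provenance="partial" if rxn.provenance == "native" else rxn.provenance,
                        catalyst=e,
                        parent_id=root,
                        direction=direction,
                    )
                    out.add_reaction(r)
                    new_ids.append(r.id)
        gpr_split[rid] = new_ids
        if out.objective_id == rid:
            out.objective_id = new_ids[0]

    if gpr_split:
        out.annotation.setdefault("gpr_split", {}).update(gpr_split)
    return out


# ---------------------------------------------------------------------------
# step 3: GECKO-form enzyme integration
# ---------------------------------------------------------------------------

def _infer_catalyst(rxn: Reaction, enz: EnzymeTable) -> str | None:
    if rxn.catalyst is not None:
        return rxn.catalyst
    direction: Direction = rxn.direction or "fwd"
    g2e = enz.gene_to_enzyme()
    candidates: list[str] = []
    for g in sorted(_gpr_genes(rxn.gpr)):
        e = g2e.get(g)
        if e is None or (rxn.root_id, direction) not in enz.records[e].kcats:
            continue
        if e not in candidates:
            candidates.append(e)
    if len(candidates) > 1:
        raise ValidationError(
            f"reaction {rxn.id!r} is catalysed by several enzymes "
            f"{candidates}; run split_complex_gprs first"
        )
    return candidates[0] if candidates else None


def build_ec_layer(
    model: StoichModel, enz: EnzymeTable, pool: PoolConfig | None = None
) -> CoralModel:
    """GECKO-form protein-constrained model: shared pool per enzyme.

    Each catalysed reaction consumes its enzyme's pool pseudometabolite at
    1/kcat mmol enzyme per unit flux; each enzyme pool is supplied from the
    total protein pool at MW g/mmol; the total pool exchange is bounded by
    E_tot = Ptot·f·σ.  The registry is populated with ranked subpool entries
    (wired to pseudoreactions only after :func:`split_subpools`).
    """
    pool = pool or PoolConfig()
    enz.validate()
    ec = CoralModel(
        id=model.id,
        pool_config=pool,
        form="gecko",
        objective_id=model.objective_id,
        annotation=dict(model.annotation),
    )
    ec.genes = list(model.genes)
    for met in model.metabolites.values():
        ec.add_metabolite(Metabolite(**met.__dict__))
    for rxn in model.reactions.values():
        ec.add_reaction(rxn.copy())

    # catalyst resolution + reversibility guard
    catalyzed: list[tuple[Reaction, str, float]] = []
    for rxn in ec.reactions.values():
        if rxn.is_pseudo:
            continue
        e = _infer_catalyst(rxn, enz)
        if e is None:
            continue
        if rxn.lower_bound < 0:
            raise ValidationError(
                f"catalysed reaction {rxn.id!r} is reversible; "
                "run split_reversible first"
            )
        direction: Direction = rxn.direction or "fwd"
        rxn.catalyst = e
        rxn.direction = direction
        kcat = enz.records[e].kcats[(rxn.root_id, direction)]
        catalyzed.append((rxn, e, kcat))

    ec.add_metabolite(
        Metabolite(id=PROT_POOL_MET, name="total protein pool", compartment="pseudo",
                   kind="total_pool")
    )
    ec.add_reaction(
        Reaction(
            id=PROT_POOL_EXCHANGE,
            stoichiometry={PROT_POOL_MET: 1.0},
            lower_bound=0.0,
            upper_bound=pool.e_tot,
            provenance="pool_exchange",
        )
    )

    enzymes_used = sorted({e for _, e, _ in catalyzed})
    for e in enzymes_used:
        mw = enz.records[e].mw
        ec.add_metabolite(
            Metabolite(id=ec.pool_met_id(e), name=f"enzyme pool {e}",
                       compartment="pseudo", kind="pool")
        )
        ec.add_reaction(
            Reaction(
                id=ec.supply_id(e),
                stoichiometry={PROT_POOL_MET: -mw, ec.pool_met_id(e): 1.0},
                lower_bound=0.0,
                upper_bound=_INF,
                provenance="supply",
                catalyst=e,
            )
        )
        ec.add_reaction(
            Reaction(
                id=f"sink_prot_{e}",
                stoichiometry={ec.pool_met_id(e): -1.0},
                lower_bound=0.0,
                upper_bound=_INF,
                provenance="sink",
                catalyst=e,
            )
        )

    # wire catalysis and build the ranked registry
    per_enzyme: dict[str, list[tuple[Reaction, float]]] = {e: [] for e in enzymes_used}
    for rxn, e, kcat in catalyzed:
        rxn.stoichiometry[ec.pool_met_id(e)] = (
            rxn.stoichiometry.get(ec.pool_met_id(e), 0.0) - 1.0 / kcat
        )
        per_enzyme[e].append((rxn, kcat))
    for e, entries in per_enzyme.items():
        mw = enz.records[e].mw
        # ascending MW/kcat; ties broken lexicographically on reaction id
        entries.sort(key=lambda rk: (mw / rk[1], rk[0].id))
        ec.registry[e] = [
            Subpool(
                subpool_id=f"{e}_{rank}",
                enzyme_id=e,
                reaction_id=rxn.id,
                source_reaction_id=rxn.root_id,
                direction=rxn.direction or "fwd",
                kcat=kcat,
                mw=mw,
                rank=rank,
            )
            for rank, (rxn, kcat) in enumerate(entries, start=1)
        ]
    ec.validate()
    return ec


# ---------------------------------------------------------------------------
# step 4: subpool split
# ---------------------------------------------------------------------------

def split_subpools(ec: CoralModel) -> CoralModel:
    """Split each enzyme's pool into one subpool per catalysed reaction.

    The enzyme-level idle sink is replaced by per-subpool draw and sink
    pseudoreactions, so that in every feasible solution the subpool draws
    of an enzyme sum exactly to its pool supply, and each reaction's flux
    is capped at kcat times its own subpool draw.
    """
    if ec.form != "gecko":
        raise ValidationError(f"expected a GECKO-form model, got form={ec.form!r}")
    out = ec.copy()
    out.form = "coral"
    for e, pools in out.registry.items():
        pool_met = out.pool_met_id(e)
        del out.reactions[f"sink_prot_{e}"]
        for sp in sorted(pools, key=lambda s: s.rank):
            sp.met_id = f"pmet_subpool_{e}_{sp.rank}"
            sp.draw_id = f"draw_{e}_{sp.rank}"
            sp.sink_id = f"sink_{e}_{sp.rank}"
            out.add_metabolite(
                Metabolite(id=sp.met_id, name=f"subpool {sp.rank} of {e}",
                           compartment="pseudo", kind="subpool")
            )
            out.add_reaction(
                Reaction(
                    id=sp.draw_id,
                    stoichiometry={pool_met: -1.0, sp.met_id: 1.0},
                    lower_bound=0.0,
                    upper_bound=_INF,
                    provenance="draw",
                    catalyst=e,
                )
            )
            out.add_reaction(
                Reaction(
                    id=sp.sink_id,
                    stoichiometry={sp.met_id: -1.0},
                    lower_bound=0.0,
                    upper_bound=_INF,
                    provenance="sink",
                    catalyst=e,
                )
            )
            rxn = out.reactions[sp.reaction_id]
            del rxn.stoichiometry[pool_met]
            rxn.stoichiometry[sp.met_id] = -1.0 / sp.kcat
    out.validate()
    return out


# ---------------------------------------------------------------------------
# step 5: kcat-ordering constraints
# ---------------------------------------------------------------------------

def add_ordering_constraints(model: CoralModel, mode: str = "chain") -> CoralModel:
    """Add enzyme-efficiency prioritisation rows over subpool draws.

    ``chain``    — kcat_{i+1}·E_{s,i+1} <= kcat_i·E_{s,i} for consecutive
                   ranks (transitively bounds every side subpool's maximal
                   velocity by the main one's);
    ``vs-main``  — every side subpool compared to rank 1 directly;
    ``equality`` — maximal velocities forced equal along the chain;
    ``off``      — no rows.
    """
    if mode not in ("off", "chain", "vs-main", "equality"):
        raise ValidationError(f"unknown ordering mode {mode!r}")
    out = model.copy()
    out.constraints = [c for c in out.constraints if not c.name.startswith("order_")]
    out.ordering_mode = mode
    if mode == "off":
        return out
    for e, pools in out.registry.items():
        ordered = sorted(pools, key=lambda s: s.rank)
        if len(ordered) < 2:
            continue
        if mode in ("chain", "equality"):
            pairs = list(zip(ordered, ordered[1:]))
        else:  # vs-main
            pairs = [(ordered[0], sp) for sp in ordered[1:]]
        for hi, lo in pairs:
            out.constraints.append(
                LinearConstraint(
                    name=f"order_{e}_{hi.rank}_{lo.rank}",
                    coefficients={lo.draw_id: lo.kcat, hi.draw_id: -hi.kcat},
                    sense="==" if mode == "equality" else "<=",
                    rhs=0.0,
                )
            )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def restructure(
    model: StoichModel,
    enz: EnzymeTable,
    pool: PoolConfig | None = None,
    ordering: str = "chain",
) -> CoralModel:
    """Run the full restructuring pipeline on a conventional GEM."""
    model.validate()
    enz.validate()
    m = split_reversible(model, enz)
    m = split_complex_gprs(m, enz)
    ec = build_ec_layer(m, enz, pool)
    coral = split_subpools(ec)
    coral = add_ordering_constraints(coral, ordering)
    coral.split_map = {
        **{k: list(v) for k, v in coral.annotation.get("reversible_split", {}).items()},
        **{k: list(v) for k, v in coral.annotation.get("gpr_split", {}).items()},
    }
    return coral
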