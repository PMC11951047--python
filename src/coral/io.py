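"""Readers and writers: GEMs (SBML/JSON via COBRApy), enzyme and underground
reaction tables (TSV), and the YAML serialization of restructured models.

Also hosts the model-curation steps that precede restructuring: merging
underground reactions into a host GEM and screening the stoichiometric
matrix for (near-)duplicate reaction columns by cosine similarity.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml
from scipy import sparse

from .core import (
    DEFAULT_BOUND,
    CoralModel,
    Direction,
    EnzymeRecord,
    EnzymeTable,
    LinearConstraint,
    Metabolite,
    PoolConfig,
    Reaction,
    StoichModel,
    Subpool,
    UndergroundReaction,
    UndergroundReactionSet,
    ValidationError,
    build_s_matrix,
)

__all__ = [
    "read_gem",
    "write_gem",
    "read_enzyme_table",
    "write_enzyme_table",
    "read_underground_table",
    "write_underground_table",
    "merge_underground",
    "find_duplicate_reactions",
    "remove_duplicate_reactions",
    "write_coral_model",
    "read_coral_model",
    "standardize_gpr",
    "DuplicatePair",
]


def standardize_gpr(gpr: str) -> str:
    """Normalise a GPR boolean expression to COBRApy's canonical dialect."""
    gpr = (gpr or "").strip()
    if not gpr:
        return ""
    from cobra.core.gene import GPR

    return GPR.from_string(gpr).to_string()


# ---------------------------------------------------------------------------
# conventional GEMs
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f not in ("sbml", "json"):
            raise ValidationError(f"unknown GEM format {fmt!r} (expected SBML or JSON)")
        return f
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ValidationError(f"cannot infer GEM format from path {path!s}")


def read_gem(path: str | Path, fmt: str | None = None) -> StoichModel:
    """Read a conventional GEM from SBML (level 3, FBC) or BiGG-style JSON."""
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    f = _infer_format(path, fmt)
    try:
        if f == "sbml":
            cm = cobra.io.read_sbml_model(str(path))
        else:
            cm = cobra.io.load_json_model(str(path))
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise ValidationError(f"failed to parse GEM {path.name!r}: {exc}") from exc
    return from_cobra(cm)


def from_cobra(cm) -> StoichModel:
    """Convert a :class:`cobra.Model` into a :class:`StoichModel`."""
    from cobra.util.solver import linear_reaction_coefficients

    model = StoichModel(id=cm.id or "model")
    for met in cm.metabolites:
        model.add_metabolite(
            Metabolite(id=met.id, name=met.name or "", compartment=met.compartment or "")
        )
    for rxn in cm.reactions:
        model.add_reaction(
            Reaction(
                id=rxn.id,
                stoichiometry={m.id: float(c) for m, c in rxn.metabolites.items()},
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                gpr=rxn.gene_reaction_rule or "",
                subsystem=rxn.subsystem or "",
            )
        )
    model.genes = sorted(g.id for g in cm.genes)
    coeffs = linear_reaction_coefficients(cm)
    if not coeffs:
        raise ValidationError(f"model {cm.id!r} designates no objective reaction")
    model.objective_id = next(iter(coeffs)).id
    model.validate()
    return model


def to_cobra(model: StoichModel):
    """Convert a :class:`StoichModel` into a :class:`cobra.Model`."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for met in model.metabolites.values():
        m = cobra.Metabolite(met.id, name=met.name, compartment=met.compartment or "c")
        mets[met.id] = m
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for rxn in model.reactions.values():
        r = cobra.Reaction(rxn.id, subsystem=rxn.subsystem)
        r.lower_bound = rxn.lower_bound
        r.upper_bound = rxn.upper_bound
        rxns.append((r, rxn))
    cm.add_reactions([r for r, _ in rxns])
    for r, rxn in rxns:
        r.add_metabolites({mets[mid]: c for mid, c in rxn.stoichiometry.items()})
        if rxn.gpr:
            r.gene_reaction_rule = rxn.gpr
    if model.objective_id is not None:
        cm.objective = model.objective_id
    return cm


def write_gem(model: StoichModel, path: str | Path, fmt: str | None = None) -> None:
    import cobra.io

    path = Path(path)
    f = _infer_format(path, fmt)
    cm = to_cobra(model)
    if f == "sbml":
        cobra.io.write_sbml_model(cm, str(path))
    else:
        cobra.io.save_json_model(cm, str(path), sort=True)


# ---------------------------------------------------------------------------
# enzyme tables
# ---------------------------------------------------------------------------

_ENZ_COLUMNS = ["enzyme", "genes", "MW_g_per_mmol", "reaction", "direction", "kcat_per_h"]


def read_enzyme_table(path: str | Path) -> EnzymeTable:
    """Read a TSV of per-(enzyme, reaction, direction) kcats.

    Columns: enzyme, genes (semicolon-separated), MW_g_per_mmol, reaction,
    direction (fwd|rev), and either kcat_per_h or kcat_per_s (converted to
    1/h on read).
    """
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    kcol = None
    scale = 1.0
    if "kcat_per_h" in df.columns:
        kcol = "kcat_per_h"
    elif "kcat_per_s" in df.columns:
        kcol, scale = "kcat_per_s", 3600.0
    required = {"enzyme", "genes", "MW_g_per_mmol", "reaction", "direction"}
    missing = required - set(df.columns)
    if missing or kcol is None:
        raise ValidationError(
            f"enzyme table {path.name!r} missing columns: "
            f"{sorted(missing) + ([] if kcol else ['kcat_per_h'])}"
        )
    table = EnzymeTable()
    for _, row in df.iterrows():
        eid = str(row["enzyme"])
        rec = table.records.get(eid)
        if rec is None:
            genes = tuple(g for g in str(row["genes"]).split(";") if g)
            rec = EnzymeRecord(eid, genes, float(row["MW_g_per_mmol"]))
            table.records[eid] = rec
        key = (str(row["reaction"]), str(row["direction"]))
        if key in rec.kcats:
            raise ValidationError(
                f"enzyme {eid!r}: duplicate kcat entry for reaction "
                f"{key[0]!r} direction {key[1]!r}"
            )
        rec.kcats[key] = float(row[kcol]) * scale
    table.validate()
    return table


def write_enzyme_table(table: EnzymeTable, path: str | Path) -> None:
    import pandas as pd

    rows = []
    for rec in table.records.values():
        for (rid, direction), kcat in rec.kcats.items():
            rows.append(
                {
                    "enzyme": rec.enzyme_id,
                    "genes": ";".join(rec.genes),
                    "MW_g_per_mmol": rec.mw,
                    "reaction": rid,
                    "direction": direction,
                    "kcat_per_h": kcat,
                }
            )
    pd.DataFrame(rows, columns=_ENZ_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# underground reaction tables
# ---------------------------------------------------------------------------

def _parse_stoich(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for item in str(text).split(";"):
        item = item.strip()
        if not item:
            continue
        mid, _, coef = item.rpartition(":")
        if not mid:
            raise ValidationError(f"malformed stoichiometry item {item!r}")
        out[mid] = float(coef)
    return out


def _format_stoich(stoich: dict[str, float]) -> str:
    return ";".join(f"{mid}:{coef:g}" for mid, coef in sorted(stoich.items()))


def read_underground_table(path: str | Path) -> UndergroundReactionSet:
    """TSV columns: reaction, stoichiometry (met:coef;met:coef), gpr, reversible."""
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"reaction", "stoichiometry"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"underground table {path.name!r} missing columns: {sorted(missing)}"
        )
    uset = UndergroundReactionSet()
    for _, row in df.iterrows():
        uset.reactions.append(
            UndergroundReaction(
                reaction_id=str(row["reaction"]),
                stoichiometry=_parse_stoich(row["stoichiometry"]),
                gpr=str(row.get("gpr", "")),
                reversible=str(row.get("reversible", "0")) in ("1", "True", "true"),
            )
        )
    return uset


def write_underground_table(uset: UndergroundReactionSet, path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "reaction": r.reaction_id,
            "stoichiometry": _format_stoich(r.stoichiometry),
            "gpr": r.gpr,
            "reversible": int(r.reversible),
        }
        for r in uset.reactions
    ]
    pd.DataFrame(rows, columns=["reaction", "stoichiometry", "gpr", "reversible"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# underground merge & duplicate screen
# ---------------------------------------------------------------------------

def merge_underground(
    model: StoichModel, und: UndergroundReactionSet
) -> StoichModel:
    """Merge underground reactions into a host GEM.

    Metabolites are resolved by exact id first, then through the set's
    explicit cross-reference mapping; anything else fails loudly with the
    full list of unmatched ids.  Merged reactions are tagged
    ``provenance="underground"`` and their GPRs normalised to the host
    dialect; new genes extend the host gene list.
    """
    merged = model.copy()
    unmatched: list[str] = []
    resolved_rxns: list[Reaction] = []
    for ur in und.reactions:
        if ur.reaction_id in merged.reactions:
            raise ValidationError(
                f"underground reaction id {ur.reaction_id!r} collides with host model"
            )
        stoich: dict[str, float] = {}
        for mid, coef in ur.stoichiometry.items():
            if mid in merged.metabolites:
                stoich[mid] = stoich.get(mid, 0.0) + coef
            elif mid in und.metabolite_mapping:
                host = und.metabolite_mapping[mid]
                if host not in merged.metabolites:
                    unmatched.append(f"{mid} -> {host}")
                else:
                    stoich[host] = stoich.get(host, 0.0) + coef
            else:
                unmatched.append(mid)
        resolved_rxns.append(
            Reaction(
                id=ur.reaction_id,
                stoichiometry=stoich,
                lower_bound=-DEFAULT_BOUND if ur.reversible else 0.0,
                upper_bound=DEFAULT_BOUND,
                gpr=standardize_gpr(ur.gpr),
                provenance="underground",
            )
        )
    if unmatched:
        raise ValidationError(
            "underground metabolites not resolvable to host namespace: "
            + ", ".join(sorted(set(unmatched)))
        )
    new_genes = set()
    for rxn in resolved_rxns:
        merged.add_reaction(rxn)
        if rxn.gpr:
            from cobra.core.gene import GPR

            new_genes.update(GPR.from_string(rxn.gpr).genes)
    merged.genes = sorted(set(merged.genes) | new_genes)
    return merged


class DuplicatePair(NamedTuple):
    reaction_a: str
    reaction_b: str
    similarity: float


def find_duplicate_reactions(
    model: StoichModel, threshold: float = 0.90
) -> list[DuplicatePair]:
    """Pairs of reactions whose stoichiometric columns have cosine similarity
    >= ``threshold``.  All-zero columns are skipped with a warning (cosine
    undefined).  Symmetric; self-pairs excluded; pairs sorted by id.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    S, _, rxn_index = build_s_matrix(model)
    ids = list(rxn_index)
    Sc = sparse.csc_matrix(S)
    norms = np.sqrt(np.asarray(Sc.multiply(Sc).sum(axis=0)).ravel())
    zero = norms == 0
    for rid, z in zip(ids, zero):
        if z:
            warnings.warn(
                f"reaction {rid!r} has an all-zero stoichiometric column; "
                "skipped in duplicate screen"
            )
    inv = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, norms))
    Sn = Sc.multiply(sparse.csr_matrix(inv)).tocsc()
    G = (Sn.T @ Sn).toarray()
    pairs: list[DuplicatePair] = []
    n = len(ids)
    for i in range(n):
        if zero[i]:
            continue
        for j in range(i + 1, n):
            if zero[j]:
                continue
            sim = float(G[i, j])
            if sim >= threshold - 1e-12:
                a, b = sorted((ids[i], ids[j]))
                pairs.append(DuplicatePair(a, b, sim))
    pairs.sort()
    return pairs


def remove_duplicate_reactions(
    model: StoichModel, threshold: float = 0.90
) -> tuple[StoichModel, list[DuplicatePair]]:
    """Drop the second member of every duplicate pair (never the objective)."""
    pairs = find_duplicate_reactions(model, threshold)
    out = model.copy()
    for pair in pairs:
        drop = pair.reaction_b
        if drop == out.objective_id:
            drop = pair.reaction_a
        out.reactions.pop(drop, None)
    return out, pairs


# ---------------------------------------------------------------------------
# CoralModel YAML dialect
# ---------------------------------------------------------------------------

_YAML_VERSION = 1


def _num(x: float) -> float:
    """YAML-safe number (inf round-trips as .inf)."""
    return float(x)


def write_coral_model(model: CoralModel, path: str | Path) -> None:
    """Serialize a restructured model, its subpool registry and pool wiring
    to a deterministic YAML document (byte-identical across reruns)."""
    doc = {
        "coral_model_version": _YAML_VERSION,
        "id": model.id,
        "form": model.form,
        "ordering_mode": model.ordering_mode,
        "pool_config": {
            "ptot": model.pool_config.ptot,
            "sigma": model.pool_config.sigma,
            "f": model.pool_config.f,
        },
        "objective": model.objective_id,
        "genes": list(model.genes),
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment, "kind": m.kind}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: _num(v) for k, v in r.stoichiometry.items()},
                "lower_bound": _num(r.lower_bound),
                "upper_bound": _num(r.upper_bound),
                "gpr": r.gpr,
                "subsystem": r.subsystem,
                "provenance": r.provenance,
                "catalyst": r.catalyst,
                "parent_id": r.parent_id,
                "direction": r.direction,
            }
            for r in model.reactions.values()
        ],
        "registry": {
            enz: [
                {
                    "subpool_id": sp.subpool_id,
                    "reaction_id": sp.reaction_id,
                    "source_reaction_id": sp.source_reaction_id,
                    "direction": sp.direction,
                    "kcat": _num(sp.kcat),
                    "mw": _num(sp.mw),
                    "rank": sp.rank,
                    "met_id": sp.met_id,
                    "draw_id": sp.draw_id,
                    "sink_id": sp.sink_id,
                }
                for sp in sorted(pools, key=lambda s: s.rank)
            ]
            for enz, pools in model.registry.items()
        },
        "constraints": [
            {
                "name": c.name,
                "coefficients": {k: _num(v) for k, v in c.coefficients.items()},
                "sense": c.sense,
                "rhs": _num(c.rhs),
            }
            for c in model.constraints
        ],
        "split_map": {k: list(v) for k, v in model.split_map.items()},
        "annotation": model.annotation,
    }
    text = yaml.safe_dump(doc, sort_keys=False, default_flow_style=False, width=100)
    Path(path).write_text(text)


def read_coral_model(path: str | Path) -> CoralModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "coral_model_version" not in doc:
        raise ValidationError(f"{path.name!r} is not a CORAL model YAML document")
    model = CoralModel(
        id=doc.get("id", "model"),
        form=doc.get("form", "coral"),
        ordering_mode=doc.get("ordering_mode", "off"),
        pool_config=PoolConfig(**doc["pool_config"]),
        objective_id=doc.get("objective"),
        annotation=doc.get("annotation", {}) or {},
    )
    for m in doc.get("metabolites", []):
        model.add_metabolite(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", ""),
                kind=m.get("kind", "native"),
            )
        )
    for r in doc.get("reactions", []):
        model.add_reaction(
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in (r.get("stoichiometry") or {}).items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gpr=r.get("gpr", "") or "",
                subsystem=r.get("subsystem", "") or "",
                provenance=r.get("provenance", "native"),
                catalyst=r.get("catalyst"),
                parent_id=r.get("parent_id"),
                direction=r.get("direction"),
            )
        )
    model.genes = list(doc.get("genes", []))
    for enz, pools in (doc.get("registry") or {}).items():
        model.registry[enz] = [
            Subpool(
                subpool_id=sp["subpool_id"],
                enzyme_id=enz,
                reaction_id=sp["reaction_id"],
                source_reaction_id=sp["source_reaction_id"],
                direction=sp["direction"],
                kcat=float(sp["kcat"]),
                mw=float(sp["mw"]),
                rank=int(sp["rank"]),
                met_id=sp.get("met_id", ""),
                draw_id=sp.get("draw_id", ""),
                sink_id=sp.get("sink_id", ""),
            )
            for sp in pools
        ]
    model.constraints = [
        LinearConstraint(
            name=c["name"],
            coefficients={k: float(v) for k, v in c["coefficients"].items()},
            sense=c["sense"],
            rhs=float(c.get("rhs", 0.0)),
        )
        for c in doc.get("constraints", [])
    ]
    model.split_map = {k: list(v) for k, v in (doc.get("split_map") or {}).items()}
    model.validate()
    return model
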