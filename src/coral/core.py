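"""Core domain types for subpool-restructured, protein-constrained GEMs.

A conventional genome-scale metabolic model (GEM) is held as a
:class:`StoichModel`.  Enzyme kinetic data (molecular weights and turnover
numbers per catalysed reaction and direction) live in an
:class:`EnzymeTable`.  Restructuring produces a :class:`CoralModel`: the
stoichiometric network augmented with pseudometabolites and pseudoreactions
that wire every catalysed reaction to its own enzyme *subpool*, each subpool
drawing on its enzyme's pool and every pool drawing on a finite total
protein pool.

Sign convention: consumption negative, production positive.  Fluxes are in
mmol/gDW/h, enzyme usages in mmol/gDW, the protein pool in g/gDW, kcat in
1/h and MW in g/mmol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
from scipy import sparse

__all__ = [
    "ValidationError",
    "Metabolite",
    "Reaction",
    "StoichModel",
    "EnzymeRecord",
    "EnzymeTable",
    "UndergroundReaction",
    "UndergroundReactionSet",
    "PoolConfig",
    "Subpool",
    "LinearConstraint",
    "CoralModel",
    "build_s_matrix",
    "PROT_POOL_MET",
    "PROT_POOL_EXCHANGE",
]

#: id of the total protein pool pseudometabolite (g protein/gDW)
PROT_POOL_MET = "prot_pool"
#: id of the exchange pseudoreaction supplying the total protein pool
PROT_POOL_EXCHANGE = "prot_pool_exchange"

#: default "effectively unbounded" flux bound, BiGG convention
DEFAULT_BOUND = 1000.0

Direction = Literal["fwd", "rev"]


class ValidationError(ValueError):
    """A model, table or file violated a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    #: native | link | subpool | pool | total_pool
    kind: str = "native"

    @property
    def is_pseudo(self) -> bool:
        return self.kind != "native"


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: str = ""
    #: native | underground | partial | iso | draw | supply | sink | pool_exchange
    provenance: str = "native"
    #: enzyme catalysing this reaction (set during restructuring)
    catalyst: str | None = None
    #: id of the reaction this one was derived from (direction/GPR splits)
    parent_id: str | None = None
    #: catalytic direction relative to the parent reaction
    direction: Direction | None = None

    @property
    def is_pseudo(self) -> bool:
        return self.provenance in ("draw", "supply", "sink", "pool_exchange")

    @property
    def root_id(self) -> str:
        """Id of the original model reaction this one descends from."""
        return self.parent_id if self.parent_id is not None else self.id

    def copy(self) -> "Reaction":
        r = Reaction(**{k: v for k, v in self.__dict__.items() if k != "stoichiometry"})
        r.stoichiometry = dict(self.stoichiometry)
        return r


@dataclass
class StoichModel:
    """A conventional GEM: stoichiometry, bounds, GPRs and one objective."""

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)
    objective_id: str | None = None
    annotation: dict = field(default_factory=dict)
    id: str = "model"

    # -- construction helpers -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValidationError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise ValidationError(
                    f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                )
        self.reactions[rxn.id] = rxn
        return rxn

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                raise ValidationError(
                    f"reaction {rxn.id!r} has lower bound {rxn.lower_bound} "
                    f"> upper bound {rxn.upper_bound}"
                )
        if self.objective_id is None:
            raise ValidationError("model designates no objective reaction")
        if self.objective_id not in self.reactions:
            raise ValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )

    def copy(self) -> "StoichModel":
        m = type(self).__new__(type(self))
        m.__dict__.update(self.__dict__)
        m.metabolites = {k: Metabolite(**v.__dict__) for k, v in self.metabolites.items()}
        m.reactions = {k: v.copy() for k, v in self.reactions.items()}
        m.genes = list(self.genes)
        m.annotation = dict(self.annotation)
        return m


@dataclass
class EnzymeRecord:
    enzyme_id: str
    genes: tuple[str, ...]
    mw: float  # g/mmol
    #: (reaction_id, direction) -> kcat in 1/h
    kcats: dict[tuple[str, Direction], float] = field(default_factory=dict)


@dataclass
class EnzymeTable:
    """Per-enzyme molecular weight, gene association and per-reaction kcats."""

    records: dict[str, EnzymeRecord] = field(default_factory=dict)

    def add(self, rec: EnzymeRecord) -> None:
        if rec.enzyme_id in self.records:
            raise ValidationError(f"duplicate enzyme id {rec.enzyme_id!r}")
        self.records[rec.enzyme_id] = rec

    def validate(self) -> None:
        for rec in self.records.values():
            if not rec.mw > 0:
                raise ValidationError(f"enzyme {rec.enzyme_id!r}: MW must be > 0")
            for (rid, direction), kcat in rec.kcats.items():
                if direction not in ("fwd", "rev"):
                    raise ValidationError(
                        f"enzyme {rec.enzyme_id!r}, reaction {rid!r}: "
                        f"direction {direction!r} not in {{fwd, rev}}"
                    )
                if not kcat > 0:
                    raise ValidationError(
                        f"enzyme {rec.enzyme_id!r}, reaction {rid!r} ({direction}): "
                        "kcat must be > 0"
                    )

    def gene_to_enzyme(self) -> dict[str, str]:
        """Map each gene to the enzyme it encodes (first record wins)."""
        out: dict[str, str] = {}
        for rec in self.records.values():
            for g in rec.genes:
                out.setdefault(g, rec.enzyme_id)
        return out

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class UndergroundReaction:
    reaction_id: str
    stoichiometry: dict[str, float]
    gpr: str = ""
    reversible: bool = False
    provenance: str = "underground"


@dataclass
class UndergroundReactionSet:
    reactions: list[UndergroundReaction] = field(default_factory=list)
    #: optional mapping from foreign metabolite ids to host-model ids
    metabolite_mapping: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reactions)


@dataclass
class PoolConfig:
    """Total protein pool parameters: E_tot = Ptot * f * sigma (g/gDW)."""

    ptot: float = 0.61  # g protein / gDW
    sigma: float = 0.5  # average saturation
    f: float = 0.5      # mass fraction of enzymes covered by the model

    def __post_init__(self) -> None:
        for name in ("ptot", "sigma", "f"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"PoolConfig.{name} must be > 0")

    @property
    def e_tot(self) -> float:
        return self.ptot * self.sigma * self.f


@dataclass
class Subpool:
    """One enzyme's resource share dedicated to one catalysed reaction.

    Rank 1 (lowest MW/kcat, i.e. largest kcat at fixed MW) is the enzyme's
    *main* reaction; higher ranks are side reactions.
    """

    subpool_id: str
    enzyme_id: str
    reaction_id: str            # model reaction served (post-split id)
    source_reaction_id: str     # original reaction id in the input GEM
    direction: Direction
    kcat: float                 # 1/h
    mw: float                   # g/mmol
    rank: int                   # 1 = main
    met_id: str = ""            # subpool pseudometabolite
    draw_id: str = ""           # pool -> subpool draw pseudoreaction
    sink_id: str = ""           # idle-capacity sink pseudoreaction

    @property
    def ratio(self) -> float:
        """Pseudo-stoichiometric cost MW/kcat (g·h/mmol) — the rank key."""
        return self.mw / self.kcat

    @property
    def is_main(self) -> bool:
        return self.rank == 1


@dataclass
class LinearConstraint:
    """An extra linear row over reaction fluxes: sum(coef*v) sense rhs."""

    name: str
    coefficients: dict[str, float]
    sense: Literal["<=", "=="]
    rhs: float = 0.0


@dataclass
class CoralModel(StoichModel):
    """A protein-constrained GEM with per-reaction enzyme subpools.

    ``registry`` is the ``.und``-style structure: for every enzyme, its
    ordered subpools with kcat, MW and pseudoreaction wiring.  ``form`` is
    ``"gecko"`` after enzyme integration (one shared pool pseudometabolite
    per enzyme) and ``"coral"`` once pools are split into subpools.
    """

    registry: dict[str, list[Subpool]] = field(default_factory=dict)
    pool_config: PoolConfig = field(default_factory=PoolConfig)
    ordering_mode: str = "off"  # off | chain | vs-main | equality
    constraints: list[LinearConstraint] = field(default_factory=list)
    form: str = "gecko"
    #: original reaction id -> ids of split products (direction/GPR splits)
    split_map: dict[str, list[str]] = field(default_factory=dict)

    def copy(self) -> "CoralModel":
        m = super().copy()
        m.registry = {
            e: [Subpool(**sp.__dict__) for sp in pools]
            for e, pools in self.registry.items()
        }
        m.pool_config = PoolConfig(**self.pool_config.__dict__)
        m.constraints = [
            LinearConstraint(c.name, dict(c.coefficients), c.sense, c.rhs)
            for c in self.constraints
        ]
        m.split_map = {k: list(v) for k, v in self.split_map.items()}
        return m

    # -- registry accessors ---------------------------------------------------
    def subpools(self) -> Iterable[Subpool]:
        for pools in self.registry.values():
            yield from pools

    def subpool(self, enzyme_id: str, rank: int) -> Subpool:
        for sp in self.registry[enzyme_id]:
            if sp.rank == rank:
                return sp
        raise KeyError(f"enzyme {enzyme_id!r} has no rank-{rank} subpool")

    def n_subpools(self) -> int:
        return sum(len(p) for p in self.registry.values())

    def is_promiscuous(self, enzyme_id: str) -> bool:
        """K >= 2 catalysed activities."""
        return len(self.registry[enzyme_id]) >= 2

    def supply_id(self, enzyme_id: str) -> str:
        return f"usage_prot_{enzyme_id}"

    def pool_met_id(self, enzyme_id: str) -> str:
        return f"prot_{enzyme_id}"

    def underground_reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.provenance == "underground"]

    def validate(self) -> None:
        super().validate()
        for enz, pools in self.registry.items():
            ranks = sorted(sp.rank for sp in pools)
            if ranks != list(range(1, len(pools) + 1)):
                raise ValidationError(f"enzyme {enz!r}: subpool ranks {ranks} not 1..K")
            ordered = sorted(pools, key=lambda sp: sp.rank)
            for a, b in zip(ordered, ordered[1:]):
                if a.ratio > b.ratio * (1 + 1e-9):
                    raise ValidationError(
                        f"enzyme {enz!r}: rank {a.rank} ratio {a.ratio} exceeds "
                        f"rank {b.rank} ratio {b.ratio}"
                    )
            if self.form == "coral":
                for sp in pools:
                    for rid, what in (
                        (sp.draw_id, "pool-draw"),
                        (sp.sink_id, "idle-sink"),
                        (sp.reaction_id, "catalysed"),
                    ):
                        if rid not in self.reactions:
                            raise ValidationError(
                                f"subpool {sp.subpool_id!r} references absent "
                                f"{what} pseudoreaction {rid!r}"
                            )
        for c in self.constraints:
            for rid in c.coefficients:
                if rid not in self.reactions:
                    raise ValidationError(
                        f"constraint {c.name!r} references unknown reaction {rid!r}"
                    )


def build_s_matrix(
    model: StoichModel,
) -> tuple[sparse.csr_matrix, dict[str, int], dict[str, int]]:
    """Stoichiometric matrix (metabolites x reactions) with index maps."""
    met_index = {mid: i for i, mid in enumerate(model.metabolites)}
    rxn_index = {rid: j for j, rid in enumerate(model.reactions)}
    rows, cols, data = [], [], []
    for rid, rxn in model.reactions.items():
        j = rxn_index[rid]
        for mid, coef in rxn.stoichiometry.items():
            if coef != 0.0:
                rows.append(met_index[mid])
                cols.append(j)
                data.append(float(coef))
    S = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(met_index), len(rxn_index))
    )
    return S, met_index, rxn_index
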