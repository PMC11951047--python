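"""Metabolite-centric flux-sum analysis.

The flux-sum of metabolite i over a flux distribution v is

    phi_i = 0.5 * sum_j |S_ij * v_j|

i.e. half the total stoichiometry-weighted absolute flux through the
metabolite; at steady state this equals both its total production and its
total consumption, and serves as a proxy for turnover.  Differences of
flux-sums between a wild-type and a defective-network solution localise
the metabolites whose turnover a defect disturbs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .core import StoichModel, ValidationError
from .lp import SolveResult

__all__ = ["FluxSumVector", "flux_sums", "flux_sum_delta"]


@dataclass
class FluxSumVector:
    """metabolite id -> phi (mmol/gDW/h), with provenance of the solution."""

    values: dict[str, float] = field(default_factory=dict)
    provenance: str = ""

    def __getitem__(self, met_id: str) -> float:
        return self.values[met_id]

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self):
        import pandas as pd

        return pd.Series(self.values, name="phi").rename_axis("metabolite").to_frame()


def flux_sums(
    model: StoichModel,
    result: SolveResult,
    include_pseudo: bool = False,
    provenance: str = "",
) -> FluxSumVector:
    """Flux-sums of every metabolite under one solution.

    Pseudometabolites (subpools, pools, linking metabolites) are accounting
    devices and excluded by default.
    """
    if not result.ok:
        raise ValidationError("flux sums require an optimal solution")
    missing = [rid for rid in model.reactions if rid not in result.fluxes]
    if missing:
        raise ValidationError(
            f"solution is missing fluxes for {len(missing)} reactions "
            f"(e.g. {missing[0]!r}); was it computed on this model?"
        )
    out = FluxSumVector(provenance=provenance)
    totals = {
        mid: 0.0
        for mid, met in model.metabolites.items()
        if include_pseudo or not met.is_pseudo
    }
    for rid, rxn in model.reactions.items():
        v = result.fluxes[rid]
        if v == 0.0:
            continue
        for mid, coef in rxn.stoichiometry.items():
            if mid in totals:
                totals[mid] += abs(coef * v)
    out.values = {mid: 0.5 * tot for mid, tot in totals.items()}
    return out


def flux_sum_delta(
    wt: FluxSumVector,
    defect: FluxSumVector,
    common_only: bool = True,
) -> dict[str, float]:
    """Per-metabolite flux-sum change of a defect vs the wild type.

    Positive values mean increased turnover in the defective network
    (phi_del - phi_wt).  With ``common_only`` the difference is taken over
    the metabolite intersection; otherwise over the union with missing
    entries treated as zero.
    """
    if common_only:
        keys = [k for k in wt.values if k in defect.values]
        if not keys:
            warnings.warn("flux-sum vectors share no metabolites; empty delta")
        return {k: defect.values[k] - wt.values[k] for k in keys}
    keys_union = dict.fromkeys(list(wt.values) + list(defect.values))
    return {
        k: defect.values.get(k, 0.0) - wt.values.get(k, 0.0) for k in keys_union
    }
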