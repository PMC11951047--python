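# Methods

This note documents the model the package implements, the numerical and
design choices behind it, what the synthetic fixtures do and do not
emulate, and the known limitations.

## The subpool formulation

A protein-constrained GEM in the GECKO style couples metabolism to a
finite protein budget: each catalysed reaction consumes enzyme capacity in
proportion to MW/kcat, and total enzyme mass is bounded by
E_tot = Ptot·f·σ. In that formulation a promiscuous enzyme appears as one
pseudometabolite shared by all of its reactions, so its resource
allocation across activities is invisible.

Here every (enzyme, reaction, direction) triple gets its own **subpool**.
Internally the wiring is:

* one total-protein pseudometabolite (g/gDW), supplied by an exchange
  pseudoreaction bounded by E_tot;
* per enzyme, a pool pseudometabolite (mmol/gDW) supplied from the total
  pool at MW g per mmol — the supply flux is the enzyme usage E_s;
* per subpool, a draw pseudoreaction pool → subpool (its flux is E_{s,i})
  and the catalysed reaction consumes the subpool metabolite at 1/kcat per
  unit flux. The composite mass cost per unit flux is therefore MW/kcat,
  while the usage variables stay molar.
* per subpool, an idle sink. Without it the metabolite balance would force
  v = kcat·E exactly — allocated-but-unused enzyme would be impossible and
  the ordering rows below would couple *fluxes* rather than capacities.
  With the sink, the balance implements the capacity inequality
  v_j ≤ kcat_{s,i}·E_{s,i}.

Pool conservation (Σ_i E_{s,i} = E_s) holds by construction of the pool
metabolite balance; the protein budget is enforced in mass units
(Σ MW_s·E_s ≤ E_tot) at the total-pool exchange. A unitless sum of molar
usages would be dimensionally inconsistent, so the mass form is the
deliberate reading of the total-pool constraint.

**Units.** Fluxes mmol/gDW/h, usages mmol/gDW, kcat 1/h (per-second input
columns are converted ×3600 at read time), MW g/mmol, pools g/gDW.

## Ranking and ordering constraints

Subpools are ranked by ascending MW/kcat; rank 1 — the largest kcat — is
the enzyme's *main* reaction, the rest are side reactions. Ties are broken
lexicographically on reaction id, deterministically. Each direction of a
reversible catalysed reaction is a distinct activity with its own subpool
(the reverse direction of an enzyme can legitimately be a side activity).

Efficiency prioritisation is modelled as linear rows over the draw fluxes.
Four topologies are available (`ordering=`):

* `chain` (default): kcat_{i+1}·E_{s,i+1} ≤ kcat_i·E_{s,i} along
  consecutive ranks — by transitivity every side subpool's attainable
  velocity is bounded by the main subpool's;
* `vs-main`: each side compared to rank 1 directly;
* `equality`: maximal velocities forced equal along the chain (the
  strictest reading — allocation within an enzyme proportional to 1/kcat);
* `off`: no rows.

The chain default follows the "succession of ordered kcat values" reading;
the alternatives exist because the exact topology is a genuinely open
design point, and equality is the assumption under which the published
analyses are interpreted in their own limitations discussion.

**Blocks release the rows they touch.** Applying the ordering rows
literally while a blocked subpool is pinned to zero would force every
lower-ranked subpool of that enzyme to zero too, and no redistribution
from main to side reactions could ever occur — the central phenomenon the
formulation is meant to expose. Block scenarios therefore drop exactly the
ordering rows in which a blocked draw is the restricting (higher-ranked)
side; inequality rows where the blocked draw sits on the lesser side are
trivially satisfied and are kept, so prioritisation among the surviving
subpools persists. Equality rows propagate a zero in both directions and
are released on any touch. The same rule applies to the draws zeroed when
underground reactions are switched off.

Because releasing rows is a relaxation, growth after a block can exceed
the *fully constrained* unblocked optimum. Pairwise screens therefore
compute their default reference (when no explicit wild-type growth rate is
given) under the same release, which restores the restriction guarantee
μ_del ≤ μ_ref. When an explicit reference (e.g. the 0.1 h⁻¹ chemostat
rate) is supplied, ratios are reported against it verbatim.

## GPR handling

GPRs are normalised to disjunctive normal form (via sympy's boolean
algebra over COBRApy's GPR parser). OR branches become duplicate
reactions; an AND conjunction of k enzyme-bearing genes becomes k partial
reactions chained 1:1 through linking pseudometabolites, so all partials
carry equal flux and jointly reproduce the original stoichiometry, each
costed by one enzyme. Subunit stoichiometry within complexes is taken as
1:1 unless data say otherwise (they rarely do). Genes with no enzyme
record, or enzymes lacking a kcat for the reaction, contribute no protein
cost and are warned about; a reaction with no costed gene at all is left
enzyme-free (no subpool, unconstrained by protein — exchanges and
spontaneous reactions behave this way by design).

## Analyses

* **FVA** over fluxes or subpool draws, per-target independent min/max
  solves (order-independent by construction), with scenarios: underground
  reactions on/off (off = both flux bounds zero, plus the corresponding
  subpool draws zeroed) and growth free or fixed (the chemostat condition
  v_bio = μ). Glucose limitation is expressed only through the fixed μ; no
  additional uptake minimisation is applied.
* **Wild-type reference**: parsimonious allocation minimising the total
  subpool draw at fixed μ (equivalently total pool usage, by
  conservation).
* **Single main blocks**: maximise growth with E_{s,1} = 0 while every
  *other* enzyme's subpool draws are held within a ±5% band of their WT
  values; all subpools of the blocked enzyme are freed so its pool can
  redistribute. Subpools unused in the WT get a [0, 1e-8] band — without
  that allowance, side subpools inactive in the WT could never absorb the
  freed pool, contradicting the redistributions the formulation predicts.
  A `pool` band mode (banding only the per-enzyme supplies) is available
  since the band's granularity is ambiguous in principle.
  After the growth solve, a second stage fixes the achieved growth and
  minimises total draw, so the reported redistribution ratios E_{s,j}/E_s
  come from a parsimonious, reproducible vertex rather than an arbitrary
  one. Redistribution outcomes are classified as: `direct_transfer`
  (rank 2 absorbs the WT main usage within the band), `majority_rank2`,
  `majority_deeper` (a rank > 2 takes the majority), `none_to_rank2`,
  `mixed`, plus `inactive` (main unused in WT), `no_sides` and `lethal`
  (infeasible or growth ≤ 1e-6 h⁻¹).
* **Pairwise blocks** of rank-k subpools (k = 1 mains; k in 2..5 sides,
  enzymes lacking rank k skipped) without the WT band; pairs are
  partitioned at a 1% growth-reduction threshold and annotated by
  promiscuity (both / one / neither enzyme with K ≥ 2). Growth ratios are
  emitted in both orientations (μ_del/μ_WT and its inverse).
* **Double gene knockouts** on the conventional GEM by boolean GPR
  evaluation — the contrast case in which an enzyme's side activities are
  lost together with its main one.
* **Flux-sums** φ_i = ½·Σ_j |S_ij·v_j| per metabolite; pseudometabolites
  (subpools, pools, linking metabolites) are excluded by default as
  accounting devices. Defect-vs-WT differences are taken over the common
  metabolite set (or the union with missing = 0).

## Numerics

LPs are assembled sparse and solved with HiGHS through
`scipy.optimize.linprog` at its default tolerances; reported solutions are
required to satisfy residuals ≤ 1e-6 (mass balance, conservation,
budget). The numerical zero for "carries flux"/"subpool used" is 1e-8.
The two-stage parsimonious solves fix growth with a 1e-9 relative slack to
avoid spurious infeasibility at the optimum. Infeasible defect problems
are reported as lethal outcomes, never raised. Monotonicity comparisons in
tests use a 1e-7 measurement slack for solver noise.

## The oracle

Every analysis is cross-checked against an independently assembled dense
LP (`fixtures.oracle_solve`): variables are network fluxes, subpool usages
and pool usages; capacity, ordering, conservation and budget constraints
are explicit dense rows generated from the subpool registry, never from
the pseudometabolite wiring. It refuses problems above 500 columns — it is
a ground-truth path for small fixtures, not a second solver.

## Synthetic fixtures

`fixtures.make_fixture` generates linear uptake→biomass pathways with a
prescribed promiscuity profile (subpool count per enzyme), log-uniform
kcats spanning 1e2–1e5 h⁻¹ (a realistic central slice of observed
turnover ranges), MW 20–60 g/mmol, side reactions that are either pathway
bypasses (productive) or demand-drained dead ends (70% productive by
default), optional AND/OR GPRs and optional underground bypasses whose
kcats are drawn below the host enzyme's smallest native kcat (so
underground activities rank as side reactions, which is how they enter
real reconstructions). All randomness flows from the spec seed; identical
specs give byte-identical serializations. Curated motif fixtures cover
the qualitative scenarios: direct transfer, a deep-rank rescuer, a
redundant promiscuous pair, an essential non-promiscuous pair, an AND
complex, an OR isozyme pair, and tied kcats.

What the fixtures do **not** emulate: genome-scale topology (thousands of
reactions, cofactor coupling, compartments), realistic biomass
compositions, or curated kcat distributions. Passing tests demonstrate the
correctness of the formulation and the analyses on networks whose ground
truth is checkable — not the numerical reproduction of any genome-scale
dataset, which requires the full *E. coli* model and kcat inputs and is
out of desk scope. Problem sizes were chosen so the whole suite and the
acceptance script run in seconds on one CPU.

## Known limitations

* The ordering-row release under blocks is an interpretation; the
  formulation itself is silent on what happens to prioritisation when a
  higher-ranked activity is removed, and both the release rule and the
  band granularity are exposed as options rather than hard-coded.
* AND-complex partials couple subunit usage through equal partial fluxes
  with 1:1 subunit stoichiometry; real complex stoichiometries are not
  inferred.
* Parsimonious allocations are unique in objective value but not
  necessarily in the allocation vector; degenerate optima are resolved by
  the solver's vertex choice after the second-stage minimisation, which is
  deterministic for fixed inputs but not canonical.
* No MILP extensions: loopless FVA, thermodynamic constraints and
  flux-sum-constrained optimisation are out of scope.
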