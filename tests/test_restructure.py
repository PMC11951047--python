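"""GPR simplification, enzyme integration, subpool splitting and the
kcat-ordering rows."""

import pytest

from coral.core import (
    EnzymeRecord,
    EnzymeTable,
    Metabolite,
    PoolConfig,
    Reaction,
    StoichModel,
    ValidationError,
)
from coral.io import write_coral_model
from coral.lp import fba, solve_lp
from coral.restructure import (
    add_ordering_constraints,
    build_ec_layer,
    restructure,
    split_complex_gprs,
    split_reversible,
    split_subpools,
)

from conftest import two_subpool_closed_form_model


def _chain_model(gpr="g1", reversible=False):
    m = StoichModel(id="chain")
    for mid in ("A", "B"):
        m.add_metabolite(Metabolite(id=mid, compartment="c"))
    m.add_reaction(Reaction(id="EX_A", stoichiometry={"A": -1.0},
                            lower_bound=-10.0, upper_bound=0.0))
    m.add_reaction(Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0},
                            lower_bound=-10.0 if reversible else 0.0, gpr=gpr))
    m.add_reaction(Reaction(id="BIOMASS", stoichiometry={"B": -1.0}))
    m.objective_id = "BIOMASS"
    m.genes = sorted({g for g in gpr.replace("(", " ").replace(")", " ").split()
                      if g not in ("and", "or")})
    return m


def _table(entries, mw=40.0):
    """entries: {enzyme: (gene, {(rxn, dir): kcat})}"""
    t = EnzymeTable()
    for e, (gene, kcats) in entries.items():
        rec = EnzymeRecord(e, (gene,), mw)
        rec.kcats.update(kcats)
        t.add(rec)
    return t


class TestSplitReversible:
    def test_reverse_half_created(self):
        m = _chain_model(reversible=True)
        t = _table({"E1": ("g1", {("R1", "fwd"): 100.0, ("R1", "rev"): 10.0})})
        out = split_reversible(m, t)
        assert out.reactions["R1"].lower_bound == 0.0
        rev = out.reactions["R1_REV"]
        assert rev.stoichiometry == {"A": 1.0, "B": -1.0}
        assert rev.upper_bound == 10.0
        assert rev.direction == "rev" and rev.root_id == "R1"

    def test_uncatalyzed_left_alone(self):
        m = _chain_model(reversible=True)
        out = split_reversible(m, EnzymeTable())
        assert "R1_REV" not in out.reactions
        assert out.reactions["R1"].lower_bound == -10.0


class TestSplitComplexGprs:
    def test_and_complex_chained(self):
        m = _chain_model(gpr="g1 and g2")
        t = _table({
            "E1": ("g1", {("R1", "fwd"): 100.0}),
            "E2": ("g2", {("R1", "fwd"): 100.0}),
        })
        out = split_complex_gprs(m, t)
        assert "R1" not in out.reactions
        p1, p2 = out.reactions["R1_part1"], out.reactions["R1_part2"]
        link = "pmet_link_R1_1"
        assert p1.stoichiometry == {"A": -1.0, link: 1.0}
        assert p2.stoichiometry == {link: -1.0, "B": 1.0}
        assert {p1.catalyst, p2.catalyst} == {"E1", "E2"}
        # linking metabolite couples the partials: the chained pair has the
        # same feasible biomass optimum as the original reaction
        assert fba(out).mu == pytest.approx(fba(m).mu)

    def test_partials_carry_equal_flux(self):
        m = _chain_model(gpr="g1 and g2")
        t = _table({
            "E1": ("g1", {("R1", "fwd"): 100.0}),
            "E2": ("g2", {("R1", "fwd"): 100.0}),
        })
        out = split_complex_gprs(m, t)
        sol = fba(out)
        assert sol.fluxes["R1_part1"] == pytest.approx(sol.fluxes["R1_part2"])
        assert sol.fluxes["R1_part1"] > 0

    def test_or_isozymes_duplicated(self):
        m = _chain_model(gpr="g1 or g2")
        t = _table({
            "E1": ("g1", {("R1", "fwd"): 100.0}),
            "E2": ("g2", {("R1", "fwd"): 50.0}),
        })
        out = split_complex_gprs(m, t)
        assert "R1" in out.reactions and "R1_iso2" in out.reactions
        assert {out.reactions["R1"].catalyst, out.reactions["R1_iso2"].catalyst} == {
            "E1", "E2"
        }

    def test_mixed_dnf_expansion(self):
        # (g1 and g2) or g3 -> a 2-chain plus a singleton, 3 reactions total
        m = _chain_model(gpr="(g1 and g2) or g3")
        t = _table({
            "E1": ("g1", {("R1", "fwd"): 100.0}),
            "E2": ("g2", {("R1", "fwd"): 100.0}),
            "E3": ("g3", {("R1", "fwd"): 100.0}),
        })
        out = split_complex_gprs(m, t)
        derived = [r for r in out.reactions.values() if r.root_id == "R1"]
        assert len(derived) == 3
        chained = [r for r in derived if r.provenance == "partial"]
        singles = [r for r in derived if r.provenance != "partial"]
        assert len(chained) == 2 and len(singles) == 1
        assert singles[0].catalyst == "E3"

    def test_unknown_gene_warns_and_leaves_enzyme_free(self):
        m = _chain_model(gpr="g_unknown")
        t = _table({"E1": ("g1", {("R1", "fwd"): 100.0})})
        with pytest.warns(UserWarning, match="no enzyme record"):
            out = split_complex_gprs(m, t)
        assert out.reactions["R1"].catalyst is None


class TestBuildEcLayer:
    def test_nonbinding_budget_flux_limited_by_substrate(self):
        m = _chain_model()
        t = _table({"E1": ("g1", {("R1", "fwd"): 3600.0})})
        ec = build_ec_layer(m, t, PoolConfig(ptot=400.0, sigma=1.0, f=1.0))
        assert fba(ec).mu == pytest.approx(10.0)

    def test_binding_budget_closed_form(self):
        # E = budget/MW = 0.04/40 = 1e-3 mmol/gDW; v = kcat*E = 3.6
        m = _chain_model()
        t = _table({"E1": ("g1", {("R1", "fwd"): 3600.0})}, mw=40.0)
        ec = build_ec_layer(m, t, PoolConfig(ptot=0.16, sigma=0.5, f=0.5))
        sol = fba(ec)
        assert sol.mu == pytest.approx(3.6, rel=1e-9)
        assert sol.pool_usage["E1"] == pytest.approx(1e-3, rel=1e-9)

    def test_reversible_catalyzed_rejected(self):
        m = _chain_model(reversible=True)
        t = _table({"E1": ("g1", {("R1", "fwd"): 100.0})})
        with pytest.raises(ValidationError, match="reversible"):
            build_ec_layer(m, t)

    def test_zero_kcat_rejected_upstream(self):
        t = _table({"E1": ("g1", {("R1", "fwd"): 0.0})})
        with pytest.raises(ValidationError, match="kcat"):
            t.validate()


class TestSplitSubpools:
    def _promiscuous(self, kcats):
        m = StoichModel(id="promisc")
        m.add_metabolite(Metabolite(id="A"))
        m.add_metabolite(Metabolite(id="B"))
        m.add_reaction(Reaction(id="EX_A", stoichiometry={"A": -1.0},
                                lower_bound=-10.0, upper_bound=0.0))
        for rid in kcats:
            m.add_reaction(Reaction(id=rid, stoichiometry={"A": -1.0, "B": 1.0}, gpr="g1"))
        m.add_reaction(Reaction(id="BIOMASS", stoichiometry={"B": -1.0}))
        m.objective_id = "BIOMASS"
        m.genes = ["g1"]
        t = _table({"E1": ("g1", {(rid, "fwd"): k for rid, k in kcats.items()})})
        return m, t

    def test_rank_order_follows_kcat(self):
        m, t = self._promiscuous({"R1": 100.0, "R2": 10.0, "R3": 1.0})
        coral = split_subpools(build_ec_layer(m, t))
        by_rank = {sp.rank: sp.reaction_id for sp in coral.registry["E1"]}
        assert by_rank == {1: "R1", 2: "R2", 3: "R3"}

    def test_single_activity_single_subpool(self):
        m, t = self._promiscuous({"R1": 100.0})
        coral = split_subpools(build_ec_layer(m, t))
        assert [sp.rank for sp in coral.registry["E1"]] == [1]

    def test_tied_kcats_broken_lexicographically(self):
        m, t = self._promiscuous({"R1": 90.0, "R3": 30.0, "R2": 30.0})
        coral = split_subpools(build_ec_layer(m, t))
        by_rank = {sp.rank: sp.reaction_id for sp in coral.registry["E1"]}
        assert by_rank == {1: "R1", 2: "R2", 3: "R3"}

    def test_counts_grow_by_subpools(self):
        m, t = self._promiscuous({"R1": 100.0, "R2": 10.0})
        ec = build_ec_layer(m, t)
        coral = split_subpools(ec)
        # per subpool: one pseudometabolite, one draw, one sink; the
        # enzyme-level sink is retired
        assert len(coral.metabolites) == len(ec.metabolites) + 2
        assert len(coral.reactions) == len(ec.reactions) + 2 * 2 - 1


class TestOrderingConstraints:
    def test_closed_form_side_flux(self):
        # pool pinned at 1 mmol, kcats (100, 10): 10*E2 <= 100*(1-E2)
        # -> E2 <= 10/11, max side flux = 100/11
        coral = two_subpool_closed_form_model()
        res = solve_lp(coral, {"R2": 1.0}, maximize=True,
                       bound_overrides={coral.supply_id("E"): (1.0, 1.0)})
        assert res.objective == pytest.approx(100.0 / 11.0, abs=1e-9)

    def test_single_subpool_no_rows(self):
        m = _chain_model()
        t = _table({"E1": ("g1", {("R1", "fwd"): 100.0})})
        coral = restructure(m, t, ordering="chain")
        assert [c for c in coral.constraints if c.name.startswith("order_")] == []

    def test_tied_pair_row_count_and_tie_invariance(self):
        coral = restructure(*_tied_model(), ordering="chain")
        rows = [c for c in coral.constraints if c.name.startswith("order_")]
        assert len(rows) == 2
        mu = fba(coral).mu
        # swapping the tied pair's rank order leaves the feasible set alone
        swapped = coral.copy()
        a = swapped.subpool("E1", 2)
        b = swapped.subpool("E1", 3)
        a.rank, b.rank = 3, 2
        swapped = add_ordering_constraints(swapped, "chain")
        assert fba(swapped).mu == pytest.approx(mu, rel=1e-9)

    def test_equality_mode_is_tighter(self):
        coral = two_subpool_closed_form_model()
        eq = add_ordering_constraints(coral, "equality")
        pin = {coral.supply_id("E"): (1.0, 1.0)}
        free_side = solve_lp(coral, {"R2": 1.0}, bound_overrides=pin).objective
        eq_side = solve_lp(eq, {"R2": 1.0}, bound_overrides=pin).objective
        assert eq_side <= free_side + 1e-9

    def test_vs_main_mode_rows_reference_rank_one(self):
        coral = restructure(*_tied_model(), ordering="vs-main")
        rows = [c for c in coral.constraints if c.name.startswith("order_")]
        main_draw = coral.subpool("E1", 1).draw_id
        assert len(rows) == 2
        assert all(main_draw in c.coefficients for c in rows)


def _tied_model():
    m = StoichModel(id="tied")
    for mid in ("A", "B"):
        m.add_metabolite(Metabolite(id=mid, compartment="c"))
    m.add_reaction(Reaction(id="EX_A", stoichiometry={"A": -1.0},
                            lower_bound=-10.0, upper_bound=0.0))
    for rid in ("R1", "R2", "R3"):
        m.add_reaction(Reaction(id=rid, stoichiometry={"A": -1.0, "B": 1.0}, gpr="g1"))
    m.add_reaction(Reaction(id="BIOMASS", stoichiometry={"B": -1.0}))
    m.objective_id = "BIOMASS"
    m.genes = ["g1"]
    t = EnzymeTable()
    rec = EnzymeRecord("E1", ("g1",), 10.0)
    rec.kcats.update({("R1", "fwd"): 90.0, ("R2", "fwd"): 30.0, ("R3", "fwd"): 30.0})
    t.add(rec)
    return m, t


class TestPipelineProperties:
    def test_determinism_byte_identical(self, toy_triplet, tmp_path):
        model, table, und = toy_triplet
        from coral.io import merge_underground

        merged = merge_underground(model, und)
        p1, p2 = tmp_path / "a.yaml", tmp_path / "b.yaml"
        write_coral_model(restructure(merged, table), p1)
        write_coral_model(restructure(merged, table), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_subpool_split_is_pure_refinement(self, toy_triplet):
        """With ordering off, subpool splitting must not change the optimum;
        with ordering on it can only restrict it."""
        model, table, und = toy_triplet
        from coral.io import merge_underground

        merged = merge_underground(model, und)
        m2 = split_complex_gprs(split_reversible(merged, table), table)
        gecko = build_ec_layer(m2, table)
        coral_off = add_ordering_constraints(split_subpools(gecko), "off")
        coral_on = add_ordering_constraints(split_subpools(gecko), "chain")
        mu_g = fba(gecko).mu
        assert fba(coral_off).mu == pytest.approx(mu_g, rel=1e-9)
        assert fba(coral_on).mu <= mu_g + 1e-9

    def test_blocking_subpool_zeroes_reaction(self, toy_coral):
        sp = next(sp for sp in toy_coral.subpools())
        res = fba(toy_coral, bound_overrides={sp.draw_id: (0.0, 0.0)})
        assert res.ok
        assert abs(res.fluxes[sp.reaction_id]) <= 1e-9
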