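"""Defect simulations: single and pairwise subpool blocks, redistribution
classes, and conventional double gene knockouts."""

import itertools

import pytest

from coral.core import Metabolite, Reaction, StoichModel, ValidationError
from coral.defects import (
    block_main_pairs,
    block_main_single,
    block_side_pairs,
    build_wt_reference,
    double_gene_knockout,
    impacted_pairs,
    screen_single_blocks,
)
from coral.fixtures import FixtureSpec, curated_fixture, make_fixture, oracle_solve
from coral.lp import fba
from coral.restructure import restructure

from conftest import build_curated


@pytest.fixture(scope="module")
def dt_coral():
    return build_curated("direct_transfer")


@pytest.fixture(scope="module")
def dt_wt(dt_coral):
    mu = fba(dt_coral).mu
    return build_wt_reference(dt_coral, mu=mu)


class TestBlockMainSingle:
    def test_direct_transfer_growth_neutral(self, dt_coral, dt_wt):
        """Side reaction duplicates the main: blocking the main is
        growth-neutral and rank 2 absorbs the pool within the band."""
        rep = block_main_single(dt_coral, dt_wt, "E_dt")
        assert rep.status == "optimal"
        assert rep.growth_ratio == pytest.approx(1.0, abs=0.05)
        assert rep.classification == "direct_transfer"
        sp2 = dt_coral.subpool("E_dt", 2).subpool_id
        assert rep.redistribution[sp2] == pytest.approx(1.0, abs=1e-6)

    def test_sole_route_block_is_lethal(self):
        coral = build_curated("essential_pair")
        wt = build_wt_reference(coral, mu=0.5 * fba(coral).mu)
        rep = block_main_single(coral, wt, "E_a")
        assert rep.lethal
        assert rep.classification == "lethal"
        assert rep.growth_ratio == 0.0

    def test_inactive_main_block_is_neutral(self):
        """Blocking an enzyme whose main subpool was unused in the WT
        changes nothing (ratio 1 within band slack)."""
        coral = build_curated("or_isozyme")
        wt = build_wt_reference(coral, mu=5.0)
        assert wt.pool_usage["E_i2"] == pytest.approx(0.0, abs=1e-9)
        rep = block_main_single(coral, wt, "E_i2")
        assert rep.classification == "inactive"
        assert rep.growth_ratio == pytest.approx(1.0, abs=0.051)

    def test_deep_rescuer_classified_deeper(self):
        """Rank 2 is a dead end, rank 3 remakes the main product: the pool
        lands on rank 3."""
        coral = build_curated("deep_rescuer")
        wt = build_wt_reference(coral, mu=fba(coral).mu)
        rep = block_main_single(coral, wt, "E_dr")
        assert rep.status == "optimal"
        sp3 = coral.subpool("E_dr", 3).subpool_id
        assert rep.redistribution[sp3] > 0.5
        assert rep.classification == "majority_deeper"

    def test_redistribution_ratios_sum_to_one(self, dt_coral, dt_wt):
        rep = block_main_single(dt_coral, dt_wt, "E_dt")
        assert sum(rep.redistribution.values()) == pytest.approx(1.0, abs=1e-6)

    def test_unknown_enzyme_raises(self, dt_coral, dt_wt):
        with pytest.raises(ValidationError, match="nonesuch"):
            block_main_single(dt_coral, dt_wt, "nonesuch")

    def test_pool_band_mode_also_solves(self, dt_coral, dt_wt):
        rep = block_main_single(dt_coral, dt_wt, "E_dt", band_mode="pool")
        assert rep.status == "optimal"
        assert rep.growth_ratio == pytest.approx(1.0, abs=0.05)


class TestScreenSingleBlocks:
    def test_flags_only_wt_active_nonlethal(self):
        coral = build_curated("or_isozyme")
        wt = build_wt_reference(coral, mu=5.0)
        reports = screen_single_blocks(coral, wt)
        flagged = [r for r in reports if r.wt_main_used and not r.lethal]
        # E_i1 carries all WT usage; blocking it shifts work to E_i2
        assert [r.enzymes[0] for r in flagged] == ["E_i1"]

    def test_all_enzymes_unused_yields_empty_flagged(self):
        coral = build_curated("direct_transfer")
        # an enzyme-free bypass makes zero enzyme usage optimal
        wt = build_wt_reference(coral, mu=0.0)
        reports = screen_single_blocks(coral, wt)
        assert [r for r in reports if r.wt_main_used] == []


class TestBlockPairs:
    def test_redundant_promiscuous_pair_keeps_growth(self):
        coral = build_curated("redundant_pair")
        reports = block_main_pairs(coral)
        (rep,) = [r for r in reports if set(r.enzymes) == {"E_x", "E_y"}]
        assert rep.growth_ratio == pytest.approx(1.0, rel=1e-6)
        assert rep.promiscuity == "both"

    def test_essential_nonpromiscuous_pair_lethal(self):
        coral = build_curated("essential_pair")
        reports = block_main_pairs(coral)
        (rep,) = reports
        assert rep.classification == "lethal"
        assert rep.promiscuity == "neither"
        assert rep.mu_del == pytest.approx(0.0, abs=1e-9)

    def test_pair_order_independent(self, toy_coral):
        enzymes = sorted(toy_coral.registry)[:2]
        fwd = block_main_pairs(toy_coral, enzymes=enzymes)
        rev = block_main_pairs(toy_coral, enzymes=enzymes[::-1])
        assert fwd[0].mu_del == pytest.approx(rev[0].mu_del, rel=1e-9)

    def test_restriction_monotonicity(self, toy_coral):
        """Blocking never increases growth: every pair ratio <= 1 against
        the model's own optimum."""
        for rep in block_main_pairs(toy_coral):
            assert rep.growth_ratio <= 1.0 + 1e-9

    def test_explicit_mu_wt_used_as_reference(self):
        coral = build_curated("redundant_pair")
        reports = block_main_pairs(coral, mu_wt=5.0)
        (rep,) = [r for r in reports if set(r.enzymes) == {"E_x", "E_y"}]
        assert rep.mu_wt == 5.0
        assert rep.growth_ratio == pytest.approx(rep.mu_del / 5.0)

    def test_impact_partition(self, toy_coral):
        reports = block_main_pairs(toy_coral)
        impacted, rest = impacted_pairs(reports, threshold=0.01)
        assert len(impacted) + len(rest) == len(reports)
        for r in impacted:
            assert r.mu_del < 0.99 * r.mu_wt

    def test_pair_ratios_match_oracle(self, toy_coral):
        """Full pair-block ratio grid agrees with the independent dense
        assembly."""
        reports = block_main_pairs(toy_coral)
        for rep in reports:
            blocks = [toy_coral.subpool(e, 1).subpool_id for e in rep.enzymes]
            osol = oracle_solve(toy_coral, "fba", blocks=blocks)
            if rep.status == "optimal":
                assert osol.objective == pytest.approx(
                    rep.mu_del, rel=1e-6, abs=1e-9
                )
            else:
                assert not osol.ok


class TestBlockSidePairs:
    def test_rank_guard(self, toy_coral):
        with pytest.raises(ValidationError, match="rank"):
            block_side_pairs(toy_coral, rank=1)

    def test_enzymes_without_rank_skipped(self, toy_coral):
        eligible = [e for e, pools in toy_coral.registry.items() if len(pools) >= 2]
        reports = block_side_pairs(toy_coral, rank=2)
        assert len(reports) == len(list(itertools.combinations(eligible, 2)))

    def test_redundant_side_pair_block_neutral(self):
        """Blocking the rank-2 duplicates of two redundant enzymes leaves
        the mains carrying growth (symmetric counterpart of the main-pair
        redundancy case)."""
        coral = build_curated("redundant_pair")
        reports = block_side_pairs(coral, rank=2)
        (rep,) = [r for r in reports if set(r.enzymes) == {"E_x", "E_y"}]
        assert rep.growth_ratio == pytest.approx(1.0, rel=1e-6)

    def test_restriction_monotonicity(self):
        """Side-pair blocks never exceed their unblocked reference."""
        spec = FixtureSpec(n_steps=3, promiscuity_profile=(2, 2), seed=5)
        model, table, _ = make_fixture(spec)
        coral = restructure(model, table)
        for rep in block_main_pairs(coral) + block_side_pairs(coral, rank=2):
            assert rep.growth_ratio <= 1.0 + 1e-9


class TestDoubleGeneKnockout:
    def test_isozyme_pair_knockout_lethal(self):
        model, table, _ = curated_fixture("or_isozyme")
        (rep,) = double_gene_knockout(model, [("g_i1", "g_i2")])
        assert rep.classification == "lethal"

    def test_irrelevant_genes_neutral(self):
        model, table, _ = curated_fixture("or_isozyme")
        # add a spare gene-bearing reaction not needed for growth
        model = model.copy()
        model.add_metabolite(Metabolite(id="Z"))
        model.add_reaction(Reaction(id="RZ", stoichiometry={"A": -1.0, "Z": 1.0},
                                    gpr="g_z1 or g_z2"))
        model.add_reaction(Reaction(id="DM_Z", stoichiometry={"Z": -1.0}))
        model.genes = sorted(model.genes + ["g_z1", "g_z2"])
        (rep,) = double_gene_knockout(model, [("g_z1", "g_z2")])
        assert rep.growth_ratio == pytest.approx(1.0)

    def test_unknown_gene_named(self):
        model, *_ = curated_fixture("or_isozyme")
        with pytest.raises(ValidationError, match="g_missing"):
            double_gene_knockout(model, [("g_i1", "g_missing")])

    def test_grid_matches_cobra(self, toy_triplet):
        """Knockout growth grid agrees with COBRApy's own gene deletion."""
        import cobra.manipulation

        from coral.io import to_cobra

        model, table, _ = toy_triplet
        genes = sorted(model.genes)[:4]
        pairs = list(itertools.combinations(genes, 2))
        reports = double_gene_knockout(model, pairs)
        cm = to_cobra(model)
        for (g1, g2), rep in zip(pairs, reports):
            with cm as probe:
                cobra.manipulation.knock_out_model_genes(probe, [g1, g2])
                mu = probe.slim_optimize(error_value=0.0)
            assert rep.mu_del == pytest.approx(mu, rel=1e-6, abs=1e-9)

    def test_subpool_block_dominates_gene_knockout(self):
        """Matched defect: the subpool pair block retains growth that the
        conventional double knockout destroys, because knockouts remove the
        side activities too."""
        model, table, _ = curated_fixture("redundant_pair")
        coral = restructure(model, table)
        (coral_rep,) = [
            r for r in block_main_pairs(coral) if set(r.enzymes) == {"E_x", "E_y"}
        ]
        (ko_rep,) = double_gene_knockout(model, [("g_x", "g_y")])
        assert coral_rep.growth_ratio >= ko_rep.growth_ratio - 1e-9
        assert coral_rep.growth_ratio == pytest.approx(1.0, rel=1e-6)
        assert ko_rep.classification == "lethal"
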