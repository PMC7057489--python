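import random

import pytest

from spchub import (
    ComponentScores,
    Dataset,
    ModelConfig,
    SSMResult,
    ValidationError,
    WeightVector,
    combine_components,
    rank_and_flag,
    round_display,
    run_ssm,
)
from spchub.synthetic import LINE_EXPECTATION, generate_line_region


def result(cid, pop, iso, vuln, ready, weights=None):
    comps = ComponentScores(pop, iso, vuln, ready)
    return SSMResult(
        community_id=cid,
        name=cid,
        components=comps,
        ssm_score=combine_components(comps, weights),
    )


class TestCombine:
    def test_dryden_equal_weights(self):
        got = combine_components(ComponentScores(0.81, 0.94, 0.29, 0.80))
        assert got == pytest.approx(0.71)
        assert round_display(got) == "0.71"

    def test_fort_frances_full_precision_then_display(self):
        got = combine_components(ComponentScores(1.00, 0.93, 0.30, 0.80))
        assert got == pytest.approx(0.7575)
        assert round_display(got) == "0.76"

    def test_all_ones_with_any_weights(self):
        comps = ComponentScores(1, 1, 1, 1)
        assert combine_components(comps, WeightVector(3, 1, 0.5, 2)) == 1.0

    def test_equal_weights_is_arithmetic_mean(self):
        rng = random.Random(5)
        for _ in range(100):
            vals = [rng.random() for _ in range(4)]
            comps = ComponentScores(*vals)
            assert combine_components(comps) == pytest.approx(
                sum(vals) / 4, abs=1e-12
            )

    def test_weighted_mean_normalizes_to_unit_interval(self):
        comps = ComponentScores(0.2, 0.9, 0.4, 0.6)
        got = combine_components(comps, WeightVector(5, 1, 1, 1))
        assert 0.0 <= got <= 1.0
        assert got == pytest.approx((5 * 0.2 + 0.9 + 0.4 + 0.6) / 8)


class TestRoundDisplay:
    @pytest.mark.parametrize(
        "x,dp,expected",
        [
            (0.325, 2, "0.33"),   # half away from zero, not banker's
            (0.405, 2, "0.41"),
            (0.71, 2, "0.71"),
            (-0.005, 2, "-0.01"),
            (0.2875, 2, "0.29"),
            (1.0, 2, "1.00"),
            (0.44999999, 2, "0.45"),
            (0.6, 1, "0.6"),
        ],
    )
    def test_decimal_half_away_from_zero(self, x, dp, expected):
        assert round_display(x, dp) == expected


class TestRankAndFlag:
    def test_eligibility_is_strict(self):
        rs = [result("A", 0.6, 0.6, 0.6, 0.6), result("B", 0.7, 0.7, 0.7, 0.7)]
        ranked = rank_and_flag(rs, 0.6)
        flags = {r.community_id: r.eligible for r in ranked}
        assert flags == {"A": False, "B": True}

    def test_tied_scores_break_by_population_component(self):
        # identical final scores, different population mixes
        rs = [
            result("kincardine-like", 0.25, 0.27, 0.30, 0.80),
            result("kapuskasing-like", 0.46, 0.44, 0.33, 0.39),
        ]
        # force an exact tie
        rs[1].ssm_score = rs[0].ssm_score
        ranked = rank_and_flag(rs, 0.6)
        assert ranked[0].community_id == "kapuskasing-like"
        assert [r.rank for r in ranked] == [1, 2]

    def test_kapuskasing_outranks_kincardine(self):
        rs = [
            result("Kincardine", 0.25, 0.27, 0.30, 0.80),
            result("Kapuskasing", 0.46, 0.44, 0.33, 0.40),
        ]
        assert round_display(rs[0].ssm_score) == round_display(rs[1].ssm_score) == "0.41"
        ranked = rank_and_flag(rs, 0.6)
        assert ranked[0].community_id == "Kapuskasing"

    def test_empty_input_gives_empty_output(self):
        assert rank_and_flag([], 0.6) == []

    def test_permutation_invariance(self):
        rng = random.Random(11)
        rs = [
            result(f"c{i}", rng.random(), rng.random(), rng.random(),
                   rng.choice([0.0, 0.2, 0.4, 0.6, 0.8, 1.0]))
            for i in range(15)
        ]
        base = {r.community_id: r.rank for r in rank_and_flag(rs, 0.6)}
        for _ in range(5):
            rng.shuffle(rs)
            again = {r.community_id: r.rank for r in rank_and_flag(rs, 0.6)}
            assert again == base

    def test_improving_a_component_never_worsens_rank(self):
        rs = [
            result("A", 0.5, 0.5, 0.5, 0.4),
            result("B", 0.6, 0.3, 0.4, 0.6),
            result("C", 0.2, 0.9, 0.6, 0.2),
        ]
        before = {r.community_id: r.rank for r in rank_and_flag(rs, 0.6)}
        rs[0] = result("A", 0.5, 0.5, 0.5, 0.8)  # raise one component of A
        after = {r.community_id: r.rank for r in rank_and_flag(rs, 0.6)}
        assert after["A"] <= before["A"]


class TestRunSsm:
    def test_line_fixture_full_trace(self, line_results):
        exp = LINE_EXPECTATION
        assert [r.community_id for r in line_results] == exp["ranking"]
        for r in line_results:
            cid = r.community_id
            assert r.components.population == pytest.approx(
                exp["population_score"][cid], abs=1e-12)
            assert r.components.isolation == pytest.approx(
                exp["isolation_score"][cid], abs=1e-12)
            assert r.components.vulnerability == pytest.approx(
                exp["vulnerability_score"][cid], abs=1e-12)
            assert r.components.readiness == exp["readiness_score"][cid]
            assert r.ssm_score == pytest.approx(exp["ssm_score"][cid], abs=1e-12)
            assert r.eligible is exp["eligible"][cid]

    def test_population_only_weights_follow_population_order(self, line_dataset):
        cfg = ModelConfig(weights=WeightVector(1, 0, 0, 0))
        out = run_ssm(line_dataset, cfg)
        pops = [r.components.population for r in out]
        assert pops == sorted(pops, reverse=True)
        assert [r.ssm_score for r in out] == pytest.approx(pops)

    def test_empty_candidate_set_returns_empty(self, line_dataset, caplog):
        cfg = ModelConfig(min_population=1e9)
        with caplog.at_level("WARNING"):
            assert run_ssm(line_dataset, cfg) == []

    def test_dominant_candidate_ranks_first(self):
        from spchub import Facility, PopulationBlock, PopulationCentre, RoadNetwork

        # hospital -- 100' -- A -- 200' -- B; all blocks sit at B, whose
        # residents also carry the higher demographic need and readiness.
        net = RoadNetwork(
            nodes={"h": (0.0, 0.0), "a": (1e5, 0.0), "b": (3e5, 0.0)},
            edges=[("h", "a", 100.0), ("a", "b", 200.0)],
        )
        from spchub import ReadinessFlags

        centres = [
            PopulationCentre("A", "A", (1e5, 0.0), 6000.0, 0.05, 0.40, 0.05, 10,
                             (0.1, 0.1, 0.1, 0.5, 0.5, 0.5, 0.1),
                             ReadinessFlags(False, False, False, None, False)),
            PopulationCentre("B", "B", (3e5, 0.0), 9000.0, 0.20, 0.55, 0.15, 10,
                             (0.5, 0.5, 0.5, 0.0, 0.0, 0.0, 0.5),
                             ReadinessFlags(True, True, True, None, True)),
        ]
        ds = Dataset(
            centres=centres,
            blocks=[PopulationBlock("blk", (3e5, 10.0), 9000.0)],
            network=net,
            facilities=[Facility("H", (0.0, 0.0), "hospital", 900)],
        )
        out = run_ssm(ds, ModelConfig())
        assert out[0].community_id == "B"
        assert out[0].rank == 1
        assert out[0].ssm_score == pytest.approx(1.0)

    def test_pcix_reference_changes_vulnerability_scaling(self, line_dataset):
        from spchub import PopulationCentre

        ref = [
            PopulationCentre(
                "REF", "Province Max", (0.0, 0.0), 1000.0,
                pct_over75=0.30, pct_female=0.60, pct_alone=0.24,
                vandix_indicators=(0.8, 0.2, 0.4, 20000.0, 0.2, 0.3, 0.4),
            )
        ]
        base = run_ssm(line_dataset, ModelConfig())
        widened = run_ssm(line_dataset, ModelConfig(), pcix_reference=ref)
        v_base = {r.community_id: r.components.vulnerability for r in base}
        v_wide = {r.community_id: r.components.vulnerability for r in widened}
        # a more-deprived reference community lowers everyone's relative score
        assert all(v_wide[c] < v_base[c] for c in v_base)
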