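import math

import pytest
from hypothesis import given, settings, strategies as st

from spchub import (
    ModelConfig,
    PcixSubscores,
    ReadinessFlags,
    UNREACHABLE,
    ValidationError,
    catchment_population,
    isolation_component,
    pcix_vulnerability,
    physician_supply_adequate,
    population_component,
    readiness_component,
    scale_subscores,
    vandix_score,
)
from spchub.synthetic import LINE_EXPECTATION


class TestCatchmentPopulation:
    def test_no_blocks_is_zero(self, line_dataset):
        centre = line_dataset.centres[3]
        assert catchment_population(line_dataset.network, centre, [], 60.0) == 0.0

    def test_infinite_limit_sums_whole_component(self, line_dataset):
        centre = line_dataset.centres[3]
        total = sum(b.population for b in line_dataset.blocks)
        got = catchment_population(
            line_dataset.network, centre, line_dataset.blocks, math.inf
        )
        assert got == total

    @pytest.mark.parametrize("idx,expected", [(3, 19000.0), (4, 15000.0), (5, 9000.0)])
    def test_line_fixture_hand_summed_totals(self, line_dataset, idx, expected):
        got = catchment_population(
            line_dataset.network, line_dataset.centres[idx], line_dataset.blocks, 60.0
        )
        assert got == expected


class TestPopulationComponent:
    def test_proportional_to_largest(self):
        assert population_component({"A": 60000, "B": 30000}) == {"A": 1.0, "B": 0.5}

    def test_single_centre_scores_one(self):
        assert population_component({"A": 123}) == {"A": 1.0}

    def test_all_zero_scores_zero(self):
        assert population_component({"A": 0, "B": 0}) == {"A": 0.0, "B": 0.0}

    def test_scale_invariance(self):
        base = {"A": 19000.0, "B": 15000.0, "C": 9000.0}
        scaled = {k: v * 37.5 for k, v in base.items()}
        a, b = population_component(base), population_component(scaled)
        for k in base:
            assert a[k] == pytest.approx(b[k])

    def test_negative_population_rejected(self):
        with pytest.raises(ValidationError):
            population_component({"A": -1})


class TestIsolationComponent:
    @pytest.mark.parametrize(
        "minutes,expected",
        [(240.0, 1.0), (120.0, 0.5), (0.0, 0.0), (300.0, 1.0), (UNREACHABLE, 1.0)],
    )
    def test_proportional_capped(self, minutes, expected):
        assert isolation_component(minutes, 240.0) == expected

    def test_negative_minutes_rejected(self):
        with pytest.raises(ValidationError):
            isolation_component(-1.0, 240.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(m1=st.floats(0, 600), m2=st.floats(0, 600))
    def test_non_decreasing_in_minutes(self, m1, m2):
        lo, hi = sorted((m1, m2))
        assert isolation_component(lo, 240.0) <= isolation_component(hi, 240.0)


class TestScaleSubscores:
    def test_max_mode_proportional(self):
        assert scale_subscores({"A": 0.18, "B": 0.09}, "max") == {"A": 1.0, "B": 0.5}

    def test_none_mode_identity(self):
        vals = {"A": 0.42, "B": 0.51}
        assert scale_subscores(vals, "none") == vals

    def test_none_mode_clips(self):
        assert scale_subscores({"A": 1.7, "B": -0.5}, "none") == {"A": 1.0, "B": 0.0}

    def test_minmax_endpoints(self):
        got = scale_subscores({"A": 5, "B": 3, "C": 1}, "minmax")
        assert got == {"A": 1.0, "B": 0.5, "C": 0.0}

    def test_degenerate_cases_score_zero(self):
        assert scale_subscores({"A": 0, "B": 0}, "max") == {"A": 0.0, "B": 0.0}
        assert scale_subscores({"A": 4.0}, "minmax") == {"A": 0.0}

    def test_negative_under_max_rejected(self):
        with pytest.raises(ValidationError):
            scale_subscores({"A": -0.1, "B": 0.3}, "max")

    def test_max_mode_attains_one(self):
        got = scale_subscores({"A": 0.3, "B": 0.7, "C": 0.7}, "max")
        assert max(got.values()) == 1.0


class TestVandixScore:
    REF = {
        "C3": (0.2, 0.05, 0.10, 60000.0, 0.8, 0.60, 0.1),
        "C4": (0.4, 0.10, 0.20, 40000.0, 0.6, 0.50, 0.2),
        "C5": (0.3, 0.10, 0.15, 50000.0, 0.7, 0.55, 0.2),
    }

    @pytest.mark.parametrize("cid", ["C3", "C4", "C5"])
    def test_hand_computed_fixture(self, cid):
        got = vandix_score(self.REF[cid], self.REF, mode="max")
        assert got == pytest.approx(LINE_EXPECTATION["vandix_score"][cid], abs=1e-12)

    def test_maximum_deprivation_scores_one_under_minmax(self):
        ref = {
            "worst": (0.9, 0.5, 0.6, 10000.0, 0.1, 0.2, 0.9),
            "best": (0.1, 0.05, 0.05, 90000.0, 0.95, 0.9, 0.1),
        }
        assert vandix_score(ref["worst"], ref, mode="minmax") == pytest.approx(1.0)
        assert vandix_score(ref["best"], ref, mode="minmax") == pytest.approx(0.0)

    def test_directions_flip_protective_indicators(self):
        ref = {"A": (0.0,) * 7, "B": (1.0,) * 7}
        all_deprivation = vandix_score(ref["B"], ref, directions=[False] * 7, mode="max")
        all_protective = vandix_score(ref["B"], ref, directions=[True] * 7, mode="max")
        assert all_deprivation == pytest.approx(1.0)
        assert all_protective == pytest.approx(0.0)

    def test_result_always_in_unit_interval(self):
        for cid in self.REF:
            for mode in ("max", "minmax", "none"):
                ref = {k: tuple(min(v, 1.0) for v in vals) for k, vals in self.REF.items()} \
                    if mode == "none" else self.REF
                assert 0.0 <= vandix_score(ref[cid], ref, mode=mode) <= 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            vandix_score((0.1,) * 7, {}, mode="max")


class TestPcixVulnerability:
    @pytest.mark.parametrize(
        "sub,expected",
        [
            (PcixSubscores(0.11, 0.49, 0.09, 0.47), 0.29),  # Goderich
            (PcixSubscores(0.08, 0.43, 0.08, 0.49), 0.27),  # Perth
            (PcixSubscores(0.0, 0.0, 0.0, 0.0), 0.0),
            (PcixSubscores(1.0, 1.0, 1.0, 1.0), 1.0),
        ],
    )
    def test_mean_of_four(self, sub, expected):
        assert pcix_vulnerability(sub) == pytest.approx(expected)


class TestPhysicianSupply:
    @pytest.mark.parametrize(
        "pop,fp,expected",
        [
            (13070, 10, True),    # exactly 1307 per physician: inclusive
            (13071, 10, False),
            (5000, 0, False),
            (0, 0, True),
            (1307, 1, True),
        ],
    )
    def test_inclusive_ratio_benchmark(self, pop, fp, expected):
        assert physician_supply_adequate(pop, fp, 1307.0) is expected


class TestReadinessComponent:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            (ReadinessFlags(False, False, True, True, False), 0.4),  # Kapuskasing
            (ReadinessFlags(True, True, True, True, True), 1.0),     # Parry Sound
            (ReadinessFlags(False, False, False, False, False), 0.0),
            (ReadinessFlags(True, False, False, False, False), 0.2),
        ],
    )
    def test_point_two_per_yes(self, flags, expected):
        assert readiness_component(flags) == expected

    def test_unresolved_physician_flag_rejected(self):
        with pytest.raises(ValidationError):
            readiness_component(ReadinessFlags(True, True, True, None, True))

    def test_score_is_exact_multiple_of_fifth(self):
        for k in range(6):
            flags = ReadinessFlags(*(i < k for i in range(5)))
            assert readiness_component(flags) in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
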