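"""Sector means, normative models, deviation maps, MD/PSD, report document."""

import json
import math

import numpy as np
import pytest

from conftest import make_flat_observer
from perisim.calibration import default_curve
from perisim.errors import (
    DegenerateCohortError,
    IncompleteResultError,
    PatternMismatchError,
    ReportSchemaError,
)
from perisim.observer import make_cohort, sensitivity_at
from perisim.patterns import SectorAssignment, assign_sectors, build_pattern
from perisim.reports import (
    NormativeModel,
    build_normative,
    deviation_maps,
    global_indices,
    grayscale_map,
    render_report,
    sector_means,
    validate_report,
)
from perisim.session import SessionConfig, run_session


def toy_sectors(n):
    quads = ["ST", "SN", "IN", "IT"]
    return {i: SectorAssignment(quadrant=quads[i % 4],
                                region="central" if i % 2 else "pericentral")
            for i in range(n)}


class TestSectorMeans:
    def test_constant_field(self, t24):
        sectors = assign_sectors(t24, "OD")
        th = {l.id: 32.0 for l in t24.locations}
        s = sector_means(th, sectors)
        for name in ("ST", "SN", "IN", "IT", "global", "central", "pericentral"):
            assert s.means[name] == 32.0 and s.sds[name] == 0.0

    def test_toy_arithmetic(self):
        th = {0: 34.0, 1: 30.0, 2: 34.0, 3: 30.0}
        s = sector_means(th, toy_sectors(4))
        assert s.means["global"] == 32.0
        assert s.sds["global"] == 2.0  # population SD

    def test_missing_threshold_rejected(self, t24):
        sectors = assign_sectors(t24, "OD")
        th = {l.id: 32.0 for l in t24.locations}
        th.popitem()
        with pytest.raises(IncompleteResultError):
            sector_means(th, sectors)

    def test_global_mean_is_weighted_quadrant_combination(self, t24, rng):
        sectors = assign_sectors(t24, "OD")
        th = {l.id: float(rng.integers(10, 40)) for l in t24.locations}
        s = sector_means(th, sectors)
        combo = sum(s.means[q] * s.counts[q] for q in ("ST", "SN", "IN", "IT"))
        assert s.means["global"] == pytest.approx(combo / 50)

    def test_simulated_healthy_central_above_pericentral(self):
        """Measured (not just true) sensitivity preserves the hill ordering."""
        rng = np.random.default_rng(8)
        cohort = make_cohort(20, "healthy", rng)
        pat = build_pattern("T-24", "OD")
        sectors = assign_sectors(pat, "OD")
        curve = default_curve()
        ok = 0
        for i, obs in enumerate(cohort):
            res = run_session(SessionConfig(eyes=("OD",), seed=1000 + i),
                              {"OD": obs}, curve)
            s = sector_means(res.thresholds["OD"], sectors)
            ok += s.means["central"] > s.means["pericentral"]
        assert ok >= 19  # >= 95%


class TestNormativeModel:
    def test_two_member_mean_sd(self, t24):
        th_a = {l.id: 30.0 for l in t24.locations}
        th_b = {l.id: 34.0 for l in t24.locations}
        model = build_normative([th_a, th_b], t24)
        lid = t24.locations[0].id
        assert model.means[lid] == 32.0
        assert model.sds[lid] == 2.0

    def test_degenerate_cohort_rejected(self, t24):
        th = {l.id: 30.0 for l in t24.locations}
        with pytest.raises(DegenerateCohortError):
            build_normative([th, dict(th)], t24)

    def test_too_small_cohort_rejected(self, t24):
        with pytest.raises(DegenerateCohortError):
            build_normative([{l.id: 30.0 for l in t24.locations}], t24)

    def test_pattern_mismatch_rejected(self, t24, t10):
        th24 = {l.id: 30.0 for l in t24.locations}
        th10 = {l.id: 31.0 for l in t10.locations}
        with pytest.raises(PatternMismatchError):
            build_normative([th24, th10], t24)

    def test_recovers_generator_means(self):
        """Model means from simulated sessions track the generating surfaces."""
        rng = np.random.default_rng(21)
        cohort = make_cohort(60, "healthy", rng)
        pat = build_pattern("T-24", "OD")
        curve = default_curve()
        ths = [run_session(SessionConfig(eyes=("OD",), seed=2000 + i),
                           {"OD": obs}, curve).thresholds["OD"]
               for i, obs in enumerate(cohort)]
        model = build_normative(ths, pat)
        true_means = {
            l.id: float(np.mean([sensitivity_at(o.surface, l.x, l.y)
                                 for o in cohort]))
            for l in pat.locations
        }
        devs = np.array([model.means[lid] - true_means[lid] for lid in true_means])
        bias = float(devs.mean())
        # last-seen estimator sits just below the continuous sensitivity
        assert -1.5 <= bias <= 0.0
        assert float(np.max(np.abs(devs - bias))) <= 1.0

    def test_json_round_trip(self, t24):
        th_a = {l.id: 30.0 + (l.id % 3) for l in t24.locations}
        th_b = {l.id: 34.0 - (l.id % 2) for l in t24.locations}
        model = build_normative([th_a, th_b], t24, provenance={"cohort_size": 2})
        restored = NormativeModel.from_json(model.to_json())
        assert restored == model


def flat_norm(pattern, mean=32.0, sd=2.0):
    return NormativeModel(
        pattern_name=pattern.name,
        means={l.id: mean for l in pattern.locations},
        sds={l.id: sd for l in pattern.locations},
    )


class TestDeviationMaps:
    def test_normative_field_gives_zero_maps(self, t24):
        norm = flat_norm(t24)
        th = {l.id: 32.0 for l in t24.locations}
        maps = deviation_maps(th, norm)
        assert all(v == 0.0 for v in maps.total_deviation.values())
        assert all(v == 0.0 for v in maps.pattern_deviation.values())
        assert all(g == ">=5%" for g in maps.grades.values())

    def test_uniform_depression_absorbed_by_general_height(self, t24):
        norm = flat_norm(t24)
        th = {l.id: 27.0 for l in t24.locations}
        maps = deviation_maps(th, norm)
        assert all(v == pytest.approx(-5.0) for v in maps.total_deviation.values())
        assert maps.general_height == pytest.approx(-5.0)
        assert all(abs(v) < 1e-9 for v in maps.pattern_deviation.values())

    def test_focal_scotoma_survives_pattern_deviation(self):
        """On a toy 10-location grid, a single deep defect stays in PD."""
        from perisim.patterns import FieldLocation, TestPattern
        locs = tuple(FieldLocation(id=i, x=3.0 + 6 * (i % 5), y=3.0 + 6 * (i // 5))
                     for i in range(10))
        pat = TestPattern(name="toy", eye="OD", spacing=6.0, locations=locs,
                          anchor_ids=(0, 1, 2, 3))
        norm = flat_norm(pat)
        th = {i: 32.0 for i in range(10)}
        th[7] = 22.0
        maps = deviation_maps(th, norm)
        assert maps.general_height == 0.0  # k = 1 -> best location
        assert maps.pattern_deviation[7] == pytest.approx(-10.0)
        assert all(maps.pattern_deviation[i] == 0.0 for i in range(10) if i != 7)
        assert maps.grades[7] == "<0.5%"

    def test_general_height_is_seventh_best_on_t24(self, t24):
        norm = flat_norm(t24)
        th = {l.id: 32.0 - l.id * 0.1 for l in t24.locations}  # distinct TDs
        maps = deviation_maps(th, norm)
        assert maps.general_height == pytest.approx(
            sorted(maps.total_deviation.values(), reverse=True)[6])

    def test_coverage_gap_rejected(self, t24, t10):
        with pytest.raises(PatternMismatchError):
            deviation_maps({l.id: 30.0 for l in t10.locations}, flat_norm(t24))


class TestGlobalIndices:
    def test_zero_field(self, t24):
        norm = flat_norm(t24)
        maps = deviation_maps({l.id: 32.0 for l in t24.locations}, norm)
        idx = global_indices(maps, norm)
        assert idx.md == 0.0 and idx.psd == 0.0

    @pytest.mark.parametrize("d", [1.0, 5.0, 12.5])
    def test_uniform_depression_identity(self, t24, d):
        norm = flat_norm(t24)
        maps = deviation_maps({l.id: 32.0 - d for l in t24.locations}, norm)
        idx = global_indices(maps, norm)
        assert idx.md == pytest.approx(-d, abs=1e-9)
        assert idx.psd == pytest.approx(0.0, abs=1e-9)

    def test_toy_weighted_arithmetic(self):
        """Hand-frozen: SDs {1,2,2}, TD {-2,0,0} -> MD -4/3, PSD sqrt(8/9)."""
        norm = NormativeModel(pattern_name="toy",
                              means={0: 30.0, 1: 30.0, 2: 30.0},
                              sds={0: 1.0, 1: 2.0, 2: 2.0})
        from perisim.reports import DeviationMaps
        maps = DeviationMaps(total_deviation={0: -2.0, 1: 0.0, 2: 0.0},
                             pattern_deviation={}, general_height=0.0, grades={})
        idx = global_indices(maps, norm)
        assert idx.md == pytest.approx(-4.0 / 3.0)
        assert idx.psd == pytest.approx(math.sqrt(8.0 / 9.0))

    def test_md_linear_psd_shift_invariant(self, t24, rng):
        norm = flat_norm(t24)
        th = {l.id: float(rng.integers(20, 40)) for l in t24.locations}
        base = global_indices(deviation_maps(th, norm), norm)
        shifted = global_indices(
            deviation_maps({k: v + 3.0 for k, v in th.items()}, norm), norm)
        assert shifted.md == pytest.approx(base.md + 3.0, abs=1e-9)
        assert shifted.psd == pytest.approx(base.psd, abs=1e-9)

    def test_pd_invariant_under_constant_shift(self, t24, rng):
        norm = flat_norm(t24)
        th = {l.id: float(rng.integers(20, 40)) for l in t24.locations}
        pd0 = deviation_maps(th, norm).pattern_deviation
        pd1 = deviation_maps({k: v + 4.0 for k, v in th.items()}, norm).pattern_deviation
        for lid in pd0:
            assert pd1[lid] == pytest.approx(pd0[lid], abs=1e-9)


class TestGrayscale:
    @pytest.mark.parametrize("th,expected", [(0, 0), (4, 0), (49, 9), (45, 9),
                                             (12, 2), (33, 6)])
    def test_five_db_bins(self, th, expected):
        assert grayscale_map({0: th})[0] == expected


@pytest.fixture(scope="module")
def result():
    observers = {e: make_flat_observer(peak=32.0, sigma=1.0, eye=e)
                 for e in ("OD", "OS")}
    return run_session(SessionConfig(seed=17), observers, default_curve())


class TestReportDocument:

    def test_required_fields_present(self, result):
        doc = render_report(result, metadata={"name": "Test Subject",
                                              "dob": "1990-01-01"})
        assert {"name", "dob", "gender", "test_id", "exam_date", "test_time",
                "strategy"} <= set(doc)
        for eye in ("OD", "OS"):
            assert {"fixation_losses", "false_positives", "false_negatives",
                    "md", "psd", "thresholds", "grayscale"} <= set(doc["per_eye"][eye])

    def test_no_normative_model_flags_and_omits_deviations(self, result):
        doc = render_report(result, metadata={})
        assert doc["normative"] == "none"
        assert "total_deviation" not in doc["per_eye"]["OD"]
        assert doc["per_eye"]["OD"]["md"] is None

    def test_normative_model_adds_deviations(self, result, t24):
        doc = render_report(result, metadata={}, norm_model=flat_norm(t24))
        assert doc["normative"] == "simulated"
        for eye in ("OD", "OS"):
            sec = doc["per_eye"][eye]
            assert len(sec["total_deviation"]) == 50
            assert sec["md"] is not None and sec["psd"] is not None

    def test_schema_violation_detected(self, result):
        doc = render_report(result, metadata={})
        del doc["strategy"]
        with pytest.raises(ReportSchemaError):
            validate_report(doc)

    def test_report_is_json_serializable(self, result, t24):
        sectors = {e: assign_sectors(build_pattern("T-24", e), e)
                   for e in ("OD", "OS")}
        doc = render_report(result, metadata={}, norm_model=flat_norm(t24),
                            sectors_by_eye=sectors)
        json.dumps(doc)
        assert "sector_means" in doc["per_eye"]["OD"]
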