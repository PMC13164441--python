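"""Calibration of the pixel models and synthetic cohort generation."""

import json
import math

import numpy as np
import pytest

from nccthist import (
    ANCHOR_TIMES,
    BG_TEMPLATE,
    CORTICAL_TEMPLATE,
    CohortConfig,
    HistogramSpec,
    area_ok,
    build_histogram,
    calibrate_entropy_pmf,
    calibrate_joint_pmf,
    calibrate_shape_pmf,
    cohort_metrics_frame,
    cohort_to_trajectories,
    detect_crossover,
    entropy_bits,
    extract_sample,
    gaussian_max_entropy,
    make_case,
    make_cohort,
    metric_set,
    mirror_mask,
    pmf_entropy_bits,
    sample_roi,
)
from nccthist.cohort import _pmf_moments

SPEC = HistogramSpec()


def pmf_checks(pmf, sd=None, entropy=None, tol=1e-4):
    """Independent re-evaluation of a calibrated pmf's moments and entropy."""
    m, sd_hat, _ = _pmf_moments(pmf.probs, SPEC)
    h_hat = pmf_entropy_bits(pmf.probs)
    assert sd_hat == pytest.approx(pmf.achieved_sd, abs=1e-12)
    if sd is not None:
        assert sd_hat == pytest.approx(sd, abs=tol)
    if entropy is not None:
        assert h_hat == pytest.approx(entropy, abs=tol)


class TestEntropyCalibration:
    def test_target_hit_to_1e6_bits(self):
        pmf = calibrate_entropy_pmf(4.34, 26.71)
        assert pmf_entropy_bits(pmf.probs) == pytest.approx(4.34, abs=1e-6)

    def test_sigma_matches_gaussian_closed_form(self):
        # 0.5·log2(2πeσ²) = 4.415  ⇒  σ ≈ 5.16
        pmf = calibrate_entropy_pmf(4.415, 26.71)
        assert pmf.params["sigma"] == pytest.approx(5.16, abs=0.02)

    def test_small_target_concentrates_mass(self):
        pmf = calibrate_entropy_pmf(0.3, 26.71)
        assert pmf.probs.max() > 0.9

    def test_unreachable_targets_rejected(self):
        with pytest.raises(ValueError, match="uniform limit"):
            calibrate_entropy_pmf(math.log2(100), 26.71)
        with pytest.raises(ValueError):
            calibrate_entropy_pmf(0.0, 26.71)


class TestJointCalibration:
    @pytest.mark.parametrize("sd,ent", [(5.16, 4.34), (3.94, 3.99)])
    def test_region_targets_hit_jointly(self, sd, ent):
        pmf = calibrate_joint_pmf(sd, ent, 26.71)
        pmf_checks(pmf, sd=sd, entropy=ent)

    def test_gaussian_bound_feasibility(self):
        h_max = gaussian_max_entropy(3.94, 25.93)
        assert h_max == pytest.approx(4.025, abs=5e-3)  # above the 3.99 target
        with pytest.raises(ValueError, match="Gaussian maximum"):
            calibrate_joint_pmf(1.0, 4.34, 26.71)

    def test_target_at_bound_reduces_to_single_gaussian(self):
        h_max = gaussian_max_entropy(5.16, 26.71)
        pmf = calibrate_joint_pmf(5.16, h_max, 26.71)
        assert pmf.params["u"] == pytest.approx(0.0, abs=1e-6)
        pmf_checks(pmf, sd=5.16, entropy=h_max)

    @pytest.mark.parametrize("kurt", [-0.6, 0.0, 0.8])
    def test_kurtosis_degree_of_freedom(self, kurt):
        pmf = calibrate_shape_pmf(5.16, 4.34, kurt, 26.71)
        pmf_checks(pmf, sd=5.16, entropy=4.34)
        assert pmf.achieved_kurtosis == pytest.approx(kurt, abs=0.05)
        assert not pmf.params["clipped_kurtosis"]

    def test_infeasible_kurtosis_is_clipped_not_fatal(self):
        # near the Gaussian bound there is no entropy budget for a strongly
        # negative kurtosis; SD and entropy still bind exactly
        h_near = gaussian_max_entropy(5.16, 26.71) - 0.005
        pmf = calibrate_shape_pmf(5.16, h_near, -1.2, 26.71)
        pmf_checks(pmf, sd=5.16, entropy=h_near)
        assert pmf.params["clipped_kurtosis"]
        assert pmf.achieved_kurtosis > -1.2


class TestSampleROI:
    def test_law_of_large_numbers_recovery(self):
        pmf = calibrate_joint_pmf(5.16, 4.34, 26.71)
        s = sample_roi(pmf, 100_000, seed=11)
        ms = metric_set(s, SPEC)
        # within-bin jitter inflates the sample SD by ~bin²/12
        assert ms.sd == pytest.approx(math.sqrt(5.16**2 + 1 / 12), abs=0.03)
        assert ms.entropy == pytest.approx(4.34, abs=0.02)
        assert ms.mean_hu == pytest.approx(26.71, abs=0.05)

    def test_seeded_reproducibility(self):
        pmf = calibrate_joint_pmf(3.94, 3.99, 25.93)
        a = sample_roi(pmf, 1000, seed=5)
        b = sample_roi(pmf, 1000, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_single_pixel_inside_support(self):
        pmf = calibrate_joint_pmf(3.94, 3.99, 25.93)
        s = sample_roi(pmf, 1, seed=2)
        assert SPEC.hu_min <= s.values[0] <= SPEC.hu_max

    def test_rebinned_sample_reproduces_pmf_draws(self):
        """In-bin jitter must never move a pixel across a bin edge."""
        pmf = calibrate_joint_pmf(5.16, 4.34, 26.71)
        s = sample_roi(pmf, 20_000, seed=9)
        h = build_histogram(s, SPEC)
        assert entropy_bits(h) == pytest.approx(pmf.achieved_entropy, abs=0.05)
        assert h.n_total == 20_000


class TestMakeCase:
    def test_planted_crossover_is_detectable_near_94_min(self):
        cfg = CohortConfig(seed=3, pixels_per_roi=20_000)
        case = make_case(CORTICAL_TEMPLATE, cfg, 101, case_id="x", crossover=True)
        tr = cohort_like_trajectory(case)
        ev = detect_crossover(tr)
        assert ev.occurred
        assert ev.time_min == pytest.approx(94.0, abs=10.0)
        assert ev.time_min == pytest.approx(case.truth["crossover_time"], abs=4.0)

    def test_bg_case_never_crosses(self):
        cfg = CohortConfig(seed=3, pixels_per_roi=20_000)
        case = make_case(BG_TEMPLATE, cfg, 77, case_id="b")
        assert not detect_crossover(cohort_like_trajectory(case)).occurred

    def test_scan_targets_follow_template_anchors(self):
        cfg = CohortConfig(seed=5, pixels_per_roi=1000)
        case = make_case(
            CORTICAL_TEMPLATE, cfg, 55, sd_target=5.16, entropy_target=4.34
        )
        for scan in case.scans:
            t = scan.time_min
            expect_sd = 5.16 * CORTICAL_TEMPLATE.sd_at(t) / 5.16
            assert scan.truth["sd_target"] == pytest.approx(expect_sd, rel=1e-9)

    def test_rasterized_phantom_contracts(self):
        cfg = CohortConfig(seed=8, pixels_per_roi=600, rasterize=True, baseline_only=True)
        case = make_case(CORTICAL_TEMPLATE, cfg, 21, case_id="r")
        scan = case.scans[0]
        plane, lmask, cmask = scan.plane, scan.lesion_mask, scan.control_mask
        assert area_ok(lmask, plane.spacing_mm)  # ≥ 1 cm²
        mid = plane.midline_col
        mirrored = mirror_mask(lmask, mid)
        assert np.array_equal(mirrored.mask, cmask.mask)
        back = mirror_mask(mirrored, mid)
        assert np.array_equal(back.mask, lmask.mask)
        # painted pixels round-trip through extraction
        got = np.sort(extract_sample(plane, lmask).values)
        assert np.allclose(got, np.sort(scan.lesion.values))


def cohort_like_trajectory(case):
    from nccthist import Trajectory, TrajectoryPoint

    pts = tuple(
        TrajectoryPoint(
            time_min=s.time_min,
            lesion=metric_set(s.lesion, SPEC),
            control=metric_set(s.control, SPEC),
        )
        for s in case.scans
    )
    return Trajectory(case_id=case.case_id, region=case.region, points=pts)


@pytest.fixture(scope="module")
def small_cohort():
    return make_cohort(CohortConfig(seed=404, pixels_per_roi=2000))


class TestMakeCohort:

    def test_counts_and_crossover_flags(self, small_cohort):
        regions = [c.region for c in small_cohort.cases]
        assert regions.count("cortical") == 27 and regions.count("bg") == 18
        planted = [c for c in small_cohort.cases if c.crossover_planted]
        assert len(planted) == 9
        assert all(c.region == "cortical" for c in planted)

    def test_manifest_is_deterministic(self):
        a = make_cohort(CohortConfig(seed=77, n_cortical=3, n_bg=2, pixels_per_roi=200))
        b = make_cohort(CohortConfig(seed=77, n_cortical=3, n_bg=2, pixels_per_roi=200))
        assert a.manifest_json() == b.manifest_json()
        json.loads(a.manifest_json())  # JSON-serializable
        c = make_cohort(CohortConfig(seed=78, n_cortical=3, n_bg=2, pixels_per_roi=200))
        assert c.manifest_json() != a.manifest_json()

    def test_scan_count_near_target(self, small_cohort):
        mean_scans = np.mean([len(c.scans) for c in small_cohort.cases])
        assert 4.4 <= mean_scans <= 6.0
        assert min(len(c.scans) for c in small_cohort.cases) >= 3

    def test_stratified_targets_reproduce_group_sd_columns(self, small_cohort):
        for region, template, n in (
            ("cortical", CORTICAL_TEMPLATE, 27),
            ("bg", BG_TEMPLATE, 18),
        ):
            tgts = np.array(
                [c.truth["sd_target"] for c in small_cohort.cases if c.region == region]
            )
            assert tgts.mean() == pytest.approx(template.target_sd, abs=1e-9)
            assert tgts.std(ddof=1) == pytest.approx(
                template.between_subject_sd_of_sd, abs=1e-9
            )

    def test_multi_seed_baseline_recovery(self):
        """Cohort-mean SD/entropy land on the group targets across seeds."""
        for seed in (11, 12, 13):
            cfg = CohortConfig(seed=seed, pixels_per_roi=20_000, baseline_only=True)
            df = cohort_metrics_frame(make_cohort(cfg))
            base = df[df.role == "lesion"]
            cort = base[base.region == "cortical"]
            bg = base[base.region == "bg"]
            assert cort["sd"].mean() == pytest.approx(5.16, abs=0.05)
            assert cort["entropy_bits"].mean() == pytest.approx(4.34, abs=0.05)
            assert bg["sd"].mean() == pytest.approx(3.94, abs=0.05)
            assert bg["entropy_bits"].mean() == pytest.approx(3.99, abs=0.05)

    def test_null_mode_generates_one_population(self):
        cfg = CohortConfig(seed=6, pixels_per_roi=500, null_mode=True, baseline_only=True)
        coh = make_cohort(cfg)
        assert coh.manifest["n_crossover_planted"] == 0
        tgts = {r: [] for r in ("cortical", "bg")}
        for c in coh.cases:
            tgts[c.region].append(c.truth["sd_target"])
        # both labels drawn from the same (basal-ganglia) template
        assert np.mean(tgts["cortical"]) == pytest.approx(np.mean(tgts["bg"]), abs=1e-9)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(seed=1, n_cortical=1)
        with pytest.raises(ValueError):
            CohortConfig(seed=1, crossover_fraction_cortical=1.4)
        with pytest.raises(ValueError):
            CohortConfig(seed=1, scans_per_subject=2.0)
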