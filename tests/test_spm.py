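"""1-D SPM: RM-ANOVA fields, smoothness estimation, RFT thresholds,
cluster inference, and the permutation cross-check."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from gaitcom.errors import DataError, StatisticError
from gaitcom.spm import (SpmDesign, estimate_fwhm, find_clusters,
                         paired_t_field, permutation_oracle, posthoc_paired_t,
                         rft_threshold, rm_anova_field, spm_anova)


def smooth_gaussian_field(rng, shape, fwhm):
    """Unit-variance Gaussian fields with the requested smoothness along the
    last axis (white noise convolved with a Gaussian kernel whose FWHM equals
    the target field FWHM)."""
    sigma = fwhm / math.sqrt(8.0 * math.log(2.0))
    pad = int(6 * sigma)
    x = rng.standard_normal(shape[:-1] + (shape[-1] + 2 * pad,))
    x = gaussian_filter1d(x, sigma, axis=-1)
    return x[..., pad: pad + shape[-1]]


# ---------------------------------------------------------------------------
# statistic fields

def test_identical_conditions_give_zero_F(rng):
    curves = rng.normal(size=(8, 1, 60))
    data = np.repeat(curves, 3, axis=1)
    F, dof, _, degenerate = rm_anova_field(data)
    assert np.allclose(F, 0.0, atol=1e-12)
    assert degenerate  # zero residual variance flagged
    assert dof == (2, 14)


def test_pure_offset_without_noise_is_flagged_degenerate():
    base = np.tile(np.linspace(0, 1, 50), (6, 1))
    data = np.stack([base, base, base + 1.0], axis=1)
    F, _, _, degenerate = rm_anova_field(data)
    assert degenerate
    assert np.all(np.isinf(F))


def test_single_node_F_matches_hand_coded_sums_of_squares():
    """4 subjects x 3 conditions toy table, decomposed by hand."""
    table = np.array([
        [3.1, 2.9, 4.0],
        [2.5, 2.7, 3.6],
        [3.8, 3.3, 4.9],
        [2.9, 3.0, 3.5],
    ])
    grand = table.mean()
    ss_cond = 4 * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_subj = 3 * ((table.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((table - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    f_ref = (ss_cond / 2) / (ss_err / 6)
    F, dof, _, _ = rm_anova_field(table[:, :, None])
    assert abs(F[0] - f_ref) < 1e-10
    assert dof == (2, 6)


def test_t_squared_equals_F_for_two_conditions(rng):
    data = rng.normal(size=(10, 2, 40))
    F, _, _, _ = rm_anova_field(data)
    t, _, _, _ = paired_t_field(data)
    assert np.max(np.abs(t ** 2 - F)) < 1e-9
    assert np.all(F >= 0.0)


# ---------------------------------------------------------------------------
# smoothness and thresholds

def test_fwhm_estimate_on_white_noise(rng):
    est = [estimate_fwhm(rng.standard_normal((10, 101))) for _ in range(1000)]
    assert 0.8 <= float(np.median(est)) <= 1.5


def test_fwhm_estimate_on_known_smooth_field(rng):
    est = [estimate_fwhm(smooth_gaussian_field(rng, (20, 101), 10.0)) for _ in range(50)]
    assert abs(np.mean(est) - 10.0) <= 1.5


def test_fwhm_constant_residuals_flag_infinite_smoothness():
    assert math.isinf(estimate_fwhm(np.ones((5, 101))))


def test_rft_threshold_zero_resels_is_plain_quantile():
    for dof, stat, q in [((2, 30), "F", stats.f.isf(0.05, 2, 30)),
                         ((1, 15), "t", stats.t.isf(0.05, 15))]:
        assert rft_threshold(0.05, dof, 0.0, stat) == pytest.approx(q, abs=1e-10)


def test_rft_threshold_monotone_in_resels():
    thresholds = [rft_threshold(0.05, (2, 30), r, "F") for r in (0.0, 1.0, 5.0, 20.0)]
    assert all(a < b for a, b in zip(thresholds, thresholds[1:]))


def test_rft_threshold_alpha_validation():
    with pytest.raises(StatisticError):
        rft_threshold(0.0, (2, 30), 5.0, "F")


def test_familywise_type_one_error_calibrated(rng):
    """Null smooth data (16 x 3 x 101, FWHM 10): family-wise rejection rate
    at alpha = 0.05 over 1000 simulations must sit near the nominal level."""
    nsim, rejections = 1000, 0
    for _ in range(nsim):
        data = smooth_gaussian_field(rng, (16, 3, 101), 10.0)
        F, dof, resid, _ = rm_anova_field(data)
        fwhm = estimate_fwhm(resid)
        threshold = rft_threshold(0.05, dof, 100.0 / fwhm, "F")
        rejections += F.max() > threshold
    assert 0.03 <= rejections / nsim <= 0.07


# ---------------------------------------------------------------------------
# clusters

def test_find_clusters_empty_and_constructed():
    field = np.zeros(101)
    assert find_clusters(field, 1.0) == []
    field[10:21] = 2.0
    field[70:76] = 3.0
    clusters = find_clusters(field, 1.0)
    assert [(c.start_node, c.end_node) for c in clusters] == [(10, 20), (70, 75)]
    assert clusters[0].start_pct == pytest.approx(10.0)
    assert clusters[1].end_pct == pytest.approx(75.0)


def test_find_clusters_matches_brute_force_scan(rng):
    field = rng.normal(size=101)
    threshold = 0.5
    clusters = find_clusters(field, threshold)
    intervals = {(c.start_node, c.end_node) for c in clusters}
    brute = set()
    start = None
    for i, v in enumerate(field):
        if v > threshold and start is None:
            start = i
        if (v <= threshold or i == 100) and start is not None:
            brute.add((start, i if v > threshold else i - 1))
            start = None
    assert intervals == brute


# ---------------------------------------------------------------------------
# omnibus + post-hoc procedures

def test_identical_pair_has_zero_t_and_no_clusters(rng):
    curves = rng.normal(size=(8, 1, 101))
    data = np.concatenate([np.repeat(curves, 2, axis=1), rng.normal(size=(8, 1, 101))], axis=1)
    design = SpmDesign(data)
    res = posthoc_paired_t(design, ("IMU", "ML5"))
    assert np.allclose(res.field, 0.0, atol=1e-12)
    assert res.clusters == []


def test_bonferroni_alpha_for_three_pairwise_comparisons(rng):
    design = SpmDesign(rng.normal(size=(6, 3, 101)), alpha=0.05)
    assert round(design.alpha_posthoc, 3) == 0.017


def test_posthoc_power_for_localized_offset(rng):
    """An offset of twice the residual SD injected into one condition over
    nodes 0-10 must produce an overlapping significant cluster in nearly
    every replicate."""
    hits = 0
    reps = 200
    for _ in range(reps):
        data = smooth_gaussian_field(rng, (16, 3, 101), 10.0)
        data[:, 2, :11] += 2.0
        design = SpmDesign(data)
        res = posthoc_paired_t(design, ("IMU", "CoM"))
        hits += any(c.start_node <= 10 for c in res.clusters)
    assert hits / reps >= 0.90


def test_omnibus_and_posthoc_clusters_overlap_for_single_condition_effect(rng):
    data = smooth_gaussian_field(rng, (16, 3, 101), 10.0)
    data[:, 2, 40:61] += 3.0
    design = SpmDesign(data)
    omnibus = spm_anova(design)
    posthoc = posthoc_paired_t(design, ("IMU", "CoM"))
    def covers(clusters):
        return any(c.start_node <= 60 and c.end_node >= 40 for c in clusters)
    assert covers(omnibus.clusters)
    assert covers(posthoc.clusters)


def test_degenerate_design_yields_no_spurious_clusters(rng):
    curves = rng.normal(size=(6, 1, 101))
    data = np.repeat(curves, 3, axis=1)
    design = SpmDesign(data)
    with pytest.warns(UserWarning, match="degenerate"):
        res = spm_anova(design)
    assert res.degenerate
    assert res.clusters == []


# ---------------------------------------------------------------------------
# permutation oracle

def test_permutation_threshold_is_quantile_and_deterministic(rng):
    data = smooth_gaussian_field(rng, (12, 3, 101), 8.0)
    design = SpmDesign(data)
    a = permutation_oracle(design, n_perm=300, seed=5)
    b = permutation_oracle(design, n_perm=300, seed=5)
    assert a.threshold == b.threshold
    assert a.threshold == pytest.approx(np.quantile(a.max_distribution, 0.95))
    assert np.array_equal(a.max_distribution, b.max_distribution)


def test_rft_threshold_agrees_with_permutation_on_smooth_null(rng):
    data = smooth_gaussian_field(rng, (16, 3, 101), 10.0)
    design = SpmDesign(data)
    res = spm_anova(design)
    perm = permutation_oracle(design, n_perm=1000, seed=3)
    assert abs(res.threshold - perm.threshold) / perm.threshold < 0.10


def test_design_validation(rng):
    with pytest.raises(DataError):
        SpmDesign(rng.normal(size=(1, 3, 101)))
    bad = rng.normal(size=(4, 3, 101))
    bad[0, 0, 0] = np.nan
    with pytest.raises(DataError):
        SpmDesign(bad)
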