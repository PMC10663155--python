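"""Preprocessing-chain behavior: centroiding, ppm binning, spatial
filtering, recalibration, consensus filtering, normalization and batch
correction — each against hand-computable or planted expectations."""

import numpy as np
import pandas as pd
import pytest

from ioncoloc.containers import MSIRun
from ioncoloc.peakflow import (
    build_representative_list,
    centroid_spectrum,
    combat_correct,
    consensus_filter,
    filter_scattered_ions,
    match_across_runs,
    match_peaks_within_run,
    median_scale_normalize,
    preprocess_runs,
    recalibrate_masses,
)
from ioncoloc.synthio import SynthConfig, generate_biclonal_runs


def _run_from_peaks(peaks, shape=(1, None), genotype=None):
    """Tiny MSIRun where each entry of ``peaks`` is one pixel's
    (mz_array, intensity_array)."""
    n = len(peaks)
    rows, cols = (1, n) if shape == (1, None) else shape
    return MSIRun(
        run_id="r",
        n_rows=rows,
        n_cols=cols,
        peaks_mz=[np.asarray(m, dtype=float) for m, _ in peaks],
        peaks_intensity=[np.asarray(i, dtype=float) for _, i in peaks],
        tissue_id=np.array(["t"] * n, dtype=object),
        genotype=np.array(genotype or ["high"] * n),
    )


# ---------------------------------------------------------------------- centroiding

def test_flat_spectrum_yields_no_peaks():
    mz = np.linspace(100, 101, 200)
    c_mz, c_int = centroid_spectrum(mz, np.full(200, 7.0))
    assert c_mz.size == 0


def test_single_gaussian_centroids_at_apex():
    mz = np.linspace(99.9, 100.1, 401)
    intensity = 100 * np.exp(-((mz - 100.0) ** 2) / (2 * 0.01**2))
    c_mz, c_int = centroid_spectrum(mz, intensity)
    assert c_mz.size == 1
    assert abs(c_mz[0] - 100.0) <= np.diff(mz)[0]
    assert c_int[0] == pytest.approx(100.0, rel=1e-3)


def test_prominence_cutoff_is_strictly_greater_than_five():
    # two triangular peaks with prominences 4 and 6 on a zero baseline
    mz = np.arange(20, dtype=float) + 100
    intensity = np.zeros(20)
    intensity[4:7] = [2, 4, 2]
    intensity[13:16] = [3, 6, 3]
    c_mz, _ = centroid_spectrum(mz, intensity, prominence_min=5)
    assert c_mz.size == 1
    assert 112 < c_mz[0] < 116


def test_empty_profile_gives_empty_list():
    c_mz, c_int = centroid_spectrum(np.empty(0), np.empty(0))
    assert c_mz.size == 0 and c_int.size == 0


# ---------------------------------------------------------------------- intra-run matching

def test_peaks_within_50ppm_merge_into_one_feature():
    run = _run_from_peaks([([100.0000], [1.0]), ([100.0030], [2.0])])
    mz, M = match_peaks_within_run(run, tol_ppm=50)
    assert mz.size == 1  # 30 ppm apart
    assert M.shape == (2, 1)


def test_peaks_100ppm_apart_stay_separate():
    run = _run_from_peaks([([100.0000], [1.0]), ([100.0100], [2.0])])
    mz, M = match_peaks_within_run(run, tol_ppm=50)
    assert mz.size == 2


def test_highest_intensity_wins_within_a_window():
    run = _run_from_peaks([([100.0000, 100.0020], [10.0, 50.0])])
    mz, M = match_peaks_within_run(run, tol_ppm=50)
    assert mz.size == 1
    assert M[0, 0] == 50.0


def test_binning_is_pixel_order_independent():
    rng = np.random.default_rng(0)
    base = [([100.0 + 1e-4 * rng.integers(0, 5), 200.0], [1.0, 2.0])
            for _ in range(6)]
    run = _run_from_peaks(base)
    mz1, M1 = match_peaks_within_run(run)
    perm = rng.permutation(6)
    run2 = _run_from_peaks([base[i] for i in perm])
    mz2, M2 = match_peaks_within_run(run2)
    np.testing.assert_allclose(mz1, mz2)
    np.testing.assert_allclose(M1[perm], M2)


# ---------------------------------------------------------------------- scattered-ion filter

def _blob_matrix(n_pixels_on, shape=(10, 10)):
    img = np.zeros(shape)
    placed = 0
    for r in range(shape[0]):
        for c in range(shape[1]):
            if placed < n_pixels_on:
                img[r, c] = 5.0
                placed += 1
    return img.reshape(-1, 1)


def test_eight_pixel_blob_dropped_nine_kept():
    tissue = np.ones(100, dtype=bool)
    keep8 = filter_scattered_ions(_blob_matrix(8), (10, 10), tissue)
    keep9 = filter_scattered_ions(_blob_matrix(9), (10, 10), tissue)
    assert not keep8[0]
    assert keep9[0]


def test_feature_only_off_tissue_dropped():
    m = _blob_matrix(12)
    tissue = np.zeros(100, dtype=bool)
    tissue[50:] = True  # presence sits in the first rows, off tissue
    keep = filter_scattered_ions(m, (10, 10), tissue)
    assert not keep[0]


# ---------------------------------------------------------------------- recalibration

def _shifted_run(shift_fn, n_pix=40, seed=0):
    rng = np.random.default_rng(seed)
    refs = np.array([150.0, 400.0, 700.0])
    peaks = []
    for _ in range(n_pix):
        extra = np.sort(rng.uniform(200, 650, 3))
        mzs = np.sort(np.concatenate([refs, extra]))
        mzs_obs = mzs * (1 + shift_fn(mzs) * 1e-6)
        peaks.append((mzs_obs, np.full(mzs.size, 10.0)))
    return _run_from_peaks(peaks), refs


def test_constant_30ppm_shift_recovered():
    run, refs = _shifted_run(lambda m: np.full_like(m, 30.0))
    out = recalibrate_masses(run, refs)
    errs = [np.min(np.abs(m[None, :] - refs[:, None]) / refs[:, None] * 1e6, axis=1)
            for m in out.peaks_mz]
    assert np.median(np.concatenate(errs)) < 5.0


def test_mass_dependent_shift_recovered():
    run, refs = _shifted_run(lambda m: 10.0 + 0.03 * m)
    out = recalibrate_masses(run, refs)
    errs = [np.min(np.abs(m[None, :] - refs[:, None]) / refs[:, None] * 1e6, axis=1)
            for m in out.peaks_mz]
    assert np.median(np.concatenate(errs)) < 5.0


def test_already_calibrated_run_changes_little():
    run, refs = _shifted_run(lambda m: np.zeros_like(m))
    out = recalibrate_masses(run, refs)
    for a, b in zip(run.peaks_mz, out.peaks_mz):
        assert np.max(np.abs(a - b) / a * 1e6) < 1.0


def test_missing_references_error_names_them():
    run, refs = _shifted_run(lambda m: np.zeros_like(m))
    bad_refs = np.array([150.0, 400.0, 999.0])
    with pytest.raises(ValueError, match="999"):
        recalibrate_masses(run, bad_refs)


# ---------------------------------------------------------------------- representative lists & inter-run matching

def test_representative_mean_includes_zeros():
    M = np.array([[0.0], [2.0], [4.0]])
    rep = build_representative_list(M, np.array([100.0]))
    assert rep["mean_intensity"].iloc[0] == 2.0


def test_inter_run_matching_at_20ppm():
    r1 = pd.DataFrame({"mz": [100.0000], "mean_intensity": [1.0]})
    r2_merge = pd.DataFrame({"mz": [100.0015], "mean_intensity": [1.0]})  # 15 ppm
    r2_split = pd.DataFrame({"mz": [100.0030], "mean_intensity": [1.0]})  # 30 ppm
    mz_m, _ = match_across_runs([r1, r2_merge])
    mz_s, _ = match_across_runs([r1, r2_split])
    assert mz_m.size == 1
    assert mz_s.size == 2


def test_single_run_consensus_undefined():
    r1 = pd.DataFrame({"mz": [100.0], "mean_intensity": [1.0]})
    with pytest.raises(ValueError):
        match_across_runs([r1])


def test_consensus_filter_zero_mean_in_any_run_drops():
    mz = np.array([100.0, 200.0])
    means = np.array([[1.0, 0.1], [0.0, 0.1], [2.0, 0.1]])
    keep = consensus_filter(mz, means)
    assert keep.tolist() == [False, True]
    with pytest.raises(ValueError, match="looser"):
        consensus_filter(mz, np.array([[0.0, 0.0], [1.0, 1.0]]))


# ---------------------------------------------------------------------- normalization

def test_median_scaling_hand_example():
    X = np.array([[0.0, 2.0, 4.0, 6.0]])
    out, flagged = median_scale_normalize(X)
    # non-zero median 4; global factor = 4 (single pixel)
    np.testing.assert_allclose(out[0], [0.0, 2.0, 4.0, 6.0])
    assert not flagged.any()


def test_scalar_multiple_pixels_identical_after_normalization():
    X = np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]])
    out, _ = median_scale_normalize(X)
    np.testing.assert_allclose(out[0], out[1])


def test_all_zero_pixel_left_unscaled_and_flagged():
    X = np.array([[0.0, 0.0], [1.0, 2.0]])
    out, flagged = median_scale_normalize(X)
    np.testing.assert_array_equal(out[0], [0.0, 0.0])
    assert flagged.tolist() == [True, False]


# ---------------------------------------------------------------------- batch correction

def test_combat_removes_planted_additive_offset():
    # large batches: empirical-Bayes shrinkage residuals vanish as 1/sqrt(n)
    rng = np.random.default_rng(1)
    X = rng.normal(10.0, 1.0, (200_000, 10))
    batch = np.repeat(["a", "b"], 100_000)
    X[batch == "b"] += 3.0
    out = combat_correct(X, batch)
    pooled_sd = out.std(axis=0)
    gap = np.abs(out[batch == "a"].mean(axis=0) - out[batch == "b"].mean(axis=0))
    assert np.all(gap < 0.01 * pooled_sd)


def test_combat_identity_on_identical_batches():
    rng = np.random.default_rng(2)
    half = rng.normal(5.0, 1.0, (200, 20))
    X = np.vstack([half, half])
    batch = np.repeat(["a", "b"], 200)
    out = combat_correct(X, batch)
    assert np.abs(out - X).max() < 0.2


def test_combat_equalizes_planted_scale_factor():
    rng = np.random.default_rng(3)
    X = rng.normal(0.0, 1.0, (600, 40))
    batch = np.repeat(["a", "b"], 300)
    X[batch == "b"] *= 2.0
    out = combat_correct(X, batch)
    ratio = out[batch == "b"].var(axis=0) / out[batch == "a"].var(axis=0)
    assert np.all((ratio > 0.8) & (ratio < 1.25))
    assert 0.9 < np.median(ratio) < 1.1


def test_combat_preserves_feature_grand_means():
    rng = np.random.default_rng(4)
    X = rng.normal(7.0, 2.0, (300, 25))
    batch = np.repeat(["a", "b", "c"], 100)
    out = combat_correct(X, batch)
    np.testing.assert_allclose(out.mean(axis=0), X.mean(axis=0), atol=0.4)


def test_combat_single_pixel_batch_errors():
    X = np.zeros((3, 4))
    with pytest.raises(ValueError, match="single pixel"):
        combat_correct(X, np.array(["a", "a", "b"]))


# ---------------------------------------------------------------------- end-to-end

def test_pipeline_recovers_planted_features_and_drops_noise(small_feature_table):
    ft, truth = small_feature_table
    planted = truth.features.query("kind == 'module'")
    for mzv in planted["mz"]:
        ppm = np.abs(ft.mz - mzv) / mzv * 1e6
        assert (ppm < 20).sum() == 1
    for mzv in truth.features.query("kind == 'noise'")["mz"]:
        ppm = np.abs(ft.mz - mzv) / mzv * 1e6
        assert not (ppm < 20).any()
    assert list(ft.mz) == sorted(ft.mz)
    assert not (ft.X == 0).all(axis=0).any()


def test_feature_table_csv_round_trip(tmp_path, small_feature_table):
    from ioncoloc.containers import FeatureTable

    ft, _ = small_feature_table
    path = tmp_path / "ft.csv"
    ft.to_csv(path)
    back = FeatureTable.from_csv(path)
    np.testing.assert_allclose(back.X, ft.X, rtol=1e-6)
    assert back.obs["genotype"].tolist() == ft.obs["genotype"].tolist()
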