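"""Multi-run MSI preprocessing.

Turns per-run pixel peak lists into one normalized, batch-corrected,
inter-run-matched feature matrix: centroiding, intra-run peak matching
(50 ppm), scattered-ion filtering (eight-connected blobs < 9 pixels), mass
recalibration against reference ions, representative per-run peak lists,
inter-run matching (20 ppm), consensus zero-mean filtering, median scaling
and empirical-Bayes batch correction with batch = acquisition run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

from .containers import FeatureTable, MSIRun

__all__ = [
    "centroid_spectrum",
    "match_peaks_within_run",
    "filter_scattered_ions",
    "recalibrate_masses",
    "build_representative_list",
    "match_across_runs",
    "consensus_filter",
    "median_scale_normalize",
    "combat_correct",
    "preprocess_runs",
]


# ---------------------------------------------------------------------------
# centroiding

def centroid_spectrum(mz: np.ndarray, intensity: np.ndarray,
                      prominence_min: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Centroid a profile spectrum.

    Local maxima with prominence strictly greater than ``prominence_min``
    are kept (shoulder peaks included); each centroid m/z is the
    intensity-weighted mean over the peak's half-prominence support and the
    reported intensity is the apex height.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.size != intensity.size:
        raise ValueError("m/z and intensity arrays must have the same length")
    if mz.size == 0:
        return np.empty(0), np.empty(0)
    if np.any(np.diff(mz) <= 0):
        raise ValueError("profile m/z must be strictly increasing")
    peaks, props = signal.find_peaks(intensity, prominence=0.0)
    keep = props["prominences"] > prominence_min
    peaks = peaks[keep]
    proms = props["prominences"][keep]
    out_mz, out_int = [], []
    for apex, prom in zip(peaks, proms):
        half = intensity[apex] - 0.5 * prom
        left = apex
        while left > 0 and intensity[left - 1] >= half and intensity[left - 1] <= intensity[left]:
            left -= 1
        right = apex
        n = intensity.size
        while right < n - 1 and intensity[right + 1] >= half and intensity[right + 1] <= intensity[right]:
            right += 1
        sl = slice(left, right + 1)
        w = intensity[sl]
        out_mz.append(float(np.sum(mz[sl] * w) / np.sum(w)))
        out_int.append(float(intensity[apex]))
    order = np.argsort(out_mz)
    return np.asarray(out_mz)[order], np.asarray(out_int)[order]


# ---------------------------------------------------------------------------
# ppm-tolerance binning ("relaxed" matching)

def _gap_split_bins(mz: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Single-linkage gap splitting: a new bin opens where the gap between
    consecutive sorted masses exceeds ``tol_ppm``.  Returns bin ids for the
    sorted input."""
    if mz.size == 0:
        return np.empty(0, dtype=int)
    gaps_ppm = np.diff(mz) / mz[:-1] * 1e6
    return np.concatenate([[0], np.cumsum(gaps_ppm > tol_ppm)])


def match_peaks_within_run(
    run: MSIRun, tol_ppm: float = 50.0
) -> tuple[np.ndarray, np.ndarray]:
    """Group peaks across a run's pixels into common-m/z features.

    All peaks are pooled, sorted by m/z and split into bins wherever
    consecutive masses are more than ``tol_ppm`` apart (deterministic and
    independent of pixel order).  When a pixel contributes several peaks to
    one bin, only the most intense is retrieved.  Returns the run-level
    common m/z values (intensity-weighted bin means) and the pixel x
    feature matrix.
    """
    n_pixels = run.n_pixels
    sizes = [m.size for m in run.peaks_mz]
    if sum(sizes) == 0:
        raise ValueError("run has no peaks")
    all_mz = np.concatenate(run.peaks_mz)
    all_int = np.concatenate(run.peaks_intensity)
    all_pix = np.repeat(np.arange(n_pixels), sizes)
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int, all_pix = all_mz[order], all_int[order], all_pix[order]
    bins = _gap_split_bins(all_mz, tol_ppm)
    n_bins = bins[-1] + 1 if bins.size else 0
    matrix = np.zeros((n_pixels, n_bins))
    # highest intensity wins within (pixel, bin)
    np.maximum.at(matrix, (all_pix, bins), all_int)
    common_mz = np.bincount(bins, weights=all_mz * all_int) / np.bincount(
        bins, weights=all_int
    )
    return common_mz, matrix


# ---------------------------------------------------------------------------
# spatial filtering

def filter_scattered_ions(
    matrix: np.ndarray,
    shape: tuple[int, int],
    tissue_mask: np.ndarray | None = None,
    min_pixels: int = 9,
    connectivity: int = 8,
    min_on_tissue_frac: float = 0.5,
) -> np.ndarray:
    """Boolean keep-mask over features.

    A feature is dropped when the largest ``connectivity``-connected
    component of its presence image (intensity > 0) has fewer than
    ``min_pixels`` pixels, or when less than ``min_on_tissue_frac`` of its
    presence lies on tissue.  When no tissue mask is given it is derived by
    Otsu-thresholding the total ion count image.
    """
    h, w = shape
    n_pixels, n_feat = matrix.shape
    if n_pixels != h * w:
        raise ValueError("matrix rows must cover the full pixel grid")
    if tissue_mask is None:
        tic = matrix.sum(axis=1).reshape(h, w)
        tissue_mask = (tic > threshold_otsu(tic)).reshape(-1)
    tissue_mask = np.asarray(tissue_mask).reshape(-1)
    structure = np.ones((3, 3)) if connectivity == 8 else None
    keep = np.zeros(n_feat, dtype=bool)
    for j in range(n_feat):
        presence = (matrix[:, j] > 0)
        n_present = presence.sum()
        if n_present == 0:
            continue
        labels, n_comp = ndimage.label(presence.reshape(h, w), structure=structure)
        if n_comp == 0:
            continue
        largest = np.bincount(labels.reshape(-1))[1:].max()
        if largest < min_pixels:
            continue
        if presence[tissue_mask].sum() / n_present < min_on_tissue_frac:
            continue
        keep[j] = True
    return keep


# ---------------------------------------------------------------------------
# mass recalibration

def recalibrate_masses(
    run: MSIRun,
    reference_masses: np.ndarray,
    search_ppm: float = 100.0,
    min_refs: int = 3,
    min_pixel_frac: float = 0.5,
) -> MSIRun:
    """Correct per-pixel m/z drift against known reference ions.

    The ppm error of each detected reference peak is fit as a robust linear
    function of m/z per pixel (least squares over that pixel's references);
    pixels with fewer than ``min_refs`` references fall back to the
    run-level fit pooled over all pixels.  The modeled ppm error is then
    subtracted from every peak mass.
    """
    refs = np.sort(np.asarray(reference_masses, dtype=float))
    per_pixel_errors = []  # (pixel, ref_mz, ppm_error)
    detected_count = np.zeros(refs.size)
    n_informative = 0
    for p, (mzs, ints) in enumerate(zip(run.peaks_mz, run.peaks_intensity)):
        if mzs.size == 0:
            continue
        found = []
        for ri, ref in enumerate(refs):
            lo = ref * (1 - search_ppm * 1e-6)
            hi = ref * (1 + search_ppm * 1e-6)
            i0, i1 = np.searchsorted(mzs, [lo, hi])
            if i1 > i0:
                j = i0 + int(np.argmax(ints[i0:i1]))
                found.append((ref, (mzs[j] - ref) / ref * 1e6))
                detected_count[ri] += 1
        if len(found) >= min_refs:
            n_informative += 1
        per_pixel_errors.append((p, found))
    n_tissue = int(run.tissue_mask.sum()) or run.n_pixels
    if n_informative < min_pixel_frac * n_tissue:
        missing = [f"{r:.4f}" for r, c in zip(refs, detected_count)
                   if c < min_pixel_frac * n_tissue]
        detail = ", ".join(missing) if missing else (
            "each reference is detected, but fewer than "
            f"{min_refs} coincide in enough pixels"
        )
        raise ValueError(
            "too few reference masses detected for recalibration; "
            f"poorly detected references: {detail}"
        )
    all_ref = np.concatenate([[f[0] for f in found] for _, found in per_pixel_errors if found])
    all_err = np.concatenate([[f[1] for f in found] for _, found in per_pixel_errors if found])
    run_fit = np.polyfit(all_ref, all_err, 1)

    new_mz = []
    err_by_pixel = dict()
    for p, found in per_pixel_errors:
        if len(found) >= min_refs:
            x = np.array([f[0] for f in found])
            y = np.array([f[1] for f in found])
            err_by_pixel[p] = np.polyfit(x, y, 1)
    out_mz = []
    for p, mzs in enumerate(run.peaks_mz):
        if mzs.size == 0:
            out_mz.append(mzs.copy())
            continue
        coeff = err_by_pixel.get(p, run_fit)
        ppm_err = np.polyval(coeff, mzs)
        out_mz.append(mzs / (1.0 + ppm_err * 1e-6))
    return MSIRun(
        run_id=run.run_id,
        n_rows=run.n_rows,
        n_cols=run.n_cols,
        peaks_mz=out_mz,
        peaks_intensity=[i.copy() for i in run.peaks_intensity],
        tissue_id=run.tissue_id.copy(),
        genotype=run.genotype.copy(),
    )


# ---------------------------------------------------------------------------
# inter-run matching

def build_representative_list(matrix: np.ndarray, common_mz: np.ndarray) -> pd.DataFrame:
    """Per-run representative peak list: (m/z, arithmetic mean intensity
    over ALL pixels of the run, zeros included)."""
    return pd.DataFrame({"mz": common_mz, "mean_intensity": matrix.mean(axis=0)})


def match_across_runs(
    rep_lists: list[pd.DataFrame], tol_ppm: float = 20.0
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Match representative per-run peak lists into inter-run common masses.

    Same gap-splitting semantics as intra-run matching.  Returns the common
    m/z values and, per run, an array mapping each run feature to its
    common-mass column (-1 when the run contributed a less intense duplicate
    to the same bin).
    """
    if len(rep_lists) < 2:
        raise ValueError("inter-run matching needs at least 2 runs")
    mzs = np.concatenate([rl["mz"].to_numpy() for rl in rep_lists])
    means = np.concatenate([rl["mean_intensity"].to_numpy() for rl in rep_lists])
    run_of = np.concatenate([
        np.full(len(rl), r) for r, rl in enumerate(rep_lists)
    ])
    idx_in_run = np.concatenate([np.arange(len(rl)) for rl in rep_lists])
    order = np.argsort(mzs, kind="stable")
    mzs, means, run_of, idx_in_run = mzs[order], means[order], run_of[order], idx_in_run[order]
    bins = _gap_split_bins(mzs, tol_ppm)
    n_bins = bins[-1] + 1
    w = means + 1e-12
    common_mz = np.bincount(bins, weights=mzs * w) / np.bincount(bins, weights=w)
    mappings = [np.full(len(rl), -1, dtype=int) for rl in rep_lists]
    best = {}
    for b, r, j, m in zip(bins, run_of, idx_in_run, means):
        key = (b, r)
        if key not in best or m > best[key][1]:
            best[key] = (j, m)
    for (b, r), (j, _) in best.items():
        mappings[r][j] = b
    return common_mz, mappings


def consensus_filter(
    common_mz: np.ndarray, per_run_means: np.ndarray
) -> np.ndarray:
    """Keep a common mass only if its mean intensity is > 0 in every run."""
    keep = np.all(per_run_means > 0, axis=0)
    if not keep.any():
        raise ValueError(
            "consensus filter removed every feature; consider looser "
            "matching tolerances"
        )
    return keep


# ---------------------------------------------------------------------------
# normalization & batch correction

def median_scale_normalize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Divide each pixel spectrum by the median of its non-zero intensities
    and restore the original scale with the global median of those medians.

    Returns the normalized matrix and a flag vector marking all-zero pixels
    (left unscaled).
    """
    X = np.asarray(X, dtype=float)
    meds = np.full(X.shape[0], np.nan)
    for i in range(X.shape[0]):
        nz = X[i][X[i] > 0]
        if nz.size:
            meds[i] = np.median(nz)
    flagged = np.isnan(meds)
    global_factor = np.median(meds[~flagged]) if (~flagged).any() else 1.0
    out = X.copy()
    ok = ~flagged
    out[ok] = X[ok] / meds[ok, None] * global_factor
    return out, flagged


def combat_correct(X: np.ndarray, batch: np.ndarray, max_iter: int = 200,
                   tol: float = 1e-6) -> np.ndarray:
    """Parametric empirical-Bayes location/scale batch correction.

    Features are standardized against the weighted grand mean and pooled
    variance; per-batch location and scale effects are shrunk toward their
    across-feature priors (normal for location, inverse-gamma for scale)
    and removed.  Batches are the acquisition runs.
    """
    X = np.asarray(X, dtype=float)
    batch = np.asarray(batch)
    levels, codes = np.unique(batch, return_inverse=True)
    n_batch = levels.size
    if n_batch < 2:
        raise ValueError("batch correction needs at least 2 batches")
    sizes = np.bincount(codes)
    if np.any(sizes < 2):
        small = levels[sizes < 2]
        raise ValueError(f"batches with a single pixel cannot be corrected: {list(small)}")
    n, g = X.shape

    batch_means = np.stack([X[codes == b].mean(axis=0) for b in range(n_batch)])
    grand_mean = (sizes[:, None] * batch_means).sum(axis=0) / n
    resid = X - batch_means[codes]
    var_pooled = (resid**2).mean(axis=0)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    Z = (X - grand_mean) / np.sqrt(var_pooled)

    Xadj = np.empty_like(Z)
    for b in range(n_batch):
        sel = codes == b
        nb = sizes[b]
        gamma_hat = Z[sel].mean(axis=0)
        delta_hat = Z[sel].var(axis=0, ddof=1)
        gbar, t2 = gamma_hat.mean(), gamma_hat.var()
        m, s2 = delta_hat.mean(), delta_hat.var()
        lam = (2 * s2 + m**2) / s2 if s2 > 0 else 2.0
        theta = (m * s2 + m**3) / s2 if s2 > 0 else m
        g_star, d_star = gamma_hat.copy(), delta_hat.copy()
        for _ in range(max_iter):
            g_new = (t2 * nb * gamma_hat + d_star * gbar) / (t2 * nb + d_star)
            ss = ((Z[sel] - g_new) ** 2).sum(axis=0)
            d_new = (theta + 0.5 * ss) / (nb / 2 + lam - 1)
            change = max(np.abs(g_new - g_star).max(), np.abs(d_new - d_star).max())
            g_star, d_star = g_new, d_new
            if change < tol:
                break
        Xadj[sel] = (Z[sel] - g_star) / np.sqrt(d_star)
    return Xadj * np.sqrt(var_pooled) + grand_mean


# ---------------------------------------------------------------------------
# pipeline

def preprocess_runs(
    runs: list[MSIRun],
    tol_intra_ppm: float = 50.0,
    tol_inter_ppm: float = 20.0,
    min_pixels: int = 9,
    reference_masses: np.ndarray | None = None,
    batch_correct: bool = True,
) -> FeatureTable:
    """Full preprocessing chain from centroided runs to a FeatureTable.

    Per run: intra-run matching at ``tol_intra_ppm``, scattered-ion and
    off-tissue filtering, optional recalibration (then rematching), and a
    representative mean-intensity list.  Across runs: matching at
    ``tol_inter_ppm``, consensus zero-mean filtering, assembly of the
    tissue-pixel matrix, median scaling and batch correction.
    """
    if len(runs) < 2:
        raise ValueError("the consensus pipeline needs at least 2 runs")
    per_run = []
    dropped_log = {}
    for run in runs:
        if reference_masses is not None:
            run = recalibrate_masses(run, reference_masses)
        common_mz, matrix = match_peaks_within_run(run, tol_intra_ppm)
        keep = filter_scattered_ions(
            matrix, (run.n_rows, run.n_cols), run.tissue_mask, min_pixels=min_pixels
        )
        dropped_log[run.run_id] = [f"{m:.4f}" for m in common_mz[~keep]]
        per_run.append((run, common_mz[keep], matrix[:, keep]))

    rep_lists = [build_representative_list(mat, mz) for _, mz, mat in per_run]
    common_mz, mappings = match_across_runs(rep_lists, tol_inter_ppm)

    per_run_means = np.zeros((len(runs), common_mz.size))
    for r, (rl, mapping) in enumerate(zip(rep_lists, mappings)):
        ok = mapping >= 0
        per_run_means[r, mapping[ok]] = rl["mean_intensity"].to_numpy()[ok]
    keep = consensus_filter(common_mz, per_run_means)
    col_of = np.cumsum(keep) - 1  # old common index -> new column

    blocks, obs_frames = [], []
    for (run, _, matrix), mapping in zip(per_run, mappings):
        tissue = run.tissue_mask
        block = np.zeros((int(tissue.sum()), int(keep.sum())))
        ok = (mapping >= 0) & keep[np.clip(mapping, 0, None)]
        block[:, col_of[mapping[ok]]] = matrix[np.ix_(tissue, np.flatnonzero(ok))]
        blocks.append(block)
        coords = run.coords[tissue]
        obs_frames.append(pd.DataFrame({
            "run_id": run.run_id,
            "tissue_id": run.tissue_id[tissue],
            "genotype": run.genotype[tissue],
            "row": coords[:, 0],
            "col": coords[:, 1],
        }))
    X = np.vstack(blocks)
    obs = pd.concat(obs_frames, ignore_index=True)

    X, flagged = median_scale_normalize(X)
    if flagged.any():
        warnings.warn(f"{int(flagged.sum())} all-zero pixel spectra left unscaled")
    if batch_correct:
        X = combat_correct(X, obs["run_id"].to_numpy())
    return FeatureTable(
        X=X,
        mz=common_mz[keep],
        obs=obs,
        provenance={
            "tol_intra_ppm": tol_intra_ppm,
            "tol_inter_ppm": tol_inter_ppm,
            "min_pixels": min_pixels,
            "dropped_features": dropped_log,
            "batch_corrected": batch_correct,
        },
    )
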