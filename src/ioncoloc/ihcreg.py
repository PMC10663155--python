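"""IHC segmentation and co-registration to MSI grids.

Thresholds deconvolved DAB images into MYC-positive masks, re-bins them in
16x16 blocks, splits blocks into MYC-high and MYC-low regions with 1-D
k-means, resamples the region map onto MSI pixel centers through a supplied
affine (or identity) transform, and contrasts metabolite levels between
regions with a mixed-effects beta regression (random intercepts for
acquisition run and tissue section).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import clonstat
from .clonstat import BetaFit

__all__ = [
    "BlockGrid",
    "myc_positive_mask",
    "block_bin",
    "kmeans_high_low",
    "coregister_to_msi",
    "region_metabolite_contrast",
]


@dataclass
class BlockGrid:
    """MYC-positive pixel counts re-binned over non-overlapping blocks."""

    counts: np.ndarray  # (H, W) ints in [0, factor^2]
    factor: int
    labels: np.ndarray | None = None  # 'high' / 'low' after clustering
    artifact_mask: np.ndarray | None = None  # True = excluded

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / float(self.factor**2)


def myc_positive_mask(dab_channel: np.ndarray, threshold: int = 230) -> np.ndarray:
    """MYC-positive pixels of a deconvolved DAB green channel.

    A pixel is positive iff its 8-bit value is strictly below ``threshold``
    (unstained pixels sit at high green intensities).
    """
    img = np.asarray(dab_channel)
    if img.dtype != np.uint8:
        raise ValueError(
            "expected an 8-bit (uint8) deconvolved DAB channel; rescale first"
        )
    return img < threshold


def block_bin(mask: np.ndarray, factor: int = 16) -> BlockGrid:
    """Sum MYC-positive pixels over non-overlapping factor x factor blocks.

    Trailing rows/columns that do not fill a whole block are dropped so
    every count shares the same denominator.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if h < factor or w < factor:
        raise ValueError(f"mask smaller than one {factor}x{factor} block")
    H, W = h // factor, w // factor
    trimmed = mask[: H * factor, : W * factor]
    counts = trimmed.reshape(H, factor, W, factor).sum(axis=(1, 3))
    return BlockGrid(counts=counts.astype(int), factor=factor)


def kmeans_high_low(grid: BlockGrid, seed: int = 0) -> BlockGrid:
    """Split blocks into MYC-high and MYC-low by k = 2 k-means on the block
    proportions (Euclidean, 10 restarts); the cluster with the higher
    centroid is 'high'."""
    props = grid.proportions.reshape(-1, 1)
    if np.unique(props).size < 2:
        raise ValueError("degenerate input: all block proportions identical")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(props)
    hi = int(np.argmax(km.cluster_centers_.ravel()))
    labels = np.where(km.labels_ == hi, "high", "low").astype(object)
    return BlockGrid(
        counts=grid.counts,
        factor=grid.factor,
        labels=labels.reshape(grid.counts.shape),
        artifact_mask=grid.artifact_mask,
    )


def coregister_to_msi(
    grid: BlockGrid,
    msi_shape: tuple[int, int],
    transform: np.ndarray | None = None,
    artifact_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Resample the high/low block map onto MSI pixel centers.

    ``transform`` maps MSI pixel coordinates (row, col) to block
    coordinates as a 2x3 affine [[a, b, tx], [c, d, ty]]; None means
    identity (block grid and MSI grid aligned 1:1).  Nearest-neighbor
    lookup; pixels mapping outside the block grid or into the artifact
    mask are labeled 'excluded'.
    """
    if grid.labels is None:
        raise ValueError("cluster the block grid before co-registration")
    h, w = msi_shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.stack([rows.ravel(), cols.ravel(), np.ones(h * w)])
    if transform is None:
        transform = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    T = np.asarray(transform, dtype=float)
    if T.shape != (2, 3):
        raise ValueError("transform must be a 2x3 affine matrix")
    mapped = T @ pts
    br = np.rint(mapped[0]).astype(int)
    bc = np.rint(mapped[1]).astype(int)
    H, W = grid.labels.shape
    inside = (br >= 0) & (br < H) & (bc >= 0) & (bc < W)
    if not inside.any():
        raise ValueError("transform maps no MSI pixel onto the block grid")
    out = np.full(h * w, "excluded", dtype=object)
    out[inside] = grid.labels[br[inside], bc[inside]]
    amask = artifact_mask if artifact_mask is not None else grid.artifact_mask
    if amask is not None:
        excl = amask.reshape(-1)
        out[excl] = "excluded"
    if np.all(out == "excluded"):
        raise ValueError("all MSI pixels excluded; empty analysis set")
    return out.reshape(h, w)


def region_metabolite_contrast(
    intensity: np.ndarray,
    region: np.ndarray,
    run_id: np.ndarray,
    tissue_id: np.ndarray,
) -> tuple[BetaFit, pd.DataFrame, str | None]:
    """Contrast a metabolite between MYC-high and MYC-low regions.

    Per tissue and region the mean intensity is computed, rescaled into
    (0, 1) by the per-run maximum, and regressed on the region indicator
    with random intercepts for run and tissue (mirroring the proportion
    framing of the spatial models).  Tissues missing one region are
    dropped with a warning; a single-tissue design falls back to a
    fixed-effects fit with a caveat.

    Returns the fit, a per-tissue paired summary (high, low, difference on
    the raw scale) and the caveat string (None when the mixed fit ran).
    """
    intensity = np.asarray(intensity, dtype=float)
    region = np.asarray(region)
    run_id = np.asarray(run_id)
    tissue_id = np.asarray(tissue_id)
    ok = np.isin(region, ("high", "low"))

    units = []
    for t in pd.unique(tissue_id[ok]):
        sel_t = ok & (tissue_id == t)
        runs = pd.unique(run_id[sel_t])
        means = {}
        for g in ("high", "low"):
            sel = sel_t & (region == g)
            if sel.sum() == 0:
                break
            means[g] = float(intensity[sel].mean())
        if len(means) < 2:
            warnings.warn(f"tissue {t!r} lacks one region; dropped")
            continue
        for g in ("high", "low"):
            units.append({"tissue": t, "run": runs[0], "region": g, "mean": means[g]})
    df = pd.DataFrame(units)
    if df.empty or df["tissue"].nunique() < 1:
        raise ValueError("no tissue has both MYC regions")

    # rescale into (0,1) by the per-run maximum of the unit means
    df["scaled"] = df["mean"] / df.groupby("run")["mean"].transform("max") * 0.98

    n_tissue = df["tissue"].nunique()
    caveat = None
    if n_tissue >= 2:
        x = (df["region"] == "high").astype(float).rename("myc_high")
        rand: dict[str, np.ndarray] = {"tissue": df["tissue"].to_numpy()}
        if df["run"].nunique() >= 2:
            rand["run"] = df["run"].to_numpy()
        fit = clonstat.beta_regression(
            df["scaled"].to_numpy(), x, random_intercepts=rand
        )
    else:
        # single tissue: no between-tissue replication, so fit the pixels
        # directly with fixed effects only
        caveat = "single tissue: fixed-effects fit on pixels, no random intercepts"
        warnings.warn(caveat)
        keep_t = df["tissue"].iloc[0]
        sel = ok & (tissue_id == keep_t)
        y = intensity[sel] / intensity[sel].max() * 0.98
        x = pd.Series((region[sel] == "high").astype(float), name="myc_high")
        fit = clonstat.beta_regression(y, x)

    paired = (
        df.pivot_table(index="tissue", columns="region", values="mean")
        .assign(difference=lambda d: d["high"] - d["low"])
        .reset_index()
    )
    return fit, paired, caveat
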