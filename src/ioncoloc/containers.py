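"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MSIRun", "FeatureTable"]


@dataclass
class MSIRun:
    """One MSI acquisition run.

    Pixels are stored row-major over an ``n_rows x n_cols`` grid.  Each
    pixel carries a centroided peak list (m/z strictly increasing,
    intensities >= 0), a tissue id and a genotype label in
    {'high', 'low', 'mix', 'off'}.
    """

    run_id: str
    n_rows: int
    n_cols: int
    peaks_mz: list  # per-pixel ndarray of m/z (Th), sorted ascending
    peaks_intensity: list  # per-pixel ndarray, same length
    tissue_id: np.ndarray  # (n_pixels,) str
    genotype: np.ndarray  # (n_pixels,) str in {high, low, mix, off}

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.genotype != "off"

    @property
    def coords(self) -> np.ndarray:
        """(n_pixels, 2) 0-based (row, col), row-major order."""
        rows, cols = np.divmod(np.arange(self.n_pixels), self.n_cols)
        return np.column_stack([rows, cols])

    def validate(self) -> None:
        n = self.n_pixels
        if not (len(self.peaks_mz) == len(self.peaks_intensity) == n):
            raise ValueError("peak lists must have one entry per pixel")
        if self.tissue_id.shape != (n,) or self.genotype.shape != (n,):
            raise ValueError("per-pixel annotations must have length n_pixels")
        bad = set(np.unique(self.genotype)) - {"high", "low", "mix", "off"}
        if bad:
            raise ValueError(f"unknown genotype labels: {sorted(bad)}")
        for mz, inten in zip(self.peaks_mz, self.peaks_intensity):
            if mz.size and np.any(np.diff(mz) <= 0):
                raise ValueError("pixel peak m/z must be strictly increasing")
            if np.any(inten < 0):
                raise ValueError("peak intensities must be non-negative")


@dataclass
class FeatureTable:
    """Pixels x features intensity matrix with inter-run-common m/z.

    ``obs`` annotates pixels (run_id, tissue_id, genotype, row, col);
    ``mz`` holds the consensus feature masses, sorted ascending.
    """

    X: np.ndarray  # (n_pixels, n_features)
    mz: np.ndarray  # (n_features,)
    obs: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def feature_names(self) -> list[str]:
        return [f"{m:.4f}" for m in self.mz]

    def pixels(self, mask) -> "FeatureTable":
        """Subset rows by a boolean mask or index array."""
        return FeatureTable(
            X=self.X[mask],
            mz=self.mz,
            obs=self.obs.iloc[np.flatnonzero(mask)
                              if np.asarray(mask).dtype == bool else mask
                              ].reset_index(drop=True),
            provenance=dict(self.provenance),
        )

    def image(self, feature: int, run_id: str) -> np.ndarray:
        """Reconstruct one feature's ion image for one run (NaN off-grid)."""
        sel = self.obs["run_id"] == run_id
        rows = self.obs.loc[sel, "row"].to_numpy()
        cols = self.obs.loc[sel, "col"].to_numpy()
        img = np.full((rows.max() + 1, cols.max() + 1), np.nan)
        img[rows, cols] = self.X[sel.to_numpy(), feature]
        return img

    def to_csv(self, path) -> None:
        df = pd.concat(
            [self.obs.reset_index(drop=True),
             pd.DataFrame(self.X, columns=self.feature_names())],
            axis=1,
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        meta_cols = [c for c in ("run_id", "tissue_id", "genotype", "row", "col")
                     if c in df.columns]
        feat_cols = [c for c in df.columns if c not in meta_cols]
        return cls(
            X=df[feat_cols].to_numpy(dtype=float),
            mz=np.array([float(c) for c in feat_cols]),
            obs=df[meta_cols].copy(),
        )
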