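"""Stable-isotope tracing on MSI feature tables.

Matches isotopologue ions (m+0..m+5) of selected metabolites in the
inter-run common mass list, strips natural ¹³C abundance with a binomial
model anchored on the raw monoisotopic image, quantifies spatial
colocalization of the labeled signals by consensus Pearson correlation over
mixed-clone pixels with a permutation null, and provides the display
conventions (max-normalization at the 99.9th percentile, proxy
binarization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import clonstat
from .containers import FeatureTable

DELTA_C13 = 1.003355  # Th
NATURAL_13C = 0.01109
K_MAX = 5

__all__ = [
    "MetaboliteSpec",
    "IsotopologueFamily",
    "ColocResult",
    "theoretical_isotopologue_mz",
    "match_isotopologues",
    "natural_abundance_correct",
    "consensus_label_correlation",
    "permutation_test",
    "correlation_dendrogram",
    "dendrogram_to_newick",
    "normalize_ion_image",
    "binarize_proxy",
    "trace_colocalization",
]


@dataclass(frozen=True)
class MetaboliteSpec:
    """A metabolite to trace: name, deprotonated monoisotopic m/z (Th) and
    carbon count."""

    name: str
    base_mz: float
    n_carbons: int

    def __post_init__(self):
        if self.base_mz <= 0:
            raise ValueError("base_mz must be positive")
        if self.n_carbons < 1:
            raise ValueError("n_carbons must be >= 1")


@dataclass
class IsotopologueFamily:
    """Matched isotopologue channels of one metabolite.

    ``feature_idx[k]`` is the matched column index for the m+k ion (or None);
    ``raw[k]`` the per-pixel raw intensities; ``labeled[k]`` the
    natural-abundance-corrected labeled component (k >= 1 only: the
    monoisotopic image is never 'corrected').
    """

    spec: MetaboliteSpec
    feature_idx: dict[int, int | None]
    raw: dict[int, np.ndarray] = field(default_factory=dict)
    labeled: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def usable(self) -> bool:
        return self.feature_idx.get(0) is not None


@dataclass
class ColocResult:
    """Consensus colocalization of labeled metabolites over mixed pixels."""

    names: list[str]
    consensus: np.ndarray
    per_run: dict[str, np.ndarray]
    p: np.ndarray
    q: np.ndarray
    cluster_labels: np.ndarray
    linkage: np.ndarray


def theoretical_isotopologue_mz(base_mz: float, k: int) -> float:
    """m/z of the m+k isotopologue: base + k * 1.003355 Th."""
    if not (0 <= k <= K_MAX):
        raise ValueError(f"k must lie in [0, {K_MAX}]")
    return base_mz + k * DELTA_C13


def match_isotopologues(
    common_mz: np.ndarray,
    mean_intensity: np.ndarray,
    spec: MetaboliteSpec,
    tol_ppm: float = 10.0,
) -> IsotopologueFamily:
    """Match each m+k channel (k = 0..5) to the common mass list.

    Candidates within ``tol_ppm`` of the theoretical mass compete on mean
    intensity across all pixels; the most intense wins.  A family whose
    monoisotopic (k=0) ion is unmatched is flagged unusable, since the
    natural-abundance correction is anchored on it.
    """
    common_mz = np.asarray(common_mz, dtype=float)
    mean_intensity = np.asarray(mean_intensity, dtype=float)
    idx: dict[int, int | None] = {}
    for k in range(min(K_MAX, spec.n_carbons) + 1):
        target = theoretical_isotopologue_mz(spec.base_mz, k)
        ppm = np.abs(common_mz - target) / target * 1e6
        cands = np.flatnonzero(ppm <= tol_ppm)
        idx[k] = int(cands[np.argmax(mean_intensity[cands])]) if cands.size else None
    fam = IsotopologueFamily(spec=spec, feature_idx=idx)
    if not fam.usable:
        warnings.warn(f"{spec.name}: monoisotopic ion unmatched; family unusable")
    return fam


def natural_abundance_correct(
    family: IsotopologueFamily, natural_p: float = NATURAL_13C
) -> IsotopologueFamily:
    """Estimate the labeled component of each m+k image (k >= 1).

    The natural m+k intensity is predicted from the raw monoisotopic image
    with the binomial ratio Binom(k; N, P) / Binom(0; N, P) and subtracted
    pixelwise; negative remainders are set to zero (label below the limit
    of detection).
    """
    if not family.usable or 0 not in family.raw:
        raise ValueError("k=0 raw image required for natural-abundance correction")
    N = family.spec.n_carbons
    raw0 = family.raw[0]
    p0 = stats.binom.pmf(0, N, natural_p)
    for k, img in family.raw.items():
        if k == 0:
            continue
        if k > N:
            warnings.warn(f"{family.spec.name}: m+{k} exceeds carbon count {N}; skipped")
            continue
        natural = raw0 * stats.binom.pmf(k, N, natural_p) / p0
        family.labeled[k] = np.maximum(np.asarray(img) - natural, 0.0)
    return family


def _corr_columns(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance images; correlations set to 0")
    Z = (M - M.mean(axis=0)) / np.where(dead, 1.0, sd)
    Z[:, dead] = 0.0
    C = Z.T @ Z / M.shape[0]
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def consensus_label_correlation(images_per_run: list[np.ndarray]) -> np.ndarray:
    """Consensus (entrywise minimum over runs) of the intra-run Pearson
    correlations between labeled-metabolite images.

    Each entry of ``images_per_run`` is an (n_mix_pixels, n_metabolites)
    matrix restricted to that run's mixed-clone pixels.
    """
    if not images_per_run:
        raise ValueError("need at least one run")
    mats = []
    for M in images_per_run:
        if M.shape[0] < 3:
            raise ValueError("each run needs at least 3 mixed-clone pixels")
        mats.append(_corr_columns(np.asarray(M, dtype=float)))
    return np.minimum.reduce(mats)


def permutation_test(
    images_per_run: list[np.ndarray],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation null for the consensus correlations.

    Every ion image's pixels are shuffled independently within each run at
    each of ``n_perm`` iterations, the consensus is recomputed, and
    p = (#{|perm| >= |observed|} + 1) / (n_perm + 1) per metabolite pair,
    Benjamini-Hochberg adjusted across pairs.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    mats = [np.asarray(M, dtype=float) for M in images_per_run]
    observed = consensus_label_correlation(mats)
    m = observed.shape[0]
    iu = np.triu_indices(m, k=1)
    obs_abs = np.abs(observed[iu])
    exceed = np.zeros(obs_abs.size)
    for _ in range(n_perm):
        perms = []
        for M in mats:
            P = np.empty_like(M)
            for j in range(m):
                P[:, j] = M[rng.permutation(M.shape[0]), j]
            perms.append(_corr_columns(P))
        cons = np.minimum.reduce(perms)
        exceed += np.abs(cons[iu]) >= obs_abs
    pvec = (exceed + 1.0) / (n_perm + 1.0)
    qvec = clonstat.bh_adjust(pvec)
    p = np.ones((m, m))
    q = np.ones((m, m))
    p[iu], q[iu] = pvec, qvec
    p.T[iu], q.T[iu] = pvec, qvec
    return p, q


def correlation_dendrogram(consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage clustering on 1 - consensus, cut into two clusters.

    Returns (labels in {1, 2}, linkage matrix).
    """
    C = np.asarray(consensus, dtype=float)
    if C.shape[0] < 2:
        raise ValueError("need at least 2 metabolites to build a dendrogram")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    offd = D[~np.eye(D.shape[0], dtype=bool)]
    if np.allclose(offd, offd.flat[0]):
        warnings.warn("degenerate tree: all pairwise distances equal; split is arbitrary but deterministic")
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    # cut_tree forces exactly two clusters even on tied (zero-height) trees
    labels = hierarchy.cut_tree(Z, n_clusters=2).ravel() + 1
    return labels, Z


def dendrogram_to_newick(linkage: np.ndarray, names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6f}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def normalize_ion_image(image: np.ndarray) -> np.ndarray:
    """Display normalization: clip at the 99.9th percentile, scale to [0, 1].

    All-zero images come back all-zero.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    hi = np.percentile(img, 99.9)
    clipped = np.minimum(img, hi)
    top = clipped.max()
    return clipped / top if top > 0 else clipped


def binarize_proxy(image_a: np.ndarray, image_b: np.ndarray) -> np.ndarray:
    """Per-pixel predominance map of two max-normalized proxy images.

    Returns 'a' where the first dominates, 'b' where the second does and
    'none' on ties (including both-zero pixels).
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    out = np.full(a.shape, "none", dtype=object)
    out[a > b] = "a"
    out[b > a] = "b"
    return out


def trace_colocalization(
    ft: FeatureTable,
    specs: list[MetaboliteSpec],
    label_k: dict[str, int] | None = None,
    tol_ppm: float = 10.0,
    natural_p: float = NATURAL_13C,
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> ColocResult:
    """Labeled-metabolite colocalization over the mixed-clone pixels.

    For each metabolite the tracer isotopologue image (``label_k``,
    defaulting to the highest matched k) is natural-abundance corrected;
    intra-run correlations over mix pixels are combined by entrywise
    minimum, tested by permutation and cut into two clusters.
    """
    mean_int = ft.X.mean(axis=0)
    genotype = ft.obs["genotype"].to_numpy()
    run_ids = ft.obs["run_id"].to_numpy()
    mix = genotype == "mix"

    names, tracer_by_name = [], {}
    for spec in specs:
        fam = match_isotopologues(ft.mz, mean_int, spec, tol_ppm)
        if not fam.usable:
            continue
        for k, j in fam.feature_idx.items():
            if j is not None:
                fam.raw[k] = ft.X[:, j]
        natural_abundance_correct(fam, natural_p)
        k = (label_k or {}).get(spec.name)
        if k is None:
            matched = [kk for kk in fam.labeled if fam.feature_idx.get(kk) is not None]
            if not matched:
                continue
            k = max(matched)
        if k not in fam.labeled:
            continue
        names.append(spec.name)
        tracer_by_name[spec.name] = fam.labeled[k]
    if len(names) < 2:
        raise ValueError("fewer than 2 traceable metabolites matched")

    images_per_run, per_run = [], {}
    for r in pd.unique(run_ids):
        sel = mix & (run_ids == r)
        M = np.column_stack([tracer_by_name[n][sel] for n in names])
        images_per_run.append(M)
        per_run[r] = _corr_columns(M)
    consensus = consensus_label_correlation(images_per_run)
    p, q = permutation_test(images_per_run, n_perm=n_perm, seed=seed)
    labels, Z = correlation_dendrogram(consensus)
    return ColocResult(
        names=names, consensus=consensus, per_run=per_run,
        p=p, q=q, cluster_labels=labels, linkage=Z,
    )
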