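"""Consensus ion-colocalization modules.

Signed-hybrid correlation networks per run, consensus by entrywise minimum
after single-quantile scaling, topological overlap, average-linkage module
cutting, eigenmetabolite summaries, beta-regression association of modules
with the MYC genotype, and projection of mixed-clone pixels onto the module
loadings.  Networks are always estimated from pure-genotype pixels only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import clonstat
from .containers import FeatureTable

__all__ = [
    "Eigenmetabolite",
    "ModuleSet",
    "signed_hybrid_adjacency",
    "scale_free_fit_index",
    "pick_consensus_soft_power",
    "smallest_qualifying_power",
    "export_edge_list",
    "single_quantile_normalize",
    "consensus_adjacency",
    "topological_overlap",
    "cut_modules",
    "module_eigenmetabolite",
    "merge_similar_modules",
    "associate_modules_with_genotype",
    "project_mix",
    "detect_modules",
]


@dataclass
class Eigenmetabolite:
    """First-PC summary of one module over the training pixels.

    Features are centered and unit-scaled with the retained ``mean`` and
    ``scale`` so new (mixed-clone) pixels can be projected later.
    """

    feature_idx: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    var_explained: float


@dataclass
class ModuleSet:
    """Feature-to-module assignment with eigenmetabolites and association."""

    labels: np.ndarray  # per-feature module label, 'unassigned' allowed
    eigens: dict[str, Eigenmetabolite]
    association: pd.DataFrame | None = None
    beta: float | None = None
    provenance: dict = field(default_factory=dict)

    def modules(self) -> list[str]:
        return sorted(self.eigens)

    def assignment_table(self, mz: np.ndarray, X: np.ndarray) -> pd.DataFrame:
        """Feature m/z, module label and module membership
        (correlation of the feature with its module's eigenmetabolite)."""
        membership = np.full(len(self.labels), np.nan)
        for name, eig in self.eigens.items():
            sel = self.labels == name
            for j in np.flatnonzero(sel):
                if X[:, j].std() > 0:
                    membership[j] = np.corrcoef(X[:, j], eig.scores)[0, 1]
        return pd.DataFrame({
            "mz": np.asarray(mz),
            "module": self.labels,
            "membership": membership,
        })


def _safe_corr(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns; zero-variance columns get zero
    correlation with everything (warned)."""
    sd = X.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance features; correlations set to 0")
    Z = (X - X.mean(axis=0)) / np.where(dead, 1.0, sd)
    Z[:, dead] = 0.0
    C = (Z.T @ Z) / X.shape[0]
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def signed_hybrid_adjacency(X: np.ndarray, beta: float) -> np.ndarray:
    """a_ij = max(cor(i, j), 0)^beta with unit diagonal.

    Only positive Pearson correlations contribute; negative ones clamp to
    zero.  ``X`` is pixels x features restricted to pure-genotype pixels.
    """
    if X.shape[0] < 3:
        raise ValueError("need at least 3 pixels to estimate correlations")
    if beta < 1:
        raise ValueError("soft power beta must be >= 1")
    A = np.clip(_safe_corr(X), 0.0, None) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def scale_free_fit_index(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """R-squared of log10 p(k) against log10 k over connectivity bins,
    signed negative when the slope is positive (the standard convention for
    scale-free topology fit)."""
    k = adjacency.sum(axis=0) - 1.0
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    centers = np.array([k[which == b].mean() if counts[b] else np.nan
                        for b in range(n_bins)])
    ok = (counts > 0) & (centers > 0)
    if ok.sum() < 3:
        return 0.0
    x = np.log10(centers[ok])
    y = np.log10(counts[ok] / counts[ok].sum())
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    return -r2 if slope > 0 else r2


def pick_consensus_soft_power(
    run_matrices: list[np.ndarray],
    r2_min: float = 0.85,
    powers=range(1, 21),
    fallback_best: bool = False,
) -> int:
    """Smallest soft power at which the scale-free fit index exceeds
    ``r2_min`` in every run.

    When no power qualifies the default is an error reporting each run's
    best fit; with ``fallback_best=True`` the power maximizing the
    worst-run fit is returned with a warning instead (useful on small
    feature panels, where the degree distribution is too coarse for the
    scale-free criterion to stabilize).
    """
    if not run_matrices:
        raise ValueError("need at least one run")
    corrs = [np.clip(_safe_corr(X), 0.0, None) for X in run_matrices]
    fits_by_power = {}
    for p in powers:
        fits = []
        for C in corrs:
            A = C**p
            np.fill_diagonal(A, 1.0)
            fits.append(scale_free_fit_index(A))
        fits_by_power[int(p)] = fits
    return smallest_qualifying_power(fits_by_power, r2_min, fallback_best=fallback_best)


def smallest_qualifying_power(
    fits_by_power: dict[int, list[float]],
    r2_min: float,
    fallback_best: bool = False,
) -> int:
    """Selection rule behind :func:`pick_consensus_soft_power`: the smallest
    power whose fit exceeds ``r2_min`` in every run — equivalently the
    largest of the per-run first-crossing powers."""
    for p in sorted(fits_by_power):
        if all(f > r2_min for f in fits_by_power[p]):
            return p
    n_runs = len(next(iter(fits_by_power.values())))
    best = {}
    for r in range(n_runs):
        pb = max(fits_by_power, key=lambda p: fits_by_power[p][r])
        best[r] = (pb, fits_by_power[pb][r])
    detail = ", ".join(
        f"run {r}: best R2={b[1]:.3f} at power {b[0]}" for r, b in best.items()
    )
    if fallback_best:
        p_best = max(fits_by_power, key=lambda p: min(fits_by_power[p]))
        warnings.warn(
            f"no soft power reaches R2 > {r2_min} in every run ({detail}); "
            f"falling back to power {p_best} with the best worst-run fit"
        )
        return int(p_best)
    raise ValueError(f"no soft power in range reaches R2 > {r2_min} in every run ({detail})")


def single_quantile_normalize(
    adjacencies: list[np.ndarray], q: float = 0.95
) -> list[np.ndarray]:
    """Scale each run's off-diagonal adjacencies so their ``q``-quantile
    matches the reference (first) run's, clipping into [0, 1]."""
    if len(adjacencies) < 2:
        raise ValueError("quantile normalization needs at least 2 runs")
    off = ~np.eye(adjacencies[0].shape[0], dtype=bool)
    quantiles = [np.quantile(A[off], q) for A in adjacencies]
    if any(x == 0 for x in quantiles):
        raise ValueError("a run's reference quantile is zero; cannot scale")
    ref = quantiles[0]
    out = []
    for A, qa in zip(adjacencies, quantiles):
        B = A.copy()
        B[off] = np.clip(A[off] * (ref / qa), 0.0, 1.0)
        out.append(B)
    return out


def consensus_adjacency(adjacencies: list[np.ndarray]) -> np.ndarray:
    """Entrywise minimum across runs — an edge must replicate everywhere."""
    shapes = {A.shape for A in adjacencies}
    if len(shapes) != 1:
        raise ValueError("adjacency matrices must share a shape")
    return np.minimum.reduce([np.asarray(A) for A in adjacencies])


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with unit diagonal; the shared-neighbor sum excludes i and j."""
    A = np.asarray(adjacency, dtype=float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    n = A.shape[0]
    k = A.sum(axis=0) - 1.0
    L = A @ A - 2.0 * A  # remove u = i and u = j terms (unit diagonal)
    num = L + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Deterministic module names M1, M2, ... by decreasing size then first
    feature index; 'unassigned' is preserved."""
    out = np.asarray(labels, dtype=object).copy()
    mods = [m for m in pd.unique(out) if m != "unassigned"]
    stats = []
    for m in mods:
        idx = np.flatnonzero(out == m)
        stats.append((-idx.size, idx[0], m))
    mapping = {m: f"M{i + 1}" for i, (_, _, m) in enumerate(sorted(stats))}
    for old, new in mapping.items():
        out[labels == old] = new
    return out


def cut_modules(
    tom: np.ndarray,
    min_size: int = 20,
    X: np.ndarray | None = None,
    reassign_cor: float = 0.3,
) -> np.ndarray:
    """Cut the average-linkage tree on 1 - TOM into modules of >= min_size.

    The static cut scans every merge height of the tree and keeps the one
    yielding the most clusters of size >= ``min_size`` (ties broken toward
    more assigned features, then toward the lower height); features in
    smaller clusters start out unassigned.  When a data matrix ``X`` is
    supplied, a PAM-like refinement follows: features correlating less than
    ``reassign_cor`` with their own module eigenmetabolite are unassigned,
    then reassigned to the best-correlated module when that correlation
    exceeds the threshold.  Modules that fall below ``min_size`` dissolve.
    """
    n = tom.shape[0]
    if n < min_size:
        warnings.warn(f"fewer features ({n}) than min module size ({min_size}); all unassigned")
        return np.full(n, "unassigned", dtype=object)
    D = 1.0 - np.asarray(tom)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    heights = np.unique(Z[:, 2])
    best_key, labels = None, np.ones(n, dtype=int)
    for h in heights[::-1]:  # descending so ties prefer the lower height
        cand = hierarchy.fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(cand)[1:]
        big = sizes >= min_size
        key = (int(big.sum()), int(sizes[big].sum()))
        if best_key is None or key >= best_key:
            best_key, labels = key, cand
    sizes = np.bincount(labels)[1:]
    out = np.array(
        [f"c{c}" if sizes[c - 1] >= min_size else "unassigned" for c in labels],
        dtype=object,
    )

    if X is not None:
        for _ in range(2):  # unassign, then one reassignment pass
            mods = [m for m in pd.unique(out)
                    if m != "unassigned" and (out == m).sum() >= 2]
            if not mods:
                break
            cors = np.full((n, len(mods)), -np.inf)
            for mi, m in enumerate(mods):
                members = np.flatnonzero(out == m)
                eig = module_eigenmetabolite(X, members)
                s = eig.scores
                if s.std() == 0:
                    continue
                for j in range(n):
                    if X[:, j].std() == 0:
                        continue
                    if j in members and members.size > 2:
                        # leave-one-out membership: a feature must track the
                        # rest of its module, not its own echo in the ME
                        loo = module_eigenmetabolite(X, members[members != j])
                        cors[j, mi] = np.corrcoef(X[:, j], loo.scores)[0, 1]
                    else:
                        cors[j, mi] = np.corrcoef(X[:, j], s)[0, 1]
            best = cors.argmax(axis=1)
            best_cor = cors[np.arange(n), best]
            new = np.where(best_cor > reassign_cor,
                           np.array(mods, dtype=object)[best], "unassigned")
            if np.array_equal(new, out):
                break
            out = new.astype(object)
        for m in [m for m in pd.unique(out) if m != "unassigned"]:
            if (out == m).sum() < min_size:
                out[out == m] = "unassigned"
    return _relabel(out)


def module_eigenmetabolite(X: np.ndarray, feature_idx: np.ndarray) -> Eigenmetabolite:
    """First principal-component scores of a module's features.

    Features are centered and unit-scaled over the training pixels before
    the SVD; the score sign is anchored so that its correlation with the
    module's average raw intensity per pixel is non-negative.
    """
    idx = np.asarray(feature_idx)
    if idx.size < 2:
        raise ValueError("module must contain at least 2 features")
    sub = X[:, idx]
    mean = sub.mean(axis=0)
    scale = sub.std(axis=0)
    dead = scale == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance features dropped from the eigenmetabolite")
        idx = idx[~dead]
        sub = X[:, idx]
        mean, scale = mean[~dead], scale[~dead]
        if idx.size < 2:
            raise ValueError("module degenerate after dropping zero-variance features")
    Zc = (sub - mean) / scale
    U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    scores = U[:, 0] * S[0]
    loadings = Vt[0]
    avg = sub.mean(axis=1)
    if np.std(avg) > 0 and np.corrcoef(scores, avg)[0, 1] < 0:
        scores, loadings = -scores, -loadings
    var_explained = float(S[0] ** 2 / (S**2).sum())
    return Eigenmetabolite(
        feature_idx=idx, scores=scores, loadings=loadings,
        mean=mean, scale=scale, var_explained=var_explained,
    )


def merge_similar_modules(
    X: np.ndarray, labels: np.ndarray, threshold: float = 0.85
) -> tuple[np.ndarray, dict[str, Eigenmetabolite]]:
    """Merge modules whose eigenmetabolites correlate above ``threshold``.

    Merging is the transitive closure over the > threshold graph (identity
    is transitive); final eigenmetabolites are recomputed on the merged
    feature sets.
    """
    labels = np.asarray(labels, dtype=object)
    mods = [m for m in pd.unique(labels) if m != "unassigned"]
    eigs = {m: module_eigenmetabolite(X, np.flatnonzero(labels == m)) for m in mods}
    parent = {m: m for m in mods}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(mods):
        for b in mods[i + 1:]:
            c = np.corrcoef(eigs[a].scores, eigs[b].scores)[0, 1]
            if c > threshold:
                parent[find(b)] = find(a)
    merged = labels.copy()
    for m in mods:
        merged[labels == m] = find(m)
    merged = _relabel(merged)
    final = {m: module_eigenmetabolite(X, np.flatnonzero(merged == m))
             for m in pd.unique(merged) if m != "unassigned"}
    return merged, final


def associate_modules_with_genotype(
    eigens: dict[str, Eigenmetabolite],
    genotype: np.ndarray,
    tissue_id: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Beta-regression association of module eigenmetabolites with genotype.

    Each module's ME is binarized at its inter-run median (ties count as
    low); the per-tissue fraction of high-ME pixels is regressed on the
    binary tissue genotype with a logit-link beta model.  Wald p-values are
    Benjamini-Hochberg adjusted across modules.
    """
    genotype = np.asarray(genotype)
    tissue_id = np.asarray(tissue_id)
    pure = np.isin(genotype, ("high", "low"))
    rows = []
    for name, eig in eigens.items():
        me = eig.scores
        if me.shape[0] != genotype.shape[0]:
            raise ValueError("eigenmetabolite scores must cover the training pixels")
        med = np.median(me[pure])
        high_me = me > med
        units = []
        for t in pd.unique(tissue_id[pure]):
            sel = pure & (tissue_id == t)
            g = pd.unique(genotype[sel])
            if g.size != 1:
                continue
            units.append((t, g[0], float(high_me[sel].mean())))
        df = pd.DataFrame(units, columns=["tissue", "genotype", "prop_high"])
        for g in ("high", "low"):
            if (df["genotype"] == g).sum() < 2:
                raise ValueError(f"need >= 2 tissues of genotype {g!r}")
        x = (df["genotype"] == "high").astype(float).rename("myc_high")
        fit = clonstat.beta_regression(df["prop_high"].to_numpy(), x)
        rows.append({
            "module": name,
            "slope": fit.params["myc_high"],
            "se": fit.se["myc_high"],
            "wald_p": fit.p["myc_high"],
        })
    res = pd.DataFrame(rows).set_index("module")
    res["bh_q"] = clonstat.bh_adjust(res["wald_p"].to_numpy())
    res["associated"] = res["bh_q"] < alpha
    return res


def project_mix(X_mix: np.ndarray, eig: Eigenmetabolite,
                columns: np.ndarray | None = None) -> np.ndarray:
    """Project new pixels onto a module's loadings using the training
    centering/scaling.  ``columns`` maps the eigenmetabolite's feature
    indices into ``X_mix`` when the matrices differ."""
    cols = eig.feature_idx if columns is None else np.asarray(columns)
    if np.any(cols >= X_mix.shape[1]):
        missing = cols[cols >= X_mix.shape[1]]
        raise ValueError(f"mix matrix lacks feature columns {missing.tolist()}")
    Z = (X_mix[:, cols] - eig.mean) / eig.scale
    return Z @ eig.loadings


def export_edge_list(
    X: np.ndarray, mz: np.ndarray, threshold: float = 0.7
) -> pd.DataFrame:
    """Plain edge list of feature pairs with Pearson correlation above
    ``threshold`` (for external network visualization)."""
    C = _safe_corr(X)
    iu = np.triu_indices(C.shape[0], k=1)
    keep = C[iu] > threshold
    return pd.DataFrame({
        "mz_a": np.asarray(mz)[iu[0][keep]],
        "mz_b": np.asarray(mz)[iu[1][keep]],
        "correlation": C[iu][keep],
    })


def detect_modules(
    ft: FeatureTable,
    min_size: int = 20,
    r2_min: float = 0.85,
    merge_threshold: float = 0.85,
    beta: int | None = None,
    quantile: float = 0.95,
) -> ModuleSet:
    """Full consensus module detection on a preprocessed FeatureTable.

    Only pure-genotype (high/low) pixels enter the network and the
    eigenmetabolites; mixed-clone pixels are later projected with
    :func:`project_mix`.
    """
    genotype = ft.obs["genotype"].to_numpy()
    pure = np.isin(genotype, ("high", "low"))
    run_ids = ft.obs["run_id"].to_numpy()
    run_matrices = [ft.X[pure & (run_ids == r)] for r in pd.unique(run_ids)]
    if beta is None:
        beta = pick_consensus_soft_power(run_matrices, r2_min=r2_min, fallback_best=True)
    adjs = [signed_hybrid_adjacency(M, beta) for M in run_matrices]
    if len(adjs) > 1:
        adjs = single_quantile_normalize(adjs, q=quantile)
    cons = consensus_adjacency(adjs)
    tom = topological_overlap(cons)
    X_pure = ft.X[pure]
    labels = cut_modules(tom, min_size=min_size, X=X_pure)
    labels, eigens = merge_similar_modules(X_pure, labels, threshold=merge_threshold)
    association = associate_modules_with_genotype(
        eigens,
        genotype[pure],
        ft.obs["tissue_id"].to_numpy()[pure],
    )
    return ModuleSet(
        labels=labels,
        eigens=eigens,
        association=association,
        beta=float(beta),
        provenance={
            "n_pure_pixels": int(pure.sum()),
            "mix_pixels_used": 0,
            "min_size": min_size,
            "merge_threshold": merge_threshold,
            "quantile": quantile,
        },
    )
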