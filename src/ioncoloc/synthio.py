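"""Synthetic biclonal-tumor MSI data with known ground truth.

Emulates the study design the pipeline targets: several acquisition runs,
each carrying a pure MYC-high tumor section, a pure MYC-low section and a
zoned 1:1 mixed section.  Planted ion-colocalization modules are shared
latent spatial fields; scattered noise ions occupy tiny pixel blobs;
isotopologue channels follow binomial natural ¹³C abundance plus
genotype-dependent labeling.  Every generator is deterministic under its
seed, so downstream stages have a parameter-recovery test surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .containers import MSIRun

DELTA_C13 = 1.003355  # Th, mass difference between 13C and 12C
NATURAL_13C = 0.01109

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "LabeledMetabolite",
    "DEFAULT_METABOLITES",
    "generate_biclonal_runs",
    "generate_ihc_fixture",
    "generate_gcms_fixture",
]


@dataclass(frozen=True)
class LabeledMetabolite:
    """A tracer-labeled metabolite to plant in the synthetic runs.

    ``label_k`` is the isotopologue produced by the tracer (e.g. 3 for a
    fully labeled three-carbon compound); ``linked_genotype`` is the clone
    in which labeling is elevated.
    """

    name: str
    base_mz: float
    n_carbons: int
    label_k: int
    linked_genotype: str  # 'high' or 'low'


# Proxy compounds mirroring the tracing readouts: Krebs-cycle proxies
# labeled preferentially in the MYC-high clone, lactagenic proxies in the
# MYC-low clone (deprotonated masses).
DEFAULT_METABOLITES = (
    LabeledMetabolite("malate_proxy", 133.0142, 4, 1, "high"),
    LabeledMetabolite("citrate_proxy", 191.0197, 6, 2, "high"),
    LabeledMetabolite("lactate_proxy", 89.0244, 3, 3, "low"),
    LabeledMetabolite("pyruvate_proxy", 87.0088, 3, 3, "low"),
)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic biclonal dataset.

    Defaults reproduce the target design: 3 acquisition runs, 64x64-pixel
    tissue sections, 2 planted colocalization modules of 10 features each
    plus 20 scattered noise ions, multiplicative per-run batch effects and
    3-fold genotype-dependent isotope labeling.
    """

    n_runs: int = 3
    grid_w: int = 64
    grid_h: int = 64
    n_modules: int = 2
    features_per_module: int = 10
    n_noise_features: int = 20
    n_background_features: int = 250  # stable ions anchoring per-pixel medians
    genotype_layout: str = "mix_zoned"  # pure_high | pure_low | mix_zoned
    batch_shift: float = 1.0  # additive per-run offset scale (a.u.)
    batch_scale: float = 1.5  # multiplicative per-run factor range
    label_effect: float = 3.0  # fold-difference of labeled intensity between genotypes
    natural_p: float = NATURAL_13C
    seed: int = 0
    metabolites: tuple = DEFAULT_METABOLITES
    max_labeled_fraction: float = 0.45
    pixel_noise_sigma: float = 0.25  # lognormal sigma of multiplicative noise
    molecules_per_pixel: int = 2000  # multinomial depth for isotopologues
    mz_jitter_ppm: float = 3.0
    run_mz_shift_ppm: tuple | None = None  # per-run calibration error, for recal tests

    def validate(self) -> None:
        for name in ("n_runs", "n_modules", "features_per_module", "n_noise_features"):
            if getattr(self, name) < 1 and name != "n_noise_features":
                raise ValueError(f"{name} must be >= 1")
        if self.grid_w < 8 or self.grid_h < 8:
            raise ValueError(
                "grid too small to host both genotype zones: minimum is 8x8 "
                f"(got {self.grid_h}x{self.grid_w})"
            )
        if not (0 < self.natural_p < 0.05):
            raise ValueError("natural_p must lie in (0, 0.05)")
        if self.genotype_layout not in ("pure_high", "pure_low", "mix_zoned"):
            raise ValueError(f"unknown genotype_layout {self.genotype_layout!r}")
        if self.label_effect < 1:
            raise ValueError("label_effect is a fold-difference, must be >= 1")

    def labeled_fractions(self) -> dict[str, dict[str, float]]:
        """Per-metabolite true labeled fraction by clone genotype.

        The linked genotype gets max_labeled_fraction * (1 - 1/label_effect)
        and the other genotype is label_effect-fold lower, so label_effect=1
        means no labeling at all.
        """
        out = {}
        for met in self.metabolites:
            linked = self.max_labeled_fraction * (1.0 - 1.0 / self.label_effect)
            other = linked / self.label_effect
            fr = {met.linked_genotype: linked,
                  ("low" if met.linked_genotype == "high" else "high"): other}
            out[met.name] = fr
        return out


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    feature_modules: dict[str, str]  # feature name -> module label or 'none'
    features: pd.DataFrame  # name, mz, kind, module
    true_clone: dict[str, np.ndarray]  # run_id -> per-pixel {high, low, off}
    grid_shape: dict[str, tuple[int, int]]  # run_id -> (n_rows, n_cols)
    linked_module: str
    labeled_fraction: dict[str, dict[str, float]]
    batch_scale: dict[str, float]
    batch_shift: dict[str, float]

    def module_of(self, mz: float, tol_ppm: float = 20.0) -> str:
        """Module label of the planted feature nearest to ``mz`` (or 'none')."""
        d = np.abs(self.features["mz"].to_numpy() - mz)
        i = int(np.argmin(d))
        if d[i] / mz * 1e6 > tol_ppm:
            return "none"
        return self.features["module"].iloc[i]


def _smooth_field(rng: np.random.Generator, h: int, w: int, sigma: float) -> np.ndarray:
    """Smoothed standard-normal field, min-max scaled to [0, 1]."""
    f = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=sigma, mode="nearest")
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.zeros((h, w))
    return (f - lo) / (hi - lo)


def _draw_masses(rng: np.random.Generator, n: int, reserved: np.ndarray,
                 lo: float = 150.0, hi: float = 800.0, min_sep: float = 0.3) -> np.ndarray:
    """Random m/z values keeping >= min_sep Th from each other and ``reserved``."""
    masses = []
    taken = list(reserved)
    while len(masses) < n:
        m = rng.uniform(lo, hi)
        if all(abs(m - t) >= min_sep for t in taken):
            masses.append(m)
            taken.append(m)
    return np.array(masses)


def _tissue_layout(cfg: SynthConfig) -> list[tuple[str, str]]:
    if cfg.genotype_layout == "pure_high":
        return [("t_high", "high")]
    if cfg.genotype_layout == "pure_low":
        return [("t_low", "low")]
    return [("t_high", "high"), ("t_low", "low"), ("t_mix", "mix")]


def _isotopologue_probs(met: LabeledMetabolite, labeled_frac: float,
                        natural_p: float, k_max: int) -> np.ndarray:
    """Expected isotopologue distribution over k = 0..k_max.

    Unlabeled molecules carry natural abundance Binom(N, p); labeled ones
    carry label_k tracer carbons plus natural abundance on the rest.
    """
    ks = np.arange(met.n_carbons + 1)
    nat = stats.binom.pmf(ks, met.n_carbons, natural_p)
    lab = np.zeros(met.n_carbons + 1)
    rest = met.n_carbons - met.label_k
    lab[met.label_k:] = stats.binom.pmf(np.arange(rest + 1), rest, natural_p)
    full = (1.0 - labeled_frac) * nat + labeled_frac * lab
    probs = np.zeros(k_max + 1)
    upto = min(k_max, met.n_carbons)
    probs[: upto + 1] = full[: upto + 1]
    probs[upto] += full[upto + 1:].sum()  # fold the tail into the last channel
    return probs


def generate_biclonal_runs(config: SynthConfig) -> tuple[list[MSIRun], GroundTruth]:
    """Generate multi-run biclonal MSI data with planted structure.

    Each run holds the tissues named by ``genotype_layout`` side by side
    with a one-pixel off-tissue border.  Module features share a smoothed
    latent spatial field (module 'M1' is restricted to the MYC-high clone
    zone and is the genotype-linked module); noise ions occupy random blobs
    of < 9 eight-connected pixels; labeled metabolites get isotopologue
    channels k = 0..5 from multinomial draws around the binomial model.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    tissues = _tissue_layout(cfg)
    h, w = cfg.grid_h, cfg.grid_w
    n_cols = w * len(tissues)

    # --- feature catalog -------------------------------------------------
    iso_mz, iso_names = [], []
    k_max = 5
    for met in cfg.metabolites:
        for k in range(min(k_max, met.n_carbons) + 1):
            iso_mz.append(met.base_mz + k * DELTA_C13)
            iso_names.append(f"{met.name}_m{k}")
    iso_mz = np.array(iso_mz)

    n_mod_feat = cfg.n_modules * cfg.features_per_module
    mod_mz = _draw_masses(rng, n_mod_feat, iso_mz)
    noise_mz = _draw_masses(rng, cfg.n_noise_features, np.concatenate([iso_mz, mod_mz]))
    bg_mz = _draw_masses(
        rng, cfg.n_background_features, np.concatenate([iso_mz, mod_mz, noise_mz])
    )

    feat_rows = []
    feature_modules = {}
    for m in range(cfg.n_modules):
        for j in range(cfg.features_per_module):
            name = f"mod{m + 1}_f{j}"
            feat_rows.append((name, mod_mz[m * cfg.features_per_module + j],
                              "module", f"M{m + 1}"))
            feature_modules[name] = f"M{m + 1}"
    for j in range(cfg.n_noise_features):
        name = f"noise_{j}"
        feat_rows.append((name, noise_mz[j], "noise", "none"))
        feature_modules[name] = "none"
    for j in range(cfg.n_background_features):
        name = f"bg_{j}"
        feat_rows.append((name, bg_mz[j], "background", "none"))
        feature_modules[name] = "none"
    for name, mzv in zip(iso_names, iso_mz):
        feat_rows.append((name, mzv, "isotopologue", "none"))
        feature_modules[name] = "none"
    features = pd.DataFrame(feat_rows, columns=["name", "mz", "kind", "module"])

    baselines = rng.uniform(2.0, 5.0, n_mod_feat)
    amplitudes = rng.uniform(15.0, 30.0, n_mod_feat)
    bg_base = rng.uniform(20.0, 40.0, cfg.n_background_features)
    met_base = {met.name: rng.uniform(60.0, 120.0) for met in cfg.metabolites}
    labeled_fraction = cfg.labeled_fractions()

    batch_scale = {}
    batch_shift = {}
    runs: list[MSIRun] = []
    true_clone: dict[str, np.ndarray] = {}

    for r in range(cfg.n_runs):
        run_id = f"run{r + 1}"
        scale = float(cfg.batch_scale ** rng.uniform(-1.0, 1.0))
        shift = float(rng.uniform(0.0, cfg.batch_shift))
        batch_scale[run_id] = scale
        batch_shift[run_id] = shift
        mz_shift = 0.0
        if cfg.run_mz_shift_ppm is not None:
            mz_shift = cfg.run_mz_shift_ppm[r]

        genotype = np.full((h, n_cols), "off", dtype=object)
        clone = np.full((h, n_cols), "off", dtype=object)
        tissue_id = np.full((h, n_cols), "off", dtype=object)
        intensity = np.zeros((h, n_cols, len(features)))

        for t, (tname, tgeno) in enumerate(tissues):
            c0 = t * w
            inner = (slice(1, h - 1), slice(c0 + 1, c0 + w - 1))
            tissue_id[inner] = tname
            genotype[inner] = tgeno
            tw = w - 2
            th = h - 2
            if tgeno == "mix":
                half = tw // 2
                clone_block = np.tile(
                    np.where(np.arange(tw) < half, "high", "low"), (th, 1)
                )
            else:
                clone_block = np.full((th, tw), tgeno, dtype=object)
            clone[inner] = clone_block

            high_mask = clone_block == "high"
            # module features: shared latent field per module per tissue;
            # the per-tissue mean is anchored so module expression level is
            # comparable across tumors while the spatial pattern varies
            for m in range(cfg.n_modules):
                field = _smooth_field(rng, th, tw, sigma=max(th, tw) / 8)
                field = np.clip(field - field.mean() + 0.5, 0.0, 1.0)
                latent = 0.25 + 0.75 * field
                if m == 0:  # genotype-linked module, active in the high clone
                    latent = latent * np.where(high_mask, 1.0, 0.05)
                for j in range(cfg.features_per_module):
                    fi = m * cfg.features_per_module + j
                    mean = baselines[fi] + amplitudes[fi] * latent
                    noise = np.exp(rng.normal(0.0, cfg.pixel_noise_sigma, (th, tw)))
                    intensity[inner[0], inner[1], fi] = mean * noise

            # background ions: spatially unstructured, uncorrelated across
            # features; they anchor the per-pixel non-zero median
            for j in range(cfg.n_background_features):
                fi = n_mod_feat + cfg.n_noise_features + j
                noise = np.exp(rng.normal(0.0, cfg.pixel_noise_sigma, (th, tw)))
                intensity[inner[0], inner[1], fi] = bg_base[j] * noise

            # isotopologue channels
            col = n_mod_feat + cfg.n_noise_features + cfg.n_background_features
            for met in cfg.metabolites:
                n_ch = min(k_max, met.n_carbons) + 1
                base = met_base[met.name] * (
                    0.6 + 0.8 * _smooth_field(rng, th, tw, sigma=max(th, tw) / 6)
                )
                total = base * np.exp(rng.normal(0.0, cfg.pixel_noise_sigma, (th, tw)))
                probs_by_geno = {
                    g: _isotopologue_probs(met, labeled_fraction[met.name][g],
                                           cfg.natural_p, min(k_max, met.n_carbons))
                    for g in ("high", "low")
                }
                counts = np.zeros((th, tw, n_ch))
                for g in ("high", "low"):
                    sel = clone_block == g
                    if not sel.any():
                        continue
                    counts[sel] = rng.multinomial(
                        cfg.molecules_per_pixel, probs_by_geno[g], size=int(sel.sum())
                    )
                counts = counts / cfg.molecules_per_pixel * total[..., None]
                intensity[inner[0], inner[1], col: col + n_ch] = counts
                col += n_ch

        # scattered noise ions: one random blob of 3..8 pixels per run
        for j in range(cfg.n_noise_features):
            fi = n_mod_feat + j
            size = int(rng.integers(3, 9))
            r0 = int(rng.integers(0, h - 3))
            c0 = int(rng.integers(0, n_cols - 3))
            cells = {(r0, c0)}
            while len(cells) < size:
                rr, cc = list(cells)[int(rng.integers(0, len(cells)))]
                rr = min(max(rr + int(rng.integers(-1, 2)), 0), h - 1)
                cc = min(max(cc + int(rng.integers(-1, 2)), 0), n_cols - 1)
                cells.add((rr, cc))
            for rr, cc in cells:
                intensity[rr, cc, fi] = rng.uniform(5.0, 15.0)

        # batch effect on every present intensity
        present = intensity > 0
        intensity = np.where(present, intensity * scale + shift, 0.0)

        # assemble per-pixel peak lists with m/z jitter
        mz_true = features["mz"].to_numpy()
        peaks_mz, peaks_int = [], []
        flat_int = intensity.reshape(-1, len(features))
        for p in range(h * n_cols):
            row = flat_int[p]
            nz = np.flatnonzero(row > 1e-9)
            if nz.size == 0:
                peaks_mz.append(np.empty(0))
                peaks_int.append(np.empty(0))
                continue
            ppm = mz_shift + rng.normal(0.0, cfg.mz_jitter_ppm, nz.size)
            mzs = mz_true[nz] * (1.0 + ppm * 1e-6)
            order = np.argsort(mzs)
            peaks_mz.append(mzs[order])
            peaks_int.append(row[nz][order])

        runs.append(MSIRun(
            run_id=run_id,
            n_rows=h,
            n_cols=n_cols,
            peaks_mz=peaks_mz,
            peaks_intensity=peaks_int,
            tissue_id=np.array([f"{run_id}:{t}" if t != "off" else "off"
                                for t in tissue_id.reshape(-1)], dtype=object),
            genotype=genotype.reshape(-1).astype(str),
        ))
        true_clone[run_id] = clone.reshape(-1).astype(str)

    truth = GroundTruth(
        feature_modules=feature_modules,
        features=features,
        true_clone=true_clone,
        grid_shape={r.run_id: (r.n_rows, r.n_cols) for r in runs},
        linked_module="M1",
        labeled_fraction=labeled_fraction,
        batch_scale=batch_scale,
        batch_shift=batch_shift,
    )
    return runs, truth


def generate_ihc_fixture(
    seed: int,
    grid: tuple[int, int] = (64, 64),
    frac_high: float = 0.5,
    effect: float = 1.0,
    block: int = 16,
):
    """Synthetic deconvolved-DAB IHC image paired with an MSI-grid metabolite map.

    Returns ``(dab_channel, pa_image, true_high_mask)``.  The DAB green
    channel is 8-bit at ``block`` times the MSI resolution: inside the true
    MYC-high region >= 90% of pixels fall below the 230 staining threshold,
    outside >= 90% lie at or above it.  ``pa_image`` is an MSI-resolution
    metabolite map whose mean is ``1 + effect`` fold higher in the high
    region (effect=0 plants no contrast).
    """
    if not (0 <= frac_high <= 1):
        raise ValueError("frac_high must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = grid
    n_high_cols = int(round(frac_high * w))
    true_high = np.zeros((h, w), dtype=bool)
    true_high[:, :n_high_cols] = True

    H, W = h * block, w * block
    big_mask = np.kron(true_high, np.ones((block, block), dtype=bool))
    dab = np.where(
        big_mask,
        rng.uniform(80, 225, (H, W)),
        rng.uniform(232, 255, (H, W)),
    )
    # a few percent of mislabeled pixels on each side keeps it realistic
    flip = rng.random((H, W)) < 0.05
    dab = np.where(flip & big_mask, rng.uniform(231, 255, (H, W)), dab)
    dab = np.where(flip & ~big_mask, rng.uniform(150, 229, (H, W)), dab)
    dab = dab.astype(np.uint8)

    base = 10.0 * (0.7 + 0.6 * _smooth_field(rng, h, w, sigma=max(h, w) / 8))
    pa = base * np.exp(rng.normal(0.0, 0.2, (h, w)))
    pa = np.where(true_high, pa * (1.0 + effect), pa)
    return dab, pa, true_high


def generate_gcms_fixture(
    seed: int,
    n_carbons: int,
    true_enrichment: float,
    n_molecules: int = 100_000,
    natural_p: float = NATURAL_13C,
) -> np.ndarray:
    """Observed GC-MS isotopologue intensity vector for one metabolite.

    Each molecule's carbons are labeled independently with probability
    ``true_enrichment``; unlabeled carbons carry natural ¹³C abundance.
    The expected vector is therefore the convolution of
    Binom(n, true_enrichment) with binomial natural abundance, and the
    returned vector is a multinomial draw of ``n_molecules`` molecules.
    """
    if not (0 <= true_enrichment <= 1):
        raise ValueError("true_enrichment must lie in [0, 1]")
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_carbons
    probs = np.zeros(n + 1)
    for j in range(n + 1):  # j tracer-labeled carbons
        pj = stats.binom.pmf(j, n, true_enrichment)
        nat = stats.binom.pmf(np.arange(n - j + 1), n - j, natural_p)
        probs[j:] += pj * nat
    counts = rng.multinomial(n_molecules, probs)
    return counts.astype(float)
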