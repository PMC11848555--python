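"""Synthetic LDI-MS cohort generator.

Emulates the statistical structure of a serum metabolic fingerprinting study:
narrow Gaussian metabolite peaks on a dense low-mass grid (m/z 100-600,
~124,000 raw points per acquisition), log-normal sample-to-sample peak-height
variation so fold changes act multiplicatively, a smooth decaying chemical
baseline, heteroscedastic detector noise, per-spectrum m/z calibration jitter,
five technical replicates per sample, multiplicative batch effects and one
standard-serum QC acquisition per batch.  Every generated cohort carries its
ground truth (peak positions, differential subset, effect sizes, pi0) so
recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import RawSpectrum

__all__ = ["SynthConfig", "SyntheticTruth", "generate_cohort", "generate_phenotypes"]

#: Neuropsychological scales emitted by :func:`generate_phenotypes`.
#: TMT-A/B are completion times: larger is worse.
SCALES = ("MMSE", "MES", "SDMT", "AVLT", "VFT", "BNT", "CDT", "CFT", "TMT-A", "TMT-B")
HIGHER_IS_WORSE = ("TMT-A", "TMT-B")

VCI_LEVELS = ("none", "mild VCI", "VaD")


@dataclass
class SynthConfig:
    """Cohort design and signal model for the synthetic generator.

    Defaults mirror the emulated study's scale: 144 cases vs 144 controls,
    134 metabolite peaks in m/z 100-600, five replicate acquisitions, six
    differential peaks (four up-, two down-regulated in cases) — all
    configurable downward for fast tests.
    """

    n_case: int = 144
    n_control: int = 144
    n_replicates: int = 5
    n_batches: int = 4
    n_peaks: int = 134
    n_differential: int = 27
    log2fc_range: tuple[float, float] = (0.6, 2.8)
    mz_range: tuple[float, float] = (100.0, 600.0)
    n_raw_points: int = 124_000
    peak_width_sigma: float = 0.02  # Da; narrow relative to the 0.05 Da bin
    height_sigma_log: float = 1.4  # per-peak log-normal spread across samples
    baseline_amplitude: float = 20.0
    noise_cv: float = 0.05
    mz_jitter_sd: float = 0.01  # Da, one calibration shift per spectrum
    batch_scale_sd: float = 0.05
    n_case_clusters: int = 1
    cluster_log2_sep: float = 0.0  # per-cluster shift on a subset of peaks
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_case", "n_control", "n_replicates", "n_batches",
                     "n_peaks", "n_differential", "n_raw_points",
                     "n_case_clusters"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config field {name!r}: must be >= 0")
        if self.n_differential > self.n_peaks:
            raise ValueError("invalid config field 'n_differential': exceeds n_peaks")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("invalid config field 'mz_range': must be ascending")
        if self.noise_cv < 0:
            raise ValueError("invalid config field 'noise_cv': must be >= 0")
        if self.peak_width_sigma <= 0:
            raise ValueError("invalid config field 'peak_width_sigma': must be > 0")
        if self.log2fc_range[0] > self.log2fc_range[1]:
            raise ValueError("invalid config field 'log2fc_range': must be ascending")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort — the oracle for recovery tests."""

    peak_mz: np.ndarray
    differential_index: np.ndarray
    true_log2fc: np.ndarray  # signed, one per differential peak
    pi0_true: float
    group_of_sample: dict[str, str]
    cluster_of_case: Optional[dict[str, int]] = None
    base_heights: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: noiseless per-sample apex heights (samples in metadata order x peaks)
    sample_peak_heights: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    sample_order: list[str] = field(default_factory=list)


def _sample_heights(cfg: SynthConfig, rng: np.random.Generator,
                    base: np.ndarray, group: str, log2fc: np.ndarray,
                    cluster_shift: np.ndarray | None) -> np.ndarray:
    h = base * np.exp(rng.normal(0.0, cfg.height_sigma_log, size=cfg.n_peaks))
    if group == "case":
        h = h * 2.0 ** log2fc
        if cluster_shift is not None:
            h = h * 2.0 ** cluster_shift
    return h


def _render_spectrum(mz_grid: np.ndarray, peak_mz: np.ndarray,
                     heights: np.ndarray, sigma: float, shift: float,
                     baseline: np.ndarray, noise_cv: float, floor: float,
                     scale: float, rng: np.random.Generator) -> np.ndarray:
    """Sum of Gaussian peaks (evaluated on local windows only) + baseline + noise."""
    signal = np.zeros_like(mz_grid)
    half = 6.0 * sigma
    for mu, h in zip(peak_mz + shift, heights):
        lo = np.searchsorted(mz_grid, mu - half)
        hi = np.searchsorted(mz_grid, mu + half)
        if hi > lo:
            x = mz_grid[lo:hi]
            signal[lo:hi] += h * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    clean = (signal + baseline) * scale
    if noise_cv > 0 or floor > 0:
        sd = noise_cv * clean + floor
        clean = clean + rng.normal(0.0, 1.0, size=clean.shape) * sd
    return np.clip(clean, 0.0, None)


def generate_cohort(config: SynthConfig) -> tuple[list[RawSpectrum], pd.DataFrame, SyntheticTruth]:
    """Generate a full synthetic cohort: spectra, metadata table and truth.

    Returns ``n_replicates`` spectra per biological sample plus one QC
    spectrum per batch.  Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    lo, hi = cfg.mz_range
    mz_grid = np.linspace(lo, hi, cfg.n_raw_points) if cfg.n_raw_points > 0 else np.empty(0)

    # Peak positions: uniform with a minimum spacing so alignment clusters are unambiguous.
    min_gap = 0.5
    peak_mz = np.array([])
    if cfg.n_peaks > 0:
        span = hi - lo - 10.0
        u = np.sort(rng.uniform(0, 1, cfg.n_peaks))
        peak_mz = lo + 5.0 + u * (span - cfg.n_peaks * min_gap) + np.arange(cfg.n_peaks) * min_gap

    base = 10.0 ** rng.uniform(1.7, 2.7, cfg.n_peaks)  # apex heights ~50-500

    diff_idx = np.sort(rng.choice(cfg.n_peaks, size=cfg.n_differential, replace=False)) \
        if cfg.n_differential > 0 else np.array([], dtype=int)
    mags = rng.uniform(*cfg.log2fc_range, size=cfg.n_differential)
    signs = np.ones(cfg.n_differential)
    signs[2::3] = -1.0  # every third differential peak down-regulated (4 up / 2 down at n=6)
    log2fc_full = np.zeros(cfg.n_peaks)
    log2fc_full[diff_idx] = mags * signs

    # Optional case sub-structure for stratification tests: each cluster gets a
    # multiplicative shift on its own subset of non-differential peaks.
    cluster_shifts = None
    if cfg.n_case_clusters > 1 and cfg.cluster_log2_sep != 0.0:
        cluster_shifts = np.zeros((cfg.n_case_clusters, cfg.n_peaks))
        candidates = np.setdiff1d(np.arange(cfg.n_peaks), diff_idx)
        per = max(1, len(candidates) // (3 * cfg.n_case_clusters))
        for c in range(cfg.n_case_clusters):
            sub = rng.choice(candidates, size=min(per, len(candidates)), replace=False)
            cluster_shifts[c, sub] = cfg.cluster_log2_sep * rng.choice([-1.0, 1.0], size=len(sub))

    baseline = cfg.baseline_amplitude * np.exp(-(mz_grid - lo) / (0.3 * (hi - lo))) \
        if cfg.n_raw_points > 0 else np.empty(0)
    floor = 0.02 * cfg.baseline_amplitude if cfg.noise_cv > 0 else 0.0
    batch_names = [f"B{b + 1}" for b in range(cfg.n_batches)]
    batch_scale = {b: float(np.exp(rng.normal(0.0, cfg.batch_scale_sd))) for b in batch_names}

    spectra: list[RawSpectrum] = []
    meta_rows = []
    group_of: dict[str, str] = {}
    cluster_of: dict[str, int] = {}
    sample_order: list[str] = []
    height_rows = []

    n_total = cfg.n_case + cfg.n_control
    for i in range(n_total):
        group = "case" if i < cfg.n_case else "control"
        sid = f"{'MMD' if group == 'case' else 'HC'}{i + 1 if group == 'case' else i - cfg.n_case + 1:03d}"
        batch = batch_names[i % cfg.n_batches] if cfg.n_batches > 0 else ""
        cluster = i % cfg.n_case_clusters if (group == "case" and cfg.n_case_clusters > 1) else 0
        shift_vec = cluster_shifts[cluster] if (cluster_shifts is not None and group == "case") else None
        heights = _sample_heights(cfg, rng, base, group, log2fc_full, shift_vec)
        group_of[sid] = group
        if group == "case" and cfg.n_case_clusters > 1:
            cluster_of[sid] = cluster + 1
        sample_order.append(sid)
        height_rows.append(heights)
        scale_b = batch_scale.get(batch, 1.0)
        for r in range(1, cfg.n_replicates + 1):
            shift = rng.normal(0.0, cfg.mz_jitter_sd) if cfg.mz_jitter_sd > 0 else 0.0
            rep_scale = float(np.exp(rng.normal(0.0, cfg.noise_cv))) if cfg.noise_cv > 0 else 1.0
            inten = _render_spectrum(mz_grid, peak_mz, heights, cfg.peak_width_sigma,
                                     shift, baseline, cfg.noise_cv, floor,
                                     scale_b * rep_scale, rng)
            spectra.append(RawSpectrum(mz_grid.copy(), inten, sample_id=sid,
                                       replicate=r, batch=batch, is_qc=False))
            meta_rows.append((sid, r, batch, group, False))

    # One standard-serum QC acquisition per batch: fixed height vector, noise only.
    for batch in batch_names:
        qid = f"QC-{batch}"
        shift = rng.normal(0.0, cfg.mz_jitter_sd) if cfg.mz_jitter_sd > 0 else 0.0
        inten = _render_spectrum(mz_grid, peak_mz, base, cfg.peak_width_sigma,
                                 shift, baseline, cfg.noise_cv, floor,
                                 batch_scale[batch], rng)
        spectra.append(RawSpectrum(mz_grid.copy(), inten, sample_id=qid,
                                   replicate=1, batch=batch, is_qc=True))
        meta_rows.append((qid, 1, batch, "QC", True))

    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "replicate", "batch", "group", "is_qc"])
    truth = SyntheticTruth(
        peak_mz=peak_mz,
        differential_index=diff_idx,
        true_log2fc=log2fc_full[diff_idx],
        pi0_true=1.0 - (cfg.n_differential / cfg.n_peaks if cfg.n_peaks else 0.0),
        group_of_sample=group_of,
        cluster_of_case=cluster_of if cluster_of else None,
        base_heights=base,
        sample_peak_heights=np.array(height_rows) if height_rows else np.empty((0, cfg.n_peaks)),
        sample_order=sample_order,
    )
    return spectra, metadata, truth


def cohort_feature_matrix(config: SynthConfig):
    """Generate a cohort directly as a fingerprint matrix (no raw rendering).

    Applies the same statistical model as :func:`generate_cohort` — log-normal
    per-sample heights, differential fold changes, batch scale factors,
    multiplicative replicate measurement noise averaged over replicates —
    but skips spectrum rendering and preprocessing, producing the
    samples x peaks matrix the full pipeline would recover.  Used for
    studies of the downstream stages at scale.

    Returns ``(FeatureMatrix, SyntheticTruth)``.
    """
    from .containers import FeatureMatrix

    cfg = SynthConfig(**{**config.__dict__, "n_raw_points": 0})
    _, metadata, truth = generate_cohort(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    n_samples = len(truth.sample_order)
    values = np.array(truth.sample_peak_heights, dtype=float)
    batches = metadata.loc[~metadata.is_qc].drop_duplicates("sample_id")["batch"].to_list()
    batch_scale = {b: float(np.exp(rng.normal(0.0, cfg.batch_scale_sd)))
                   for b in sorted(set(batches))}
    for i in range(n_samples):
        rep_noise = np.exp(rng.normal(0.0, cfg.noise_cv,
                                      size=(max(cfg.n_replicates, 1), cfg.n_peaks)))
        values[i] = values[i] * rep_noise.mean(axis=0) * batch_scale.get(batches[i], 1.0)
    labels = np.array([truth.group_of_sample[s] for s in truth.sample_order])
    fm = FeatureMatrix(values=values, signal_mz=truth.peak_mz,
                       sample_ids=list(truth.sample_order), labels=labels,
                       batch=np.array(batches),
                       provenance={"generator": "cohort_feature_matrix",
                                   "seed": cfg.seed})
    return fm, truth


def generate_phenotypes(truth: SyntheticTruth, effect: float,
                        seed: int = 0) -> pd.DataFrame:
    """Neuropsychology table for the case samples of a cohort.

    One designated metabolite-pattern cluster (the highest-numbered) is
    shifted downward by ``effect`` pooled standard deviations on every scale
    (upward on TMT times, which are worse-is-higher), and carries elevated
    probabilities of mild VCI / vascular dementia.

    Parameters
    ----------
    truth
        Cohort truth with ``cluster_of_case`` assigned.
    effect
        Shift in pooled-SD units; must be >= 0.
    """
    if truth.cluster_of_case is None or not truth.cluster_of_case:
        raise ValueError("no case clusters assigned; generate the cohort with n_case_clusters > 1")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    cases = sorted(truth.cluster_of_case, key=truth.sample_order.index)
    clusters = np.array([truth.cluster_of_case[s] for s in cases])
    designated = clusters.max()

    means = {"MMSE": 27, "MES": 85, "SDMT": 45, "AVLT": 50, "VFT": 18,
             "BNT": 24, "CDT": 3.2, "CFT": 32, "TMT-A": 55, "TMT-B": 130}
    sds = {"MMSE": 2.5, "MES": 8, "SDMT": 9, "AVLT": 10, "VFT": 4,
           "BNT": 3, "CDT": 0.7, "CFT": 4, "TMT-A": 18, "TMT-B": 40}

    rows: dict[str, np.ndarray] = {}
    for scale in SCALES:
        direction = +1.0 if scale in HIGHER_IS_WORSE else -1.0
        shift = np.where(clusters == designated, direction * effect * sds[scale], 0.0)
        rows[scale] = means[scale] + shift + rng.normal(0.0, sds[scale], size=len(cases))

    base_p = np.array([0.80, 0.15, 0.05])
    elevated = base_p * np.array([1.0, np.exp(effect / 2), np.exp(effect)])
    elevated = elevated / elevated.sum()
    vci = [
        VCI_LEVELS[rng.choice(3, p=elevated if c == designated else base_p)]
        for c in clusters
    ]

    df = pd.DataFrame({"sample_id": cases, "cluster": clusters, **rows, "VCI": vci})
    return df.set_index("sample_id")
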