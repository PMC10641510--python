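"""Synthetic fNIRS cohort generator with known ground truth.

Emulates a two-condition (resting-state / passive story listening) pediatric
recording session: 50 measurement channels at two wavelengths (760/850 nm),
7.8 Hz sampling, an 18-block task design with ~20 s stimuli and 15-20 s
pseudo-randomized inter-stimulus intervals. Every stochastic choice flows
from the supplied seed, and every planted quantity (edge correlations,
artifact intervals, bad channels, group and moderation effects) is recorded
in a :class:`GroundTruth` object so downstream stages can be validated
without any real recording.

Generative model for one subject and condition
----------------------------------------------
Clean oxy-hemoglobin dynamics are the sum of a task-evoked response
(canonical double-gamma HRF convolved with the block design, task condition
only) and endogenous fluctuations drawn from a multivariate normal with a
planted channel-by-channel correlation matrix, temporally smoothed by a
kernel shared across channels (identical per-channel filtering leaves the
zero-lag cross-correlation structure untouched). HbR is modelled as a
sign-flipped, scaled copy of HbO. Concentrations are projected to optical
density via the modified Beer-Lambert law, and cardiac pulsation, 1/f drift,
white measurement noise, motion artifacts and poorly coupled channels are
added in the optical-density domain before exponentiation to raw intensity:

    I(lambda, c, t) = I0 * 10 ** (-dOD_total(lambda, c, t))
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AnnotationSet, Interval, Montage, RawRecording, default_montage
from .optics import dpf_general, extinction_pair

__all__ = [
    "SimConfig",
    "LatentStructure",
    "CohortEffects",
    "GroundTruth",
    "canonical_hrf",
    "build_block_design",
    "target_correlation",
    "nearest_positive_definite_corr",
    "correlated_series",
    "generate_subject",
    "generate_cohort",
    "inject_seizure_intervals",
]


@dataclass(frozen=True)
class LatentStructure:
    """Planted correlation structure, by hemisphere block and condition.

    Baseline edge correlations are ``within_hemi`` inside a hemisphere and
    ``between_hemi`` across hemispheres; the task condition raises
    within-hemisphere coupling by ``task_increment``. ``planted_edges`` pins
    explicit (i, j, rho) values on top (applied to both conditions).
    """

    within_hemi: float = 0.35
    between_hemi: float = 0.15
    task_increment: float = 0.10
    planted_edges: tuple[tuple[int, int, float], ...] = ()


@dataclass(frozen=True)
class CohortEffects:
    """Group-level effects planted into a simulated cohort.

    ``fc_left_offset`` / ``fc_right_offset`` shift patients'
    intra-hemispheric correlations (the clinical expectation being a left
    decrement and a right increment). ``age_slope`` is the per-year drift of
    edge coupling (applied in Fisher-z space). The cognition model is
    ``score = score_baseline + slope_g * metric + N(0, score_noise_sd)``
    with a standardized network metric and a group-specific slope
    implementing the moderation effect.
    """

    fc_left_offset: float = -0.08
    fc_right_offset: float = 0.04
    age_slope: float = 0.01
    slope_patients: float = -1.4
    slope_controls: float = 0.0
    score_baseline: float = 100.0
    score_noise_sd: float = 3.0


@dataclass(frozen=True)
class SimConfig:
    """Recording / paradigm parameters for the synthetic generator."""

    n_channels: int = 50
    fs: float = 7.8
    wavelengths: tuple[float, float] = (760.0, 850.0)
    duration_s: float = 720.0
    n_blocks: int = 18
    stim_dur_s: float = 20.0
    isi_range_s: tuple[float, float] = (15.0, 20.0)
    latent_structure: LatentStructure = field(default_factory=LatentStructure)
    artifact_spec: tuple[tuple[str, float, float, float], ...] = ()
    bad_channel_frac: float = 0.0
    seed: int = 0
    # amplitude / noise parameters (micromolar for hemodynamics, OD for nuisances)
    evoked_amp_uM: float = 0.5
    hemo_sd_uM: float = 1.0
    hemo_smooth_s: float = 0.5
    hbr_ratio: float = -0.4
    cardiac_od_amp: float = 4e-3
    drift_od_amp: float = 2e-3
    noise_od_sd: float = 1e-3
    baseline_intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s < 60:
            raise ValueError("duration_s must be at least 60 s")
        lo, hi = self.isi_range_s
        if lo > hi:
            raise ValueError("isi_range_s lower bound exceeds upper bound")
        if not 0 <= self.bad_channel_frac <= 1:
            raise ValueError("bad_channel_frac must lie in [0, 1]")
        for kind, _, _, frac in self.artifact_spec:
            if kind not in ("spike", "step", "drift"):
                raise ValueError(f"unknown artifact kind {kind!r}")
            if not 0 <= frac <= 1:
                raise ValueError("artifact channel fraction must lie in [0, 1]")

    @property
    def n_times(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream validation."""

    true_edge_corr: dict[str, np.ndarray] = field(default_factory=dict)
    artifact_intervals: list[tuple[float, float, list[int]]] = field(default_factory=list)
    excluded_intervals: list[tuple[float, float]] = field(default_factory=list)
    bad_channels: set[int] = field(default_factory=set)
    cohort_effects: CohortEffects | None = None
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_edge_corr": {k: v.tolist() for k, v in self.true_edge_corr.items()},
            "artifact_intervals": [
                [onset, dur, list(map(int, chans))]
                for onset, dur, chans in self.artifact_intervals
            ],
            "excluded_intervals": [list(iv) for iv in self.excluded_intervals],
            "bad_channels": sorted(int(c) for c in self.bad_channels),
            "cohort_effects": asdict(self.cohort_effects) if self.cohort_effects else None,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        gt = cls()
        gt.true_edge_corr = {
            k: np.asarray(v, dtype=float) for k, v in payload["true_edge_corr"].items()
        }
        gt.artifact_intervals = [
            (float(o), float(d), list(map(int, ch))) for o, d, ch in payload["artifact_intervals"]
        ]
        gt.excluded_intervals = [tuple(iv) for iv in payload["excluded_intervals"]]
        gt.bad_channels = set(payload["bad_channels"])
        if payload["cohort_effects"] is not None:
            gt.cohort_effects = CohortEffects(**payload["cohort_effects"])
        gt.seed = payload["seed"]
        return gt


def canonical_hrf(fs: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak ~6 s, undershoot ~16 s).

    Returned kernel is sampled at ``fs`` and normalized to unit peak.
    """
    t = np.arange(0, duration_s, 1.0 / fs)
    from scipy.stats import gamma as gamma_dist

    peak = gamma_dist.pdf(t, 6.0, scale=1.0)
    undershoot = gamma_dist.pdf(t, 16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def build_block_design(cfg: SimConfig, seed: int | None = None) -> AnnotationSet:
    """Stimulus schedule: ``n_blocks`` blocks with pseudo-random ISIs.

    Gaps between consecutive stimuli are drawn uniformly from
    ``isi_range_s``; the first block starts after one ISI-length lead-in.
    Blocks that would end beyond ``duration_s`` are truncated from the
    schedule. Raises if not even one block fits.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lo, hi = cfg.isi_range_s
    onsets = []
    t = float(rng.uniform(lo, hi))
    for _ in range(cfg.n_blocks):
        if t + cfg.stim_dur_s > cfg.duration_s:
            break
        onsets.append(t)
        t += cfg.stim_dur_s + float(rng.uniform(lo, hi))
    if not onsets:
        raise ValueError("duration too short for a single stimulus block")
    return AnnotationSet(Interval(o, cfg.stim_dur_s, "stimulus") for o in onsets)


def nearest_positive_definite_corr(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the nearest unit-diagonal PD matrix.

    Eigenvalue clipping followed by re-standardization to a correlation
    matrix; sufficient for generative use (a valid Cholesky factor exists).
    """
    sym = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, eps, None)
    fixed = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def target_correlation(
    cfg: SimConfig,
    montage: Montage,
    condition: str,
    group: str = "control",
    age: float | None = None,
    effects: CohortEffects | None = None,
) -> np.ndarray:
    """Planted correlation matrix for one subject/condition.

    Applies the latent block structure, group offsets on intra-hemispheric
    edges for patients, a per-year age drift in Fisher-z space, and any
    explicitly planted edges, then repairs to the nearest PD correlation.
    """
    ls = cfg.latent_structure
    n = cfg.n_channels
    hemi = montage.hemisphere
    same_hemi = hemi[:, None] == hemi[None, :]
    corr = np.where(same_hemi, ls.within_hemi, ls.between_hemi).astype(float)
    if condition == "task":
        corr[same_hemi] += ls.task_increment
    if group == "epilepsy" and effects is not None:
        left = hemi == "L"
        corr[np.outer(left, left)] += effects.fc_left_offset
        corr[np.outer(~left, ~left)] += effects.fc_right_offset
    if age is not None and effects is not None and effects.age_slope:
        off_diag = ~np.eye(n, dtype=bool)
        z = np.arctanh(np.clip(corr[off_diag], -0.999, 0.999))
        corr[off_diag] = np.tanh(z + effects.age_slope * (age - 12.0))
    for i, j, rho in ls.planted_edges:
        corr[i, j] = corr[j, i] = rho
    np.fill_diagonal(corr, 1.0)
    return nearest_positive_definite_corr(corr)


def _smoothing_kernel(fs: float, width_s: float) -> np.ndarray:
    """Unit-energy Gaussian kernel; identical filtering across channels."""
    if width_s <= 0:
        return np.ones(1)
    sigma = width_s * fs
    half = int(np.ceil(4 * sigma))
    t = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (t / sigma) ** 2)
    return k / np.sqrt(np.sum(k**2))


def correlated_series(
    corr: np.ndarray,
    n_times: int,
    rng: np.random.Generator,
    fs: float = 7.8,
    smooth_s: float = 0.5,
) -> np.ndarray:
    """Zero-mean unit-variance series with population correlation ``corr``.

    Channels share a single smoothing kernel, so smoothing rescales every
    covariance entry identically and the correlation matrix is preserved
    exactly in population.
    """
    chol = np.linalg.cholesky(corr)
    innovations = rng.standard_normal((corr.shape[0], n_times))
    series = chol @ innovations
    kernel = _smoothing_kernel(fs, smooth_s)
    if kernel.size > 1:
        pad = kernel.size // 2
        padded = np.pad(series, ((0, 0), (pad, pad)), mode="wrap")
        series = np.array(
            [np.convolve(ch, kernel, mode="valid") for ch in padded]
        )
    return series


def _stimulus_regressor(cfg: SimConfig, stimuli: AnnotationSet) -> np.ndarray:
    boxcar = stimuli.mask(cfg.n_times, cfg.fs, labels=["stimulus"]).astype(float)
    hrf = canonical_hrf(cfg.fs)
    reg = np.convolve(boxcar, hrf)[: cfg.n_times]
    peak = np.abs(reg).max()
    return reg / peak if peak > 0 else reg  # unit peak: evoked_amp_uM is the response amplitude


def clean_hemodynamics(
    cfg: SimConfig,
    corr: np.ndarray,
    stimuli: AnnotationSet | None,
    rng: np.random.Generator,
    evoked_gains: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free HbO component (µM) and its implied correlation matrix.

    The evoked response is a shared waveform with per-channel gains; its
    variance over the record adds a rank-one term to the endogenous
    covariance, and the returned matrix is the implied total correlation of
    the clean component (stored as ground truth).
    """
    endo = cfg.hemo_sd_uM * correlated_series(
        corr, cfg.n_times, rng, fs=cfg.fs, smooth_s=cfg.hemo_smooth_s
    )
    cov = cfg.hemo_sd_uM**2 * corr
    hbo = endo
    if stimuli is not None and len(stimuli) and cfg.evoked_amp_uM:
        waveform = _stimulus_regressor(cfg, stimuli)
        gains = (
            np.ones(cfg.n_channels) if evoked_gains is None else np.asarray(evoked_gains)
        )
        hbo = endo + cfg.evoked_amp_uM * gains[:, None] * waveform[None, :]
        v_e = float(np.var(waveform))
        cov = cov + (cfg.evoked_amp_uM**2 * v_e) * np.outer(gains, gains)
    d = np.sqrt(np.diag(cov))
    implied = cov / np.outer(d, d)
    np.fill_diagonal(implied, 1.0)
    return hbo, implied


def _forward_od(
    cfg: SimConfig, montage: Montage, hbo: np.ndarray, hbr: np.ndarray, age: float
) -> np.ndarray:
    """Modified Beer-Lambert forward projection to dOD, per wavelength."""
    dist_cm = montage.distance_mm / 10.0
    od = np.empty((cfg.n_channels, 2, cfg.n_times))
    for w, lam in enumerate(cfg.wavelengths):
        eps_hbo, eps_hbr = extinction_pair(lam)
        dpf = dpf_general(lam, age)
        od[:, w, :] = (eps_hbo * hbo + eps_hbr * hbr) * (dist_cm * dpf)[:, None]
    return od


def _inject_artifacts(
    cfg: SimConfig, od: np.ndarray, rng: np.random.Generator
) -> list[tuple[float, float, list[int]]]:
    """Add motion artifacts (in-place) per artifact_spec; returns the log."""
    n_times = od.shape[2]
    log: list[tuple[float, float, list[int]]] = []
    if not cfg.artifact_spec:
        return log
    # amplitude unit: robust SD of the moving-average deviation of the OD
    # signal (the same statistic the artifact detector thresholds on)
    from scipy.ndimage import uniform_filter1d

    win = max(3, int(round(6.0 * cfg.fs)))
    dev = od - uniform_filter1d(od, size=win, axis=2, mode="nearest")
    mad = np.median(np.abs(dev - np.median(dev, axis=2, keepdims=True)), axis=2)
    sd_unit = float(np.median(1.4826 * mad))
    occupied = np.zeros(n_times, dtype=bool)
    for kind, amp_sd, dur_s, frac in cfg.artifact_spec:
        n_aff = max(1, int(round(frac * cfg.n_channels)))
        channels = sorted(rng.choice(cfg.n_channels, size=n_aff, replace=False).tolist())
        n_dur = max(1, int(round(dur_s * cfg.fs)))
        gap = int(round(8.0 * cfg.fs))  # keep events separable
        for _ in range(200):
            onset_idx = int(rng.integers(0, max(1, n_times - n_dur)))
            lo = max(0, onset_idx - gap)
            hi = min(n_times, onset_idx + n_dur + gap)
            if not occupied[lo:hi].any():
                break
        occupied[onset_idx : onset_idx + n_dur] = True
        seg = slice(onset_idx, onset_idx + n_dur)
        scale = amp_sd * sd_unit
        if kind == "spike":
            # flat-topped transient: stays above detector threshold for most
            # of its nominal duration (a pure Gaussian would not)
            from scipy.signal.windows import tukey

            shape = tukey(n_dur, alpha=0.5)
        elif kind == "step":
            shape = np.ones(n_dur)
        else:  # drift
            shape = np.linspace(0.0, 1.0, n_dur)
        signs = rng.choice([-1.0, 1.0], size=n_aff)
        for ch, s in zip(channels, signs):
            od[ch, :, seg] += s * scale * shape
        log.append((onset_idx / cfg.fs, n_dur / cfg.fs, channels))
    return log


def generate_subject(
    cfg: SimConfig,
    subject_meta: dict | None = None,
    seed: int | None = None,
    condition: str = "task",
    montage: Montage | None = None,
    effects: CohortEffects | None = None,
) -> tuple[RawRecording, AnnotationSet, GroundTruth]:
    """Simulate one recording (one condition) with full ground truth.

    ``subject_meta`` may carry ``id``, ``group`` ('epilepsy'/'control') and
    ``age`` (years); defaults are a 12-year-old control.
    """
    meta = {"id": "sim", "group": "control", "age": 12.0}
    meta.update(subject_meta or {})
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    montage = montage or default_montage(cfg.n_channels)

    annotations = AnnotationSet()
    stimuli = None
    if condition == "task":
        stimuli = build_block_design(cfg, seed=int(rng.integers(2**31)))
        annotations.extend(stimuli)

    corr = target_correlation(
        cfg, montage, condition, group=meta["group"], age=meta["age"], effects=effects
    )
    hbo, implied_corr = clean_hemodynamics(cfg, corr, stimuli, rng)
    hbr = cfg.hbr_ratio * hbo
    od = _forward_od(cfg, montage, hbo, hbr, meta["age"])

    # poorly coupled channels: nearly no cardiac signal, inflated noise
    n_bad = int(round(cfg.bad_channel_frac * cfg.n_channels))
    bad = set(rng.choice(cfg.n_channels, size=n_bad, replace=False).tolist()) if n_bad else set()

    t = np.arange(cfg.n_times) / cfg.fs
    if cfg.cardiac_od_amp:
        f_card = float(rng.uniform(0.9, 1.6))  # subject's heart rate, within 0.8-2.3 Hz
        phase = rng.uniform(0, 0.3, size=cfg.n_channels)
        amp = cfg.cardiac_od_amp * rng.uniform(0.7, 1.3, size=cfg.n_channels)
        for ch in bad:
            amp[ch] *= 0.02
        cardiac = amp[:, None] * np.sin(2 * np.pi * f_card * t[None, :] + phase[:, None])
        od += cardiac[:, None, :]
    if cfg.drift_od_amp:
        freqs = rng.uniform(0.003, 0.02, size=(cfg.n_channels, 2, 3))
        phases = rng.uniform(0, 2 * np.pi, size=(cfg.n_channels, 2, 3))
        amps = cfg.drift_od_amp / (1.0 + np.arange(3))
        drift = np.sum(
            amps[None, None, :, None]
            * np.sin(2 * np.pi * freqs[..., None] * t + phases[..., None]),
            axis=2,
        )
        od += drift
    if cfg.noise_od_sd:
        noise_scale = np.full(cfg.n_channels, cfg.noise_od_sd)
        for ch in bad:
            noise_scale[ch] *= 8.0
        od += noise_scale[:, None, None] * rng.standard_normal(od.shape)

    artifact_log = _inject_artifacts(cfg, od, rng)
    for onset, dur, chans in artifact_log:
        annotations.add(Interval(onset, dur, "artifact", tuple(chans)))

    intensity = cfg.baseline_intensity * 10.0 ** (-od)
    recording = RawRecording(
        intensity=intensity,
        fs=cfg.fs,
        wavelengths=cfg.wavelengths,
        montage=montage,
        subject=dict(meta, condition=condition),
    )
    gt = GroundTruth(
        true_edge_corr={condition: implied_corr},
        artifact_intervals=artifact_log,
        bad_channels=bad,
        cohort_effects=effects,
        seed=seed,
    )
    return recording, annotations, gt


def inject_seizure_intervals(
    recording: RawRecording,
    k: int,
    seed: int,
    duration_s: float = 30.0,
    ground_truth: GroundTruth | None = None,
) -> AnnotationSet:
    """Draw ``k`` non-overlapping exclusion intervals (EEG-identified events).

    The fNIRS trace itself is left untouched -- exclusion windows are an
    annotation concern; raises if the intervals cannot be placed without
    overlap.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    total = recording.duration_s
    if k * duration_s > total:
        raise ValueError("exclusion intervals cannot fit in the recording")
    rng = np.random.default_rng(seed)
    onsets: list[float] = []
    for _ in range(10000):
        if len(onsets) == k:
            break
        cand = float(rng.uniform(0, total - duration_s))
        if all(abs(cand - o) >= duration_s for o in onsets):
            onsets.append(cand)
    if len(onsets) < k:
        raise ValueError("could not place non-overlapping exclusion intervals")
    out = AnnotationSet(Interval(o, duration_s, "exclusion") for o in sorted(onsets))
    if ground_truth is not None:
        ground_truth.excluded_intervals = [(iv.onset_s, iv.duration_s) for iv in out]
    return out


def modular_network(
    rng: np.random.Generator,
    n_nodes: int = 50,
    block: int = 25,
    n_bridges: int = 10,
    within: tuple[float, float] = (0.30, 0.60),
    between: tuple[float, float] = (0.0, 0.008),
    bridge: tuple[float, float] = (0.45, 0.60),
) -> np.ndarray:
    """Synthetic connectivity matrix with two dense blocks and sparse bridges.

    The canonical small-world test bed: high within-block coupling, a
    handful of strong inter-block bridges, and residual cross-block values
    below any useful sparsity threshold. Thresholded versions keep high
    clustering while the bridges keep paths short, so the normalized
    small-world index stays above 1 across the sparsity range.
    """
    b = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, 1)
    for i, j in zip(*iu):
        same = (i < block) == (j < block)
        lo, hi = within if same else between
        v = rng.uniform(lo, hi)
        b[i, j] = b[j, i] = v
    for _ in range(n_bridges):
        i = int(rng.integers(0, block))
        j = int(rng.integers(block, n_nodes))
        b[i, j] = b[j, i] = rng.uniform(*bridge)
    return b


def _simulate_clinical(rng: np.random.Generator, age: float) -> dict:
    onset = float(rng.uniform(1.0, max(1.5, age - 1.0)))
    return {
        "epilepsy_type": str(rng.choice(["FLE", "TLE"])),
        "lateralization": str(rng.choice(["left", "right", "bilateral"], p=[0.5, 0.35, 0.15])),
        "onset_age": onset,
        "duration": age - onset,
        "seizure_control": str(rng.choice(["yes", "no"], p=[0.6, 0.4])),
        "asm_count": int(rng.integers(1, 3)),
    }


def generate_cohort(
    n_patients: int,
    n_controls: int,
    cfg: SimConfig | None = None,
    effects: CohortEffects | None = None,
    seed: int = 0,
    signals: bool = False,
) -> tuple[list, pd.DataFrame, GroundTruth]:
    """Simulate a cohort: subject table, planted effects, optional signals.

    Ages are uniform on 6-18 y. Each subject carries a standardized network
    metric (the moderation target) and a cognitive score generated from the
    group-specific slope model. With ``signals=True`` each subject also gets
    a rest and a task recording (returned as dicts of condition ->
    (RawRecording, AnnotationSet, GroundTruth)); otherwise ``subjects`` is
    an empty list and only the table and ground truth are produced.
    """
    if n_patients < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per group")
    cfg = cfg or SimConfig()
    effects = effects or CohortEffects()
    rng = np.random.default_rng(seed)
    montage = default_montage(cfg.n_channels)

    rows = []
    subjects = []
    groups = ["epilepsy"] * n_patients + ["control"] * n_controls
    for i, group in enumerate(groups):
        age = float(rng.uniform(6.0, 18.0))
        metric = float(rng.standard_normal())
        slope = effects.slope_patients if group == "epilepsy" else effects.slope_controls
        score = (
            effects.score_baseline
            + slope * metric
            + float(rng.normal(0, effects.score_noise_sd))
        )
        row = {
            "subject": f"sub-{i + 1:03d}",
            "group": group,
            "age": age,
            "sex": str(rng.choice(["F", "M"])),
            "ses_income": int(rng.integers(1, 6)),
            "ses_parent_edu": float(rng.uniform(2, 6)),
            "metric_true": metric,
            "estimated_iq": score,
            "receptive_language": score + float(rng.normal(0, 5.0)),
            "expressive_language": score + float(rng.normal(0, 5.0)),
        }
        if group == "epilepsy":
            row.update(_simulate_clinical(rng, age))
        else:
            row.update(
                {
                    "epilepsy_type": None,
                    "lateralization": None,
                    "onset_age": np.nan,
                    "duration": np.nan,
                    "seizure_control": None,
                    "asm_count": np.nan,
                }
            )
        rows.append(row)
        if signals:
            subject_seed = int(rng.integers(2**31))
            meta = {"id": row["subject"], "group": group, "age": age}
            per_cond = {}
            for j, condition in enumerate(("rest", "task")):
                per_cond[condition] = generate_subject(
                    cfg,
                    meta,
                    seed=subject_seed + j,
                    condition=condition,
                    montage=montage,
                    effects=effects,
                )
            subjects.append(per_cond)

    table = pd.DataFrame(rows)
    gt = GroundTruth(cohort_effects=effects, seed=seed)
    return subjects, table, gt
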