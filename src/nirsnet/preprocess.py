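"""Raw intensity -> HbO/HbR preprocessing.

Stage order (each stage consumes the previous stage's bookkeeping):

1. cardiac-coherence channel QC (poor optode-scalp coupling),
2. moving-average artifact detection (6 s / 3 SD / 3 s / 5%-of-channels
   rules, correlated-channel augmentation, <2 s merge),
3. PARAFAC correction of isolated artifact intervals; long or uncorrectable
   noise is excluded, as are EEG-identified seizure intervals,
4. delta optical density,
5. fourth-order zero-phase Butterworth band-pass 0.001-0.5 Hz,
6. modified Beer-Lambert law with age-dependent differential pathlength
   factors,
7. global signal regression.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .core import AnnotationSet, HemoSeries, Interval, Montage, RawRecording
from .optics import dpf_general, extinction_matrix
from .parafac import cp_als

__all__ = [
    "PreprocessConfig",
    "cardiac_coherence_qc",
    "detect_artifacts",
    "parafac_correct",
    "mark_exclusions",
    "to_delta_od",
    "bandpass",
    "beer_lambert",
    "global_signal_regression",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters with study-standard defaults."""

    cardiac_band: tuple[float, float] = (0.8, 2.3)
    coherence_threshold: float = 0.1
    artifact_window_s: float = 6.0
    artifact_sd_k: float = 3.0
    artifact_min_dur_s: float = 3.0
    artifact_min_frac: float = 0.05
    artifact_corr_thr: float = 0.8
    artifact_merge_gap_s: float = 2.0
    long_noise_s: float = 10.0
    parafac_rank: int = 3
    parafac_context_s: float = 4.0
    parafac_taper_s: float = 1.0
    filter_band: tuple[float, float] = (0.001, 0.5)
    filter_order: int = 4
    dpf_override: tuple[float, float] | None = None
    extinction_override: tuple[tuple[float, float], tuple[float, float]] | None = None


# ---------------------------------------------------------------------------
# channel QC


def _welch_cross_spectra(x: np.ndarray, fs: float, nperseg: int):
    """Channel-by-channel cross-spectral matrices by Welch averaging.

    Returns (freqs, S) with S of shape (n_freqs, C, C). Hann window, 50%
    overlap, per-segment mean removal.
    """
    n_ch, n_t = x.shape
    step = nperseg // 2
    if n_t < 2 * nperseg:
        raise ValueError("recording too short for coherence estimation (needs >= 2 windows)")
    starts = range(0, n_t - nperseg + 1, step)
    win = np.hanning(nperseg)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    S = np.zeros((freqs.size, n_ch, n_ch), dtype=complex)
    count = 0
    for s in starts:
        seg = x[:, s : s + nperseg]
        seg = (seg - seg.mean(axis=1, keepdims=True)) * win
        X = np.fft.rfft(seg, axis=1)  # (C, F)
        S += np.einsum("cf,df->fcd", X, np.conj(X))
        count += 1
    S /= count
    return freqs, S


def cardiac_coherence_qc(
    raw: RawRecording,
    band: tuple[float, float] = (0.8, 2.3),
    threshold: float = 0.1,
    nperseg: int = 256,
) -> np.ndarray:
    """Flag channels with poor scalp coupling via cardiac-band coherence.

    The cardiac peak frequency is located on the channel-median power
    spectrum within ``band``; each channel's median magnitude-squared
    coherence with all other channels at that frequency must reach
    ``threshold`` to be retained.
    """
    lo, hi = band
    nyq = raw.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError("cardiac band must lie within (0, fs/2)")
    # work on delta-OD averaged over wavelengths: cardiac pulsation is
    # present at both wavelengths and the log transform removes scale
    dod = to_delta_od(raw.intensity)
    x = dod.mean(axis=1)
    freqs, S = _welch_cross_spectra(x, raw.fs, nperseg)
    in_band = (freqs >= lo) & (freqs <= hi)
    psd = np.real(np.einsum("fcc->fc", S))
    peak_band_idx = np.argmax(np.median(psd[in_band], axis=1))
    f_idx = np.flatnonzero(in_band)[peak_band_idx]
    Sf = S[f_idx]
    p = np.real(np.diag(Sf))
    denom = np.outer(p, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(Sf) ** 2 / denom
    np.fill_diagonal(coh, np.nan)
    med = np.nanmedian(coh, axis=1)
    return med >= threshold


# ---------------------------------------------------------------------------
# artifact detection


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_artifacts(
    series: np.ndarray,
    fs: float,
    window_s: float = 6.0,
    sd_k: float = 3.0,
    min_dur_s: float = 3.0,
    min_frac: float = 0.05,
    corr_thr: float = 0.8,
    merge_gap_s: float = 2.0,
) -> AnnotationSet:
    """Moving-average artifact detection on a channels x time array.

    A sample is a candidate when its deviation from the ``window_s`` moving
    average exceeds ``sd_k`` robust standard deviations (1.4826*MAD of the
    deviation signal over the whole record). Per-channel candidate runs
    longer than ``min_dur_s`` that coincide on at least ``min_frac`` of
    channels become artifact intervals; channels whose segment correlates
    above ``corr_thr`` with the flagged channels' mean segment are added to
    the affected set, and intervals closer than ``merge_gap_s`` are merged
    into one event.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n_ch, n_t = series.shape
    win = int(round(window_s * fs))
    if n_t < win:
        raise ValueError("series shorter than the detection window")
    dev = series - uniform_filter1d(series, size=max(3, win), axis=1, mode="nearest")
    mad = np.median(np.abs(dev - np.median(dev, axis=1, keepdims=True)), axis=1, keepdims=True)
    robust_sd = 1.4826 * mad
    robust_sd[robust_sd == 0] = np.inf
    flagged = np.abs(dev) > sd_k * robust_sd

    # close sub-half-second gaps so a noisy artifact stays one run
    gap = max(1, int(round(0.5 * fs)))
    min_len = int(round(min_dur_s * fs))
    per_channel = np.zeros_like(flagged)
    for c in range(n_ch):
        fm = flagged[c].copy()
        for s, e in _runs(~fm):
            if 0 < s and e < n_t and e - s <= gap:
                fm[s:e] = True
        for s, e in _runs(fm):
            if e - s > min_len:
                per_channel[c, s:e] = True

    n_required = max(1, int(np.ceil(min_frac * n_ch)))
    group = per_channel.sum(axis=0) >= n_required
    events = [(s, e) for s, e in _runs(group) if e - s > min_len]

    merge_gap = int(round(merge_gap_s * fs))
    merged: list[list[int]] = []
    for s, e in events:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    out = AnnotationSet()
    for s, e in merged:
        affected = set(np.flatnonzero(per_channel[:, s:e].any(axis=1)).tolist())
        if affected:
            ref = series[sorted(affected), s:e].mean(axis=0)
            ref = ref - ref.mean()
            ref_sd = ref.std()
            if ref_sd > 0:
                for c in range(n_ch):
                    if c in affected:
                        continue
                    seg = series[c, s:e] - series[c, s:e].mean()
                    sd = seg.std()
                    if sd > 0 and float(seg @ ref) / (seg.size * sd * ref_sd) > corr_thr:
                        affected.add(c)
        out.add(
            Interval(s / fs, (e - s) / fs, "artifact", tuple(sorted(affected)))
        )
    return out


# ---------------------------------------------------------------------------
# PARAFAC correction


def parafac_correct(
    series: np.ndarray,
    interval: Interval,
    fs: float,
    rank: int = 3,
    context_s: float = 4.0,
    taper_s: float = 1.0,
    variance_ratio_thr: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Subtract the artifact's trilinear signature inside ``interval``.

    ``series`` is channels x wavelengths x time. The interval plus context
    padding is decomposed (time x channel x wavelength) by CP-ALS with
    ``rank`` components, reduced when an extra component adds <1% explained
    variance. Components whose within-interval variance exceeds
    ``variance_ratio_thr`` times their context variance are treated as the
    artifact and subtracted inside the interval, with a linear cross-fade
    over ``taper_s`` at each boundary so the corrected segment joins the
    surrounding signal continuously. Returns the corrected copy and an info
    dict (``corrected`` False when ALS failed or nothing dominated).
    """
    series = np.asarray(series, dtype=float)
    n_ch, n_wl, n_t = series.shape
    sl = interval.sample_slice(fs)
    pad = int(round(context_s * fs))
    lo = max(0, sl.start - pad)
    hi = min(n_t, sl.stop + pad)
    seg = series[:, :, lo:hi]
    tensor = np.moveaxis(seg, 2, 0)  # time x channel x wavelength
    inner0 = slice(sl.start - lo, min(sl.stop, n_t) - lo)
    ctx0 = np.ones(hi - lo, dtype=bool)
    ctx0[inner0] = False
    # baseline from context samples only: the artifact must stay out of it
    base_src = tensor[ctx0] if ctx0.any() else tensor
    tensor0 = tensor - base_src.mean(axis=0, keepdims=True)

    fit = None
    prev_ev = 0.0
    for r in range(1, rank + 1):
        cand = cp_als(tensor0, r, seed=seed)
        ev = 1.0 - cand.rel_error**2
        if fit is not None and ev - prev_ev < 0.01:
            break
        fit, prev_ev = cand, ev
    if fit is None or not fit.converged:
        warnings.warn("PARAFAC did not converge; interval left for exclusion")
        return series.copy(), {"corrected": False, "reason": "non-convergence"}

    inner = slice(sl.start - lo, min(sl.stop, n_t) - lo)
    inner_len = inner.stop - inner.start
    context_mask = np.ones(hi - lo, dtype=bool)
    context_mask[inner] = False
    removed = []
    artifact = np.zeros_like(tensor0)
    for r in range(fit.weights.size):
        comp_time = fit.weights[r] * fit.factors[0][:, r]
        v_in = float(np.var(comp_time[inner])) if inner_len > 1 else 0.0
        v_out = float(np.var(comp_time[context_mask])) if context_mask.sum() > 1 else 0.0
        if v_out == 0 or v_in / v_out > variance_ratio_thr:
            artifact += fit.component(r)
            removed.append(r)
    if not removed:
        return series.copy(), {"corrected": False, "reason": "no dominating component"}

    weight = np.zeros(hi - lo)
    weight[inner] = 1.0
    n_taper = max(1, int(round(taper_s * fs)))
    ramp = np.linspace(0.0, 1.0, n_taper + 2)[1:-1]
    if inner.start > 0:
        a = max(inner.start - n_taper, 0)
        weight[a : inner.start] = ramp[-(inner.start - a) :]
    if inner.stop < hi - lo:
        b = min(inner.stop + n_taper, hi - lo)
        weight[inner.stop : b] = ramp[::-1][: b - inner.stop]

    corrected = series.copy()
    corrected[:, :, lo:hi] -= np.moveaxis(artifact * weight[:, None, None], 0, 2)
    return corrected, {
        "corrected": True,
        "components_removed": removed,
        "explained_variance": prev_ev,
    }


# ---------------------------------------------------------------------------
# masking, dOD, filtering, Beer-Lambert, GSR


def mark_exclusions(
    annotations: AnnotationSet,
    n_times: int,
    fs: float,
    long_noise_s: float = 10.0,
    failed_intervals: AnnotationSet | None = None,
) -> np.ndarray:
    """Validity mask: False under seizure exclusions and unrecoverable noise.

    Artifact intervals longer than ``long_noise_s`` and intervals whose
    correction failed are excluded; overlaps are unioned.
    """
    mask = np.ones(n_times, dtype=bool)
    for iv in annotations:
        drop = iv.label == "exclusion" or (
            iv.label == "artifact" and iv.duration_s > long_noise_s
        )
        if drop:
            sl = iv.sample_slice(fs)
            mask[max(0, sl.start) : min(n_times, sl.stop)] = False
    if failed_intervals is not None:
        for iv in failed_intervals:
            sl = iv.sample_slice(fs)
            mask[max(0, sl.start) : min(n_times, sl.stop)] = False
    return mask


def to_delta_od(intensity: np.ndarray, valid_mask: np.ndarray | None = None) -> np.ndarray:
    """Delta optical density: -log10(I / I_ref), I_ref = valid-sample mean."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        raise ValueError("intensity must be strictly positive")
    if valid_mask is None:
        ref = intensity.mean(axis=-1, keepdims=True)
    else:
        valid = np.asarray(valid_mask, dtype=bool)
        if not valid.any():
            raise ValueError("no valid samples for the dOD reference")
        ref = intensity[..., valid].mean(axis=-1, keepdims=True)
    return -np.log10(intensity / ref)


def bandpass(
    series: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.001, 0.5),
    order: int = 4,
    valid_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase Butterworth band-pass, segment-wise across masked gaps.

    Each contiguous valid segment is filtered forward-backward on its own;
    data are never interpolated through exclusions. Segments too short for
    the filter's edge padding are dropped from the mask with a warning.
    Returns (filtered, effective_mask); invalid samples are zeroed.
    """
    lo, hi = band
    nyq = fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError("band must lie within (0, fs/2)")
    series = np.asarray(series, dtype=float)
    n_t = series.shape[-1]
    mask = np.ones(n_t, dtype=bool) if valid_mask is None else np.asarray(valid_mask, dtype=bool).copy()
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # Zero-phase application in the frequency domain: forward-backward
    # filtering is multiplication by |H(w)|^2 with zero phase, and the
    # recursive form is numerically unreliable with the 0.001 Hz corner at
    # fs 7.8 (poles at the edge of the unit circle), so |H|^2 is applied to
    # the reflect-padded spectrum of each valid segment instead.
    min_len = 3 * 3 * (2 * sos.shape[0] + 1)
    out = np.zeros_like(series)
    for s, e in _runs(mask):
        n_seg = e - s
        if n_seg <= min_len:
            warnings.warn(f"segment [{s}, {e}) too short for zero-phase filtering; dropped")
            mask[s:e] = False
            continue
        pad = n_seg  # full reflection on both sides
        seg = series[..., s:e]
        padded = np.concatenate(
            [seg[..., pad - 1 :: -1], seg, seg[..., -1 : -pad - 1 : -1]], axis=-1
        )
        freqs = np.fft.rfftfreq(padded.shape[-1], d=1.0 / fs)
        _, h = sps.sosfreqz(sos, worN=2 * np.pi * freqs / fs)
        gain = np.abs(h) ** 2
        spec = np.fft.rfft(padded, axis=-1)
        filt = np.fft.irfft(spec * gain, n=padded.shape[-1], axis=-1)
        out[..., s:e] = filt[..., pad : pad + n_seg]
    return out, mask


def beer_lambert(
    dod: np.ndarray,
    wavelengths: tuple[float, float],
    age_years: float,
    montage: Montage,
    dpf_override: tuple[float, float] | None = None,
    extinction_override=None,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Invert the modified Beer-Lambert law per channel.

    Solves, for each channel with source-detector distance d (cm) and
    age-dependent DPF(lambda):

        dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * d * DPF(lambda)

    Returns (hbo, hbr) in µM and the DPF pair used.
    """
    dod = np.asarray(dod, dtype=float)
    if dod.ndim != 3 or dod.shape[1] != 2:
        raise ValueError("dod must be (n_channels, 2, n_times)")
    eps = (
        np.asarray(extinction_override, dtype=float)
        if extinction_override is not None
        else extinction_matrix(wavelengths)
    )
    if abs(np.linalg.det(eps)) < 1e-12:
        raise ValueError("extinction matrix is singular")
    dpf = (
        tuple(dpf_override)
        if dpf_override is not None
        else tuple(dpf_general(lam, age_years) for lam in wavelengths)
    )
    dist_cm = montage.distance_mm / 10.0
    hbo = np.empty((dod.shape[0], dod.shape[2]))
    hbr = np.empty_like(hbo)
    for c in range(dod.shape[0]):
        A = eps * (dist_cm[c] * np.asarray(dpf))[:, None]
        conc = np.linalg.solve(A, dod[c])
        hbo[c], hbr[c] = conc[0], conc[1]
    return hbo, hbr, dpf


def global_signal_regression(
    series: np.ndarray, retained: np.ndarray | None = None, valid_mask: np.ndarray | None = None
) -> np.ndarray:
    """Regress the mean of retained channels out of every channel (OLS).

    Residuals are orthogonal to the global-mean regressor on the valid
    samples; invalid samples are carried through with the same fit.
    """
    series = np.asarray(series, dtype=float)
    n_ch, n_t = series.shape
    keep = np.ones(n_ch, dtype=bool) if retained is None else np.asarray(retained, dtype=bool)
    if keep.sum() < 2:
        raise ValueError("need at least 2 retained channels for global regression")
    valid = np.ones(n_t, dtype=bool) if valid_mask is None else np.asarray(valid_mask, dtype=bool)
    g = series[keep].mean(axis=0)
    X = np.column_stack([np.ones(valid.sum()), g[valid]])
    beta, *_ = np.linalg.lstsq(X, series[:, valid].T, rcond=None)
    full_X = np.column_stack([np.ones(n_t), g])
    return series - (full_X @ beta).T


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class QCReport:
    retained_channels: np.ndarray
    artifact_intervals: AnnotationSet
    corrected_intervals: list
    excluded_intervals: list
    percent_valid: float
    dpf: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "n_retained": int(self.retained_channels.sum()),
            "excluded_channels": np.flatnonzero(~self.retained_channels).tolist(),
            "artifact_intervals": [
                [iv.onset_s, iv.duration_s] for iv in self.artifact_intervals
            ],
            "corrected_intervals": self.corrected_intervals,
            "excluded_intervals": self.excluded_intervals,
            "percent_valid": self.percent_valid,
            "dpf": list(self.dpf) if self.dpf else None,
        }


def preprocess_recording(
    raw: RawRecording,
    annotations: AnnotationSet | None = None,
    config: PreprocessConfig | None = None,
    seed: int = 0,
) -> tuple[HemoSeries, QCReport]:
    """Full preprocessing chain on one recording.

    ``annotations`` carries externally supplied intervals (seizure
    exclusions, stimulus blocks); detected artifacts are appended to it for
    the QC report.
    """
    cfg = config or PreprocessConfig()
    ann = AnnotationSet(annotations or [])

    retained = cardiac_coherence_qc(
        raw, band=cfg.cardiac_band, threshold=cfg.coherence_threshold
    )

    dod0 = to_delta_od(raw.intensity)
    flat = dod0.reshape(-1, raw.n_times)
    detected = detect_artifacts(
        flat,
        raw.fs,
        window_s=cfg.artifact_window_s,
        sd_k=cfg.artifact_sd_k,
        min_dur_s=cfg.artifact_min_dur_s,
        min_frac=cfg.artifact_min_frac,
        corr_thr=cfg.artifact_corr_thr,
        merge_gap_s=cfg.artifact_merge_gap_s,
    )

    intensity = raw.intensity.copy()
    corrected_log = []
    failed = AnnotationSet()
    for iv in detected:
        if iv.duration_s > cfg.long_noise_s:
            continue  # handled by mark_exclusions
        fixed, info = parafac_correct(
            intensity,
            iv,
            raw.fs,
            rank=cfg.parafac_rank,
            context_s=cfg.parafac_context_s,
            taper_s=cfg.parafac_taper_s,
            seed=seed,
        )
        if info["corrected"]:
            intensity = fixed
            corrected_log.append([iv.onset_s, iv.duration_s])
        else:
            failed.add(iv)

    all_ann = AnnotationSet(list(ann) + list(detected))
    valid = mark_exclusions(
        all_ann, raw.n_times, raw.fs, long_noise_s=cfg.long_noise_s, failed_intervals=failed
    )

    dod = to_delta_od(intensity, valid_mask=valid)
    filtered, valid = bandpass(
        dod, raw.fs, band=cfg.filter_band, order=cfg.filter_order, valid_mask=valid
    )
    age = float(raw.subject.get("age", 12.0))
    hbo, hbr, dpf = beer_lambert(
        filtered,
        raw.wavelengths,
        age,
        raw.montage,
        dpf_override=cfg.dpf_override,
        extinction_override=cfg.extinction_override,
    )
    hbo = global_signal_regression(hbo, retained=retained, valid_mask=valid)
    hbr = global_signal_regression(hbr, retained=retained, valid_mask=valid)

    series = HemoSeries(
        hbo=hbo,
        hbr=hbr,
        fs=raw.fs,
        valid_mask=valid,
        retained_channels=retained,
        dpf=dpf,
        montage=raw.montage,
        subject=dict(raw.subject),
    )
    excluded = [
        [iv.onset_s, iv.duration_s]
        for iv in all_ann
        if iv.label == "exclusion" or (iv.label == "artifact" and iv.duration_s > cfg.long_noise_s)
    ] + [[iv.onset_s, iv.duration_s] for iv in failed]
    report = QCReport(
        retained_channels=retained,
        artifact_intervals=detected,
        corrected_intervals=corrected_log,
        excluded_intervals=excluded,
        percent_valid=100.0 * valid.mean(),
        dpf=dpf,
    )
    return series, report
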