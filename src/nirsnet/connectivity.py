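"""Subject-level functional connectivity from HbO series.

Circular bootstrap (200 random 60-s windows, wrap-around allowed, windows
overlapping a masked sample rejected) -> zero-lag Pearson correlation per
window -> element-wise average (stage A) -> Fisher z (atanh) -> age effect
regressed out edge-wise across the cohort (stage B) -> task-minus-rest
residual (stage R).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import FCMatrix, HemoSeries

__all__ = [
    "AgeModel",
    "circular_bootstrap_windows",
    "window_correlation",
    "average_windows",
    "fisher_transform",
    "subject_fc",
    "regress_age",
    "residual_matrix",
]


def circular_bootstrap_windows(
    n_times: int,
    fs: float,
    n: int = 200,
    win_s: float = 60.0,
    valid_mask: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Start indices of ``n`` valid circular windows of ``win_s`` seconds.

    Starts are uniform over the circularized recording; a window is valid
    iff none of its (possibly wrapped) samples is masked. Draws are capped
    at 100*n; exceeding the cap raises with the achievable count.
    """
    win_len = int(round(win_s * fs))
    mask = np.ones(n_times, dtype=bool) if valid_mask is None else np.asarray(valid_mask, bool)
    if mask.sum() < win_len:
        raise ValueError("total valid time shorter than one window")
    rng = np.random.default_rng(seed)
    # precompute validity of every circular start: a start s is valid iff
    # the circular window [s, s+win_len) hits no masked sample
    bad = ~mask
    bad_circ = np.r_[bad, bad[: win_len - 1]]
    # windowed any-bad via cumulative sum
    cs = np.r_[0, np.cumsum(bad_circ)]
    window_bad = cs[win_len:] - cs[:-win_len] > 0
    valid_starts = ~window_bad[:n_times]
    if not valid_starts.any():
        raise ValueError("no valid circular window exists under the mask")
    starts = []
    for _ in range(100 * n):
        s = int(rng.integers(0, n_times))
        if valid_starts[s]:
            starts.append(s)
            if len(starts) == n:
                break
    if len(starts) < n:
        raise ValueError(
            f"only {len(starts)} valid windows found within the draw cap (requested {n})"
        )
    return np.asarray(starts)


def _extract_window(x: np.ndarray, start: int, win_len: int) -> np.ndarray:
    """Circular slice along the last axis."""
    n_t = x.shape[-1]
    idx = (start + np.arange(win_len)) % n_t
    return x[..., idx]


def window_correlation(window: np.ndarray) -> np.ndarray:
    """Zero-lag Pearson correlation matrix; diagonal 0, NaN for flat channels."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] < 2 or window.shape[1] < 2:
        raise ValueError("window must be (n_channels >= 2, n_samples >= 2)")
    centered = window - window.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    flat = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered @ centered.T) / window.shape[1] / np.outer(sd, sd)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    np.fill_diagonal(corr, 0.0)
    # numerical guard: keep off-diagonals strictly inside [-1, 1]
    return np.clip(corr, -1.0, 1.0, out=corr)


def average_windows(
    matrices: list[np.ndarray],
    subject: str = "",
    condition: str = "task",
    channels: list[str] | None = None,
) -> FCMatrix:
    """Element-wise mean over window correlation matrices (stage A).

    Entries missing (NaN) in some windows are averaged over the windows
    where they are defined; a pair missing everywhere raises.
    """
    if not matrices:
        raise ValueError("need at least one window")
    stack = np.stack(matrices)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    missing = np.isnan(mean)
    np.fill_diagonal(missing, False)
    if missing.any():
        i, j = np.argwhere(missing)[0]
        raise ValueError(f"edge ({i}, {j}) is undefined in every window")
    np.fill_diagonal(mean, 0.0)
    # guard against |rho| = 1 from duplicated channels in every window
    off = ~np.eye(mean.shape[0], dtype=bool)
    mean[off] = np.clip(mean[off], -1 + 1e-12, 1 - 1e-12)
    return FCMatrix(
        values=(mean + mean.T) / 2.0,
        stage="A",
        condition=condition,
        subject=subject,
        n_samples_used=len(matrices),
        channels=channels,
    )


def fisher_transform(fc: FCMatrix) -> FCMatrix:
    """Element-wise atanh; values at |rho| = 1 are clipped with a warning."""
    if fc.stage != "A":
        raise ValueError("fisher_transform expects a stage-A matrix")
    vals = fc.values.copy()
    off = ~np.eye(vals.shape[0], dtype=bool)
    clip = np.abs(vals[off]) >= 1.0
    if clip.any():
        warnings.warn("correlations at |rho| = 1 clipped to 1 - 1e-7 before atanh")
        vals[off] = np.clip(vals[off], -1 + 1e-7, 1 - 1e-7)
    z = np.arctanh(vals)
    np.fill_diagonal(z, 0.0)
    return FCMatrix(
        values=z,
        stage="B",
        condition=fc.condition,
        subject=fc.subject,
        n_samples_used=fc.n_samples_used,
        channels=fc.channels,
    )


def subject_fc(
    hemo: HemoSeries,
    n_windows: int = 200,
    win_s: float = 60.0,
    seed: int = 0,
    condition: str = "task",
) -> FCMatrix:
    """Stage-A FC for one subject from its HbO series."""
    starts = circular_bootstrap_windows(
        hemo.n_times, hemo.fs, n=n_windows, win_s=win_s, valid_mask=hemo.valid_mask, seed=seed
    )
    win_len = int(round(win_s * hemo.fs))
    mats = [window_correlation(_extract_window(hemo.hbo, s, win_len)) for s in starts]
    return average_windows(
        mats,
        subject=str(hemo.subject.get("id", "")),
        condition=condition,
        channels=hemo.montage.channels if hemo.montage else None,
    )


@dataclass
class AgeModel:
    """Edge-wise linear age model fitted across subjects: z = b0 + b1*age."""

    beta0: np.ndarray
    beta1: np.ndarray
    mean_age: float

    def predict(self, age: float) -> np.ndarray:
        return self.beta0 + self.beta1 * age


def regress_age(
    matrices: list[FCMatrix], ages: np.ndarray, keep_level: bool = True
) -> tuple[AgeModel, list[FCMatrix]]:
    """Remove the developmental (age) effect edge-wise across the cohort.

    Fits z_edge = b0 + b1*age by OLS over all supplied subjects (patients
    and controls pooled, one condition) and returns stage-B matrices
    B_n = z_n - b1*(age_n - mean age): the age effect is removed while the
    grand connectivity level is retained, so downstream absolute thresholds
    remain meaningful. ``keep_level=False`` returns raw residuals
    z_n - b0 - b1*age_n instead. With (near-)zero age variance the
    matrices are returned unchanged with a warning.
    """
    if len(matrices) < 3:
        raise ValueError("need at least 3 subjects to fit the age model")
    ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != len(matrices):
        raise ValueError("ages length must match number of subjects")
    stack = np.stack([m.values for m in matrices])  # (n_sub, C, C)
    mean_age = float(ages.mean())
    var_age = float(((ages - mean_age) ** 2).sum())
    n = stack.shape[0]
    if var_age < 1e-12:
        warnings.warn("zero age variance; stage B equals the input matrices")
        beta1 = np.zeros(stack.shape[1:])
        beta0 = stack.mean(axis=0)
    else:
        centered_age = ages - mean_age
        beta1 = np.tensordot(centered_age, stack - stack.mean(axis=0), axes=(0, 0)) / var_age
        beta0 = stack.mean(axis=0) - beta1 * mean_age
    model = AgeModel(beta0=beta0, beta1=beta1, mean_age=mean_age)
    out = []
    for m, age in zip(matrices, ages):
        if keep_level:
            b = m.values - beta1 * (age - mean_age)
        else:
            b = m.values - beta0 - beta1 * age
        np.fill_diagonal(b, 0.0)
        out.append(
            FCMatrix(
                values=(b + b.T) / 2.0,
                stage="B",
                condition=m.condition,
                subject=m.subject,
                n_samples_used=m.n_samples_used,
                channels=m.channels,
            )
        )
    return model, out


def residual_matrix(b_task: FCMatrix, b_rest: FCMatrix) -> FCMatrix:
    """Task-minus-rest residual (stage R) for one subject."""
    if b_task.values.shape != b_rest.values.shape:
        raise ValueError("channel sets differ between task and rest matrices")
    if b_task.channels and b_rest.channels and b_task.channels != b_rest.channels:
        raise ValueError("channel names differ between task and rest matrices")
    r = b_task.values - b_rest.values
    np.fill_diagonal(r, 0.0)
    return FCMatrix(
        values=(r + r.T) / 2.0,
        stage="R",
        condition="residual",
        subject=b_task.subject,
        n_samples_used=min(b_task.n_samples_used, b_rest.n_samples_used),
        channels=b_task.channels,
    )
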