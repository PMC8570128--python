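"""ERP preprocessing: epoching, artifact rejection, bad-channel spline
interpolation, Butterworth band-pass, average reference, instantaneous
spatial smoothing, and per-subject/condition averaging.

The pipeline order is fixed: epoch -> reject -> interpolate -> filter ->
re-reference -> smooth -> average.  Epoch windows are half-open
[start, end) in ms with sample 0 at stimulus onset; the default
-50..550 ms window at 512 Hz gives round(0.6 * 512) = 307 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from scipy.special import eval_legendre

from .io import Recording
from .layout import ElectrodeLayout

__all__ = [
    "Epochs",
    "EpochedERP",
    "PreprocessError",
    "n_epoch_samples",
    "epoch",
    "reject_artifacts",
    "interpolate_bad_channels",
    "bandpass",
    "average_reference",
    "spatial_smooth",
    "average_erp",
    "preprocess_recording",
]


class PreprocessError(ValueError):
    pass


def n_epoch_samples(window: tuple[float, float], srate: float) -> int:
    """Samples in a half-open [start, end) ms window."""
    return int(round((window[1] - window[0]) / 1000.0 * srate))


def epoch_times_ms(window: tuple[float, float], srate: float) -> np.ndarray:
    n = n_epoch_samples(window, srate)
    return window[0] + np.arange(n) * 1000.0 / srate


@dataclass
class Epochs:
    """Single-subject epoched data: trial x channel x time, in uV."""

    data: np.ndarray
    conditions: list[str]
    srate: float
    window: tuple[float, float]
    log: list[dict] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def times_ms(self) -> np.ndarray:
        return epoch_times_ms(self.window, self.srate)


@dataclass
class EpochedERP:
    """Group ERPs: subject x condition x channel x time, in uV."""

    data: np.ndarray
    srate: float
    window: tuple[float, float]
    conditions: list[str]
    channel_labels: list[str]
    n_epochs_accepted: np.ndarray  # subject x condition
    rejection_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        expect = n_epoch_samples(self.window, self.srate)
        if self.data.shape[-1] != expect:
            raise PreprocessError(
                f"time axis has {self.data.shape[-1]} samples, window/srate imply {expect}"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def times_ms(self) -> np.ndarray:
        return epoch_times_ms(self.window, self.srate)

    def time_indices(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Sample indices of a half-open [start, end) ms sub-window."""
        t = self.times_ms()
        return np.flatnonzero((t >= window_ms[0]) & (t < window_ms[1]))


# ---------------------------------------------------------------------------

def epoch(
    rec: Recording,
    window: tuple[float, float] = (-50.0, 550.0),
    keep_incorrect: bool = False,
) -> Epochs:
    """Cut stimulus-locked epochs out of a continuous recording.

    Trials with incorrect responses are dropped (logged, reason
    ``incorrect_response``) unless ``keep_incorrect``.  Events whose
    window would cross a recording edge are logged with reason ``edge``
    rather than silently discarded.
    """
    n = n_epoch_samples(window, rec.srate)
    offset = int(round(window[0] / 1000.0 * rec.srate))
    kept, conds, log = [], [], []
    for ti, (s, cond, correct) in enumerate(rec.events):
        if not correct and not keep_incorrect:
            log.append({"trial": ti, "reason": "incorrect_response", "condition": cond})
            continue
        start = s + offset
        if start < 0 or start + n > rec.n_samples:
            log.append({"trial": ti, "reason": "edge", "condition": cond})
            continue
        kept.append(rec.data[:, start:start + n])
        conds.append(cond)
    data = np.stack(kept) if kept else np.empty((0, rec.n_channels, n))
    return Epochs(data, conds, rec.srate, tuple(window), log)


def reject_artifacts(
    epochs: Epochs, threshold: float = 100.0
) -> tuple[Epochs, list[dict]]:
    """Drop every epoch containing any |sample| > threshold uV.

    Returns the retained epochs and a rejection log recording the
    (trial, channel, sample) of the first violation per rejected epoch.
    """
    if threshold <= 0:
        raise PreprocessError("rejection threshold must be positive")
    keep = np.ones(epochs.n_trials, dtype=bool)
    rejections = []
    for i, ep in enumerate(epochs.data):
        viol = np.argwhere(np.abs(ep) > threshold)
        if len(viol):
            keep[i] = False
            ch, s = viol[0]
            rejections.append(
                {"trial": i, "reason": "amplitude", "channel": int(ch),
                 "sample": int(s), "value": float(ep[ch, s])}
            )
    out = Epochs(
        epochs.data[keep],
        [c for c, k in zip(epochs.conditions, keep) if k],
        epochs.srate,
        epochs.window,
        epochs.log + rejections,
    )
    return out, rejections


# ---------------------------------------------------------------------------
# spherical spline interpolation (Perrin-style)

def _spline_g(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n ** m * (n + 1.0) ** m)
    x = np.clip(cosang, -1.0, 1.0)
    p = np.stack([eval_legendre(k, x) for k in n])
    return (coef[:, None, None] * p).sum(axis=0) / (4 * np.pi)


def interpolate_bad_channels(
    epochs: Epochs | np.ndarray,
    bad: list[str],
    layout: ElectrodeLayout,
    m: int = 4,
    reg: float = 1e-5,
):
    """Replace bad channels by spherical-spline estimates from the rest.

    Splines of order ``m`` with Tikhonov regularization ``reg`` on the
    interpolation system; good channels are untouched.
    """
    if not bad:
        return epochs
    if len(bad) >= layout.n_channels / 4:
        raise PreprocessError(
            f"{len(bad)} bad channels is too many for {layout.n_channels} electrodes"
        )
    data = epochs.data if isinstance(epochs, Epochs) else np.asarray(epochs, float)
    arr = data.reshape(-1, data.shape[-2], data.shape[-1]) if data.ndim == 3 else data[None]
    bad_idx = layout.index(bad)
    good_idx = np.setdiff1d(np.arange(layout.n_channels), bad_idx)
    pos = layout.positions
    g_gg = _spline_g(pos[good_idx] @ pos[good_idx].T, m=m)
    g_bg = _spline_g(pos[bad_idx] @ pos[good_idx].T, m=m)
    ng = len(good_idx)
    sys = np.zeros((ng + 1, ng + 1))
    sys[:ng, :ng] = g_gg + reg * np.eye(ng)
    sys[:ng, ng] = 1.0
    sys[ng, :ng] = 1.0
    out = arr.copy()
    for ep in range(arr.shape[0]):
        rhs = np.vstack([arr[ep, good_idx, :], np.zeros(arr.shape[-1])])
        sol = np.linalg.solve(sys, rhs)
        c, c0 = sol[:ng], sol[ng]
        out[ep, bad_idx, :] = g_bg @ c + c0
    out = out.reshape(data.shape)
    if isinstance(epochs, Epochs):
        return Epochs(out, list(epochs.conditions), epochs.srate, epochs.window,
                      epochs.log + [{"reason": "interpolated", "channels": list(bad)}])
    return out


# ---------------------------------------------------------------------------

def bandpass(
    epochs: Epochs | np.ndarray,
    band: tuple[float, float] = (1.0, 30.0),
    order: int = 2,
    srate: float | None = None,
):
    """Zero-phase band-pass: cascaded 2nd-order Butterworth high- and
    low-pass, applied forward-backward along the time axis."""
    if isinstance(epochs, Epochs):
        srate = epochs.srate
    if srate is None:
        raise PreprocessError("srate required when filtering a bare array")
    lo, hi = band
    if not 0 < lo < hi < srate / 2:
        raise PreprocessError(f"band {band} outside (0, Nyquist={srate / 2})")
    sos_hp = scipy.signal.butter(order, lo, "highpass", fs=srate, output="sos")
    sos_lp = scipy.signal.butter(order, hi, "lowpass", fs=srate, output="sos")
    sos = np.vstack([sos_hp, sos_lp])
    data = epochs.data if isinstance(epochs, Epochs) else np.asarray(epochs, float)
    out = scipy.signal.sosfiltfilt(sos, data, axis=-1)
    if isinstance(epochs, Epochs):
        return Epochs(out, list(epochs.conditions), epochs.srate, epochs.window,
                      list(epochs.log))
    return out


def average_reference(epochs: Epochs | np.ndarray):
    """Subtract the per-sample mean over channels (channel axis = -2)."""
    data = epochs.data if isinstance(epochs, Epochs) else np.asarray(epochs, float)
    if data.shape[-2] < 2:
        raise PreprocessError("average reference needs at least 2 channels")
    out = data - data.mean(axis=-2, keepdims=True)
    if isinstance(epochs, Epochs):
        return Epochs(out, list(epochs.conditions), epochs.srate, epochs.window,
                      list(epochs.log))
    return out


def spatial_smooth(
    epochs: Epochs | np.ndarray,
    layout: ElectrodeLayout,
    sigma: float | None = None,
):
    """Instantaneous spatial filter: each channel becomes a Gaussian
    distance-weighted average of itself and its neighbors.

    ``sigma`` is in unit-sphere chord distance; the default is the
    median nearest-neighbor distance of the layout.  The operator is
    linear and purely spatial (no temporal mixing); weights are
    row-normalized so a spatially constant map is unchanged.
    """
    pos = layout.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    if sigma is None:
        nn = np.where(np.eye(len(pos), dtype=bool), np.inf, d).min(axis=1)
        sigma = float(np.median(nn))
    if sigma <= 0:
        return epochs
    w = np.exp(-0.5 * (d / sigma) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    data = epochs.data if isinstance(epochs, Epochs) else np.asarray(epochs, float)
    out = np.einsum("ij,...jt->...it", w, data)
    if isinstance(epochs, Epochs):
        return Epochs(out, list(epochs.conditions), epochs.srate, epochs.window,
                      list(epochs.log))
    return out


# ---------------------------------------------------------------------------

def average_erp(
    per_subject: list[Epochs],
    conditions: list[str],
    channel_labels: list[str],
) -> EpochedERP:
    """Average accepted epochs per subject and condition.

    Subjects with an empty condition cell are flagged in the
    rejection_log and their cell is NaN (excluded from group stats by
    the statistics layer).
    """
    if not per_subject:
        raise PreprocessError("no subjects")
    srate, window = per_subject[0].srate, per_subject[0].window
    n = n_epoch_samples(window, srate)
    n_ch = per_subject[0].data.shape[1] if per_subject[0].n_trials else len(channel_labels)
    data = np.full((len(per_subject), len(conditions), n_ch, n), np.nan)
    counts = np.zeros((len(per_subject), len(conditions)), dtype=int)
    log: list[dict] = []
    for si, ep in enumerate(per_subject):
        conds = np.array(ep.conditions)
        for ci, cond in enumerate(conditions):
            sel = conds == cond if len(conds) else np.array([], bool)
            counts[si, ci] = int(sel.sum())
            if counts[si, ci] == 0:
                log.append({"subject": si, "condition": cond, "reason": "empty_cell"})
                continue
            data[si, ci] = ep.data[sel].mean(axis=0)
    return EpochedERP(data, srate, window, list(conditions), list(channel_labels),
                      counts, log)


def preprocess_recording(
    rec: Recording,
    layout: ElectrodeLayout,
    window: tuple[float, float] = (-50.0, 550.0),
    reject_threshold: float = 100.0,
    band: tuple[float, float] = (1.0, 30.0),
    filter_order: int = 2,
    bad_channels: list[str] | None = None,
    manual_exclude: list[int] | None = None,
    smooth_sigma: float | None = None,
) -> Epochs:
    """Full single-subject chain in the fixed order:
    epoch -> reject -> interpolate -> filter -> re-reference -> smooth.

    ``manual_exclude`` is an injectable list of trial indices standing in
    for visual-inspection rejection.
    """
    eps = epoch(rec, window=window)
    if manual_exclude:
        keep = np.array([i not in set(manual_exclude) for i in range(eps.n_trials)])
        eps = Epochs(eps.data[keep],
                     [c for c, k in zip(eps.conditions, keep) if k],
                     eps.srate, eps.window,
                     eps.log + [{"reason": "manual", "trials": sorted(manual_exclude)}])
    eps, _ = reject_artifacts(eps, threshold=reject_threshold)
    if bad_channels:
        eps = interpolate_bad_channels(eps, bad_channels, layout)
    eps = bandpass(eps, band=band, order=filter_order)
    eps = average_reference(eps)
    eps = spatial_smooth(eps, layout, sigma=smooth_sigma)
    return eps
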