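"""Synthetic multi-subject ERP data with known ground truth.

Emulates the structure of a 128-channel continuous-recognition-task
ERP study: three conditions (New, Rep3, NBack) per subject, each built
as a schedule of quasi-stable scalp topographies in fixed post-stimulus
windows, scaled by a per-subject log-normal gain, plus sensor noise.
Planted templates, planted source nodes and planted blink artifacts
give every downstream stage a recoverable answer.

Defaults mirror the study conditions the pipeline is meant for:
20 subjects, -50..550 ms epochs at 512 Hz, condition-specific maps in
the 145-300 ms window (New/NBack share a map that Rep3 does not) and a
late 405-470 ms map stronger for NBack than New, with fronto-central
loading.  Map amplitudes are on the GFP scale (a unit-norm template
times amplitude a has GFP a/sqrt(n_channels)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import ElectrodeLayout
from .microstate import TemplateMapSet, spatial_correlation
from .preprocess import EpochedERP, n_epoch_samples, epoch_times_ms
from .io import Recording
from .sequence import TaskSequence

__all__ = [
    "GroundTruth",
    "make_templates",
    "default_ground_truth",
    "simulate_erp_dataset",
    "simulate_raw_with_artifacts",
]


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    window_schedule maps condition -> list of
    (window_ms (start, end), template_index, amplitude_uV); windows must
    not overlap within a condition and amplitudes are positive.
    """

    templates: TemplateMapSet
    window_schedule: dict[str, list[tuple[tuple[float, float], int, float]]]
    noise_sd: float = 1.0
    subject_gain_sigma: float = 0.2
    source_nodes: dict[str, int] = field(default_factory=dict)
    crossfade_ms: float = 10.0
    noise_mode: str = "white"       # or "correlated"
    noise_corr_scale: float = 0.3   # chord-distance scale of correlated noise
    noise_band: tuple[float, float] | None = (1.0, 30.0)  # None = broadband white

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for cond, sched in self.window_schedule.items():
            sched = sorted(sched, key=lambda x: x[0][0])
            for (w, ti, amp) in sched:
                if amp <= 0:
                    raise ValueError(f"{cond}: amplitude must be positive, got {amp}")
                if not 0 <= ti < self.templates.k:
                    raise ValueError(f"{cond}: template index {ti} out of range")
                if w[0] >= w[1]:
                    raise ValueError(f"{cond}: window {w} not ordered")
            for (w1, _, _), (w2, _, _) in zip(sched, sched[1:]):
                if w2[0] < w1[1]:
                    raise ValueError(f"{cond}: overlapping windows {w1} and {w2}")
            self.window_schedule[cond] = sched

    @property
    def conditions(self) -> list[str]:
        return list(self.window_schedule)


def make_templates(k: int, layout: ElectrodeLayout, seed: int = 0,
                   max_abs_corr: float = 0.5, frontal_bias: float = 0.0,
                   max_tries: int = 200) -> TemplateMapSet:
    """k smooth, unit-norm, mutually low-correlated scalp maps.

    Each map is the scalp pattern of a random dipole inside the head
    (potential ~ d.(x - c)/|x - c|^3 sampled at the electrodes),
    average-referenced and normalized.  Candidates are rejected until
    pairwise |spatial correlation| < ``max_abs_corr`` against all
    accepted maps (best candidate kept if the budget runs out).
    ``frontal_bias`` in [0, 1] pulls dipole locations toward the
    anterior-superior quadrant.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > layout.n_channels:
        raise ValueError(f"k={k} exceeds {layout.n_channels} channels")
    rng = np.random.default_rng(seed)
    pos = layout.positions
    frontal = np.array([0.0, 0.8, 0.6])

    def candidate() -> np.ndarray:
        c = rng.normal(size=3)
        c = c / np.linalg.norm(c) * rng.uniform(0.2, 0.6)
        c = (1 - frontal_bias) * c + frontal_bias * frontal * rng.uniform(0.3, 0.6)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        diff = pos - c
        v = diff @ d / np.linalg.norm(diff, axis=1) ** 3
        v = v - v.mean()
        return v / np.linalg.norm(v)

    maps: list[np.ndarray] = []
    for _ in range(k):
        best, best_r = None, np.inf
        for _ in range(max_tries):
            v = candidate()
            r = max((abs(spatial_correlation(v, m)) for m in maps), default=0.0)
            if r < best_r:
                best, best_r = v, r
            if r < max_abs_corr:
                break
        maps.append(best)
    return TemplateMapSet(np.stack(maps))


def default_ground_truth(
    layout: ElectrodeLayout,
    seed: int = 0,
    noise_sd: float = 1.0,
    subject_gain_sigma: float = 0.2,
    early_amp: float = 5.0,
    late_strong: float = 5.0,
    late_weak: float = 2.5,
) -> GroundTruth:
    """The packaged study-like ground truth.

    Five templates; a common perceptual map at 0-145 ms; in 145-300 ms
    New and NBack express map 0 while Rep3 expresses map 1 (the
    encoding-like dissociation); a shared map at 300-405 ms; in
    405-470 ms map 2 is stronger for NBack than for New and Rep3 (the
    recognition-like contrast); the closing 470-550 ms re-expresses the
    shared map 3 so the whole post-stimulus epoch carries topographies,
    as real ERPs do.
    """
    templates = make_templates(5, layout, seed=seed, frontal_bias=0.5)
    sched = {
        "New": [((0.0, 145.0), 3, 4.0), ((145.0, 300.0), 0, early_amp),
                ((300.0, 405.0), 4, 4.0), ((405.0, 470.0), 2, late_weak),
                ((470.0, 550.0), 3, 3.0)],
        "Rep3": [((0.0, 145.0), 3, 4.0), ((145.0, 300.0), 1, early_amp),
                 ((300.0, 405.0), 4, 4.0), ((405.0, 470.0), 2, late_weak),
                 ((470.0, 550.0), 3, 3.0)],
        "NBack": [((0.0, 145.0), 3, 4.0), ((145.0, 300.0), 0, early_amp),
                  ((300.0, 405.0), 4, 4.0), ((405.0, 470.0), 2, late_strong),
                  ((470.0, 550.0), 3, 3.0)],
    }
    return GroundTruth(templates, sched, noise_sd=noise_sd,
                       subject_gain_sigma=subject_gain_sigma)


def _activation_courses(
    sched, times_ms: np.ndarray, crossfade_ms: float
) -> list[tuple[np.ndarray, int, float]]:
    """Per scheduled window: activation time course with linear
    cross-fades where two windows share a boundary."""
    out = []
    for wi, (w, ti, amp) in enumerate(sched):
        a = ((times_ms >= w[0]) & (times_ms < w[1])).astype(float)
        out.append([a, ti, amp, w])
    if crossfade_ms > 0:
        for (a1, _, _, w1), (a2, _, _, w2) in zip(out, out[1:]):
            if abs(w1[1] - w2[0]) < 1e-9:  # adjacent: blend across the boundary
                b = w1[1]
                zone = (times_ms >= b - crossfade_ms / 2) & (times_ms < b + crossfade_ms / 2)
                ramp = (times_ms[zone] - (b - crossfade_ms / 2)) / crossfade_ms
                a1[zone] = 1.0 - ramp
                a2[zone] = ramp
    return [(a, ti, amp) for a, ti, amp, _ in out]


def _noise(rng, shape, truth: GroundTruth, layout: ElectrodeLayout | None,
           srate: float = 512.0):
    """Sensor noise: Gaussian, band-limited to the analysis band (the
    ERPs this emulates are band-pass filtered, so their residual noise
    is temporally smooth), variance-normalized to noise_sd per sample,
    optionally spatially correlated."""
    if truth.noise_sd == 0:
        return np.zeros(shape)
    if truth.noise_band is None:
        return rng.normal(scale=truth.noise_sd, size=shape)
    import scipy.signal

    # generate with padding and crop the interior: filtfilt edge
    # transients would otherwise inflate variance at the epoch edges
    pad = int(round(srate))
    pshape = shape[:-1] + (shape[-1] + 2 * pad,)
    noise = rng.normal(scale=truth.noise_sd, size=pshape)
    lo, hi = truth.noise_band
    sos = np.vstack([
        scipy.signal.butter(2, lo, "highpass", fs=srate, output="sos"),
        scipy.signal.butter(2, hi, "lowpass", fs=srate, output="sos"),
    ])
    noise = scipy.signal.sosfiltfilt(sos, noise, axis=-1)[..., pad:-pad]
    sd = noise.std()
    if sd > 0:
        noise *= truth.noise_sd / sd
    if truth.noise_mode == "correlated" and layout is not None:
        d = np.linalg.norm(layout.positions[:, None] - layout.positions[None, :], axis=-1)
        cov = np.exp(-d / truth.noise_corr_scale)
        chol = np.linalg.cholesky(cov + 1e-9 * np.eye(len(d)))
        # normalize rows so per-channel variance stays noise_sd^2
        chol /= np.linalg.norm(chol, axis=1, keepdims=True)
        noise = np.einsum("ij,...jt->...it", chol, noise)
    return noise


def simulate_erp_dataset(
    truth: GroundTruth,
    n_subjects: int = 20,
    layout: ElectrodeLayout | None = None,
    srate: float = 512.0,
    epoch_window: tuple[float, float] = (-50.0, 550.0),
    seed: int = 0,
) -> tuple[EpochedERP, dict]:
    """Simulate per-subject, per-condition average ERPs.

    Each ERP is the scheduled sum of amplitude x subject_gain x template
    (linearly cross-faded at shared window boundaries) plus sensor
    noise; the pre-stimulus baseline is pure noise.  Returns the
    EpochedERP and a dict with the per-subject gains and the noise-free
    signal.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if layout is None:
        from .layout import biosemi128_layout

        layout = biosemi128_layout()
    n_ch = truth.templates.maps.shape[1]
    if n_ch != layout.n_channels:
        raise ValueError("template channel count does not match layout")
    times = epoch_times_ms(epoch_window, srate)
    for cond, sched in truth.window_schedule.items():
        for (w, _, _) in sched:
            if w[0] < epoch_window[0] or w[1] > epoch_window[1]:
                raise ValueError(f"{cond}: scheduled window {w} outside epoch {epoch_window}")
    conds = truth.conditions
    rng = np.random.default_rng(seed)
    gains = np.exp(rng.normal(0.0, truth.subject_gain_sigma, size=n_subjects))

    signal = np.zeros((len(conds), n_ch, len(times)))
    for ci, cond in enumerate(conds):
        for a, ti, amp in _activation_courses(truth.window_schedule[cond], times,
                                              truth.crossfade_ms):
            signal[ci] += amp * np.outer(truth.templates.maps[ti], a)

    data = gains[:, None, None, None] * signal[None] + _noise(
        rng, (n_subjects, len(conds), n_ch, len(times)), truth, layout, srate
    )
    erps = EpochedERP(
        data, srate, tuple(epoch_window), list(conds), list(layout.labels),
        n_epochs_accepted=np.full((n_subjects, len(conds)), 1, dtype=int),
    )
    return erps, {"subject_gains": gains, "signal": signal}


def simulate_raw_with_artifacts(
    seq: TaskSequence,
    truth: GroundTruth,
    layout: ElectrodeLayout | None = None,
    srate: float = 512.0,
    stim_ms: float = 2000.0,
    isi_ms: float = 700.0,
    blink_rate: float = 0.0,
    blink_amp: float = 150.0,
    blink_trials: list[int] | None = None,
    blink_duration_ms: float = 300.0,
    epoch_window: tuple[float, float] = (-50.0, 550.0),
    seed: int = 0,
) -> tuple[Recording, dict]:
    """Continuous recording for a task sequence, with optional blinks.

    Stimulus onsets are spaced ``stim_ms + isi_ms`` apart; conditions in
    the ground-truth schedule get their scheduled topographies, other
    trial types just noise.  Blinks are frontal-weighted raised-cosine
    transients of the given amplitude, at Poisson times
    (``blink_rate``/min) and/or centered in the epochs of
    ``blink_trials``.  Returns the recording and a dict with blink
    sample times and the ground-truth list of contaminated trials
    (trials whose epoch window overlaps a blink).
    """
    if layout is None:
        from .layout import biosemi128_layout

        layout = biosemi128_layout()
    rng = np.random.default_rng(seed)
    n_ch = layout.n_channels
    trial_step = int(round((stim_ms + isi_ms) / 1000.0 * srate))
    lead_in = int(round(srate))  # 1 s of padding at each end
    onsets = lead_in + np.arange(len(seq.trials)) * trial_step
    n_samples = int(onsets[-1] + trial_step + lead_in)
    data = _noise(rng, (n_ch, n_samples), truth, layout, srate)

    times_rel = epoch_times_ms(epoch_window, srate)
    post = times_rel >= 0
    for onset, (_, ttype, _) in zip(onsets, seq.trials):
        sched = truth.window_schedule.get(ttype)
        if not sched:
            continue
        for a, ti, amp in _activation_courses(sched, times_rel, truth.crossfade_ms):
            sl = slice(onset, onset + post.sum())
            data[:, sl] += amp * np.outer(truth.templates.maps[ti], a[post])

    # blink artifact: frontal-weighted raised cosine
    frontal = np.array([0.0, 0.8, 0.6])
    w = np.maximum(layout.positions @ frontal, 0.0) ** 2
    w /= w.max() if w.max() > 0 else 1.0
    blink_len = int(round(blink_duration_ms / 1000.0 * srate))
    shape = 0.5 * (1 - np.cos(2 * np.pi * np.arange(blink_len) / blink_len))

    blink_starts: list[int] = []
    if blink_rate > 0:
        rate_per_sample = blink_rate / 60.0 / srate
        blink_starts += list(np.flatnonzero(rng.random(n_samples - blink_len) < rate_per_sample))
    ep_off = int(round(epoch_window[0] / 1000.0 * srate))
    ep_n = n_epoch_samples(epoch_window, srate)
    if blink_trials:
        for ti in blink_trials:
            center = onsets[ti] + ep_off + ep_n // 2
            blink_starts.append(int(center - blink_len // 2))
    for s in blink_starts:
        data[:, s:s + blink_len] += blink_amp * np.outer(w, shape[: data.shape[1] - s])

    contaminated = []
    for i, onset in enumerate(onsets):
        e0, e1 = onset + ep_off, onset + ep_off + ep_n
        if any(s < e1 and s + blink_len > e0 for s in blink_starts):
            contaminated.append(i)

    events = [(int(o), t if t in truth.window_schedule else t, True)
              for o, (_, t, _) in zip(onsets, seq.trials)]
    rec = Recording(data, srate, list(layout.labels), events)
    return rec, {"blink_starts": sorted(int(s) for s in blink_starts),
                 "contaminated_trials": contaminated}


def source_ground_truth(
    lead,
    layout: ElectrodeLayout,
    seed: int = 0,
    noise_sd: float = 1.0,
    subject_gain_sigma: float = 0.2,
    amp: float = 5.0,
) -> GroundTruth:
    """Ground truth whose condition-specific maps are forward projections
    of single nodes of a lead field, for end-to-end source recovery.

    Conditions differ in WHICH node is active, not in gain (per-node
    time standardization is scale-invariant, so pure gain contrasts are
    deliberately not planted): in the early window (145-205 ms) New and
    NBack activate one node while Rep3 activates a different one (the
    encoding-like contrast); in the late window (405-470 ms) NBack
    activates its own node while New and Rep3 share another (the
    recognition-like contrast).  Shared dipolar maps fill 0-145 and
    210-300 ms.  ``source_nodes`` records the planted node indices.
    """
    rng = np.random.default_rng(seed)
    # superficial nodes have the strongest, most distinctive scalp maps
    radii = np.linalg.norm(lead.node_positions, axis=1)
    superficial = np.flatnonzero(radii >= np.percentile(radii, 60))

    def pick_distinct(n_pick: int) -> list[int]:
        chosen: list[int] = []
        for _ in range(500):
            cand = int(rng.choice(superficial))
            if cand in chosen:
                continue
            if all(abs(spatial_correlation(lead.gain[cand], lead.gain[c])) < 0.5
                   for c in chosen):
                chosen.append(cand)
            if len(chosen) == n_pick:
                break
        if len(chosen) < n_pick:
            raise ValueError("could not find mutually distinct source nodes")
        return chosen

    e_shared, e_rep, l_nback, l_other = pick_distinct(4)
    shared = make_templates(2, layout, seed=seed + 1)

    def from_node(n: int) -> np.ndarray:
        v = lead.gain[n] - lead.gain[n].mean()
        return v / np.linalg.norm(v)

    maps = np.vstack([from_node(e_shared), from_node(e_rep),
                      from_node(l_nback), from_node(l_other), shared.maps])
    templates = TemplateMapSet(maps)
    sched = {
        "New": [((0.0, 145.0), 4, 4.0), ((145.0, 205.0), 0, amp),
                ((210.0, 300.0), 5, 4.0), ((405.0, 470.0), 3, amp)],
        "Rep3": [((0.0, 145.0), 4, 4.0), ((145.0, 205.0), 1, amp),
                 ((210.0, 300.0), 5, 4.0), ((405.0, 470.0), 3, amp)],
        "NBack": [((0.0, 145.0), 4, 4.0), ((145.0, 205.0), 0, amp),
                  ((210.0, 300.0), 5, 4.0), ((405.0, 470.0), 2, amp)],
    }
    return GroundTruth(templates, sched, noise_sd=noise_sd,
                       subject_gain_sigma=subject_gain_sigma,
                       source_nodes={"early_shared": int(e_shared),
                                     "early_rep3": int(e_rep),
                                     "late_nback": int(l_nback),
                                     "late_other": int(l_other)})


def tiling_ground_truth(
    layout: ElectrodeLayout,
    k: int = 5,
    seed: int = 0,
    noise_sd: float = 1.0,
    amp: float = 5.0,
    epoch_span: tuple[float, float] = (0.0, 550.0),
    conditions: tuple[str, ...] = ("New", "Rep3", "NBack"),
) -> GroundTruth:
    """k templates tiling the post-stimulus epoch in equal windows,
    identical across conditions: the canonical template-recovery
    configuration (no condition contrasts, every map at the standard
    amplitude)."""
    templates = make_templates(k, layout, seed=seed)
    edges = np.linspace(epoch_span[0], epoch_span[1], k + 1)
    sched = [((float(a), float(b)), i, amp) for i, (a, b) in
             enumerate(zip(edges, edges[1:]))]
    return GroundTruth(templates, {c: list(sched) for c in conditions},
                       noise_sd=noise_sd)
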