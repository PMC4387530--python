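"""Synthetic calcium-imaging data with known ground truth.

Generates per-cell calcium transients for the 14 transient classes observed
in urothelial monolayers (nine under ATP perfusion, five more after scratch
wounding), lays cells out as a confluent monolayer (optionally with a
scratch-wound strip removed), and renders two reciprocal dye channels so
that the green/red ratio is a monotone function of calcium.

The waveform family is piecewise exponential relaxation between target
levels plus raised-cosine spikes: each class is a schedule of (start time,
target level, time constant) segments.  Where a class's plateau exceeds half
its peak, the post-peak decay undershoots to a floor below the half-maximum
(so the FWHM is well defined for every cell) and then relaxes up to the
plateau.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd

from . import defaults as dflt
from .signatures import Trace

ATP_CLASSES = ("1a", "1b", "1c", "2a", "2b", "2c", "3a", "3b", "3c")
WOUND_CLASSES = ("1a", "1b", "1c", "2a", "2b", "W1", "W2", "W3", "W4", "W5")
ALL_CLASSES = ATP_CLASSES + ("W1", "W2", "W3", "W4", "W5")
SPIKING_CLASSES = ("2c", "3b", "3c")


@dataclasses.dataclass
class TransientParams:
    """Generative parameters of one cell's calcium transient.

    Levels are ratio a.u. above baseline; times in seconds.  ``extras``
    holds per-class timing knobs (second-peak time, spike epoch bounds,
    decay floor) expressed mostly as fractions of the post-stimulus span.
    """

    baseline: float = 0.2
    peak_amplitude: float = 0.0
    peak_time_s: float = 60.0
    rise_tau_s: float = 8.0
    decay_tau_s: float = 60.0
    plateau_level: float = 0.0
    plateau2_level: float = 0.0
    spike_interval_s: float = 0.0
    spike_amplitude: float = 0.0
    noise_sd: float = 0.0
    class_label: str = "1a"
    extras: dict = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        if self.class_label not in ALL_CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        for name in ("baseline", "peak_amplitude", "plateau_level",
                     "plateau2_level", "spike_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("time constants must be > 0")
        if self.class_label in SPIKING_CLASSES and self.spike_interval_s <= 0:
            raise ValueError("spiking class needs spike_interval_s > 0")


@dataclasses.dataclass
class WoundGeometry:
    """Scratch-wound edge as a polyline in pixel coordinates (x, y)."""

    edge: np.ndarray            # (n, 2) vertices
    removed_side: str = "left"  # side of the field the strip was removed from
    wound_time_s: float = dflt.DEFAULT_PRESTIM_S

    def __post_init__(self) -> None:
        self.edge = np.asarray(self.edge, dtype=float)
        if self.edge.ndim != 2 or self.edge.shape[0] < 2 or self.edge.shape[1] != 2:
            raise ValueError("wound edge needs >= 2 (x, y) vertices")
        if self.removed_side not in ("left", "right"):
            raise ValueError("removed_side must be 'left' or 'right'")


@dataclasses.dataclass
class Cell:
    centroid_px: tuple[float, float]  # (x, y)
    radius_px: float
    params: TransientParams
    true_class: str


@dataclasses.dataclass
class CellLayout:
    field_size_px: tuple[int, int]  # (H, W)
    pixel_size_um: float
    cells: list[Cell]
    wound: WoundGeometry | None = None

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("layout must contain at least one cell")
        h, w = self.field_size_px
        for c in self.cells:
            x, y = c.centroid_px
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError("cell centroid outside field")
            if c.radius_px <= 0:
                raise ValueError("cell radius must be > 0")

    @property
    def centroids(self) -> np.ndarray:
        return np.array([c.centroid_px for c in self.cells], dtype=float)


@dataclasses.dataclass
class ImageSequence:
    """Two-channel ratiometric time-lapse stack (arbitrary units)."""

    red: np.ndarray    # (T, H, W)
    green: np.ndarray
    frame_interval_s: float
    pixel_size_um: float = dflt.DEFAULT_PIXEL_SIZE_UM
    stimulus_time_s: float = dflt.DEFAULT_PRESTIM_S
    dye_polarity: str = "green_up"

    def __post_init__(self) -> None:
        if self.red.shape != self.green.shape:
            raise ValueError("red and green stacks must have identical shape")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.red.shape[0]

    def calcium_channels(self) -> tuple[np.ndarray, np.ndarray]:
        """(calcium-increasing, calcium-decreasing) channel stacks."""
        if self.dye_polarity == "green_up":
            return self.green, self.red
        return self.red, self.green


# ---------------------------------------------------------------------------
# waveform construction


def decay_floor_for(peak_amplitude: float, plateau_level: float) -> float:
    """Post-peak decay floor guaranteeing a half-maximum crossing."""
    return min(plateau_level, 0.35 * peak_amplitude)


def decay_tau_for_fwhm(peak_amplitude: float, floor: float,
                       fwhm_s: float) -> float:
    """Decay time constant placing the half-maximum crossing at ``fwhm_s``."""
    a, f = peak_amplitude, floor
    if f >= a / 2:
        raise ValueError("decay floor must lie below half the peak")
    return fwhm_s / math.log((a - f) / (a / 2 - f))


def _relax(time_grid: np.ndarray, segments: list[tuple[float, float, float]],
           ) -> np.ndarray:
    """Evaluate sequential exponential relaxation toward segment targets."""
    t = time_grid
    v = np.zeros_like(t)
    if not segments:
        return v
    level = 0.0
    for k, (ts, target, tau) in enumerate(segments):
        te = segments[k + 1][0] if k + 1 < len(segments) else np.inf
        idx = (t >= ts) & (t < te)
        if idx.any():
            v[idx] = target + (level - target) * np.exp(-(t[idx] - ts) / tau)
        span = (min(te, t[-1]) - ts)
        level = target + (level - target) * math.exp(-max(span, 0.0) / tau)
    return v


def _add_spikes(time_grid: np.ndarray, v: np.ndarray,
                spikes: list[tuple[float, float, float]]) -> None:
    for t0, amp, width in spikes:
        idx = (time_grid >= t0) & (time_grid <= t0 + width)
        if idx.any():
            phase = (time_grid[idx] - t0) / width
            v[idx] += 0.5 * amp * (1.0 - np.cos(2.0 * np.pi * phase))


def _rise_decay(segments: list, t_peak: float, amp: float, rise_tau: float,
                decay_target: float, decay_tau: float, v0: float) -> None:
    """Append a rise segment reaching ``amp`` exactly at ``t_peak``.

    The rise span is chosen so the slopes flanking the peak are of similar
    magnitude, which keeps the time of the maximum well defined (a cusp
    with one flat flank drifts under any smoothing).
    """
    drop = max(amp - decay_target, 1e-6)
    k = math.log(max(1.0, decay_tau * max(amp, 1e-6)
                     / (rise_tau * drop)))
    k = min(6.0, max(2.5, k))
    dur = k * rise_tau
    t_on = t_peak - dur
    e = math.exp(-dur / rise_tau)
    boosted = (amp - v0 * e) / (1.0 - e)
    segments.append((t_on, boosted, rise_tau))
    segments.append((t_peak, decay_target, decay_tau))


def _half_crossing_time(t_peak: float, amp: float, floor: float,
                        tau: float) -> float:
    if floor >= amp / 2:
        return t_peak + 2.0 * tau
    return t_peak + tau * math.log((amp - floor) / (amp / 2 - floor))


def _schedule(p: TransientParams, stim: float, t_end: float
              ) -> tuple[list, list]:
    """Build the (segments, spikes) schedule for one transient."""
    ex = p.extras
    A, C, C2 = p.peak_amplitude, p.plateau_level, p.plateau2_level
    T = t_end - stim
    tp = stim + p.peak_time_s
    segs: list[tuple[float, float, float]] = []
    spikes: list[tuple[float, float, float]] = []
    width = ex.get("spike_width_s", 40.0)

    def spike_train(t0: float, t1: float) -> None:
        t = t0
        while t + width <= t1:
            spikes.append((t, p.spike_amplitude, width))
            t += p.spike_interval_s

    sec = p.class_label
    if sec == "1a":
        if C > 0:
            segs.append((stim + ex.get("onset_s", 120.0), C, 500.0))
    elif sec == "1b":
        level = max(C, A)
        segs.append((stim + ex.get("onset_s", 300.0), level, p.rise_tau_s))
    elif sec in ("1c", "W1"):
        floor = ex.get("decay_floor", decay_floor_for(A, C) if sec == "W1"
                       else min(C, 0.03))
        _rise_decay(segs, tp, A, p.rise_tau_s, floor, p.decay_tau_s, 0.0)
        if sec == "W1" and C - floor > 0.02:
            th = _half_crossing_time(tp, A, floor, p.decay_tau_s)
            segs.append((th + ex.get("recovery_delay_s", 30.0), C,
                         ex.get("recovery_tau_s", 90.0)))
    elif sec in ("2a", "2b", "W2", "W3"):
        floor = ex.get("decay_floor", decay_floor_for(A, C))
        _rise_decay(segs, tp, A, p.rise_tau_s, floor, p.decay_tau_s, 0.0)
        th = _half_crossing_time(tp, A, floor, p.decay_tau_s)
        if C - floor > 0.02:  # undershoot, then relax up to the plateau
            segs.append((th + ex.get("recovery_delay_s", 30.0), C,
                         ex.get("recovery_tau_s", 90.0)))
        if sec == "2b":
            t2 = stim + ex.get("second_peak_frac", 0.45) * T
            a2 = ex.get("second_peak_amp", 0.8 * A)
            _rise_decay(segs, t2, a2, ex.get("second_rise_tau_s", 10.0),
                        C2 if C2 > 0 else C,
                        ex.get("second_decay_tau_s", 60.0), C)
        elif sec == "W2":
            t_off = stim + ex.get("plateau_end_frac", 0.45) * T
            segs.append((t_off, 0.02, ex.get("offset_tau_s", 120.0)))
        elif sec == "W3":
            t_step = stim + ex.get("step_frac", 0.5) * T
            segs.append((t_step, C2, ex.get("step_tau_s", 60.0)))
    elif sec in ("3a", "W4"):
        floor = ex.get("decay_floor", 0.03)
        _rise_decay(segs, tp, A, p.rise_tau_s, floor, p.decay_tau_s, 0.0)
        t2 = stim + ex.get("second_peak_frac", 0.3 if sec == "W4" else 0.35) * T
        a2 = ex.get("second_peak_amp", 0.8 * A)
        tgt = C if sec == "W4" else floor
        _rise_decay(segs, t2, a2, ex.get("second_rise_tau_s", 10.0), tgt,
                    ex.get("second_decay_tau_s", 60.0 if sec == "3a" else 90.0),
                    floor)
    elif sec == "2c":
        floor = ex.get("decay_floor", 0.03)
        _rise_decay(segs, tp, A, p.rise_tau_s, floor, p.decay_tau_s, 0.0)
        t_pl = t_end - ex.get("terminal_plateau_s", 600.0)
        segs.append((t_pl, C, 60.0))
        ts0 = stim + ex.get("spike_start_frac", 0.25) * T
        spike_train(ts0, t_pl - 120.0)
    elif sec == "3b":
        floor = ex.get("decay_floor", 0.03)
        _rise_decay(segs, tp, A, p.rise_tau_s, floor, p.decay_tau_s, 0.0)
        ts0 = stim + ex.get("spike_start_frac", 0.2) * T
        spike_train(ts0, t_end - 60.0)
    elif sec == "3c":
        _rise_decay(segs, tp, A, p.rise_tau_s, C, p.decay_tau_s, 0.0)
        ts0 = stim + ex.get("spike_start_frac", 0.3) * T
        segs.append((ts0 - 60.0, 0.05, 40.0))
        spike_train(ts0, t_end - 60.0)
    elif sec == "W5":
        floor = ex.get("decay_floor", 0.03)
        _rise_decay(segs, tp, A, p.rise_tau_s, floor, p.decay_tau_s, 0.0)
        t_r2 = stim + ex.get("late_rise_frac", 0.4) * T
        segs.append((t_r2, C, ex.get("late_rise_tau_s", 150.0)))
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(f"unknown class label {sec!r}")

    segs.sort(key=lambda s: s[0])
    return segs, spikes


def noiseless_values(params: TransientParams, time_grid: np.ndarray,
                     stimulus_time_s: float = 0.0) -> np.ndarray:
    """Noise-free waveform (above-baseline) on the given grid."""
    segs, spikes = _schedule(params, stimulus_time_s, float(time_grid[-1]))
    v = _relax(time_grid, segs)
    _add_spikes(time_grid, v, spikes)
    return v


def make_transient(params: TransientParams, time_grid: np.ndarray,
                   rng_seed: int, stimulus_time_s: float = 0.0) -> Trace:
    """Render one transient on ``time_grid`` with additive Gaussian noise."""
    params.validate()
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.size < 2:
        raise ValueError("time_grid needs at least 2 samples")
    if np.any(np.diff(time_grid) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    rel = noiseless_values(params, time_grid, stimulus_time_s)
    vals = params.baseline + rel
    if params.noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        vals = vals + rng.normal(0.0, params.noise_sd, size=vals.shape)
    return Trace(time_grid.copy(), np.clip(vals, 0.0, None))


def ground_truth_metrics(params: TransientParams, time_grid: np.ndarray,
                         stimulus_time_s: float = 0.0,
                         response_threshold: float = 0.15,
                         initial_window_s: float = 600.0) -> dict:
    """Signature metrics of the noiseless waveform, from the construction.

    Computed by direct array operations on the noise-free trace (windowed
    argmax, first half-maximum crossing) and from the schedule itself
    (terminal plateau target, spike interval) — independent of the
    denoising / median / peak-finding machinery of the extraction pipeline.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    rel = noiseless_values(params, time_grid, stimulus_time_s)
    segs, spikes = _schedule(params, stimulus_time_s, float(time_grid[-1]))

    win = (time_grid >= stimulus_time_s) & (
        time_grid <= stimulus_time_s + initial_window_s)
    widx = np.flatnonzero(win)
    i_pk = widx[int(np.argmax(rel[widx]))]
    ph = float(rel[i_pk])

    if params.class_label == "W3":
        plateau = params.plateau_level
        plateau2 = params.plateau2_level
    else:
        plateau = float(segs[-1][1]) if segs else 0.0
        plateau2 = 0.0

    has_peak = ph >= response_threshold and plateau <= ph
    peak_time_min = (time_grid[i_pk] - stimulus_time_s) / 60.0 if has_peak else 0.0
    fwhm_min = 0.0
    if has_peak:
        below = np.flatnonzero(rel[i_pk:] < ph / 2.0)
        if below.size:
            fwhm_min = (time_grid[i_pk + below[0]] - time_grid[i_pk]) / 60.0
        else:
            fwhm_min = (time_grid[-1] - time_grid[i_pk]) / 60.0

    spike_times = np.array([s[0] + 0.5 * s[2] for s in spikes])
    rate = (1.0 / float(np.mean(np.diff(spike_times)))
            if spike_times.size >= 2 else 0.0)
    return {"peak_height": ph, "peak_time_min": float(peak_time_min),
            "fwhm_min": float(fwhm_min), "plateau_height": float(plateau),
            "plateau2_height": float(plateau2), "spike_rate_per_s": rate,
            "has_peak": bool(has_peak), "n_spikes": int(spike_times.size)}


# ---------------------------------------------------------------------------
# population priors


def _lognorm(rng: np.random.Generator, mean: float, sd: float,
             lo: float | None = None, hi: float | None = None) -> float:
    if mean <= 0:
        return 0.0
    s2 = math.log(1.0 + (sd / mean) ** 2) if sd > 0 else 0.0
    x = rng.lognormal(math.log(mean) - s2 / 2.0, math.sqrt(s2)) if s2 > 0 else mean
    if lo is not None:
        x = max(lo, x)
    if hi is not None:
        x = min(hi, x)
    return float(x)


def default_time_grid(protocol: str = "ATP",
                      frame_interval_s: float = 1.0) -> np.ndarray:
    dur = dflt.ATP_DURATION_S if protocol == "ATP" else dflt.WOUND_DURATION_S
    return np.arange(0.0, dflt.DEFAULT_PRESTIM_S + dur + 1e-9,
                     frame_interval_s)


def atp_shape_priors(noise_sd: float = 0.03) -> dict:
    """Per-secondary-class parameter priors for the ATP protocol.

    Amplitude/plateau/FWHM scales follow the per-class population statistics;
    timing knobs are shape conventions chosen so each class satisfies its
    defining predicate.
    """

    def base(rng):
        return float(np.clip(rng.normal(0.2, 0.03), 0.05, None))

    def p_1a(rng):
        return TransientParams(baseline=base(rng), peak_amplitude=0.0,
                               plateau_level=_lognorm(rng, 0.03, 0.02, hi=0.08),
                               noise_sd=noise_sd, class_label="1a")

    def p_1b(rng):
        return TransientParams(
            baseline=base(rng), peak_amplitude=0.0,
            plateau_level=_lognorm(rng, 0.30, 0.10, lo=0.16, hi=0.8),
            rise_tau_s=float(rng.uniform(260, 380)), noise_sd=noise_sd,
            class_label="1b",
            extras={"onset_s": float(rng.uniform(240, 420))})

    def p_1c(rng):
        a = _lognorm(rng, 0.5, 0.15, lo=0.22)
        fwhm_s = _lognorm(rng, 90, 30, lo=35)
        floor = min(0.02, 0.35 * a)
        return TransientParams(
            baseline=base(rng), peak_amplitude=a,
            peak_time_s=float(rng.uniform(460, 700)), rise_tau_s=55.0,
            decay_tau_s=decay_tau_for_fwhm(a, floor, fwhm_s),
            plateau_level=0.02, noise_sd=noise_sd, class_label="1c",
            extras={"decay_floor": floor})

    def rapid_peak(rng, mean=1.04, sd=0.32):
        a = _lognorm(rng, mean, sd, lo=0.3, hi=3.0)
        tp = float(np.clip(rng.normal(68, 10), 45, 110))
        return a, tp

    def p_2a(rng):
        a, tp = rapid_peak(rng)
        c = min(_lognorm(rng, 0.79, 0.20, lo=0.15), 0.9 * a)
        fwhm_s = _lognorm(rng, 235, 70, lo=60)
        floor = decay_floor_for(a, c)
        return TransientParams(
            baseline=base(rng), peak_amplitude=a, peak_time_s=tp,
            rise_tau_s=8.0, decay_tau_s=decay_tau_for_fwhm(a, floor, fwhm_s),
            plateau_level=c, noise_sd=noise_sd, class_label="2a")

    def p_2b(rng):
        a, tp = rapid_peak(rng)
        c = min(_lognorm(rng, 0.50, 0.12, lo=0.18), 0.8 * a)
        fwhm_s = _lognorm(rng, 150, 50, lo=60)
        floor = decay_floor_for(a, c)
        return TransientParams(
            baseline=base(rng), peak_amplitude=a, peak_time_s=tp,
            rise_tau_s=8.0, decay_tau_s=decay_tau_for_fwhm(a, floor, fwhm_s),
            plateau_level=c, plateau2_level=c, noise_sd=noise_sd,
            class_label="2b",
            extras={"second_peak_frac": float(rng.uniform(0.40, 0.55)),
                    "second_peak_amp":
                        c + max(0.18, float(rng.uniform(0.3, 0.5)) * a)})

    def p_2c(rng):
        a, tp = rapid_peak(rng, 1.0, 0.30)
        fwhm_s = _lognorm(rng, 100, 30, lo=45, hi=145)
        # spiking begins only after the decay has reached baseline
        start_frac = float(np.clip((tp + 4 * fwhm_s + 300) / 2100, 0.25, 0.45))
        return TransientParams(
            baseline=base(rng), peak_amplitude=a, peak_time_s=tp,
            rise_tau_s=8.0, decay_tau_s=decay_tau_for_fwhm(a, 0.03, fwhm_s),
            plateau_level=min(float(rng.uniform(0.25, 0.5)), 0.75 * a),
            spike_interval_s=float(rng.uniform(150, 330)),
            spike_amplitude=max(0.2, float(rng.uniform(0.4, 0.7)) * a),
            noise_sd=noise_sd, class_label="2c",
            extras={"spike_start_frac": start_frac})

    def p_3a(rng):
        a, tp = rapid_peak(rng, 0.98, 0.30)
        fwhm_s = _lognorm(rng, 109, 33, lo=45, hi=150)
        return TransientParams(
            baseline=base(rng), peak_amplitude=a, peak_time_s=tp,
            rise_tau_s=8.0, decay_tau_s=decay_tau_for_fwhm(a, 0.03, fwhm_s),
            plateau_level=0.03, noise_sd=noise_sd, class_label="3a",
            extras={"second_peak_frac": float(rng.uniform(0.35, 0.5)),
                    "second_peak_amp": float(rng.uniform(0.75, 0.95)) * a})

    def p_3b(rng):
        a, tp = rapid_peak(rng, 0.98, 0.30)
        fwhm_s = _lognorm(rng, 109, 33, lo=45, hi=200)
        start_frac = float(np.clip((tp + 4 * fwhm_s + 300) / 2100, 0.2, 0.55))
        return TransientParams(
            baseline=base(rng), peak_amplitude=a, peak_time_s=tp,
            rise_tau_s=8.0, decay_tau_s=decay_tau_for_fwhm(a, 0.03, fwhm_s),
            plateau_level=0.03,
            spike_interval_s=float(rng.uniform(300, 640)),
            spike_amplitude=max(0.2, float(rng.uniform(0.4, 0.7)) * a),
            noise_sd=noise_sd, class_label="3b",
            extras={"spike_start_frac": start_frac})

    def p_3c(rng):
        a, tp = rapid_peak(rng, 0.98, 0.30)
        a = max(a, 0.5)   # the sub-half-maximum plateau needs headroom
        c = float(np.clip(rng.uniform(0.18, min(0.45 * a, 0.5)), 0.16, 0.5))
        fwhm_s = _lognorm(rng, 109, 33, lo=45)
        return TransientParams(
            baseline=base(rng), peak_amplitude=a, peak_time_s=tp,
            rise_tau_s=8.0, decay_tau_s=decay_tau_for_fwhm(a, c, fwhm_s),
            plateau_level=c,
            spike_interval_s=float(rng.uniform(200, 440)),
            spike_amplitude=max(0.2, float(rng.uniform(0.4, 0.7)) * a),
            noise_sd=noise_sd, class_label="3c")

    return {"1a": p_1a, "1b": p_1b, "1c": p_1c, "2a": p_2a, "2b": p_2b,
            "2c": p_2c, "3a": p_3a, "3b": p_3b, "3c": p_3c}


def wound_shape_priors(side: str, noise_sd: float = 0.03) -> dict:
    """Per-secondary-class priors for the wound protocol, one side at a time.

    Amplitudes, FWHMs and plateau levels are drawn from the side-specific
    (proximal/distal) lognormal fits of the cell-level feature statistics.
    """
    st = dflt.WOUND_FEATURE_STATS[side]

    def base(rng):
        return float(np.clip(rng.normal(0.2, 0.03), 0.05, None))

    def draw_amp(rng, lo=0.2):
        return _lognorm(rng, *st["peak_height"], lo=lo, hi=3.5)

    def draw_fwhm_s(rng):
        return 60.0 * _lognorm(rng, *st["fwhm_min"], lo=0.4, hi=20.0)

    def draw_plateau(rng, lo=0.13, hi=None):
        return _lognorm(rng, *st["plateau_height"], lo=lo, hi=hi)

    def p_1a(rng):
        return TransientParams(baseline=base(rng), peak_amplitude=0.0,
                               plateau_level=_lognorm(rng, 0.03, 0.02, hi=0.08),
                               noise_sd=noise_sd, class_label="1a")

    def p_1b(rng):
        return TransientParams(
            baseline=base(rng),
            plateau_level=_lognorm(rng, 0.28, 0.12, lo=0.05, hi=0.8),
            rise_tau_s=float(rng.uniform(260, 380)), noise_sd=noise_sd,
            class_label="1b", extras={"onset_s": float(rng.uniform(240, 420))})

    def p_1c(rng):
        a = draw_amp(rng, lo=0.25)
        floor = min(0.02, 0.35 * a)
        return TransientParams(
            baseline=base(rng), peak_amplitude=a,
            peak_time_s=float(rng.uniform(460, 700)), rise_tau_s=55.0,
            decay_tau_s=decay_tau_for_fwhm(a, floor, _lognorm(rng, 90, 30, lo=35)),
            plateau_level=0.02, noise_sd=noise_sd, class_label="1c",
            extras={"decay_floor": floor})

    def p_W1(rng):
        a = draw_amp(rng, lo=0.3)
        c = min(draw_plateau(rng), 0.45 * a)
        floor = decay_floor_for(a, c)
        return TransientParams(
            baseline=base(rng), peak_amplitude=a,
            peak_time_s=float(rng.uniform(480, 700)), rise_tau_s=60.0,
            decay_tau_s=decay_tau_for_fwhm(a, floor, _lognorm(rng, 120, 40, lo=50)),
            plateau_level=max(c, 0.13), noise_sd=noise_sd, class_label="W1")

    def rapid(rng):
        a = draw_amp(rng, lo=0.3)
        tp = float(np.clip(rng.normal(70, 15), 45, 120))
        return a, tp

    def p_2a(rng):
        a, tp = rapid(rng)
        c = min(draw_plateau(rng), 0.9 * a)
        floor = decay_floor_for(a, c)
        return TransientParams(
            baseline=base(rng), peak_amplitude=a, peak_time_s=tp,
            rise_tau_s=8.0,
            decay_tau_s=decay_tau_for_fwhm(a, floor, draw_fwhm_s(rng)),
            plateau_level=c, noise_sd=noise_sd, class_label="2a")

    def p_2b(rng):
        a, tp = rapid(rng)
        c = min(max(draw_plateau(rng), 0.18), 0.8 * a)
        floor = decay_floor_for(a, c)
        return TransientParams(
            baseline=base(rng), peak_amplitude=a, peak_time_s=tp,
            rise_tau_s=8.0,
            decay_tau_s=decay_tau_for_fwhm(a, floor, _lognorm(rng, 150, 50, lo=60)),
            plateau_level=c, plateau2_level=c, noise_sd=noise_sd,
            class_label="2b",
            extras={"second_peak_frac": float(rng.uniform(0.40, 0.55)),
                    "second_peak_amp":
                        c + max(0.18, float(rng.uniform(0.3, 0.5)) * a)})

    def p_W2(rng):
        a, tp = rapid(rng)
        c = min(max(draw_plateau(rng), 0.15), 0.8 * a)
        floor = decay_floor_for(a, c)
        return TransientParams(
            baseline=base(rng), peak_amplitude=a, peak_time_s=tp,
            rise_tau_s=8.0,
            decay_tau_s=decay_tau_for_fwhm(a, floor, draw_fwhm_s(rng)),
            plateau_level=c, noise_sd=noise_sd, class_label="W2",
            extras={"plateau_end_frac": float(rng.uniform(0.35, 0.5))})

    def p_W3(rng):
        a, tp = rapid(rng)
        c = min(max(draw_plateau(rng), 0.32), 0.9 * a)
        c2 = max(0.13, c - max(0.16, 0.5 * c))
        floor = decay_floor_for(a, c)
        # the first plateau must settle well before the step
        return TransientParams(
            baseline=base(rng), peak_amplitude=a, peak_time_s=tp,
            rise_tau_s=8.0,
            decay_tau_s=decay_tau_for_fwhm(a, floor,
                                           _lognorm(rng, 100, 40, lo=40, hi=130)),
            plateau_level=c, plateau2_level=c2, noise_sd=noise_sd,
            class_label="W3",
            extras={"step_frac": float(rng.uniform(0.45, 0.6))})

    def p_W4(rng):
        a, tp = rapid(rng)
        c = min(max(draw_plateau(rng), 0.14), 0.5, 0.8 * a)
        return TransientParams(
            baseline=base(rng), peak_amplitude=a, peak_time_s=tp,
            rise_tau_s=8.0,
            decay_tau_s=decay_tau_for_fwhm(a, 0.03, _lognorm(rng, 100, 35, lo=45,
                                                             hi=150)),
            plateau_level=c, noise_sd=noise_sd, class_label="W4",
            extras={"second_peak_frac": float(rng.uniform(0.35, 0.5)),
                    "second_peak_amp":
                        c + max(0.18, float(rng.uniform(0.35, 0.6)) * a)})

    def p_W5(rng):
        a, tp = rapid(rng)
        c = min(max(draw_plateau(rng), 0.14), 0.6, 0.8 * a)
        return TransientParams(
            baseline=base(rng), peak_amplitude=a, peak_time_s=tp,
            rise_tau_s=8.0,
            decay_tau_s=decay_tau_for_fwhm(a, 0.03, _lognorm(rng, 100, 35, lo=45)),
            plateau_level=c, noise_sd=noise_sd, class_label="W5",
            extras={"late_rise_frac": float(rng.uniform(0.35, 0.5))})

    return {"1a": p_1a, "1b": p_1b, "1c": p_1c, "2a": p_2a, "2b": p_2b,
            "W1": p_W1, "W2": p_W2, "W3": p_W3, "W4": p_W4, "W5": p_W5}


def make_population(mixture: dict[str, float], n: int, param_priors: dict,
                    rng_seed: int, time_grid: np.ndarray | None = None,
                    stimulus_time_s: float = dflt.DEFAULT_PRESTIM_S
                    ) -> list[tuple[Trace, str, TransientParams]]:
    """Draw ``n`` transients from a secondary-class mixture."""
    if not mixture:
        raise ValueError("mixture must not be empty")
    probs = np.array(list(mixture.values()), dtype=float)
    if np.any(probs < 0):
        raise ValueError("mixture probabilities must be >= 0")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("mixture probabilities must sum to 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = list(mixture.keys())
    rng = np.random.default_rng(rng_seed)
    if time_grid is None:
        time_grid = default_time_grid(
            "wound" if any(c.startswith("W") for c in labels) else "ATP")
    out = []
    draws = rng.choice(len(labels), size=n, p=probs)
    for k in draws:
        cls = labels[k]
        params = param_priors[cls](rng)
        seed = int(rng.integers(0, 2**31 - 1))
        out.append((make_transient(params, time_grid, seed, stimulus_time_s),
                    cls, params))
    return out


def primary_class_population(primary: str, n: int, rng_seed: int,
                             time_grid: np.ndarray | None = None,
                             stimulus_time_s: float = dflt.DEFAULT_PRESTIM_S,
                             noise_sd: float = 0.03
                             ) -> tuple[list[Trace], pd.DataFrame]:
    """Transients whose signature metrics follow one primary class's moments.

    Per-cell target metrics are drawn from the class's population statistics
    (lognormal with the published mean and cell-level s.d.) and realized
    through the class's canonical waveform; the returned table holds the
    *realized* ground-truth metrics of each noiseless waveform.
    """
    if primary not in dflt.ATP_PRIMARY_STATS:
        raise ValueError(f"unknown primary class {primary!r}")
    stats = dflt.ATP_PRIMARY_STATS[primary]
    n_class = dflt.ATP_PRIMARY_N[primary]
    # cell-level s.d. from the printed s.e.m.; CV capped at 1 to stay
    # consistent with the cell-level CVs printed for the wound protocol
    sd = {k: min(sem * math.sqrt(n_class), m) if m > 0 else 0.0
          for k, (m, sem) in stats.items()}
    mean = {k: m for k, (m, sem) in stats.items()}
    spike_frac = dflt.ATP_SPIKING_FRACTION[primary]
    spike_mean = (mean["spike_rate_per_s"] / spike_frac if spike_frac > 0
                  else 0.0)
    rng = np.random.default_rng(rng_seed)
    if time_grid is None:
        time_grid = default_time_grid("ATP")
    t_end = float(time_grid[-1])
    T = t_end - stimulus_time_s

    traces: list[Trace] = []
    truth_rows = []
    for _ in range(n):
        b = float(np.clip(rng.normal(0.2, 0.03), 0.05, None))
        if primary == "1":
            ph = _lognorm(rng, mean["peak_height"], sd["peak_height"], hi=2.5)
            pt = _lognorm(rng, mean["peak_time_min"], sd["peak_time_min"],
                          lo=2.2, hi=25.0)
            fw = _lognorm(rng, mean["fwhm_min"], sd["fwhm_min"], lo=0.2,
                          hi=25.0)
            c = _lognorm(rng, mean["plateau_height"], sd["plateau_height"],
                         hi=0.6)
            if ph >= 0.15:
                floor = min(c, 0.35 * ph)
                params = TransientParams(
                    baseline=b, peak_amplitude=ph, peak_time_s=pt * 60.0,
                    rise_tau_s=55.0,
                    decay_tau_s=decay_tau_for_fwhm(ph, floor, fw * 60.0),
                    plateau_level=floor, noise_sd=noise_sd, class_label="1c",
                    extras={"decay_floor": floor})
            else:
                params = TransientParams(baseline=b, peak_amplitude=0.0,
                                         plateau_level=c, noise_sd=noise_sd,
                                         class_label="1a")
        else:
            m_ph, s_ph = mean["peak_height"], sd["peak_height"]
            ph = _lognorm(rng, m_ph, s_ph, lo=0.25, hi=3.0)
            pt = _lognorm(rng, mean["peak_time_min"], sd["peak_time_min"],
                          lo=0.35, hi=9.0 if primary == "3" else 5.0)
            # the half-maximum crossing must fall inside the recording's
            # initial-response window, else the peak is unresolvable
            fw = _lognorm(rng, mean["fwhm_min"], sd["fwhm_min"], lo=0.3,
                          hi=8.0)
            spiking = rng.random() < spike_frac
            rate = (_lognorm(rng, spike_mean, 0.35 * spike_mean,
                             lo=1.3e-3, hi=8e-3) if spiking else 0.0)
            start_frac = min(0.55, max(0.15, (pt * 60 + 4 * fw * 60 + 300) / T))
            if primary == "2":
                # plateau correlates with the peak; a ratio draw keeps the
                # population plateau mean at its target under the
                # plateau <= peak constraint
                c = ph * _lognorm(rng, 0.76, 0.18, lo=0.15, hi=0.85)
                if spiking:
                    params = TransientParams(
                        baseline=b, peak_amplitude=ph, peak_time_s=pt * 60.0,
                        rise_tau_s=8.0,
                        decay_tau_s=decay_tau_for_fwhm(ph, 0.03, fw * 60.0),
                        plateau_level=c, spike_interval_s=1.0 / rate,
                        spike_amplitude=max(0.2, 0.55 * ph),
                        noise_sd=noise_sd, class_label="2c",
                        extras={"decay_floor": 0.03,
                                "spike_start_frac": start_frac})
                else:
                    floor = decay_floor_for(ph, c)
                    params = TransientParams(
                        baseline=b, peak_amplitude=ph, peak_time_s=pt * 60.0,
                        rise_tau_s=8.0,
                        decay_tau_s=decay_tau_for_fwhm(ph, floor, fw * 60.0),
                        plateau_level=c, noise_sd=noise_sd, class_label="2a")
            else:  # primary == "3"
                c = _lognorm(rng, mean["plateau_height"],
                             sd["plateau_height"], lo=0.01)
                # pedestal capped so spikes still re-base below the
                # inter-spike return level
                cap = min(0.35 * ph, max(0.2, 0.35 * ph - 0.06))
                floor = min(c, cap)
                if spiking:
                    params = TransientParams(
                        baseline=b, peak_amplitude=ph, peak_time_s=pt * 60.0,
                        rise_tau_s=8.0,
                        decay_tau_s=decay_tau_for_fwhm(ph, floor, fw * 60.0),
                        plateau_level=floor, spike_interval_s=1.0 / rate,
                        spike_amplitude=max(0.2, 0.5 * ph),
                        noise_sd=noise_sd, class_label="3b",
                        extras={"decay_floor": floor,
                                "spike_start_frac": start_frac})
                else:
                    params = TransientParams(
                        baseline=b, peak_amplitude=ph, peak_time_s=pt * 60.0,
                        rise_tau_s=8.0,
                        decay_tau_s=decay_tau_for_fwhm(ph, floor, fw * 60.0),
                        plateau_level=floor, noise_sd=noise_sd,
                        class_label="3a",
                        extras={"decay_floor": floor,
                                "second_peak_frac": min(
                                    0.9, max(0.35, start_frac + 0.1)),
                                "second_peak_amp": 0.85 * ph})
        seed = int(rng.integers(0, 2**31 - 1))
        traces.append(make_transient(params, time_grid, seed, stimulus_time_s))
        truth_rows.append(ground_truth_metrics(params, time_grid,
                                               stimulus_time_s))
    return traces, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# layouts and rendering


def _grid_layout(field_size_px: tuple[int, int], n_target: int,
                 rng: np.random.Generator, radius_frac: float = 0.40,
                 jitter_frac: float = 0.05
                 ) -> list[tuple[float, float, float]]:
    """Jittered rectangular packing; returns (x, y, radius) triples."""
    h, w = field_size_px
    nx = max(1, int(round(math.sqrt(n_target * w / h))))
    ny = max(1, int(round(n_target / nx)))
    px, py = w / nx, h / ny
    pitch = min(px, py)
    cells = []
    for j in range(ny):
        for i in range(nx):
            x = (i + 0.5) * px + rng.uniform(-jitter_frac, jitter_frac) * pitch
            y = (j + 0.5) * py + rng.uniform(-jitter_frac, jitter_frac) * pitch
            r = radius_frac * pitch * rng.uniform(0.92, 1.08)
            cells.append((float(np.clip(x, 1, w - 2)),
                          float(np.clip(y, 1, h - 2)), r))
    return cells


def make_monolayer_layout(n_cells: int = 121,
                          field_size_px: tuple[int, int] = (512, 512),
                          pixel_size_um: float = dflt.DEFAULT_PIXEL_SIZE_UM,
                          mixture: dict[str, float] | None = None,
                          param_priors: dict | None = None,
                          rng_seed: int = 0) -> CellLayout:
    """Confluent monolayer with ATP-protocol transients."""
    rng = np.random.default_rng(rng_seed)
    mixture = mixture or dflt.atp_pooled_mixture()
    priors = param_priors or atp_shape_priors()
    labels = list(mixture.keys())
    probs = np.array([mixture[k] for k in labels])
    probs = probs / probs.sum()
    cells = []
    for x, y, r in _grid_layout(field_size_px, n_cells, rng):
        cls = labels[int(rng.choice(len(labels), p=probs))]
        cells.append(Cell((x, y), r, priors[cls](rng), cls))
    return CellLayout(field_size_px, pixel_size_um, cells)


def _wound_class_draw(rng: np.random.Generator, side: str) -> str:
    groups = dflt.WOUND_GROUP_MIXTURE[side]
    names = list(groups.keys())
    p = np.array([groups[g] for g in names])
    p = p / p.sum()
    grp = names[int(rng.choice(len(names), p=p))]
    split = dflt.WOUND_SECONDARY_SPLIT[side][grp]
    secs = list(split.keys())
    ps = np.array([split[s] for s in secs])
    return secs[int(rng.choice(len(secs), p=ps / ps.sum()))]


def make_wound_layout(field_size_px: tuple[int, int] = (512, 512),
                      pixel_size_um: float = dflt.DEFAULT_PIXEL_SIZE_UM,
                      density_per_mm2: float = 2600.0,
                      wound_strip_width_px: int = 60,
                      distance_response_model=None,
                      rng_seed: int = 0,
                      proximal_um: float = 100.0) -> CellLayout:
    """Monolayer with a scratch strip removed and distance-dependent params.

    Cells inside the strip are excluded (removed by wounding); surviving
    cells draw their class and transient parameters from the proximal
    (< ``proximal_um`` from the edge) or distal mixture.  A custom
    ``distance_response_model(rng, distance_um) -> (class, params)`` may
    replace the default two-zone model.
    """
    if wound_strip_width_px <= 0:
        raise ValueError("wound_strip_width_px must be > 0")
    h, w = field_size_px
    if wound_strip_width_px >= w:
        raise ValueError("wound strip must lie inside the field")
    rng = np.random.default_rng(rng_seed)
    area_mm2 = (h * pixel_size_um * 1e-3) * (w * pixel_size_um * 1e-3)
    n_target = max(1, int(round(density_per_mm2 * area_mm2)))
    edge_x = float(wound_strip_width_px)
    wound = WoundGeometry(np.array([[edge_x, 0.0], [edge_x, float(h)]]),
                          removed_side="left")
    priors = {side: wound_shape_priors(side) for side in ("proximal", "distal")}
    cells = []
    for x, y, r in _grid_layout(field_size_px, n_target, rng):
        if x <= edge_x + 1.0:  # inside or touching the scratch strip
            continue
        d_um = (x - edge_x) * pixel_size_um
        if distance_response_model is not None:
            cls, params = distance_response_model(rng, d_um)
        else:
            side = "proximal" if d_um < proximal_um else "distal"
            cls = _wound_class_draw(rng, side)
            params = priors[side][cls](rng)
        cells.append(Cell((x, y), r, params, cls))
    if not cells:
        raise ValueError("density yields no surviving cells")
    return CellLayout(field_size_px, pixel_size_um, cells, wound=wound)


@dataclasses.dataclass
class ImagingParams:
    """Rendering model for the two reciprocal dye channels."""

    background: float = 15.0
    green_gain: float = 60.0       # calcium-increasing dye, linear
    red_gain: float = 120.0        # calcium-decreasing dye
    red_saturation: float = 8.0    # red = gain / (1 + x / red_saturation)
    load_cv: float = 0.15          # per-cell dye-loading spread
    read_noise_sd: float = 1.5
    shot_noise_frac: float = 0.04  # noise sd grows as sqrt(intensity)
    edge_softness_px: float = 1.5
    dye_polarity: str = "green_up"
    overlap_warn_frac: float = 0.2


def dye_intensities(x: np.ndarray | float, imaging: ImagingParams
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (green, red) cell intensities for calcium level ``x``."""
    x = np.asarray(x, dtype=float)
    green = imaging.green_gain * x
    red = imaging.red_gain / (1.0 + x / imaging.red_saturation)
    return green, red


def render_sequence(layout: CellLayout, frame_interval_s: float,
                    duration_s: float, imaging: ImagingParams | None = None,
                    rng_seed: int = 0,
                    stimulus_time_s: float = dflt.DEFAULT_PRESTIM_S
                    ) -> tuple[ImageSequence, CellLayout]:
    """Render the layout into a two-channel stack; returns truth alongside."""
    if duration_s < 2 * frame_interval_s:
        raise ValueError("duration must cover at least 2 frames")
    im = imaging or ImagingParams()
    rng = np.random.default_rng(rng_seed)
    h, w = layout.field_size_px
    times = np.arange(0.0, duration_s + 1e-9, frame_interval_s)
    nt = times.size

    # static per-cell footprints (cells are stationary during recording)
    footprints = []
    coverage = np.zeros((h, w), dtype=np.float32)
    for cell in layout.cells:
        cx, cy = cell.centroid_px
        r = cell.radius_px
        x0, x1 = max(0, int(cx - r - 4)), min(w, int(cx + r + 5))
        y0, y1 = max(0, int(cy - r - 4)), min(h, int(cy + r + 5))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        wmap = 1.0 / (1.0 + np.exp((dist - r) / im.edge_softness_px))
        load = float(rng.lognormal(0.0, im.load_cv))
        footprints.append(((slice(y0, y1), slice(x0, x1)),
                           wmap.astype(np.float32), load))
        coverage[y0:y1, x0:x1] += (wmap > 0.5)
    overlap_frac = float((coverage > 1.5).sum() / max(1, (coverage > 0.5).sum()))
    if overlap_frac > im.overlap_warn_frac:
        warnings.warn(f"cell overlap fraction {overlap_frac:.2f} exceeds "
                      f"{im.overlap_warn_frac}", stacklevel=2)

    # per-cell calcium time courses (noise-free; noise enters at the camera)
    calcium = np.stack([
        cell.params.baseline + noiseless_values(cell.params, times,
                                                stimulus_time_s)
        for cell in layout.cells])
    g_cell, r_cell = dye_intensities(calcium, im)

    green = np.full((nt, h, w), im.background, dtype=np.float32)
    red = np.full((nt, h, w), im.background, dtype=np.float32)
    for ci, (sl, wmap, load) in enumerate(footprints):
        gv = (load * g_cell[ci]).astype(np.float32)
        rv = (load * r_cell[ci]).astype(np.float32)
        green[(slice(None),) + sl] += gv[:, None, None] * wmap
        red[(slice(None),) + sl] += rv[:, None, None] * wmap
    for stack in (green, red):
        noise = rng.standard_normal(stack.shape).astype(np.float32)
        stack += noise * (im.read_noise_sd
                          + im.shot_noise_frac * np.sqrt(np.clip(stack, 0, None)))
        np.clip(stack, 0.0, None, out=stack)

    seq = ImageSequence(red=red, green=green,
                        frame_interval_s=frame_interval_s,
                        pixel_size_um=layout.pixel_size_um,
                        stimulus_time_s=stimulus_time_s,
                        dye_polarity=im.dye_polarity)
    return seq, layout
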