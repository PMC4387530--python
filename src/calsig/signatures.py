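"""Ratiometric trace extraction and calcium-signature metrics.

A cell's calcium signature is the time course of the ratio of a
calcium-quenched dye channel to a calcium-enhanced one, averaged over the
cell's ROI.  Four features summarize each signature: the height of the
initial peak (A), the full-width half-maximum of that peak (B, the time for
the trace to fall to baseline + A/2), the height of the sustained plateau
(C) and the spike interval (D) when the cell enters a spiking mode.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import find_peaks


@dataclasses.dataclass
class Trace:
    """One cell's ratiometric intensity time series (arbitrary units)."""

    times_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times_s.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.times_s)))

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])


@dataclasses.dataclass
class MetricParams:
    """Thresholds controlling signature-metric extraction.

    All heights are ratio a.u. above baseline; times in seconds.
    """

    response_threshold: float = 0.15   # minimum initial-peak height
    plateau_threshold: float = 0.10    # minimum sustained elevation
    plateau_min_duration_s: float = 120.0
    initial_window_s: float = 600.0    # initial-response search window
    spike_prominence: float = 0.12
    spike_min_separation_s: float = 60.0
    rebase_fraction: float = 0.35      # inter-spike return level, x peak height
    slope_threshold: float = 0.01      # a.u./s; below this a sample is "slow"
    denoise_window_s: float = 15.0
    plateau2_min_step: float = 0.12    # minimum drop defining a dual plateau


@dataclasses.dataclass
class SignatureMetrics:
    baseline: float = 0.0
    peak_height: float = 0.0
    peak_time_min: float = 0.0
    fwhm_min: float = 0.0
    plateau_height: float = 0.0
    plateau2_height: float = 0.0
    spike_times_s: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0))
    spike_rate_per_s: float = 0.0
    has_peak: bool = False
    has_plateau: bool = False
    is_spiking: bool = False

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spike_times_s"] = list(np.asarray(self.spike_times_s, dtype=float))
        d["n_spikes"] = len(d["spike_times_s"])
        return d


def extract_trace(seq, roimap, roi_id: int, eps: float = 1e-6) -> Trace:
    """Average the per-pixel dye ratio over one ROI at every frame.

    The ratio is increasing-dye / decreasing-dye (green / red with the
    default polarity), so it rises monotonically with calcium.
    """
    mask = roimap.labels == roi_id
    if not mask.any():
        raise ValueError(f"ROI {roi_id} has no pixels")
    up, down = seq.calcium_channels()
    vals = (up[:, mask] / (down[:, mask] + eps)).mean(axis=1)
    times = np.arange(up.shape[0]) * seq.frame_interval_s
    return Trace(times, vals)


def denoise(trace: Trace, slope_threshold: float = 0.01,
            window_s: float = 15.0) -> Trace:
    """Local averaging restricted to slowly changing parts of the trace.

    Samples whose central-difference slope over ``window_s`` is below
    ``slope_threshold`` are replaced by the local mean over the same window;
    rapidly changing samples (peak flanks, spike edges) pass through
    untouched, so peaks are not broadened.
    """
    t, v = trace.times_s, trace.values
    dt = trace.dt_s
    w = max(3, int(round(window_s / dt)))
    if w % 2 == 0:
        w += 1
    h = w // 2
    slope = np.gradient(v, t)
    ip, im = np.minimum(np.arange(v.size) + h, v.size - 1), np.maximum(
        np.arange(v.size) - h, 0)
    span = t[ip] - t[im]
    with np.errstate(invalid="ignore", divide="ignore"):
        central = np.where(span > 0, (v[ip] - v[im]) / span, slope)
    local_mean = uniform_filter1d(v, size=w, mode="nearest")
    out = np.where(np.abs(central) < slope_threshold, local_mean, v)
    return Trace(t.copy(), out)


def _running_median(values: np.ndarray, dt: float, window_s: float) -> np.ndarray:
    w = max(3, int(round(window_s / dt)))
    if w % 2 == 0:
        w += 1
    return median_filter(values, size=w, mode="nearest")


def detect_spikes(times: np.ndarray, rel: np.ndarray, start_idx: int,
                  peak_height: float, params: MetricParams) -> np.ndarray:
    """Post-initial-response spike times.

    Local maxima with sufficient prominence count as spikes only when the
    trace returns below baseline + rebase_fraction * peak_height between
    consecutive maxima (and before the first one), which separates genuine
    repetitive spiking from bumps riding on a plateau.
    """
    dt = float(np.median(np.diff(times)))
    seg = rel[start_idx:]
    if seg.size < 3:
        return np.empty(0)
    dist = max(1, int(round(params.spike_min_separation_s / dt)))
    idx, _ = find_peaks(seg, prominence=params.spike_prominence, distance=dist)
    if idx.size == 0:
        return np.empty(0)
    rebase = params.rebase_fraction * max(peak_height, params.spike_prominence)
    kept: list[int] = []
    prev = 0
    for i in idx:
        trough = seg[prev:i + 1].min() if i > prev else seg[i]
        if trough < rebase:
            kept.append(i)
            prev = i
    return times[start_idx + np.asarray(kept, dtype=int)] if kept else np.empty(0)


def compute_metrics(trace: Trace, stimulus_time_s: float,
                    params: MetricParams | None = None) -> SignatureMetrics:
    """Extract the signature metrics from a (denoised) trace.

    Baseline is the pre-stimulus mean (first 5% of samples when the
    recording starts at the stimulus).  The initial peak is the maximum
    within the initial-response window after the stimulus; FWHM is measured
    from the peak to the first fall below baseline + peak/2 and is zero by
    definition when there is no peak.  The plateau is the median of the
    final third of the recording; a dual plateau (step down between two
    sustained levels) populates ``plateau2_height``.
    """
    p = params or MetricParams()
    t, v = trace.times_s, trace.values
    dt = trace.dt_s

    pre = t < stimulus_time_s
    if pre.sum() >= 3:
        baseline = float(v[pre].mean())
    else:
        baseline = float(v[:max(2, v.size // 20)].mean())
    rel = v - baseline

    m = SignatureMetrics(baseline=baseline)

    win = (t >= stimulus_time_s) & (t <= stimulus_time_s + p.initial_window_s)
    if not win.any():
        return m
    widx = np.flatnonzero(win)
    i_pk = widx[int(np.argmax(rel[widx]))]
    m.peak_height = float(rel[i_pk])
    m.has_peak = m.peak_height >= p.response_threshold
    # peak time from a lightly smoothed copy: the raw argmax of a broad
    # peak jitters with residual noise
    w9 = max(3, int(round(9.0 / dt)) | 1)
    sm = uniform_filter1d(rel, size=w9, mode="nearest")
    i_pk = widx[int(np.argmax(sm[widx]))]
    if m.has_peak:
        m.peak_time_min = float((t[i_pk] - stimulus_time_s) / 60.0)

    # plateau: median of the final third, sustained through the tail
    last3 = t >= t[0] + (2.0 / 3.0) * (t[-1] - t[0])
    m.plateau_height = float(np.median(rel[last3]))
    tail = t >= t[-1] - p.plateau_min_duration_s
    m.has_plateau = (m.plateau_height >= p.plateau_threshold
                     and float(np.median(rel[tail])) >= p.plateau_threshold)

    # a late elevation exceeding the initial-window maximum means the trace
    # had no genuine initial peak (slow riser), only a climbing shoulder
    if m.has_peak and m.plateau_height > m.peak_height:
        m.has_peak = False
        m.peak_time_min = 0.0

    if m.has_peak:
        half = m.peak_height / 2.0
        after = rel[i_pk:]
        below = np.flatnonzero(after < half)
        if below.size:
            m.fwhm_min = float((t[i_pk + below[0]] - t[i_pk]) / 60.0)
        else:
            m.fwhm_min = float((t[-1] - t[i_pk]) / 60.0)
    else:
        m.fwhm_min = 0.0

    # spikes after the initial response
    start = min(i_pk + max(1, int(round(60.0 / dt))), v.size - 1)
    m.spike_times_s = detect_spikes(t, rel, start, m.peak_height, p)
    if m.spike_times_s.size >= 2:
        m.is_spiking = True
        m.spike_rate_per_s = float(1.0 / np.mean(np.diff(m.spike_times_s)))

    # dual plateau: locate the largest step-down in the smoothed post-peak
    # trace and require a genuine two-level profile (flat on both sides)
    if not m.is_spiking and m.spike_times_s.size == 0 and m.has_peak:
        smooth = _running_median(rel, dt, 90.0)
        post = np.flatnonzero(t >= t[i_pk] + 60.0 * max(m.fwhm_min, 1.0))
        h = max(1, int(round(120.0 / dt)))       # half-width of step window
        side = max(3, int(round(240.0 / dt)))    # min flat span per side
        wflat = max(side, int(round(600.0 / dt)))
        if post.size > 2 * (h + side):
            seg = smooth[post]
            drops = seg[2 * h:] - seg[:-2 * h]
            # the initial decay also produces large drops; the plateau step
            # is the LAST drop exceeding the step threshold
            cand = np.flatnonzero(drops <= -p.plateau2_min_step)
            if cand.size:
                k = int(cand[-1]) + h
                pre = seg[max(0, k - h - wflat): k - h]
                post_seg = seg[k + h: k + h + wflat]
                if pre.size >= side and post_seg.size >= side:
                    l1 = float(np.median(pre))
                    l2 = float(np.median(post_seg))
                    flat_pre = abs(np.median(pre[:pre.size // 2])
                                   - np.median(pre[pre.size // 2:])) <= 0.05
                    flat_post = abs(
                        np.median(post_seg[:post_seg.size // 2])
                        - np.median(post_seg[post_seg.size // 2:])) <= 0.05
                    if (l1 - l2 >= p.plateau2_min_step
                            and l2 >= p.plateau_threshold
                            and flat_pre and flat_post):
                        m.plateau_height = l1
                        m.plateau2_height = l2
    return m


def metrics_table(metrics: list[SignatureMetrics],
                  roi_ids: list[int] | None = None) -> pd.DataFrame:
    """One row per ROI, columns = signature-metric fields."""
    rows = []
    for i, m in enumerate(metrics):
        d = m.as_dict()
        d.pop("spike_times_s")
        d["roi_id"] = roi_ids[i] if roi_ids is not None else i
        rows.append(d)
    df = pd.DataFrame(rows)
    cols = ["roi_id"] + [c for c in df.columns if c != "roi_id"]
    return df[cols]


def normalize_features(table: pd.DataFrame,
                       columns: list[str] | None = None
                       ) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Min-max scale each feature column to [0, 1] across the population.

    Used only for scatter/cluster displays; classification always works on
    unscaled values.  Constant columns map to all zeros and are flagged.
    """
    cols = columns or [c for c in table.columns
                       if np.issubdtype(table[c].dtype, np.number)]
    out = table.copy()
    degenerate: dict[str, bool] = {}
    for c in cols:
        lo, hi = float(table[c].min()), float(table[c].max())
        if hi > lo:
            out[c] = (table[c] - lo) / (hi - lo)
            degenerate[c] = False
        else:
            out[c] = 0.0
            degenerate[c] = True
    return out, degenerate


def denormalize_features(scaled: pd.DataFrame, original: pd.DataFrame,
                         columns: list[str] | None = None) -> pd.DataFrame:
    """Invert :func:`normalize_features` given the original table."""
    cols = columns or [c for c in scaled.columns
                       if np.issubdtype(scaled[c].dtype, np.number)]
    out = scaled.copy()
    for c in cols:
        lo, hi = float(original[c].min()), float(original[c].max())
        if hi > lo:
            out[c] = scaled[c] * (hi - lo) + lo
        else:
            out[c] = lo
    return out
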