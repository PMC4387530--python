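"""Rule-based assignment of calcium transients to the 14-class taxonomy.

Nine secondary classes describe the ATP-perfusion recordings (grouped into
three primary classes: slow-or-absent response, rapid peak then plateau,
rapid peak then spiking) and five additional classes appear only after
scratch wounding (W1-W5, all eventually stabilizing in a sustained
plateau); wounded monolayers never spike.  The decision tree branches on
onset latency (rapid vs slow), the number of discrete post-initial peaks,
detected spiking, and the sequence of stable post-peak epochs (elevated vs
baseline levels).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import defaults as dflt
from .signatures import MetricParams, SignatureMetrics, Trace, _running_median
from scipy.signal import find_peaks

ATP_PRIMARY_NAMES = {"1": "slow or absent response",
                     "2": "rapid peak, then plateau",
                     "3": "rapid peak, then spiking"}
WOUND_PRIMARY_NAMES = {"slow": "slow or absent response",
                       "peak_plateau": "peak-plateau",
                       "peak_baseline": "peak-baseline"}


@dataclasses.dataclass(frozen=True)
class TransientClass:
    protocol: str       # "ATP" or "wound"
    secondary: str      # e.g. "2a", "3b", "W4"

    def __post_init__(self) -> None:
        if self.protocol not in ("ATP", "wound"):
            raise ValueError("protocol must be 'ATP' or 'wound'")
        table = (dflt.ATP_PRIMARY_OF_SECONDARY if self.protocol == "ATP"
                 else dflt.WOUND_PRIMARY_OF_SECONDARY)
        if self.secondary not in table:
            raise ValueError(f"unknown secondary class {self.secondary!r} "
                             f"for protocol {self.protocol}")

    @property
    def primary(self) -> str:
        if self.protocol == "ATP":
            return dflt.ATP_PRIMARY_OF_SECONDARY[self.secondary]
        return dflt.WOUND_PRIMARY_OF_SECONDARY[self.secondary]


@dataclasses.dataclass
class ClassifyParams:
    """Decision thresholds; levels in ratio a.u. above baseline, times in s."""

    response_threshold: float = 0.15
    plateau_threshold: float = 0.10
    rapid_latency_s: float = 120.0       # onset slower than this is "slow"
    second_peak_prominence_frac: float = 0.25  # x initial peak height
    min_spike_count: int = 2             # rebase-gated maxima to call spiking
    epoch_median_window_s: float = 90.0
    min_epoch_s: float = 150.0
    terminal_min_s: float = 300.0        # a terminal plateau must persist this long
    dual_step_min: float = 0.12          # level drop defining a dual plateau
    early_window_s: float = 600.0


@dataclasses.dataclass
class _Epoch:
    t0: float
    t1: float
    elevated: bool
    level: float
    level_start: float = 0.0
    level_end: float = 0.0

    @property
    def duration(self) -> float:
        return self.t1 - self.t0

    def stable_elevated(self, tol: float = 0.06) -> bool:
        """Elevated and not decaying: a plateau rather than a decay tail."""
        return self.elevated and self.level_end >= self.level_start - tol


def _onset_latency_s(t: np.ndarray, rel: np.ndarray, stim: float,
                     metrics: SignatureMetrics, p: ClassifyParams) -> float:
    """Time from stimulus to half the initial peak on the rising edge."""
    if metrics.peak_height >= p.response_threshold:
        target = 0.5 * metrics.peak_height
    else:
        target = p.plateau_threshold
    idx = np.flatnonzero((t >= stim) & (rel >= target))
    if idx.size == 0:
        return float("inf")
    return float(t[idx[0]] - stim)


def _epochs(t: np.ndarray, rel: np.ndarray, start_idx: int,
            p: ClassifyParams) -> list[_Epoch]:
    """Stable post-peak epochs from a running median of the trace."""
    if start_idx >= t.size - 2:
        return []
    dt = float(np.median(np.diff(t)))
    smooth = _running_median(rel[start_idx:], dt, p.epoch_median_window_s)
    elevated = smooth >= p.plateau_threshold
    tt = t[start_idx:]
    # raw runs
    runs: list[_Epoch] = []
    k0 = 0
    for k in range(1, elevated.size + 1):
        if k == elevated.size or elevated[k] != elevated[k0]:
            runs.append(_Epoch(float(tt[k0]), float(tt[k - 1]),
                               bool(elevated[k0]),
                               float(np.median(smooth[k0:k]))))
            k0 = k
    # absorb short runs into their predecessor, then merge same-state
    merged: list[_Epoch] = []
    for ep in runs:
        if merged and (ep.duration < p.min_epoch_s):
            merged[-1].t1 = ep.t1
        elif merged and merged[-1].elevated == ep.elevated:
            merged[-1].t1 = ep.t1
            merged[-1].level = max(merged[-1].level, ep.level)
        else:
            merged.append(ep)
    # re-merge adjacent same-state epochs created by absorption
    out: list[_Epoch] = []
    for ep in merged:
        if out and out[-1].elevated == ep.elevated:
            out[-1].t1 = ep.t1
            out[-1].level = max(out[-1].level, ep.level)
        else:
            out.append(ep)
    # start/end levels over the final epoch extents
    for ep in out:
        i0 = int(np.searchsorted(tt, ep.t0))
        i1 = max(i0 + 1, int(np.searchsorted(tt, ep.t1)))
        third = max(1, (i1 - i0) // 3)
        ep.level_start = float(np.median(smooth[i0:i0 + third]))
        ep.level_end = float(np.median(smooth[i1 - third:i1]))
    return out


def _state_at(epochs: list[_Epoch], t: float) -> bool | None:
    """Elevated/baseline state of the epoch containing time ``t``."""
    for ep in epochs:
        if ep.t0 <= t <= ep.t1:
            return ep.elevated
    return None


def _post_peak_start(t: np.ndarray, stim: float,
                     metrics: SignatureMetrics) -> int:
    t_ref = stim + 60.0 * metrics.peak_time_min + 60.0 * max(
        metrics.fwhm_min, 1.0) + 30.0
    return int(np.searchsorted(t, t_ref))


def _secondary_peaks(t: np.ndarray, rel: np.ndarray, start_idx: int,
                     metrics: SignatureMetrics, p: ClassifyParams
                     ) -> np.ndarray:
    """Discrete post-initial maxima regardless of inter-peak level."""
    if start_idx >= rel.size - 2:
        return np.empty(0)
    prom = max(p.second_peak_prominence_frac * metrics.peak_height, 0.12)
    dt = float(np.median(np.diff(t)))
    # cap the width so broad plateaus are not mistaken for discrete peaks
    idx, _ = find_peaks(rel[start_idx:], prominence=prom,
                        distance=max(1, int(round(60.0 / dt))),
                        width=(None, max(2.0, 180.0 / dt)), rel_height=0.5)
    return t[start_idx + idx]


def classify_transient(metrics: SignatureMetrics, trace: Trace,
                       protocol: str, stimulus_time_s: float,
                       params: ClassifyParams | None = None
                       ) -> TransientClass:
    """Assign one (denoised) transient to its secondary class.

    Every input maps to exactly one class; off-taxonomy shapes fall into
    the nearest class of the protocol (documented in the methods note).
    Spiking under the wound protocol is classified by the ATP rules with a
    warning, since wounded monolayers are not expected to spike.
    """
    p = params or ClassifyParams()
    t, v = trace.times_s, trace.values
    rel = v - metrics.baseline

    responding = (metrics.peak_height >= p.response_threshold
                  or metrics.plateau_height >= p.plateau_threshold)
    if not responding:
        return TransientClass(protocol, "1a")

    latency = _onset_latency_s(t, rel, stimulus_time_s, metrics, p)
    rapid = latency <= p.rapid_latency_s

    start = _post_peak_start(t, stimulus_time_s, metrics)
    epochs = _epochs(t, rel, start, p)
    terminal = epochs[-1] if epochs else None
    terminal_plateau = (terminal is not None and terminal.elevated
                        and terminal.duration >= p.terminal_min_s)

    if not rapid:
        if not metrics.has_peak:
            return TransientClass(protocol, "1b")
        if terminal_plateau:
            return TransientClass(protocol,
                                  "W1" if protocol == "wound" else "1b")
        return TransientClass(protocol, "1c")

    if not metrics.has_peak:
        # rapid rise without a discrete peak: plateau-only response
        return TransientClass(protocol, "2a" if terminal_plateau else "1a")

    spiking = metrics.spike_times_s.size >= p.min_spike_count
    if spiking:
        if protocol == "wound":
            warnings.warn("spiking detected under the wound protocol; "
                          "classified by ATP rules", stacklevel=2)
        last_spike = float(metrics.spike_times_s[-1])
        spike_free_tail = t[-1] - last_spike >= p.terminal_min_s
        if terminal_plateau and spike_free_tail:
            return TransientClass(protocol, "2c")
        # plateau vs baseline before spiking: robust level in the window
        # just ahead of the first spike (3c drops its plateau only at onset)
        first_spike = float(metrics.spike_times_s[0])
        w0 = np.searchsorted(t, first_spike - 240.0)
        w1 = np.searchsorted(t, first_spike - 90.0)
        w0 = max(w0, start)
        if w1 > w0 + 2 and float(np.median(rel[w0:w1])) >= p.plateau_threshold:
            return TransientClass(protocol, "3c")
        return TransientClass(protocol, "3b")

    second = _secondary_peaks(t, rel, start, metrics, p)
    if second.size >= 1:
        # level immediately ahead of the second peak: plateau or baseline?
        t2 = float(second[0])
        dt = float(np.median(np.diff(t)))
        smooth = _running_median(rel, dt, 90.0)
        w0 = max(start, int(np.searchsorted(t, t2 - 180.0)))
        w1 = max(w0 + 2, int(np.searchsorted(t, t2 - 60.0)))
        if float(np.median(smooth[w0:w1])) >= p.plateau_threshold:
            return TransientClass(protocol, "2b")
        if protocol == "wound":
            return TransientClass(protocol, "W4")
        return TransientClass(protocol, "2b" if terminal_plateau else "3a")

    if protocol == "ATP":
        return TransientClass(protocol, "2a" if terminal_plateau else "3a")

    # wound protocol, rapid single peak, no spiking
    if terminal_plateau:
        mid_baseline = any((not ep.elevated) and ep.duration >= p.min_epoch_s
                           for ep in epochs[:-1])
        if mid_baseline:
            return TransientClass(protocol, "W5")
        if (metrics.plateau2_height > 0
                and metrics.plateau_height - metrics.plateau2_height
                >= p.dual_step_min):
            return TransientClass(protocol, "W3")
        return TransientClass(protocol, "2a")
    return TransientClass(protocol, "W2")


@dataclasses.dataclass
class ClassTable:
    """Per-replicate secondary counts and primary-class percentages."""

    counts: pd.DataFrame            # index secondary, columns replicate
    primary_percent: pd.DataFrame   # index primary, columns replicate
    primary_summary: pd.DataFrame   # mean, sem, n_replicates per primary


def tabulate(labels: list[tuple[object, TransientClass]]) -> ClassTable:
    """Tabulate (replicate, class) assignments.

    Primary percentages are computed per replicate; the summary reports
    their mean +/- s.e.m. across replicates (s.e.m. 0 with a single
    replicate, flagged by ``n_replicates``).
    """
    if not labels:
        raise ValueError("no labels to tabulate")
    df = pd.DataFrame({"replicate": [r for r, _ in labels],
                       "secondary": [c.secondary for _, c in labels],
                       "primary": [c.primary for _, c in labels]})
    counts = (df.groupby(["secondary", "replicate"]).size()
              .unstack(fill_value=0))
    prim_counts = (df.groupby(["primary", "replicate"]).size()
                   .unstack(fill_value=0))
    primary_percent = 100.0 * prim_counts / prim_counts.sum(axis=0)
    n_rep = primary_percent.shape[1]
    summary = pd.DataFrame({
        "mean_percent": primary_percent.mean(axis=1),
        "sem_percent": (primary_percent.std(axis=1, ddof=1) / np.sqrt(n_rep)
                        if n_rep > 1 else 0.0),
        "n_replicates": n_rep,
    })
    return ClassTable(counts, primary_percent, summary)


def feature_scatter(table: pd.DataFrame, grouping: str = "spiking"
                    ) -> pd.DataFrame:
    """Normalized feature pairs with group tags for scatter displays.

    ``grouping='spiking'`` tags cells that entered a spiking mode;
    ``grouping='proximal'`` expects a ``distance_um`` column and tags cells
    within 100 um of the wound edge.
    """
    from .signatures import normalize_features
    if table.empty:
        return pd.DataFrame(columns=["peak_height", "plateau_height",
                                     "fwhm_min", "spike_rate_per_s", "group"])
    feats = ["peak_height", "plateau_height", "fwhm_min", "spike_rate_per_s"]
    scaled, _ = normalize_features(table[feats].copy(), feats)
    if grouping == "spiking":
        scaled["group"] = np.where(table["is_spiking"], "spiking",
                                   "non-spiking")
    elif grouping == "proximal":
        scaled["group"] = np.where(table["distance_um"] < 100.0, "proximal",
                                   "distal")
    else:
        raise ValueError("grouping must be 'spiking' or 'proximal'")
    return scaled.reset_index(drop=True)
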