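"""Published summary statistics used as generator and analysis defaults.

These tables summarize calcium-transient populations recorded from confluent
normal human urothelial (NHU) monolayers: an ATP-perfusion protocol (25 uM
ATP, 35 min, three replicate donor lines) and a scratch-wound protocol
(45 min, proximal = < 100 um from the wound edge).  The synthetic-data
generator treats them as the ground-truth study conditions; they are not
tuning knobs.
"""

from __future__ import annotations

# Per-replicate secondary-class counts for the ATP protocol.
# Replicate cell totals: 114, 117, 126.
ATP_CLASS_COUNTS: dict[int, dict[str, int]] = {
    1: {"1a": 12, "1b": 8, "1c": 4, "2a": 27, "2b": 5, "2c": 7,
        "3a": 6, "3b": 24, "3c": 21},
    2: {"1a": 11, "1b": 13, "1c": 5, "2a": 24, "2b": 3, "2c": 10,
        "3a": 3, "3b": 29, "3c": 29},
    3: {"1a": 8, "1b": 11, "1c": 1, "2a": 31, "2b": 6, "2c": 3,
        "3a": 4, "3b": 33, "3c": 29},
}

#: secondary -> primary grouping for the ATP taxonomy
ATP_PRIMARY_OF_SECONDARY = {
    "1a": "1", "1b": "1", "1c": "1",
    "2a": "2", "2b": "2", "2c": "2",
    "3a": "3", "3b": "3", "3c": "3",
}

#: pooled cell counts per primary class over the three ATP replicates
ATP_PRIMARY_N = {"1": 73, "2": 116, "3": 168}

# Mean and s.e.m. (across cells, pooled replicates) of the signature metrics
# per primary ATP class.  Peak/plateau heights are ratio a.u. above baseline,
# peak time and FWHM in minutes, spiking rate in 1/s.
ATP_PRIMARY_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "1": {"peak_height": (0.11, 0.05), "peak_time_min": (6.95, 3.26),
          "fwhm_min": (0.72, 0.61), "plateau_height": (0.07, 0.03),
          "spike_rate_per_s": (0.0, 0.0)},
    "2": {"peak_height": (1.04, 0.03), "peak_time_min": (1.13, 0.01),
          "fwhm_min": (3.92, 0.72), "plateau_height": (0.79, 0.03),
          "spike_rate_per_s": (1.1e-3, 0.6e-3)},
    "3": {"peak_height": (0.98, 0.03), "peak_time_min": (4.20, 0.92),
          "fwhm_min": (1.81, 0.11), "plateau_height": (0.28, 0.05),
          "spike_rate_per_s": (1.9e-3, 0.4e-3)},
}

#: fraction of cells in each primary class that spike, and the implied mean
#: rate of the spiking subset (pooled class mean divided by that fraction)
ATP_SPIKING_FRACTION = {"1": 0.0, "2": 20 / 116, "3": 155 / 168}

# Cell-level mean / s.d. of wound-protocol signature metrics, split at the
# 100 um proximal/distal boundary.  n = 76 proximal, 178 distal.
WOUND_FEATURE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "proximal": {"peak_height": (1.301, 0.4895),
                 "peak_time_min": (1.033, 3.275),
                 "fwhm_min": (3.176, 4.657),
                 "plateau_height": (0.3156, 0.2919)},
    "distal": {"peak_height": (0.5484, 0.5854),
               "peak_time_min": (0.5132, 0.8725),
               "fwhm_min": (0.7623, 0.9670),
               "plateau_height": (0.1648, 0.08274)},
}

WOUND_N = {"proximal": 76, "distal": 178}

# Early-response group mixtures for the wound protocol (fractions of cells
# whose first-10-min behaviour is slow/absent, peak-plateau or peak-baseline).
WOUND_GROUP_MIXTURE = {
    "proximal": {"slow": 0.10, "peak_plateau": 0.64, "peak_baseline": 0.26},
    "distal": {"slow": 0.405, "peak_plateau": 0.010, "peak_baseline": 0.585},
}

# Secondary-class split within each early-response group.  The wound recordings
# share classes 1a/1b/2a/2b with the ATP protocol and add five wound-specific
# shapes W1-W5; spiking classes were never observed after wounding.
WOUND_SECONDARY_SPLIT = {
    "proximal": {
        "slow": {"1a": 0.2, "1b": 0.4, "W1": 0.4},
        "peak_plateau": {"2a": 0.55, "2b": 0.10, "W2": 0.15, "W3": 0.20},
        "peak_baseline": {"W4": 0.35, "W5": 0.65},
    },
    "distal": {
        "slow": {"1a": 0.35, "1b": 0.45, "W1": 0.20},
        "peak_plateau": {"2a": 0.7, "W2": 0.3},
        "peak_baseline": {"W4": 0.2, "W5": 0.8},
    },
}

#: wound-protocol secondary -> early-response primary group
WOUND_PRIMARY_OF_SECONDARY = {
    "1a": "slow", "1b": "slow", "1c": "slow", "W1": "slow",
    "2a": "peak_plateau", "2b": "peak_plateau",
    "W2": "peak_plateau", "W3": "peak_plateau",
    "W4": "peak_baseline", "W5": "peak_baseline",
    # spiking classes are ATP-only; if they ever appear under the wound
    # protocol they are grouped by their early-response shape
    "2c": "peak_baseline", "3a": "peak_baseline", "3b": "peak_baseline",
    "3c": "peak_plateau",
}

#: default recording geometry: 1 frame/s, 512 x 512 px at 0.65 um/px
DEFAULT_PIXEL_SIZE_UM = 0.65
DEFAULT_FRAME_INTERVAL_S = 1.0
DEFAULT_FIELD_PX = (512, 512)
#: ATP recordings run 35 min post-stimulus; wound recordings 45 min
ATP_DURATION_S = 35 * 60.0
WOUND_DURATION_S = 45 * 60.0
#: pre-stimulus span used for baseline estimation
DEFAULT_PRESTIM_S = 120.0


def atp_pooled_mixture() -> dict[str, float]:
    """Secondary-class mixture pooled over the three ATP replicates."""
    totals: dict[str, int] = {}
    for counts in ATP_CLASS_COUNTS.values():
        for sec, n in counts.items():
            totals[sec] = totals.get(sec, 0) + n
    grand = sum(totals.values())
    return {sec: n / grand for sec, n in totals.items()}
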