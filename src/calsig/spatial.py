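"""Spatial statistics relating calcium signatures to wound proximity.

Distances are measured from each ROI centroid to the wound-edge polyline.
Cells are split at a nominal 100 um threshold into proximal (< 100 um) and
distal cells, compared feature-by-feature with a two-tailed Mann-Whitney U
test, and the split threshold itself is swept from 10 to 400 um in 10 um
steps (<= x vs > x) to locate the distance of greatest significance.
Primary transient classes are compared with Kruskal-Wallis plus Dunn's
multiple-comparison post test.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import SignatureMetrics


@dataclasses.dataclass
class SpatialRecord:
    roi_id: int
    distance_um: float
    metrics: SignatureMetrics

    def __post_init__(self) -> None:
        if self.distance_um < 0:
            raise ValueError("distance_um must be >= 0")


@dataclasses.dataclass
class SweepResult:
    feature: str
    thresholds_um: np.ndarray
    p_values: np.ndarray           # NaN where a side is under-populated
    n_below: np.ndarray
    n_above: np.ndarray


def _point_segment_distance(pt: np.ndarray, a: np.ndarray,
                            b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((pt - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(pt - (a + t * ab)))


def distance_to_wound(centroid_px: tuple[float, float], wound,
                      pixel_size_um: float) -> float:
    """Minimum Euclidean distance (um) from a centroid to the wound edge."""
    pt = np.asarray(centroid_px, dtype=float)
    edge = wound.edge
    d = min(_point_segment_distance(pt, edge[i], edge[i + 1])
            for i in range(len(edge) - 1))
    # a centroid on the removed side of the scratch sits at the edge itself
    if wound.removed_side == "left" and pt[0] < edge[:, 0].min():
        import warnings
        warnings.warn("centroid on the removed side of the wound; distance 0",
                      stacklevel=2)
        return 0.0
    if wound.removed_side == "right" and pt[0] > edge[:, 0].max():
        import warnings
        warnings.warn("centroid on the removed side of the wound; distance 0",
                      stacklevel=2)
        return 0.0
    return d * pixel_size_um


def split_proximal_distal(records: list[SpatialRecord],
                          threshold_um: float = 100.0
                          ) -> tuple[list[SpatialRecord], list[SpatialRecord]]:
    """Strict partition: proximal d < threshold, distal d >= threshold."""
    proximal = [r for r in records if r.distance_um < threshold_um]
    distal = [r for r in records if r.distance_um >= threshold_um]
    if not proximal or not distal:
        import warnings
        warnings.warn("one side of the proximal/distal split is empty",
                      stacklevel=2)
    return proximal, distal


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U with midranks for ties.

    Exact p by enumeration for small tie-free samples (n_x + n_y <= 12),
    otherwise the tie-corrected normal approximation with continuity
    correction.  Identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u = x.size * y.size / 2.0
        return u, 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def threshold_sweep(records: list[SpatialRecord], features: list[str],
                    thresholds_um: np.ndarray | None = None,
                    min_group_size: int = 3) -> dict[str, SweepResult]:
    """Mann-Whitney p as a function of the split distance (<= x vs > x)."""
    if not records:
        raise ValueError("no records")
    if all(r.distance_um is None for r in records):
        raise ValueError("no wound geometry / distances available")
    thr = (np.arange(10.0, 400.0 + 1e-9, 10.0) if thresholds_um is None
           else np.asarray(thresholds_um, dtype=float))
    d = np.array([r.distance_um for r in records])
    out: dict[str, SweepResult] = {}
    for feat in features:
        vals = np.array([getattr(r.metrics, feat) for r in records],
                        dtype=float)
        p = np.full(thr.shape, np.nan)
        nb = np.zeros(thr.shape, dtype=int)
        na = np.zeros(thr.shape, dtype=int)
        for i, x in enumerate(thr):
            below, above = vals[d <= x], vals[d > x]
            nb[i], na[i] = below.size, above.size
            if below.size >= min_group_size and above.size >= min_group_size:
                p[i] = mann_whitney_u(below, above)[1]
        out[feat] = SweepResult(feat, thr, p, nb, na)
    return out


def kruskal_wallis_dunn(groups: list[np.ndarray], labels: list[str] | None = None
                        ) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis H (tie-corrected) with Dunn's post test.

    Dunn z statistics compare group mean ranks using the pooled-rank
    variance with tie correction; two-sided p values are Bonferroni
    adjusted over the k(k-1)/2 pairs.  All-identical data give H = 0, p = 1
    and all pairwise p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    labels = labels or [f"group{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("need >= 3 observations in total")
    pairs = list(itertools.combinations(range(len(groups)), 2))
    if np.all(pooled == pooled[0]):
        rows = [{"group_a": labels[i], "group_b": labels[j], "z": 0.0,
                 "p_adjusted": 1.0} for i, j in pairs]
        return 0.0, 1.0, pd.DataFrame(rows)
    h, p = stats.kruskal(*groups)

    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean()
                  for i in range(len(groups))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    m = len(pairs)
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_pair = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "z": float(z), "p_adjusted": float(p_pair)})
    return float(h), float(p), pd.DataFrame(rows)


def summarize(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """mean / s.d. (n-1) / s.e.m. per group; dispersion NaN when n = 1."""
    rows = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 1:
            raise ValueError(f"group {name!r} is empty")
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
        rows.append({"group": name, "n": vals.size,
                     "mean": float(vals.mean()), "sd": sd,
                     "sem": sd / np.sqrt(vals.size) if vals.size > 1
                     else float("nan")})
    return pd.DataFrame(rows).set_index("group")
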