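"""Kymograph quantification: firings, autocorrelation, activity patches and
polarization statistics.

The polarity pipeline mirrors the standard image-analysis route: binarize
the PKB kymograph, label connected high-activity patches (8-connectivity,
with the space axis treated as periodic), filter small patches, and derive
front counts and polarization classifications from the surviving patch
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FiringEvent",
    "PatchRecord",
    "PolarityMetrics",
    "temporal_autocorrelation",
    "detect_firings",
    "excited_level",
    "firing_durations",
    "FIRING_THRESHOLD_FRACTION",
    "binarize",
    "extract_patches",
    "patch_count_series",
    "polarity_metrics",
    "sweep_heatmaps",
]

# Frozen firing-detection conventions (calibrated once against the
# published baseline firing statistics, then fixed).  Ras excursions are
# tall narrow spikes, so a low fractional threshold captures the full
# event; PKB rides a slow decay tail, so a higher threshold keeps separate
# events separate.
FIRING_THRESHOLD_FRACTION: Dict[str, float] = {"ras": 0.03, "pkb": 0.20}
FIRING_MIN_DURATION = 10.0   # s
FIRING_MERGE_WINDOW = 30.0   # s


@dataclass(frozen=True)
class FiringEvent:
    """One supra-threshold excursion at a single membrane site."""

    site: int
    start: float
    end: float
    peak: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PatchRecord:
    """One connected high-activity region of a binarized kymograph."""

    area: int                 # pixels
    t_start: float            # s
    t_end: float              # s
    angular_extent: float     # degrees
    orientation: float        # degrees of major axis from the time axis
    centroid_t: float         # s
    centroid_angle: float     # degrees

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class PolarityMetrics:
    """Per-simulation polarity summary."""

    dominant_patch_count: int
    longest_patch_duration: float
    mean_patch_width: float
    fraction_time_polarized: float
    is_polarized: bool


# ---------------------------------------------------------------------------
# temporal autocorrelation
# ---------------------------------------------------------------------------

def temporal_autocorrelation(kymo_species: np.ndarray,
                             max_lag: Optional[int] = None
                             ) -> Dict[str, np.ndarray]:
    """Normalised temporal autocorrelation of every spatial trace.

    Returns per-site curves plus their mean and standard-deviation
    envelope.  A zero-variance trace is flagged and assigned correlation 0
    at positive lags.
    """
    X = np.asarray(kymo_species, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a (space, time) array with >= 2 time points")
    ns, nt = X.shape
    if max_lag is None:
        max_lag = nt - 1
    max_lag = min(max_lag, nt - 1)
    Xc = X - X.mean(axis=1, keepdims=True)
    var = (Xc * Xc).mean(axis=1)
    flat = var <= 0
    safe = np.where(flat, 1.0, var)
    curves = np.empty((ns, max_lag + 1))
    for lag in range(max_lag + 1):
        curves[:, lag] = ((Xc[:, :nt - lag] * Xc[:, lag:]).sum(axis=1)
                          / (nt * safe))
    curves[flat, 0] = 1.0
    curves[flat, 1:] = 0.0
    return {
        "lags": np.arange(max_lag + 1),
        "curves": curves,
        "mean": curves.mean(axis=0),
        "std": curves.std(axis=0),
        "flat_traces": np.nonzero(flat)[0],
    }


# ---------------------------------------------------------------------------
# firing detection
# ---------------------------------------------------------------------------

def detect_firings(trace: np.ndarray, threshold: float,
                   min_duration: float = FIRING_MIN_DURATION,
                   merge_window: float = FIRING_MERGE_WINDOW,
                   dt: float = 1.0, site: int = 0) -> List[FiringEvent]:
    """Maximal supra-threshold intervals of one trace.

    Intervals separated by gaps shorter than ``merge_window`` are merged;
    events shorter than ``min_duration`` are dropped.
    """
    trace = np.asarray(trace, float)
    above = trace > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(trace))
    merged: List[Tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) * dt < merge_window:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    events = []
    for s, e in merged:
        if (e - s) * dt >= min_duration:
            events.append(FiringEvent(site=site, start=s * dt, end=e * dt,
                                      peak=float(trace[s:e].max())))
    return events


def excited_level(kymo_species: np.ndarray, basal: float,
                  min_fraction: float = 0.1) -> float:
    """Mean excited-trace peak: average of per-site maxima over sites whose
    excursion exceeds ``min_fraction`` of the global dynamic range."""
    X = np.asarray(kymo_species, float)
    peaks = X.max(axis=1)
    gate = basal + min_fraction * (peaks.max() - basal)
    fired = peaks[peaks > gate]
    return float(fired.mean()) if fired.size else float(peaks.max())


def firing_durations(kymos: Sequence[np.ndarray], basal: float,
                     species: str = "ras",
                     dt: float = 1.0) -> np.ndarray:
    """Pooled firing durations over several kymographs of one species,
    using the frozen per-species detection threshold."""
    frac = FIRING_THRESHOLD_FRACTION[species]
    exc = np.mean([excited_level(k, basal) for k in kymos])
    thr = basal + frac * (exc - basal)
    durs = []
    for k in kymos:
        for i, trace in enumerate(k):
            durs.extend(ev.duration
                        for ev in detect_firings(trace, thr, dt=dt, site=i))
    return np.asarray(durs)


# ---------------------------------------------------------------------------
# binarization and patch extraction
# ---------------------------------------------------------------------------

def binarize(kymo_species: np.ndarray, threshold: Optional[float] = None,
             basal: Optional[float] = None,
             excited: Optional[float] = None) -> np.ndarray:
    """Boolean activity mask of a kymograph.

    With an explicit ``threshold`` that value is used; otherwise the
    default model-informed rule is the midpoint between ``basal`` and
    ``excited``.  A constant kymograph yields an all-false mask (with a
    warning via numpy's errstate semantics left to the caller).
    """
    X = np.asarray(kymo_species, float)
    if threshold is None:
        if basal is None or excited is None:
            raise ValueError("need threshold, or basal and excited levels")
        threshold = 0.5 * (basal + excited)
    if X.max() == X.min():
        return np.zeros_like(X, dtype=bool)
    return X > threshold


def _label_periodic(binary: np.ndarray) -> Tuple[np.ndarray, int]:
    """8-connected labelling with wraparound along axis 0 (space)."""
    structure = np.ones((3, 3), bool)
    lab, nlab = ndimage.label(binary, structure=structure)
    if nlab == 0:
        return lab, 0
    parent = np.arange(nlab + 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    top, bot = lab[0], lab[-1]
    nt = binary.shape[1]
    for t in range(nt):
        if top[t]:
            for tt in (t - 1, t, t + 1):
                if 0 <= tt < nt and bot[tt]:
                    ra, rb = find(top[t]), find(bot[tt])
                    if ra != rb:
                        parent[rb] = ra
    remap = {}
    out = np.zeros_like(lab)
    for l in range(1, nlab + 1):
        r = find(l)
        if r not in remap:
            remap[r] = len(remap) + 1
        out[lab == l] = remap[r]
    return out, len(remap)


def extract_patches(binary: np.ndarray, min_area: int = 50,
                    degrees_per_site: Optional[float] = None,
                    record_interval: float = 1.0) -> List[PatchRecord]:
    """Connected components of a binary kymograph as patch records.

    Components touching both spatial edges at overlapping times are merged
    before measurement (the membrane is a ring).  Patches smaller than
    ``min_area`` pixels are excluded; the rest are returned sorted by area,
    largest first.  Orientation is the angle of the second-moment ellipse
    major axis relative to the time axis, in [0, 90] degrees (pixel units).
    """
    binary = np.asarray(binary, bool)
    ns, nt = binary.shape
    if degrees_per_site is None:
        degrees_per_site = 360.0 / ns
    lab, nlab = _label_periodic(binary)
    records = []
    for l in range(1, nlab + 1):
        rows, cols = np.nonzero(lab == l)
        area = rows.size
        if area < min_area:
            continue
        occupied = np.zeros(ns, bool)
        occupied[rows] = True
        if occupied.all():
            rr = rows.astype(float)
            extent_sites = ns
        else:
            gap = int(np.argmin(occupied))       # an unoccupied row
            rr = (rows - gap - 1) % ns
            extent_sites = int(rr.max() - rr.min() + 1)
        mu_s, mu_t = rr.mean(), cols.mean()
        ds, dtc = rr - mu_s, cols - mu_t
        mss, mtt, mst = (ds * ds).mean(), (dtc * dtc).mean(), (ds * dtc).mean()
        theta = 0.5 * np.degrees(np.arctan2(2.0 * mst, mtt - mss))
        orient = abs(theta)
        if orient > 90.0:
            orient = 180.0 - orient
        records.append(PatchRecord(
            area=int(area),
            t_start=float(cols.min() * record_interval),
            t_end=float(cols.max() * record_interval),
            angular_extent=float(extent_sites * degrees_per_site),
            orientation=float(orient),
            centroid_t=float(mu_t * record_interval),
            centroid_angle=float((mu_s * degrees_per_site) % 360.0)))
    records.sort(key=lambda r: -r.area)
    return records


def patch_count_series(records: Sequence[PatchRecord], n_timepoints: int,
                       record_interval: float = 1.0,
                       orientation_max: Optional[float] = 30.0) -> np.ndarray:
    """Number of (optionally orientation-filtered) patches covering each
    recorded time point."""
    counts = np.zeros(n_timepoints, int)
    for r in records:
        if orientation_max is not None and r.orientation >= orientation_max:
            continue
        i0 = int(round(r.t_start / record_interval))
        i1 = int(round(r.t_end / record_interval))
        counts[i0:i1 + 1] += 1
    return counts


def _mode_smallest(counts: np.ndarray) -> int:
    """Statistical mode; ties broken toward the smaller count."""
    vals, occ = np.unique(counts, return_counts=True)
    return int(vals[np.argmax(occ)])    # np.unique sorts ascending


def polarity_metrics(records: Sequence[PatchRecord], n_timepoints: int,
                     record_interval: float = 1.0,
                     orientation_max: float = 30.0,
                     min_polarized_fraction: float = 0.10,
                     orientation_exclude: float = 60.0,
                     criterion: str = "methods") -> PolarityMetrics:
    """Polarity summary and classification of one kymograph.

    ``criterion='methods'`` (default): polarized iff the most frequent
    filtered-patch count is one, more than ``min_polarized_fraction`` of
    the simulation is spent in that single-front state, and the
    largest-area patch's orientation does not exceed
    ``orientation_exclude`` degrees (guards against hyperactive cells).
    ``criterion='width'``: polarized iff the dominant count is one and the
    mean patch width is below 60 degrees.
    """
    if not records:
        return PolarityMetrics(0, 0.0, 0.0, 0.0, False)
    counts = patch_count_series(records, n_timepoints, record_interval,
                                orientation_max)
    mode = _mode_smallest(counts)
    frac_one = float((counts == 1).mean())
    longest = records[0].duration        # records sorted by area desc
    mean_width = float(np.mean([r.angular_extent for r in records]))
    if criterion == "methods":
        is_pol = (mode == 1 and frac_one > min_polarized_fraction
                  and records[0].orientation <= orientation_exclude)
    elif criterion == "width":
        is_pol = mode == 1 and mean_width < 60.0
    else:
        raise ValueError("criterion must be 'methods' or 'width'")
    return PolarityMetrics(
        dominant_patch_count=mode,
        longest_patch_duration=float(longest),
        mean_patch_width=mean_width,
        fraction_time_polarized=frac_one,
        is_polarized=bool(is_pol))


# ---------------------------------------------------------------------------
# sweep-level heatmaps
# ---------------------------------------------------------------------------

def sweep_heatmaps(metrics: pd.DataFrame, axis1: str, axis2: str
                   ) -> Dict[str, pd.DataFrame]:
    """Aggregate per-replicate sweep metrics into heatmap matrices.

    ``metrics`` must be tidy with columns ``axis1``, ``axis2`` and any of
    ``log10_ras_activity``, ``total_distance``, ``final_displacement``,
    ``is_polarized``, ``fraction_time_polarized``, ``longest_patch_duration``,
    ``mean_patch_width``, ``dominant_patch_count``.  Mean (or, for the
    polarized flag, the count of polarized replicates) is reported per grid
    cell; missing cells stay NaN.
    """
    out: Dict[str, pd.DataFrame] = {}
    for col in ("log10_ras_activity", "total_distance", "final_displacement",
                "fraction_time_polarized", "longest_patch_duration",
                "mean_patch_width", "dominant_patch_count"):
        if col in metrics:
            out[col] = metrics.pivot_table(index=axis2, columns=axis1,
                                           values=col, aggfunc="mean")
    if "is_polarized" in metrics:
        out["polarized_count"] = metrics.pivot_table(
            index=axis2, columns=axis1, values="is_polarized", aggfunc="sum")
    return out
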