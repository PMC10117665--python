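"""Mobility quantification from heading time series and centroid tracks.

In the four-cell droplet pattern the fish heading relative to the flow axes
is the mobility readout: active fish hold the upstream "source" heading
(90/270 deg), passive fish are swept onto the "sink" axis (0/180 deg).
This module computes circular summaries of heading, folded deviations from
the two axes, a mobility class, the chance-alignment probability of a
cohort, mean squared displacement of free-swimming tracks, and the recovery
trend of an anesthetized fish regaining activity.

Folding: a rod's head can point at either of two opposite source directions
(both are upstream holds), so deviations are distances to the nearest
member of the axis pair and live in ``[0, 90]``; source and sink deviations
of any heading sum to exactly 90 degrees.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .tracking import TrackedTrajectory


@dataclass
class AngleSeries:
    """Heading time series; angles wrapped to [0, 360) degrees."""

    times: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float) % 360.0
        if len(self.times) != len(self.angles_deg):
            raise ValueError("times and angles_deg must have equal length")


@dataclass(frozen=True)
class CircularSummary:
    circ_mean_deg: float  # nan when undefined
    resultant_length: float  # in [0, 1]
    mean_defined: bool


@dataclass(frozen=True)
class ClassThresholds:
    """Decision windows for the mobility classes.

    Defaults encode the observed angular windows: intact fish hold the
    source axis within ~10 deg with tight dispersion (the 80-100 deg band),
    disrupted fish sit on the sink axis within ~20 deg (covering -20..20 and
    180..220), recovering fish scatter within ~40 deg of the source axis
    with at least moderate concentration.
    """

    intact_source_dev_deg: float = 10.0
    intact_min_resultant: float = 0.9
    disrupted_sink_dev_deg: float = 20.0
    disrupted_min_resultant: float = 0.9
    recovering_source_dev_deg: float = 40.0
    recovering_min_resultant: float = 0.5


@dataclass
class MobilityReport:
    circ_mean_deg: float
    resultant_length: float
    source_deviation_deg: float
    sink_deviation_deg: float
    class_label: str = "indeterminate"
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MSDCurve:
    lags: np.ndarray  # s
    msd_values: np.ndarray  # m^2


def circular_summary(series: AngleSeries) -> CircularSummary:
    """Vector-mean direction and mean resultant length of a heading series.

    The circular mean is the angle of the average unit vector; the resultant
    length in [0, 1] measures angular concentration.  Antipodally balanced
    data give a near-zero resultant and an undefined mean (flagged).
    """
    if len(series.angles_deg) < 1:
        raise ValueError("need at least one sample")
    th = np.radians(series.angles_deg)
    z = np.mean(np.cos(th)) + 1j * np.mean(np.sin(th))
    r = float(abs(z))
    if r < 1e-9:
        return CircularSummary(float("nan"), 0.0, False)
    return CircularSummary(math.degrees(np.angle(z)) % 360.0, r, True)


def source_deviation(angle_deg) -> np.ndarray | float:
    """Angular distance (deg, in [0, 90]) to the source axis {90, 270}."""
    a = (np.asarray(angle_deg, dtype=float) - 90.0) % 180.0
    d = np.minimum(a, 180.0 - a)
    return float(d) if d.ndim == 0 else d


def sink_deviation(angle_deg) -> np.ndarray | float:
    """Angular distance (deg, in [0, 90]) to the sink axis {0, 180}."""
    a = np.asarray(angle_deg, dtype=float) % 180.0
    d = np.minimum(a, 180.0 - a)
    return float(d) if d.ndim == 0 else d


def folded_source_angle(angle_deg) -> np.ndarray | float:
    """Heading folded to [0, 90]: 0 = on the sink axis, 90 = on the source."""
    return 90.0 - source_deviation(angle_deg)


def chance_alignment_pvalue(n_fish: int, window_deg: float = 30.0) -> float:
    """Probability that ``n`` independent uniform headings share one window.

    The circle is partitioned into ``360/window`` equal bins; the chance
    that all ``n`` headings land in one particular bin is ``(w/360)^n`` and
    the union bound over the bins multiplies by their count:

        p = (w/360)^n * (360/w),   capped at 1.

    For ``(n, w) = (5, 30)`` this is ``12^-4 = 4.8225e-5``.
    """
    if n_fish < 1:
        raise ValueError("n_fish must be >= 1")
    k = 360.0 / window_deg
    if abs(k - round(k)) > 1e-9:
        raise ValueError("window_deg must divide 360 (partition-based bound)")
    return min((window_deg / 360.0) ** n_fish * k, 1.0)


def simulate_alignment_probability(
    n_fish: int,
    window_deg: float,
    n_cohorts: int,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the alignment probability and its binomial SE.

    Cohorts of ``n_fish`` i.i.d. uniform headings are drawn; a cohort counts
    as aligned when all its headings fall in the same bin of the fixed
    ``360/window``-bin partition.
    """
    rng = np.random.default_rng(seed)
    n_bins = int(round(360.0 / window_deg))
    bins = rng.integers(0, n_bins, size=(n_cohorts, n_fish))
    hits = np.all(bins == bins[:, :1], axis=1)
    p = float(np.mean(hits))
    se = math.sqrt(max(p * (1 - p), 1.0 / n_cohorts) / n_cohorts)
    return p, se


def smallest_enclosing_arc(angles_deg: np.ndarray) -> float:
    """Width (deg) of the smallest circular arc containing all angles."""
    a = np.sort(np.asarray(angles_deg, dtype=float) % 360.0)
    if len(a) < 2:
        return 0.0
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    return 360.0 - float(gaps.max())


def cohort_alignment_pvalue(
    mean_angles_deg: np.ndarray, window_deg: float = 30.0
) -> float | None:
    """Alignment p-value of a cohort, or None when not aligned.

    Reported when every per-fish circular mean fits inside one ``window_deg``
    arc (the observed "narrow region"); the value itself is the partition
    bound of :func:`chance_alignment_pvalue`.
    """
    if smallest_enclosing_arc(mean_angles_deg) <= window_deg:
        return chance_alignment_pvalue(len(mean_angles_deg), window_deg)
    return None


def msd(track: TrackedTrajectory, lags: np.ndarray | None = None) -> MSDCurve:
    """Time-averaged mean squared displacement of a centroid track.

    ``MSD(tau) = < |r(t + tau) - r(t)|^2 >_t`` over all overlapping pairs;
    the track must be uniformly sampled and every lag a multiple of the
    sampling interval.  Lags at or beyond the track duration are dropped.
    """
    t = track.times_s
    if len(t) < 2:
        raise ValueError("track too short for MSD")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("MSD requires a uniformly sampled track")
    dt = float(dt[0])
    n = len(t)
    if lags is None:
        lags = np.arange(1, n) * dt
    lags = np.asarray(lags, dtype=float)
    ks = np.rint(lags / dt).astype(int)
    if not np.allclose(ks * dt, lags, rtol=1e-6, atol=1e-12):
        raise ValueError("each lag must be a multiple of the sampling interval")
    keep = (ks >= 0) & (ks < n)
    ks = ks[keep]
    out = np.empty(len(ks))
    r = np.column_stack([track.x_m, track.y_m])
    for i, k in enumerate(ks):
        if k == 0:
            out[i] = 0.0
        else:
            d = r[k:] - r[:-k]
            out[i] = float(np.mean(np.sum(d * d, axis=1)))
    return MSDCurve(ks * dt, out)


def report(
    series: AngleSeries,
    thresholds: ClassThresholds | None = None,
    meta: dict | None = None,
) -> MobilityReport:
    """Full per-fish mobility report: circular summary, deviations, class."""
    cs = circular_summary(series)
    if not cs.mean_defined:
        rep = MobilityReport(float("nan"), cs.resultant_length, float("nan"),
                             float("nan"), "indeterminate", meta or {})
        return rep
    rep = MobilityReport(
        cs.circ_mean_deg,
        cs.resultant_length,
        source_deviation(cs.circ_mean_deg),
        sink_deviation(cs.circ_mean_deg),
        meta=meta or {},
    )
    rep.class_label = classify(rep, thresholds)
    return rep


def classify(
    rep: MobilityReport, thresholds: ClassThresholds | None = None
) -> str:
    """Assign a mobility class from a report (thresholds configurable)."""
    th = thresholds or ClassThresholds()
    if not np.isfinite(rep.circ_mean_deg):
        return "indeterminate"
    if (
        rep.source_deviation_deg <= th.intact_source_dev_deg
        and rep.resultant_length >= th.intact_min_resultant
    ):
        return "intact"
    if (
        rep.sink_deviation_deg <= th.disrupted_sink_dev_deg
        and rep.resultant_length >= th.disrupted_min_resultant
    ):
        return "disrupted"
    if (
        rep.source_deviation_deg <= th.recovering_source_dev_deg
        and rep.resultant_length >= th.recovering_min_resultant
    ):
        return "recovering"
    return "indeterminate"


def bin_circular_means(
    series: AngleSeries, bin_duration_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-time-bin circular means of a heading series."""
    t0 = series.times[0]
    idx = np.floor((series.times - t0) / bin_duration_s).astype(int)
    centers, means = [], []
    for b in np.unique(idx):
        sel = idx == b
        cs = circular_summary(AngleSeries(series.times[sel], series.angles_deg[sel]))
        centers.append(t0 + (b + 0.5) * bin_duration_s)
        means.append(cs.circ_mean_deg)
    return np.array(centers), np.array(means)


@dataclass(frozen=True)
class RecoveryTrend:
    initial_deg: float  # folded source angle of the first bin
    final_deg: float  # folded source angle of the last bin
    time_to_half_s: float  # first crossing of 45 deg; nan if never
    monotone: bool


def recovery_trend(
    bin_times: np.ndarray, bin_mean_deg: np.ndarray
) -> RecoveryTrend:
    """Recovery summary from binned circular means.

    Angles are folded to the source-alignment scale (0 = sink axis, 90 =
    source axis); the trend reports the first and last bin values and the
    linearly interpolated first crossing of the 45-degree midpoint.  A
    non-monotone folded series sets ``monotone=False`` and still reports the
    first crossing.
    """
    if len(bin_times) < 3:
        raise ValueError("need at least 3 time bins")
    folded = 90.0 - np.asarray(source_deviation(np.asarray(bin_mean_deg)))
    mono = bool(np.all(np.diff(folded) >= -1e-9))
    t_half = float("nan")
    for i in range(len(folded) - 1):
        lo, hi = folded[i], folded[i + 1]
        if (lo - 45.0) * (hi - 45.0) <= 0 and lo != hi:
            t_half = float(
                bin_times[i]
                + (45.0 - lo) / (hi - lo) * (bin_times[i + 1] - bin_times[i])
            )
            break
        if lo == 45.0:
            t_half = float(bin_times[i])
            break
    return RecoveryTrend(float(folded[0]), float(folded[-1]), t_half, mono)
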