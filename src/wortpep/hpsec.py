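"""Size-exclusion chromatography: calibration, class integration, pooling.

In SEC larger molecules elute earlier, and over a column's working range
log10(molecular mass) is approximately linear in retention time.  The
module fits that calibration from a standards table, converts between
retention time and mass, splits a detector trace into molecular-weight
class areas (default boundaries 3, 10 and 50 kDa, i.e. classes <3, 3–10,
10–50 and >50 kDa), and pools the trace into fixed-width elution-time
fractions as an automated fraction collector would.

Class boundaries own their upper edge on the mass axis as half-open
intervals [low, high), so a molecule of exactly 10 kDa belongs to the
10–50 kDa class; for the continuous area integrals the choice only
matters at isolated points.  Areas are trapezoidal, with the trace
linearly interpolated at window edges so that pooling conserves total
area exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BOUNDARIES_KDA = (3.0, 10.0, 50.0)


class CalibrationError(ValueError):
    pass


class IntegrationError(ValueError):
    pass


@dataclass(frozen=True)
class Chromatogram:
    """A detector trace: strictly increasing times (min) and signal."""

    detector: str  # "UV280" or "RI"
    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and signal must be equal-length 1-D arrays")
        if t.size < 2:
            raise ValueError("a chromatogram needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Chromatogram":
        """Two-column tab-separated trace with a ``# detector:`` header line."""
        detector = "UV280"
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            detector = first.lstrip("#").split(":")[-1].strip() or detector
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["time_min", "signal"], header=None)
        return cls(detector, df["time_min"].to_numpy(),
                   df["signal"].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# detector: {self.detector}\n")
            for t, s in zip(self.times, self.signal):
                fh.write(f"{t:.6g}\t{s:.8g}\n")


@dataclass(frozen=True)
class CalibrationStandard:
    name: str
    mass_kda: float
    retention_time_min: float

    def __post_init__(self) -> None:
        if self.mass_kda <= 0:
            raise ValueError(f"{self.name}: mass must be positive")
        if not (0 <= self.retention_time_min <= 45):
            raise ValueError(f"{self.name}: retention time outside the "
                             f"0-45 min run")


def read_standards(path: str | Path) -> list[CalibrationStandard]:
    """Standards table: columns ``name``, ``mass_kda``, ``retention_time_min``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [CalibrationStandard(r["name"], float(r["mass_kda"]),
                                float(r["retention_time_min"]))
            for _, r in df.iterrows()]


@dataclass(frozen=True)
class CalibrationCurve:
    """log10(mass/kDa) = slope · RT + intercept, over [rt_min, rt_max]."""

    slope: float
    intercept: float
    r_squared: float
    rt_min: float
    rt_max: float
    suspect: bool = False  # positive slope: larger molecules eluting later

    def in_range(self, retention_time_min: float | np.ndarray) -> np.ndarray:
        rt = np.asarray(retention_time_min, dtype=float)
        return (rt >= self.rt_min) & (rt <= self.rt_max)


def fit_calibration(standards: Sequence[CalibrationStandard]) -> CalibrationCurve:
    """Ordinary least squares of log10(mass) on retention time."""
    if len(standards) < 2:
        raise CalibrationError("need at least 2 calibration standards")
    rt = np.array([s.retention_time_min for s in standards], dtype=float)
    if len(np.unique(rt)) != len(rt):
        raise CalibrationError("duplicate retention times among standards")
    logm = np.log10([s.mass_kda for s in standards])
    fit = stats.linregress(rt, logm)
    r2 = 1.0 if len(standards) == 2 else float(fit.rvalue) ** 2
    suspect = fit.slope >= 0
    if suspect:
        warnings.warn("calibration slope is non-negative: in SEC larger "
                      "molecules should elute earlier; check the standards",
                      stacklevel=2)
    return CalibrationCurve(float(fit.slope), float(fit.intercept), r2,
                            float(rt.min()), float(rt.max()), suspect)


def rt_to_mw(curve: CalibrationCurve, retention_time_min, *,
             with_flag: bool = False):
    """Mass (kDa) at a retention time; optionally flag extrapolation."""
    rt = np.asarray(retention_time_min, dtype=float)
    if not np.all(np.isfinite(rt)):
        raise ValueError("retention time must be finite")
    mw = 10.0 ** (curve.slope * rt + curve.intercept)
    mw = mw.item() if np.isscalar(retention_time_min) else mw
    if with_flag:
        extrapolated = bool(np.any(~curve.in_range(rt)))
        return mw, extrapolated
    return mw


def mw_to_rt(curve: CalibrationCurve, mass_kda, *, with_flag: bool = False):
    """Retention time at a mass (kDa); exact inverse of :func:`rt_to_mw`."""
    m = np.asarray(mass_kda, dtype=float)
    if not np.all(np.isfinite(m)) or np.any(m <= 0):
        raise ValueError("mass must be finite and positive")
    rt = (np.log10(m) - curve.intercept) / curve.slope
    rt = rt.item() if np.isscalar(mass_kda) else rt
    if with_flag:
        extrapolated = bool(np.any(~curve.in_range(np.asarray(rt))))
        return rt, extrapolated
    return rt


@dataclass(frozen=True)
class MWClassProfile:
    """Area percentage per molecular-weight class.

    ``boundaries_kda`` has b entries; ``percentages`` has b+1, ordered
    from the lightest class upward: (<b0, b0–b1, ..., >b_last).
    """

    boundaries_kda: tuple[float, ...]
    percentages: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.percentages) != len(self.boundaries_kda) + 1:
            raise ValueError("need one more percentage than boundaries")
        if any(p < -1e-9 for p in self.percentages):
            raise ValueError("negative class percentage")
        if abs(sum(self.percentages) - 100.0) > 1e-9:
            raise ValueError("class percentages must sum to 100")

    @property
    def class_labels(self) -> tuple[str, ...]:
        b = self.boundaries_kda
        inner = [f"{lo:g}-{hi:g} kDa" for lo, hi in zip(b[:-1], b[1:])]
        return (f"<{b[0]:g} kDa", *inner, f">{b[-1]:g} kDa")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mw_class": self.class_labels,
                             "area_percent": self.percentages})


def _area_between(times: np.ndarray, signal: np.ndarray,
                  t_lo: float, t_hi: float) -> float:
    """Trapezoidal area of the trace restricted to [t_lo, t_hi], with the
    signal linearly interpolated at the window edges."""
    t_lo = max(t_lo, times[0])
    t_hi = min(t_hi, times[-1])
    if t_hi <= t_lo:
        return 0.0
    inside = (times > t_lo) & (times < t_hi)
    tt = np.concatenate(([t_lo], times[inside], [t_hi]))
    ss = np.interp(tt, times, signal)
    return float(np.trapezoid(ss, tt))


def _linear_baseline(chrom: Chromatogram,
                     window: tuple[float, float]) -> np.ndarray:
    """Signal with a straight line between the trace values at the two
    window endpoints subtracted."""
    t0, t1 = window
    y0, y1 = np.interp([t0, t1], chrom.times, chrom.signal)
    line = y0 + (chrom.times - t0) * (y1 - y0) / (t1 - t0)
    return chrom.signal - line


def integrate_classes(chrom: Chromatogram, curve: CalibrationCurve,
                      boundaries_kda: Sequence[float] = DEFAULT_BOUNDARIES_KDA,
                      *, clip_negative: bool = True,
                      baseline_window: tuple[float, float] | None = None,
                      ) -> MWClassProfile:
    """Split the trace area into molecular-weight class percentages.

    Boundaries (ascending kDa) are mapped to retention-time cut points via
    the calibration; with a negative slope the lightest class is the
    latest-eluting window.  Negative signal is clipped to zero before
    integration unless ``clip_negative=False``; an optional linear
    baseline between ``baseline_window`` endpoints is subtracted first.
    """
    b = tuple(float(x) for x in boundaries_kda)
    if not b or any(x2 <= x1 for x1, x2 in zip(b, b[1:])):
        raise ValueError("boundaries must be strictly ascending and non-empty")
    signal = (_linear_baseline(chrom, baseline_window)
              if baseline_window else chrom.signal)
    if clip_negative:
        signal = np.clip(signal, 0.0, None)
    times = chrom.times
    if times[-1] < curve.rt_min or times[0] > curve.rt_max:
        raise IntegrationError("chromatogram lies entirely outside the "
                               "calibration range")
    cuts = np.asarray(mw_to_rt(curve, np.array(b)))
    # Mass-axis windows lightest→heaviest; on the time axis that is
    # latest→earliest for a negative slope.
    edges_mass = [0.0, *b, np.inf]
    areas = []
    for lo_m, hi_m in zip(edges_mass[:-1], edges_mass[1:]):
        t_hi = times[-1] if lo_m == 0.0 else float(mw_to_rt(curve, lo_m))
        t_lo = times[0] if np.isinf(hi_m) else float(mw_to_rt(curve, hi_m))
        if curve.slope > 0:  # suspect fit; windows flip
            t_lo, t_hi = t_hi, t_lo
        # A window integral can only go negative in unclipped mode, from
        # noise alone; class shares are floored at zero.
        areas.append(max(_area_between(times, signal, t_lo, t_hi), 0.0))
    total = float(sum(areas))
    if total <= 0:
        raise IntegrationError("no integrable area in the chromatogram")
    pct = tuple(100.0 * a / total for a in areas)
    # Absorb float round-off so the invariant 'sums to 100' holds exactly.
    corr = 100.0 - sum(pct)
    imax = max(range(len(pct)), key=lambda i: pct[i])
    pct = tuple(p + corr if i == imax else p for i, p in enumerate(pct))
    return MWClassProfile(b, pct)


def plot_profile(chrom: Chromatogram, curve: CalibrationCurve,
                 boundaries_kda: Sequence[float] = DEFAULT_BOUNDARIES_KDA,
                 path: str | Path | None = None):
    """Diagnostic figure: the trace with class cut points marked.

    Requires matplotlib (optional dependency).  Returns the figure;
    saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(chrom.times, chrom.signal, lw=0.8, color="black")
    for b in boundaries_kda:
        rt = float(mw_to_rt(curve, b))
        if chrom.times[0] <= rt <= chrom.times[-1]:
            ax.axvline(rt, ls="--", lw=0.8, color="tab:red")
            ax.annotate(f"{b:g} kDa", (rt, ax.get_ylim()[1]),
                        ha="center", va="bottom", fontsize=8)
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel(f"{chrom.detector} signal (a.u.)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def pool_fractions(chrom: Chromatogram, width_min: float = 1.0) -> pd.DataFrame:
    """Pool the trace into consecutive fixed-width elution-time fractions.

    Windows tile the run from time zero, so with the default 1-minute
    width the fraction index equals the elution minute.  Returns a table
    (fraction_index, rt_start_min, rt_end_min, area); window areas sum to
    the total trace area exactly.
    """
    if width_min <= 0:
        raise ValueError("fraction width must be positive")
    t_end = chrom.times[-1]
    n = int(np.ceil(round(t_end / width_min, 9)))
    rows = []
    for k in range(1, n + 1):
        lo, hi = (k - 1) * width_min, k * width_min
        rows.append((k, lo, hi,
                     _area_between(chrom.times, chrom.signal, lo, hi)))
    return pd.DataFrame(rows, columns=["fraction_index", "rt_start_min",
                                       "rt_end_min", "area"])
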