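"""Fluorogenic protease-activity kinetics analysis.

Plate-reader time series of product accumulation (AMC release from an
elastase substrate such as Suc-Ala-Ala-Ala-AMC) are blank-subtracted,
technical replicates averaged, and the inhibitor-sensitive fraction of the
activity — the pointwise difference between the uninhibited and inhibited
curves — extracted.  Linear-phase activity rates and percent inhibition
summarise each condition.

Signals are treated as generic arbitrary-unit (AU) intensities; the
readout modality (absorbance or fluorescence) is carried as metadata only,
since the arithmetic is identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats


class AlignmentError(ValueError):
    """Two series that must share a time grid do not."""


class GroupingError(ValueError):
    """Series from different conditions were mixed in one average."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticSeries:
    """One well's raw or blank-subtracted time series."""

    time_min: np.ndarray
    signal: np.ndarray
    condition: str = "sample"
    inhibitor: str = "none"
    replicate: int | str = 1
    signal_unit: str = "AU"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, float)
        s = np.asarray(self.signal, float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("time_min and signal must be equal-length 1-D")
        if t.size > 1 and not (np.diff(t) > 0).all():
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class ActivityCurve:
    """Blank-subtracted, replicate-averaged product accumulation."""

    time_min: np.ndarray
    product: np.ndarray
    sem: np.ndarray
    n_replicates: int
    condition: str = "sample"
    inhibitor: str = "none"

    def __post_init__(self) -> None:
        if not (len(self.time_min) == len(self.product) == len(self.sem)):
            raise ValueError("curve arrays must share one grid")


@dataclass(frozen=True)
class InhibitorSensitiveFraction:
    """Activity attributable to the inhibitor-sensitive enzyme."""

    inhibitor: str
    time_min: np.ndarray
    sensitive_product: np.ndarray


@dataclass(frozen=True)
class RateEstimate:
    """OLS slope of product vs time."""

    slope: float            # AU/min
    stderr: float
    intercept: float
    window_min: tuple[float, float]


@dataclass(frozen=True)
class PercentInhibition:
    value_pct: float | None
    se_pct: float | None
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _check_grids(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or not np.array_equal(a, b):
        raise AlignmentError("time grids differ")


def blank_subtract(sample: KineticSeries, blank: KineticSeries) -> KineticSeries:
    """Pointwise ``sample − blank``.

    Negative values are retained (not clipped) to keep the differencing
    unbiased; their presence is flagged.
    """
    _check_grids(sample.time_min, blank.time_min)
    diff = sample.signal - blank.signal
    flags = sample.flags
    if (diff < 0).any():
        flags = flags + ("negative_values",)
    return replace(sample, signal=diff, flags=flags)


def average_replicates(series: list[KineticSeries]) -> ActivityCurve:
    """Pointwise mean and SEM across technical replicates of one condition."""
    if not series:
        raise GroupingError("no series to average")
    key = (series[0].condition, series[0].inhibitor)
    for s in series[1:]:
        if (s.condition, s.inhibitor) != key:
            raise GroupingError(
                f"mixed conditions in one average: {key} vs "
                f"{(s.condition, s.inhibitor)}")
        _check_grids(series[0].time_min, s.time_min)
    sig = np.vstack([s.signal for s in series])
    n = sig.shape[0]
    sem = sig.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(sig.shape[1])
    return ActivityCurve(
        time_min=series[0].time_min.copy(),
        product=sig.mean(axis=0),
        sem=sem,
        n_replicates=n,
        condition=key[0],
        inhibitor=key[1],
    )


def sensitive_fraction(
    uninhibited: ActivityCurve,
    inhibited: ActivityCurve,
    inhibitor: str | None = None,
) -> InhibitorSensitiveFraction:
    """Inhibitor-sensitive activity: ``uninhibited(t) − inhibited(t)``.

    Exactly additive by construction: inhibited + sensitive reconstructs
    the uninhibited curve at machine precision.
    """
    _check_grids(uninhibited.time_min, inhibited.time_min)
    return InhibitorSensitiveFraction(
        inhibitor=inhibitor or inhibited.inhibitor,
        time_min=uninhibited.time_min.copy(),
        sensitive_product=uninhibited.product - inhibited.product,
    )


def activity_rate(
    curve: ActivityCurve,
    window_min: tuple[float, float] | None = None,
) -> RateEstimate:
    """Least-squares slope of product vs time over a window (default: all)."""
    t, y = curve.time_min, curve.product
    if window_min is not None:
        sel = (t >= window_min[0]) & (t <= window_min[1])
        t, y = t[sel], y[sel]
    if t.size < 2:
        raise ValueError("need at least two timepoints for a rate")
    fit = stats.linregress(t, y)
    stderr = 0.0 if np.isnan(fit.stderr) else float(fit.stderr)
    return RateEstimate(slope=float(fit.slope), stderr=stderr,
                        intercept=float(fit.intercept),
                        window_min=(float(t[0]), float(t[-1])))


def percent_inhibition(
    uninhibited: ActivityCurve,
    inhibited: ActivityCurve,
    window_min: tuple[float, float] | None = None,
) -> PercentInhibition:
    """``100·(1 − slope_inhibited / slope_uninhibited)`` with propagated SE.

    Undefined (flagged) when the uninhibited slope is zero or negative.
    """
    ru = activity_rate(uninhibited, window_min)
    ri = activity_rate(inhibited, window_min)
    if ru.slope <= 0:
        return PercentInhibition(None, None, ("nonpositive_uninhibited_slope",))
    ratio = ri.slope / ru.slope
    if ri.slope != 0:
        se = abs(ratio) * np.hypot(ri.stderr / ri.slope, ru.stderr / ru.slope)
    else:
        se = ri.stderr / ru.slope
    return PercentInhibition(100.0 * (1.0 - ratio), 100.0 * float(se))


# ---------------------------------------------------------------------------
# Tidy-table driver
# ---------------------------------------------------------------------------

PLATE_COLUMNS = ("well", "condition", "inhibitor", "replicate", "time_min", "signal")


def series_from_table(plate: pd.DataFrame) -> list[KineticSeries]:
    """One :class:`KineticSeries` per well from a tidy plate table."""
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise ValueError(f"plate table lacks columns: {sorted(missing)}")
    out = []
    for well, grp in plate.groupby("well", sort=True):
        grp = grp.sort_values("time_min")
        out.append(KineticSeries(
            time_min=grp["time_min"].to_numpy(float),
            signal=grp["signal"].to_numpy(float),
            condition=str(grp["condition"].iloc[0]),
            inhibitor=str(grp["inhibitor"].iloc[0]),
            replicate=grp["replicate"].iloc[0],
        ))
    return out


def analyze_plate(plate: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Full kinetics analysis of a tidy plate table.

    Blank wells (``condition == "blank"``) are averaged into one blank
    curve which is subtracted from every sample well; replicates are then
    averaged per (condition, inhibitor); sensitive fractions are taken
    against the matching uninhibited (``inhibitor == "none"``) curve; and
    rates / percent inhibition summarise each condition.

    Returns ``{"curves": ..., "sensitive": ..., "rates": ...}``.
    """
    series = series_from_table(plate)
    blanks = [s for s in series if s.condition == "blank"]
    samples = [s for s in series if s.condition != "blank"]
    if not samples:
        raise ValueError("plate contains no sample wells")

    if blanks:
        blank_curve = average_replicates(blanks)
        blank_series = KineticSeries(blank_curve.time_min, blank_curve.product)
        samples = [
            blank_subtract(s, replace(blank_series, condition=s.condition,
                                      inhibitor=s.inhibitor))
            for s in samples
        ]

    curves: dict[tuple[str, str], ActivityCurve] = {}
    for key in sorted({(s.condition, s.inhibitor) for s in samples}):
        curves[key] = average_replicates(
            [s for s in samples if (s.condition, s.inhibitor) == key])

    curve_rows, sens_rows, rate_rows = [], [], []
    for (cond, inh), c in curves.items():
        for t, p, e in zip(c.time_min, c.product, c.sem):
            curve_rows.append({"condition": cond, "inhibitor": inh,
                               "time_min": t, "product": p, "sem": e,
                               "n_replicates": c.n_replicates})
        rate = activity_rate(c)
        row = {"condition": cond, "inhibitor": inh, "rate_au_per_min": rate.slope,
               "rate_stderr": rate.stderr, "percent_inhibition": np.nan,
               "percent_inhibition_se": np.nan, "flags": ""}
        if inh != "none" and (cond, "none") in curves:
            uninh = curves[(cond, "none")]
            frac = sensitive_fraction(uninh, c)
            for t, v in zip(frac.time_min, frac.sensitive_product):
                sens_rows.append({"condition": cond, "inhibitor": inh,
                                  "time_min": t, "sensitive_product": v})
            pi = percent_inhibition(uninh, c)
            if pi.value_pct is not None:
                row["percent_inhibition"] = pi.value_pct
                row["percent_inhibition_se"] = pi.se_pct
            row["flags"] = ";".join(pi.flags)
        rate_rows.append(row)

    return {
        "curves": pd.DataFrame(curve_rows),
        "sensitive": pd.DataFrame(
            sens_rows, columns=["condition", "inhibitor", "time_min",
                                "sensitive_product"]),
        "rates": pd.DataFrame(rate_rows),
    }
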