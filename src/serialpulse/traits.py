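"""Fitness-trait extraction from clone-level OD time series.

Four traits per clone, all computed from blank-corrected optical density:

* **maximum growth rate** (h^-1): slope of the steepest ordinary
  least-squares regression over any contiguous window of 30 measurement
  points (2.5 h at 5-min sampling, by the 30 x 5 min convention), fitted
  by default to ln(OD) so the trait is a per-capita rate;
* **yield**: the maximum biomass reached during the assay;
* **mortality**: total = yield - end biomass; proportional = total/yield;
* **biofilm**: a scalar summary of the crystal-violet dissolution read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ODCurve",
    "GrowthRateFit",
    "YieldResult",
    "MortalityResult",
    "CloneTraits",
    "window_duration_h",
    "max_growth_rate",
    "yield_max",
    "mortality",
    "biofilm_amount",
    "extract_traits",
    "extract_all",
]

#: Blank-corrected OD below this value is indistinguishable from background.
DETECTION_FLOOR = 1e-4


@dataclass
class ODCurve:
    """One well's OD time series on a uniform sampling grid.

    times are hours from inoculation; ``blank_od`` is subtracted before any
    trait computation.
    """

    times: np.ndarray
    od: np.ndarray
    blank_od: float = 0.0
    sample_interval_min: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.od.shape:
            raise ValidationError("times and od must be matching 1-d arrays")
        if self.times.size < 2:
            raise ValidationError("need at least 2 samples")
        if not np.all(np.isfinite(self.od)) or not np.all(np.isfinite(self.times)):
            raise ValidationError("times and od must be finite")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(np.abs(steps - steps[0]) > 1e-9):
            bad = self.times[1:][np.abs(steps - steps[0]) > 1e-9]
            raise ValidationError(f"non-uniform time grid at t={bad[:5]} h")
        if self.sample_interval_min is None:
            self.sample_interval_min = float(steps[0] * 60.0)

    @property
    def corrected(self) -> np.ndarray:
        return self.od - self.blank_od


def window_duration_h(window_points: int, sample_interval_min: float) -> float:
    """Reported duration of a regression window: points x sampling step.

    30 points at 5-min sampling are reported as a 2.5 h window.
    """
    return window_points * sample_interval_min / 60.0


@dataclass
class GrowthRateFit:
    rate: float            # h^-1 (log mode) or OD h^-1 (linear mode)
    window_start_h: float
    degenerate: bool = False   # all windows at the detection floor


def max_growth_rate(
    curve: ODCurve,
    window_points: int = 30,
    log_mode: bool = True,
    weighted: bool = True,
    detection_floor: float = DETECTION_FLOOR,
) -> GrowthRateFit:
    """Steepest regression slope over all contiguous windows of
    ``window_points`` measurement points.

    Blank-corrected OD is floored at ``detection_floor`` before taking the
    log; windows entirely at the floor are skipped.  Ties are broken by the
    earliest window.  A curve constant at the floor yields rate 0 with the
    ``degenerate`` flag set.

    In log mode the per-window fit is variance-weighted by default:
    measurement noise scales with the total OD, so by the delta method the
    standard deviation of ln(OD - blank) scales as OD/(OD - blank), and
    each point gets weight ((OD - blank)/OD)^2.  This prevents the near-
    blank portion of the curve, where log-noise is amplified, from
    producing spuriously steep windows.  With a zero blank the weights are
    uniform and the fit is plain OLS; ``weighted=False`` forces OLS.
    On noiseless log-linear data both fits give the exact slope.
    """
    if window_points < 2:
        raise ValidationError(f"window_points must be >= 2, got {window_points}")
    n = curve.times.size
    if n < window_points + 1:
        raise ValidationError(
            f"curve has {n} samples; need > {window_points} for a window scan"
        )
    corrected = curve.corrected
    floored = np.maximum(corrected, detection_floor)
    y = np.log(floored) if log_mode else corrected

    sw = np.lib.stride_tricks.sliding_window_view
    if log_mode and weighted:
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.square(floored / np.maximum(curve.od, floored))
        w = np.clip(np.nan_to_num(w, nan=0.0, posinf=0.0), 1e-12, None)
        Ww, Yw, Tw = sw(w, window_points), sw(y, window_points), sw(curve.times, window_points)
        wsum = Ww.sum(axis=1)
        tbar = (Ww * Tw).sum(axis=1) / wsum
        ybar = (Ww * Yw).sum(axis=1) / wsum
        tdev = Tw - tbar[:, None]
        stt = (Ww * tdev**2).sum(axis=1)
        sty = (Ww * tdev * (Yw - ybar[:, None])).sum(axis=1)
        slopes = sty / stt
    else:
        t_win = curve.times[:window_points]
        tc = t_win - t_win.mean()
        stt = float(np.dot(tc, tc))
        slopes = sw(y, window_points) @ tc / stt

    at_floor = corrected <= detection_floor
    dead_windows = sw(at_floor, window_points).all(axis=1)
    if dead_windows.all():
        return GrowthRateFit(rate=0.0, window_start_h=float("nan"), degenerate=True)
    slopes = np.where(dead_windows, -np.inf, slopes)
    top = float(slopes.max())
    # earliest window within fp jitter of the maximum wins (deterministic)
    tol = 1e-9 * max(1.0, abs(top))
    best = int(np.argmax(slopes >= top - tol))
    return GrowthRateFit(rate=float(slopes[best]), window_start_h=float(curve.times[best]))


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    """Centered running median with edge-value padding (odd width)."""
    if width <= 1:
        return values
    if width % 2 == 0:
        raise ValidationError(f"smoothing width must be odd, got {width}")
    half = width // 2
    padded = np.pad(values, half, mode="edge")
    return np.median(
        np.lib.stride_tricks.sliding_window_view(padded, width), axis=1
    )


@dataclass
class YieldResult:
    yield_od: float
    peak_time_h: float


def yield_max(curve: ODCurve, smooth_width: int = 5) -> YieldResult:
    """Maximum blank-corrected OD after a running-median despike filter.

    ``smooth_width = 1`` disables smoothing (raw maximum).
    """
    smoothed = _smooth(curve.corrected, smooth_width)
    idx = int(np.argmax(smoothed))
    return YieldResult(yield_od=float(smoothed[idx]), peak_time_h=float(curve.times[idx]))


@dataclass
class MortalityResult:
    total_mortality: float
    proportional_mortality: float
    undefined: bool = False   # peak at or below the detection floor


def mortality(
    curve: ODCurve,
    smooth_width: int = 5,
    end_samples: int = 12,
    detection_floor: float = DETECTION_FLOOR,
) -> MortalityResult:
    """Biomass decline after the peak: (max - end, (max - end)/max).

    End biomass is the mean of the final ``end_samples`` smoothed readings
    (the last hour at 5-min sampling) for robustness to endpoint noise; the
    same smoothed series supplies the maximum, so total mortality is never
    negative.  A curve that never rises above the detection floor has no
    defined mortality.
    """
    if end_samples < 1:
        raise ValidationError(f"end_samples must be >= 1, got {end_samples}")
    smoothed = _smooth(curve.corrected, smooth_width)
    peak = float(smoothed.max())
    if peak <= detection_floor:
        return MortalityResult(float("nan"), float("nan"), undefined=True)
    end = float(smoothed[-end_samples:].mean())
    total = peak - end
    return MortalityResult(total_mortality=total, proportional_mortality=total / peak)


def biofilm_amount(
    absorbance: np.ndarray,
    blank: np.ndarray | None = None,
    summary: str = "mean",
) -> float:
    """Scalar summary of the crystal-violet dissolution read.

    Time-averaged mean absorbance by default (``summary="max"`` for the
    maximum).  A matching blank series is subtracted point-wise when
    provided; an empty blank triggers a warning and no subtraction.
    """
    values = np.asarray(absorbance, dtype=float)
    if values.size == 0:
        raise ValidationError("absorbance series is empty")
    if blank is not None:
        blank = np.asarray(blank, dtype=float)
        if blank.size == 0:
            warnings.warn("empty blank series; no blank subtraction applied")
        elif blank.size not in (1, values.size):
            raise ValidationError(
                f"blank length {blank.size} does not match series length {values.size}"
            )
        else:
            values = values - blank
    if summary == "mean":
        return float(values.mean())
    if summary == "max":
        return float(values.max())
    raise ValidationError(f"unknown summary {summary!r}")


@dataclass
class CloneTraits:
    """The four extracted fitness traits (+ bookkeeping) of one clone."""

    max_growth_rate: float
    growth_window_start: float
    yield_od: float
    total_mortality: float
    proportional_mortality: float
    biofilm: float
    degenerate_growth: bool = False
    mortality_undefined: bool = False


def extract_traits(
    curve: ODCurve,
    biofilm_signal: float = float("nan"),
    window_points: int = 30,
    log_mode: bool = True,
    smooth_width: int = 5,
    end_samples: int = 12,
) -> CloneTraits:
    """All OD-derived traits of one clone, plus its biofilm endpoint."""
    growth = max_growth_rate(curve, window_points=window_points, log_mode=log_mode)
    yld = yield_max(curve, smooth_width=smooth_width)
    mort = mortality(curve, smooth_width=smooth_width, end_samples=end_samples)
    return CloneTraits(
        max_growth_rate=growth.rate,
        growth_window_start=growth.window_start_h,
        yield_od=yld.yield_od,
        total_mortality=mort.total_mortality,
        proportional_mortality=mort.proportional_mortality,
        biofilm=biofilm_signal,
        degenerate_growth=growth.degenerate,
        mortality_undefined=mort.undefined,
    )


_TRAIT_COLS = [
    "max_growth_rate",
    "growth_window_start",
    "yield_od",
    "total_mortality",
    "proportional_mortality",
    "biofilm",
]


def extract_all(dataset, **extract_kwargs) -> pd.DataFrame:
    """One traits row per clone, with treatment metadata carried through.

    ``dataset`` is an :class:`~serialpulse.growth_curves.ExperimentDataset`
    or any iterable of objects with ``meta()``, ``curve`` and ``biofilm``
    attributes.  Per-clone failures are recorded in an ``error`` column
    rather than aborting the run.
    """
    records = getattr(dataset, "records", dataset)
    rows = []
    for rec in records:
        row = dict(rec.meta())
        try:
            traits = extract_traits(rec.curve, rec.biofilm, **extract_kwargs)
            for col in _TRAIT_COLS:
                row[col] = getattr(traits, col)
            row["degenerate_growth"] = traits.degenerate_growth
            row["mortality_undefined"] = traits.mortality_undefined
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - per-clone isolation is the contract
            for col in _TRAIT_COLS:
                row[col] = float("nan")
            row["degenerate_growth"] = True
            row["mortality_undefined"] = True
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
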