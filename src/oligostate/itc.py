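"""ITC thermogram peak integration and temperature-trend analysis.

Dilution/dissociation ITC experiments inject small aliquots of concentrated
protein into buffer; each injection produces a transient power peak whose
time integral is the injection heat. For a self-associating protein the total
dissociation heat grows as the temperature drops (complexes are more stable
cold), and this qualitative trend is the analysis endpoint here — no binding
model is fitted, because overlapping oligomer equilibria make the isotherm
uninterpretable in terms of a single dissociation constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

__all__ = [
    "Thermogram",
    "InjectionHeat",
    "TrendSummary",
    "integrate_injections",
    "temperature_trend",
]


@dataclass
class Thermogram:
    """Differential power trace (uW = uJ/s) with its injection schedule."""

    time: np.ndarray  # s, strictly increasing
    power: np.ndarray  # uW
    injection_times: np.ndarray  # s
    temperature_c: float = 25.0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        self.injection_times = np.atleast_1d(
            np.asarray(self.injection_times, dtype=float))
        if self.time.shape != self.power.shape or self.time.ndim != 1:
            raise ValueError("time and power must be 1-D arrays of equal length")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if len(self.injection_times):
            if (self.injection_times.min() < self.time[0]
                    or self.injection_times.max() > self.time[-1]):
                raise ValueError(
                    "injection times must lie within the time support")
            if not np.all(np.diff(self.injection_times) > 0):
                raise ValueError("injection times must be increasing")


@dataclass
class InjectionHeat:
    index: int
    heat: float  # uJ, signed
    baseline_window: tuple[float, float]
    integration_window: tuple[float, float]


@dataclass
class TrendSummary:
    totals: dict  # temperature (C) -> total |heat| (uJ)
    ordering: list  # temperatures sorted ascending
    monotone_decreasing: bool  # |Q| strictly decreasing with temperature
    ties: list


def integrate_injections(tg: Thermogram, window: float = 290.0,
                         baseline_frac: float = 0.2) -> list[InjectionHeat]:
    """Integrate per-injection heats with local linear baseline removal.

    For every injection, a straight line is fitted to the trailing
    ``baseline_frac`` of the two inter-injection segments bracketing the
    peak — the end of the preceding segment and the end of the injection's
    own segment, where the response tail has decayed — then subtracted, and
    the residual power integrated by the trapezoidal rule over
    [t_inj, t_inj + window]. Anchoring the line on both sides keeps the
    integral insensitive to detector noise in the fitted slope, which a
    one-sided extrapolation would amplify across the window. The window must
    not reach the next injection.
    """
    t, p = tg.time, tg.power
    if np.any(~np.isfinite(p)):
        raise ValueError("power trace contains NaN/inf")
    inj = tg.injection_times
    if len(inj) == 0:
        raise ValueError("thermogram has no injections to integrate")
    if len(inj) > 1 and window > np.min(np.diff(inj)):
        raise ValueError("integration window overlaps the next injection")
    heats = []
    for k, t_inj in enumerate(inj):
        seg_start = tg.time[0] if k == 0 else inj[k - 1]
        base_lo = t_inj - baseline_frac * (t_inj - seg_start)
        seg_end = inj[k + 1] if k + 1 < len(inj) else t[-1]
        post_lo = seg_end - baseline_frac * (seg_end - t_inj)
        # strict upper bounds: the sample at seg_end belongs to the next peak
        bsel = ((t >= base_lo) & (t < t_inj)) | ((t >= post_lo) & (t < seg_end))
        if np.count_nonzero(bsel) < 2:
            raise ValueError(f"injection {k}: not enough baseline samples")
        coef = np.polyfit(t[bsel], p[bsel], 1)
        t_end = min(t_inj + window, t[-1])
        isel = (t >= t_inj) & (t <= t_end)
        if np.count_nonzero(isel) < 2:
            raise ValueError(f"injection {k}: not enough samples to integrate")
        resid = p[isel] - np.polyval(coef, t[isel])
        heat = float(np.trapezoid(resid, t[isel]))
        heats.append(InjectionHeat(index=k, heat=heat,
                                   baseline_window=(float(base_lo),
                                                    float(seg_end)),
                                   integration_window=(float(t_inj),
                                                       float(t_end))))
    return heats


def temperature_trend(series: Mapping[float, Sequence[Union[InjectionHeat, float]]],
                      ) -> TrendSummary:
    """Check whether the total dissociation heat decreases with temperature.

    ``series`` maps temperature (C) to that run's injection heats. The
    per-temperature statistic is |sum of signed heats|; the verdict is strict
    monotone decrease of |Q| as temperature rises. Equal totals are reported
    as ties (verdict not strict).
    """
    if len(series) < 2:
        raise ValueError("temperature trend requires >= 2 temperatures")
    totals = {}
    for temp, heats in series.items():
        vals = [h.heat if isinstance(h, InjectionHeat) else float(h)
                for h in heats]
        totals[float(temp)] = abs(sum(vals))
    ordering = sorted(totals)
    qs = [totals[tt] for tt in ordering]
    ties = [(ordering[i], ordering[i + 1]) for i in range(len(qs) - 1)
            if qs[i] == qs[i + 1]]
    monotone = all(qs[i] > qs[i + 1] for i in range(len(qs) - 1))
    return TrendSummary(totals=totals, ordering=ordering,
                        monotone_decreasing=monotone, ties=ties)
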