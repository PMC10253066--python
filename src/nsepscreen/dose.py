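"""Dose-response characterization and exposure bookkeeping.

Two small, physical pieces of the screen:

* a linear fit of mean ΔF against pulse number over the linear regime
  (0–``limit`` pulses), with 95% confidence and prediction bands, plus a
  flag for above-limit points falling outside the extrapolated prediction
  band ("diverged" — the heavy-dose regime where swelling and rupture
  scatter the readout);
* the adiabatic upper bound on Joule heating of the cuvette contents,
  ΔT = σE²τN/(ρc), which disregards all heat dissipation and is therefore
  a worst case. With typical growth-medium properties a 20-pulse train of
  300-ns, 7 kV/cm pulses stays below 1 °C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm


@dataclass(frozen=True)
class ExposureSpec:
    """One pulsed-field exposure: 300-ns pulses in a 1-mm gap cuvette."""

    pulse_width: float = 300e-9  # s
    voltage: float = 700.0  # V
    gap: float = 1e-3  # m
    n_pulses: int = 20
    repetition_rate: float = 20.0  # Hz

    def __post_init__(self):
        if min(self.pulse_width, self.voltage, self.gap, self.repetition_rate) <= 0:
            raise ValueError("exposure parameters must be positive")
        if self.n_pulses < 0:
            raise ValueError("n_pulses must be >= 0")

    @property
    def field(self) -> float:
        """Electric field E = voltage / gap, V/m."""
        return self.voltage / self.gap

    @property
    def train_duration(self) -> float:
        """Duration of the pulse train, s."""
        if self.n_pulses == 0:
            return 0.0
        return (self.n_pulses - 1) / self.repetition_rate

    @property
    def total_exposure_time(self) -> float:
        """Cumulative time under field, s (τ × N)."""
        return self.pulse_width * self.n_pulses


@dataclass(frozen=True)
class MediumProps:
    """Electrical and thermal properties of the exposure medium.

    Defaults are typical growth-medium / physiological-saline values:
    conductivity 1.4 S/m and volumetric heat capacity 4.18 MJ·m⁻³·K⁻¹
    (water-like).
    """

    conductivity: float = 1.4  # S/m
    volumetric_heat_capacity: float = 4.18e6  # J m^-3 K^-1

    def __post_init__(self):
        if self.conductivity <= 0 or self.volumetric_heat_capacity <= 0:
            raise ValueError("medium properties must be positive")


def adiabatic_heating(exposure: ExposureSpec, medium: MediumProps = MediumProps()) -> float:
    """Worst-case temperature rise ΔT = σ E² τ N / (ρc), in kelvin.

    Strictly linear in the pulse count N; heat dissipation during and
    between pulses is disregarded, so the real rise is smaller.
    """
    e = exposure.field
    return (
        medium.conductivity
        * e**2
        * exposure.pulse_width
        * exposure.n_pulses
        / medium.volumetric_heat_capacity
    )


@dataclass
class DoseResponseFit:
    """OLS fit of mean ΔF on pulse number over the linear regime."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    limit: float
    n_points: int
    #: above-limit points: (pulses, value, lower, upper, diverged)
    divergence: list[tuple[float, float, float, float, bool]] = field(
        default_factory=list
    )
    _result: object = field(default=None, repr=False)

    def predict(self, pulses) -> np.ndarray:
        x = np.atleast_1d(np.asarray(pulses, dtype=float))
        return self.intercept + self.slope * x

    def band(self, pulses, kind: str = "confidence", alpha: float = 0.05):
        """(lower, upper) 95% band of the fit line (``confidence``) or of a
        single new observation (``prediction``)."""
        x = np.atleast_1d(np.asarray(pulses, dtype=float))
        pred = self._result.get_prediction(sm.add_constant(x, has_constant="add"))
        if kind == "confidence":
            ci = pred.conf_int(alpha=alpha)
        elif kind == "prediction":
            ci = pred.conf_int(obs=True, alpha=alpha)
        else:
            raise ValueError("kind must be 'confidence' or 'prediction'")
        return ci[:, 0], ci[:, 1]


def fit_dose_response(
    points: Sequence[tuple[float, float]], limit: float = 50.0
) -> DoseResponseFit:
    """Fit the 0–``limit`` pulse range by OLS and flag diverged points.

    Points above ``limit`` are judged individually against the
    extrapolated 95% *prediction* band (a single measured point, not the
    line, is being tested). At least 3 in-range points are required.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (pulses, value) pairs")
    in_range = pts[pts[:, 0] <= limit]
    if in_range.shape[0] < 3:
        raise ValueError("need >= 3 points at or below the linear limit")
    x, y = in_range[:, 0], in_range[:, 1]
    res = sm.OLS(y, sm.add_constant(x)).fit()
    fit = DoseResponseFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        limit=float(limit),
        n_points=int(in_range.shape[0]),
        _result=res,
    )
    above = pts[pts[:, 0] > limit]
    if above.size:
        lower, upper = fit.band(above[:, 0], kind="prediction")
        for (px, py), lo, hi in zip(above, lower, upper):
            fit.divergence.append(
                (float(px), float(py), float(lo), float(hi), not lo <= py <= hi)
            )
    return fit
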