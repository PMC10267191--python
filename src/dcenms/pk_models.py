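"""Forward tissue-concentration models for nested DCE-MRI pharmacokinetics.

Three physiologically nested compartmental models describe the tissue
contrast-agent concentration surrogate ``C_t(t)`` (ΔR1, s⁻¹) driven by a
whole-blood arterial input ``C_AIF(t)``:

* Model 1 — intact vasculature, no leakage::

      C_t(t) = vp · C_AIF(t) / (1 − Hct)

* Model 2 — leakage without measurable back-flux (Patlak)::

      C_t(t) = [vp · C_AIF(t) + Ktrans · ∫₀ᵗ C_AIF(λ) dλ] / (1 − Hct)

* Model 3 — leakage with back-flux (extended Patlak / extended Tofts)::

      C_t(t) = [vp · C_AIF(t) + Ktrans · ∫₀ᵗ C_AIF(λ) e^{−kep (t−λ)} dλ] / (1 − Hct)

ΔR1 is used directly as the concentration proxy; the (unknown) relaxivity
constant multiplies both the tissue curve and the AIF and therefore cancels
in every fitted parameter.

Units: times are seconds internally; ``ktrans`` and ``kep`` are exposed in
min⁻¹ (field convention) and converted at the API boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "AIFTrace",
    "PKParams",
    "ConcentrationCurve",
    "exp_convolution",
    "ctissue",
    "DEFAULT_HCT",
]

#: Default hematocrit fraction (configurable everywhere it is consumed).
DEFAULT_HCT = 0.45

_SECONDS_PER_MINUTE = 60.0


def _validate_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("need a 1-D time axis with at least 2 points")
    if not np.all(np.isfinite(times)):
        raise ValueError("non-finite time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


@dataclass(frozen=True)
class AIFTrace:
    """Whole-blood contrast-concentration surrogate over the study time grid.

    Parameters
    ----------
    times : array
        Seconds from experiment start, strictly increasing.
    c_aif : array
        Whole-blood CA concentration surrogate (ΔR1 units, s⁻¹).
    hct : float
        Hematocrit fraction in [0, 0.9); converts whole blood to plasma via
        ``C_p = c_aif / (1 − hct)``.
    normalization : str
        Provenance of any reference-tissue scaling applied ("raw" if none).
    """

    times: np.ndarray
    c_aif: np.ndarray
    hct: float = DEFAULT_HCT
    normalization: str = "raw"

    def __post_init__(self) -> None:
        times = _validate_times(self.times)
        c = np.asarray(self.c_aif, dtype=float)
        if c.shape != times.shape:
            raise ValueError("c_aif and times must have the same length")
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite AIF values")
        if not (0.0 <= self.hct < 0.9):
            raise ValueError(f"hct {self.hct!r} outside [0, 0.9)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "c_aif", c)

    @property
    def cp(self) -> np.ndarray:
        """Plasma concentration ``C_AIF / (1 − Hct)``."""
        return self.c_aif / (1.0 - self.hct)

    def with_values(self, c_aif: np.ndarray, normalization: Optional[str] = None) -> "AIFTrace":
        return replace(
            self,
            c_aif=np.asarray(c_aif, dtype=float),
            normalization=self.normalization if normalization is None else normalization,
        )


@dataclass(frozen=True)
class PKParams:
    """Pharmacokinetic parameters of the nested models.

    ``ve`` is defined as ``ktrans / kep`` and only exists when ``kep > 0``.
    Fit outputs may fall outside the physical ranges; they are flagged by the
    fitting layer, never silently clipped here.
    """

    vp: float
    ktrans: Optional[float] = None
    kep: Optional[float] = None

    @property
    def ve(self) -> Optional[float]:
        if self.kep is None or self.ktrans is None or self.kep <= 0:
            return None
        return self.ktrans / self.kep

    def required_for(self, model: int) -> None:
        if model not in (1, 2, 3):
            raise ValueError(f"model must be 1, 2 or 3, got {model!r}")
        if model >= 2 and self.ktrans is None:
            raise ValueError(f"model {model} requires ktrans")
        if model == 3 and self.kep is None:
            raise ValueError("model 3 requires kep")


@dataclass(frozen=True)
class ConcentrationCurve:
    """A tissue concentration-surrogate time course (ΔR1, s⁻¹)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = _validate_times(self.times)
        v = np.asarray(self.values, dtype=float)
        if v.shape != times.shape:
            raise ValueError("values and times must have the same length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", v)


def _exp_conv_values(times: np.ndarray, values: np.ndarray, kep_per_s: float) -> np.ndarray:
    """y(t_i) = ∫₀^{t_i} e^{−kep (t_i − λ)} c(λ) dλ, c piecewise linear.

    Recursive exact-exponential scheme: over each interval the kernel is
    integrated in closed form against the linear interpolant, which is
    unconditionally stable and reduces to the cumulative trapezoid at kep = 0.
    """
    if kep_per_s < 0:
        raise ValueError("kep must be non-negative")
    t = np.asarray(times, float)
    c = np.asarray(values, float)
    dt = np.diff(t)
    if kep_per_s == 0.0:
        out = np.empty_like(c)
        out[0] = 0.0
        np.cumsum(0.5 * dt * (c[:-1] + c[1:]), out=out[1:])
        return out
    x = kep_per_s * dt
    decay = np.exp(-x)
    w0 = -np.expm1(-x) / kep_per_s  # (1 − e^{−k dt}) / k
    # (k dt − (1 − e^{−k dt})) / (k² dt); series for small k dt to avoid
    # catastrophic cancellation.
    small = x < 1e-4
    with np.errstate(invalid="ignore", divide="ignore"):
        w1 = np.where(small, dt * (0.5 - x / 6.0 + x * x / 24.0),
                      (x + np.expm1(-x)) / (kep_per_s * kep_per_s * dt))
    inc = c[:-1] * w0 + (c[1:] - c[:-1]) * w1
    out = np.empty_like(c)
    out[0] = 0.0
    if np.allclose(dt, dt[0], rtol=1e-10, atol=0.0):
        # uniform grid: y_i = E·y_{i-1} + inc_i is a first-order IIR filter
        out[1:] = lfilter([1.0], [1.0, -decay[0]], inc)
    else:
        acc = 0.0
        for i in range(dt.size):
            acc = acc * decay[i] + inc[i]
            out[i + 1] = acc
    return out


def exp_convolution(aif: AIFTrace, kep: float) -> ConcentrationCurve:
    """Exponential-kernel convolution of the whole-blood AIF.

    Parameters
    ----------
    aif : AIFTrace
    kep : float
        Back-flux rate in min⁻¹, ≥ 0. ``kep = 0`` degenerates exactly to the
        plain cumulative integral.
    """
    if kep < 0:
        raise ValueError("kep must be non-negative")
    y = _exp_conv_values(aif.times, aif.c_aif, kep / _SECONDS_PER_MINUTE)
    return ConcentrationCurve(aif.times, y)


def ctissue(aif: AIFTrace, params: PKParams, model: int) -> ConcentrationCurve:
    """Forward tissue curve for one of the three nested models.

    ``ktrans``/``kep`` are in min⁻¹ and converted internally against the
    second-based time axis. The ``1/(1 − Hct)`` plasma conversion is applied
    here, once, to every term.
    """
    params.required_for(model)
    if aif.hct >= 1.0:
        raise ValueError("hct must be < 1")
    cp = aif.cp
    vals = params.vp * cp
    if model >= 2:
        kep_per_s = 0.0
        if model == 3:
            kep_per_s = params.kep / _SECONDS_PER_MINUTE
        integral = _exp_conv_values(aif.times, cp, kep_per_s)
        vals = vals + (params.ktrans / _SECONDS_PER_MINUTE) * integral
    return ConcentrationCurve(aif.times, vals)
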