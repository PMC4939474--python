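"""Closed-form FCS correlation model for a diffusing fluorophore with three dark states.

The fluorescence autocorrelation function G(tau) of pH-sensitive fluorophores
(fluorescein on lipids or on membrane proteins) diffusing through a 3D-Gaussian
confocal volume is modelled as the product of a translational-diffusion factor
and a sum of exponential blinking terms for three independent dark states:

* protonation of the dye (fraction ``P``, relaxation time ``tau_prot``),
* triplet-state formation (``T``, ``tau_T``),
* a slower, most likely redox-related, dark state (``R``, ``tau_R``).

Explicitly::

    G(tau) = 1/(N (1-P-T-R)) * (1 + tau/tau_D)^-1 * (1 + tau/(beta^2 tau_D))^-1/2
             * (1-P-T-R + P e^(-tau/tau_prot) + T e^(-tau/tau_T) + R e^(-tau/tau_R))
             + 1

``N`` is the mean number of fluorescent particles in the detection volume,
``tau_D`` their diffusion time and ``beta`` the axial/lateral aspect ratio of
the detection volume.  The protonated form of fluorescein is dark, so the
protonation equilibrium and its relaxation appear directly as the (P,
tau_prot) blinking term; this is what links the correlation curves to proton
exchange kinetics at the membrane-water interface.

The module also provides the molecular brightness (mean detected intensity
per *actively fluorescing* molecule) and the two-pKa titration curve used for
the pH dependence of the normalized molecular brightness (NMB)::

    NMB(pH) = a/(1 + 10^(pKa1-pH)) + (1-a)/(1 + 10^(pKa2-pH)) + c

All quantities are in SI-style units: seconds, counts/s, molar.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "ParameterDomainError",
    "FCSModelParams",
    "CurveMeta",
    "FCSCurve",
    "TitrationParams",
    "correlation_value",
    "correlation_curve",
    "diffusion_factor",
    "molecular_brightness",
    "titration_value",
]

ArrayLike = Union[float, Sequence[float], np.ndarray]

#: Names of the nine model parameters, in canonical order.
PARAM_NAMES = ("N", "tau_D", "beta", "P", "tau_prot", "T", "tau_T", "R", "tau_R")


class ParameterDomainError(ValueError):
    """Model parameters outside the physical domain of the correlation model."""


@dataclass(frozen=True)
class FCSModelParams:
    """Parameter set of the three-dark-state FCS model.

    Parameters
    ----------
    N : float
        Mean occupancy of the detection volume (> 0).
    tau_D : float
        Translational diffusion time through the detection volume (s).
    beta : float
        Axial/lateral extension ratio of the detection volume (> 1).
    P, tau_prot : float
        Protonated (dark) fraction and protonation relaxation time (s).
    T, tau_T : float
        Triplet fraction and triplet relaxation time (s).
    R, tau_R : float
        Redox dark fraction and its relaxation time (s).
    """

    N: float
    tau_D: float
    beta: float = 5.0
    P: float = 0.0
    tau_prot: float = 1e-6
    T: float = 0.0
    tau_T: float = 1.45e-6
    R: float = 0.0
    tau_R: float = 4e-5

    def __post_init__(self) -> None:
        if not self.N > 0:
            raise ParameterDomainError(f"N must be > 0, got {self.N}")
        if not self.beta > 1:
            raise ParameterDomainError(f"beta must be > 1, got {self.beta}")
        for name in ("tau_D", "tau_prot", "tau_T", "tau_R"):
            value = getattr(self, name)
            if not value > 0:
                raise ParameterDomainError(f"{name} must be > 0, got {value}")
        for name in ("P", "T", "R"):
            value = getattr(self, name)
            if not 0.0 <= value < 1.0:
                raise ParameterDomainError(f"{name} must be in [0, 1), got {value}")
        if not self.P + self.T + self.R < 1.0:
            raise ParameterDomainError(
                f"total dark fraction P+T+R must be < 1, got {self.P + self.T + self.R}"
            )

    @property
    def bright_fraction(self) -> float:
        """Fraction of molecules not in any dark state, ``1 - P - T - R``."""
        return 1.0 - self.P - self.T - self.R

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def replace(self, **changes: float) -> "FCSModelParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class CurveMeta:
    """Per-curve sample metadata: identity, pH/[H+], buffer, mean intensity."""

    sample_id: str = ""
    pH: Optional[float] = None
    h_conc: Optional[float] = None
    buffer_name: Optional[str] = None
    buffer_conc: float = 0.0
    mean_intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pH is not None:
            expected = 10.0 ** (-self.pH)
            if self.h_conc is None:
                object.__setattr__(self, "h_conc", expected)
            elif abs(self.h_conc - expected) > 1e-12 * expected:
                raise ValueError(
                    f"h_conc {self.h_conc!r} inconsistent with pH {self.pH!r} "
                    f"(expected {expected!r})"
                )
        if self.buffer_conc < 0:
            raise ValueError(f"buffer_conc must be >= 0, got {self.buffer_conc}")


@dataclass(frozen=True)
class FCSCurve:
    """A measured or synthetic autocorrelation curve: G(tau) on a lag grid.

    ``lags`` must be strictly increasing and positive; ``values`` finite and
    of the same length.  ``meta`` carries the sample context (pH, buffer, ...)
    needed downstream by the kinetics analysis.
    """

    lags: np.ndarray
    values: np.ndarray
    meta: Optional[CurveMeta] = None

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        if lags.ndim != 1 or values.ndim != 1:
            raise ValueError("lags and values must be one-dimensional")
        if len(lags) != len(values):
            raise ValueError(
                f"lags and values length mismatch: {len(lags)} != {len(values)}"
            )
        if len(lags) > 0:
            if not np.all(lags > 0):
                raise ValueError("all lag times must be > 0")
            if not np.all(np.diff(lags) > 0):
                raise ValueError("lag times must be strictly increasing")
            if not np.all(np.isfinite(values)):
                raise ValueError("correlation values must be finite")

    def __len__(self) -> int:
        return len(self.lags)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FCSCurve):
            return NotImplemented
        return (
            np.array_equal(self.lags, other.lags)
            and np.array_equal(self.values, other.values)
            and self.meta == other.meta
        )


@dataclass(frozen=True)
class TitrationParams:
    """Two-pKa titration curve parameters; convention ``pKa1 <= pKa2``.

    ``a`` is the amplitude of the first (lower-pKa) transition, ``c`` an
    offset: the curve runs from ``c`` at low pH to ``1 + c`` at high pH.
    """

    a: float
    pKa1: float
    pKa2: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"amplitude a must be in [0, 1], got {self.a}")
        if self.pKa1 > self.pKa2:
            raise ValueError(
                f"pKa1 must be <= pKa2 (ordering convention), got {self.pKa1} > {self.pKa2}"
            )


def diffusion_factor(tau: ArrayLike, N: float, tau_D: float, beta: float) -> ArrayLike:
    """Pure 3D-Gaussian translational diffusion term of the correlation, G_D(tau) - 1.

    Equals ``(1/N) (1 + tau/tau_D)^-1 (1 + tau/(beta^2 tau_D))^-1/2``.
    """
    tau = np.asarray(tau, dtype=float)
    out = (1.0 / N) / ((1.0 + tau / tau_D) * np.sqrt(1.0 + tau / (beta**2 * tau_D)))
    return out if out.ndim else float(out)


def correlation_value(params: FCSModelParams, tau: ArrayLike) -> ArrayLike:
    """Evaluate the three-dark-state model correlation G(tau).

    Accepts a scalar lag or an array of lags (s, >= 0); returns the same shape.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lag time tau must be >= 0")
    bright = params.bright_fraction
    dark_sum = (
        bright
        + params.P * np.exp(-tau / params.tau_prot)
        + params.T * np.exp(-tau / params.tau_T)
        + params.R * np.exp(-tau / params.tau_R)
    )
    diff = (1.0 + tau / params.tau_D) * np.sqrt(1.0 + tau / (params.beta**2 * params.tau_D))
    out = dark_sum / (params.N * bright * diff) + 1.0
    return out if out.ndim else float(out)


def correlation_curve(
    params: FCSModelParams,
    lag_grid: ArrayLike,
    meta: Optional[CurveMeta] = None,
) -> FCSCurve:
    """Vectorized model evaluation on a lag grid, packaged as an :class:`FCSCurve`."""
    lag_grid = np.asarray(lag_grid, dtype=float)
    if len(lag_grid) == 0:
        return FCSCurve(lags=lag_grid, values=np.empty(0), meta=meta)
    values = correlation_value(params, lag_grid)
    return FCSCurve(lags=lag_grid, values=np.asarray(values), meta=meta)


def molecular_brightness(mean_intensity: float, params: FCSModelParams) -> float:
    """Mean intensity per actively fluorescing molecule, ``<F> / (N (1-T-P-R))``.

    The denominator counts only molecules outside all three dark states; the
    division therefore removes the trivial dependence of the detected count
    rate on occupancy and dark-state populations, isolating the per-molecule
    brightness used in the pH titration analysis.
    """
    if mean_intensity < 0:
        raise ValueError(f"mean_intensity must be >= 0, got {mean_intensity}")
    return mean_intensity / (params.N * params.bright_fraction)


def titration_value(tp: TitrationParams, pH: ArrayLike) -> ArrayLike:
    """Two-pKa titration curve (normalized molecular brightness vs pH).

    Strictly increasing in pH; tends to ``c`` at low pH and ``1 + c`` at
    high pH.
    """
    pH = np.asarray(pH, dtype=float)
    out = (
        tp.a / (1.0 + 10.0 ** (tp.pKa1 - pH))
        + (1.0 - tp.a) / (1.0 + 10.0 ** (tp.pKa2 - pH))
        + tp.c
    )
    return out if out.ndim else float(out)
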