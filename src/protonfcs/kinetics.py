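"""From per-curve fit results to protonation rate constants and antenna geometry.

For a one-step reversible protonation reaction, the relaxation rate of the
protonation blinking term is linear in the bulk proton concentration::

    k_prot = k_off + kappa_on * [H+]_bulk

so an ordinary least-squares line through (``[H+]``, ``k_prot = 1/tau_prot``)
points yields the second-order protonation rate constant ``kappa_on``
(slope, M^-1 s^-1) and the deprotonation rate ``k_off`` (intercept, s^-1).
On membranes the linear regime holds at high pH, where the membrane acts as a
fully developed proton-collecting antenna; the fit is therefore restricted to
points with ``[H+] <= h_max`` (default 10 nM, i.e. pH >= 8).

The module also fits the two-pKa titration of the normalized molecular
brightness, and evaluates the proton-collecting-antenna radius from the
mean-square displacement of a surface proton during its dwell time::

    R_PCA ~ sqrt(2 D_s tau_s / pi)

plus the disc/annulus membrane-area arithmetic used to compare nanodisc
geometries (lipid area around an embedded protein, fold changes of kappa_on).

Units: nm and nm^2 for geometry, seconds and molar for kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .correlation import CurveMeta, TitrationParams
from .fitting import FitResult

__all__ = [
    "ProtonationKinetics",
    "AntennaGeometry",
    "TitrationFit",
    "kprot_points",
    "detectable_kprot_points",
    "fit_protonation",
    "fit_titration",
    "antenna_radius",
    "dwell_time",
    "disc_area",
    "annulus_area",
    "fold_change",
    "mean_sd",
]


@dataclass(frozen=True)
class ProtonationKinetics:
    """Linear-fit output: kappa_on (slope), k_off (intercept), standard errors.

    ``warn_negative_koff`` flags a fitted negative intercept; the value is
    reported as-is (not clamped) so that pathological fits remain visible.
    """

    kappa_on: float
    k_off: float
    se_kappa_on: float
    se_k_off: float
    n_points: int
    h_range: Tuple[float, float]
    warn_negative_koff: bool = False

    def __post_init__(self) -> None:
        if not self.kappa_on > 0:
            raise ValueError(f"kappa_on must be > 0, got {self.kappa_on}")
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")


@dataclass(frozen=True)
class AntennaGeometry:
    """Consistent (R_PCA, D_s, tau_s) triple for 2D surface diffusion."""

    R_PCA: float
    D_s: float
    tau_s: float

    def __post_init__(self) -> None:
        for name in ("R_PCA", "D_s", "tau_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        expected = antenna_radius(self.D_s, self.tau_s)
        if abs(self.R_PCA - expected) > 1e-9 * expected:
            raise ValueError(
                f"inconsistent geometry: R_PCA={self.R_PCA} but sqrt(2 D_s tau_s / pi)={expected}"
            )


@dataclass(frozen=True)
class TitrationFit:
    """Two-pKa titration fit output with linearized standard errors."""

    params: TitrationParams
    stderr: dict
    converged: bool
    cost: float


def kprot_points(
    results: Iterable[Tuple[FitResult, Optional[CurveMeta]]],
) -> list[Tuple[float, float]]:
    """Pair each curve's fitted relaxation rate with its proton concentration.

    Takes (FitResult, CurveMeta) pairs; if the second element is None the
    FitResult's own ``meta`` attribute is used.  Returns ([H+] in M,
    k_prot = 1/tau_prot in s^-1) pairs in input order.
    """
    points = []
    for i, item in enumerate(results):
        if isinstance(item, FitResult):
            fit, meta = item, item.meta
        else:
            fit, meta = item
            if meta is None:
                meta = fit.meta
        if meta is None or meta.h_conc is None:
            name = getattr(meta, "sample_id", "") or f"curve {i}"
            raise ValueError(f"missing pH metadata for {name!r}")
        tau = fit.params.tau_prot
        if not tau > 0:
            raise ValueError(f"non-positive fitted tau_prot for curve {i}")
        points.append((float(meta.h_conc), 1.0 / tau))
    return points


def detectable_kprot_points(
    fits: Sequence[FitResult],
    curves: Sequence,
    p_min: float = 0.08,
) -> list[Tuple[float, float]]:
    """(``[H+]``, ``k_prot``) pairs restricted to curves where the rate is
    actually measurable.

    Two detectability conditions, mirroring how fragile curves are excluded
    in practice: the fitted protonated fraction must be at least ``p_min``
    (too small a dark fraction leaves the relaxation time undetermined), and
    the fitted relaxation time must fall inside the curve's sampled lag
    window (a decay faster than the first lag or slower than the last is not
    resolved by the measurement).
    """
    points = []
    for fit, curve in zip(fits, curves):
        tau = fit.params.tau_prot
        if fit.params.P < p_min:
            continue
        if not (curve.lags[0] <= tau <= curve.lags[-1]):
            continue
        meta = fit.meta if fit.meta is not None else curve.meta
        if meta is None or meta.h_conc is None:
            raise ValueError(f"missing pH metadata for {getattr(meta, 'sample_id', '') or 'curve'}")
        points.append((float(meta.h_conc), 1.0 / tau))
    return points


def fit_protonation(
    points: Sequence[Tuple[float, float]], h_max: float = 1e-8
) -> ProtonationKinetics:
    """Ordinary least-squares line through (``[H+]``, ``k_prot``) points.

    Points with ``[H+] > h_max`` are excluded (high-pH antenna regime); the
    returned object records how many points entered the fit and over which
    [H+] range.  Slope = kappa_on, intercept = k_off.
    """
    pts = [(h, k) for h, k in points if h <= h_max]
    if len(pts) < 2:
        raise ValueError(
            f"need >= 2 points with [H+] <= {h_max:g} M, got {len(pts)}"
        )
    h = np.array([p[0] for p in pts])
    k = np.array([p[1] for p in pts])
    res = stats.linregress(h, k)
    se_slope = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    se_icpt = float(res.intercept_stderr) if np.isfinite(res.intercept_stderr) else 0.0
    return ProtonationKinetics(
        kappa_on=float(res.slope),
        k_off=float(res.intercept),
        se_kappa_on=se_slope,
        se_k_off=se_icpt,
        n_points=len(pts),
        h_range=(float(h.min()), float(h.max())),
        warn_negative_koff=bool(res.intercept < 0),
    )


def _titration_model(pH, a, pKa1, pKa2, c):
    return a / (1.0 + 10.0 ** (pKa1 - pH)) + (1.0 - a) / (1.0 + 10.0 ** (pKa2 - pH)) + c


def fit_titration(
    points: Sequence[Tuple[float, float]],
    init: Optional[TitrationParams] = None,
) -> TitrationFit:
    """Least-squares fit of the two-pKa titration curve to (pH, NMB) points.

    Requires at least 4 points spanning more than one pH unit.  The result is
    returned in the ``pKa1 <= pKa2`` convention; if the optimizer crosses the
    ordering, the sites are swapped together with ``a <-> 1 - a``.  Degenerate
    data (flat NMB) and optimizer failures are flagged via ``converged``.
    """
    if len(points) < 4:
        raise ValueError(f"need >= 4 titration points, got {len(points)}")
    pH = np.array([p[0] for p in points], dtype=float)
    nmb = np.array([p[1] for p in points], dtype=float)
    if pH.max() - pH.min() <= 1.0:
        raise ValueError("titration points must span more than 1 pH unit")
    if np.ptp(nmb) == 0:
        return TitrationFit(
            params=TitrationParams(a=0.5, pKa1=pH.mean(), pKa2=pH.mean(), c=float(nmb[0])),
            stderr={},
            converged=False,
            cost=0.0,
        )
    if init is None:
        mid = float(np.median(pH))
        init = TitrationParams(a=0.5, pKa1=mid - 0.5, pKa2=mid + 0.5, c=float(nmb.min()))
    p0 = [init.a, init.pKa1, init.pKa2, init.c]
    lo = [0.0, pH.min() - 6, pH.min() - 6, -np.inf]
    hi = [1.0, pH.max() + 6, pH.max() + 6, np.inf]
    try:
        popt, pcov = optimize.curve_fit(
            _titration_model, pH, nmb, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except RuntimeError:
        return TitrationFit(params=init, stderr={}, converged=False, cost=math.inf)
    a, pka1, pka2, c = (float(v) for v in popt)
    perr = np.sqrt(np.diag(pcov))
    se = {name: float(e) for name, e in zip(("a", "pKa1", "pKa2", "c"), perr)}
    if pka1 > pka2:  # enforce ordering convention by site swap
        pka1, pka2 = pka2, pka1
        a = 1.0 - a
        se["a"], se["pKa1"], se["pKa2"] = se["a"], se["pKa2"], se["pKa1"]
    resid = nmb - _titration_model(pH, a, pka1, pka2, c)
    return TitrationFit(
        params=TitrationParams(a=a, pKa1=pka1, pKa2=pka2, c=c),
        stderr=se,
        converged=bool(np.all(np.isfinite(popt))),
        cost=float(np.sum(resid**2)),
    )


def antenna_radius(D_s: float, tau_s: float) -> float:
    """Proton-collecting antenna radius (nm) from 2D mean-square displacement,
    ``R_PCA = sqrt(2 D_s tau_s / pi)`` with D_s in nm^2/s and tau_s in s."""
    if not (D_s > 0 and tau_s > 0):
        raise ValueError("D_s and tau_s must be > 0")
    return math.sqrt(2.0 * D_s * tau_s / math.pi)


def dwell_time(R_PCA: float, D_s: float) -> float:
    """Surface dwell time (s) implied by an antenna radius: inverse of
    :func:`antenna_radius`, ``tau_s = pi R_PCA^2 / (2 D_s)``."""
    if not (R_PCA > 0 and D_s > 0):
        raise ValueError("R_PCA and D_s must be > 0")
    return math.pi * R_PCA**2 / (2.0 * D_s)


def disc_area(diameter: float) -> float:
    """Area (nm^2) of a circular membrane disc of the given diameter (nm)."""
    if not diameter > 0:
        raise ValueError("diameter must be > 0")
    return math.pi * diameter**2 / 4.0


def annulus_area(nd_diameter: float, protein_diameter: float) -> float:
    """Lipid area (nm^2) remaining in a nanodisc around an embedded protein."""
    if not (nd_diameter > 0 and protein_diameter > 0):
        raise ValueError("diameters must be > 0")
    if protein_diameter >= nd_diameter:
        raise ValueError(
            f"protein diameter {protein_diameter} must be smaller than disc diameter {nd_diameter}"
        )
    return math.pi * (nd_diameter**2 - protein_diameter**2) / 4.0


def fold_change(kappa_a: float, kappa_b: float) -> float:
    """Ratio of two rate constants (dimensionless)."""
    if not (kappa_a > 0 and kappa_b > 0):
        raise ValueError("rate constants must be > 0")
    return kappa_a / kappa_b


def mean_sd(values: Sequence[float]) -> Tuple[float, float]:
    """Mean and sample standard deviation across independent experiments."""
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
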