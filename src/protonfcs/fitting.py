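"""Weighted nonlinear least-squares fitting of FCS curves, single and global.

A pH or buffer series recorded on one sample shares its diffusion time and
photophysics: the diffusion time ``tau_D``, the aspect ratio ``beta``, and
the triplet and redox dark-state parameters (``T``, ``tau_T``, ``R``,
``tau_R``) do not depend on pH or buffer concentration, while the occupancy
``N`` and the protonation parameters (``P``, ``tau_prot``) do.  The global
fit therefore ties the former across all curves of a series and leaves the
latter free per curve, which is what makes the slow protonation blinking term
separable from the other two dark states.

Optimization uses the Levenberg-Marquardt algorithm (lmfit/MINPACK) with box
bounds handled by lmfit's internal parameter transformation.  Triplet
parameters can be constrained to the empirically stable window observed on
fluorescein calibration samples (``tau_T`` in 1.4-1.5 us, ``T`` in 24-28%)
via :func:`apply_triplet_bounds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import lmfit
import numpy as np

from .correlation import PARAM_NAMES, FCSCurve, FCSModelParams

__all__ = [
    "FitSpec",
    "FitResult",
    "GlobalFitResult",
    "DegenerateDataError",
    "apply_triplet_bounds",
    "initial_guess",
    "fit_curve",
    "fit_global",
    "DEFAULT_SHARED",
    "DEFAULT_PER_CURVE",
]

#: Default parameter partition for a global series fit.
DEFAULT_SHARED = frozenset({"tau_D", "beta", "T", "tau_T", "R", "tau_R"})
DEFAULT_PER_CURVE = frozenset({"N", "P", "tau_prot"})

#: Default box bounds.  Besides keeping every parameter in the model domain
#: they encode weak physical priors that remove pathological basins: confocal
#: aspect ratios lie in the single digits, the triplet relaxes on ~1 us and
#: the redox dark state is slower than the triplet.  All overridable per fit.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "N": (1e-6, 1e6),
    "tau_D": (1e-7, 1.0),
    "beta": (1.5, 20.0),
    "P": (0.0, 0.999),
    "tau_prot": (1e-9, 1.0),
    "T": (0.0, 0.999),
    "tau_T": (1e-7, 1e-5),
    "R": (0.0, 0.999),
    "tau_R": (2e-6, 1e-2),
}

#: Triplet window observed on fluorescein calibration measurements.
TRIPLET_TAU_BOUNDS = (1.4e-6, 1.5e-6)
TRIPLET_FRACTION_BOUNDS = (0.24, 0.28)

_MAX_ITER = 2000
_COST_TOL = 1e-10


class DegenerateDataError(ValueError):
    """Raised when the data carry no information to fit (e.g. constant values)."""


@dataclass(frozen=True)
class FitSpec:
    """Partition of the nine model parameters into shared / per-curve / fixed.

    Every parameter of the correlation model must appear in exactly one of
    the three groups.  ``bounds`` overrides the default box bounds per
    parameter name; ``weights`` optionally supplies per-point standard
    deviations (one array per curve) used to weight the residuals.
    """

    shared: frozenset = DEFAULT_SHARED
    per_curve: frozenset = DEFAULT_PER_CURVE
    fixed: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    weights: Optional[Sequence[np.ndarray]] = None

    def __post_init__(self) -> None:
        shared = frozenset(self.shared)
        per_curve = frozenset(self.per_curve)
        object.__setattr__(self, "shared", shared)
        object.__setattr__(self, "per_curve", per_curve)
        overlap = shared & per_curve
        if overlap:
            raise ValueError(f"parameters cannot be both shared and per-curve: {sorted(overlap)}")
        fixed_names = set(self.fixed)
        for group, names in (("shared", shared), ("per_curve", per_curve), ("fixed", fixed_names)):
            unknown = names - set(PARAM_NAMES)
            if unknown:
                raise ValueError(f"unknown parameter(s) in {group}: {sorted(unknown)}")
        covered = shared | per_curve | fixed_names
        missing = set(PARAM_NAMES) - covered
        if missing:
            raise ValueError(f"parameters not assigned to any group: {sorted(missing)}")
        double = (shared | per_curve) & fixed_names
        if double:
            raise ValueError(f"parameters both fitted and fixed: {sorted(double)}")

    @property
    def free(self) -> frozenset:
        return self.shared | self.per_curve

    def bound_for(self, name: str) -> tuple[float, float]:
        lo, hi = DEFAULT_BOUNDS[name]
        if name in self.bounds:
            blo, bhi = self.bounds[name]
            lo, hi = max(lo, blo), min(hi, bhi)
        return lo, hi


def amplitude_weights(curves: Sequence[FCSCurve], floor: float = 0.05) -> list[np.ndarray]:
    """Per-point standard-deviation estimates proportional to the correlation
    amplitude plus a floor, ``sigma_i ~ (G_i - 1 + floor) * G_i``.

    Correlator noise scales with the correlation amplitude, so uniform
    weighting lets the noisy short-lag points drown out the clean tail; these
    relative weights (the absolute scale is irrelevant to the least-squares
    solution) restore the balance.  Computed from the data, so no knowledge
    of the true noise level is needed.
    """
    return [np.maximum((c.values - 1.0 + floor) * c.values, 1e-12) for c in curves]


def apply_triplet_bounds(spec: FitSpec) -> FitSpec:
    """Install the empirical triplet window (tau_T 1.4-1.5 us, T 24-28%).

    Existing bounds are intersected, so a spec that already constrains the
    triplet parameters more tightly keeps its tighter interval.
    """
    bounds = dict(spec.bounds)
    for name, (lo, hi) in (("tau_T", TRIPLET_TAU_BOUNDS), ("T", TRIPLET_FRACTION_BOUNDS)):
        if name in bounds:
            blo, bhi = bounds[name]
            bounds[name] = (max(lo, blo), min(hi, bhi))
        else:
            bounds[name] = (lo, hi)
    return replace(spec, bounds=bounds)


def initial_guess(curve: FCSCurve, spec: Optional[FitSpec] = None) -> FCSModelParams:
    """Heuristic starting point: N from the short-lag amplitude, tau_D from
    the half-decay lag, dark fractions at generic values (P=0.1, T=0.25, R=0.05)."""
    g0 = float(curve.values[0])
    amp = max(g0 - 1.0, 1e-6)
    n0 = 1.0 / amp
    half = 1.0 + 0.5 * amp
    below = np.nonzero(curve.values <= half)[0]
    tau_d0 = float(curve.lags[below[0]]) if len(below) else float(curve.lags[-1])
    guess = {
        "N": n0,
        "tau_D": tau_d0,
        "beta": 5.0,
        "P": 0.1,
        "tau_prot": 1e-5,
        "T": 0.25,
        "tau_T": 1.45e-6,
        "R": 0.05,
        "tau_R": 4e-5,
    }
    if spec is not None:
        guess.update(spec.fixed)
        for name in PARAM_NAMES:
            lo, hi = spec.bound_for(name)
            guess[name] = min(max(guess[name], lo), hi)
    # keep the starting point inside the model domain
    try:
        return FCSModelParams(**guess)
    except ValueError:
        total = guess["P"] + guess["T"] + guess["R"]
        scale = 0.95 / total
        for name in ("P", "T", "R"):
            guess[name] *= scale
        return FCSModelParams(**guess)


@dataclass(frozen=True)
class FitResult:
    """Result of fitting one curve: best-fit parameters, uncertainties, diagnostics."""

    params: FCSModelParams
    stderr: Mapping[str, Optional[float]]
    residuals: np.ndarray
    cost: float
    converged: bool
    n_iter: int
    meta: object = None  # CurveMeta of the fitted curve, if any

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("cost must be >= 0")


@dataclass(frozen=True)
class GlobalFitResult:
    """Joint fit of a curve series: per-curve results plus the shared estimates."""

    per_curve: Sequence[FitResult]
    shared: Mapping[str, float]
    shared_stderr: Mapping[str, Optional[float]]
    cost: float
    converged: bool
    n_iter: int

    def __iter__(self):
        return iter(self.per_curve)

    def __len__(self) -> int:
        return len(self.per_curve)


# -- model evaluation on raw floats (fit path must tolerate trial values that
#    momentarily violate the dark-fraction invariant; penalize instead of raise)

def _model_values(lags: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    bright = 1.0 - p["P"] - p["T"] - p["R"]
    if bright <= 1e-9:
        return np.full_like(lags, 1e9)
    dark = (
        bright
        + p["P"] * np.exp(-lags / p["tau_prot"])
        + p["T"] * np.exp(-lags / p["tau_T"])
        + p["R"] * np.exp(-lags / p["tau_R"])
    )
    diff = (1.0 + lags / p["tau_D"]) * np.sqrt(1.0 + lags / (p["beta"] ** 2 * p["tau_D"]))
    return dark / (p["N"] * bright * diff) + 1.0


def _check_curves(curves: Sequence[FCSCurve], spec: FitSpec) -> None:
    if spec.weights is not None and len(spec.weights) != len(curves):
        raise ValueError(
            f"weights supplied for {len(spec.weights)} curves but {len(curves)} curves given"
        )
    for i, curve in enumerate(curves):
        if len(curve) == 0:
            raise DegenerateDataError(f"curve {i} is empty")
        if np.ptp(curve.values) == 0:
            raise DegenerateDataError(f"curve {i} has constant correlation values")


def _build_parameters(
    curves: Sequence[FCSCurve], spec: FitSpec, init: Optional[FCSModelParams]
) -> lmfit.Parameters:
    params = lmfit.Parameters()
    init_map = init.as_dict() if init is not None else initial_guess(curves[0], spec).as_dict()
    for name in sorted(spec.shared) + sorted(spec.fixed):
        fixed = name in spec.fixed
        value = spec.fixed[name] if fixed else init_map[name]
        lo, hi = spec.bound_for(name)
        if fixed:
            params.add(name, value=value, vary=False)
        else:
            params.add(name, value=min(max(value, lo), hi), min=lo, max=hi)
    for i, curve in enumerate(curves):
        auto = initial_guess(curve, spec).as_dict() if init is None else None
        for name in sorted(spec.per_curve):
            value = auto[name] if auto is not None else init_map[name]
            lo, hi = spec.bound_for(name)
            params.add(f"{name}_c{i}", value=min(max(value, lo), hi), min=lo, max=hi)
    return params


def _curve_param_map(pvals: Mapping[str, float], spec: FitSpec, i: int) -> dict[str, float]:
    out: dict[str, float] = {}
    for name in PARAM_NAMES:
        if name in spec.per_curve:
            out[name] = pvals[f"{name}_c{i}"]
        else:
            out[name] = pvals[name]
    return out


def _params_from_values(values: Mapping[str, float]) -> FCSModelParams:
    clean = dict(values)
    # round-off at the domain edge after optimization
    total = clean["P"] + clean["T"] + clean["R"]
    if total >= 1.0:
        scale = (1.0 - 1e-9) / total
        for name in ("P", "T", "R"):
            clean[name] *= scale
    return FCSModelParams(**clean)


# Multi-start grids for the stage-wise initialization.  The protonation
# relaxation time and the diffusion time are the least constrained
# parameters a priori (both span decades, and on dark-state-dominated curves
# the half-decay heuristic for tau_D locks onto the blinking decay instead).
# The three exponential dark states are individually interchangeable on a
# single curve (label switching); pinning the shared photophysics while the
# per-curve protonation term is located, then refitting the shared block,
# keeps the labels anchored the same way a practitioner's stage fitting does.
_TAU_PROT_STARTS = (1e-6, 1e-5, 1e-4)
_TAU_D_STARTS = (1e-5, 1e-4, 1e-3)
_PRESOLVE_ROUNDS = 2


def _clip(value: float, lo: float, hi: float) -> float:
    return min(max(value, lo), hi)


def _conditional_curve_fit(
    curve: FCSCurve,
    spec: FitSpec,
    shared_vals: Mapping[str, float],
    warm: Optional[Mapping[str, float]] = None,
    sigma: Optional[np.ndarray] = None,
) -> tuple[dict[str, float], float]:
    """Fit one curve's per-curve parameters with shared/fixed values pinned,
    multi-starting over whichever of (tau_prot, tau_D) are per-curve."""
    auto = initial_guess(curve, spec).as_dict()
    tau_p_starts = _TAU_PROT_STARTS if "tau_prot" in spec.per_curve else (None,)
    tau_d_starts = _TAU_D_STARTS if "tau_D" in spec.per_curve else (None,)

    start_sets: list[dict[str, float]] = []
    if warm is not None:
        start_sets.append(dict(warm))
    for tp0 in tau_p_starts:
        for td0 in tau_d_starts:
            start = {}
            for name in spec.per_curve:
                if name == "tau_prot" and tp0 is not None:
                    start[name] = tp0
                elif name == "tau_D" and td0 is not None:
                    start[name] = td0
                else:
                    start[name] = auto[name]
            start_sets.append(start)

    def resid(p):
        res = curve.values - _model_values(curve.lags, p.valuesdict())
        return res if sigma is None else res / sigma

    best: Optional[dict[str, float]] = None
    best_cost = np.inf
    for start in start_sets:
        params = lmfit.Parameters()
        for name in PARAM_NAMES:
            lo, hi = spec.bound_for(name)
            if name in spec.fixed:
                params.add(name, value=spec.fixed[name], vary=False)
            elif name in spec.per_curve:
                params.add(name, value=_clip(start[name], lo, hi), min=lo, max=hi)
            else:
                params.add(name, value=_clip(shared_vals[name], lo, hi), vary=False)
        out = lmfit.minimize(resid, params, method="leastsq", max_nfev=2000)
        cost = float(np.sum(np.asarray(out.residual) ** 2))
        if cost < best_cost:
            best_cost = cost
            best = {n: float(out.params[n].value) for n in spec.per_curve}
    assert best is not None
    return best, best_cost


def _shared_block_fit(
    curves: Sequence[FCSCurve],
    spec: FitSpec,
    per_vals: Sequence[Mapping[str, float]],
    shared_start: Mapping[str, float],
    sigmas: Optional[Sequence[np.ndarray]] = None,
) -> tuple[dict[str, float], float]:
    """Fit the shared parameters jointly with all per-curve values pinned."""
    if not spec.shared:
        return dict(shared_start), np.nan
    params = lmfit.Parameters()
    for name in sorted(spec.shared):
        lo, hi = spec.bound_for(name)
        params.add(name, value=_clip(shared_start[name], lo, hi), min=lo, max=hi)

    def resid(p):
        sv = p.valuesdict()
        parts = []
        for j, (curve, pv) in enumerate(zip(curves, per_vals)):
            full = dict(sv)
            full.update(pv)
            full.update(spec.fixed)
            res = curve.values - _model_values(curve.lags, full)
            if sigmas is not None:
                res = res / np.asarray(sigmas[j], dtype=float)
            parts.append(res)
        return np.concatenate(parts)

    out = lmfit.minimize(resid, params, method="leastsq", max_nfev=2000)
    vals = {n: float(out.params[n].value) for n in spec.shared}
    return vals, float(np.sum(np.asarray(out.residual) ** 2))


def _presolve(
    curves: Sequence[FCSCurve], spec: FitSpec, base: FCSModelParams
) -> list[tuple[list[dict[str, float]], dict[str, float]]]:
    """Stage-wise initialization: alternate per-curve and shared-block fits
    from each shared-diffusion-time start.  Every branch is returned as a
    candidate — the joint fit decides between basins on its own objective."""
    base_map = base.as_dict()
    tau_d_shared = "tau_D" in spec.shared
    tau_d_grid = _TAU_D_STARTS if tau_d_shared else (None,)
    sigmas = spec.weights

    candidates = []
    for td0 in tau_d_grid:
        shared_vals = {n: base_map[n] for n in spec.shared}
        if td0 is not None:
            shared_vals["tau_D"] = td0
        per: list[Optional[dict[str, float]]] = [None] * len(curves)
        for _round in range(_PRESOLVE_ROUNDS):
            stage = [
                _conditional_curve_fit(
                    c, spec, shared_vals, warm=w,
                    sigma=None if sigmas is None else np.asarray(sigmas[j], dtype=float),
                )
                for j, (c, w) in enumerate(zip(curves, per))
            ]
            per = [s[0] for s in stage]
            if spec.shared:
                shared_vals, _ = _shared_block_fit(curves, spec, per, shared_vals, sigmas)
        candidates.append(([dict(p) for p in per], dict(shared_vals)))  # type: ignore[arg-type]
    return candidates


def _fit(
    curves: Sequence[FCSCurve], spec: FitSpec, init: Optional[FCSModelParams]
) -> GlobalFitResult:
    _check_curves(curves, spec)
    n_free = len(spec.shared) + len(spec.per_curve) * len(curves)
    n_points = sum(len(c) for c in curves)
    if n_points < n_free:
        raise ValueError(
            f"not enough data points ({n_points}) for {n_free} free parameters"
        )

    sigmas = spec.weights

    def residual(params: lmfit.Parameters) -> np.ndarray:
        pvals = params.valuesdict()
        parts = []
        for i, curve in enumerate(curves):
            model = _model_values(curve.lags, _curve_param_map(pvals, spec, i))
            res = curve.values - model
            if sigmas is not None:
                res = res / np.asarray(sigmas[i], dtype=float)
            parts.append(res)
        return np.concatenate(parts)

    if len(curves) > 1 or init is None:
        # stage-wise initialization, then one joint fit per candidate basin;
        # the lowest final cost wins
        base = init if init is not None else initial_guess(curves[0], spec)
        candidates = _presolve(curves, spec, base)
    else:
        candidates = [None]

    out = None
    best_cost = np.inf
    for cand in candidates:
        lm_params = _build_parameters(curves, spec, init)
        if cand is not None:
            starts, shared_start = cand
            for name, value in shared_start.items():
                lo, hi = spec.bound_for(name)
                lm_params[name].value = min(max(value, lo), hi)
            for i, start in enumerate(starts):
                for name in spec.per_curve:
                    lo, hi = spec.bound_for(name)
                    lm_params[f"{name}_c{i}"].value = min(max(start[name], lo), hi)
        minimizer = lmfit.Minimizer(residual, lm_params)
        trial = minimizer.minimize(
            method="leastsq", xtol=_COST_TOL, ftol=_COST_TOL, max_nfev=_MAX_ITER * max(n_free, 1)
        )
        trial_cost = float(np.sum(np.asarray(trial.residual) ** 2))
        if trial_cost < best_cost:
            best_cost = trial_cost
            out = trial
    assert out is not None

    # Rescue pass: a fitted relaxation time outside a curve's lag window is
    # unmeasurable — the per-curve protonation term collapsed into a dead
    # amplitude.  Refit such curves alone (shared values pinned, multi-start)
    # and polish the joint solution once if anything moved.
    if "tau_prot" in spec.per_curve:
        pvals = out.params.valuesdict()
        shared_now = {n: pvals[n] for n in spec.shared}
        rescued = False
        for i, curve in enumerate(curves):
            tau = pvals[f"tau_prot_c{i}"]
            if curve.lags[0] <= tau <= curve.lags[-1]:
                continue
            sigma_i = None if sigmas is None else np.asarray(sigmas[i], dtype=float)
            start, _ = _conditional_curve_fit(curve, spec, shared_now, sigma=sigma_i)
            for name, value in start.items():
                lo, hi = spec.bound_for(name)
                out.params[f"{name}_c{i}"].value = min(max(value, lo), hi)
            rescued = True
        if rescued:
            polish = lmfit.Minimizer(residual, out.params).minimize(
                method="leastsq", xtol=_COST_TOL, ftol=_COST_TOL,
                max_nfev=_MAX_ITER * max(n_free, 1),
            )
            if float(np.sum(np.asarray(polish.residual) ** 2)) < best_cost:
                out = polish

    pvals = out.params.valuesdict()
    converged = bool(out.success)

    def _stderr(name: str) -> Optional[float]:
        par = out.params.get(name)
        if par is None or par.stderr is None or not math.isfinite(par.stderr):
            return None
        return float(par.stderr)

    per_curve = []
    offset = 0
    full_res = np.asarray(out.residual, dtype=float)
    for i, curve in enumerate(curves):
        values = _curve_param_map(pvals, spec, i)
        res_i = full_res[offset : offset + len(curve)]
        offset += len(curve)
        stderr = {}
        for name in PARAM_NAMES:
            key = f"{name}_c{i}" if name in spec.per_curve else name
            stderr[name] = None if name in spec.fixed else _stderr(key)
        per_curve.append(
            FitResult(
                params=_params_from_values(values),
                stderr=stderr,
                residuals=res_i,
                cost=float(np.sum(res_i**2)),
                converged=converged,
                n_iter=int(out.nfev),
                meta=curve.meta,
            )
        )
    shared = {name: float(pvals[name]) for name in spec.shared}
    shared_stderr = {name: _stderr(name) for name in spec.shared}
    return GlobalFitResult(
        per_curve=per_curve,
        shared=shared,
        shared_stderr=shared_stderr,
        cost=float(np.sum(full_res**2)),
        converged=converged,
        n_iter=int(out.nfev),
    )


def fit_curve(
    curve: FCSCurve,
    spec: Optional[FitSpec] = None,
    init: Optional[FCSModelParams] = None,
) -> FitResult:
    """Levenberg-Marquardt least-squares fit of a single correlation curve.

    ``spec`` controls which parameters are free (the shared/per-curve split is
    irrelevant for one curve: their union is fitted), which are fixed, and the
    box bounds.  Non-convergence is reported through ``FitResult.converged``;
    degenerate (constant) data raise :class:`DegenerateDataError`.
    """
    if spec is None:
        spec = FitSpec()
    result = _fit([curve], spec, init)
    per = result.per_curve[0]
    return FitResult(
        params=per.params,
        stderr=per.stderr,
        residuals=per.residuals,
        cost=result.cost,
        converged=result.converged,
        n_iter=result.n_iter,
        meta=curve.meta,
    )


def fit_global(
    curves: Sequence[FCSCurve],
    spec: Optional[FitSpec] = None,
    init: Optional[FCSModelParams] = None,
) -> GlobalFitResult:
    """Joint fit of a curve series with shared photophysics/diffusion parameters.

    One optimization over all curves: parameters in ``spec.shared`` take a
    single common value, parameters in ``spec.per_curve`` are free per curve.
    Curves may sit on different lag grids.  A single-curve series reduces to
    :func:`fit_curve`.
    """
    curves = list(curves)
    if len(curves) == 0:
        raise ValueError("fit_global requires at least one curve")
    if spec is None:
        spec = FitSpec()
    return _fit(curves, spec, init)
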