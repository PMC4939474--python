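"""Seeded generator of synthetic FCS curves and series.

Raw correlator exports for the nanodisc experiments are not publicly
deposited, so parameter-recovery benchmarks and end-to-end pipeline tests run
on synthetic curves with the statistical structure the analysis assumes:
model curves from the three-dark-state correlation function, protonation
parameters set by the two-state equilibrium at a sample's (kappa_on, k_off),
and multiplicative, amplitude-proportional measurement noise.

The bundled :data:`SAMPLES` table carries the measured rate constants of
fluorescein in water, on solubilized cytochrome c oxidase (CytcO), and on 9-
and 12-nm nanodiscs (with the dye on a lipid or on reconstituted CytcO),
together with the fitted two-pKa pairs of their brightness titrations.  These
are the study conditions every seeded benchmark in this package is generated
under.

Noise model: ``G_i -> G_i * (1 + eps_i)`` with ``eps_i ~ N(0, noise_eps *
(G_i - 1 + 0.05))`` truncated at +-5 sigma — amplitude-proportional with a
floor so that tail lags stay noisy, as in real semi-log correlator curves.
Real correlator noise is lag-correlated; the independent-noise model here is
a declared simplification, not a claim of realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .correlation import (
    CurveMeta,
    FCSCurve,
    FCSModelParams,
    TitrationParams,
    correlation_value,
    titration_value,
)

__all__ = [
    "SampleSpec",
    "SeriesManifest",
    "SAMPLES",
    "default_lag_grid",
    "protonation_at_ph",
    "assemble_params",
    "generate_curve",
    "generate_ph_series",
    "generate_brightness_series",
    "MAX_DARK_TOTAL",
]

#: Cap on the total dark fraction P+T+R of a generated curve.  At pH well
#: below the effective pK the two-state protonated fraction approaches 1 and
#: the additive dark-state model leaves the physical domain (its amplitude
#: diverges); experimentally such curves are not usable either, which is why
#: series are recorded at pH near or above the pKa.  The generator clips P so
#: that P+T+R <= MAX_DARK_TOTAL and records the clipped value as ground truth.
MAX_DARK_TOTAL = 0.95


@dataclass(frozen=True)
class SampleSpec:
    """Ground-truth description of one sample type.

    ``kappa_on`` (M^-1 s^-1) and ``k_off`` (s^-1) set the protonation
    equilibrium and relaxation at any pH; ``N``, ``tau_D``, ``beta`` and the
    photophysics (T, tau_T, R, tau_R) complete the correlation model.
    ``pKa_pair`` (optional) drives brightness-titration series.
    """

    sample_id: str
    kappa_on: float
    k_off: float
    N: float = 4.0
    tau_D: float = 3e-4
    beta: float = 5.0
    T: float = 0.26
    tau_T: float = 1.45e-6
    R: float = 0.08
    tau_R: float = 4e-5
    pKa_pair: Optional[TitrationParams] = None

    def __post_init__(self) -> None:
        if not (self.kappa_on > 0 and self.k_off > 0):
            raise ValueError("kappa_on and k_off must be > 0")

    @property
    def pK_eff(self) -> float:
        """pH at which the dye is half protonated, log10(kappa_on / k_off)."""
        return float(np.log10(self.kappa_on / self.k_off))


#: Measured protonation rate constants per sample (kappa_on in M^-1 s^-1,
#: k_off in s^-1) with the two-pKa pairs fitted to the brightness titrations.
#: Diffusion times distinguish free dye, detergent-solubilized protein and
#: nanodiscs; photophysics defaults are shared (triplet window 24-28%,
#: 1.4-1.5 us, plus a slower redox dark state).
SAMPLES: dict[str, SampleSpec] = {
    s.sample_id: s
    for s in (
        SampleSpec(
            sample_id="flu",
            kappa_on=4e10,
            k_off=2.5e4,
            tau_D=3e-5,
            pKa_pair=None,
        ),
        SampleSpec(
            sample_id="CytcO-flu",
            kappa_on=1.01e11,
            k_off=6.85e4,
            tau_D=1.5e-4,
            pKa_pair=TitrationParams(a=0.035, pKa1=5.0, pKa2=6.6),
        ),
        SampleSpec(
            sample_id="ND9-CytcO-flu",
            kappa_on=1.44e11,
            k_off=4.66e4,
            tau_D=3e-4,
            pKa_pair=TitrationParams(a=0.145, pKa1=6.0, pKa2=7.2),
        ),
        SampleSpec(
            sample_id="ND9-flu",
            kappa_on=7.54e12,
            k_off=6.72e4,
            tau_D=3e-4,
            pKa_pair=TitrationParams(a=0.10, pKa1=7.3, pKa2=8.1),
        ),
        SampleSpec(
            sample_id="ND12-CytcO-flu",
            kappa_on=7.71e12,
            k_off=6.99e4,
            tau_D=3.5e-4,
            pKa_pair=TitrationParams(a=0.52, pKa1=7.3, pKa2=8.8),
        ),
        SampleSpec(
            sample_id="ND12-flu",
            kappa_on=7.35e12,
            k_off=5.28e4,
            tau_D=3.5e-4,
            pKa_pair=TitrationParams(a=0.41, pKa1=6.8, pKa2=8.7),
        ),
    )
}


def default_lag_grid(n: int = 128, lo: float = 1e-7, hi: float = 1.0) -> np.ndarray:
    """Log-spaced lag grid emulating a semi-log hardware correlator export."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def protonation_at_ph(spec: SampleSpec, pH: float) -> Tuple[float, float]:
    """Two-state equilibrium at a given pH: (protonated fraction P, tau_prot).

    ``tau_prot = 1/(k_off + kappa_on [H+])`` and ``P = kappa_on [H+] /
    (kappa_on [H+] + k_off)``; the protonated form is dark.
    """
    h = 10.0 ** (-pH)
    k_on = spec.kappa_on * h
    k_prot = k_on + spec.k_off
    return k_on / k_prot, 1.0 / k_prot


def assemble_params(spec: SampleSpec, pH: float) -> FCSModelParams:
    """Full correlation-model parameter set for a sample at a given pH.

    The protonated fraction is clipped so that the total dark fraction stays
    within :data:`MAX_DARK_TOTAL` (see note there); ``tau_prot`` is never
    altered, so protonation-rate recovery is unaffected by the clip.
    """
    P, tau_prot = protonation_at_ph(spec, pH)
    P = min(P, MAX_DARK_TOTAL - spec.T - spec.R)
    return FCSModelParams(
        N=spec.N,
        tau_D=spec.tau_D,
        beta=spec.beta,
        P=P,
        tau_prot=tau_prot,
        T=spec.T,
        tau_T=spec.tau_T,
        R=spec.R,
        tau_R=spec.tau_R,
    )


@dataclass(frozen=True)
class SeriesManifest:
    """Ground truth emitted alongside every generated series.

    Tests and downstream consumers read generating parameters from here —
    never from generator internals.
    """

    spec: SampleSpec
    pH_values: Tuple[float, ...]
    noise_eps: float
    seed: int
    params: Tuple[FCSModelParams, ...] = ()
    buffer_name: Optional[str] = None
    buffer_conc: float = 0.0
    file_paths: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "sample_id": self.spec.sample_id,
            "kappa_on": self.spec.kappa_on,
            "k_off": self.spec.k_off,
            "N": self.spec.N,
            "tau_D": self.spec.tau_D,
            "beta": self.spec.beta,
            "T": self.spec.T,
            "tau_T": self.spec.tau_T,
            "R": self.spec.R,
            "tau_R": self.spec.tau_R,
            "pH_values": list(self.pH_values),
            "noise_eps": self.noise_eps,
            "seed": self.seed,
            "buffer_name": self.buffer_name,
            "buffer_conc": self.buffer_conc,
            "file_paths": list(self.file_paths),
            "per_curve": [p.as_dict() for p in self.params],
        }
        if self.spec.pKa_pair is not None:
            tp = self.spec.pKa_pair
            d["pKa_pair"] = {"a": tp.a, "pKa1": tp.pKa1, "pKa2": tp.pKa2, "c": tp.c}
        return d


def generate_curve(
    spec: SampleSpec,
    pH: float,
    noise_eps: float = 0.0,
    lag_grid: Optional[np.ndarray] = None,
    seed: int = 0,
) -> FCSCurve:
    """One synthetic correlation curve for a sample at a given pH.

    Bit-reproducible for a given seed; ``noise_eps = 0`` returns the exact
    model curve.
    """
    if noise_eps < 0:
        raise ValueError("noise_eps must be >= 0")
    if lag_grid is None:
        lag_grid = default_lag_grid()
    params = assemble_params(spec, pH)
    g = np.asarray(correlation_value(params, lag_grid), dtype=float)
    if noise_eps > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_eps * (g - 1.0 + 0.05)
        eps = rng.normal(0.0, 1.0, size=g.shape)
        eps = np.clip(eps, -5.0, 5.0) * sigma  # truncate at +-5 sigma
        g = g * (1.0 + eps)
    meta = CurveMeta(sample_id=spec.sample_id, pH=pH)
    return FCSCurve(lags=np.asarray(lag_grid, dtype=float), values=g, meta=meta)


def generate_ph_series(
    spec: SampleSpec,
    pH_list: Sequence[float],
    noise_eps: float = 0.0,
    seed: int = 0,
    lag_grid: Optional[np.ndarray] = None,
) -> Tuple[list[FCSCurve], SeriesManifest]:
    """One curve per pH with shared photophysics, plus the ground-truth manifest."""
    if len(pH_list) < 2:
        raise ValueError("need at least 2 pH values for a series")
    curves = []
    params = []
    for i, pH in enumerate(pH_list):
        curves.append(
            generate_curve(spec, pH, noise_eps=noise_eps, lag_grid=lag_grid, seed=seed + i)
        )
        params.append(assemble_params(spec, pH))
    manifest = SeriesManifest(
        spec=spec,
        pH_values=tuple(float(p) for p in pH_list),
        noise_eps=noise_eps,
        seed=seed,
        params=tuple(params),
    )
    return curves, manifest


def generate_brightness_series(
    spec: SampleSpec,
    pH_list: Sequence[float],
    noise_eps: float = 0.0,
    seed: int = 0,
) -> Tuple[list[Tuple[float, float]], SeriesManifest]:
    """(pH, normalized molecular brightness) points from the sample's pKa pair.

    Noise is additive with standard deviation ``noise_eps`` (the NMB is an
    order-1 normalized quantity).
    """
    if len(pH_list) < 2:
        raise ValueError("need at least 2 pH values for a series")
    if spec.pKa_pair is None:
        raise ValueError(f"sample {spec.sample_id!r} has no pKa pair attached")
    rng = np.random.default_rng(seed)
    points = []
    for pH in pH_list:
        nmb = float(titration_value(spec.pKa_pair, pH))
        if noise_eps > 0:
            nmb += float(np.clip(rng.normal(0.0, 1.0), -5.0, 5.0)) * noise_eps
        points.append((float(pH), nmb))
    manifest = SeriesManifest(
        spec=spec,
        pH_values=tuple(float(p) for p in pH_list),
        noise_eps=noise_eps,
        seed=seed,
    )
    return points, manifest
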