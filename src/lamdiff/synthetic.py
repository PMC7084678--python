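"""Parametric forward model of a stacked-bilayer unit cell.

The real-space model is the community-standard minimal centrosymmetric
parameterization of a lipid multilayer unit cell: a hydrocarbon slab with
smoothed (error-function) edges, two Gaussian headgroup peaks at ``±z_H``,
a Gaussian methyl trough at the bilayer centre, and a water slab whose
scattering length density (SLD) is a linear H2O/D2O mix.  The profile is
periodized over neighbouring unit cells, which makes the closed-form
Fourier coefficients *exact* (the cell integral of a periodized Gaussian
equals the full-line integral of one Gaussian).

Form factors carry their true sign, so the generator doubles as the ground
truth for the phasing stage: for fixed geometry the signed ``f_n`` is an
affine function of the D2O volume fraction, which is the physical basis of
contrast-variation phasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import Diffractogram

# Coherent scattering lengths (fm -> angstrom) over a 30 A^3 water molecule:
#   b_H = -3.739 fm, b_D = +6.671 fm, b_O = +5.803 fm
RHO_H2O = (2 * (-3.739e-5) + 5.803e-5) / 30.0  # -5.583e-7 A^-2
RHO_D2O = (2 * (+6.671e-5) + 5.803e-5) / 30.0  # +6.382e-6 A^-2

_SQRT2PI = np.sqrt(2.0 * np.pi)


def water_sld(x_D2O: float) -> float:
    """SLD of an H2O/D2O mix as a linear function of the D2O volume fraction.

    Pure H2O is negative (~-0.56e-6 /A^2), pure D2O strongly positive
    (~6.38e-6 /A^2); the mix crosses zero near 8% D2O, the classic water
    contrast-match point.
    """
    x = float(x_D2O)
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"x_D2O={x_D2O} must lie in [0, 1]")
    return x * RHO_D2O + (1.0 - x) * RHO_H2O


@dataclass(frozen=True)
class BilayerModel:
    """Centrosymmetric stacked-bilayer unit cell.

    Lengths in angstrom, SLDs in 1/angstrom^2.  ``z_H`` is the headgroup
    peak position measured from the bilayer centre, so the true Luzzati
    peak-to-peak thickness is ``D_B_true = 2 z_H``.
    """

    D: float = 50.4
    z_H: float = 18.7
    sigma_H: float = 2.5
    rho_H: float = 1.8e-6
    rho_CH: float = -0.4e-6
    rho_CH3: float = -1.0e-6
    sigma_CH3: float = 3.0
    x_D2O: float = 0.08

    def __post_init__(self) -> None:
        if not (0.0 < self.z_H < self.D / 2):
            raise ValueError("require 0 < z_H < D/2")
        if self.sigma_H <= 0 or self.sigma_CH3 <= 0:
            raise ValueError("Gaussian widths must be positive")
        if not (0.0 <= self.x_D2O <= 1.0):
            raise ValueError("x_D2O must lie in [0, 1]")

    @property
    def D_B_true(self) -> float:
        return 2.0 * self.z_H

    @property
    def rho_water(self) -> float:
        return water_sld(self.x_D2O)

    def with_contrast(self, x_D2O: float) -> "BilayerModel":
        return replace(self, x_D2O=x_D2O)


def model_profile(model: BilayerModel, z) -> np.ndarray | float:
    """Evaluate the model SLD profile on ``z`` within one unit cell.

    The profile is the periodized sum over image cells of

      water + (rho_CH - rho_w) * smoothed_box(|z| < z_H)
            + (rho_H - rho_CH) * [G(z - z_H) + G(z + z_H)]
            + (rho_CH3 - rho_CH) * G(z)

    so it is even, continuous, and equal to the water SLD in the slab
    beyond the headgroups (up to Gaussian tails).
    """
    from scipy.special import erf

    z_arr = np.asarray(z, dtype=float)
    if np.any(np.abs(z_arr) > model.D / 2 + 1e-9):
        raise ValueError("z outside the unit cell [-D/2, D/2]")
    rho_w = model.rho_water
    out = np.full_like(z_arr, rho_w, dtype=float)
    s2 = np.sqrt(2.0)
    for m in range(-3, 4):
        u = z_arr - m * model.D
        step = 0.5 * (
            erf((u + model.z_H) / (s2 * model.sigma_H))
            - erf((u - model.z_H) / (s2 * model.sigma_H))
        )
        out += (model.rho_CH - rho_w) * step
        out += (model.rho_H - model.rho_CH) * (
            np.exp(-((u - model.z_H) ** 2) / (2 * model.sigma_H**2))
            + np.exp(-((u + model.z_H) ** 2) / (2 * model.sigma_H**2))
        )
        out += (model.rho_CH3 - model.rho_CH) * np.exp(
            -(u**2) / (2 * model.sigma_CH3**2)
        )
    return out if np.ndim(z) else float(out)


def model_form_factors(model: BilayerModel, orders: int) -> np.ndarray:
    """Signed Fourier coefficients f_n, n = 1..orders, in closed form.

    f_n = integral over one cell of (rho(z) - mean) cos(2 pi n z / D) dz.
    Because the profile is a periodized sum of Gaussians and an
    erf-smoothed box, each cell integral equals the analytic full-line
    cosine transform of a single component; the sign carries the phase.
    """
    if orders < 1:
        raise ValueError("orders must be >= 1")
    n = np.arange(1, orders + 1)
    k = 2.0 * np.pi * n / model.D
    rho_w = model.rho_water
    box = (
        (model.rho_CH - rho_w)
        * (2.0 * np.sin(k * model.z_H) / k)
        * np.exp(-(k**2) * model.sigma_H**2 / 2)
    )
    head = (
        (model.rho_H - model.rho_CH)
        * 2.0
        * model.sigma_H
        * _SQRT2PI
        * np.exp(-(k**2) * model.sigma_H**2 / 2)
        * np.cos(k * model.z_H)
    )
    methyl = (
        (model.rho_CH3 - model.rho_CH)
        * model.sigma_CH3
        * _SQRT2PI
        * np.exp(-(k**2) * model.sigma_CH3**2 / 2)
    )
    return box + head + methyl


@dataclass(frozen=True)
class AcquisitionModel:
    """Instrumental settings for the synthetic detector.

    ``q_grid`` spans 0.06-0.51 /A by default; ``peak_width`` is the Gaussian
    instrumental broadening (sigma, /A); ``background`` holds polynomial
    coefficients in ascending order; noise is a Gaussian approximation to
    counting statistics with standard deviation ``noise_scale * sqrt(I)``;
    ``lorentz_exponent`` p attenuates Bragg intensities as ``q^-p``;
    ``intensity_scale`` converts squared SLD-profile amplitudes (~1e-9 in
    A^-2 units) to a detector-like counts scale.
    """

    q_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.06, 0.5101, 0.0005)
    )
    peak_width: float = 0.004
    background: tuple = (50.0,)
    noise_scale: float = 1.0
    lorentz_exponent: float = 1.0
    seed: int = 0
    intensity_scale: float = 1.0e12

    def __post_init__(self) -> None:
        q = np.asarray(self.q_grid, dtype=float)
        object.__setattr__(self, "q_grid", q)
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q_grid must be positive and strictly increasing")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def _background_curve(acq: AcquisitionModel) -> np.ndarray:
    return np.polynomial.polynomial.polyval(acq.q_grid, np.asarray(acq.background, float))


def synthesize_diffractogram(
    model: BilayerModel, acq: AcquisitionModel, orders: int = 8
) -> Diffractogram:
    """Forward-model a 1D diffractogram of a lamellar stack.

    Each Bragg order n contributes a normalized Gaussian at q_n = 2 pi n / D
    with integrated intensity ``scale * f_n^2 * q_n^-p``, on top of a smooth
    polynomial background, plus seeded counting noise.
    """
    q = acq.q_grid
    f = model_form_factors(model, orders)
    signal = _background_curve(acq).copy()
    n_visible = 0
    for n in range(1, orders + 1):
        qn = 2.0 * np.pi * n / model.D
        if qn < q[0] - 4 * acq.peak_width or qn > q[-1] + 4 * acq.peak_width:
            continue
        n_visible += 1
        area = acq.intensity_scale * f[n - 1] ** 2 * qn ** (-acq.lorentz_exponent)
        signal += (
            area
            / (acq.peak_width * _SQRT2PI)
            * np.exp(-((q - qn) ** 2) / (2 * acq.peak_width**2))
        )
    meta = {
        "x_D2O": model.x_D2O,
        "label": "synthetic",
        "seed": str(acq.seed),
    }
    if n_visible == 0:
        warnings.warn("no Bragg order falls inside the q window", stacklevel=2)
        meta["warning"] = "no_peak_in_window"
    sigma = np.maximum(acq.noise_scale * np.sqrt(np.abs(signal)), 1e-12)
    rng = np.random.default_rng(acq.seed)
    noisy = signal + (rng.normal(0.0, sigma) if acq.noise_scale > 0 else 0.0)
    return Diffractogram(q, noisy, sigma, meta)


def synthesize_contrast_series(
    model: BilayerModel,
    fractions,
    acq: AcquisitionModel,
    orders: int = 8,
) -> list[Diffractogram]:
    """One diffractogram per D2O fraction, sharing geometry, seeds derived
    deterministically from the base seed so each contrast has independent
    noise regardless of measurement order."""
    fractions = list(fractions)
    if not fractions:
        raise ValueError("need at least one D2O fraction")
    out = []
    for x in fractions:
        sub_seed = int(
            np.random.SeedSequence([acq.seed, int(round(1_000_000 * x))]).generate_state(1)[0]
            % (2**31)
        )
        out.append(
            synthesize_diffractogram(
                model.with_contrast(x), replace(acq, seed=sub_seed), orders=orders
            )
        )
    return out


# first reciprocal-lattice ratios of a 2D hexagonal lattice: 1, sqrt3, 2, sqrt7
HEX_RATIOS = (1.0, np.sqrt(3.0), 2.0, np.sqrt(7.0))


def synthesize_nonlamellar(
    q1: float,
    acq: AcquisitionModel,
    amplitudes: tuple = (3000.0, 1200.0, 700.0, 400.0),
) -> Diffractogram:
    """Hexagonal-phase scan: peaks at q1 * {1, sqrt3, sqrt4, sqrt7}."""
    if q1 <= 0:
        raise ValueError("q1 must be positive")
    q = acq.q_grid
    signal = _background_curve(acq).copy()
    for ratio, area in zip(HEX_RATIOS, amplitudes):
        qn = q1 * ratio
        signal += (
            area
            / (acq.peak_width * _SQRT2PI)
            * np.exp(-((q - qn) ** 2) / (2 * acq.peak_width**2))
        )
    sigma = np.maximum(acq.noise_scale * np.sqrt(np.abs(signal)), 1e-12)
    rng = np.random.default_rng(acq.seed)
    noisy = signal + (rng.normal(0.0, sigma) if acq.noise_scale > 0 else 0.0)
    return Diffractogram(q, noisy, sigma, {"label": "synthetic_hexagonal"})


def random_model(rng: np.random.Generator) -> BilayerModel:
    """Draw a physically plausible PC-like bilayer model.

    Ranges bracket fluid-phase phosphatidylcholine-type multilayers:
    repeat 42-60 A, headgroup peaks well inside the half-cell, headgroup
    SLD above the hydrocarbon plateau and methyl trough below it.
    """
    D = rng.uniform(42.0, 60.0)
    z_H = rng.uniform(0.3 * D, 0.42 * D)
    return BilayerModel(
        D=D,
        z_H=z_H,
        sigma_H=rng.uniform(2.0, 3.5),
        rho_H=rng.uniform(1.2e-6, 2.5e-6),
        rho_CH=rng.uniform(-0.5e-6, -0.2e-6),
        rho_CH3=rng.uniform(-1.2e-6, -0.7e-6),
        sigma_CH3=rng.uniform(2.0, 3.5),
        x_D2O=0.08,
    )


def truth_dict(model: BilayerModel, acq: AcquisitionModel | None = None) -> dict:
    out = {
        "D": model.D,
        "z_H": model.z_H,
        "sigma_H": model.sigma_H,
        "rho_H": model.rho_H,
        "rho_CH": model.rho_CH,
        "rho_CH3": model.rho_CH3,
        "sigma_CH3": model.sigma_CH3,
        "x_D2O": model.x_D2O,
        "D_B_true": model.D_B_true,
    }
    if acq is not None:
        out.update(
            peak_width=acq.peak_width,
            noise_scale=acq.noise_scale,
            lorentz_exponent=acq.lorentz_exponent,
            seed=acq.seed,
        )
    return out
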