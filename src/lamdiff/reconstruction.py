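"""Fourier synthesis of the 1D neutron scattering length density profile.

For a centrosymmetric lamellar stack the relative NSLD across one unit
cell is the truncated cosine series

    rho(z) = (2/D) * sum_{n=1}^{M} nu_n |f_n| cos(2 pi n z / D)

on z in [-D/2, D/2].  There is no zeroth-order term, so the profile is
relative (arbitrary units, zero mean); only shape and peak positions are
meaningful, which is all the downstream thickness analysis uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phasing import PhaseAssignment, StructureFactorTable
from .synthetic import BilayerModel, model_form_factors, model_profile

__all__ = ["NSLDProfile", "reconstruct_nsld", "fourier_partial_sum", "truncation_error"]


@dataclass
class NSLDProfile:
    z: np.ndarray
    rho: np.ndarray
    D: float
    M: int
    nu: dict
    x_D2O: float | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, float)
        self.rho = np.asarray(self.rho, float)
        if len(self.z) != len(self.rho):
            raise ValueError("z and rho lengths differ")
        if not np.allclose(self.rho, self.rho[::-1], atol=1e-10 * max(1.0, np.abs(self.rho).max())):
            raise ValueError("profile not even in z")

    @property
    def grid_step(self) -> float:
        return float(self.z[1] - self.z[0])


def fourier_partial_sum(D: float, coeffs: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Evaluate (2/D) sum_n c_n cos(2 pi n z / D) with signed c_n (n from 1)."""
    z = np.asarray(z, float)
    out = np.zeros_like(z)
    for n, c in enumerate(coeffs, start=1):
        out += (2.0 / D) * c * np.cos(2.0 * np.pi * n * z / D)
    return out


def reconstruct_nsld(
    sf: StructureFactorTable,
    phases: PhaseAssignment,
    grid_step: float = 0.1,
    x_D2O: float | None = None,
) -> NSLDProfile:
    """Truncated cosine synthesis of the relative NSLD at one contrast.

    Amplitudes are taken from the table at ``x_D2O`` (default: the phase
    assignment's reference fraction); every order present must have a sign.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    x = phases.reference_fraction if x_D2O is None else x_D2O
    sub = sf.amplitudes_at(x)
    if len(sub) == 0:
        raise ValueError(f"no amplitudes at x_D2O={x}")
    orders = sub["order"].astype(int).tolist()
    missing = [n for n in orders if n not in phases.nu]
    if missing:
        raise ValueError(f"orders {missing} present in table but not phased")
    half_n = int(np.ceil((sf.D / 2) / grid_step))
    z = np.arange(-half_n, half_n + 1) * (sf.D / 2) / half_n
    coeffs = np.zeros(max(orders))
    for n, amp in zip(orders, sub["amplitude"]):
        coeffs[n - 1] = phases.nu[n] * amp
    rho = fourier_partial_sum(sf.D, coeffs, z)
    return NSLDProfile(z=z, rho=rho, D=sf.D, M=max(orders), nu=dict(phases.nu), x_D2O=x)


def truncation_error(model: BilayerModel, M: int, n_ref: int = 256) -> float:
    """L2 distance between the centred model profile and its M-order partial sum.

    By Parseval the squared distance equals the tail coefficient energy
    sum_{n>M} (2/D) f_n^2; the reference series is truncated at ``n_ref``
    orders, far beyond where the Gaussian-damped coefficients vanish.
    ``M = 0`` (empty sum) returns the L2 norm of the centred profile itself.
    """
    if M < 0:
        raise ValueError("M must be >= 0")
    f = model_form_factors(model, max(n_ref, M + 1))
    tail = f[M:]
    return float(np.sqrt(np.sum((2.0 / model.D) * tail**2)))
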