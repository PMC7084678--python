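"""Bilayer structural parameters from the NSLD profile (Luzzati accounting).

The chain implemented here, with first-order (delta-method) error
propagation from the two measured inputs (lattice constant D and headgroup
peak-to-peak distance D_B):

    D_B  = z+ - z-                 (Gaussian fits to the two headgroup peaks)
    D_w  = D - D_B                 (interbilayer water thickness)
    A    = 2 V_l / D_B             (interfacial area per lipid)
    2D_c = 2 V_c / A               (hydrophobic core thickness)
    n_w  = A * D_w / (2 V_w)       (waters per lipid in the interbilayer slab)

V_l, V_c are the lipid molecular and hydrophobic-core volumes supplied via
config; V_w = 30 A^3 per water molecule.  A Monte-Carlo propagation mode
(normal resampling of D and D_B) is provided as an independent cross-check
of the delta-method standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .reconstruction import NSLDProfile

__all__ = [
    "VolumeSet",
    "BilayerParameters",
    "headgroup_peak_to_peak",
    "water_thickness",
    "area_per_lipid",
    "hydrophobic_thickness",
    "waters_per_lipid",
    "propagate_errors",
    "bilayer_parameters",
]


@dataclass(frozen=True)
class VolumeSet:
    """Molecular volumes (A^3). Defaults are documented approximations for a
    diphytanyl PC-rich mixture, flagged as such; override from measurement
    when available."""

    V_l: float = 1400.0
    V_c: float = 1175.0
    V_w: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.V_c < self.V_l):
            raise ValueError("require 0 < V_c < V_l")
        if self.V_w <= 0:
            raise ValueError("V_w must be positive")


@dataclass
class BilayerParameters:
    D: float
    D_se: float
    D_B: float
    D_B_se: float
    two_Dc: float
    two_Dc_se: float
    D_w: float
    D_w_se: float
    A: float
    A_se: float
    n_w: float
    n_w_se: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(self.D_w, self.D - self.D_B, atol=1e-9):
            raise ValueError("identity D_w = D - D_B violated")

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "D", "D_se", "D_B", "D_B_se", "two_Dc", "two_Dc_se",
                "D_w", "D_w_se", "A", "A_se", "n_w", "n_w_se",
            )
        } | {"meta": self.meta}


def _gauss_c(z, A, mu, s, c):
    return A * np.exp(-((z - mu) ** 2) / (2 * s * s)) + c


def _fit_headgroup(z: np.ndarray, rho: np.ndarray, sign: int) -> tuple[float, float]:
    """Gaussian fit to the headgroup peak on one half-cell (sign = +/-1).

    The fit window runs from the peak to the nearest inflection point on
    either side (taken symmetric: the smaller distance on both sides).
    Returns (position, SE).
    """
    half = (z * sign) > 1e-9
    zi, ri = z[half], rho[half]
    i_pk = int(np.argmax(ri))
    if i_pk == 0 or i_pk == len(ri) - 1:
        raise ValueError("no interior headgroup maximum on half-cell")
    d2 = np.gradient(np.gradient(ri, zi), zi)
    # nearest curvature sign change on each side of the peak
    left = np.nonzero(d2[:i_pk] > 0)[0]
    right = np.nonzero(d2[i_pk:] > 0)[0]
    dl = zi[i_pk] - zi[left[-1]] if len(left) else zi[i_pk] - zi[0]
    dr = zi[i_pk + right[0]] - zi[i_pk] if len(right) else zi[-1] - zi[i_pk]
    w = min(dl, dr)
    m = (zi >= zi[i_pk] - w) & (zi <= zi[i_pk] + w)
    if m.sum() < 5:
        m = slice(max(0, i_pk - 3), i_pk + 4)
    p0 = [ri[i_pk] - ri.min(), zi[i_pk], max(w / 2, 1e-3), ri.min()]
    popt, pcov = curve_fit(_gauss_c, zi[m], ri[m], p0=p0, maxfev=10000)
    return float(popt[1]), float(np.sqrt(max(pcov[1, 1], 0.0)))


def headgroup_peak_to_peak(profile: NSLDProfile) -> tuple[float, float]:
    """Luzzati bilayer thickness D_B: distance between the two headgroup
    maxima of the NSLD profile, each located by a Gaussian fit.

    Returns (D_B, SE); SEs of the two peak positions combine in quadrature.
    Raises on flat or monotone profiles (no headgroup peaks).
    """
    rho = profile.rho
    if np.ptp(rho) < 1e-30:
        raise ValueError("no headgroup peaks: profile is flat")
    zp, se_p = _fit_headgroup(profile.z, rho, +1)
    zm, se_m = _fit_headgroup(profile.z, rho, -1)
    if zp <= 0 or zm >= 0:
        raise ValueError("headgroup peaks not on opposite sides of the centre")
    if abs(zp + zm) > 3.0 * max(np.hypot(se_p, se_m), profile.grid_step):
        raise ValueError(f"headgroup peaks asymmetric: z+ = {zp:.3f}, z- = {zm:.3f}")
    return float(zp - zm), float(np.hypot(se_p, se_m))


def water_thickness(D: float, D_B: float, D_se: float = 0.0, D_B_se: float = 0.0):
    """D_w = D - D_B with quadrature SE."""
    if D <= D_B:
        raise ValueError("non-physical water layer: D <= D_B")
    return D - D_B, float(np.hypot(D_se, D_B_se))


def area_per_lipid(D_B: float, vols: VolumeSet, D_B_se: float = 0.0):
    """A = 2 V_l / D_B; relative SE equals relative SE of D_B."""
    if D_B <= 0:
        raise ValueError("D_B must be positive")
    A = 2.0 * vols.V_l / D_B
    return A, A * D_B_se / D_B


def hydrophobic_thickness(A: float, vols: VolumeSet, A_se: float = 0.0):
    """2 D_c = 2 V_c / A; relative SE equals relative SE of A."""
    if A <= 0:
        raise ValueError("A must be positive")
    two_Dc = 2.0 * vols.V_c / A
    return two_Dc, two_Dc * A_se / A


def waters_per_lipid(A: float, D_w: float, vols: VolumeSet, A_se: float = 0.0, D_w_se: float = 0.0):
    """n_w = A D_w / (2 V_w), waters in the interbilayer slab per lipid.

    Treats A and D_w as independent; use :func:`propagate_errors` for the
    correlated chain from (D, D_B).
    """
    if A < 0 or D_w < 0:
        raise ValueError("A and D_w must be non-negative")
    n_w = A * D_w / (2.0 * vols.V_w)
    if A > 0 and D_w > 0:
        se = n_w * np.hypot(A_se / A, D_w_se / D_w)
    else:
        se = 0.0
    return n_w, float(se)


def _chain(D: float, D_B: float, vols: VolumeSet) -> dict:
    D_w = D - D_B
    A = 2.0 * vols.V_l / D_B
    return {
        "D_w": D_w,
        "A": A,
        "two_Dc": 2.0 * vols.V_c / A,
        "n_w": A * D_w / (2.0 * vols.V_w),
    }


def propagate_errors(
    D: float,
    D_se: float,
    D_B: float,
    D_B_se: float,
    vols: VolumeSet,
    method: str = "delta",
    n_draws: int = 100_000,
    seed: int = 0,
) -> dict:
    """Propagate SEs of (D, D_B) through the full parameter chain.

    ``delta`` uses first-order analytic partial derivatives; ``monte-carlo``
    resamples (D, D_B) from independent normals and reports sample SDs —
    a model-free cross-check of the linearization.
    """
    if D_se <= 0 or D_B_se <= 0:
        raise ValueError("standard errors must be positive")
    vals = _chain(D, D_B, vols)
    if method == "delta":
        # partials w.r.t. (D, D_B)
        A = vals["A"]
        ses = {
            "D_w": np.hypot(D_se, D_B_se),
            "A": A * D_B_se / D_B,
            "two_Dc": (vols.V_c / vols.V_l) * D_B_se,  # 2Dc = (Vc/Vl) D_B
            "n_w": np.hypot(
                (vols.V_l / (vols.V_w * D_B)) * D_se,
                (vols.V_l * D / (vols.V_w * D_B**2)) * D_B_se,
            ),
        }
    elif method == "monte-carlo":
        rng = np.random.default_rng(seed)
        Ds = rng.normal(D, D_se, n_draws)
        DBs = rng.normal(D_B, D_B_se, n_draws)
        sampled = _chain(Ds, DBs, vols)
        ses = {k: float(np.std(sampled[k], ddof=1)) for k in vals}
    else:
        raise ValueError(f"unknown propagation method {method!r}")
    return {k: (float(vals[k]), float(ses[k])) for k in vals}


def bilayer_parameters(
    D: float,
    D_se: float,
    profile: NSLDProfile,
    vols: VolumeSet,
    meta: dict | None = None,
) -> BilayerParameters:
    """Full parameter extraction from a lattice constant and an NSLD profile."""
    D_B, D_B_se = headgroup_peak_to_peak(profile)
    if D <= D_B:
        raise ValueError("non-physical: recovered D_B exceeds lattice constant")
    prop = propagate_errors(D, max(D_se, 1e-9), D_B, max(D_B_se, 1e-9), vols)
    return BilayerParameters(
        D=D,
        D_se=D_se,
        D_B=D_B,
        D_B_se=D_B_se,
        two_Dc=prop["two_Dc"][0],
        two_Dc_se=prop["two_Dc"][1],
        D_w=prop["D_w"][0],
        D_w_se=prop["D_w"][1],
        A=prop["A"][0],
        A_se=prop["A"][1],
        n_w=prop["n_w"][0],
        n_w_se=prop["n_w"][1],
        meta=meta or {},
    )
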