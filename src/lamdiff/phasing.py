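"""Structure-factor amplitudes and contrast-variation phase determination.

For a centrosymmetric unit cell the structure factors are real, so each
order carries only a sign nu_n in {-1, +1}.  The sign is recovered from the
physics of D2O contrast variation: the water SLD — and therefore the signed
f_n at fixed geometry — is an affine function of the D2O volume fraction.
For each order we enumerate sign patterns over the measured contrasts and
keep the pattern whose weighted straight-line fit of signed f_n vs x_D2O
has the highest R^2.  The overall global sign of the phase vector is fixed
by the convention that the reconstructed profile at the reference contrast
has its minimum at the bilayer centre (the terminal-methyl trough).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .reduction import LatticeAssignment, PeakSet

__all__ = ["StructureFactorTable", "PhaseAssignment", "lorentz_correct", "assign_phases"]


@dataclass
class StructureFactorTable:
    """Rows of (order, x_D2O, |f_n|, SE); one lamellar lattice per table."""

    table: pd.DataFrame  # columns: order, x_D2O, amplitude, amplitude_se, flagged
    lorentz_exponent: float
    D: float
    D_se: float = 0.0

    def __post_init__(self) -> None:
        req = {"order", "x_D2O", "amplitude", "amplitude_se"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"table must have columns {sorted(req)}")
        if (self.table["amplitude"] < 0).any():
            raise ValueError("amplitudes must be non-negative")
        if self.table.duplicated(["order", "x_D2O"]).any():
            raise ValueError("duplicate (order, x_D2O) pair")

    @property
    def orders(self) -> list[int]:
        return sorted(self.table["order"].unique().tolist())

    @property
    def fractions(self) -> list[float]:
        return sorted(self.table["x_D2O"].unique().tolist())

    def amplitudes_at(self, x_D2O: float, atol: float = 1e-9) -> pd.DataFrame:
        m = np.isclose(self.table["x_D2O"], x_D2O, atol=atol)
        return self.table[m].sort_values("order")

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["lorentz_exponent"] = self.lorentz_exponent
        out["D"] = self.D
        out.to_csv(path, index=False)


@dataclass
class PhaseAssignment:
    """Signs per order plus the per-order linear-fit diagnostics."""

    nu: dict  # order -> +1 / -1
    fits: dict  # order -> {slope, intercept, r2, r2_second_best}
    reference_fraction: float
    ambiguous: dict = field(default_factory=dict)  # order -> bool
    water_slab: dict = field(default_factory=dict)  # fitted {width, smoothing} (A)

    def nu_vector(self, orders) -> np.ndarray:
        return np.array([self.nu[n] for n in orders], dtype=float)

    def to_json_dict(self) -> dict:
        return {
            "nu": {str(k): int(v) for k, v in self.nu.items()},
            "fits": {str(k): v for k, v in self.fits.items()},
            "reference_fraction": self.reference_fraction,
            "ambiguous": {str(k): bool(v) for k, v in self.ambiguous.items()},
        }


def lorentz_correct(
    peaks_by_fraction: dict[float, PeakSet],
    assignment: LatticeAssignment,
    p: float = 1.0,
) -> StructureFactorTable:
    """Convert integrated Bragg intensities to structure-factor amplitudes.

    For oriented multilayers the standard correction is |f_n| =
    sqrt(I_n * q_n^p) with p = 1 (q_z Lorentz factor).  ``p`` is exposed
    because conventions differ: p = 0 disables the correction and p = -1
    gives the literal reading of I_n = |f_n|^2 * q_z as a division.
    Negative intensities (noise) yield zero amplitude, flagged.
    """
    if assignment.phase_class not in ("lamellar",):
        raise ValueError(
            "Lorentz correction requires peaks indexed on a single lamellar lattice"
        )
    D = assignment.lattices[0].D
    rows = []
    for x, ps in peaks_by_fraction.items():
        for pk in ps:
            if pk.order is None:
                continue
            qn = 2.0 * np.pi * pk.order / D
            corr = qn**p
            inten = pk.integrated_intensity
            flagged = inten < 0
            amp = 0.0 if flagged else float(np.sqrt(inten * corr))
            if amp > 0:
                amp_se = corr * pk.intensity_se / (2.0 * amp)
            else:
                amp_se = float(np.sqrt(max(pk.intensity_se * corr, 0.0)))
            rows.append(
                {
                    "order": int(pk.order),
                    "x_D2O": float(x),
                    "amplitude": amp,
                    "amplitude_se": float(amp_se),
                    "flagged": bool(flagged),
                }
            )
    return StructureFactorTable(
        pd.DataFrame(rows),
        lorentz_exponent=p,
        D=D,
        D_se=assignment.lattices[0].D_se,
    )


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares line; returns slope, intercept, weighted R^2."""
    W = np.sum(w)
    xb = np.sum(w * x) / W
    yb = np.sum(w * y) / W
    sxx = np.sum(w * (x - xb) ** 2)
    if sxx <= 0:
        return 0.0, yb, 1.0
    slope = np.sum(w * (x - xb) * (y - yb)) / sxx
    intercept = yb - slope * xb
    ss_res = np.sum(w * (y - slope * x - intercept) ** 2)
    ss_tot = np.sum(w * (y - yb) ** 2)
    if ss_tot <= 0:
        r2 = 1.0 if ss_res <= 1e-30 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(max(min(r2, 1.0), 0.0))


def _water_transform(d: float, s: float, k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Cosine transform (per unit amplitude) of a smoothed water slab of
    width ``d`` centred on the unit-cell boundary z = +/- D/2, with
    Gaussian edge smoothing ``s``:  w_n = (-1)^n (2/k) sin(k d/2) e^{-k^2 s^2/2}."""
    return ((-1.0) ** n) * (2.0 / k) * np.sin(k * d / 2.0) * np.exp(-(k**2) * s**2 / 2.0)


def _fit_water_slab(slopes: np.ndarray, orders: np.ndarray, D: float):
    """Fit |slope_n| to the smoothed-slab water model; returns the signed
    model transform at the optimum (arbitrary positive scale).

    Only magnitudes enter the fit (each order's measured slope sign is
    known only up to that order's flip); the *signs* of the fitted
    transform then orient every order absolutely, because heavy water is
    denser in scattering than light water, so the water term grows with
    the D2O fraction.
    """
    from scipy.optimize import minimize

    n = np.asarray(orders, float)
    k = 2.0 * np.pi * n / D
    scale = float(np.abs(slopes).max())
    absb = np.abs(slopes) / scale

    def sse(p):
        d, s = p
        if not (1.0 <= d <= 0.49 * D and 0.3 <= s <= 7.0):
            return 1e6
        g = _water_transform(d, s, k, n)
        den = float(np.sum(g * g))
        if den <= 0:
            return 1e6
        c = float(np.sum(absb * np.abs(g))) / den
        return float(np.sum((absb - c * np.abs(g)) ** 2))

    seeds = sorted(
        ((sse((d, s)), (d, s)) for d in np.linspace(2.0, 0.48 * D, 60) for s in np.linspace(0.5, 6.0, 10))
    )[:3]
    best = None
    for _, p0 in seeds:
        res = minimize(sse, p0, method="Nelder-Mead", options={"xatol": 1e-9, "fatol": 1e-18})
        if best is None or res.fun < best.fun:
            best = res
    d_opt, s_opt = best.x
    return _water_transform(d_opt, s_opt, k, n), float(d_opt), float(s_opt)


def assign_phases(
    sf: StructureFactorTable,
    reference_fraction: float = 0.08,
    ambiguity_threshold: float = 0.01,
) -> PhaseAssignment:
    """Determine the sign of each structure factor from contrast linearity.

    Two-step procedure:

    1. Per order, all 2^(c-1) sign patterns over the c contrasts are scored
       (first contrast fixed positive); the pattern maximizing the weighted
       R^2 of signed f_n vs x_D2O wins.  This pins each order's sign
       *sequence* up to one per-order flip.
    2. The per-order flips are resolved physically: the slope vector of
       signed f_n vs x_D2O is the cosine transform of the interbilayer
       water distribution, modelled as a smoothed slab centred on the
       unit-cell boundary.  The slab width and edge smoothing are fitted to
       the slope magnitudes; each order is then oriented so its measured
       slope sign matches the fitted transform (heavy water raises the
       water SLD, fixing the overall orientation absolutely).

    nu_n is the sign of the oriented best-fit line at the reference
    fraction.  The deterministic global-sign convention — the reconstructed
    reference-contrast profile has its minimum at z = 0, the
    terminal-methyl trough — fixes the overall sign whenever the water
    orientation is unavailable (no contrast dependence), and otherwise
    serves as a consistency check.  Orders whose best and runner-up
    pattern R^2 differ by less than ``ambiguity_threshold`` are flagged
    ambiguous.
    """
    fracs = sf.fractions
    if len(fracs) < 2:
        raise ValueError("phases undeterminable from one contrast")
    orders = sf.orders
    slopes = np.zeros(len(orders))
    intercepts = np.zeros(len(orders))
    fits: dict[int, dict] = {}
    ambiguous: dict[int, bool] = {}
    for i, n in enumerate(orders):
        sub = sf.table[sf.table["order"] == n].sort_values("x_D2O")
        x = sub["x_D2O"].to_numpy(float)
        a = sub["amplitude"].to_numpy(float)
        se = sub["amplitude_se"].to_numpy(float)
        w = 1.0 / se**2 if np.all(se > 0) else np.ones_like(a)
        if len(x) < 2:
            raise ValueError(f"order {n}: need >= 2 contrasts")
        scored = []
        for signs in product((1.0, -1.0), repeat=len(x) - 1):
            s = np.concatenate([[1.0], signs])
            slope, intercept, r2 = _wls_line(x, s * a, w)
            scored.append((r2, slope, intercept))
        scored.sort(key=lambda t: -t[0])
        r2_best, slopes[i], intercepts[i] = scored[0]
        r2_second = scored[1][0] if len(scored) > 1 else 0.0
        fits[n] = {"r2": r2_best, "r2_second_best": r2_second}
        ambiguous[n] = (r2_best - r2_second) < ambiguity_threshold

    # orient each order against the fitted water-slab transform
    if np.abs(slopes).max() > 0:
        g, d_w_fit, s_fit = _fit_water_slab(slopes, np.array(orders), sf.D)
        flips = np.where(np.sign(slopes) == np.sign(g), 1.0, -1.0)
        flips[np.sign(g) == 0] = 1.0
    else:  # no contrast dependence at all: orientation undeterminable
        g = np.zeros(len(orders))
        d_w_fit = s_fit = float("nan")
        flips = np.ones(len(orders))
        ambiguous = {n: True for n in orders}
    slopes *= flips
    intercepts *= flips

    nu: dict[int, int] = {}
    for i, n in enumerate(orders):
        val_ref = slopes[i] * reference_fraction + intercepts[i]
        nu[n] = 1 if val_ref >= 0 else -1
        fits[n].update(
            slope=float(slopes[i]),
            intercept=float(intercepts[i]),
            water_transform=float(g[i]),
        )

    # methyl-trough convention: the reconstructed reference profile should
    # have its minimum at the bilayer centre.  When the water orientation
    # was available this is a consistency check only (the orientation is
    # already absolute); when it was not, it fixes the global sign.
    ref = sf.amplitudes_at(reference_fraction)
    if len(ref) == len(orders):
        amps = {int(r["order"]): float(r["amplitude"]) for _, r in ref.iterrows()}
    else:  # reference not measured: use fitted line magnitude
        amps = {n: abs(fits[n]["slope"] * reference_fraction + fits[n]["intercept"]) for n in orders}
    z = np.linspace(-sf.D / 2, sf.D / 2, 501)
    rho = np.zeros_like(z)
    for n in orders:
        rho += (2.0 / sf.D) * nu[n] * amps[n] * np.cos(2 * np.pi * n * z / sf.D)
    trough_at_centre = rho[len(z) // 2] <= (rho.min() + rho.max()) / 2
    orientation_available = np.abs(slopes).max() > 0
    if not trough_at_centre:
        if orientation_available:
            warnings.warn(
                "profile minimum not at the bilayer centre despite water-based "
                "orientation; keeping the physical orientation",
                stacklevel=2,
            )
        else:
            nu = {n: -v for n, v in nu.items()}
            for n in orders:
                fits[n]["slope"] *= -1
                fits[n]["intercept"] *= -1
    return PhaseAssignment(
        nu=nu,
        fits=fits,
        reference_fraction=reference_fraction,
        ambiguous=ambiguous,
        water_slab={"width": d_w_fit, "smoothing": s_fit},
    )
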