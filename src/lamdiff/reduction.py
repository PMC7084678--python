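"""Diffractogram reduction: background, Bragg peak fitting, lattice indexing.

The reduction chain turns a 1D scan into a set of fitted Gaussian Bragg
peaks and an assignment of those peaks onto one or more lattices:

* lamellar — positions at q_n = 2 pi n / D, integer n >= 1;
* hexagonal — positions at q1 * {1, sqrt3, sqrt4, sqrt7};
* coexisting_lamellar — two interleaved lamellar series (the signature of a
  lamellar-lamellar phase transition in a partially hydrated stack).

Lamellar lattice constants come from a weighted least-squares line through
the origin of q_n vs n; D = 2 pi / slope.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_widths

from .io import Diffractogram
from .synthetic import HEX_RATIOS, _SQRT2PI

__all__ = [
    "BraggPeak",
    "PeakSet",
    "Lattice",
    "LatticeAssignment",
    "q_from_two_theta",
    "subtract_background",
    "fit_peaks",
    "index_lattice",
    "classify_phase",
]


def q_from_two_theta(two_theta_deg, wavelength_A: float):
    """Convert scattered angle 2*theta (degrees) to q = 2 pi sin(2theta)/lambda."""
    return 2.0 * np.pi * np.sin(np.deg2rad(two_theta_deg)) / wavelength_A


@dataclass
class BraggPeak:
    center: float
    center_se: float
    width: float
    width_se: float
    integrated_intensity: float
    intensity_se: float
    order: int | None = None
    lattice_id: int | None = None

    def to_dict(self) -> dict:
        return {
            "center": self.center,
            "center_se": self.center_se,
            "width": self.width,
            "width_se": self.width_se,
            "integrated_intensity": self.integrated_intensity,
            "intensity_se": self.intensity_se,
            "order": self.order,
            "lattice_id": self.lattice_id,
        }


@dataclass
class PeakSet:
    peaks: list[BraggPeak]
    meta: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self):
        return len(self.peaks)

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.peaks])

    def sorted(self) -> "PeakSet":
        return PeakSet(sorted(self.peaks, key=lambda p: p.center), dict(self.meta))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"meta": self.meta, "peaks": [p.to_dict() for p in self.peaks]},
                fh,
                indent=1,
            )


@dataclass
class Lattice:
    D: float
    D_se: float
    kind: str = "lamellar"  # or "hexagonal"


@dataclass
class LatticeAssignment:
    phase_class: str  # lamellar | hexagonal | coexisting_lamellar | unindexed
    lattices: list[Lattice]
    assignment: dict  # peak index -> (lattice_id, order index)
    residuals: dict  # peak index -> |q_obs - q_pred|
    low_confidence: bool = False
    rationale: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "phase_class": self.phase_class,
                    "lattices": [
                        {"D": lat.D, "D_se": lat.D_se, "kind": lat.kind}
                        for lat in self.lattices
                    ],
                    "assignment": {str(k): list(v) for k, v in self.assignment.items()},
                    "residuals": {str(k): v for k, v in self.residuals.items()},
                    "low_confidence": self.low_confidence,
                    "rationale": self.rationale,
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# background subtraction


def subtract_background(
    d: Diffractogram,
    method: str = "linear",
    exclusion: list[tuple[float, float]] | None = None,
    degree: int | None = None,
) -> Diffractogram:
    """Fit and subtract a smooth polynomial baseline.

    The baseline is fitted on points outside the ``exclusion`` windows
    (peak regions).  Post-subtraction intensities are left as-is — slightly
    negative values are noise and clipping them would bias integrated
    intensities.
    """
    if method == "constant":
        deg = 0
    elif method == "linear":
        deg = 1
    elif method == "polynomial":
        deg = 2 if degree is None else int(degree)
    else:
        raise ValueError(f"unknown background method {method!r}")
    mask = np.ones(len(d.q), dtype=bool)
    for lo, hi in exclusion or []:
        if lo < d.q[0] - 1e-12 or hi > d.q[-1] + 1e-12:
            raise ValueError(f"exclusion window ({lo}, {hi}) outside q range")
        mask &= ~((d.q >= lo) & (d.q <= hi))
    if not mask.any():
        raise ValueError("all points excluded; cannot fit baseline")
    w = None if d.sigma is None else 1.0 / d.sigma[mask]
    coeffs = np.polynomial.polynomial.polyfit(d.q[mask], d.intensity[mask], deg, w=w)
    baseline = np.polynomial.polynomial.polyval(d.q, coeffs)
    out = d.copy()
    out.intensity = d.intensity - baseline
    out.meta["background_method"] = f"{method}:deg{deg}"
    out.meta.pop("background_coeffs", None)
    return out


def auto_exclusion_windows(d: Diffractogram, half_width_pts: int = 30) -> list[tuple[float, float]]:
    """Peak windows for baseline fitting, from a rough peak detection."""
    idx, _ = find_peaks(d.intensity, prominence=_default_prominence(d))
    out = []
    for i in idx:
        lo = d.q[max(0, i - half_width_pts)]
        hi = d.q[min(len(d.q) - 1, i + half_width_pts)]
        out.append((float(lo), float(hi)))
    return out


# ---------------------------------------------------------------------------
# peak fitting


def _default_prominence(d: Diffractogram) -> float:
    if d.sigma is not None:
        return 5.0 * float(np.median(d.sigma))
    # robust noise estimate from the second difference
    dd = np.diff(d.intensity, 2)
    return 5.0 * 1.4826 * float(np.median(np.abs(dd - np.median(dd)))) / np.sqrt(6.0)


def _multi_gauss(q, *params):
    # params: [A1, mu1, s1, ..., Ak, muk, sk, b0, b1]
    k = (len(params) - 2) // 3
    out = params[-2] + params[-1] * q
    for i in range(k):
        A, mu, s = params[3 * i : 3 * i + 3]
        out = out + A * np.exp(-((q - mu) ** 2) / (2 * s * s))
    return out


def fit_peaks(
    d: Diffractogram,
    guesses: list[float] | None = None,
    prominence: float | None = None,
    window_widths: float = 4.0,
    min_snr: float = 5.0,
) -> PeakSet:
    """Detect and fit Gaussian Bragg peaks with a local linear baseline.

    Peaks whose windows overlap (centres within ~3 widths) are co-fitted as
    a sum of Gaussians.  Integrated intensity is ``A sigma sqrt(2 pi)`` with
    a standard error from the fit covariance; non-converged peaks are
    flagged and excluded with a warning, never silently dropped.  Detected
    candidates whose fitted area is below ``min_snr`` standard errors are
    noise spikes and are likewise excluded with a warning (set
    ``min_snr=0`` to keep everything).
    """
    q, y = d.q, d.intensity
    sig = d.sigma
    if guesses is None:
        prom = prominence if prominence is not None else _default_prominence(d)
        idx, props = find_peaks(y, prominence=prom)
        if len(idx) == 0:
            raise ValueError("no peak above prominence threshold")
        # relative floor: drop candidates 4 decades below the strongest peak
        keep = props["prominences"] >= 1e-4 * props["prominences"].max()
        idx = idx[keep]
        widths_pts = peak_widths(y, idx, rel_height=0.5)[0]
        dq = float(np.median(np.diff(q)))
        init = [
            (float(q[i]), max(w * dq / 2.355, dq), float(y[i]))
            for i, w in zip(idx, widths_pts)
        ]
    else:
        dq = float(np.median(np.diff(q)))
        init = []
        for g in guesses:
            i = int(np.argmin(np.abs(q - g)))
            init.append((float(q[i]), 4 * dq, float(y[i])))
    init.sort()

    # group peaks whose centres are within 3 widths of each other
    groups: list[list[tuple[float, float, float]]] = [[init[0]]]
    for c, w, a in init[1:]:
        pc, pw, _ = groups[-1][-1]
        if c - pc < 3.0 * (w + pw):
            groups[-1].append((c, w, a))
        else:
            groups.append([(c, w, a)])

    peaks: list[BraggPeak] = []
    for group in groups:
        lo = group[0][0] - window_widths * group[0][1] * 2
        hi = group[-1][0] + window_widths * group[-1][1] * 2
        m = (q >= lo) & (q <= hi)
        if m.sum() < 3 * len(group) + 2 + 3:
            pad = (3 * len(group) + 5 - m.sum()) // 2 + 1
            i0, i1 = np.nonzero(m)[0][[0, -1]]
            m[max(0, i0 - pad) : min(len(q), i1 + pad + 1)] = True
        p0, lower, upper = [], [], []
        for c, w, a in group:
            p0 += [max(a, 1e-12), c, w]
            lower += [0.0, lo, 1e-6 * (hi - lo)]
            upper += [np.inf, hi, hi - lo]
        p0 += [0.0, 0.0]
        lower += [-np.inf, -np.inf]
        upper += [np.inf, np.inf]
        p0 = [min(max(v, lo_), hi_) for v, lo_, hi_ in zip(p0, lower, upper)]
        eps = 1e-12
        p0 = [
            v + eps if v <= lo_ else (v - eps if v >= hi_ else v)
            for v, lo_, hi_ in zip(p0, lower, upper)
        ]
        try:
            popt, pcov = curve_fit(
                _multi_gauss,
                q[m],
                y[m],
                p0=p0,
                sigma=None if sig is None else sig[m],
                absolute_sigma=sig is not None,
                bounds=(lower, upper),
                maxfev=20000,
            )
        except RuntimeError:
            warnings.warn(
                f"peak fit near q={group[0][0]:.4f} did not converge; excluded",
                stacklevel=2,
            )
            continue
        for i in range(len(group)):
            A, mu, s = popt[3 * i : 3 * i + 3]
            if not (q[m][0] < mu < q[m][-1]):
                warnings.warn(
                    f"fitted centre {mu:.4f} escaped its window; excluded",
                    stacklevel=2,
                )
                continue
            varA, varmu, vars_ = (
                pcov[3 * i, 3 * i],
                pcov[3 * i + 1, 3 * i + 1],
                pcov[3 * i + 2, 3 * i + 2],
            )
            covAs = pcov[3 * i, 3 * i + 2]
            area = A * s * _SQRT2PI
            # delta method: Var(area) = (s sqrt2pi)^2 VarA + (A sqrt2pi)^2 Vars + 2 cross
            var_area = (
                (s * _SQRT2PI) ** 2 * varA
                + (A * _SQRT2PI) ** 2 * vars_
                + 2 * (s * _SQRT2PI) * (A * _SQRT2PI) * covAs
            )
            peaks.append(
                BraggPeak(
                    center=float(mu),
                    center_se=float(np.sqrt(max(varmu, 0.0))),
                    width=float(s),
                    width_se=float(np.sqrt(max(vars_, 0.0))),
                    integrated_intensity=float(area),
                    intensity_se=float(np.sqrt(max(var_area, 0.0))),
                )
            )
    if min_snr > 0:
        kept = []
        for pk in peaks:
            if pk.intensity_se > 0 and pk.integrated_intensity < min_snr * pk.intensity_se:
                warnings.warn(
                    f"peak at q={pk.center:.4f} below {min_snr:g}-sigma significance; excluded",
                    stacklevel=2,
                )
            else:
                kept.append(pk)
        peaks = kept
    if not peaks:
        raise ValueError("no peak could be fitted")
    return PeakSet(sorted(peaks, key=lambda p: p.center), dict(d.meta))


# ---------------------------------------------------------------------------
# lattice indexing


def _wls_through_origin(x: np.ndarray, y: np.ndarray, se: np.ndarray):
    """Weighted LS slope of y = s*x; returns (s, se_s)."""
    w = 1.0 / np.maximum(se, 1e-12) ** 2
    sxx = np.sum(w * x * x)
    s = np.sum(w * x * y) / sxx
    # weight-based variance; add residual-based floor for overdispersion
    var_w = 1.0 / sxx
    if len(x) > 1:
        resid = y - s * x
        var_r = np.sum(w * resid**2) / ((len(x) - 1) * sxx)
        var_w = max(var_w, var_r)
    return float(s), float(np.sqrt(var_w))


def _fit_series(
    centers: np.ndarray, ses: np.ndarray, multipliers: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Fit q = slope * multiplier; return slope, slope SE, residuals."""
    s, s_se = _wls_through_origin(multipliers, centers, ses)
    return s, s_se, centers - s * multipliers


def _try_lamellar(centers, ses, tolerance):
    """Best single-lamellar indexing, or None."""
    best = None
    cand_q1 = {centers[0] / n0 for n0 in (1, 2, 3)}
    if len(centers) > 1:
        diffs = np.diff(centers)
        cand_q1.add(float(np.median(diffs)))
    for q1c in cand_q1:
        if q1c <= 0:
            continue
        orders = np.round(centers / q1c).astype(int)
        if np.any(orders < 1):
            continue
        s, s_se, resid = _fit_series(centers, ses, orders.astype(float))
        rel = np.abs(resid) / centers
        if np.max(rel) > tolerance:
            continue
        score = (int(np.sum(orders)), float(np.max(rel)))
        if best is None or score < best[0]:
            best = (score, orders, s, s_se, resid)
    return best


def _try_hexagonal(centers, ses, tolerance):
    if len(centers) < 2:
        return None
    ratios = np.asarray(HEX_RATIOS)
    q1c = centers[0]
    mult = np.array([ratios[np.argmin(np.abs(centers[i] / q1c - ratios))] for i in range(len(centers))])
    if len(set(mult.tolist())) < len(mult):
        return None
    # must actually use a non-integer ratio, else it's lamellar territory
    s, s_se, resid = _fit_series(centers, ses, mult)
    rel = np.abs(resid) / centers
    if np.max(rel) > tolerance:
        return None
    if not np.any(np.isin(np.round(mult**2).astype(int), (3, 7))):
        return None
    return mult, s, s_se, resid


def _try_coexisting(centers, ses, tolerance):
    """Two interleaved lamellar series, each with >= 2 orders."""
    n = len(centers)
    if n < 4:
        return None
    best = None
    for i, j in combinations(range(min(n, 4)), 2):
        q1a, q1b = centers[i], centers[j]
        if abs(q1a - q1b) / q1a < 1e-6:
            continue
        assign = []
        ok = True
        for c in centers:
            cand = []
            for lat_id, q1 in ((0, q1a), (1, q1b)):
                order = max(1, int(round(c / q1)))
                cand.append((abs(c - order * q1) / c, lat_id, order))
            cand.sort()
            if cand[0][0] > tolerance:
                ok = False
                break
            assign.append((cand[0][1], cand[0][2]))
        if not ok:
            continue
        groups = {0: [], 1: []}
        for idx, (lat_id, order) in enumerate(assign):
            groups[lat_id].append((idx, order))
        if any(len({o for _, o in g}) < 2 for g in groups.values()):
            continue
        fits = {}
        maxrel = 0.0
        for lat_id, g in groups.items():
            idxs = np.array([i0 for i0, _ in g])
            mult = np.array([float(o) for _, o in g])
            s, s_se, resid = _fit_series(centers[idxs], ses[idxs], mult)
            rel = np.abs(resid) / centers[idxs]
            maxrel = max(maxrel, float(np.max(rel)))
            fits[lat_id] = (idxs, mult, s, s_se, resid)
        if maxrel > tolerance:
            continue
        if best is None or maxrel < best[0]:
            best = (maxrel, assign, fits)
    return best


def index_lattice(peaks: PeakSet, tolerance: float = 0.01) -> LatticeAssignment:
    """Index fitted peaks onto lamellar / hexagonal / coexisting lattices.

    Hypotheses are tried in order of parsimony: one lamellar series, one
    hexagonal series, two coexisting lamellar series; the first hypothesis
    whose worst relative position residual is within ``tolerance`` wins.
    A single peak is indexed as lamellar first order, flagged low-confidence.
    """
    ps = peaks.sorted()
    if len(ps) == 0:
        raise ValueError("no peaks to index")
    centers = ps.centers
    ses = np.array([max(p.center_se, 1e-9) for p in ps.peaks])

    if len(ps) == 1:
        D = 2.0 * np.pi / centers[0]
        D_se = D * ses[0] / centers[0]
        ps.peaks[0].order, ps.peaks[0].lattice_id = 1, 0
        return LatticeAssignment(
            phase_class="lamellar",
            lattices=[Lattice(float(D), float(D_se))],
            assignment={0: (0, 1)},
            residuals={0: 0.0},
            low_confidence=True,
            rationale="single peak; assumed first lamellar order (low confidence)",
        )

    lam = _try_lamellar(centers, ses, tolerance)
    if lam is not None:
        _, orders, s, s_se, resid = lam
        D = 2.0 * np.pi / s
        D_se = D * s_se / s
        for pk, n in zip(ps.peaks, orders):
            pk.order, pk.lattice_id = int(n), 0
        return LatticeAssignment(
            phase_class="lamellar",
            lattices=[Lattice(float(D), float(D_se))],
            assignment={i: (0, int(n)) for i, n in enumerate(orders)},
            residuals={i: float(abs(r)) for i, r in enumerate(resid)},
            rationale=(
                f"positions consistent with q_n = 2*pi*n/D, orders {orders.tolist()}, "
                f"D = {D:.2f} A, max rel residual "
                f"{float(np.max(np.abs(resid) / centers)):.2e}"
            ),
        )

    hexa = _try_hexagonal(centers, ses, tolerance)
    if hexa is not None:
        mult, s, s_se, resid = hexa
        # 2D hexagonal lattice parameter a = 4 pi / (sqrt(3) q1)
        a = 4.0 * np.pi / (np.sqrt(3.0) * s)
        a_se = a * s_se / s
        for pk, m in zip(ps.peaks, mult):
            pk.order, pk.lattice_id = int(round(m**2)), 0
        return LatticeAssignment(
            phase_class="hexagonal",
            lattices=[Lattice(float(a), float(a_se), kind="hexagonal")],
            assignment={i: (0, int(round(m**2))) for i, m in enumerate(mult)},
            residuals={i: float(abs(r)) for i, r in enumerate(resid)},
            rationale=(
                f"position ratios {np.round(centers / centers[0], 3).tolist()} match "
                "1:sqrt3:sqrt4:sqrt7 hexagonal series; lattice parameter "
                f"a = {a:.2f} A"
            ),
        )

    co = _try_coexisting(centers, ses, tolerance)
    if co is not None:
        _, assign, fits = co
        lattices, assignment, residuals = [], {}, {}
        for lat_id in sorted(fits):
            idxs, mult, s, s_se, resid = fits[lat_id]
            D = 2.0 * np.pi / s
            D_se = D * s_se / s
            lattices.append(Lattice(float(D), float(D_se)))
            for i0, m, r in zip(idxs, mult, resid):
                assignment[int(i0)] = (lat_id, int(m))
                residuals[int(i0)] = float(abs(r))
                ps.peaks[int(i0)].order = int(m)
                ps.peaks[int(i0)].lattice_id = lat_id
        return LatticeAssignment(
            phase_class="coexisting_lamellar",
            lattices=lattices,
            assignment=assignment,
            residuals=residuals,
            rationale=(
                "two interleaved lamellar series: D = "
                + ", ".join(f"{lat.D:.2f} A" for lat in lattices)
            ),
        )

    return LatticeAssignment(
        phase_class="unindexed",
        lattices=[],
        assignment={},
        residuals={},
        rationale="no lattice hypothesis fits all peaks within tolerance",
    )


def classify_phase(assignment: LatticeAssignment) -> tuple[str, str]:
    """Return the phase class with its human-readable rationale."""
    return assignment.phase_class, assignment.rationale
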