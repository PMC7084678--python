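"""Plain-text diffractogram I/O.

The on-disk dialect is deliberately minimal: ``#``-prefixed header lines
carrying ``key=value`` metadata, followed by whitespace-separated numeric
columns ``q  intensity  [sigma]`` with q in inverse angstroms and intensity
in arbitrary units.  The same dialect is written by the synthetic generator
and consumed by the reduction stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: metadata keys the dialect understands; anything else is a per-line error
KNOWN_META_KEYS = {
    "temperature_C",
    "relative_humidity",
    "x_D2O",
    "wavelength_A",
    "label",
    "seed",
    "warning",
}

_FLOAT_KEYS = {"temperature_C", "relative_humidity", "x_D2O", "wavelength_A"}


@dataclass
class Diffractogram:
    """One background-subtractable 1D scan.

    Attributes
    ----------
    q : ndarray
        Strictly increasing scattering-vector grid (1/angstrom).
    intensity : ndarray
        Scattered intensity (a.u.); may be slightly negative after
        background subtraction.
    sigma : ndarray or None
        Per-point standard uncertainties (a.u.), strictly positive.
    meta : dict
        Condition metadata (temperature_C, relative_humidity, x_D2O,
        wavelength_A, label, ...).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or len(self.q) < 2:
            raise ValueError("q must be a 1D grid with at least 2 points")
        if np.any(np.diff(self.q) <= 0):
            i = int(np.argmax(np.diff(self.q) <= 0))
            raise ValueError(f"q grid not strictly increasing at index {i + 1}")
        if len(self.intensity) != len(self.q):
            raise ValueError("q and intensity lengths differ")
        if self.sigma is not None:
            if len(self.sigma) != len(self.q):
                raise ValueError("q and sigma lengths differ")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma values must be strictly positive")
        x = self.meta.get("x_D2O")
        if x is not None and not (0.0 <= float(x) <= 1.0):
            raise ValueError(f"x_D2O={x} outside [0, 1]")

    def copy(self) -> "Diffractogram":
        return Diffractogram(
            self.q.copy(),
            self.intensity.copy(),
            None if self.sigma is None else self.sigma.copy(),
            dict(self.meta),
        )


def read_diffractogram(path: str | Path) -> Diffractogram:
    """Read a diffractogram file, validating grid monotonicity and metadata.

    A missing sigma column is synthesized as ``sqrt(max(intensity, 1))``
    (counting-statistics placeholder) with a warning.
    """
    path = Path(path)
    meta: dict = {}
    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if not body or "=" not in body:
                    continue
                key, _, val = body.partition("=")
                key, val = key.strip(), val.strip()
                if key not in KNOWN_META_KEYS:
                    raise ValueError(
                        f"{path.name}:{lineno}: unknown metadata key {key!r} "
                        f"(known: {sorted(KNOWN_META_KEYS)})"
                    )
                meta[key] = float(val) if key in _FLOAT_KEYS else val
                continue
            parts = line.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric data row {line!r}"
                ) from None
            if len(vals) not in (2, 3):
                raise ValueError(
                    f"{path.name}:{lineno}: expected 2 or 3 columns, got {len(vals)}"
                )
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise ValueError(f"{path.name}:{lineno}: inconsistent column count")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path.name}: no data rows")
    arr = np.array(rows)
    q, intensity = arr[:, 0], arr[:, 1]
    if np.any(np.diff(q) <= 0):
        bad = int(np.argmax(np.diff(q) <= 0)) + 1
        raise ValueError(f"{path.name}: q not strictly increasing at data row {bad + 1}")
    if arr.shape[1] == 3:
        sigma = arr[:, 2]
    else:
        warnings.warn(
            f"{path.name}: no sigma column; synthesizing sqrt(max(I, 1))",
            stacklevel=2,
        )
        sigma = np.sqrt(np.maximum(intensity, 1.0))
    return Diffractogram(q, intensity, sigma, meta)


def write_diffractogram(d: Diffractogram, path: str | Path) -> None:
    """Write the exact dialect consumed by :func:`read_diffractogram`."""
    path = Path(path)
    with open(path, "w") as fh:
        for key in sorted(d.meta):
            if key in KNOWN_META_KEYS:
                fh.write(f"# {key}={d.meta[key]}\n")
        for i in range(len(d.q)):
            if d.sigma is not None:
                fh.write(f"{d.q[i]:.8g} {d.intensity[i]:.10g} {d.sigma[i]:.10g}\n")
            else:
                fh.write(f"{d.q[i]:.8g} {d.intensity[i]:.10g}\n")


def write_truth(params: dict, path: str | Path) -> None:
    """Sidecar key=value truth file recording generator ground truth."""
    with open(path, "w") as fh:
        for key in sorted(params):
            fh.write(f"{key}={params[key]!r}\n")


def read_truth(path: str | Path) -> dict:
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or "=" not in line:
                continue
            key, _, val = line.partition("=")
            try:
                out[key.strip()] = float(val)
            except ValueError:
                out[key.strip()] = val.strip().strip("'\"")
    return out


def write_profile(z: np.ndarray, rho: np.ndarray, path: str | Path, meta: dict | None = None) -> None:
    """Two-column ASCII (z, rho) profile with '#' metadata header."""
    with open(path, "w") as fh:
        for key in sorted(meta or {}):
            fh.write(f"# {key}={(meta or {})[key]}\n")
        for zi, ri in zip(z, rho):
            fh.write(f"{zi:.6g} {ri:.10g}\n")


def read_profile(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a (z, rho) profile file written by :func:`write_profile`."""
    meta: dict = {}
    z, rho = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            a, b = line.split()[:2]
            z.append(float(a))
            rho.append(float(b))
    return np.array(z), np.array(rho), meta
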