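"""End-to-end orchestration: read -> subtract -> fit -> index -> phase ->
reconstruct -> parameters -> report, over a set of measurement conditions.

A condition is one sample state (temperature / relative humidity) measured
at one or more D2O contrasts.  Conditions with a full contrast series get
phased and reconstructed; single-contrast conditions need a user-supplied
phase vector; non-lamellar or under-determined conditions are reported
lattice-only (class and lattice constants, parameters marked unavailable),
never silently degraded.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import read_diffractogram, write_profile
from .parameters import BilayerParameters, VolumeSet, bilayer_parameters
from .phasing import PhaseAssignment, assign_phases, lorentz_correct
from .reconstruction import reconstruct_nsld
from .reduction import (
    auto_exclusion_windows,
    classify_phase,
    fit_peaks,
    index_lattice,
    subtract_background,
)

logger = logging.getLogger("lamdiff")

PARAM_ROWS = ("D", "D_B", "two_Dc", "D_w", "n_w")


@dataclass
class RunConfig:
    """Configuration of a multi-condition analysis run."""

    conditions: dict[str, list[str]]  # label -> diffractogram file paths
    background: str = "linear"
    tolerance: float = 0.01
    lorentz_exponent: float = 1.0
    reference_x: float = 0.08
    grid_step: float = 0.1
    volumes: VolumeSet = field(default_factory=VolumeSet)
    outdir: str | None = None
    seed: int = 0
    phase_override: dict | None = None  # order -> +/-1, for 1-contrast runs
    meta_overrides: dict = field(default_factory=dict)  # path -> {key: value}

    def __post_init__(self) -> None:
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        for label, files in self.conditions.items():
            for f in files:
                if not Path(f).exists():
                    raise FileNotFoundError(f"condition {label!r}: missing file {f}")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "conditions": self.conditions,
                "background": self.background,
                "tolerance": self.tolerance,
                "lorentz_exponent": self.lorentz_exponent,
                "reference_x": self.reference_x,
                "grid_step": self.grid_step,
                "volumes": [self.volumes.V_l, self.volumes.V_c, self.volumes.V_w],
                "seed": self.seed,
                "phase_override": self.phase_override,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ConditionResult:
    label: str
    phase_class: str
    lattices: list  # of reduction.Lattice
    parameters: BilayerParameters | None
    notes: list[str] = field(default_factory=list)

    @property
    def D(self) -> float | None:
        return self.lattices[0].D if self.lattices else None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "phase_class": self.phase_class,
            "lattices": [{"D": lat.D, "D_se": lat.D_se, "kind": lat.kind} for lat in self.lattices],
            "parameters": None if self.parameters is None else self.parameters.to_dict(),
            "notes": self.notes,
        }


def _reduce_one(path: str, cfg: RunConfig):
    d = read_diffractogram(path)
    d.meta.update(cfg.meta_overrides.get(str(path), {}))
    excl = auto_exclusion_windows(d)
    if excl:
        d = subtract_background(d, method=cfg.background, exclusion=excl)
    peaks = fit_peaks(d)
    assignment = index_lattice(peaks, tolerance=cfg.tolerance)
    return d, peaks, assignment


def run_condition(cfg: RunConfig, label: str) -> ConditionResult:
    """Analyse one condition end to end; writes artifacts if cfg.outdir set."""
    files = cfg.conditions[label]
    notes: list[str] = []
    outdir = None
    if cfg.outdir:
        outdir = Path(cfg.outdir) / label
        outdir.mkdir(parents=True, exist_ok=True)

    reduced = {}
    for path in files:
        d, peaks, assignment = _reduce_one(path, cfg)
        x = float(d.meta.get("x_D2O", np.nan))
        reduced[path] = (d, peaks, assignment, x)
        if outdir:
            peaks.to_json(outdir / (Path(path).stem + ".peaks.json"))
            assignment.to_json(outdir / (Path(path).stem + ".lattice.json"))

    # classify on the reference contrast (or the first file)
    ref_path = files[0]
    for path, (_, _, _, x) in reduced.items():
        if np.isclose(x, cfg.reference_x, atol=1e-6):
            ref_path = path
            break
    _, ref_peaks, ref_assign, _ = reduced[ref_path]
    phase_class, rationale = classify_phase(ref_assign)
    notes.append(f"phase classification: {phase_class} ({rationale})")

    if phase_class != "lamellar":
        notes.append("parameters unavailable: non-lamellar or coexisting lattice")
        result = ConditionResult(label, phase_class, ref_assign.lattices, None, notes)
        _write_result(result, outdir, cfg)
        return result

    usable_orders = sorted({p.order for p in ref_peaks if p.order is not None})
    if len(usable_orders) < 2:
        notes.append(
            f"parameters unavailable: only {len(usable_orders)} usable Bragg order(s); "
            "lattice-only report"
        )
        result = ConditionResult(label, phase_class, ref_assign.lattices, None, notes)
        _write_result(result, outdir, cfg)
        return result

    D_ref = ref_assign.lattices[0].D
    lamellar = {}
    for path, (_, peaks, assign, x) in reduced.items():
        if assign.phase_class != "lamellar" or not np.isfinite(x):
            notes.append(f"{path}: excluded from contrast series (not lamellar)")
            continue
        if abs(assign.lattices[0].D - D_ref) / D_ref > 2 * cfg.tolerance:
            notes.append(f"{path}: excluded (lattice constant inconsistent with reference)")
            continue
        lamellar[x] = peaks
    sf = lorentz_correct(lamellar, ref_assign, p=cfg.lorentz_exponent)
    if cfg.phase_override is not None:
        phases = PhaseAssignment(
            nu={int(k): int(v) for k, v in cfg.phase_override.items()},
            fits={},
            reference_fraction=cfg.reference_x,
        )
        notes.append("phases: user-supplied vector")
    elif len(sf.fractions) >= 2:
        phases = assign_phases(sf, reference_fraction=cfg.reference_x)
        notes.append(
            "phases from contrast linearity: "
            + ", ".join(f"{n}:{'+' if phases.nu[n] > 0 else '-'}" for n in sorted(phases.nu))
        )
    else:
        notes.append(
            "parameters unavailable: single contrast and no phase vector supplied"
        )
        result = ConditionResult(label, phase_class, ref_assign.lattices, None, notes)
        _write_result(result, outdir, cfg)
        return result

    profile = reconstruct_nsld(sf, phases, grid_step=cfg.grid_step, x_D2O=cfg.reference_x)
    params = bilayer_parameters(
        D=ref_assign.lattices[0].D,
        D_se=ref_assign.lattices[0].D_se,
        profile=profile,
        vols=cfg.volumes,
        meta={"label": label, "x_D2O": cfg.reference_x, "M": profile.M},
    )
    result = ConditionResult(label, phase_class, ref_assign.lattices, params, notes)
    if outdir:
        sf.to_csv(outdir / "structure_factors.csv")
        with open(outdir / "phases.json", "w") as fh:
            json.dump(phases.to_json_dict(), fh, indent=1)
        write_profile(
            profile.z, profile.rho, outdir / "nsld_profile.txt",
            meta={"label": label, "x_D2O": cfg.reference_x},
        )
    _write_result(result, outdir, cfg)
    return result


def _write_result(result: ConditionResult, outdir: Path | None, cfg: RunConfig) -> None:
    for note in result.notes:
        logger.info("[%s] %s", result.label, note)
    if outdir:
        with open(outdir / "result.json", "w") as fh:
            json.dump(
                result.to_dict()
                | {"lamdiff_version": __version__, "config_hash": cfg.config_hash(), "seed": cfg.seed},
                fh,
                indent=1,
            )


def run_report(results: list[ConditionResult]) -> pd.DataFrame:
    """Condition-by-parameter table (rows D, D_B, 2D_c, D_w, n_w).

    Cells are "value +/- SE" rounded to 0.1; empty where a parameter was
    unavailable (lattice-only conditions keep their D).
    """
    if not results:
        raise ValueError("no completed conditions")
    table = {}
    for res in results:
        col = {}
        if res.parameters is not None:
            p = res.parameters
            for row in PARAM_ROWS:
                col[row] = f"{getattr(p, row):.1f} ± {getattr(p, row + '_se'):.1f}"
        elif res.lattices:
            for i, lat in enumerate(res.lattices):
                key = "D" if i == 0 else f"D({i + 1})"
                col[key] = f"{lat.D:.1f} ± {lat.D_se:.1f}"
        table[res.label] = col
    df = pd.DataFrame(table)
    idx = [r for r in PARAM_ROWS if r in df.index] + [
        r for r in df.index if r not in PARAM_ROWS
    ]
    return df.reindex(idx)


def report_to_json(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump({c: df[c].dropna().to_dict() for c in df.columns}, fh, indent=1)


def report_from_json(path) -> pd.DataFrame:
    with open(path) as fh:
        data = json.load(fh)
    df = pd.DataFrame(data)
    idx = [r for r in PARAM_ROWS if r in df.index] + [
        r for r in df.index if r not in PARAM_ROWS
    ]
    return df.reindex(idx)
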