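"""Factorial sweep runner and report helpers.

Runs the simulator and the edge-metrics chain over a grid of
(kernel, QIR level, dose, tube diameter, iodine concentration, seed)
cells, collects one long-format row per cell, and pivots/summarises the
results: per-kernel slope plateaus relative to a reference kernel and
per-dose slope-score grids.

The full factorial of the phantom experiment is 10 kernels x 3 QIR
levels x 6 doses x 5 diameters x 5 concentrations; the default
desk-scale configuration subsamples it (3 x 3 x 2 x 2 x 3) so a sweep
runs in seconds.  The noise-free blurred slice is cached per
(kernel, diameter, concentration), so extra seeds only cost a noise
synthesis and an analysis each.  With an ``output_dir`` the sweep is
resumable: finished cells are stored as JSON and skipped on rerun.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .edge_metrics import analyze_image
from .kernel_model import AcquisitionSpec, KernelSpec, kernel_from_table
from .phantom_sim import GridSpec, PhantomSpec, simulate_noise_free, simulate_slice

__all__ = [
    "SweepConfig",
    "SweepResult",
    "run_sweep",
    "plateau_summary",
    "PlateauSummary",
    "score_grid",
    "default_desk_config",
    "full_study_config",
]

_ROW_METRICS = ("noise_sd", "amplitude", "mean_slope_maximum", "slope_score")


@dataclass(frozen=True)
class SweepConfig:
    """Factor lists of a sweep; the cell set is their Cartesian product."""

    kernels: tuple[KernelSpec, ...]
    qir_levels: tuple[int, ...] = (2, 3, 4)
    ctdis: tuple[float, ...] = (1.0, 3.0)
    diameters: tuple[float, ...] = (1.0, 3.0)
    concentrations: tuple[float, ...] = (0.0, 9.25, 37.0)
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    output_dir: Path | None = None
    grid: GridSpec = GridSpec()

    def __post_init__(self) -> None:
        for name in ("kernels", "qir_levels", "ctdis", "diameters", "concentrations", "seeds"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")

    @property
    def n_cells(self) -> int:
        return (
            len(self.kernels)
            * len(self.qir_levels)
            * len(self.ctdis)
            * len(self.diameters)
            * len(self.concentrations)
            * len(self.seeds)
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "SweepConfig":
        kernels = tuple(
            k if isinstance(k, KernelSpec) else kernel_from_table(str(k))
            for k in d["kernels"]
        )
        out = d.get("output_dir")
        return cls(
            kernels=kernels,
            qir_levels=tuple(int(q) for q in d.get("qir_levels", (2, 3, 4))),
            ctdis=tuple(float(c) for c in d.get("ctdis", (1.0, 3.0))),
            diameters=tuple(float(x) for x in d.get("diameters", (1.0, 3.0))),
            concentrations=tuple(float(c) for c in d.get("concentrations", (0.0, 9.25, 37.0))),
            seeds=tuple(int(s) for s in d.get("seeds", (0, 1, 2, 3, 4))),
            output_dir=Path(out) if out else None,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SweepConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_desk_config(**overrides) -> SweepConfig:
    """Desk-scale sweep: 3 kernels x 3 QIR x 2 doses x 2 diameters x 3 concentrations."""
    base = dict(
        kernels=tuple(kernel_from_table(k) for k in ("Qr44", "Qr60", "Qr72")),
        qir_levels=(2, 3, 4),
        ctdis=(1.0, 3.0),
        diameters=(1.0, 3.0),
        concentrations=(0.0, 9.25, 37.0),
        seeds=(0, 1, 2, 3, 4),
    )
    base.update(overrides)
    return SweepConfig(**base)


def full_study_config(**overrides) -> SweepConfig:
    """The full factorial of the phantom experiment (4500 cells at 1 seed)."""
    table_names = ("Qr36", "Qr40", "Qr44", "Qr48", "Qr56", "Qr60", "Qr64", "Qr68", "Qr72", "Qr76")
    base = dict(
        kernels=tuple(kernel_from_table(k) for k in table_names),
        qir_levels=(2, 3, 4),
        ctdis=(1.0, 2.0, 3.0, 4.0, 10.0, 30.0),
        diameters=(1.0, 2.0, 3.0, 4.0, 5.0),
        concentrations=(0.0, 4.63, 9.25, 18.5, 37.0),
        seeds=(0,),
    )
    base.update(overrides)
    return SweepConfig(**base)


@dataclass
class SweepResult:
    """Long-format sweep table: one row per factor-combination cell."""

    table: pd.DataFrame
    config: SweepConfig

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _cell_key(kernel: KernelSpec, qir: int, ctdi: float, d: float, conc: float, seed: int) -> str:
    payload = json.dumps(
        [kernel.name, kernel.rho50, kernel.rho10, qir, ctdi, d, conc, seed],
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def run_sweep(config: SweepConfig) -> SweepResult:
    """Simulate and analyse every cell of the factor grid.

    Deterministic given the seed list.  Per-cell failures are recorded in
    an ``error`` column instead of aborting the sweep.  When
    ``config.output_dir`` is set, each finished cell is written as a JSON
    file named by a content hash of its parameters, and cells already on
    disk are loaded instead of recomputed.
    """
    out_dir = config.output_dir
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    for kernel in config.kernels:
        for d in config.diameters:
            for conc in config.concentrations:
                phantom = PhantomSpec(inner_diameter=d, iodine_concentration=conc)
                base = None  # noise-free slice, shared across qir/ctdi/seed
                for qir in config.qir_levels:
                    for ctdi in config.ctdis:
                        acq = AcquisitionSpec(ctdi=ctdi, qir_level=qir)
                        for seed in config.seeds:
                            row = {
                                "kernel": kernel.name,
                                "sharpness": kernel.sharpness_level,
                                "qir": qir,
                                "ctdi": ctdi,
                                "diameter": d,
                                "concentration": conc,
                                "seed": seed,
                                "error": "",
                            }
                            cache = (
                                out_dir / f"{_cell_key(kernel, qir, ctdi, d, conc, seed)}.json"
                                if out_dir is not None
                                else None
                            )
                            if cache is not None and cache.exists():
                                row.update(json.loads(cache.read_text()))
                                rows.append(row)
                                continue
                            try:
                                if base is None:
                                    base = simulate_noise_free(phantom, kernel, config.grid)
                                img = simulate_slice(
                                    phantom, kernel, acq, seed, grid=config.grid,
                                    _noise_free_image=base,
                                )
                                metrics = analyze_image(img, phantom).to_row()
                            except Exception as exc:  # pragma: no cover - defensive
                                row["error"] = f"{type(exc).__name__}: {exc}"
                                metrics = {m: np.nan for m in _ROW_METRICS}
                            row.update(metrics)
                            if cache is not None and not row["error"]:
                                cache.write_text(json.dumps(metrics))
                            rows.append(row)
    table = pd.DataFrame(rows)
    return SweepResult(table=table, config=config)


@dataclass
class PlateauSummary:
    """Per-kernel slope maxima relative to a reference kernel."""

    per_kernel: pd.DataFrame  # kernel, mean_slope_maximum, rel_diff_pct
    reference_kernel: str
    threshold_pct: float
    plateau_kernels: tuple[str, ...]  # kernels within threshold of the reference

    def rel_diff(self, kernel: str) -> float:
        row = self.per_kernel.set_index("kernel")
        return float(row.loc[kernel, "rel_diff_pct"])


def plateau_summary(
    result: "SweepResult | pd.DataFrame | Mapping[str, float] | pd.Series",
    reference_kernel: str,
    threshold_pct: float = 10.0,
) -> PlateauSummary:
    """Summarise per-kernel mean slope maxima against a reference kernel.

    Accepts a sweep result, a long-format table with ``kernel`` and
    ``mean_slope_maximum`` columns, or a plain kernel -> slope mapping
    (e.g. the published slope column).  Relative differences are percent
    of the reference value (unrounded); ``plateau_kernels`` lists every
    kernel whose |relative difference| is strictly below the threshold.
    """
    if isinstance(result, SweepResult):
        slopes = result.table.groupby("kernel")["mean_slope_maximum"].mean()
    elif isinstance(result, pd.DataFrame):
        slopes = result.groupby("kernel")["mean_slope_maximum"].mean()
    elif isinstance(result, pd.Series):
        slopes = result.astype(float)
    else:
        slopes = pd.Series({str(k): float(v) for k, v in result.items()})
    if reference_kernel not in slopes.index:
        raise KeyError(f"reference kernel {reference_kernel!r} not present")
    ref = float(slopes[reference_kernel])
    rel = 100.0 * (slopes - ref) / ref
    per_kernel = pd.DataFrame(
        {
            "kernel": slopes.index,
            "mean_slope_maximum": slopes.values,
            "rel_diff_pct": rel.values,
        }
    ).reset_index(drop=True)
    plateau = tuple(slopes.index[np.abs(rel.values) < threshold_pct])
    return PlateauSummary(
        per_kernel=per_kernel,
        reference_kernel=reference_kernel,
        threshold_pct=threshold_pct,
        plateau_kernels=plateau,
    )


def score_grid(
    result: SweepResult | pd.DataFrame, output_dir: str | Path | None = None
) -> dict[float, pd.DataFrame]:
    """Per-dose slope-score grids: (kernel, qir) rows x (diameter, concentration).

    Scores are aggregated across seeds by median.  With ``output_dir``
    each grid is also written as ``slope_scores_ctdi_<dose>.csv``.
    """
    table = result.table if isinstance(result, SweepResult) else result
    grids: dict[float, pd.DataFrame] = {}
    for ctdi, sub in table.groupby("ctdi"):
        grid = sub.pivot_table(
            index=["kernel", "qir"],
            columns=["diameter", "concentration"],
            values="slope_score",
            aggfunc="median",
        )
        grids[float(ctdi)] = grid
        if output_dir is not None:
            out = Path(output_dir)
            out.mkdir(parents=True, exist_ok=True)
            grid.to_csv(out / f"slope_scores_ctdi_{ctdi:g}.csv")
    return grids
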