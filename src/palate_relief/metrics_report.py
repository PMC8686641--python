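"""Stress-distribution volumes and relief/no-relief ratio reporting.

The study's core metric is the mucosa volume within which the von Mises
stress reaches each threshold or higher ("stress-distribution volume"),
accumulated from the piecewise-constant element stresses.  Ratios are
expressed in percent with the no-relief model as 100%.  Both the
cumulative ("or higher") representation and disjoint per-bin volumes are
computed and written, since either reading of a binned distribution plot
can be wanted downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .meshgen import TetMesh, PART_MUCOSA
from .elastic_fem import StressField
from . import mesh_io

__all__ = [
    "VolumeDistribution",
    "ScenarioResult",
    "StudyReport",
    "UndefinedRatioError",
    "stress_volume_distribution",
    "volume_ratio",
    "build_ratio_table",
    "render_report",
]


class UndefinedRatioError(ZeroDivisionError):
    """Ratio requested against a zero baseline volume."""


@dataclass(frozen=True)
class VolumeDistribution:
    """Mucosa volume (mm^3) at or above each stress threshold (MPa).

    ``cumulative[i]`` is the volume with von Mises >= ``thresholds[i]``;
    ``bins`` holds the disjoint volumes in ``[0, t_0), [t_0, t_1), ...,
    [t_last, inf)`` (one more entry than thresholds), which sum to
    ``total_volume``.
    """

    thresholds: tuple[float, ...]
    cumulative: tuple[float, ...]
    bins: tuple[float, ...]
    total_volume: float

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds)
        if len(t) == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be a non-empty strictly ascending list")
        if len(self.cumulative) != len(t) or len(self.bins) != len(t) + 1:
            raise ValueError("inconsistent distribution lengths")

    def volume_at_or_above(self, threshold: float) -> float:
        """Cumulative volume at a threshold that is in the grid."""
        t = np.asarray(self.thresholds)
        i = np.flatnonzero(np.isclose(t, threshold, rtol=0, atol=1e-12))
        if len(i) == 0:
            raise KeyError(f"threshold {threshold} not in distribution grid {t}")
        return self.cumulative[int(i[0])]


def stress_volume_distribution(
    stress: StressField, mesh: TetMesh, thresholds: Sequence[float]
) -> VolumeDistribution:
    """Accumulate mucosa element volumes by von Mises value.

    Plate elements are excluded; thresholds must be strictly ascending.
    """
    t = np.asarray(thresholds, dtype=float)
    if len(t) == 0 or np.any(np.diff(t) <= 0):
        raise ValueError(f"thresholds must be strictly ascending, got {thresholds}")
    mucosa = mesh.part == PART_MUCOSA
    if not mucosa.any():
        raise ValueError("mesh has no mucosa elements")
    vols = mesh.volumes()[mucosa]
    vm = stress.vm[mucosa]
    total = float(vols.sum())
    cumulative = tuple(float(vols[vm >= ti].sum()) for ti in t)
    edges = np.concatenate([[0.0], t, [np.inf]])
    bins = tuple(
        float(vols[(vm >= lo) & (vm < hi)].sum())
        for lo, hi in zip(edges[:-1], edges[1:])
    )
    return VolumeDistribution(
        thresholds=tuple(float(v) for v in t),
        cumulative=cumulative,
        bins=bins,
        total_volume=total,
    )


def volume_ratio(
    d: VolumeDistribution, baseline: VolumeDistribution, threshold: float
) -> float:
    """Percent of baseline stress-distribution volume at a threshold.

    ``100 * V_d(>= threshold) / V_baseline(>= threshold)``; a zero baseline
    volume makes the ratio undefined and raises, so tables report it as
    not-applicable rather than silently zero.
    """
    base = baseline.volume_at_or_above(threshold)
    if base <= 0:
        raise UndefinedRatioError(
            f"baseline volume at threshold {threshold} MPa is zero; ratio undefined"
        )
    return 100.0 * (d.volume_at_or_above(threshold) / base)


def build_ratio_table(
    distributions: Mapping[str, VolumeDistribution], baseline_name: str = "no_relief"
) -> pd.DataFrame:
    """Scenario x threshold table of percent ratios (baseline = 100).

    Undefined entries (zero baseline volume) are NaN and rendered as
    ``n/a`` in CSV output.
    """
    baseline = distributions[baseline_name]
    thresholds = baseline.thresholds
    rows = {}
    for name, d in distributions.items():
        if d.thresholds != thresholds:
            raise ValueError(f"scenario {name!r} uses a different threshold grid")
        row = []
        for t in thresholds:
            try:
                row.append(volume_ratio(d, baseline, t))
            except UndefinedRatioError:
                row.append(np.nan)
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(thresholds))
    table.index.name = "scenario"
    return table


@dataclass
class ScenarioResult:
    """Everything computed for one study scenario."""

    name: str
    mesh: TetMesh
    displacement: "object"  # DisplacementField
    stress: StressField
    distribution: VolumeDistribution
    relieved_footprint_area: float = 0.0


@dataclass
class StudyReport:
    """Full multi-scenario study output.

    ``scenarios`` maps scenario name to its result (meshes, fields,
    distributions), ``ratios`` is the percent table with the no-relief row
    exactly 100 wherever the baseline volume is nonzero, and ``provenance``
    records the resolved configuration, seed and mesh statistics.
    """

    scenarios: dict[str, ScenarioResult]
    ratios: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def distributions(self) -> dict[str, VolumeDistribution]:
        return {n: s.distribution for n, s in self.scenarios.items()}


def _CSV_FLOAT(v) -> str:
    # repr of a Python float round-trips exactly and is deterministic
    return repr(float(v))


def render_report(report: StudyReport, outdir: str | os.PathLike) -> list[str]:
    """Write the report: ratio CSV, distribution CSV, VTU maps, one plot.

    Returns the list of files written.  Output is deterministic for fixed
    inputs (full-precision CSV floats, fixed column order).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    written = []

    ratio_path = os.path.join(outdir, "ratios.csv")
    # threshold columns as plain strings so the formatter only touches data
    report.ratios.rename(columns=lambda c: f"{c:g}").to_csv(
        ratio_path, float_format=_CSV_FLOAT, na_rep="n/a"
    )
    written.append(ratio_path)

    rows = []
    for name, d in report.distributions.items():
        for i, t in enumerate(d.thresholds):
            rows.append(
                {
                    "scenario": name,
                    "threshold_mpa": t,
                    "cumulative_volume_mm3": d.cumulative[i],
                    "bin_volume_mm3": d.bins[i + 1],
                }
            )
    dist_path = os.path.join(outdir, "distributions.csv")
    pd.DataFrame(rows).to_csv(dist_path, index=False, float_format=_CSV_FLOAT)
    written.append(dist_path)

    for name, res in report.scenarios.items():
        path = os.path.join(outdir, f"{name}.vtu")
        mesh_io.write_mesh(res.mesh, path, cell_data={"von_mises": res.stress.vm})
        written.append(path)

    fig, ax = plt.subplots(figsize=(6.0, 4.0))
    for name, d in report.distributions.items():
        ax.plot(d.thresholds, d.cumulative, marker="o", ms=3, label=name)
    ax.set_xlabel("von Mises stress threshold (MPa)")
    ax.set_ylabel("mucosa volume at or above threshold (mm$^3$)")
    ax.set_yscale("log")
    ax.legend(fontsize=7)
    fig.tight_layout()
    plot_path = os.path.join(outdir, "distribution_plot.png")
    fig.savefig(plot_path, dpi=130)
    plt.close(fig)
    written.append(plot_path)
    return written
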