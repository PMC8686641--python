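"""Borderline-based selective relief of a palatal plate.

Relief is the deliberate gap (here 0.25 mm) left between a plate's
tissue-facing surface and the mucosa so that a region transmits no load.
This module implements three designs and the driver that compares them:

* **no relief** — plate bonded to the mucosa everywhere (the baseline);
* **borderline relief** — the no-relief model is solved once, every
  interface region whose adjacent mucosa reaches a cutoff ("borderline")
  von Mises stress or more is relieved, and the relieved model is
  re-solved.  Selection is single-pass: regions always come from the
  no-relief stress field, never from a post-relief field;
* **mid-palatal relief** — the conventional 10 mm wide strip along the
  palate midline.

Mechanically, relief is realised by decoupling the bonded interface over
the selected facets: interface nodes are duplicated so plate and mucosa
deform independently there.  In a linear bonded model with an open gap no
force crosses a relieved area, so decoupling is equivalent to trimming the
plate while keeping every scenario on the same mesh (directly comparable
volumes).  A post-solve check warns when the mucosal bulge would close the
physical gap, the one situation where the equivalence breaks (contact is
not modelled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .palate_synth import PalateConfig, build_geometry, sample_thickness_map
from .meshgen import TetMesh, PART_MUCOSA, PART_PLATE, mesh_layered
from .elastic_fem import (
    BoundaryConditions,
    DisplacementField,
    MaterialParams,
    MUCOSA_DEFAULT,
    PLATE_RESIN,
    StressField,
    assemble_and_solve,
    make_load,
    recover_stress,
)
from .metrics_report import (
    ScenarioResult,
    StudyReport,
    build_ratio_table,
    stress_volume_distribution,
)

__all__ = [
    "ReliefSpec",
    "RegionMask",
    "StudyConfig",
    "select_relief_region",
    "apply_relief",
    "build_relief_region",
    "build_mid_palatal_region",
    "check_gap_closure",
    "run_study",
    "DEFAULT_BORDERLINES",
    "DEFAULT_REPORT_THRESHOLDS",
]

#: Borderline cutoffs swept by the study (MPa).
DEFAULT_BORDERLINES = (0.04, 0.06, 0.08, 0.10, 0.14)
#: Reporting grid spanning the stress range observed in the baseline model.
DEFAULT_REPORT_THRESHOLDS = (
    0.02, 0.04, 0.06, 0.08, 0.10, 0.12, 0.14, 0.16, 0.18, 0.20,
)


@dataclass(frozen=True)
class ReliefSpec:
    """One relief design: none, borderline-thresholded, or mid-palatal strip."""

    mode: str = "none"
    borderline: float | None = None  # MPa, mode="borderline" only
    depth: float = 0.25  # mm
    width: float = 10.0  # mm, mode="mid_palatal" only

    def __post_init__(self) -> None:
        if self.mode not in ("none", "borderline", "mid_palatal"):
            raise ValueError(f"unknown relief mode {self.mode!r}")
        if self.depth <= 0:
            raise ValueError(f"relief depth must be > 0, got {self.depth}")
        if self.width <= 0:
            raise ValueError(f"relief width must be > 0, got {self.width}")
        if self.mode == "borderline" and (self.borderline is None or self.borderline <= 0):
            raise ValueError("borderline mode requires a positive borderline stress")


@dataclass(frozen=True)
class RegionMask:
    """A set of interface facet ids selected for relief."""

    facet_ids: tuple[int, ...]
    footprint_area: float  # mm^2, projected onto the footprint plane

    def __len__(self) -> int:
        return len(self.facet_ids)

    @classmethod
    def from_ids(cls, mesh: TetMesh, ids: np.ndarray) -> "RegionMask":
        facets = mesh.interface_facets()
        ids = np.unique(np.asarray(ids, dtype=np.int64))
        if len(ids) and (ids.min() < 0 or ids.max() >= len(facets)):
            raise ValueError("facet ids outside the mesh's interface facet set")
        return cls(
            facet_ids=tuple(int(i) for i in ids),
            footprint_area=float(facets.footprint_area[ids].sum()),
        )


def select_relief_region(
    stress: StressField, mesh: TetMesh, borderline: float
) -> RegionMask:
    """Interface facets whose adjacent mucosa reaches the borderline stress.

    A facet is selected when the maximum von Mises stress over mucosa
    elements touching the facet (sharing at least one of its nodes) is at
    or above the borderline — a conservative projection from element
    stresses to the interface.  ``stress`` must be the no-relief field.
    """
    facets = mesh.interface_facets()
    mucosa = mesh.part == PART_MUCOSA
    node_max = np.zeros(mesh.n_nodes)
    np.maximum.at(
        node_max,
        mesh.tets[mucosa].ravel(),
        np.repeat(stress.vm[mucosa], 4),
    )
    facet_max = node_max[facets.tris].max(axis=1)
    ids = np.flatnonzero(facet_max >= borderline)
    return RegionMask.from_ids(mesh, ids)


def build_mid_palatal_region(mesh: TetMesh, width: float = 10.0) -> RegionMask:
    """Conventional relief strip of the given breadth along the midline."""
    facets = mesh.interface_facets()
    if len(facets) == 0:
        raise ValueError("mesh has no plate-mucosa interface")
    xs = mesh.nodes[np.unique(facets.tris), 0]
    footprint_width = float(xs.max() - xs.min())
    if width >= footprint_width:
        raise ValueError(
            f"strip width {width} mm exceeds the interface footprint width "
            f"{footprint_width:.3g} mm"
        )
    cx = np.abs(facets.centroid_xy[:, 0])
    ids = np.flatnonzero(cx <= width / 2.0)
    if len(ids) == 0:
        # width narrower than one facet row: take the facets hugging the midline
        ids = np.flatnonzero(cx <= cx.min() + 1e-9)
        warnings.warn(
            f"strip width {width} mm is narrower than one facet row; "
            f"relieving the single row nearest the midline instead",
            stacklevel=2,
        )
    return RegionMask.from_ids(mesh, ids)


def apply_relief(mesh: TetMesh, region: RegionMask, depth: float = 0.25) -> TetMesh:
    """Decouple the plate from the mucosa over the selected facets.

    Every interface node incident to a relieved facet is duplicated and all
    plate elements touching it are reconnected to the duplicate, so no
    force crosses the relieved region (tractions there are exactly zero).
    The decoupled zone therefore extends to the closure of the region —
    bonded facets sharing a node with the region lose that node's bond —
    which errs on the side of more relief.  Original node indices are
    preserved (duplicates are appended), keeping node sets and load
    definitions valid.  An empty region returns an unmodified copy.

    ``depth`` (mm) is the physical gap recorded for the post-solve
    gap-closure check (:func:`check_gap_closure`); it does not alter the
    mesh geometry.
    """
    if depth <= 0:
        raise ValueError(f"relief depth must be > 0, got {depth}")
    out = mesh.copy()
    if len(region) == 0:
        return out
    facets = mesh.interface_facets()
    ids = np.asarray(region.facet_ids, dtype=np.int64)
    dup = np.unique(facets.tris[ids])

    n_old = mesh.n_nodes
    remap = np.arange(n_old + len(dup), dtype=np.int64)
    remap[dup] = n_old + np.arange(len(dup))

    out.nodes = np.vstack([out.nodes, mesh.nodes[dup]])
    plate_rows = out.part == PART_PLATE
    out.tets[plate_rows] = remap[out.tets[plate_rows]]
    out.relief_pairs = np.column_stack([dup, remap[dup]])
    out.relieved_facets = ids.copy()
    out._facets = None
    out.validate()
    return out


def check_gap_closure(
    mesh: TetMesh, u: DisplacementField, depth: float = 0.25
) -> int:
    """Count relieved node pairs whose relative approach exceeds the gap.

    The relieved plate surface sits ``depth`` mm away from the mucosa; the
    linear model is valid while the mucosal bulge toward the plate stays
    below that.  Returns the number of violating pairs and warns when any
    exist (gap contact is not modelled).
    """
    if mesh.relief_pairs is None or len(mesh.relief_pairs) == 0:
        return 0
    orig, dupl = mesh.relief_pairs[:, 0], mesh.relief_pairs[:, 1]
    # approach = mucosa surface moving oralward (+z) relative to the plate
    approach = u.values[orig, 2] - u.values[dupl, 2]
    n_bad = int(np.sum(approach > depth))
    if n_bad:
        warnings.warn(
            f"{n_bad} relieved interface nodes bulge past the {depth} mm gap; "
            "gap closure (contact) is not modelled, results there are "
            "approximate",
            stacklevel=2,
        )
    return n_bad


def build_relief_region(
    mesh: TetMesh, spec: ReliefSpec, stress: StressField | None = None
) -> RegionMask:
    """Region for a relief design: empty, borderline-selected, or strip.

    ``stress`` (the no-relief field) is required for borderline mode.
    """
    if spec.mode == "none":
        return RegionMask(facet_ids=(), footprint_area=0.0)
    if spec.mode == "borderline":
        if stress is None:
            raise ValueError("borderline relief needs the no-relief stress field")
        return select_relief_region(stress, mesh, spec.borderline)
    return build_mid_palatal_region(mesh, spec.width)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the full multi-scenario relief study.

    Defaults follow the reference protocol: 111 N bite force applied at the
    plate centre, borderlines 0.04-0.14 MPa inside the (0.02, 0.20) MPa
    stress range, 0.25 mm relief depth and a 10 mm mid-palatal strip.  The
    study mesh resolution defaults to 1.5 mm on the synthetic geometry.
    """

    palate: PalateConfig = field(default_factory=PalateConfig)
    plate_material: MaterialParams = PLATE_RESIN
    mucosa_material: MaterialParams = MUCOSA_DEFAULT
    bite_force: float = 111.0  # N
    patch_radius: float = 3.0  # mm
    borderlines: tuple[float, ...] = DEFAULT_BORDERLINES
    stress_range: tuple[float, float] = (0.02, 0.20)  # MPa
    report_thresholds: tuple[float, ...] = DEFAULT_REPORT_THRESHOLDS
    relief_depth: float = 0.25  # mm
    mid_palatal_width: float = 10.0  # mm
    mesh_edge: float = 1.5  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bite_force <= 0:
            raise ValueError("bite_force must be > 0")
        if self.relief_depth <= 0 or self.mid_palatal_width <= 0:
            raise ValueError("relief depth and width must be > 0")
        lo, hi = self.stress_range
        if not lo < hi:
            raise ValueError("stress_range must be (low, high) with low < high")
        b = np.asarray(self.borderlines)
        if len(b) and np.any(np.diff(b) <= 0):
            raise ValueError("borderlines must be strictly increasing")
        if len(b) and (b[0] <= lo or b[-1] >= hi):
            raise ValueError(
                f"borderlines must lie strictly inside the stress range {self.stress_range}"
            )
        t = np.asarray(self.report_thresholds)
        if len(t) == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("report_thresholds must be strictly ascending")

    # -- (de)serialisation for YAML/JSON configs -----------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["palate"]["thickness_bounds"] = [list(b) for b in self.palate.thickness_bounds]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "palate" in d and not isinstance(d["palate"], PalateConfig):
            p = dict(d["palate"])
            if "thickness_bounds" in p:
                p["thickness_bounds"] = tuple(tuple(b) for b in p["thickness_bounds"])
            d["palate"] = PalateConfig(**p)
        for key in ("plate_material", "mucosa_material"):
            if key in d and not isinstance(d[key], MaterialParams):
                d[key] = MaterialParams(**d[key])
        for key in ("borderlines", "report_thresholds", "stress_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def materials(self) -> dict[str, MaterialParams]:
        return {"plate": self.plate_material, "mucosa": self.mucosa_material}


def _scenario_name(borderline: float) -> str:
    return f"borderline_{borderline:g}"


def run_study(config: StudyConfig | None = None) -> StudyReport:
    """Run the full relief comparison on the synthetic palate.

    Executes, in order: the no-relief baseline solve; one borderline-relief
    scenario per configured borderline, each selecting its region from the
    *baseline* stress field (single pass); and the mid-palatal strip
    scenario.  With the default borderline list that is 7 scenarios.
    Deterministic for a fixed config (the seed fixes the thickness map).
    """
    cfg = StudyConfig() if config is None else config
    thickness = sample_thickness_map(cfg.palate, cfg.seed)
    geometry = build_geometry(cfg.palate, thickness)
    mesh0 = mesh_layered(geometry, cfg.mesh_edge)

    def _solve(mesh: TetMesh, name: str):
        try:
            bc = make_load(mesh, cfg.bite_force, cfg.patch_radius)
            u = assemble_and_solve(mesh, cfg.materials, bc)
            s = recover_stress(mesh, cfg.materials, u)
            return u, s
        except Exception as exc:
            raise type(exc)(f"scenario {name!r}: {exc}") from exc

    scenarios: dict[str, ScenarioResult] = {}

    u0, s0 = _solve(mesh0, "no_relief")
    d0 = stress_volume_distribution(s0, mesh0, cfg.report_thresholds)
    scenarios["no_relief"] = ScenarioResult("no_relief", mesh0, u0, s0, d0, 0.0)

    for b in cfg.borderlines:
        name = _scenario_name(b)
        region = select_relief_region(s0, mesh0, b)
        mesh_b = apply_relief(mesh0, region, cfg.relief_depth)
        u_b, s_b = _solve(mesh_b, name)
        check_gap_closure(mesh_b, u_b, cfg.relief_depth)
        d_b = stress_volume_distribution(s_b, mesh_b, cfg.report_thresholds)
        scenarios[name] = ScenarioResult(
            name, mesh_b, u_b, s_b, d_b, region.footprint_area
        )

    region_mid = build_mid_palatal_region(mesh0, cfg.mid_palatal_width)
    mesh_m = apply_relief(mesh0, region_mid, cfg.relief_depth)
    u_m, s_m = _solve(mesh_m, "mid_palatal")
    check_gap_closure(mesh_m, u_m, cfg.relief_depth)
    d_m = stress_volume_distribution(s_m, mesh_m, cfg.report_thresholds)
    scenarios["mid_palatal"] = ScenarioResult(
        "mid_palatal", mesh_m, u_m, s_m, d_m, region_mid.footprint_area
    )

    ratios = build_ratio_table({n: s.distribution for n, s in scenarios.items()})
    provenance = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "thickness_map_mm": list(thickness.thickness),
        "mesh": {"n_nodes": mesh0.n_nodes, "n_tets": mesh0.n_tets},
        "max_von_mises_no_relief_mpa": float(s0.vm[mesh0.part == PART_MUCOSA].max()),
    }
    return StudyReport(scenarios=scenarios, ratios=ratios, provenance=provenance)
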