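"""End-to-end orchestration: phantom cohort -> centerlines -> profiles ->
plane fits -> cohort tables.

Each phantom specimen is processed structure by structure (the three canals
and the common crus; posterior and superior are rasterized together with the
crus so the junction, its skeleton branches and its adjacent-region section
artifacts are genuinely exercised).  All randomness (cohort jitter, damage
scores) derives from the single config seed; a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as ch
from . import cross_section as cs
from . import morphometry as mm
from .centerline import Centerline, SmoothingParams, extract_centerline
from .phantom import (CANAL_NAMES, PhantomSpec, cohort_specs, ground_truth,
                      rasterize)

log = logging.getLogger("canalmorph")

STRUCTURES = CANAL_NAMES + ("common_crus",)


@dataclass
class RunConfig:
    """Parameters of a cohort run.  Defaults follow the reference workflow:
    2 mm ROI, smoothing (0.8, 0.05, 100), inclusion thresholds <=2 bony /
    0 membranous.  The default voxel size is a reduced-resolution tier;
    0.015 mm reproduces the source-data resolution at ~16x the cost."""

    n_specimens: int = 31
    seed: int = 0
    voxel_size_mm: float = 0.03
    roi_mm: float = 2.0
    pixel_mm: float | None = None          # defaults to voxel size
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    spur_fraction: float = 0.1
    adjacency_threshold: float = 0.2
    bony_score_max: int = 2
    membranous_score_max: int = 0
    lateral_bulge_fraction: float = 0.29
    damage_probabilities: tuple = (0.75, 0.10, 0.08, 0.07)  # P(score 0..3)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0 or self.roi_mm <= 0:
            raise ValueError("voxel size and ROI must be positive")
        if not 0 <= self.adjacency_threshold <= 1:
            raise ValueError("adjacency threshold must lie in [0, 1]")


@dataclass
class SpecimenResult:
    specimen: int
    ok: bool = True
    error: str = ""
    centerlines: dict = field(default_factory=dict)   # (structure, comp) -> Centerline
    profiles: dict = field(default_factory=dict)      # structure -> ProfileSet
    planes: dict = field(default_factory=dict)        # (canal, comp) -> FitPlane
    angles: pd.DataFrame | None = None
    lengths: dict = field(default_factory=dict)       # (structure, comp) -> mm
    ground_truth: object = None
    scores: ch.QualityScores | None = None


def _draw_scores(rng: np.random.Generator, probs) -> ch.QualityScores:
    vals = rng.choice(4, size=len(ch.SECTIONS), p=np.asarray(probs))
    return ch.QualityScores(dict(zip(ch.SECTIONS, (int(v) for v in vals))))


def run_specimen(config: RunConfig, spec: PhantomSpec,
                 specimen_id: int = 0) -> SpecimenResult:
    """Process one phantom specimen through every stage."""
    result = SpecimenResult(specimen=specimen_id)
    try:
        spec = PhantomSpec(spec.canals, config.voxel_size_mm, spec.pad, spec.seed)
        result.ground_truth = ground_truth(spec)
        present = [c.name for c in spec.canals]
        has_crus = "common_crus" in present
        for structure in present:
            # centerlines come from the structure's own tube; sections are
            # extracted from the volume including the adjoining crus so that
            # junction frames genuinely show (and reject) adjacent regions
            vol_solo, gt = rasterize(spec.subset([structure]))
            if has_crus and structure in ("posterior", "superior"):
                vol_ctx, _ = rasterize(spec.subset([structure, "common_crus"]))
            else:
                vol_ctx = vol_solo
            for comp in ("bony", "membranous"):
                line = extract_centerline(
                    vol_solo, comp, gt.end_planes[(structure, comp)],
                    gt.ampulla_ends[structure], params=config.smoothing,
                    spur_fraction=config.spur_fraction, canal=structure)
                result.centerlines[(structure, comp)] = line
                result.lengths[(structure, comp)] = line.length_mm
            frames = cs.section_profile(
                vol_ctx, result.centerlines[(structure, "bony")],
                roi_mm=config.roi_mm, pixel_mm=config.pixel_mm,
                adjacency_threshold=config.adjacency_threshold)
            dist, flags = mm.perpendicular_distance_profile(
                result.centerlines[(structure, "bony")],
                result.centerlines[(structure, "membranous")],
                roi_mm=config.roi_mm)
            result.profiles[structure] = mm.profile_from_frames(
                structure, frames, dist, flags)
        for canal in [c for c in CANAL_NAMES if c in present]:
            prof = result.profiles[canal]
            crus_prof = result.profiles.get("common_crus")
            for comp in ("bony", "membranous"):
                areas = (prof.area_bony_mm2 if comp == "bony"
                         else prof.area_endo_mm2)
                areas = np.where(prof.valid, areas, np.nan)
                crus_line = crus_areas = None
                if has_crus and canal in ("posterior", "superior"):
                    crus_line = result.centerlines[("common_crus", comp)]
                    crus_areas = (crus_prof.area_bony_mm2 if comp == "bony"
                                  else crus_prof.area_endo_mm2)
                    crus_areas = np.where(crus_prof.valid, crus_areas, np.nan)
                pts, w, traversal = mm.assemble_fit_points(
                    result.centerlines[(canal, comp)], areas,
                    crus_line, crus_areas)
                result.planes[(canal, comp)] = mm.fit_plane_weighted(
                    pts, w, traversal, canal=canal, compartment=comp)
        result.angles = mm.angle_table(result.planes)
    except Exception as exc:       # a failed specimen must not sink the cohort
        log.exception("specimen %d failed", specimen_id)
        result.ok = False
        result.error = f"{type(exc).__name__}: {exc}"
    return result


@dataclass
class CohortResult:
    specimens: list[SpecimenResult]
    lengths: pd.DataFrame
    angles: pd.DataFrame
    length_table: pd.DataFrame
    angle_table: pd.DataFrame
    envelopes: dict               # (structure, quantity) -> CohortEnvelope
    average_centerlines: dict     # (structure, comp) -> Centerline
    provenance: dict


def run_cohort(config: RunConfig,
               specs: list[PhantomSpec] | None = None) -> CohortResult:
    """Generate (or accept) a phantom cohort and aggregate all statistics.

    Quality scores are drawn per specimen and section; sections failing the
    inclusion rule are dropped from cohort statistics for the respective
    compartment, as are failed specimens.
    """
    if specs is None:
        specs = cohort_specs(config.n_specimens, seed=config.seed,
                             voxel_size=config.voxel_size_mm,
                             lateral_bulge_fraction=config.lateral_bulge_fraction)
    rng = np.random.default_rng(config.seed + 7919)
    results = []
    for i, spec in enumerate(specs):
        res = run_specimen(config, spec, specimen_id=i)
        res.scores = _draw_scores(rng, config.damage_probabilities)
        results.append(res)
        log.info("specimen %d: %s", i, "ok" if res.ok else res.error)
    good = [r for r in results if r.ok]
    if not good:
        raise RuntimeError("every specimen failed; nothing to aggregate")

    def included(r, structure, comp):
        return ch.include_section(r.scores, structure, comp,
                                  config.bony_score_max,
                                  config.membranous_score_max)

    length_rows, angle_rows = [], []
    for r in good:
        for (structure, comp), L in r.lengths.items():
            if included(r, structure, comp):
                length_rows.append({"specimen": r.specimen, "structure": structure,
                                    "compartment": comp, "length_mm": L})
        for _, row in r.angles.iterrows():
            comp = row["compartment"]
            canals = (row["pair"].split("-") if comp != "bony-vs-membranous"
                      else [row["pair"]])
            comp_chk = "membranous" if comp != "bony" else "bony"
            if all(included(r, c, comp_chk) for c in canals):
                angle_rows.append({"specimen": r.specimen, **row})
    lengths = pd.DataFrame(length_rows)
    angles = pd.DataFrame(angle_rows)

    envelopes = {}
    for structure in STRUCTURES:
        for qty in ("area_endo_mm2", "area_peri_mm2", "area_bony_mm2",
                    "distance_mm", "ratio"):
            comp = "bony" if qty in ("area_peri_mm2", "area_bony_mm2") \
                else "membranous"
            profs = [getattr(r.profiles[structure], qty)
                     if qty != "ratio" else r.profiles[structure].ratio
                     for r in good
                     if structure in r.profiles and included(r, structure, comp)]
            if profs:
                envelopes[(structure, qty)] = ch.aggregate(profs)

    averages = {}
    for structure in STRUCTURES:
        for comp in ("bony", "membranous"):
            lines = [r.centerlines[(structure, comp)] for r in good
                     if (structure, comp) in r.centerlines
                     and included(r, structure, comp)]
            if lines:
                averages[(structure, comp)] = ch.average_centerline(lines)

    out = CohortResult(
        specimens=results,
        lengths=lengths,
        angles=angles,
        length_table=ch.summary_length_table(lengths) if len(lengths) else
        pd.DataFrame(),
        angle_table=ch.summary_angle_table(
            angles[angles.compartment != "bony-vs-membranous"])
        if len(angles) else pd.DataFrame(),
        envelopes=envelopes,
        average_centerlines=averages,
        provenance={"config": {k: (asdict(v) if hasattr(v, "__dataclass_fields__")
                                   else v)
                               for k, v in asdict(config).items()},
                    "n_requested": len(specs),
                    "n_succeeded": len(good)},
    )
    if config.out_dir:
        write_cohort(out, config.out_dir)
    return out


def write_cohort(result: CohortResult, out_dir: str | Path) -> None:
    """Write cohort tables, envelopes and provenance as CSV/JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.lengths.to_csv(out / "lengths.csv", index=False)
    result.angles.to_csv(out / "angles.csv", index=False)
    result.length_table.to_csv(out / "length_table.csv")
    result.angle_table.to_csv(out / "angle_table.csv")
    for (structure, qty), env in result.envelopes.items():
        env.to_frame().to_csv(out / f"envelope_{structure}_{qty}.csv",
                              index=False)
    for (structure, comp), line in result.average_centerlines.items():
        pd.DataFrame(line.points, columns=["x_mm", "y_mm", "z_mm"]).assign(
            percent=line.percent).to_csv(
            out / f"average_centerline_{structure}_{comp}.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(result.provenance,
                                                    indent=2, default=str))
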