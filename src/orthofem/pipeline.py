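"""End-to-end study orchestration: population -> H model -> DoE ->
sensitivity -> homogeneous comparison -> validation fixtures.

A single master seed spawns the substreams for anatomy generation, the
design of experiments and the synthetic validation surface, so any stage
is reproducible in isolation and re-running a config reproduces every
numeric output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import RigidTransform, crop_unaffected, export_colormap, icp_align, signed_distance
from .doe import (
    ComparisonResult,
    aggregate_population,
    compare_with_homogeneous,
    generate_osf_design,
    local_sensitivity,
    run_design,
)
from .fem import (
    DEFAULT_ADVANCEMENT,
    DEFAULT_IMPACTION,
    RegionStiffnessCache,
    homogeneous_model,
)
from .materials import DOE_STIFFNESS_RANGES, MaterialMap, homogeneous_materials
from .phantom import (
    LandmarkSet,
    PhantomConfig,
    generate_population,
    make_synthetic_postop_surface,
    skin_surface,
)
from .io import write_vtk_mesh, write_vtk_surface

log = logging.getLogger("orthofem")


class PipelineError(RuntimeError):
    """A study stage failed; the message names the stage and subject."""


@dataclass
class RunConfig:
    """Settings of one full study run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    materials: MaterialMap = field(default_factory=homogeneous_materials)
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DOE_STIFFNESS_RANGES)
    )
    advancement: float = DEFAULT_ADVANCEMENT
    impaction: float = DEFAULT_IMPACTION
    n_points: int = 25
    master_seed: int = 0
    validation_noise_sd: float = 0.0
    crop_threshold: float = 0.1
    output_dir: Path = Path("orthofem_run")
    log_level: str = "INFO"

    def derived_seeds(self) -> dict[str, int]:
        """Substream seeds spawned from the master seed (all < 2^31)."""
        state = np.random.SeedSequence(self.master_seed).generate_state(3)
        return {
            "anatomy": int(state[0] & 0x7FFFFFFF),
            "doe": int(state[1] & 0x7FFFFFFF),
            "validation": int(state[2] & 0x7FFFFFFF),
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "phantom_config" in data:
            kwargs["phantom"] = PhantomConfig.from_yaml(data.pop("phantom_config"))
        if "material_table" in data and data["material_table"]:
            kwargs["materials"] = MaterialMap.from_yaml(data.pop("material_table"))
        else:
            data.pop("material_table", None)
        if "ranges" in data:
            kwargs["ranges"] = {k: tuple(v) for k, v in data.pop("ranges").items()}
        if "output_dir" in data:
            kwargs["output_dir"] = Path(data.pop("output_dir"))
        kwargs.update(data)
        return cls(**kwargs)


@dataclass
class StudyResult:
    """In-memory results of :func:`run_full_study`."""

    population: list
    h_displacements: pd.DataFrame
    design: pd.DataFrame
    responses: list[pd.DataFrame]
    sensitivities: list[pd.DataFrame]
    sensitivity_table: pd.DataFrame
    comparison: ComparisonResult
    validation_summary: dict
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _landmark_frame(subject: int, landmarks: LandmarkSet, u: np.ndarray) -> pd.DataFrame:
    rows = []
    for name in landmarks.names():
        vec = u[landmarks.node(name)]
        rows.append(
            {
                "subject": subject,
                "landmark": name,
                "ux": vec[0],
                "uy": vec[1],
                "uz": vec[2],
                "total_mm": float(np.linalg.norm(vec)),
            }
        )
    return pd.DataFrame(rows)


def run_full_study(config: RunConfig) -> StudyResult:
    """Execute the whole study and write its artifact bundle.

    For each of the ``n_subjects`` phantoms: the homogeneous (H) model,
    the ``n_points``-point DoE and the 2*n_params+1 sensitivity solves.
    Population tables, comparison statistics, validation fixtures and a
    manifest (seeds, solve counts, file hashes) land under
    ``config.output_dir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.derived_seeds()
    t_start = time.time()
    stage = "population"
    subject = -1
    solves = {"h_model": 0, "design_points": 0, "sensitivity": 0}
    try:
        phantom_cfg = replace(config.phantom, anatomical_variation_seed=seeds["anatomy"])
        population = generate_population(phantom_cfg)
        log.info("built %d subjects in %.1fs", len(population), time.time() - t_start)

        stage = "doe_design"
        design = generate_osf_design(config.ranges, config.n_points, seed=seeds["doe"])
        design_frame = design.to_frame()
        design_frame.insert(0, "point", [f"DP{i + 1}" for i in range(design.n_points)])
        design_frame.to_csv(out / "design.csv", index=False)

        h_frames = []
        responses: list[pd.DataFrame] = []
        sensitivities: list[pd.DataFrame] = []
        for subject, (mesh, landmarks) in enumerate(population):
            sdir = out / "subjects" / f"s{subject}"
            sdir.mkdir(parents=True, exist_ok=True)
            cache = RegionStiffnessCache.for_materials(mesh, config.materials)

            stage = "h_model"
            field_h, _ = homogeneous_model(
                mesh, landmarks, config.materials,
                config.advancement, config.impaction, cache,
            )
            solves["h_model"] += 1
            h_frames.append(_landmark_frame(subject, landmarks, field_h.u))
            write_vtk_mesh(mesh, sdir / "mesh.vtk", point_vectors={"u": field_h.u})
            landmarks.to_json(sdir / "landmarks.json")
            skin, skin_nodes = skin_surface(mesh)
            write_vtk_surface(
                skin, sdir / "skin_h.vtk",
                point_scalars={"u_mag_mm": np.linalg.norm(field_h.u[skin_nodes], axis=1)},
            )

            stage = "doe_responses"
            resp = run_design(
                mesh, landmarks, design, config.materials,
                config.advancement, config.impaction, cache,
            )
            solves["design_points"] += design.n_points
            solves["h_model"] += 1  # H row of the response table
            resp.to_csv(sdir / "responses.csv")
            responses.append(resp)

            stage = "sensitivity"
            sens = local_sensitivity(
                mesh, landmarks, config.ranges, config.materials,
                config.advancement, config.impaction, cache,
            )
            solves["sensitivity"] += 2 * len(config.ranges) + 1
            sens.to_csv(sdir / "sensitivity.csv")
            sensitivities.append(sens)
            log.info("subject %d done (%.1fs elapsed)", subject, time.time() - t_start)

        stage = "population_statistics"
        subject = -1
        h_displacements = pd.concat(h_frames, ignore_index=True)
        h_displacements.to_csv(out / "h_landmark_displacements.csv", index=False)
        sensitivity_table = aggregate_population(sensitivities)
        sensitivity_table.to_csv(out / "sensitivity_table.csv", index=False)
        comparison = compare_with_homogeneous(responses)
        comparison.table.to_csv(out / "comparison.csv", index=False)
        comparison.p_values.to_csv(out / "comparison_pvalues.csv", index=False)
        _comparison_boxplot(comparison, out / "comparison_boxplot.png")

        stage = "validation"
        validation_summary = _validation_loop(config, population[0], seeds["validation"], out)

        stage = "manifest"
        manifest = {
            "orthofem_version": __version__,
            "master_seed": config.master_seed,
            "derived_seeds": seeds,
            "n_subjects": len(population),
            "n_design_points": design.n_points,
            "solves": solves,
            "design_point_solves": solves["design_points"],
            "total_solves": sum(solves.values()),
            "advancement_mm": config.advancement,
            "impaction_mm": config.impaction,
            "elapsed_s": round(time.time() - t_start, 2),
            "files": {},
        }
        for f in sorted(out.rglob("*")):
            if f.is_file() and f.name != "manifest.json":
                manifest["files"][str(f.relative_to(out))] = _sha256(f)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise PipelineError(
            f"stage {stage!r} failed"
            + (f" on subject {subject}" if subject >= 0 else "")
            + f": {exc}"
        ) from exc

    return StudyResult(
        population=population,
        h_displacements=h_displacements,
        design=design_frame,
        responses=responses,
        sensitivities=sensitivities,
        sensitivity_table=sensitivity_table,
        comparison=comparison,
        validation_summary=validation_summary,
        manifest=manifest,
    )


def _validation_loop(config: RunConfig, subject, seed: int, out: Path) -> dict:
    """Predicted skin vs synthetic post-op surface: ICP + crop + distance."""
    mesh, landmarks = subject
    vdir = out / "validation"
    vdir.mkdir(parents=True, exist_ok=True)
    cache = RegionStiffnessCache.for_materials(mesh, config.materials)
    field, _ = homogeneous_model(
        mesh, landmarks, config.materials, config.advancement, config.impaction, cache
    )
    skin, skin_nodes = skin_surface(mesh)
    u_skin = field.u[skin_nodes]
    predicted = type(skin)(vertices=skin.vertices + u_skin, faces=skin.faces)

    rng = np.random.default_rng(seed)
    offset = RigidTransform.from_rotvec(
        rng.uniform(-0.05, 0.05, size=3), rng.uniform(-2, 2, size=3)
    )
    postop = make_synthetic_postop_surface(
        skin, u_skin, noise_sd=config.validation_noise_sd, rigid_offset=offset, seed=seed
    )
    predicted.save(vdir / "predicted_skin.ply")
    postop.save(vdir / "synthetic_postop.ply")

    icp = icp_align(predicted, postop)
    aligned = type(skin)(vertices=icp.transform.apply(predicted.vertices), faces=skin.faces)
    cropped, kept = crop_unaffected(aligned, u_skin, threshold=config.crop_threshold)
    dmap = signed_distance(cropped, postop)
    export_colormap(
        cropped, dmap,
        vdir / "distance_map.ply", vtk_path=vdir / "distance_map.vtk",
        csv_path=vdir / "distance_map.csv",
    )
    summary = {
        "mean_mm": dmap.mean,
        "sd_mm": dmap.sd,
        "mean_abs_mm": float(np.abs(dmap.distances).mean()),
        "n_vertices": dmap.n_vertices,
        "n_vertices_before_crop": len(aligned.vertices),
        "icp_rms_mm": icp.rms,
        "icp_iterations": len(icp.rms_history),
        "noise_sd_mm": config.validation_noise_sd,
        "crop_threshold_mm": config.crop_threshold,
    }
    with open(vdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _comparison_boxplot(comparison: ComparisonResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    data, labels = [], []
    for landmark in ("N", "UL", "C"):
        sub = comparison.table[comparison.table["landmark"] == landmark]
        data += [sub["max_minus_H"].to_numpy(), sub["min_minus_H"].to_numpy()]
        labels += [f"{landmark}$_{{max}}$-H", f"{landmark}$_{{min}}$-H"]
    ax.boxplot(data, tick_labels=labels)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("displacement difference vs H model [mm]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_report(output_dir) -> Path:
    """Render the study artifacts into a Markdown summary (idempotent)."""
    out = Path(output_dir)
    required = [
        "sensitivity_table.csv",
        "comparison_pvalues.csv",
        "h_landmark_displacements.csv",
        "validation/summary.json",
        "manifest.json",
    ]
    missing = [name for name in required if not (out / name).exists()]
    if missing:
        raise PipelineError(f"missing artifacts: {missing}")
    sens = pd.read_csv(out / "sensitivity_table.csv")
    if sens.empty:
        raise PipelineError("sensitivity table is empty")
    pvals = pd.read_csv(out / "comparison_pvalues.csv")
    h_disp = pd.read_csv(out / "h_landmark_displacements.csv")
    with open(out / "validation" / "summary.json") as fh:
        val = json.load(fh)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)

    lines = [
        "# orthofem study report",
        "",
        f"orthofem {manifest['orthofem_version']}, master seed {manifest['master_seed']}, "
        f"{manifest['n_subjects']} subjects x {manifest['n_design_points']} design points "
        f"({manifest['design_point_solves']} design-point solves, "
        f"{manifest['total_solves']} solves total).",
        "",
        "## Muscle sensitivities (%)",
        "",
        sens.to_markdown(index=False, floatfmt=".3g"),
        "",
        "## Homogeneous-model comparison (paired Wilcoxon p)",
        "",
        pvals.to_markdown(index=False, floatfmt=".4g"),
        "",
        "![comparison box plot](comparison_boxplot.png)",
        "",
        "## H-model landmark displacements (mm)",
        "",
        h_disp.groupby("landmark")["total_mm"].describe()[["mean", "std", "min", "max"]]
        .to_markdown(floatfmt=".3f"),
        "",
        "## Validation (synthetic post-op surface)",
        "",
        f"- mean signed distance: {val['mean_mm']:.4g} mm (SD {val['sd_mm']:.4g} mm)",
        f"- mean |distance|: {val['mean_abs_mm']:.4g} mm over {val['n_vertices']} vertices",
        f"- ICP RMS {val['icp_rms_mm']:.4g} mm in {val['icp_iterations']} iterations",
        "",
    ]
    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
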