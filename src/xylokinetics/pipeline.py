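"""End-to-end orchestration: simulate -> zonate -> traits -> kinetics -> stats.

A single YAML/dict config drives the run; one root seed is split per stage.
Every stage writes plain CSV/JSON artifacts and the run ends with a manifest
recording inputs, outputs, SHA-256 hashes, seeds and package version.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .errors import PreconditionError, StageError
from .kinetics import DEFAULT_PERIODS, estimate_kinetics
from .simulate import SimulationParams, TreatmentSchedule, simulate_experiment
from .stats import (
    FIBRE_CSA_WINDOWS,
    VESSEL_CSA_WINDOWS,
    WALL_THICKNESS_WINDOWS,
    fit_lwp_glm,
    fit_trait_lmm,
    relative_increment_test,
    windowed_contrasts,
)
from .traits import smooth_trend, summarize_increments, treatment_contrast, wall_thickness
from .zonation import (
    assign_cells,
    compute_increments,
    cycle_boundaries,
    increments_from_frame,
    increments_frame,
    interval_boundaries,
)

__all__ = [
    "simulate_to_dir",
    "zonate_experiment",
    "trait_tables",
    "kinetics_table",
    "stats_results",
    "run_all",
]


def simulate_to_dir(params: SimulationParams, outdir, seed: int | None = None) -> dict:
    """Run the generator and write all five input tables plus ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp = simulate_experiment(params, seed=seed)
    io.write_detection_table(exp.detections, outdir / "detections.csv")
    io.write_growth_table(exp.growth, outdir / "growth.csv")
    io.write_lwp_table(exp.lwp, outdir / "lwp.csv")
    io.write_environment_log(exp.environment, outdir / "environment.csv")
    io.write_schedule_table(exp.schedule.to_frame(), outdir / "schedule.csv")
    exp.cambium.to_csv(outdir / "cambium.csv", index=False)
    exp.phases.to_csv(outdir / "phases.csv", index=False)
    io.write_truth(exp.truth, outdir / "truth.json")
    return {
        "detections": str(outdir / "detections.csv"),
        "growth": str(outdir / "growth.csv"),
        "lwp": str(outdir / "lwp.csv"),
        "environment": str(outdir / "environment.csv"),
        "schedule": str(outdir / "schedule.csv"),
        "cambium": str(outdir / "cambium.csv"),
        "phases": str(outdir / "phases.csv"),
        "truth": str(outdir / "truth.json"),
    }


def _boundaries_for(days, schedule, choice) -> list[int]:
    choice = choice or {"step": 3}
    if "days" in choice:
        return list(choice["days"])
    if choice.get("preset") == "cycles" and schedule is not None:
        return cycle_boundaries(schedule, int(np.max(days)))
    return interval_boundaries(days, int(choice.get("step", 3)))


def zonate_experiment(
    growth: pd.DataFrame,
    detections: pd.DataFrame,
    schedule: TreatmentSchedule | None = None,
    boundaries: dict | list | None = None,
    cambium_y: float | None = None,
    orientation: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Date every tree's cells; returns (dated_cells, increments) tables.

    ``boundaries`` is either an explicit list of days or a spec dict
    ({"step": n} for the 2-3 day sampling preset, {"preset": "cycles"} for
    drought/watering-cycle boundaries).
    """
    if isinstance(boundaries, (list, tuple)):
        boundaries = {"days": list(boundaries)}
    dated_frames, inc_frames = [], []
    meta = growth[["tree_id", "block", "treatment"]].drop_duplicates("tree_id")
    for tid, tree_growth in growth.groupby("tree_id", sort=False):
        bounds = _boundaries_for(tree_growth["day"].to_numpy(), schedule, boundaries)
        incs = compute_increments(tree_growth, bounds, schedule)
        cells = detections[detections["sample_id"] == tid]
        dated = assign_cells(cells, incs, cambium_y=cambium_y, orientation=orientation)
        dated_frames.append(dated)
        inc_frames.append(increments_frame(incs, sample_id=tid))
    dated = pd.concat(dated_frames, ignore_index=True)
    dated = dated.merge(
        meta.rename(columns={"tree_id": "sample_id"}), on="sample_id", how="left"
    )
    return dated, pd.concat(inc_frames, ignore_index=True)


def trait_tables(
    dated: pd.DataFrame,
    increments: pd.DataFrame,
    contrast_trait: str = "vessel_csa",
    span: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-(sample, period) trait table plus a PI-CI smoothed contrast curve
    of a cell-level trait (vessel_csa, fibre_csa or wall_thickness)."""
    frames = []
    for sid, grp in dated.groupby("sample_id", sort=False):
        incs = increments_from_frame(
            increments[increments["sample_id"] == sid]
        )
        tab = summarize_increments(grp, incs)
        frames.append(tab)
    traits = pd.concat(frames, ignore_index=True)
    traits = traits.merge(
        dated[["sample_id", "treatment"]].drop_duplicates(), on="sample_id", how="left"
    )

    cell_values = cell_level_values(dated, contrast_trait)
    contrast = None
    if cell_values is not None and cell_values["treatment"].nunique() == 2:
        curves = {}
        for trt, grp in cell_values.groupby("treatment"):
            if len(grp) >= 4:
                curves[trt] = smooth_trend(
                    grp.rename(columns={"mid_day": "day"})[["day", "value"]],
                    span=span,
                    treatment=trt,
                )
        if {"PI", "CI"} <= set(curves):
            c = treatment_contrast(curves["PI"], curves["CI"])
            contrast = pd.DataFrame(
                {"day": c.day_grid, "difference": c.values, "trait": contrast_trait}
            )
    return traits, contrast


def cell_level_values(dated: pd.DataFrame, trait: str) -> pd.DataFrame | None:
    """Cell-level (sample, treatment, mid_day, value) rows for one trait."""
    assigned = dated[dated["dating"] == "assigned"].copy()
    if trait == "vessel_csa":
        sel = assigned[assigned["cell_class"] == "vessel"].copy()
        sel["value"] = sel["cell_area"]
    elif trait == "fibre_csa":
        sel = assigned[assigned["cell_class"] == "fibre"].copy()
        sel["value"] = sel["cell_area"]
    elif trait == "wall_thickness":
        sel = assigned[assigned["cell_class"] == "fibre"].copy()
        if len(sel):
            sel["value"] = wall_thickness(
                sel["cell_area"].to_numpy(), sel["lumen_area"].to_numpy()
            )
        else:
            sel["value"] = pd.Series(dtype=float)
    else:
        raise PreconditionError(f"unknown cell-level trait '{trait}'")
    if len(sel) == 0:
        return None
    return sel[["sample_id", "treatment", "mid_day", "value"]]


def kinetics_table(
    dated: pd.DataFrame,
    increments: pd.DataFrame,
    cambium: pd.DataFrame,
    phases: pd.DataFrame,
    period_defs=None,
) -> pd.DataFrame:
    frames = []
    for sid, grp in dated.groupby("sample_id", sort=False):
        incs = increments_from_frame(increments[increments["sample_id"] == sid])
        frames.append(
            estimate_kinetics(grp, incs, cambium, phases, period_defs=period_defs)
        )
    out = pd.concat(frames, ignore_index=True)
    return out.merge(
        dated[["sample_id", "treatment"]].drop_duplicates(), on="sample_id", how="left"
    )


def _label_periods(values: pd.DataFrame, period_defs) -> pd.DataFrame:
    out = values.copy()
    out["period"] = None
    for label, start, end in period_defs:
        m = (out["mid_day"] >= start) & (out["mid_day"] <= end)
        out.loc[m, "period"] = label
    return out.dropna(subset=["period"])


def stats_results(
    dated: pd.DataFrame,
    growth: pd.DataFrame,
    lwp: pd.DataFrame,
    schedule: TreatmentSchedule,
    period_defs=None,
    holm: bool = False,
) -> dict:
    """Run the full statistical layer; returns a JSON-ready dict."""
    period_defs = period_defs or DEFAULT_PERIODS
    results = {}

    lwp_df = lwp.merge(
        growth[["tree_id", "treatment"]].drop_duplicates(), on="tree_id", how="left"
    )
    lwp_df["cycle"] = [schedule.label_on(int(d)) for d in lwp_df["day"]]
    lwp_df = lwp_df.dropna(subset=["cycle"])
    results["lwp_glm"] = fit_lwp_glm(lwp_df).to_dict()

    window_map = {
        "vessel_csa": VESSEL_CSA_WINDOWS,
        "fibre_csa": FIBRE_CSA_WINDOWS,
        "wall_thickness": WALL_THICKNESS_WINDOWS,
    }
    for trait, windows in window_map.items():
        values = cell_level_values(dated, trait)
        if values is None:
            continue
        entry = {}
        labelled = _label_periods(values, period_defs)
        if (
            labelled["period"].nunique() >= 2
            and labelled["treatment"].nunique() == 2
            and (labelled.groupby("treatment")["sample_id"].nunique() >= 2).all()
        ):
            entry["lmm"] = fit_trait_lmm(labelled).to_dict()
        entry["windowed_contrasts"] = windowed_contrasts(
            values, windows, holm=holm
        ).to_dict(orient="records")
        results[trait] = entry

    results["relative_increment"] = relative_increment_test(growth).to_dict()
    return results


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(config: dict, outdir) -> dict:
    """Execute the full pipeline from a config dict; returns the manifest.

    Config keys: ``simulate`` (generator parameter overrides; omit to read
    existing input files from ``inputs``), ``boundaries``, ``periods``,
    ``contrast_trait``, ``span``, ``holm``, ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": [], "outputs": {}}
    seed = int(config.get("seed", 0))
    manifest["seed"] = seed

    # --- stage: simulate or load -------------------------------------------
    if "simulate" in config:
        try:
            params = SimulationParams(**{**config["simulate"], "seed": seed})
            paths = simulate_to_dir(params, outdir / "inputs")
        except Exception as exc:
            raise StageError("simulate", exc) from exc
        manifest["stages"].append("simulate")
    else:
        paths = dict(config.get("inputs", {}))
        missing = [k for k in ("detections", "growth", "lwp", "schedule") if k not in paths]
        if missing:
            raise StageError(
                "load", PreconditionError(f"config missing input paths: {missing}")
            )
        for key, p in paths.items():
            if not Path(p).exists():
                raise StageError("load", FileNotFoundError(p))
    try:
        detections = io.read_detection_table(paths["detections"],
                                             column_map=config.get("column_map"))
        growth = io.read_growth_table(paths["growth"])
        lwp = io.read_lwp_table(paths["lwp"])
        schedule = TreatmentSchedule.from_frame(io.read_schedule_table(paths["schedule"]))
        cambium = pd.read_csv(paths["cambium"]) if "cambium" in paths else None
        phases = pd.read_csv(paths["phases"]) if "phases" in paths else None
    except Exception as exc:
        raise StageError("load", exc) from exc
    manifest["stages"].append("load")

    # --- stage: zonate ------------------------------------------------------
    try:
        dated, increments = zonate_experiment(
            growth, detections, schedule, config.get("boundaries")
        )
        dated.to_csv(outdir / "dated_cells.csv", index=False)
        increments.to_csv(outdir / "increments.csv", index=False)
    except Exception as exc:
        raise StageError("zonate", exc) from exc
    manifest["stages"].append("zonate")

    period_defs = [tuple(p) for p in config.get("periods", DEFAULT_PERIODS)]

    # --- stage: traits ------------------------------------------------------
    try:
        traits, contrast = trait_tables(
            dated,
            increments,
            contrast_trait=config.get("contrast_trait", "vessel_csa"),
            span=float(config.get("span", 0.3)),
        )
        traits.to_csv(outdir / "traits.csv", index=False)
        if contrast is not None:
            contrast.to_csv(outdir / "contrast.csv", index=False)
    except Exception as exc:
        raise StageError("traits", exc) from exc
    manifest["stages"].append("traits")

    # --- stage: kinetics ----------------------------------------------------
    try:
        if cambium is not None and phases is not None:
            kin = kinetics_table(dated, increments, cambium, phases, period_defs)
            kin.to_csv(outdir / "kinetics.csv", index=False)
        else:
            kin = None
    except Exception as exc:
        raise StageError("kinetics", exc) from exc
    manifest["stages"].append("kinetics")

    # --- stage: stats -------------------------------------------------------
    try:
        res = stats_results(
            dated, growth, lwp, schedule,
            period_defs=period_defs, holm=bool(config.get("holm", False)),
        )
        (outdir / "stats.json").write_text(json.dumps(res, indent=2, default=float))
    except Exception as exc:
        raise StageError("stats", exc) from exc
    manifest["stages"].append("stats")

    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
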