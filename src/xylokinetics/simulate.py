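"""Synthetic cyclic-drought xylogenesis experiments with known ground truth.

The generator emulates the data structure of a greenhouse trial in which
seedlings are either continuously irrigated (CI) or periodically irrigated
(PI, alternating drought/watering cycles), producing

* a treatment schedule of alternating drought (DT) / watering (WT) cycles,
* daily stem diameter and height series per tree, with elastic shrinkage
  episodes during severe drought,
* daily pre-dawn leaf water potential (LWP, negative MPa) per tree,
* a 30-min cadence temperature / relative-humidity logger table,
* per-cell detection tables (fibres and vessels with cell area, lumen area
  and centroid positions) whose radial placement is consistent with the
  cumulative stem growth, and
* cambial-zone and enlargement-phase cell counts along radial files.

All drought responses are driven by a single water-status mechanism: the
daily growth multiplier is 1 above an LWP threshold and declines linearly to
0 at the drought minimum; cell-trait drought multipliers and shrinkage apply
only on days when LWP is below the threshold.  Ground-truth kinetic
parameters (cell production rate phi, cambial cell count eta_c, enlargement
cohort eta_x) are recorded so downstream estimators can be validated by
parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .errors import PreconditionError, ScheduleSpanError

__all__ = [
    "SimulationParams",
    "Cycle",
    "TreatmentSchedule",
    "TreeSeries",
    "SyntheticExperiment",
    "generate_schedule",
    "simulate_tree",
    "simulate_cells",
    "simulate_environment",
    "simulate_experiment",
    "affected_days",
    "effect_windows",
]

DETECTION_COLUMNS = [
    "sample_id",
    "cell_class",
    "cell_area",
    "lumen_area",
    "centroid_x",
    "centroid_y",
]


@dataclass(frozen=True)
class Cycle:
    """One treatment cycle, half-open day interval [start_day, end_day)."""

    label: str
    start_day: int
    end_day: int
    status: str  # "droughted" | "watered"

    @property
    def length(self) -> int:
        return self.end_day - self.start_day


@dataclass(frozen=True)
class TreatmentSchedule:
    """Contiguous, alternating drought/watering cycles."""

    cycles: tuple[Cycle, ...]

    def __post_init__(self):
        prev_end = None
        prev_status = None
        for c in self.cycles:
            if c.end_day <= c.start_day:
                raise PreconditionError(f"cycle {c.label} has non-positive length")
            if prev_end is not None and c.start_day != prev_end:
                raise PreconditionError(
                    f"cycles not contiguous at day {c.start_day} ({c.label})"
                )
            if prev_status is not None and c.status == prev_status:
                raise PreconditionError(f"cycles not alternating at {c.label}")
            prev_end = c.end_day
            prev_status = c.status

    @property
    def span(self) -> int:
        return self.cycles[-1].end_day - self.cycles[0].start_day

    def status_on(self, day: int) -> str:
        for c in self.cycles:
            if c.start_day <= day < c.end_day:
                return c.status
        return "watered"  # outside the schedule trees are watered

    def label_on(self, day: int) -> str | None:
        for c in self.cycles:
            if c.start_day <= day < c.end_day:
                return c.label
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.label, c.start_day, c.end_day, c.status) for c in self.cycles],
            columns=["label", "start_day", "end_day", "status"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TreatmentSchedule":
        cycles = tuple(
            Cycle(str(r.label), int(r.start_day), int(r.end_day), str(r.status))
            for r in df.itertuples()
        )
        return cls(cycles)


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of a synthetic experiment.

    Lengths are micrometres unless noted; diameters at the I/O boundary are
    millimetres, heights centimetres, water potentials negative megapascals.
    """

    n_trees_per_treatment: int = 12
    n_days: int = 75
    n_cycles: int = 6
    # kinetics ground truth
    cells_per_day: float = 2.0          # phi_true, fibre cells/day per radial file
    mean_fibre_diameter: float = 10.0   # D, um
    cambial_zone_cells: float = 4.0     # eta_c_true
    enlargement_cohort: float = 6.0     # eta_x_true
    mean_vessel_diameter: float = 30.0  # um
    vessel_frequency_true: float = 138.0  # vessels per mm^2 of section
    # water status
    lwp_baseline: float = -0.5          # MPa
    lwp_drought_min: float = -2.4       # MPa, worst-cycle minimum
    lwp_threshold: float = -2.0         # MPa, below which drought effects act
    lwp_noise_sd: float = 0.05          # MPa
    # drought effect multipliers, applied on days with LWP < threshold
    drought_effect_vessel_csa: float = 0.8
    drought_effect_fibre_csa: float = 0.9
    drought_effect_wall: float = 0.9
    # growth and noise
    baseline_growth_rate: float | None = None  # um/day radial; default phi*D
    growth_cv: float = 0.1
    shrinkage_amplitude: float = 0.15   # mm on diameter during severe drought
    trait_cv: float = 0.3               # lognormal CV of per-cell areas
    wall_thickness_mean: float = 1.5    # um
    wall_cv: float = 0.1
    placement_noise_sd: float = 2.0     # um, radial placement of centroids
    vessel_lumen_fraction: float = 0.85
    effect_lag_days: float | None = None  # enlargement carry-over; default t_sigma
    size_begin: float = 30.0            # um^2, fibre size entering enlargement
    initial_diameter: float = 5.0       # mm
    initial_height: float = 50.0        # cm
    image_width: float = 0.4            # mm, tangential image width
    sampling_step: int = 3              # days between cambial counts
    seed: int = 0

    def __post_init__(self):
        if self.n_days < 2:
            raise PreconditionError("n_days must be >= 2")
        if self.n_trees_per_treatment < 1:
            raise PreconditionError("need at least one tree per treatment")
        for name in (
            "cells_per_day",
            "mean_fibre_diameter",
            "mean_vessel_diameter",
            "vessel_frequency_true",
            "wall_thickness_mean",
            "initial_diameter",
            "initial_height",
            "image_width",
        ):
            if getattr(self, name) <= 0:
                raise PreconditionError(f"{name} must be > 0")
        for name in (
            "drought_effect_vessel_csa",
            "drought_effect_fibre_csa",
            "drought_effect_wall",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1.5):
                raise PreconditionError(f"{name} must lie in (0, 1.5]")
        for name in ("lwp_baseline", "lwp_drought_min", "lwp_threshold"):
            if getattr(self, name) > 0:
                raise PreconditionError(f"{name} must be <= 0 (MPa)")
        if self.lwp_drought_min > self.lwp_baseline:
            raise PreconditionError("lwp_drought_min must be <= lwp_baseline")

    @property
    def growth_rate(self) -> float:
        """Baseline radial growth rate, um/day (phi * D unless overridden)."""
        if self.baseline_growth_rate is not None:
            return self.baseline_growth_rate
        return self.cells_per_day * self.mean_fibre_diameter

    @property
    def effect_lag(self) -> int:
        """Days of enlargement carry-over for trait drought effects.

        A cell's final size is set during its enlargement phase, which lasts
        about t_sigma = eta_x / phi days after production; cells produced up
        to that many days before a sub-threshold LWP episode are therefore
        affected by it.
        """
        if self.effect_lag_days is not None:
            return int(round(self.effect_lag_days))
        phi = self.growth_rate / self.mean_fibre_diameter
        return int(round(self.enlargement_cohort / phi))

    def truth(self) -> dict:
        """Ground-truth quantities for recovery tests."""
        d = asdict(self)
        phi = self.growth_rate / self.mean_fibre_diameter
        d.update(
            phi_true=phi,
            t_phi_true=self.cambial_zone_cells / phi,
            t_sigma_true=self.enlargement_cohort / phi,
        )
        return d


@dataclass
class TreeSeries:
    """Daily series for one tree: measured diameter, height, LWP and the
    (unobservable) structural radial increments that drive cell production."""

    tree_id: str
    block: str
    treatment: str  # "CI" | "PI"
    days: np.ndarray
    diameter: np.ndarray            # mm, includes elastic shrinkage
    height: np.ndarray              # cm
    lwp: np.ndarray                 # MPa, daily pre-dawn
    radial_increment: np.ndarray    # um/day, structural xylem growth

    def growth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tree_id": self.tree_id,
                "block": self.block,
                "treatment": self.treatment,
                "day": self.days,
                "diameter": self.diameter,
                "height": self.height,
            }
        )

    def lwp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tree_id": self.tree_id, "day": self.days, "psi_pd": self.lwp}
        )


def generate_schedule(
    n_cycles: int,
    drought_range: tuple[int, int] = (3, 7),
    watered_range: tuple[int, int] = (3, 7),
    seed: int = 0,
    n_days: int | None = None,
    extend_final: bool = True,
) -> TreatmentSchedule:
    """Draw an alternating WT/DT schedule: WT0 lead-in, then DT1, WT1, ...

    Drought lengths are uniform on ``drought_range`` (inclusive), watering
    lengths on ``watered_range``.  If ``n_days`` is given and the schedule
    would overrun it, a :class:`ScheduleSpanError` is raised; otherwise the
    final watering cycle is stretched to cover the experiment window.
    """
    if n_cycles < 1:
        raise PreconditionError("n_cycles must be >= 1")
    for lo, hi in (drought_range, watered_range):
        if lo < 1 or hi < lo:
            raise PreconditionError("cycle length ranges must be positive")
    rng = np.random.default_rng(seed)
    cycles = []
    day = 0
    lead = int(rng.integers(watered_range[0], watered_range[1] + 1))
    cycles.append(Cycle("WT0", day, day + lead, "watered"))
    day += lead
    for i in range(1, n_cycles + 1):
        dt = int(rng.integers(drought_range[0], drought_range[1] + 1))
        cycles.append(Cycle(f"DT{i}", day, day + dt, "droughted"))
        day += dt
        wt = int(rng.integers(watered_range[0], watered_range[1] + 1))
        cycles.append(Cycle(f"WT{i}", day, day + wt, "watered"))
        day += wt
    if n_days is not None:
        if day > n_days:
            raise ScheduleSpanError(
                f"schedule spans {day} days but the experiment has {n_days}"
            )
        if extend_final and day < n_days:
            last = cycles[-1]
            cycles[-1] = replace(last, end_day=n_days)
    return TreatmentSchedule(tuple(cycles))


def _cycle_minima(schedule: TreatmentSchedule, params: SimulationParams, rng) -> dict:
    """Per-drought-cycle LWP minima.  Two cycles (the first, and the fifth if
    present) are 'severe' and reach the global drought minimum; the rest draw
    a milder minimum between threshold-adjacent and severe levels."""
    dts = [c for c in schedule.cycles if c.status == "droughted"]
    minima = {}
    severe = {0, 4} if len(dts) > 4 else {0, len(dts) - 1}
    for i, c in enumerate(dts):
        if i in severe:
            sev = 1.0
        else:
            sev = rng.uniform(0.5, 0.9)
        minima[c.label] = params.lwp_baseline + sev * (
            params.lwp_drought_min - params.lwp_baseline
        )
    return minima


def simulate_tree(
    schedule: TreatmentSchedule,
    params: SimulationParams,
    treatment: str,
    seed: int,
    tree_id: str = "T01",
    block: str = "A",
) -> TreeSeries:
    """Simulate one tree's daily diameter, height and pre-dawn LWP.

    CI trees stay near ``lwp_baseline``; PI trees decline linearly toward
    the cycle minimum over each drought cycle and rebound on rewatering.
    The structural radial increment is ``growth_rate`` scaled by a
    piecewise-linear function of LWP (1 above threshold, 0 at the drought
    minimum); measured diameter additionally carries a reversible elastic
    shrinkage term on sub-threshold days.
    """
    if treatment not in ("CI", "PI"):
        raise PreconditionError("treatment must be 'CI' or 'PI'")
    rng = np.random.default_rng(seed)
    n = params.n_days
    days = np.arange(n)
    minima = _cycle_minima(schedule, params, rng)

    lwp = np.full(n, params.lwp_baseline, dtype=float)
    if treatment == "PI":
        for c in schedule.cycles:
            if c.status != "droughted":
                continue
            lo = minima[c.label]
            for t, d in enumerate(range(c.start_day, min(c.end_day, n))):
                frac = (t + 1) / c.length
                lwp[d] = params.lwp_baseline + frac * (lo - params.lwp_baseline)
    lwp = lwp + rng.normal(0.0, params.lwp_noise_sd, n)
    lwp = np.minimum(lwp, 0.0)

    # growth multiplier: 1 above threshold, linear to 0 at drought minimum
    thr, lo = params.lwp_threshold, params.lwp_drought_min
    f = np.clip((lwp - lo) / (thr - lo), 0.0, 1.0)
    f[lwp >= thr] = 1.0

    if params.growth_cv > 0:
        sig2 = np.log1p(params.growth_cv**2)
        gnoise = rng.lognormal(-sig2 / 2, np.sqrt(sig2), n)
    else:
        gnoise = np.ones(n)
    radial = params.growth_rate * f * gnoise  # um/day, >= 0

    # reversible elastic shrinkage on sub-threshold days (mm on diameter)
    deficit = np.clip((thr - lwp) / (thr - lo), 0.0, 1.0)
    elastic = np.where(lwp < thr, -params.shrinkage_amplitude * deficit, 0.0)

    diameter = params.initial_diameter + 2 * np.cumsum(radial) / 1000.0 + elastic
    hscale = 0.04  # cm of height per um of radial growth; noisy copy of trend
    if params.growth_cv > 0:
        hnoise = rng.lognormal(-sig2 / 2, np.sqrt(sig2), n)
    else:
        hnoise = np.ones(n)
    height = params.initial_height + hscale * np.cumsum(radial * hnoise)

    return TreeSeries(
        tree_id=tree_id,
        block=block,
        treatment=treatment,
        days=days,
        diameter=diameter,
        height=height,
        lwp=lwp,
        radial_increment=radial,
    )


def affected_days(lwp: np.ndarray, params: SimulationParams) -> np.ndarray:
    """Boolean mask of production days whose cells carry drought effects.

    A cell's final dimensions are set during its enlargement phase
    (~``effect_lag`` = t_sigma days).  A production day is affected if a
    sub-threshold LWP episode overlaps that phase: episodes reach back to
    cells produced up to ``effect_lag`` days before them (still enlarging
    when the drought peaks) and forward the same number of days (tissue
    water status recovers over a few days after rewatering).
    """
    sub = np.asarray(lwp) < params.lwp_threshold
    out = sub.copy()
    for k in range(1, params.effect_lag + 1):
        out[:-k] |= sub[k:]   # produced before the episode, enlarging into it
        out[k:] |= sub[:-k]   # produced during post-episode recovery
    return out


def effect_windows(lwp: np.ndarray, params: SimulationParams) -> list[tuple[int, int]]:
    """Contiguous (start_day, end_day) runs of affected days (inclusive)."""
    mask = affected_days(lwp, params)
    windows = []
    start = None
    for d, m in enumerate(mask):
        if m and start is None:
            start = d
        elif not m and start is not None:
            windows.append((start, d - 1))
            start = None
    if start is not None:
        windows.append((start, len(mask) - 1))
    return windows


def simulate_cells(tree: TreeSeries, params: SimulationParams, seed: int) -> pd.DataFrame:
    """Generate the per-cell detection table for one tree.

    Fibres are produced along one radial file at ``radial_increment / D``
    cells per day (a fractional accumulator keeps production and growth
    exactly consistent); vessels arrive as a Poisson process with intensity
    ``vessel_frequency_true * image_width * daily growth``.  Cells are placed
    radially so the newest sit nearest the cambium (depth 0, centroid_y
    increasing into the wood).  Trait drought multipliers scale vessel area,
    fibre area and wall thickness for cells whose enlargement phase overlaps
    a sub-threshold LWP episode (see :func:`affected_days`).

    Returns a DataFrame in the detection-table schema plus a ``true_day``
    ground-truth column (readers ignore extra columns).
    """
    if len(tree.days) < 2:
        raise PreconditionError("tree series needs at least 2 days")
    rng = np.random.default_rng(seed)
    g = np.asarray(tree.radial_increment, dtype=float)
    total = float(np.sum(g))
    cum = np.cumsum(g)
    if total <= 0:
        warnings.warn(f"tree {tree.tree_id}: zero total growth, no cells generated")
        return pd.DataFrame(columns=DETECTION_COLUMNS + ["true_day"])

    D = params.mean_fibre_diameter
    sub = affected_days(tree.lwp, params)  # drought-effect days (with carry-over)
    sig2 = np.log1p(params.trait_cv**2)
    sig = np.sqrt(sig2)
    wsig2 = np.log1p(params.wall_cv**2)
    wsig = np.sqrt(wsig2)
    tang_um = params.image_width * 1000.0

    rows_day, rows_depth, rows_class, rows_area, rows_lumen = [], [], [], [], []

    carry = 0.0
    for d in range(len(g)):
        band_old = total - (cum[d] - g[d])  # deeper boundary of this day's band
        # fibres: one radial file, cells tile the day's growth band
        carry += g[d] / D
        n_f = int(np.floor(carry))
        carry -= n_f
        if n_f > 0:
            spacing = g[d] / n_f
            depths = band_old - (np.arange(n_f) + 0.5) * spacing
            mean_a = np.pi * (D / 2) ** 2
            if sub[d]:
                mean_a *= params.drought_effect_fibre_csa
            areas = rng.lognormal(np.log(mean_a) - sig2 / 2, sig, n_f)
            wt = params.wall_thickness_mean * rng.lognormal(-wsig2 / 2, wsig, n_f)
            if sub[d]:
                wt = wt * params.drought_effect_wall
            r = np.sqrt(areas / np.pi)
            wt = np.minimum(wt, 0.95 * r)
            lumen = np.pi * (r - wt) ** 2
            rows_day.append(np.full(n_f, d))
            rows_depth.append(depths)
            rows_class.append(np.full(n_f, "fibre", dtype=object))
            rows_area.append(areas)
            rows_lumen.append(lumen)
        # vessels: Poisson in the section area added this day
        lam = params.vessel_frequency_true * params.image_width * (g[d] / 1000.0)
        n_v = int(rng.poisson(lam))
        if n_v > 0:
            depths = band_old - rng.uniform(0.0, g[d], n_v)
            mean_a = np.pi * (params.mean_vessel_diameter / 2) ** 2
            if sub[d]:
                mean_a *= params.drought_effect_vessel_csa
            areas = rng.lognormal(np.log(mean_a) - sig2 / 2, sig, n_v)
            lumen = params.vessel_lumen_fraction * areas
            rows_day.append(np.full(n_v, d))
            rows_depth.append(depths)
            rows_class.append(np.full(n_v, "vessel", dtype=object))
            rows_area.append(areas)
            rows_lumen.append(lumen)

    if not rows_day:
        warnings.warn(f"tree {tree.tree_id}: growth too small to produce cells")
        return pd.DataFrame(columns=DETECTION_COLUMNS + ["true_day"])

    day = np.concatenate(rows_day)
    depth = np.concatenate(rows_depth)
    if params.placement_noise_sd > 0:
        depth = depth + rng.normal(0.0, params.placement_noise_sd, len(depth))
    cells = pd.DataFrame(
        {
            "sample_id": tree.tree_id,
            "cell_class": np.concatenate(rows_class),
            "cell_area": np.concatenate(rows_area),
            "lumen_area": np.concatenate(rows_lumen),
            "centroid_x": rng.uniform(0.0, tang_um, len(depth)),
            "centroid_y": depth,  # cambium at y = 0, wood extends to +y
            "true_day": day,
        }
    )
    return cells


def simulate_environment(n_days: int, seed: int = 0) -> pd.DataFrame:
    """30-min cadence greenhouse logger: temperature (sinusoidal diel cycle
    around 21.8 degC) and relative humidity (around 58%)."""
    rng = np.random.default_rng(seed)
    steps = n_days * 48
    t_hours = np.arange(steps) * 0.5
    diel = np.sin(2 * np.pi * (t_hours % 24 - 9) / 24)
    temp = 21.8 + 6.0 * diel + rng.normal(0, 0.8, steps)
    rh = np.clip(58.0 - 12.0 * diel + rng.normal(0, 3.0, steps), 0, 100)
    ts = pd.Timestamp("2017-03-22") + pd.to_timedelta(t_hours, unit="h")
    return pd.DataFrame(
        {"timestamp": ts, "temperature": temp, "relative_humidity": rh}
    )


@dataclass
class SyntheticExperiment:
    """A full synthetic experiment bundle (both treatments)."""

    params: SimulationParams
    schedule: TreatmentSchedule
    trees: list[TreeSeries] = field(default_factory=list)
    detections: pd.DataFrame = None
    growth: pd.DataFrame = None
    lwp: pd.DataFrame = None
    environment: pd.DataFrame = None
    cambium: pd.DataFrame = None
    phases: pd.DataFrame = None
    truth: dict = None


def _counts_frame(
    tree_ids, n_days, step, level, seed
) -> pd.DataFrame:
    """Integer cell counts along three radial files every ``step`` days,
    jittered by at most one cell around ``level``."""
    rng = np.random.default_rng(seed)
    recs = []
    days = np.arange(0, n_days, step)
    for tid in tree_ids:
        for d in days:
            counts = np.maximum(1, np.round(level + rng.integers(-1, 2, 3))).astype(int)
            recs.append((tid, int(d), *counts, counts.mean()))
    return pd.DataFrame(
        recs, columns=["sample_id", "day", "file1", "file2", "file3", "mean_count"]
    )


def simulate_experiment(
    params: SimulationParams | None = None, seed: int | None = None
) -> SyntheticExperiment:
    """Simulate a complete two-treatment experiment.

    A single root seed (``seed`` or ``params.seed``) is split per tree and
    per table, so the whole bundle is reproducible bit-for-bit.
    """
    params = params or SimulationParams()
    root = params.seed if seed is None else seed
    ss = np.random.SeedSequence(root)
    n_sub = 4 * params.n_trees_per_treatment + 8
    subs = ss.generate_state(n_sub) % (2**31)

    schedule = None
    for attempt in range(1000):  # redraw deterministically until it fits
        try:
            schedule = generate_schedule(
                params.n_cycles, (3, 7), (3, 7),
                seed=int(subs[0]) + attempt, n_days=params.n_days,
            )
            break
        except ScheduleSpanError:
            continue
    if schedule is None:
        raise ScheduleSpanError(
            f"{params.n_cycles} cycles cannot fit in {params.n_days} days"
        )
    blocks = {"CI": ("B", "C"), "PI": ("A", "D")}
    trees, det_frames, growth_frames, lwp_frames = [], [], [], []
    k = 1
    for trt in ("CI", "PI"):
        for i in range(params.n_trees_per_treatment):
            tid = f"{trt}{i + 1:02d}"
            block = blocks[trt][i % 2]
            tree = simulate_tree(
                schedule, params, trt, seed=int(subs[k]), tree_id=tid, block=block
            )
            k += 1
            cells = simulate_cells(tree, params, seed=int(subs[k]))
            k += 1
            trees.append(tree)
            det_frames.append(cells)
            growth_frames.append(tree.growth_frame())
            lwp_frames.append(tree.lwp_frame())

    tree_ids = [t.tree_id for t in trees]
    cambium = _counts_frame(
        tree_ids, params.n_days, params.sampling_step,
        params.cambial_zone_cells, int(subs[k]),
    )
    phases = _counts_frame(
        tree_ids, params.n_days, params.sampling_step,
        params.enlargement_cohort, int(subs[k + 1]),
    )
    phases = phases.rename(columns={"mean_count": "eta_x"})
    phases["size_begin"] = params.size_begin
    env = simulate_environment(params.n_days, seed=int(subs[k + 2]))

    return SyntheticExperiment(
        params=params,
        schedule=schedule,
        trees=trees,
        detections=pd.concat(det_frames, ignore_index=True),
        growth=pd.concat(growth_frames, ignore_index=True),
        lwp=pd.concat(lwp_frames, ignore_index=True),
        environment=env,
        cambium=cambium,
        phases=phases[["sample_id", "day", "eta_x", "size_begin"]],
        truth=params.truth(),
    )
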