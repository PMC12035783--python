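"""Cell dating: convert diameter series into radial growth increments and
assign each detected cell a formation period from its radial depth.

The procedure mirrors how intra-experiment wood formation is reconstructed
from dendrometer-style daily diameter measurements: the diameter change
between consecutive period boundaries, halved (one radius) and clamped at
zero during shrinkage, gives each period's radial width; the cumulative
widths, anchored at the cambium (youngest tissue at depth 0), tile the wood
formed during the experiment; a cell's y-centroid, referenced to the cambial
boundary, then places it in exactly one period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvariantError, PreconditionError
from .simulate import TreatmentSchedule, TreeSeries

__all__ = [
    "GrowthIncrement",
    "compute_increments",
    "assign_cells",
    "increments_frame",
    "increments_from_frame",
    "interval_boundaries",
    "cycle_boundaries",
]


@dataclass(frozen=True)
class GrowthIncrement:
    """One period's radial growth band.

    ``period_index`` counts from 1 (oldest).  Depths are micrometres from
    the cambium; ``cum_outer`` is the younger (shallower) boundary, so the
    band occupies the half-open interval [cum_outer, cum_inner).
    """

    period_index: int
    start_day: int
    end_day: int
    width: float
    cum_outer: float
    cum_inner: float
    status: str  # droughted | watered | control

    @property
    def mid_day(self) -> float:
        return 0.5 * (self.start_day + self.end_day)


def interval_boundaries(days, step: int = 3) -> list[int]:
    """Evenly spaced period boundaries every ``step`` days (the sampling
    cadence preset); always includes the final day."""
    days = np.asarray(days)
    lo, hi = int(days.min()), int(days.max())
    bounds = list(range(lo, hi, step))
    if bounds[-1] != hi:
        bounds.append(hi)
    return bounds


def cycle_boundaries(schedule: TreatmentSchedule, last_day: int) -> list[int]:
    """Period boundaries at drought/watering cycle transitions."""
    bounds = [c.start_day for c in schedule.cycles]
    bounds.append(min(schedule.cycles[-1].end_day, last_day))
    return [b for b in bounds if b <= last_day]


def _status_for(
    start: int, end: int, schedule: TreatmentSchedule | None, treatment: str
) -> str:
    if treatment == "CI" or schedule is None:
        return "control"
    days = range(start, max(end, start + 1))
    n_dr = sum(schedule.status_on(d) == "droughted" for d in days)
    return "droughted" if 2 * n_dr > len(range(start, max(end, start + 1))) else "watered"


def compute_increments(
    tree,
    boundaries,
    schedule: TreatmentSchedule | None = None,
    radius_scale: float = 0.5,
) -> list[GrowthIncrement]:
    """Compute radial growth increments between consecutive boundary days.

    ``tree`` is a :class:`~xylokinetics.simulate.TreeSeries` or a growth
    DataFrame for a single tree (columns day, diameter in mm).  Width of
    period i is ``max(0, (diameter(b_{i+1}) - diameter(b_i)) * radius_scale)``
    in micrometres: diameter change is halved to one radius and shrinkage
    (negative change) is treated as elastic, contributing no width.
    Cumulative depths are anchored at the youngest increment (depth 0).
    """
    if isinstance(tree, TreeSeries):
        days = np.asarray(tree.days)
        diam = np.asarray(tree.diameter)
        treatment = tree.treatment
    else:
        df = tree.sort_values("day")
        days = df["day"].to_numpy()
        diam = df["diameter"].to_numpy()
        treatment = df["treatment"].iloc[0] if "treatment" in df else "PI"

    boundaries = list(boundaries)
    if len(boundaries) < 2:
        raise PreconditionError("need at least two boundary days")
    if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
        raise PreconditionError("boundaries must be strictly increasing")
    if boundaries[0] < days.min() or boundaries[-1] > days.max():
        raise PreconditionError(
            f"boundaries [{boundaries[0]}, {boundaries[-1]}] outside the "
            f"series' day range [{days.min()}, {days.max()}]"
        )

    day_to_diam = dict(zip(days.tolist(), diam.tolist()))
    widths = []
    for b1, b2 in zip(boundaries, boundaries[1:]):
        delta_mm = day_to_diam[b2] - day_to_diam[b1]
        widths.append(max(0.0, delta_mm * radius_scale * 1000.0))

    # youngest (last) increment at depth 0; accumulate backwards
    n = len(widths)
    cum_outer = np.concatenate([np.cumsum(widths[::-1])[::-1][1:], [0.0]])
    increments = []
    for i in range(n):
        increments.append(
            GrowthIncrement(
                period_index=i + 1,
                start_day=int(boundaries[i]),
                end_day=int(boundaries[i + 1]),
                width=widths[i],
                cum_outer=float(cum_outer[i]),
                cum_inner=float(cum_outer[i] + widths[i]),
                status=_status_for(boundaries[i], boundaries[i + 1], schedule, treatment),
            )
        )
    return increments


def _check_tiling(increments: list[GrowthIncrement]) -> None:
    incs = sorted(increments, key=lambda g: g.period_index)
    for older, younger in zip(incs, incs[1:]):
        if not np.isclose(older.cum_outer, younger.cum_inner, atol=1e-9):
            raise InvariantError(
                f"increments {older.period_index} and {younger.period_index} "
                "do not tile (gap or overlap in cumulative depths)"
            )
    if incs and abs(incs[-1].cum_outer) > 1e-9:
        raise InvariantError("youngest increment must start at depth 0")


def assign_cells(
    cells: pd.DataFrame,
    increments: list[GrowthIncrement],
    cambium_y: float | None = None,
    orientation: int = 1,
) -> pd.DataFrame:
    """Date each cell to a growth increment from its y-centroid.

    depth_from_cambium = orientation * (centroid_y - cambium_y); a cell
    belongs to increment i iff cum_outer_i <= depth < cum_inner_i.  Cells
    deeper than the total experiment growth are flagged ``pre_experiment``
    (formed before monitoring started); negative depths (on the phloem side
    of the cambial boundary) are ``unassigned``.  If ``cambium_y`` is not
    given it defaults to the extreme centroid on the cambial side.
    """
    if orientation not in (1, -1):
        raise PreconditionError("orientation must be +1 or -1")
    _check_tiling(increments)
    out = cells.copy()
    if len(out) == 0:
        out["depth_from_cambium"] = pd.Series(dtype=float)
        out["period_index"] = pd.Series(dtype="Int64")
        out["dating"] = pd.Series(dtype=object)
        return out

    y = out["centroid_y"].to_numpy(dtype=float)
    if cambium_y is None:
        cambium_y = float(y.min() if orientation == 1 else y.max())
    depth = orientation * (y - cambium_y)

    incs = sorted(increments, key=lambda g: g.period_index)
    total = incs[0].cum_inner if incs else 0.0
    # ascending edges youngest-first: cum_inner of period k, k-1, ..., 1
    edges = np.array([g.cum_inner for g in incs[::-1]])
    k = len(incs)
    j = np.searchsorted(edges, depth, side="right")
    period = k - j  # 0 => deeper than all increments

    dating = np.where(
        depth < 0, "unassigned", np.where(depth >= total, "pre_experiment", "assigned")
    )
    period = np.where(dating == "assigned", period, 0)

    out["depth_from_cambium"] = depth
    out["period_index"] = pd.array(
        np.where(dating == "assigned", period, np.nan), dtype="Int64"
    )
    out["dating"] = dating

    meta = pd.DataFrame(
        {
            "period_index": [g.period_index for g in incs],
            "start_day": [g.start_day for g in incs],
            "end_day": [g.end_day for g in incs],
            "mid_day": [g.mid_day for g in incs],
            "width_um": [g.width for g in incs],
            "status": [g.status for g in incs],
        }
    )
    meta["period_index"] = meta["period_index"].astype("Int64")
    out = out.merge(meta, on="period_index", how="left")
    return out


def increments_frame(
    increments: list[GrowthIncrement], sample_id: str | None = None
) -> pd.DataFrame:
    df = pd.DataFrame([vars(g) for g in increments])
    if sample_id is not None:
        df.insert(0, "sample_id", sample_id)
    return df


def increments_from_frame(df: pd.DataFrame) -> list[GrowthIncrement]:
    return [
        GrowthIncrement(
            int(r.period_index),
            int(r.start_day),
            int(r.end_day),
            float(r.width),
            float(r.cum_outer),
            float(r.cum_inner),
            str(r.status),
        )
        for r in df.itertuples()
    ]
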