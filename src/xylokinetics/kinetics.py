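"""Cambial kinetics: developmental rates and durations per growth period.

The rate of cell production along a radial file is the period's radial
growth divided by the mean diameter of the cells formed in it and by the
period length:

    phi_i = g_i / (D_i * t_i)                 [cells/day]

The cambial cell count eta_c and the count of cells in a developmental
phase (enlargement or wall thickening) eta_x then convert the production
rate into durations, and a size change across a phase into a rate:

    t_phi   = eta_c / phi_i                   [days, cell-cycle duration]
    t_sigma = eta_x / phi_i                   [days, phase duration]
    rate    = (Size_end - Size_begin) / t_sigma

These are steady-state identities: t_phi * phi = eta_c and
t_sigma * phi = eta_x hold exactly for every estimate.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import PreconditionError
from .traits import equivalent_diameter
from .zonation import GrowthIncrement

__all__ = [
    "cell_production_rate",
    "cell_cycle_duration",
    "phase_duration",
    "phase_rate",
    "estimate_kinetics",
    "DEFAULT_PERIODS",
]

# Inclusive day windows: two focal growth periods and the stretch between.
DEFAULT_PERIODS = [
    ("Period 1", 18, 28),
    ("in-between", 29, 59),
    ("Period 2", 60, 72),
]


def cell_production_rate(g_i: float, d_i: float, t_i: float) -> float:
    """phi_i = g_i / (D_i * t_i): radial growth per day in units of cells.

    g_i is the total radial growth in the period (um), D_i the mean
    diameter of cells formed in it (um), t_i the period length (days).
    """
    if d_i <= 0 or t_i <= 0:
        raise PreconditionError("cell_production_rate: D_i and t_i must be > 0")
    if g_i < 0:
        raise PreconditionError("cell_production_rate: g_i must be >= 0")
    return g_i / (d_i * t_i)


def cell_cycle_duration(eta_c: float, phi_i: float) -> float:
    """t_phi = eta_c / phi_i (days); NaN flags an undefined duration when
    no cells are being produced."""
    if eta_c < 0 or phi_i < 0:
        raise PreconditionError("cell_cycle_duration: negative input")
    if eta_c == 0:
        return 0.0
    if phi_i == 0:
        return float("nan")
    return eta_c / phi_i


def phase_duration(eta_x: float, phi_i: float) -> float:
    """t_sigma = eta_x / phi_i (days); NaN when phi_i = 0 with eta_x > 0."""
    if eta_x < 0 or phi_i < 0:
        raise PreconditionError("phase_duration: negative input")
    if eta_x == 0:
        return 0.0
    if phi_i == 0:
        return float("nan")
    return eta_x / phi_i


def phase_rate(size_end: float, size_begin: float, t_sigma: float) -> float:
    """Rate of enlargement or wall thickening: (end - begin) / t_sigma."""
    if not math.isfinite(t_sigma):
        return float("nan")
    if t_sigma <= 0:
        raise PreconditionError("phase_rate: t_sigma must be > 0")
    return (size_end - size_begin) / t_sigma


def _window_mean(df: pd.DataFrame, col: str, start: int, end: int) -> float:
    """Mean of ``col`` over rows with day in [start, end]; falls back to the
    rows at the nearest sampled day if the window holds none."""
    if df.empty:
        return float("nan")
    sel = df[(df["day"] >= start) & (df["day"] <= end)]
    if sel.empty:
        mid = 0.5 * (start + end)
        nearest = df.loc[(df["day"] - mid).abs().idxmin(), "day"]
        sel = df[df["day"] == nearest]
    return float(sel[col].mean())


def estimate_kinetics(
    dated: pd.DataFrame,
    increments: list[GrowthIncrement],
    cambium: pd.DataFrame,
    phases: pd.DataFrame,
    period_defs: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Estimate kinetics per sample and analysis period.

    Per (sample, period window): g_i sums increment widths pro-rated by
    each increment's fractional day-overlap with the window (so windows that
    cut across increment boundaries neither drop nor double-count growth),
    D_i is the mean equivalent-circle diameter of the fibres dated to
    increments whose mid-day falls in the window, t_i the window length in
    days.
    eta_c comes from the cambial-count table (mean of ``mean_count`` over
    the window, nearest sampling day if empty) and eta_x / Size_begin from
    the phase-count table; Size_end is the mean fibre area in the window.
    Periods with no dated fibres are flagged missing.
    """
    period_defs = period_defs or DEFAULT_PERIODS
    inc_mid = {g.period_index: g.mid_day for g in increments}

    def growth_in(start: int, end: int) -> float:
        """Increment widths pro-rated by day-overlap with [start, end]."""
        g_sum = 0.0
        for g in increments:
            span = g.end_day - g.start_day
            if span <= 0:
                continue
            overlap = min(g.end_day, end + 1) - max(g.start_day, start)
            if overlap > 0:
                g_sum += g.width * min(1.0, overlap / span)
        return g_sum

    assigned = dated[(dated["dating"] == "assigned")].copy()
    assigned["mid_day"] = assigned["period_index"].map(inc_mid).astype(float)

    rows = []
    for sample_id, cells in assigned.groupby("sample_id", sort=False):
        cam = cambium[cambium["sample_id"] == sample_id]
        pha = phases[phases["sample_id"] == sample_id]
        for label, start, end in period_defs:
            t_i = end - start + 1
            periods_in = [
                p for p, mid in inc_mid.items() if start <= mid <= end
            ]
            g_i = growth_in(start, end)
            fib = cells[
                (cells["cell_class"] == "fibre")
                & (cells["period_index"].isin(periods_in))
            ]
            eta_c = _window_mean(cam, "mean_count", start, end)
            eta_x = _window_mean(pha, "eta_x", start, end)
            size_begin = _window_mean(pha, "size_begin", start, end)
            base = dict(
                sample_id=sample_id,
                period_label=label,
                start_day=start,
                end_day=end,
                t_i=t_i,
                g_i=g_i,
                eta_c=eta_c,
                eta_x=eta_x,
                size_begin=size_begin,
            )
            if len(fib) == 0 or g_i == 0:
                phi = 0.0 if g_i == 0 and len(fib) == 0 else float("nan")
                rows.append(
                    base
                    | dict(
                        d_i=float("nan"),
                        phi=phi,
                        t_phi=float("nan"),
                        t_sigma=float("nan"),
                        size_end=float("nan"),
                        phase_rate=float("nan"),
                        flag="missing",
                    )
                )
                continue
            d_i = float(np.mean(equivalent_diameter(fib["cell_area"].to_numpy())))
            phi = cell_production_rate(g_i, d_i, t_i)
            t_phi = cell_cycle_duration(eta_c, phi)
            t_sigma = phase_duration(eta_x, phi)
            size_end = float(fib["cell_area"].mean())
            rows.append(
                base
                | dict(
                    d_i=d_i,
                    phi=phi,
                    t_phi=t_phi,
                    t_sigma=t_sigma,
                    size_end=size_end,
                    phase_rate=phase_rate(size_end, size_begin, t_sigma),
                    flag="ok",
                )
            )
    cols = [
        "sample_id",
        "period_label",
        "start_day",
        "end_day",
        "t_i",
        "g_i",
        "d_i",
        "phi",
        "eta_c",
        "t_phi",
        "eta_x",
        "t_sigma",
        "size_begin",
        "size_end",
        "phase_rate",
        "flag",
    ]
    return pd.DataFrame(rows, columns=cols)
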