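"""Statistical layer: Gamma GLM for water potential, Treatment x Period
mixed models with windowed contrasts, and relative-increment t tests.

Conventions
-----------
* Pre-dawn leaf water potential is stored as negative MPa; the Gamma GLM
  (identity link) needs a positive response, so it is fitted on magnitudes
  ``|psi_pd|`` and coefficients are reported on that scale (a positive
  treatment coefficient means more negative water potential).
* The trait mixed model is ``value ~ Treatment * Period`` with a random
  intercept per sample.  A per-cell random intercept is unidentifiable with
  one observation per cell and is therefore not fitted by default.
* Windowed contrasts compare per-sample mean trait values between
  treatments inside stated day windows with Welch t tests; no multiplicity
  correction is applied unless requested (Holm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import PreconditionError, RowError

__all__ = [
    "ModelResult",
    "fit_lwp_glm",
    "fit_trait_lmm",
    "windowed_contrasts",
    "relative_increment_test",
    "VESSEL_CSA_WINDOWS",
    "FIBRE_CSA_WINDOWS",
    "WALL_THICKNESS_WINDOWS",
]

# Day windows in which treatment differences were probed for each trait.
VESSEL_CSA_WINDOWS = [(26, 30), (64, 70)]
FIBRE_CSA_WINDOWS = [(23, 28), (64, 71)]
WALL_THICKNESS_WINDOWS = [(18, 24), (24, 28), (60, 65), (65, 72)]

ALPHA = 0.05


@dataclass
class ModelResult:
    """Fitted-model summary: term table, optional contrast table, metadata."""

    model: str
    terms: pd.DataFrame  # columns: term, estimate, se, stat, p
    contrasts: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def p_for(self, pattern: str) -> float:
        """p-value of the first term whose name contains ``pattern``."""
        hit = self.terms[self.terms["term"].str.contains(pattern, regex=False)]
        if hit.empty:
            raise KeyError(pattern)
        return float(hit["p"].iloc[0])

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "terms": self.terms.to_dict(orient="records"),
            "meta": self.meta,
        }
        if self.contrasts is not None:
            d["contrasts"] = self.contrasts.to_dict(orient="records")
        return d


def fit_lwp_glm(lwp: pd.DataFrame) -> ModelResult:
    """Gamma GLM (identity link) of water-potential magnitude on
    Treatment + Cycle.

    ``lwp`` needs columns psi_pd (<= 0), treatment and cycle.  Requires both
    treatments and at least two cycle levels.
    """
    for col in ("psi_pd", "treatment", "cycle"):
        if col not in lwp.columns:
            raise PreconditionError(f"LWP GLM: missing column '{col}'")
    if lwp["treatment"].nunique() < 2:
        raise PreconditionError("LWP GLM: both treatments must be present")
    if lwp["cycle"].nunique() < 2:
        raise PreconditionError("LWP GLM: need at least two cycles")
    df = lwp.copy()
    df["magnitude"] = -df["psi_pd"].astype(float)
    if (df["magnitude"] <= 0).any():
        raise RowError("LWP GLM: non-positive magnitude after sign flip")

    model = smf.glm(
        "magnitude ~ C(treatment) + C(cycle)",
        data=df,
        family=sm.families.Gamma(link=sm.families.links.Identity()),
    )
    res = model.fit()
    terms = pd.DataFrame(
        {
            "term": res.params.index,
            "estimate": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "stat": res.tvalues.to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )
    return ModelResult(
        model="lwp_glm",
        terms=terms,
        meta={
            "family": "Gamma(identity)",
            "response": "|psi_pd| (MPa magnitude)",
            "n": int(res.nobs),
            "alpha": ALPHA,
        },
    )


def _interaction_wald(res, names: list[str]) -> tuple[float, float, int]:
    """Joint Wald chi-square test that all named fixed effects are zero."""
    pnames = list(res.model.exog_names)
    idx = [pnames.index(n) for n in names]
    beta = np.asarray(res.fe_params)[idx]
    cov = np.asarray(res.cov_params())[np.ix_(idx, idx)]
    stat = float(beta @ np.linalg.solve(cov, beta))
    dof = len(idx)
    return stat, float(sps.chi2.sf(stat, dof)), dof


def fit_trait_lmm(
    cells: pd.DataFrame,
    value_col: str = "value",
    nested_cell_effect: bool = False,
) -> ModelResult:
    """Linear mixed model of a cell-level trait on Treatment x Period.

    ``cells`` needs columns sample_id, treatment, period and the trait in
    ``value_col``.  Fixed effects: Treatment, Period, Treatment:Period;
    random intercept per sample (optionally a nested per-cell variance
    component, off by default since it is unidentifiable with a single
    observation per cell).  The headline test is the joint Wald test of all
    interaction coefficients; it lands in the term table as
    ``Treatment:Period``.  Falls back to OLS if the mixed fit fails.
    """
    for col in ("sample_id", "treatment", "period", value_col):
        if col not in cells.columns:
            raise PreconditionError(f"trait LMM: missing column '{col}'")
    if cells["treatment"].nunique() < 2:
        raise PreconditionError("trait LMM: both treatments must be present")
    if cells["period"].nunique() < 2:
        raise PreconditionError("trait LMM: need at least two periods")
    per_trt = cells.groupby("treatment")["sample_id"].nunique()
    if (per_trt < 2).any():
        raise PreconditionError("trait LMM: need >= 2 samples per treatment")

    df = cells.dropna(subset=[value_col]).copy()
    formula = f"{value_col} ~ C(treatment) * C(period)"
    meta = {"formula": formula, "random": "~1 | sample_id", "alpha": ALPHA}
    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kwargs = {"groups": df["sample_id"]}
            if nested_cell_effect:
                df["_cell"] = np.arange(len(df)).astype(str)
                kwargs["vc_formula"] = {"cell": "0 + C(_cell)"}
            model = smf.mixedlm(formula, df, **kwargs)
            res = model.fit(reml=True, method="lbfgs")
        if not np.all(np.isfinite(np.asarray(res.bse_fe))):
            raise ValueError("singular mixed fit")
        params = res.fe_params
        bse = res.bse_fe
        pvals = res.pvalues[: len(params)]
        inter = [n for n in res.model.exog_names if ":" in n]
        wstat, wp, dof = _interaction_wald(res, inter)
    except Exception as exc:  # singular/non-converged: simplified structure
        fallback = True
        meta["warning"] = f"mixed fit failed ({exc}); refit as OLS"
        res = smf.ols(formula, df).fit()
        params = res.params
        bse = res.bse
        pvals = res.pvalues
        inter = [n for n in res.params.index if ":" in n]
        ftest = res.f_test(" = ".join(inter) + " = 0" if len(inter) > 1 else inter[0] + " = 0")
        wstat, wp, dof = float(ftest.fvalue), float(ftest.pvalue), len(inter)

    terms = pd.DataFrame(
        {
            "term": list(params.index),
            "estimate": np.asarray(params),
            "se": np.asarray(bse),
            "stat": np.asarray(params) / np.asarray(bse),
            "p": np.asarray(pvals),
        }
    )
    terms = pd.concat(
        [
            terms,
            pd.DataFrame(
                [
                    {
                        "term": "Treatment:Period",
                        "estimate": np.nan,
                        "se": np.nan,
                        "stat": wstat,
                        "p": wp,
                    }
                ]
            ),
        ],
        ignore_index=True,
    )
    meta["interaction_dof"] = dof
    meta["ols_fallback"] = fallback
    return ModelResult(model="trait_lmm", terms=terms, meta=meta)


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def windowed_contrasts(
    cells: pd.DataFrame,
    windows: list[tuple[int, int]],
    value_col: str = "value",
    day_col: str = "mid_day",
    holm: bool = False,
) -> pd.DataFrame:
    """Treatment contrasts of per-sample mean traits inside day windows.

    For each (start, end) window, cells with ``day_col`` in [start, end] are
    averaged per sample and the two treatments compared with a Welch t test.
    The estimate is mean(PI) - mean(CI).
    """
    rows = []
    for start, end in windows:
        sel = cells[(cells[day_col] >= start) & (cells[day_col] <= end)].dropna(
            subset=[value_col]
        )
        per_sample = (
            sel.groupby(["treatment", "sample_id"], observed=True)[value_col]
            .mean()
            .reset_index()
        )
        pi = per_sample.loc[per_sample["treatment"] == "PI", value_col].to_numpy()
        ci = per_sample.loc[per_sample["treatment"] == "CI", value_col].to_numpy()
        if len(pi) < 2 or len(ci) < 2:
            rows.append((start, end, np.nan, np.nan, np.nan, len(pi), len(ci)))
            continue
        t, p = sps.ttest_ind(pi, ci, equal_var=False)
        rows.append(
            (start, end, float(pi.mean() - ci.mean()), float(t), float(p),
             len(pi), len(ci))
        )
    out = pd.DataFrame(
        rows,
        columns=["window_start", "window_end", "estimate", "stat", "p", "n_pi", "n_ci"],
    )
    if holm:
        ok = out["p"].notna()
        adj = out["p"].copy()
        adj[ok] = _holm(out.loc[ok, "p"].to_numpy())
        out["p_holm"] = adj
    return out


def relative_increment_test(growth: pd.DataFrame) -> ModelResult:
    """Relative growth increments (end / start value per tree) compared
    between treatments: ANOVA first, then a two-sample t test, for both
    stem diameter and height."""
    for col in ("tree_id", "treatment", "day", "diameter", "height"):
        if col not in growth.columns:
            raise PreconditionError(f"relative increment: missing column '{col}'")
    rows = []
    ratios = {}
    for metric in ("diameter", "height"):
        per_tree = []
        for tid, grp in growth.groupby("tree_id", sort=False):
            grp = grp.sort_values("day")
            start, end = float(grp[metric].iloc[0]), float(grp[metric].iloc[-1])
            if start <= 0:
                raise RowError(f"relative increment: non-positive start {metric} "
                               f"for tree {tid}")
            per_tree.append((tid, grp["treatment"].iloc[0], end / start))
        df = pd.DataFrame(per_tree, columns=["tree_id", "treatment", "ratio"])
        ratios[metric] = df
        ci = df.loc[df["treatment"] == "CI", "ratio"].to_numpy()
        pi = df.loc[df["treatment"] == "PI", "ratio"].to_numpy()
        if len(ci) < 2 or len(pi) < 2:
            raise PreconditionError("relative increment: need >= 2 trees per treatment")
        if ci.var(ddof=1) == 0 and pi.var(ddof=1) == 0 and ci.mean() == pi.mean():
            fstat, fp, tstat, tp = 0.0, 1.0, 0.0, 1.0  # degenerate: no variation
        else:
            fstat, fp = sps.f_oneway(ci, pi)
            tstat, tp = sps.ttest_ind(ci, pi)
        rows.append((f"{metric}:anova", np.nan, np.nan, float(fstat), float(fp)))
        rows.append(
            (f"{metric}:t", float(ci.mean() - pi.mean()),
             float(np.sqrt(ci.var(ddof=1) / len(ci) + pi.var(ddof=1) / len(pi))),
             float(tstat), float(tp))
        )
    terms = pd.DataFrame(rows, columns=["term", "estimate", "se", "stat", "p"])
    return ModelResult(
        model="relative_increment",
        terms=terms,
        meta={
            "ratio_means": {
                m: ratios[m].groupby("treatment")["ratio"].mean().to_dict()
                for m in ratios
            },
            "alpha": ALPHA,
        },
    )
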