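"""Drug-response metrics from a fitted growth model and concordance tests.

Four metrics quantify each treatment arm against the untreated arm:

i.   ``delta_growth_rate``      — change in log-daily growth rate, delta_g.
ii.  ``delta_auc``              — difference in area under the marginal
     log-volume curve over [0, T]; for the linear predictor this equals the
     closed form beta_g * T + delta_g * T^2 / 2 exactly (negative = less
     tumor burden under treatment).
iii. ``growth_rate_on_treatment`` — log-daily growth rate under treatment,
     beta1 + delta_g, with SE from the full contrast variance
     sqrt(V[b1,b1] + V[d,d] + 2 V[b1,d]).
iv.  ``end_volume``             — per-mouse predicted volume (mm^3) at the
     end of treatment, using the mouse-level random effects (BLUPs).

Concordance with the matched patients' pathologic complete response (pCR)
labels is assessed with Wilcoxon rank-sum tests per metric (exact
distribution for small untied samples), with Benjamini-Hochberg correction
across the family of tests.

``factorial_sequential`` analyzes 3x3 sequential-treatment trials: one
mixed model per second-line treatment with the first-line treatment as the
grouping covariate, all four metrics per (first-line, second-line) cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .growth_model import (
    GrowthModelFit,
    fit_growth_model,
    marginal_log_curve,
    predict_mouse_log_volume,
)
from .synthetic_data import UNTREATED, TrialDataset

METRIC_NAMES = ("delta_growth_rate", "delta_auc", "growth_rate_on_treatment", "end_volume")


def _weekly_grid(t_end: float) -> np.ndarray:
    return np.arange(0.0, t_end + 1e-9, 7.0) if t_end >= 7 else np.array([0.0, t_end])


def metric_delta_growth(fit: GrowthModelFit, arm: str, alpha: float = 0.05):
    """Metric i: change in log-growth rate vs untreated (delta_g), with SE/CI/p."""
    if arm == fit.reference:
        from .growth_model import ContrastResult

        return ContrastResult(0.0, 0.0, fit.df_resid, np.nan, np.nan, 0.0, 0.0)
    c = pd.Series(0.0, index=fit.params.index)
    c[f"day:arm[{arm}]"] = 1.0
    return fit.contrast(c.to_numpy(), alpha=alpha)


def metric_delta_auc(
    fit: GrowthModelFit,
    arm: str,
    t_end: float | None = None,
    alpha: float = 0.05,
    scale: str = "log",
    grid=None,
):
    """Metric ii: AUC difference (treated minus untreated) over [0, t_end].

    On the modeled log scale the marginal curves are linear in t, so the
    trapezoid AUC difference reduces to the closed form
    beta_g * T + delta_g * T^2 / 2, a linear contrast of the fixed effects
    (inference comes for free).  ``scale='raw'`` instead integrates the
    exponentiated marginal curves on the weekly grid (sensitivity variant,
    point estimate only).
    """
    T = fit.t_end if t_end is None else float(t_end)
    if T <= 0:
        raise ValueError("t_end must be positive")
    if arm not in fit.arms:
        raise KeyError(f"unknown arm: {arm!r}")
    if scale == "raw":
        g = _weekly_grid(T) if grid is None else np.asarray(grid, dtype=float)
        a = np.trapezoid(np.exp(marginal_log_curve(fit, arm, g)), g)
        u = np.trapezoid(np.exp(marginal_log_curve(fit, fit.reference, g)), g)
        from .growth_model import ContrastResult

        return ContrastResult(float(a - u), np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)
    if arm == fit.reference:
        from .growth_model import ContrastResult

        return ContrastResult(0.0, 0.0, fit.df_resid, np.nan, np.nan, 0.0, 0.0)
    c = pd.Series(0.0, index=fit.params.index)
    c[f"arm[{arm}]"] = T
    c[f"day:arm[{arm}]"] = T * T / 2.0
    return fit.contrast(c.to_numpy(), alpha=alpha)


def auc_trapezoid(fit: GrowthModelFit, arm: str, t_end: float, grid=None) -> float:
    """Numeric trapezoid AUC difference of the marginal log curves (cross-check)."""
    g = _weekly_grid(t_end) if grid is None else np.asarray(grid, dtype=float)
    a = np.trapezoid(marginal_log_curve(fit, arm, g), g)
    u = np.trapezoid(marginal_log_curve(fit, fit.reference, g), g)
    return float(a - u)


def metric_growth_on_treatment(fit: GrowthModelFit, arm: str, alpha: float = 0.05):
    """Metric iii: log-daily growth rate under treatment, beta1 + delta_g."""
    if arm not in fit.arms:
        raise KeyError(f"unknown arm: {arm!r}")
    c = pd.Series(0.0, index=fit.params.index)
    c["day"] = 1.0
    if arm != fit.reference:
        c[f"day:arm[{arm}]"] = 1.0
    return fit.contrast(c.to_numpy(), alpha=alpha)


def metric_end_volume(fit: GrowthModelFit, t_end: float | None = None) -> pd.DataFrame:
    """Metric iv: per-mouse predicted volume (mm^3) at the end of treatment."""
    T = fit.t_end if t_end is None else float(t_end)
    if T <= 0:
        raise ValueError("t_end must be positive")
    rows = [
        (m, fit.mouse_arm[m], float(np.exp(predict_mouse_log_volume(fit, m, T))))
        for m in fit.random_effects.index
    ]
    return pd.DataFrame(rows, columns=["mouse", "arm", "volume_mm3"])


def compute_metrics(
    fit: GrowthModelFit, t_end: float | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """All four metrics for every treated arm, tidy (one row per estimate)."""
    T = fit.t_end if t_end is None else float(t_end)
    rows = []

    def add(arm, metric, r, mouse=None):
        rows.append(
            dict(
                model=fit.model_id, arm=arm, metric=metric, mouse=mouse,
                estimate=r.estimate, se=r.se, df=r.df,
                ci_lo=r.ci_lo, ci_hi=r.ci_hi, p=r.p,
            )
        )

    for arm in fit.arms:
        if arm != fit.reference:
            add(arm, "delta_growth_rate", metric_delta_growth(fit, arm, alpha))
            add(arm, "delta_auc", metric_delta_auc(fit, arm, T, alpha))
        add(arm, "growth_rate_on_treatment", metric_growth_on_treatment(fit, arm, alpha))
    ev = metric_end_volume(fit, T)
    for _, row in ev.iterrows():
        rows.append(
            dict(
                model=fit.model_id, arm=row["arm"], metric="end_volume", mouse=row["mouse"],
                estimate=row["volume_mm3"], se=np.nan, df=np.nan,
                ci_lo=np.nan, ci_hi=np.nan, p=np.nan,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pCR concordance


@dataclass
class ConcordanceResult:
    """Per-metric Wilcoxon rank-sum comparison of pCR vs non-pCR estimates."""

    table: pd.DataFrame  # metric, n_pcr, n_non_pcr, statistic, p, p_adj, test
    adjust_method: str

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha]


def wilcoxon_rank_sum(x, y) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact distribution when both groups have <= 12 observations and no
    ties; otherwise the normal approximation with continuity correction
    and midrank tie handling.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = x.size <= 12 and y.size <= 12 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def concordance_test(
    values: pd.DataFrame,
    pcr_labels,
    adjust: str = "fdr_bh",
) -> ConcordanceResult:
    """Compare per-model drug-response estimates between pCR and non-pCR groups.

    ``values`` is tidy with columns (model, metric, estimate); metrics with a
    value per mouse (end volume) may carry several rows per model, which are
    pooled within the pCR group.  ``pcr_labels`` maps model -> bool (True =
    the matched patient achieved pCR).  P values are corrected across the
    family of per-metric tests (Benjamini-Hochberg by default).
    """
    labels = pd.Series(pcr_labels).astype(bool)
    rows = []
    for metric, sub in values.groupby("metric", sort=False):
        known = sub[sub["model"].isin(labels.index)]
        is_pcr = known["model"].map(labels)
        x = known.loc[is_pcr, "estimate"].to_numpy()
        y = known.loc[~is_pcr, "estimate"].to_numpy()
        if x.size == 0 or y.size == 0:
            raise ValueError(f"metric {metric!r}: need models in both pCR and non-pCR groups")
        stat, p, method = wilcoxon_rank_sum(x, y)
        rows.append(dict(metric=metric, n_pcr=x.size, n_non_pcr=y.size,
                         statistic=stat, p=p, test=method))
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"].to_numpy(), method=adjust)[1]
    return ConcordanceResult(table, adjust)


# ---------------------------------------------------------------------------
# 3x3 factorial sequential-treatment analysis


@dataclass
class FactorialResult:
    """Per-second-line fits and the 3x3 grid of response metrics."""

    fits: dict  # second-line treatment -> GrowthModelFit (arms = first-line groups)
    metrics: pd.DataFrame  # first_line, second_line, metric, estimate, ...


def factorial_sequential(
    datasets: dict,
    first_line_labels=(UNTREATED, "CT", "olaparib"),
    method: str = "REML",
) -> FactorialResult:
    """Sequential-treatment analysis: one mixed model per second-line arm.

    ``datasets`` maps each second-line treatment to a TrialDataset whose
    ``arm`` column holds the *first-line* treatment of each mouse.  Each fit
    uses first-line untreated as the reference, so arm contrasts measure how
    the first-line exposure reshapes response to that second-line treatment.
    """
    fits = {}
    frames = []
    for second, ds in datasets.items():
        present = set(ds.data["arm"].unique())
        missing = set(first_line_labels) - present
        if missing:
            raise ValueError(f"second-line {second!r}: missing first-line groups {sorted(missing)}")
        fit = fit_growth_model(ds, method=method, reference=UNTREATED)
        fits[second] = fit
        m = compute_metrics(fit)
        m = m.rename(columns={"arm": "first_line"})
        m.insert(1, "second_line", second)
        frames.append(m)
    metrics = pd.concat(frames, ignore_index=True)
    return FactorialResult(fits, metrics)
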