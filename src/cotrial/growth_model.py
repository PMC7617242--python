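"""Log-linear mixed-effects tumor-growth model for one PDTX trial.

The model assumes exponential tumor growth:

    log TV_it = beta0 + beta_g + (beta1 + delta_g) * t + u0_i + u1_i * t + eps_it

with fixed arm effects (reference arm: untreated), per-mouse random
intercepts and slopes with an unstructured 2x2 covariance, and iid
residuals.  Estimation is by REML (ML optional) via statsmodels MixedLM.

Inference on fixed-effect contrasts uses the Satterthwaite degrees-of-
freedom approximation, computed from a numerical Hessian of the REML
log-likelihood over the variance parameters; the residual df
(n_obs - n_fixed) is used as a fallback whenever the approximation is
numerically unreliable (e.g. variance components pinned at zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .synthetic_data import UNTREATED, TrialDataset

_FLOOR_MM3 = 1.0  # detection floor for regressed/unmeasurable tumors


@dataclass
class ContrastResult:
    """t-based inference for one linear contrast of the fixed effects."""

    estimate: float
    se: float
    df: float
    tstat: float
    p: float
    ci_lo: float
    ci_hi: float


@dataclass
class GrowthModelFit:
    """Fitted growth model: fixed effects, vcov, random effects, variance components."""

    params: pd.Series  # fixed effects on the log-volume scale
    vcov: pd.DataFrame  # variance-covariance of the fixed effects
    df_resid: float
    arms: list
    reference: str
    random_effects: pd.DataFrame  # index mouse; columns u0, u1
    mouse_arm: pd.Series  # mouse -> arm
    sd_u0: float
    sd_u1: float
    corr_u: float
    sd_eps: float
    method: str
    converged: bool
    singular: bool
    n_obs: int
    n_mice: int
    n_floored: int
    t_end: float
    model_id: str = ""
    _groups: list = field(default_factory=list, repr=False)  # (y_i, X_i, Z_i) per mouse
    _theta: np.ndarray | None = field(default=None, repr=False)  # (g00, g01, g11, s2)

    # -- linear predictor helpers -------------------------------------------------

    def contrast_vector(self, arm: str, t: float = 0.0) -> np.ndarray:
        """Coefficient vector c with c'beta = marginal log volume of ``arm`` at day t."""
        if arm not in self.arms:
            raise KeyError(f"unknown arm: {arm!r}")
        c = pd.Series(0.0, index=self.params.index)
        c["Intercept"] = 1.0
        c["day"] = t
        if arm != self.reference:
            c[f"arm[{arm}]"] = 1.0
            c[f"day:arm[{arm}]"] = t
        return c.to_numpy()

    def contrast(self, c, alpha: float = 0.05, df_method: str = "satterthwaite") -> ContrastResult:
        """Estimate, SE, t, p and CI for the linear contrast c'beta."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params.to_numpy())
        var = float(c @ self.vcov.to_numpy() @ c)
        se = float(np.sqrt(max(var, 0.0)))
        df = self.contrast_df(c) if df_method == "satterthwaite" else self.df_resid
        if se == 0.0:
            t = np.inf if est != 0 else 0.0
            p = 0.0 if est != 0 else 1.0
            return ContrastResult(est, se, df, t, p, est, est)
        t = est / se
        p = float(2.0 * scipy.stats.t.sf(abs(t), df))
        q = scipy.stats.t.ppf(1.0 - alpha / 2.0, df)
        return ContrastResult(est, se, df, t, p, est - q * se, est + q * se)

    def contrast_df(self, c) -> float:
        """Satterthwaite df for contrast c; residual df on numerical failure."""
        df = _satterthwaite_df(self, np.asarray(c, dtype=float))
        return df if df is not None else self.df_resid

    def to_dict(self) -> dict:
        """JSON-serializable fit summary."""
        return {
            "model_id": self.model_id,
            "method": self.method,
            "reference": self.reference,
            "arms": list(self.arms),
            "coefficients": self.params.to_dict(),
            "vcov": self.vcov.to_numpy().tolist(),
            "coef_names": list(self.params.index),
            "variance_components": {
                "sd_u0": self.sd_u0,
                "sd_u1": self.sd_u1,
                "corr_u": self.corr_u,
                "sd_eps": self.sd_eps,
            },
            "df_resid": self.df_resid,
            "n_obs": self.n_obs,
            "n_mice": self.n_mice,
            "n_floored": self.n_floored,
            "t_end": self.t_end,
            "converged": self.converged,
            "singular": self.singular,
        }


def design_matrix(df: pd.DataFrame, arms: list, reference: str) -> pd.DataFrame:
    """Fixed-effects design: intercept, arm mains, day, day-by-arm interactions."""
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    others = [a for a in arms if a != reference]
    for a in others:
        X[f"arm[{a}]"] = (df["arm"] == a).astype(float)
    X["day"] = df["day"].astype(float)
    for a in others:
        X[f"day:arm[{a}]"] = X[f"arm[{a}]"] * X["day"]
    return X


def fit_growth_model(
    data: TrialDataset,
    method: str = "REML",
    reference: str = UNTREATED,
    model_id: str | None = None,
) -> GrowthModelFit:
    """Fit the log-linear mixed growth model for one PDTX model's trial.

    ``data`` must contain a single PDTX model (use ``TrialDataset.subset_model``
    otherwise).  Volumes below the 1 mm^3 detection floor are floored before
    the log transform (the count is recorded on the fit); negative volumes
    are rejected.  A fit with a variance component pinned at (numerical)
    zero is returned with ``singular=True`` rather than failing silently.
    """
    if method.upper() not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    df = data.data.copy()
    models = df["model"].unique()
    if model_id is None:
        if len(models) > 1:
            raise ValueError("dataset holds multiple PDTX models; fit one at a time")
        model_id = str(models[0]) if len(models) else ""
    else:
        df = df[df["model"] == model_id]

    if (df["volume_mm3"] < 0).any():
        raise ValueError("negative tumor volumes are not permitted")
    arms = sorted(df["arm"].unique())
    if reference not in arms:
        raise ValueError(f"reference arm {reference!r} missing from data")

    n_floored = int((df["volume_mm3"] < _FLOOR_MM3).sum())
    vol = df["volume_mm3"].clip(lower=_FLOOR_MM3)
    y = np.log(vol.to_numpy())
    X = design_matrix(df, arms, reference)
    mouse = df["mouse"].astype(str)
    mouse_arm = df.groupby(mouse)["arm"].first()
    n_obs, p = X.shape
    df_resid = float(n_obs - p)

    # ordinary least squares: degenerate (perfect-fit) detection + fallback
    beta_ols, ssr, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    resid = y - X.to_numpy() @ beta_ols
    if float(resid @ resid) <= 1e-12 * max(n_obs, 1):
        params = pd.Series(beta_ols, index=X.columns)
        vcov = pd.DataFrame(0.0, index=X.columns, columns=X.columns)
        re = pd.DataFrame(0.0, index=mouse_arm.index, columns=["u0", "u1"])
        return GrowthModelFit(
            params, vcov, df_resid, arms, reference, re, mouse_arm,
            0.0, 0.0, 0.0, 0.0, method.upper(), True, True,
            n_obs, len(mouse_arm), n_floored, data.t_end, model_id,
        )

    exog_re = pd.DataFrame({"Intercept": 1.0, "day": df["day"].astype(float)}, index=df.index)
    mdl = sm.MixedLM(y, X, groups=mouse.to_numpy(), exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mdl.fit(reml=(method.upper() == "REML"))
    converged = bool(getattr(res, "converged", True))

    params = pd.Series(res.fe_params.to_numpy(), index=X.columns)
    vcov = pd.DataFrame(
        res.cov_params().to_numpy()[:p, :p], index=X.columns, columns=X.columns
    )
    G = res.cov_re.to_numpy()
    s2 = float(res.scale)
    sd_u0, sd_u1 = float(np.sqrt(max(G[0, 0], 0.0))), float(np.sqrt(max(G[1, 1], 0.0)))
    corr = float(G[0, 1] / (sd_u0 * sd_u1)) if sd_u0 > 0 and sd_u1 > 0 else 0.0
    eigs = np.linalg.eigvalsh(G)
    singular = bool(eigs.min() <= 1e-10 * max(eigs.max(), 1e-12) or s2 <= 1e-12)

    re_rows = {}
    for m, ser in res.random_effects.items():
        vals = ser.to_numpy()
        re_rows[str(m)] = (float(vals[0]), float(vals[1]))
    re = pd.DataFrame.from_dict(re_rows, orient="index", columns=["u0", "u1"])
    re = re.reindex(mouse_arm.index)

    groups = []
    for m, sub in df.assign(_y=y).groupby(mouse, sort=True):
        Xi = design_matrix(sub, arms, reference).to_numpy()
        Zi = np.column_stack([np.ones(len(sub)), sub["day"].to_numpy(dtype=float)])
        groups.append((sub["_y"].to_numpy(), Xi, Zi))
    theta = np.array([G[0, 0], G[0, 1], G[1, 1], s2])

    return GrowthModelFit(
        params, vcov, df_resid, arms, reference, re, mouse_arm,
        sd_u0, sd_u1, corr, float(np.sqrt(s2)), method.upper(), converged, singular,
        n_obs, len(mouse_arm), n_floored, data.t_end, model_id,
        _groups=groups, _theta=theta,
    )


def predict_mouse_log_volume(fit: GrowthModelFit, mouse: str, t) -> np.ndarray | float:
    """Conditional (BLUP) prediction of log volume for one mouse at day(s) t."""
    mouse = str(mouse)
    if mouse not in fit.random_effects.index:
        raise KeyError(f"unknown mouse: {mouse!r}")
    arm = fit.mouse_arm[mouse]
    u0, u1 = fit.random_effects.loc[mouse, ["u0", "u1"]]
    t = np.asarray(t, dtype=float)
    out = marginal_log_curve(fit, arm, t) + u0 + u1 * t
    return float(out) if out.ndim == 0 else out


def marginal_log_curve(fit: GrowthModelFit, arm: str, t) -> np.ndarray | float:
    """Fixed-effects-only (population mean) log-volume curve for an arm."""
    if arm not in fit.arms:
        raise KeyError(f"unknown arm: {arm!r}")
    t = np.asarray(t, dtype=float)
    b = fit.params
    out = b["Intercept"] + b["day"] * t
    if arm != fit.reference:
        out = out + b[f"arm[{arm}]"] + b[f"day:arm[{arm}]"] * t
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Satterthwaite degrees of freedom (REML-based)


def _reml_loglike(theta: np.ndarray, groups: list) -> float:
    """Restricted log-likelihood at variance parameters theta = (g00, g01, g11, s2)."""
    G = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    s2 = theta[3]
    if s2 <= 0 or np.linalg.eigvalsh(G).min() < -1e-12:
        return -np.inf
    p = groups[0][1].shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    for y, X, Z in groups:
        V = Z @ G @ Z.T + s2 * np.eye(len(y))
        sign, ld = np.linalg.slogdet(V)
        if sign <= 0:
            return -np.inf
        logdet += ld
        Vi_X = np.linalg.solve(V, X)
        Vi_y = np.linalg.solve(V, y)
        XtViX += X.T @ Vi_X
        XtViy += X.T @ Vi_y
        ytViy += y @ Vi_y
    sign, ld_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, XtViy)
    quad = ytViy - beta @ XtViy
    return -0.5 * (logdet + ld_x + quad)


def _fe_contrast_var(theta: np.ndarray, groups: list, c: np.ndarray) -> float:
    """c' Cov(beta_hat)(theta) c with Cov = (sum X'V^-1 X)^-1."""
    G = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    s2 = theta[3]
    p = groups[0][1].shape[1]
    XtViX = np.zeros((p, p))
    for _, X, Z in groups:
        V = Z @ G @ Z.T + s2 * np.eye(Z.shape[0])
        XtViX += X.T @ np.linalg.solve(V, X)
    return float(c @ np.linalg.solve(XtViX, c))


def _satterthwaite_df(fit: GrowthModelFit, c: np.ndarray) -> float | None:
    """Satterthwaite df: 2*(c'Vc)^2 / Var(c'Vc), via the numerical REML Hessian.

    Returns None when the approximation is unreliable (boundary fit,
    non-invertible Hessian, non-positive variance of the variance).
    """
    if not fit._groups or fit._theta is None or fit.singular:
        return None
    theta = fit._theta
    groups = fit._groups
    scale = np.maximum(np.abs(theta), 1e-8)

    try:
        f0 = _fe_contrast_var(theta, groups, c)
        if f0 <= 0:
            return None
        # gradient of the contrast variance wrt variance parameters
        grad = np.zeros(4)
        for j in range(4):
            h = 1e-5 * scale[j]
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            grad[j] = (_fe_contrast_var(tp, groups, c) - _fe_contrast_var(tm, groups, c)) / (2 * h)
        # observed REML information (numerical Hessian of -loglik)
        H = np.zeros((4, 4))
        hs = 1e-4 * scale
        for j in range(4):
            for k in range(j, 4):
                pp = theta.copy(); pp[j] += hs[j]; pp[k] += hs[k]
                pm = theta.copy(); pm[j] += hs[j]; pm[k] -= hs[k]
                mp = theta.copy(); mp[j] -= hs[j]; mp[k] += hs[k]
                mm = theta.copy(); mm[j] -= hs[j]; mm[k] -= hs[k]
                vals = [_reml_loglike(t, groups) for t in (pp, pm, mp, mm)]
                if not all(np.isfinite(vals)):
                    return None
                H[j, k] = H[k, j] = -(vals[0] - vals[1] - vals[2] + vals[3]) / (4 * hs[j] * hs[k])
        Acov = np.linalg.pinv(H)
        var_f = float(grad @ Acov @ grad)
        if var_f <= 0:
            return None
        df = 2.0 * f0**2 / var_f
    except (np.linalg.LinAlgError, FloatingPointError, ValueError):
        return None
    if not np.isfinite(df) or df < 1.0:
        return None
    return float(min(df, fit.df_resid))
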