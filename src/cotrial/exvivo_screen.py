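"""Scoring of high-throughput ex vivo drug screens on dissociated PDTX cells.

Per (sample, drug): control-normalized observed responses, a nonparametric
isotonic (monotone least-squares) dose-response fit over technical
replicates, and a trapezoid AUC over log10 concentration normalized to
[0, 1].  An increase in AUC denotes a gain in sensitivity, so the shift
post-treated minus untreated measures treatment-induced sensitization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .synthetic_data import ScreenPlate


def observed_response(intensity, neg_mean: float, pos_mean: float):
    """Observed response (%) = 100 - 100 * (I - neg) / (pos - neg).

    Equals 100 at the negative-control intensity and 0 at the
    positive-control intensity; values outside [0, 100] are not clipped.
    """
    if neg_mean == pos_mean:
        raise ValueError("degenerate controls: negative and positive means are equal")
    i = np.asarray(intensity, dtype=float)
    out = 100.0 - 100.0 * (i - neg_mean) / (pos_mean - neg_mean)
    return float(out) if out.ndim == 0 else out


def fit_isotonic(doses, responses, increasing: bool = True) -> np.ndarray:
    """Monotone least-squares (pool-adjacent-violators) fit over wells ordered by dose.

    Replicate wells at the same dose share one fitted value (the pooled
    block solution).  Returns fitted values aligned with the input order.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must align")
    if np.unique(doses).size < 2:
        raise ValueError("need at least 2 distinct doses")
    if not np.all(np.isfinite(responses)):
        raise ValueError("responses must be finite")
    iso = IsotonicRegression(increasing=increasing, out_of_bounds="clip")
    return iso.fit_transform(doses, responses)


@dataclass
class DoseResponseFit:
    """Isotonic dose-response fit for one (sample, drug) pair."""

    sample: str
    drug: str
    doses: np.ndarray  # per well, umol/L
    responses: np.ndarray  # observed response (%) per well
    fitted: np.ndarray  # isotonic fit per well
    increasing: bool = True

    def dose_grid(self) -> np.ndarray:
        return np.unique(self.doses)

    def fitted_by_dose(self) -> pd.DataFrame:
        df = pd.DataFrame({"dose": self.doses, "response": self.responses, "fitted": self.fitted})
        return df.groupby("dose", as_index=False).agg(
            mean_response=("response", "mean"), fitted=("fitted", "mean")
        )


def fit_dose_response(
    plate: ScreenPlate,
    sample: str = "",
    control_stat: str = "mean",
    increasing: bool = True,
) -> DoseResponseFit:
    """Normalize a plate against its controls and fit the isotonic curve."""
    neg = plate.control_mean("neg", control_stat)
    pos = plate.control_mean("pos", control_stat)
    wells = plate.sample_wells()
    if wells.empty:
        raise ValueError("plate has no sample wells")
    doses = wells["conc_umol"].to_numpy(dtype=float)
    resp = observed_response(wells["intensity"].to_numpy(), neg, pos)
    fitted = fit_isotonic(doses, resp, increasing=increasing)
    drug = str(wells["drug"].iloc[0])
    return DoseResponseFit(sample, drug, doses, np.asarray(resp), fitted, increasing)


def curve_auc(fit: DoseResponseFit) -> float:
    """Normalized trapezoid AUC of the fitted curve over log10 concentration.

    The integral is divided by 100 x the log10 dose range, giving values in
    [0, 1] when responses lie in [0, 100]; higher = more sensitive.
    """
    by_dose = fit.fitted_by_dose()
    if len(by_dose) < 2:
        raise ValueError("need at least 2 distinct doses for an AUC")
    x = np.log10(by_dose["dose"].to_numpy())
    y = by_dose["fitted"].to_numpy()
    return float(np.trapezoid(y, x) / (100.0 * (x[-1] - x[0])))


def screen_shift(untreated_fit: DoseResponseFit, posttreated_fit: DoseResponseFit) -> float:
    """AUC shift, post-treated minus untreated; positive = gained sensitivity."""
    if untreated_fit.drug != posttreated_fit.drug:
        raise ValueError("AUC shift requires the same drug")
    if not np.array_equal(untreated_fit.dose_grid(), posttreated_fit.dose_grid()):
        raise ValueError("AUC shift requires matching dose grids")
    return curve_auc(posttreated_fit) - curve_auc(untreated_fit)


def score_screen(
    plates: dict,
    control_stat: str = "mean",
    increasing: bool = True,
) -> pd.DataFrame:
    """AUC matrix for a set of plates keyed by (sample, drug) -> ScreenPlate.

    Returns a tidy frame (sample, drug, auc); pivot for the sample x drug
    matrix mirroring an in-vivo-arm by compound sensitivity panel.
    """
    rows = []
    for (sample, drug), plate in plates.items():
        fit = fit_dose_response(plate, sample=sample, control_stat=control_stat,
                                increasing=increasing)
        rows.append(dict(sample=sample, drug=drug, auc=curve_auc(fit)))
    return pd.DataFrame(rows)
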