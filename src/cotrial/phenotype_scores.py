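"""Metacell phenotype quantification for treated/untreated PDTX single cells.

Covers the downstream single-cell steps: cell QC (UMI and mitochondrial
filters), per-metacell log2 gene-enrichment footprints, anchor-correlated
gene signatures, epithelial / mesenchymal / immediate-early-response (IER)
scores, EMT and IER stratification along the phenotype continuum,
transcription-factor trajectories across strata, and per-condition cell
state composition.  Metacell (MC) partitions and state labels are consumed
as input; deriving them is out of scope.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .synthetic_data import CellMatrix, MetacellModel

#: Anchor genes defining the epithelial, mesenchymal and IER signatures.
ANCHORS = {"epithelial": "KRT81", "mesenchymal": "VIM", "ier": "JUNB"}

#: Metacell states entering the EMT continuum / IER stratifications.
EMT_STATES = ("epithelial", "EM-hybrid", "EM-hybrid-IER", "mesenchymal")
IER_STATES = ("EM-hybrid", "EM-hybrid-IER")


def qc_filter_cells(
    cells: CellMatrix, min_nonmito_umis: int = 750, max_mito_frac: float = 0.40
) -> np.ndarray:
    """Boolean keep-mask: >= 750 non-mitochondrial UMIs AND mito fraction strictly < 0.40."""
    counts = sp.csr_matrix(cells.counts)
    is_mito = cells.genes["is_mito"].to_numpy(dtype=bool)
    mito = np.asarray(counts[:, is_mito].sum(axis=1)).ravel()
    total = np.asarray(counts.sum(axis=1)).ravel()
    nonmito = total - mito
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return (nonmito >= min_nonmito_umis) & (mito_frac < max_mito_frac)


def umi_per_1000(counts) -> np.ndarray:
    """Normalize UMI counts to UMIs per 1,000 total (rows sum to 1000)."""
    x = np.asarray(counts, dtype=float)
    if x.ndim == 1:
        tot = x.sum()
        if tot <= 0:
            raise ValueError("unit has no UMIs")
        return 1000.0 * x / tot
    tot = x.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("every unit must have positive total UMIs")
    return 1000.0 * x / tot


def mc_enrichment(model: MetacellModel, eps: float = 1e-5) -> pd.DataFrame:
    """Per-metacell log2 gene enrichment vs the pooled dataset.

    e_{g,m} = log2((f_{g,m} + eps) / (f_{g,pool} + eps)) with f the UMI
    fractions within metacell m and in the pool of all metacells.  The
    regularization eps (on the fraction scale) keeps zeros finite.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    counts = model.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("every metacell must have positive total UMIs")
    f_mc = counts / totals
    f_pool = counts.sum(axis=0) / counts.sum()
    e = np.log2((f_mc + eps) / (f_pool + eps))
    return pd.DataFrame(e, index=model.counts.index, columns=model.counts.columns)


def anchor_gene_signature(
    enrichment: pd.DataFrame, anchor: str, n: int = 50
) -> list[str]:
    """The n genes whose enrichment profiles across MCs correlate best with the anchor.

    Pearson correlation of log2 enrichment profiles; the anchor correlates
    1 with itself so is always included.  Ties break by gene-id order; n
    larger than the gene count returns every gene.
    """
    if anchor not in enrichment.columns:
        raise KeyError(f"anchor gene {anchor!r} absent from the enrichment matrix")
    mat = enrichment.to_numpy()
    a = enrichment[anchor].to_numpy()
    centered = mat - mat.mean(axis=0)
    ac = a - a.mean()
    denom = np.sqrt((centered**2).sum(axis=0) * (ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, centered.T @ ac / np.where(denom > 0, denom, 1.0), -np.inf)
    corr = pd.Series(corr, index=enrichment.columns)
    corr[anchor] = np.inf  # self-correlation: anchor always leads its own signature
    order = sorted(enrichment.columns, key=lambda g: (-corr[g], g))
    return order[: min(n, len(order))]


def score_mcs(enrichment: pd.DataFrame, signature) -> pd.Series:
    """Per-MC score: mean log2 enrichment over the signature genes."""
    signature = list(signature)
    if not signature:
        raise ValueError("signature must be non-empty")
    missing = [g for g in signature if g not in enrichment.columns]
    if missing:
        raise KeyError(f"signature genes absent: {missing[:5]}")
    return enrichment[signature].mean(axis=1)


def stratify(scores: pd.Series, n_strata: int, method: str = "equal_width") -> pd.Series:
    """Bin MCs into ordered strata (1..n) by score.

    ``equal_width`` splits the observed score range into equal-width bins
    (quantile binning behind ``method='quantile'``).  Labels are monotone
    in score.  If all scores coincide, every MC lands in stratum 1 and a
    warning is emitted.
    """
    if n_strata < 2:
        raise ValueError("n_strata must be >= 2")
    if len(scores) < n_strata:
        raise ValueError("fewer metacells than strata")
    s = scores.to_numpy(dtype=float)
    lo, hi = s.min(), s.max()
    if lo == hi:
        warnings.warn("all scores identical; single stratum", stacklevel=2)
        return pd.Series(1, index=scores.index)
    if method == "equal_width":
        edges = np.linspace(lo, hi, n_strata + 1)
    elif method == "quantile":
        edges = np.quantile(s, np.linspace(0, 1, n_strata + 1))
    else:
        raise ValueError(f"unknown binning method: {method!r}")
    labels = np.clip(np.searchsorted(edges[1:-1], s, side="right") + 1, 1, n_strata)
    return pd.Series(labels, index=scores.index)


def emt_strata(
    model: MetacellModel,
    enrichment: pd.DataFrame,
    n_strata: int = 5,
    signatures: dict | None = None,
    method: str = "equal_width",
) -> pd.DataFrame:
    """EMT1..5 stratification by mesenchymal-minus-epithelial score.

    Restricted to epithelial / EM-hybrid(-IER) / mesenchymal MCs; returns
    per-MC scores and the EMT stratum label.
    """
    if signatures is None:
        signatures = {k: anchor_gene_signature(enrichment, a) for k, a in ANCHORS.items()}
    states = model.mcs.set_index("mc")["state"]
    keep = states[states.isin(EMT_STATES)].index
    if keep.empty:
        raise ValueError("no metacells in EMT-continuum states")
    sub = enrichment.loc[keep]
    s_epi = score_mcs(sub, signatures["epithelial"])
    s_mes = score_mcs(sub, signatures["mesenchymal"])
    s_ier = score_mcs(sub, signatures["ier"])
    basis = s_mes - s_epi
    out = pd.DataFrame(
        {"S_epi": s_epi, "S_mes": s_mes, "S_ier": s_ier, "mes_minus_epi": basis}
    )
    out["emt_stratum"] = stratify(basis, n_strata, method=method)
    return out


def ier_strata(
    model: MetacellModel,
    enrichment: pd.DataFrame,
    n_strata: int = 4,
    signature: list | None = None,
    method: str = "equal_width",
) -> pd.DataFrame:
    """IER1..4 stratification of EM-hybrid(-IER) MCs by the IER score."""
    if signature is None:
        signature = anchor_gene_signature(enrichment, ANCHORS["ier"])
    states = model.mcs.set_index("mc")["state"]
    keep = states[states.isin(IER_STATES)].index
    if keep.empty:
        raise ValueError("no EM-hybrid metacells for the IER stratification")
    s_ier = score_mcs(enrichment.loc[keep], signature)
    out = pd.DataFrame({"S_ier": s_ier})
    out["ier_stratum"] = stratify(s_ier, n_strata, method=method)
    return out


def tf_trajectory(
    enrichment: pd.DataFrame, tf_list, strata: pd.Series
) -> pd.DataFrame:
    """Mean log2 enrichment per (TF, stratum), strata ordered 1..n.

    TFs absent from the enrichment matrix are dropped with a warning.
    """
    present = [tf for tf in tf_list if tf in enrichment.columns]
    dropped = [tf for tf in tf_list if tf not in enrichment.columns]
    if dropped:
        warnings.warn(f"TFs absent from enrichment matrix, dropped: {dropped}", stacklevel=2)
    if not present:
        raise ValueError("no requested TFs present")
    sub = enrichment.loc[strata.index, present]
    out = sub.groupby(strata).mean().T
    out.columns = [int(c) for c in out.columns]
    return out[sorted(out.columns)]


def state_composition(cells: pd.DataFrame, states: pd.Series) -> pd.DataFrame:
    """Percent of cells per metacell state within each condition (rows sum to 100).

    ``cells`` needs columns (cell, condition, mc); ``states`` maps mc -> state.
    Cells mapped to an unlabeled MC are rejected.
    """
    mapped = cells["mc"].map(states)
    if mapped.isna().any():
        bad = cells.loc[mapped.isna(), "mc"].unique()
        raise ValueError(f"cells mapped to metacells without state labels: {list(bad)[:5]}")
    tab = pd.crosstab(cells["condition"], mapped)
    return 100.0 * tab.div(tab.sum(axis=1), axis=0)


def phenotype_report(model: MetacellModel, eps: float = 1e-5) -> pd.DataFrame:
    """Convenience end-to-end scoring: enrichment, scores and strata per MC."""
    e = mc_enrichment(model, eps=eps)
    emt = emt_strata(model, e)
    out = emt.reindex(model.counts.index)
    try:
        ier = ier_strata(model, e)
        out["ier_stratum"] = ier["ier_stratum"].reindex(out.index)
    except ValueError:
        out["ier_stratum"] = np.nan
    out.insert(0, "mc", out.index)
    out.insert(1, "state", model.mcs.set_index("mc")["state"].reindex(out.index).to_numpy())
    return out.reset_index(drop=True)
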