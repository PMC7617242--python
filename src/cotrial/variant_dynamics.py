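"""Treatment-emergent / treatment-depleted mutation calls and VAF concordance.

A variant is *present* in a sample when its VAF reaches the detection
threshold.  Emergent mutations are present in no untreated sample but in at
least one treated or post-treated ("exposed") sample; depleted mutations
are present in two or more distinct untreated mice and in no exposed
sample.  Cross-sample concordance is Spearman rank correlation of VAFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .synthetic_data import UNTREATED, VariantTable

EXPOSED_GROUPS = ("treated", "post-treated")

#: Variant effects retained when annotation is available.
DEFAULT_EFFECTS = ("nonsynonymous SNV", "frameshift insertion", "frameshift deletion", "stopgain")


@dataclass
class MutationCallSet:
    """Classified variants with per-group support counts."""

    emergent: list
    depleted: list
    presence_vaf_min: float
    support: pd.DataFrame  # variant_id, n_untreated_samples, n_untreated_mice, n_exposed_samples, call

    def calls(self) -> pd.Series:
        return self.support.set_index("variant_id")["call"]


def classify_mutations(
    table: VariantTable,
    presence_vaf_min: float = 0.05,
    effects: tuple | None = DEFAULT_EFFECTS,
) -> MutationCallSet:
    """Classify variants as emergent, depleted or neither.

    Presence = VAF >= ``presence_vaf_min``.  The >= 2 untreated requirement
    for depleted variants counts distinct untreated *mice*, so multi-region
    samples of one mouse count once.  When an ``effect`` annotation column
    is present, only the default damaging effect classes are considered;
    unannotated tables are classified as-is.
    """
    df = table.data
    if UNTREATED not in set(df["group"]):
        raise ValueError("variant table has no untreated samples")
    if effects is not None and "effect" in df.columns:
        df = df[df["effect"].isin(effects)]

    present = df[df["vaf"] >= presence_vaf_min]
    untr = present[present["group"] == UNTREATED]
    expo = present[present["group"].isin(EXPOSED_GROUPS)]

    all_variants = pd.Index(sorted(df["variant_id"].unique()), name="variant_id")
    n_untr_samples = untr.groupby("variant_id")["sample_id"].nunique().reindex(all_variants, fill_value=0)
    mouse_col = "mouse_id" if "mouse_id" in df.columns else "sample_id"
    n_untr_mice = untr.groupby("variant_id")[mouse_col].nunique().reindex(all_variants, fill_value=0)
    n_expo_samples = expo.groupby("variant_id")["sample_id"].nunique().reindex(all_variants, fill_value=0)

    emergent_mask = (n_untr_samples == 0) & (n_expo_samples >= 1)
    depleted_mask = (n_untr_mice >= 2) & (n_expo_samples == 0)
    call = pd.Series("none", index=all_variants)
    call[emergent_mask] = "emergent"
    call[depleted_mask] = "depleted"

    support = pd.DataFrame(
        {
            "variant_id": all_variants,
            "n_untreated_samples": n_untr_samples.to_numpy(),
            "n_untreated_mice": n_untr_mice.to_numpy(),
            "n_exposed_samples": n_expo_samples.to_numpy(),
            "call": call.to_numpy(),
        }
    )
    return MutationCallSet(
        emergent=sorted(all_variants[emergent_mask]),
        depleted=sorted(all_variants[depleted_mask]),
        presence_vaf_min=presence_vaf_min,
        support=support,
    )


def vaf_concordance(
    table: VariantTable, sample_a: str, sample_b: str, method: str = "spearman"
) -> float:
    """Rank correlation of VAFs between two samples.

    The variant universe is every variant recorded with positive VAF in
    either sample; a variant absent from one sample contributes VAF 0
    there.  Requires at least 3 such variants.
    """
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    df = table.data
    a = df[df["sample_id"] == sample_a].set_index("variant_id")["vaf"]
    b = df[df["sample_id"] == sample_b].set_index("variant_id")["vaf"]
    if a.index.has_duplicates or b.index.has_duplicates:
        raise ValueError("(variant, sample) entries must be unique")
    universe = sorted(set(a.index[a > 0]) | set(b.index[b > 0]))
    if len(universe) < 3:
        raise ValueError("need at least 3 variants present in either sample")
    va = a.reindex(universe, fill_value=0.0).to_numpy()
    vb = b.reindex(universe, fill_value=0.0).to_numpy()
    rho = scipy.stats.spearmanr(va, vb).statistic
    return float(rho)


def write_calls_tsv(calls: MutationCallSet, path) -> None:
    calls.support.to_csv(path, sep="\t", index=False)
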