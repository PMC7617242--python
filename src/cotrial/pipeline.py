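"""End-to-end reproducible runs over synthetic coclinical-trial data.

The demo pipeline emulates the coclinical design: a panel of PDTX models
is simulated (some pCR-like with strongly negative treatment effects on
the growth rate, some non-pCR-like with near-null effects), each model's
trial is fitted with the log-linear mixed model, the four drug-response
metrics are computed, and metric-wise Wilcoxon concordance with the pCR
labels is tested with Benjamini-Hochberg correction.  Optional stages
exercise the ex vivo screen scoring, variant classification and metacell
phenotype scoring on matched synthetic inputs.

Every stochastic stage receives a seed derived deterministically from the
run seed, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exvivo_screen import curve_auc, fit_dose_response, screen_shift
from .growth_model import fit_growth_model
from .phenotype_scores import phenotype_report
from .response_metrics import compute_metrics, concordance_test
from .synthetic_data import (
    UNTREATED,
    GrowthSimConfig,
    MetacellSimConfig,
    ScreenSimConfig,
    VariantSimConfig,
    simulate_metacells,
    simulate_screen,
    simulate_trial,
    simulate_variant_table,
)
from .variant_dynamics import classify_mutations

_MOD = 2**31 - 1


def derive_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage child seed (kept below 2^31)."""
    return (int(seed) * 1000003 + 7919 * (stage + 1)) % _MOD


@dataclass
class RunConfig:
    """Configuration for one reproducible pipeline run."""

    seed: int
    out_dir: str = "cotrial_run"
    n_pcr_models: int = 4
    n_non_pcr_models: int = 4
    n_mice_per_arm: int = 5
    beta0: float = float(np.log(100.0))
    beta1: float = 0.05
    delta_pcr: float = -0.08  # treatment effect on log-growth rate, pCR-like models
    delta_non_pcr: float = -0.005  # near-null effect, non-pCR-like models
    sd_u0: float = 0.2
    sd_u1: float = 0.005
    sd_eps: float = 0.2
    t_end: float = 77.0
    alpha: float = 0.05
    run_screen: bool = False
    run_variants: bool = False
    run_phenotype: bool = False
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if seed is not None:
            raw["seed"] = seed
        if "seed" not in raw or raw["seed"] is None:
            raise ValueError("seed is mandatory: set it in the config file or pass --seed")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def simulate_panel(config: RunConfig) -> tuple[dict, dict]:
    """Simulate one trial per PDTX model; returns (datasets, pcr_labels)."""
    datasets, labels = {}, {}
    idx = 0
    for kind, n_models, delta in (
        ("pCR", config.n_pcr_models, config.delta_pcr),
        ("nonpCR", config.n_non_pcr_models, config.delta_non_pcr),
    ):
        for j in range(n_models):
            model_id = f"{kind}{j + 1:02d}"
            sim = GrowthSimConfig(
                n_models=1,
                n_mice_per_arm=config.n_mice_per_arm,
                beta0=config.beta0,
                beta1=config.beta1,
                arm_slope_shift={"treated": delta},
                sd_u0=config.sd_u0,
                sd_u1=config.sd_u1,
                sd_eps=config.sd_eps,
                t_end=config.t_end,
                seed=derive_seed(config.seed, idx),
            )
            ds = simulate_trial(sim)
            ds.data["model"] = model_id
            datasets[model_id] = ds
            labels[model_id] = kind == "pCR"
            idx += 1
    return datasets, labels


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> fit -> metrics -> concordance (+ optional stages).

    Writes metrics.csv, concordance.csv and report.json under
    ``config.out_dir`` and returns the run report as a dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    datasets, labels = simulate_panel(config)
    metric_frames = []
    for model_id, ds in datasets.items():
        try:
            fit = fit_growth_model(ds, model_id=model_id)
        except Exception as err:  # annotate stage + input before propagating
            raise RuntimeError(f"stage 'fit' failed for model {model_id!r}: {err}") from err
        metric_frames.append(compute_metrics(fit, config.t_end, alpha=config.alpha))
    metrics = pd.concat(metric_frames, ignore_index=True)
    metrics.to_csv(out / "metrics.csv", index=False)

    # concordance: treated-arm estimates per model; end volumes pooled per mouse
    treated = metrics[(metrics["arm"] == "treated")]
    values = treated[["model", "metric", "estimate"]]
    conc = concordance_test(values, labels)
    conc.table.to_csv(out / "concordance.csv", index=False)
    sig = conc.significant(config.alpha)["metric"].tolist()
    report["stages"]["trial"] = {
        "n_models": len(datasets),
        "pcr_labels": labels,
        "significant_metrics": sig,
        "concordance": conc.table.to_dict(orient="records"),
    }

    if config.run_screen:
        plates = {
            ("untreated", "olaparib"): simulate_screen(
                ScreenSimConfig(hill_ec50=1.0, seed=derive_seed(config.seed, 101))
            ),
            ("post-treated", "olaparib"): simulate_screen(
                ScreenSimConfig(hill_ec50=0.1, seed=derive_seed(config.seed, 102))
            ),
        }
        f_un = fit_dose_response(plates[("untreated", "olaparib")], sample="untreated")
        f_po = fit_dose_response(plates[("post-treated", "olaparib")], sample="post-treated")
        report["stages"]["screen"] = {
            "auc_untreated": curve_auc(f_un),
            "auc_post_treated": curve_auc(f_po),
            "auc_shift": screen_shift(f_un, f_po),
        }

    if config.run_variants:
        table = simulate_variant_table(VariantSimConfig(seed=derive_seed(config.seed, 201)))
        calls = classify_mutations(table)
        calls.support.to_csv(out / "variant_calls.tsv", sep="\t", index=False)
        report["stages"]["variants"] = {
            "n_emergent": len(calls.emergent),
            "n_depleted": len(calls.depleted),
        }

    if config.run_phenotype:
        model = simulate_metacells(MetacellSimConfig(seed=derive_seed(config.seed, 301)))
        scores = phenotype_report(model)
        scores.to_csv(out / "phenotype_scores.csv", index=False)
        report["stages"]["phenotype"] = {
            "n_mcs": int(len(scores)),
            "n_emt_strata": int(scores["emt_stratum"].nunique()),
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
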