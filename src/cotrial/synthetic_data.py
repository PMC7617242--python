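"""Synthetic data generators for every pipeline stage.

Each generator runs the corresponding analysis model forward so the
downstream estimators can be validated against known truth:

* ``simulate_trial`` — exponential tumor growth with per-mouse random
  intercepts/slopes and arm-specific growth-rate shifts, i.e. the
  log-linear mixed model run forward.
* ``simulate_screen`` — monotone sigmoidal (Hill) viability curves with
  multiplicative technical-replicate noise plus control wells.
* ``simulate_variant_table`` — multi-sample VAF tables with a shared
  clonal backbone plus group-restricted (emergent/depleted/private)
  variants, truth labels attached.
* ``simulate_metacells`` — multinomial UMI counts for metacells mixing
  epithelial / mesenchymal / immediate-early-response / mitochondrial
  gene programs, with the underlying single cells retained for QC tests.

All generators are deterministic given their config seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .trial_design import TREATMENT_DURATION_DAYS

UNTREATED = "untreated"


def _default_measurement_days() -> list[int]:
    # weekly caliper measurements, day 0 through day 77
    return list(range(0, TREATMENT_DURATION_DAYS + 1, 7))


@dataclass
class GrowthSimConfig:
    """Forward model for one (or several) PDTX in vivo trials.

    log TV_it = (beta0 + shift_g + u0_i) + (beta1 + delta_g + u1_i) * t + eps_it

    with (u0, u1) bivariate normal (sds ``sd_u0``/``sd_u1``, correlation
    ``corr_u``) and eps iid normal with sd ``sd_eps``.  Defaults describe a
    tumor enrolled at ~100 mm^3 growing at 5%/day (doubling time ~2 weeks),
    with mouse-to-mouse growth-rate scatter of 0.005/day and ~20%
    multiplicative measurement noise, measured weekly for 11 weeks.
    """

    n_models: int = 1
    arms: tuple = (UNTREATED, "treated")
    n_mice_per_arm: int = 5
    t_end: float = float(TREATMENT_DURATION_DAYS)
    measurement_days: list = field(default_factory=_default_measurement_days)
    beta0: float = float(np.log(100.0))  # log mm^3 at enrollment
    beta1: float = 0.05  # per day, untreated log-growth rate
    arm_intercept_shift: dict = field(default_factory=dict)  # log mm^3
    arm_slope_shift: dict = field(default_factory=dict)  # per day (delta_g)
    sd_u0: float = 0.2
    sd_u1: float = 0.005
    corr_u: float = 0.0
    sd_eps: float = 0.2
    design: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if UNTREATED not in self.arms:
            raise ValueError(f"arms must include {UNTREATED!r}")
        if min(self.sd_u0, self.sd_u1, self.sd_eps) < 0:
            raise ValueError("standard deviations must be non-negative")
        if abs(self.corr_u) > 1:
            raise ValueError("corr_u must lie in [-1, 1]")
        if any(d < 0 or d > self.t_end for d in self.measurement_days):
            raise ValueError("measurement_days must lie in [0, t_end]")
        for name in (self.arm_intercept_shift, self.arm_slope_shift):
            if name.get(UNTREATED, 0.0) != 0.0:
                raise ValueError("untreated arm must have zero shifts")


@dataclass
class TrialDataset:
    """Longitudinal caliper/volume records for one preclinical trial."""

    data: pd.DataFrame  # model, mouse, arm, day, width_mm, height_mm, volume_mm3
    design: int = 2
    t_end: float = float(TREATMENT_DURATION_DAYS)
    random_effects_truth: pd.DataFrame | None = None  # mouse, u0, u1 (simulations only)

    def arms(self) -> list[str]:
        return sorted(self.data["arm"].unique())

    def subset_model(self, model_id) -> "TrialDataset":
        sub = self.data[self.data["model"] == model_id].reset_index(drop=True)
        return TrialDataset(sub, design=self.design, t_end=self.t_end)


def simulate_trial(config: GrowthSimConfig) -> TrialDataset:
    """Run the growth model forward; returns volumes on the mm^3 scale.

    Caliper width and height are back-derived assuming W = H, so
    TV = W^2 H / 2 reproduces the simulated volume exactly.
    """
    rng = np.random.default_rng(config.seed)
    cov = np.array(
        [
            [config.sd_u0**2, config.corr_u * config.sd_u0 * config.sd_u1],
            [config.corr_u * config.sd_u0 * config.sd_u1, config.sd_u1**2],
        ]
    )
    chol = np.linalg.cholesky(cov + 1e-300 * np.eye(2)) if cov.any() else np.zeros((2, 2))
    days = np.asarray(config.measurement_days, dtype=float)

    rows = []
    truth = []
    for im in range(config.n_models):
        model_id = f"PDTX{im + 1:02d}"
        for arm in config.arms:
            shift = config.arm_intercept_shift.get(arm, 0.0)
            delta = config.arm_slope_shift.get(arm, 0.0)
            for j in range(config.n_mice_per_arm):
                mouse = f"{model_id}-{arm}-{j + 1}"
                u0, u1 = chol @ rng.standard_normal(2)
                eps = rng.normal(0.0, config.sd_eps, size=days.size) if config.sd_eps else 0.0
                logv = (config.beta0 + shift + u0) + (config.beta1 + delta + u1) * days + eps
                vol = np.exp(logv)
                w = np.cbrt(2.0 * vol)
                for day, v, wid in zip(days, vol, w):
                    rows.append((model_id, mouse, arm, day, wid, wid, v))
                truth.append((model_id, mouse, u0, u1))
    data = pd.DataFrame(
        rows, columns=["model", "mouse", "arm", "day", "width_mm", "height_mm", "volume_mm3"]
    )
    truth_df = pd.DataFrame(truth, columns=["model", "mouse", "u0", "u1"])
    return TrialDataset(data, design=config.design, t_end=config.t_end, random_effects_truth=truth_df)


# ---------------------------------------------------------------------------
# Ex vivo screen plates


@dataclass
class ScreenSimConfig:
    """Hill-curve viability screen with technical replicates and controls.

    Sample-well intensity is ``viability(c) * intensity_scale`` with
    viability(c) = floor + (1 - floor) / (1 + (c/EC50)^slope) and
    multiplicative lognormal-free noise (normal with CV ``noise_cv``).
    Negative-control wells carry background (zero) intensity; positive
    controls carry full (untreated) intensity, matching the response
    normalization 100 - 100*(I - neg)/(pos - neg).
    """

    drug: str = "olaparib"
    doses: tuple = (10.0, 3.0, 1.0, 0.3, 0.1, 0.03, 0.01)  # umol/L
    n_tech_reps: int = 3
    hill_ec50: float = 0.3  # umol/L
    hill_slope: float = 1.0
    floor_viability: float = 0.05
    intensity_scale: float = 1.0e6
    noise_cv: float = 0.05
    n_control_wells: int = 16  # per control role
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be strictly positive")
        if self.n_tech_reps < 1:
            raise ValueError("n_tech_reps must be >= 1")
        if not 0 <= self.floor_viability <= 1:
            raise ValueError("floor_viability must lie in [0, 1]")
        if self.intensity_scale == 0:
            raise ValueError("intensity_scale must be non-zero")


@dataclass
class ScreenPlate:
    """Well-level screen intensities; role is 'sample', 'neg' or 'pos'."""

    wells: pd.DataFrame  # drug, conc_umol, rep, intensity, role

    def sample_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == "sample"]

    def control_mean(self, role: str, stat: str = "mean") -> float:
        vals = self.wells.loc[self.wells["role"] == role, "intensity"]
        if vals.empty:
            raise ValueError(f"no {role!r} control wells")
        return float(vals.median() if stat == "median" else vals.mean())


def hill_viability(conc, ec50: float, slope: float, floor: float) -> np.ndarray:
    """Fraction of viable cells at concentration ``conc`` (decreasing Hill curve)."""
    c = np.asarray(conc, dtype=float)
    return floor + (1.0 - floor) / (1.0 + (c / ec50) ** slope)


def simulate_screen(config: ScreenSimConfig) -> ScreenPlate:
    rng = np.random.default_rng(config.seed)

    def noisy(base: np.ndarray) -> np.ndarray:
        if config.noise_cv == 0:
            return base
        return base * (1.0 + rng.normal(0.0, config.noise_cv, size=np.shape(base)))

    rows = []
    for dose in config.doses:
        v = hill_viability(dose, config.hill_ec50, config.hill_slope, config.floor_viability)
        base = np.full(config.n_tech_reps, v * config.intensity_scale)
        for rep, inten in enumerate(noisy(base), start=1):
            rows.append((config.drug, dose, rep, inten, "sample"))
    # negative controls: background (no signal); positive controls: untreated viability
    for rep in range(1, config.n_control_wells + 1):
        rows.append((config.drug, np.nan, rep, 0.0, "neg"))
    pos = noisy(np.full(config.n_control_wells, config.intensity_scale))
    for rep, inten in enumerate(pos, start=1):
        rows.append((config.drug, np.nan, rep, inten, "pos"))
    return ScreenPlate(pd.DataFrame(rows, columns=["drug", "conc_umol", "rep", "intensity", "role"]))


# ---------------------------------------------------------------------------
# Variant tables


@dataclass
class VariantSimConfig:
    """Multi-sample VAF table with a planted clonal/emergent/depleted structure."""

    n_clonal: int = 5
    n_emergent: int = 3
    n_depleted: int = 2
    n_private: int = 4
    group_sizes: dict = field(
        default_factory=lambda: {"untreated": 3, "treated": 3, "post-treated": 3}
    )
    vaf_noise_sd: float = 0.03
    presence_vaf: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_clonal, self.n_emergent, self.n_depleted, self.n_private) < 0:
            raise ValueError("variant counts must be non-negative")
        if UNTREATED not in self.group_sizes:
            raise ValueError("group_sizes must include the untreated group")
        if self.n_depleted > 0 and self.group_sizes[UNTREATED] < 2:
            raise ValueError("depleted variants require >= 2 untreated mice")


@dataclass
class VariantTable:
    """Long-format VAF table; one row per (variant, sample)."""

    data: pd.DataFrame  # variant_id, sample_id, group, mouse_id, region, vaf
    truth: dict | None = None  # variant_id -> {clonal, emergent, depleted, private}

    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())


def simulate_variant_table(config: VariantSimConfig) -> VariantTable:
    rng = np.random.default_rng(config.seed)
    samples = []  # (sample_id, group, mouse_id)
    for group, n in config.group_sizes.items():
        for i in range(n):
            prefix = {"untreated": "U", "treated": "T", "post-treated": "P"}.get(group, group[:1])
            mouse = f"{prefix}{i + 1}"
            samples.append((f"{mouse}-R1", group, mouse))
    sdf = pd.DataFrame(samples, columns=["sample_id", "group", "mouse_id"])
    untreated_idx = sdf.index[sdf["group"] == UNTREATED].to_list()
    exposed_idx = sdf.index[sdf["group"] != UNTREATED].to_list()

    counter = itertools.count(1)
    rows, truth = [], {}

    def add_variant(kind: str, present_idx: list[int]) -> None:
        # each variant carries a base VAF shared across samples (clonal
        # structure); per-sample noise perturbs it
        vid = f"var{next(counter):04d}"
        truth[vid] = kind
        present = set(present_idx)
        base = float(np.clip(rng.normal(config.presence_vaf, 0.1), 0.15, 0.95))
        for i, (sid, grp, mid) in enumerate(zip(sdf["sample_id"], sdf["group"], sdf["mouse_id"])):
            v = np.clip(base + rng.normal(0.0, config.vaf_noise_sd), 0.0, 1.0) if config.vaf_noise_sd else base
            rows.append((vid, sid, grp, mid, "R1", float(v) if i in present else 0.0))

    for _ in range(config.n_clonal):
        add_variant("clonal", list(sdf.index))
    for _ in range(config.n_emergent):
        k = int(rng.integers(1, len(exposed_idx) + 1)) if exposed_idx else 0
        add_variant("emergent", list(rng.choice(exposed_idx, size=k, replace=False)))
    for _ in range(config.n_depleted):
        k = int(rng.integers(2, len(untreated_idx) + 1))
        add_variant("depleted", list(rng.choice(untreated_idx, size=k, replace=False)))
    for _ in range(config.n_private):
        # private variants live in a single untreated sample: a variant
        # private to an exposed sample would be emergent by definition,
        # which would blur the planted truth labels
        add_variant("private", [int(rng.choice(untreated_idx))])

    data = pd.DataFrame(
        rows, columns=["variant_id", "sample_id", "group", "mouse_id", "region", "vaf"]
    )
    return VariantTable(data, truth=truth)


# ---------------------------------------------------------------------------
# Metacell UMI matrices


def _default_programs() -> dict:
    """Named gene programs; anchors (KRT81, VIM, JUNB) and canonical markers included."""
    epithelial = ["KRT81", "CLDN3", "SLPI", "ELF5"] + [f"EPI{i:03d}" for i in range(56)]
    mesenchymal = ["VIM", "ITGA6", "EGFR", "TWIST1", "TWIST2", "SNAI2"] + [
        f"MES{i:03d}" for i in range(54)
    ]
    ier = ["FOS", "JUNB", "ATF5", "NFATC1"] + [f"IER{i:03d}" for i in range(26)]
    mito = [f"MT-G{i}" for i in range(10)]
    return {"epithelial": epithelial, "mesenchymal": mesenchymal, "ier": ier, "mito": mito}


@dataclass
class MetacellSimConfig:
    """Metacell UMI counts as mixtures of gene programs.

    If ``mixture_weights`` is None, a default epithelial-to-mesenchymal
    gradient is planted across metacells (with an IER bump on the hybrid
    middle), so EMT and IER strata are populated.
    """

    n_mcs: int = 40
    n_genes: int = 400
    program_genes: dict = field(default_factory=_default_programs)
    mixture_weights: np.ndarray | None = None  # n_mcs x n_programs, rows sum to 1
    umis_per_mc: int = 20000
    n_cells_per_mc: int = 20
    conditions: tuple = (UNTREATED, "treated", "post-treated")
    seed: int = 0

    def __post_init__(self) -> None:
        if any(len(g) == 0 for g in self.program_genes.values()):
            raise ValueError("program gene sets must be non-empty")
        if self.mixture_weights is not None:
            w = np.asarray(self.mixture_weights, dtype=float)
            if w.shape[0] != self.n_mcs:
                raise ValueError("mixture_weights must have one row per metacell")
            if not np.allclose(w.sum(axis=1), 1.0):
                raise ValueError("mixture weights per metacell must sum to 1")


@dataclass
class CellMatrix:
    """Single-cell UMI counts with mito flags and condition labels."""

    counts: sp.csr_matrix  # cells x genes
    genes: pd.DataFrame  # gene, is_mito
    cells: pd.DataFrame  # cell, condition, mc


@dataclass
class MetacellModel:
    """Metacell expression model: pooled counts plus cell-level provenance."""

    counts: pd.DataFrame  # mcs x genes UMI counts
    genes: pd.DataFrame  # gene, is_mito
    mcs: pd.DataFrame  # mc, state, n_cells
    cells: CellMatrix | None = None
    mixture_weights: pd.DataFrame | None = None  # truth, simulations only


def _default_gradient_weights(n_mcs: int, programs: list[str]) -> np.ndarray:
    """Epithelial->mesenchymal gradient with an IER bump on hybrid MCs."""
    w = np.zeros((n_mcs, len(programs)))
    i_epi = programs.index("epithelial")
    i_mes = programs.index("mesenchymal")
    i_ier = programs.index("ier") if "ier" in programs else None
    i_bg = programs.index("background")
    frac = np.linspace(0.0, 1.0, n_mcs)
    for m, f in enumerate(frac):
        ier = 0.0
        if i_ier is not None and 0.35 <= f <= 0.65 and m % 2 == 0:
            ier = 0.25
        signal = 0.7 - ier
        w[m, i_epi] = signal * (1.0 - f)
        w[m, i_mes] = signal * f
        if i_ier is not None:
            w[m, i_ier] = ier
        w[m, i_bg] = 0.3
    return w


def _state_label(w: pd.Series) -> str:
    epi, mes = w.get("epithelial", 0.0), w.get("mesenchymal", 0.0)
    ier = w.get("ier", 0.0)
    tot = epi + mes
    if tot == 0:
        return "other"
    f = mes / tot
    if ier >= 0.15:
        return "EM-hybrid-IER"
    if f <= 0.25:
        return "epithelial"
    if f >= 0.75:
        return "mesenchymal"
    return "EM-hybrid"


def simulate_metacells(config: MetacellSimConfig) -> MetacellModel:
    """Draw multinomial UMI counts per cell and pool them into metacells.

    Expected gene frequencies per metacell are the program-mixture of
    per-program frequency vectors; all cells of a metacell share its
    mixture, so metacell counts are multinomial with those frequencies.
    """
    rng = np.random.default_rng(config.seed)
    programs = dict(config.program_genes)
    program_names = list(programs)

    # gene universe: program genes first, then background filler genes
    genes: list[str] = []
    for gs in programs.values():
        genes.extend(g for g in gs if g not in genes)
    n_fill = max(config.n_genes - len(genes), 0)
    genes.extend(f"BG{i:04d}" for i in range(n_fill))
    gene_idx = {g: i for i, g in enumerate(genes)}

    # per-program frequency vectors: 90% of mass on the program's genes
    # (geometric-ish decay), 10% spread over the whole gene universe
    freqs = {}
    for name, gs in programs.items():
        f = np.full(len(genes), 0.1 / len(genes))
        w = 0.9 ** np.arange(len(gs))
        w = 0.9 * w / w.sum()
        for g, wi in zip(gs, w):
            f[gene_idx[g]] += wi
        freqs[name] = f / f.sum()
    freqs["background"] = np.full(len(genes), 1.0 / len(genes))
    program_names = program_names + ["background"]

    if config.mixture_weights is None:
        names_no_mito = [p for p in program_names if p != "mito"]
        w_sub = _default_gradient_weights(config.n_mcs, names_no_mito)
        weights = np.zeros((config.n_mcs, len(program_names)))
        for j, p in enumerate(names_no_mito):
            weights[:, program_names.index(p)] = w_sub[:, j]
    else:
        weights = np.zeros((config.n_mcs, len(program_names)))
        given = np.asarray(config.mixture_weights, dtype=float)
        for j, p in enumerate(config.program_genes):
            weights[:, program_names.index(p)] = given[:, j]
        if given.shape[1] == len(config.program_genes) + 1:  # trailing background column
            weights[:, program_names.index("background")] = given[:, -1]

    is_mito = np.array([g.startswith("MT-") for g in genes])
    umis_per_cell = max(config.umis_per_mc // config.n_cells_per_mc, 1)

    mc_rows, cell_rows, cell_counts = [], [], []
    wdf_rows = []
    for m in range(config.n_mcs):
        mc_id = f"MC{m + 1:03d}"
        p = sum(weights[m, j] * freqs[name] for j, name in enumerate(program_names))
        p = p / p.sum()
        counts_m = np.zeros(len(genes), dtype=np.int64)
        cond = config.conditions[m % len(config.conditions)]
        for c in range(config.n_cells_per_mc):
            cell_count = rng.multinomial(umis_per_cell, p)
            counts_m += cell_count
            cell_counts.append(cell_count)
            cell_rows.append((f"{mc_id}-c{c + 1}", cond, mc_id))
        wser = pd.Series(weights[m], index=program_names)
        mc_rows.append((mc_id, _state_label(wser), config.n_cells_per_mc))
        wdf_rows.append(weights[m])

    genes_df = pd.DataFrame({"gene": genes, "is_mito": is_mito})
    mcs_df = pd.DataFrame(mc_rows, columns=["mc", "state", "n_cells"])
    cells_df = pd.DataFrame(cell_rows, columns=["cell", "condition", "mc"])
    cells = CellMatrix(sp.csr_matrix(np.asarray(cell_counts)), genes_df, cells_df)
    counts = pd.DataFrame(
        np.asarray(cell_counts).reshape(config.n_mcs, config.n_cells_per_mc, -1).sum(axis=1),
        index=mcs_df["mc"],
        columns=genes,
    )
    wdf = pd.DataFrame(wdf_rows, index=mcs_df["mc"], columns=program_names)
    return MetacellModel(counts, genes_df, mcs_df, cells=cells, mixture_weights=wdf)


# ---------------------------------------------------------------------------
# Plain-text IO (CSV/TSV/MatrixMarket)


def write_trial_csv(ds: TrialDataset, path) -> None:
    ds.data.to_csv(path, index=False)


def read_trial_csv(path, design: int = 2, t_end: float = TREATMENT_DURATION_DAYS) -> TrialDataset:
    df = pd.read_csv(path)
    required = {"model", "mouse", "arm", "day", "volume_mm3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    return TrialDataset(df, design=design, t_end=t_end)


def write_screen_csv(plate: ScreenPlate, path) -> None:
    plate.wells.to_csv(path, index=False)


def read_screen_csv(path) -> ScreenPlate:
    return ScreenPlate(pd.read_csv(path))


def write_variants_tsv(table: VariantTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> VariantTable:
    return VariantTable(pd.read_csv(path, sep="\t"))


def write_metacell_model(model: MetacellModel, prefix) -> None:
    """Write counts as MatrixMarket plus genes/MCs metadata CSVs."""
    from scipy.io import mmwrite

    mmwrite(f"{prefix}_counts.mtx", sp.coo_matrix(model.counts.to_numpy()))
    model.genes.to_csv(f"{prefix}_genes.csv", index=False)
    model.mcs.to_csv(f"{prefix}_mcs.csv", index=False)
    if model.cells is not None:
        model.cells.cells.to_csv(f"{prefix}_cells.csv", index=False)


def read_metacell_model(prefix) -> MetacellModel:
    from scipy.io import mmread

    genes = pd.read_csv(f"{prefix}_genes.csv")
    mcs = pd.read_csv(f"{prefix}_mcs.csv")
    counts = pd.DataFrame(
        np.asarray(mmread(f"{prefix}_counts.mtx").todense()),
        index=mcs["mc"],
        columns=genes["gene"],
    )
    return MetacellModel(counts, genes, mcs)
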