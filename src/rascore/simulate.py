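"""Synthetic multi-study, two-tissue expression compendia with ground truth.

The generator emulates the statistical structure of a merged microarray
compendium for a systemic inflammatory disease studied in two tissues
(synovium biopsies and whole blood): several datasets per tissue with
additive/multiplicative per-gene batch effects, a planted co-directional
case-vs-control signal whose magnitude is larger in synovium than in blood,
blocks of highly inter-correlated genes driven by a shared latent factor,
male-specific Y-chromosome genes, treatment-attenuated effects, strong
class imbalance in blood, and a clinical disease-activity variable (DAS28)
correlated with the latent disease burden.

Everything is driven by a single integer seed; identical configs produce
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ANNOTATION_COLUMNS, Compendium, ExpressionStudy, GroundTruth

TISSUES = ("synovium", "blood")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic compendium.

    Defaults mirror the discovery design being emulated: blood is strongly
    case-imbalanced (300 cases vs 90 controls over 4 datasets, ~3.4:1),
    synovium smaller (90 vs 30 over 3 datasets); 30 up- and 30 down-
    regulated genes planted co-directionally with synovium effects roughly
    twice the blood effects; five 5-gene redundant blocks; per-gene
    residual variances drawn from a scaled inverse-chi-square so that
    empirical-Bayes variance moderation has something to shrink.
    """

    n_genes: int = 2000
    n_datasets: dict = field(default_factory=lambda: {"synovium": 3, "blood": 4})
    n_cases: dict = field(default_factory=lambda: {"synovium": 90, "blood": 300})
    n_controls: dict = field(default_factory=lambda: {"synovium": 30, "blood": 90})
    planted_up: int = 30
    planted_down: int = 30
    # per-tissue uniform range of |log2FC| for planted genes
    effect_range: dict = field(
        default_factory=lambda: {"synovium": (1.0, 2.0), "blood": (0.6, 1.2)}
    )
    n_redundant_blocks: int = 5
    block_size: int = 5
    block_corr: float = 0.9
    block_factor_sd: float = 0.5
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.1
    n_y_genes: int = 8
    sex_effect: float = 4.0
    male_fraction: float = 0.5
    missing_sex_fraction: float = 0.4
    treated_fraction: float = 0.5
    treatment_effect: float = 0.25
    treatment_categories: tuple = ("csDMARD", "biologic")
    burden_sd: float = 0.3
    # gene-specific disease-response heterogeneity (per unit burden): real
    # markers track partially distinct aspects of disease, which keeps
    # pairwise correlations between planted genes well below 1
    response_sd: float = 0.3
    das28_intercept: float = 2.0
    das28_slope: float = 2.5
    das28_noise_sd: float = 1.7
    das28_dataset_fraction: float = 0.5
    oa_overlap_fraction: float = 0.5
    oa_effect_scale: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    var_prior_df: float = 4.0
    var_prior_scale: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        reserved = (
            self.planted_up
            + self.planted_down
            + self.n_redundant_blocks * self.block_size
            + self.n_y_genes
        )
        if reserved > self.n_genes:
            raise ValueError(
                f"planted + block + Y genes ({reserved}) exceed n_genes ({self.n_genes})"
            )
        for name in (
            "n_genes",
            "planted_up",
            "planted_down",
            "n_redundant_blocks",
            "block_size",
            "n_y_genes",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for tissue, (lo, hi) in self.effect_range.items():
            if lo <= 0 or hi < lo:
                raise ValueError(f"effect range for {tissue} must have positive bounds")
        if not 0 < self.block_corr < 1:
            raise ValueError("block_corr must be in (0,1)")
        for t in self.n_datasets:
            if self.n_datasets[t] < 1:
                raise ValueError("need at least one dataset per tissue")

    @property
    def tissues(self) -> tuple:
        return tuple(self.n_datasets)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @property
    def generating_das28_correlation(self) -> float:
        """Population Pearson r between latent burden and simulated DAS28."""
        s = self.das28_slope * self.burden_sd
        return s / float(np.hypot(s, self.das28_noise_sd))


@dataclass
class ClinicalCohorts:
    """Clinical annotation table plus the extra cohorts it refers to."""

    table: pd.DataFrame
    treatment_pairs: ExpressionStudy = None
    oa_cohorts: dict = field(default_factory=dict)
    polyjia_cohort: ExpressionStudy = None


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _gene_params(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign per-gene baseline mean, residual sd and true effects."""
    g = config.n_genes
    genes = [f"G{i:05d}" for i in range(g)]
    mean = rng.normal(config.baseline_mean, config.baseline_sd, g)
    # scaled inverse-chi-square residual variances: d0*s0^2 / chi2(d0)
    var = (
        config.var_prior_df
        * config.var_prior_scale
        / rng.chisquare(config.var_prior_df, g)
    )
    params = pd.DataFrame(
        {
            "mean": mean,
            "sd": np.sqrt(var),
            "block": -1,
            "is_y": False,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    for t in config.tissues:
        params[f"beta_{t}"] = 0.0

    order = rng.permutation(g)
    pos = 0
    up = [genes[i] for i in order[pos : pos + config.planted_up]]
    pos += config.planted_up
    down = [genes[i] for i in order[pos : pos + config.planted_down]]
    pos += config.planted_down
    block_membership: dict[str, int] = {}
    block_sign = {}
    for b in range(config.n_redundant_blocks):
        members = [genes[i] for i in order[pos : pos + config.block_size]]
        pos += config.block_size
        for m in members:
            block_membership[m] = b
            params.loc[m, "block"] = b
        block_sign[b] = 1.0 if b % 2 == 0 else -1.0
    y_genes = [genes[i] for i in order[pos : pos + config.n_y_genes]]
    params.loc[y_genes, "is_y"] = True

    for t in config.tissues:
        lo, hi = config.effect_range[t]
        params.loc[up, f"beta_{t}"] = rng.uniform(lo, hi, len(up))
        params.loc[down, f"beta_{t}"] = -rng.uniform(lo, hi, len(down))
        for b in range(config.n_redundant_blocks):
            members = [m for m, bb in block_membership.items() if bb == b]
            params.loc[members, f"beta_{t}"] = block_sign[b] * rng.uniform(lo, hi)
    params.attrs["planted_up"] = up
    params.attrs["planted_down"] = down
    params.attrs["y_genes"] = y_genes
    params.attrs["block_membership"] = block_membership
    return params


def _draw_samples(
    config: SimulationConfig,
    params: pd.DataFrame,
    rng: np.random.Generator,
    *,
    n_cases: int,
    n_controls: int,
    tissue: str,
    dataset: str,
    prefix: str,
    batch_shift: np.ndarray | None = None,
    batch_scale: np.ndarray | None = None,
    case_status: str = "case",
    effect_scale: float = 1.0,
    effect_mask: np.ndarray | None = None,
    allow_treatment: bool = True,
    fixed_burden: np.ndarray | None = None,
    treatment_override: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one dataset's matrix and sample table from the population model.

    Returns (values genes x samples, sample table).  ``effect_mask`` limits
    the planted signal to a gene subset (used for the OA cohort);
    ``effect_scale`` scales its magnitude.
    """
    g = len(params)
    n = n_cases + n_controls
    sample_ids = [f"{prefix}_s{i:03d}" for i in range(n)]
    is_case = np.array([True] * n_cases + [False] * n_controls)
    if fixed_burden is not None:
        burden = fixed_burden
    else:
        burden = np.where(is_case, rng.normal(1.0, config.burden_sd, n), 0.0)
    male = rng.random(n) < config.male_fraction
    if treatment_override is not None:
        treated = treatment_override
    elif allow_treatment:
        treated = is_case & (rng.random(n) < config.treated_fraction)
    else:
        treated = np.zeros(n, dtype=bool)
    categories = np.where(
        treated,
        rng.choice(config.treatment_categories, n),
        "",
    )

    mu = params["mean"].to_numpy()
    sd = params["sd"].to_numpy()
    beta = params[f"beta_{tissue}"].to_numpy() * effect_scale
    if effect_mask is not None:
        beta = beta * effect_mask
    sign = np.sign(beta)
    atten = np.where(treated, config.treatment_effect, 0.0)
    # treated cases: |log2FC| attenuated by treatment_effect, floored at 0
    beta_eff = sign[:, None] * np.clip(
        np.abs(beta)[:, None] - atten[None, :], 0.0, None
    )
    response = np.broadcast_to(burden[None, :], (g, n))
    if config.response_sd > 0:
        response = response + rng.normal(0.0, config.response_sd, (g, n)) * (
            burden[None, :] != 0
        )
    eff = beta_eff * response

    if batch_shift is None:
        batch_shift = np.zeros(g)
    if batch_scale is None:
        batch_scale = np.ones(g)

    values = mu[:, None] + batch_shift[:, None] + eff
    noise_sd = (sd * batch_scale)[:, None]
    values = values + rng.normal(0.0, 1.0, (g, n)) * noise_sd

    # redundant blocks: shared latent factor replaces the independent noise
    block_ids = sorted(set(params.attrs["block_membership"].values()))
    blocks = params["block"].to_numpy()
    noise_ratio = np.sqrt(1.0 / config.block_corr - 1.0)
    for b in block_ids:
        rows = np.where(blocks == b)[0]
        if rows.size == 0:
            continue
        factor = rng.normal(0.0, config.block_factor_sd, n)
        fnoise = rng.normal(
            0.0, config.block_factor_sd * noise_ratio, (rows.size, n)
        )
        values[rows, :] = (
            mu[rows, None]
            + batch_shift[rows, None]
            + eff[rows, :]
            + factor[None, :]
            + fnoise
        )

    y_rows = params["is_y"].to_numpy()
    values[y_rows, :] += config.sex_effect * male[None, :]

    das28 = np.full(n, np.nan)
    table = pd.DataFrame(
        {
            "dataset": dataset,
            "tissue": tissue,
            "status": np.where(is_case, case_status, "control"),
            "sex": np.where(male, "male", "female"),
            "treatment": categories,
            "das28": das28,
            "rf_status": "",
            "pair_id": "",
            "timepoint": "",
            "burden": burden,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    vdf = pd.DataFrame(values, index=params.index.copy(), columns=sample_ids)
    return vdf, table


def generate_compendium(
    config: SimulationConfig,
) -> tuple[dict[str, list[ExpressionStudy]], GroundTruth]:
    """Generate the per-tissue study lists and the ground-truth record."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = _gene_params(config, rng)

    studies: dict[str, list[ExpressionStudy]] = {}
    tables = []
    for tissue in config.tissues:
        nd = config.n_datasets[tissue]
        case_counts = _split_counts(config.n_cases[tissue], nd)
        control_counts = _split_counts(config.n_controls[tissue], nd)
        n_das28 = int(np.ceil(config.das28_dataset_fraction * nd))
        studies[tissue] = []
        for d in range(nd):
            dataset = f"{tissue}_ds{d}"
            shift = rng.normal(0.0, config.batch_shift_sd, config.n_genes)
            scale = np.exp(rng.normal(0.0, config.batch_scale_sd, config.n_genes))
            values, table = _draw_samples(
                config,
                params,
                rng,
                n_cases=case_counts[d],
                n_controls=control_counts[d],
                tissue=tissue,
                dataset=dataset,
                prefix=dataset,
                batch_shift=shift,
                batch_scale=scale,
            )
            if d < n_das28:
                cases = table["status"].to_numpy() == "case"
                table.loc[cases, "das28"] = (
                    config.das28_intercept
                    + config.das28_slope * table.loc[cases, "burden"].to_numpy()
                    + rng.normal(0.0, config.das28_noise_sd, int(cases.sum()))
                )
            # hide sex for a fraction of samples in the public annotations
            blank = rng.random(len(table)) < config.missing_sex_fraction
            public = table.copy()
            public["true_sex"] = table["sex"]
            public.loc[blank, "sex"] = ""
            studies[tissue].append(
                ExpressionStudy(
                    values=values,
                    annotations=public[ANNOTATION_COLUMNS],
                    name=dataset,
                )
            )
            tables.append(public)

    sample_table = pd.concat(tables)
    true_fc = params[[f"beta_{t}" for t in config.tissues]].copy()
    true_fc.columns = list(config.tissues)
    truth = GroundTruth(
        planted_up=params.attrs["planted_up"],
        planted_down=params.attrs["planted_down"],
        block_membership=params.attrs["block_membership"],
        true_log2fc=true_fc,
        sample_table=sample_table,
        gene_params=params,
        y_genes=params.attrs["y_genes"],
        config=config,
    )
    return studies, truth


def generate_validation_sets(
    truth: GroundTruth,
    n_sets: int = 5,
    n_cases: int = 40,
    n_controls: int = 40,
    tissue: str = "blood",
    seed: int | None = None,
) -> list[ExpressionStudy]:
    """Independent batch-free cohorts drawn from the same population."""
    config: SimulationConfig = truth.config
    rng = np.random.default_rng(config.seed + 90_001 if seed is None else seed)
    out = []
    for s in range(n_sets):
        name = f"validation_{tissue}_{s}"
        values, table = _draw_samples(
            config,
            truth.gene_params,
            rng,
            n_cases=n_cases,
            n_controls=n_controls,
            tissue=tissue,
            dataset=name,
            prefix=name,
        )
        out.append(
            ExpressionStudy(
                values=values, annotations=_publicize(table), name=name
            )
        )
    return out


def _publicize(table: pd.DataFrame) -> pd.DataFrame:
    return table.reindex(columns=ANNOTATION_COLUMNS).fillna(
        {c: "" for c in ANNOTATION_COLUMNS if c != "das28"}
    )


def generate_clinical_annotations(
    truth: GroundTruth, config: SimulationConfig | None = None
) -> ClinicalCohorts:
    """Clinical layer: RF status, paired pre/post treatment, OA and polyJIA.

    RF seropositivity is assigned independently of the planted signal, so
    any score built from the signal is RF-agnostic by construction.  The
    paired cohort draws each patient once and expresses the attenuated
    signal post-treatment; the OA cohorts express ``oa_overlap_fraction``
    of the planted genes at ``oa_effect_scale`` magnitude; the polyJIA
    cohort expresses the full blood signal.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 70_003)
    params = truth.gene_params

    table = truth.sample_table.copy()
    cases = table["status"] == "case"
    rf = np.where(rng.random(int(cases.sum())) < 0.7, "positive", "negative")
    table.loc[cases, "rf_status"] = rf

    # paired pre/post treatment cohort (blood)
    n_pairs = 30
    burden = rng.normal(1.0, config.burden_sd, n_pairs)
    pre_v, pre_t = _draw_samples(
        config,
        params,
        rng,
        n_cases=n_pairs,
        n_controls=0,
        tissue="blood",
        dataset="treatment_cohort",
        prefix="pre",
        fixed_burden=burden,
        treatment_override=np.zeros(n_pairs, dtype=bool),
    )
    post_v, post_t = _draw_samples(
        config,
        params,
        rng,
        n_cases=n_pairs,
        n_controls=0,
        tissue="blood",
        dataset="treatment_cohort",
        prefix="post",
        fixed_burden=burden,
        treatment_override=np.ones(n_pairs, dtype=bool),
    )
    # per-person offsets shared by the pre and post draws of each patient
    indiv = rng.normal(0.0, 1.0, pre_v.shape) * (
        0.5 * params["sd"].to_numpy()[:, None]
    )
    pre_v = pre_v + indiv
    post_v = post_v + indiv
    for i, t in enumerate((pre_t, post_t)):
        t["pair_id"] = [f"pair{j:03d}" for j in range(n_pairs)]
        t["timepoint"] = "pre" if i == 0 else "post"
    pair_values = pd.concat([pre_v, post_v], axis=1)
    pair_table = pd.concat([pre_t, post_t])
    pairs = ExpressionStudy(
        values=pair_values,
        annotations=_publicize(pair_table),
        name="treatment_cohort",
    )

    # OA cohorts: signal restricted to a random planted subset, reduced scale
    planted = truth.planted_up + truth.planted_down
    n_keep = int(round(config.oa_overlap_fraction * len(planted)))
    keep = set(rng.choice(planted, n_keep, replace=False)) if n_keep else set()
    mask = params.index.isin(keep).astype(float)
    oa_cohorts = {}
    for tissue in config.tissues:
        name = f"oa_cohort_{tissue}"
        ra_v, ra_t = _draw_samples(
            config,
            params,
            rng,
            n_cases=40,
            n_controls=0,
            tissue=tissue,
            dataset=name,
            prefix=f"{name}_ra",
        )
        oa_v, oa_t = _draw_samples(
            config,
            params,
            rng,
            n_cases=40,
            n_controls=0,
            tissue=tissue,
            dataset=name,
            prefix=f"{name}_oa",
            case_status="OA",
            effect_scale=config.oa_effect_scale,
            effect_mask=mask,
            allow_treatment=False,
        )
        oa_cohorts[tissue] = ExpressionStudy(
            values=pd.concat([ra_v, oa_v], axis=1),
            annotations=_publicize(pd.concat([ra_t, oa_t])),
            name=name,
        )

    jia_v, jia_t = _draw_samples(
        config,
        params,
        rng,
        n_cases=40,
        n_controls=40,
        tissue="blood",
        dataset="polyjia_cohort",
        prefix="polyjia",
        case_status="polyJIA",
        allow_treatment=False,
    )
    polyjia = ExpressionStudy(
        values=jia_v, annotations=_publicize(jia_t), name="polyjia_cohort"
    )

    return ClinicalCohorts(
        table=table,
        treatment_pairs=pairs,
        oa_cohorts=oa_cohorts,
        polyjia_cohort=polyjia,
    )


def generate_fpkm_table(
    n_genes: int = 50, n_samples: int = 6, seed: int = 0
) -> pd.DataFrame:
    """Small positive FPKM-like table (exists to exercise fpkm_to_log_tpm)."""
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=1.0, sigma=1.5, size=(n_genes, n_samples))
    return pd.DataFrame(
        values,
        index=[f"G{i:05d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
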