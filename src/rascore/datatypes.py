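"""Core containers shared by every pipeline stage.

Expression data lives in pandas DataFrames oriented genes x samples, on the
log2 scale unless a function says otherwise.  Per-sample annotations are a
DataFrame indexed by sample id with the columns of the annotation TSV
dialect (``dataset, tissue, status, sex, treatment, das28, rf_status,
pair_id, timepoint``); missing values are empty strings for categorical
fields and NaN for numeric ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = [
    "dataset",
    "tissue",
    "status",
    "sex",
    "treatment",
    "das28",
    "rf_status",
    "pair_id",
    "timepoint",
]


def _check_alignment(values: pd.DataFrame, annotations: pd.DataFrame) -> None:
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dup[:5]}")
    if not values.columns.equals(annotations.index):
        missing = values.columns.difference(annotations.index).tolist()
        extra = annotations.index.difference(values.columns).tolist()
        raise ValueError(
            "annotation rows must correspond 1:1 to sample columns "
            f"(missing={missing[:5]}, extra={extra[:5]})"
        )
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")


@dataclass
class ExpressionStudy:
    """One dataset: gene x sample log2 expression plus sample annotations."""

    values: pd.DataFrame
    annotations: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        _check_alignment(self.values, self.annotations)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class Compendium:
    """Merged multi-study matrix restricted to common genes.

    ``annotations['dataset']`` is the batch label used by ComBat and the
    batch-predictability diagnostics.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    tissue: str = ""
    quantile_normalized: bool = False
    batch_adjusted: bool = False

    def __post_init__(self) -> None:
        _check_alignment(self.values, self.annotations)
        if "dataset" not in self.annotations.columns:
            raise ValueError("compendium annotations require a 'dataset' column")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def batches(self) -> pd.Series:
        return self.annotations["dataset"]

    def status(self) -> pd.Series:
        return self.annotations["status"]

    def copy_with(self, values: pd.DataFrame, **flags) -> "Compendium":
        kwargs = dict(
            tissue=self.tissue,
            quantile_normalized=self.quantile_normalized,
            batch_adjusted=self.batch_adjusted,
        )
        kwargs.update(flags)
        return Compendium(values=values, annotations=self.annotations.copy(), **kwargs)


@dataclass
class GroundTruth:
    """Latent state of a simulated compendium, for evaluation only.

    ``true_log2fc`` is a genes x tissues DataFrame of untreated case-vs-
    control effects (0 for null genes).  ``gene_params`` / ``sample_table``
    keep the generative parameters so that additional clinical cohorts can
    be drawn from the same population.
    """

    planted_up: list[str]
    planted_down: list[str]
    block_membership: dict[str, int]
    true_log2fc: pd.DataFrame
    sample_table: pd.DataFrame
    gene_params: pd.DataFrame = field(repr=False, default=None)
    y_genes: list[str] = field(default_factory=list)
    config: object = None

    @property
    def signal_genes(self) -> list[str]:
        """All genes with nonzero true effect (planted plus block genes)."""
        nz = self.true_log2fc.index[(self.true_log2fc != 0).any(axis=1)]
        return list(nz)
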