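import warnings

import numpy as np
import pandas as pd
import pytest

from rascore.feature_selection import FSConfig
from rascore.pipeline import preprocess_tissue
from rascore.simulate import SimulationConfig, generate_compendium


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        yield


def small_config(**overrides) -> SimulationConfig:
    """A fast, reduced-scale compendium used across the unit tests."""
    base = dict(
        n_genes=400,
        n_datasets={"synovium": 2, "blood": 2},
        n_cases={"synovium": 40, "blood": 80},
        n_controls={"synovium": 20, "blood": 24},
        planted_up=12,
        planted_down=12,
        n_redundant_blocks=2,
        block_size=4,
        n_y_genes=6,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    cfg = small_config()
    studies, truth = generate_compendium(cfg)
    return cfg, studies, truth


@pytest.fixture(scope="session")
def small_adjusted(small_sim):
    """Quantile-normalized, merged, sex-imputed, batch-adjusted compendia."""
    cfg, studies, truth = small_sim
    adjusted = {}
    merged = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tissue in cfg.tissues:
            m, a, _ = preprocess_tissue(studies[tissue], tissue, truth.y_genes)
            merged[tissue], adjusted[tissue] = m, a
    return merged, adjusted, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def toy_study(values: np.ndarray, status=None, dataset="ds0", tissue="blood"):
    """Wrap a raw array into an annotated expression matrix pair."""
    from rascore.datatypes import ANNOTATION_COLUMNS, ExpressionStudy

    g, n = values.shape
    genes = [f"G{i:03d}" for i in range(g)]
    samples = [f"s{j}" for j in range(n)]
    ann = pd.DataFrame(
        {c: [""] * n for c in ANNOTATION_COLUMNS},
        index=pd.Index(samples, name="sample_id"),
    )
    ann["dataset"] = dataset
    ann["tissue"] = tissue
    ann["das28"] = np.nan
    if status is not None:
        ann["status"] = list(status)
    return ExpressionStudy(
        values=pd.DataFrame(values, index=genes, columns=samples),
        annotations=ann,
        name=dataset,
    )
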