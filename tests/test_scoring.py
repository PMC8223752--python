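import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rascore.scoring import (
    ScorePanel,
    bootstrap_or,
    compare_gene_sets,
    fisher_combine,
    ra_score,
    random_panel_null,
    score_das28_correlation,
    score_group_effect,
    validate_genes,
)
from rascore.simulate import generate_clinical_annotations, generate_validation_sets

from .conftest import small_config


def _log2_matrix(rows, genes, samples=None):
    arr = np.asarray(rows, dtype=float)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


class TestRAScore:
    def test_closed_form_two_gene_panel(self):
        m = _log2_matrix([[3.0], [5.0], [1.0], [3.0]], ["u1", "u2", "d1", "d2"])
        panel = ScorePanel(up_genes=["u1", "u2"], down_genes=["d1", "d2"])
        # GM(up) = 2^mean(3,5) = 16, GM(down) = 2^mean(1,3) = 4
        assert ra_score(m, panel).iloc[0] == pytest.approx(12.0)

    def test_uniform_expression_closed_form(self):
        m = _log2_matrix([[4.0], [4.0], [2.0]], ["u1", "u2", "d1"])
        panel = ScorePanel(up_genes=["u1", "u2"], down_genes=["d1"])
        assert ra_score(m, panel).iloc[0] == pytest.approx(2**4 - 2**2)

    def test_constant_shift_scales_both_terms(self, rng):
        m = _log2_matrix(rng.normal(7, 1, size=(6, 5)), [f"g{i}" for i in range(6)])
        panel = ScorePanel(
            up_genes=["g0", "g1", "g2"], down_genes=["g3", "g4", "g5"]
        )
        base = ra_score(m, panel)
        shifted = ra_score(m + 3.0, panel)
        np.testing.assert_allclose(shifted, base * 8.0, rtol=1e-12)

    def test_monotone_in_panel_genes(self, rng):
        m = _log2_matrix(rng.normal(7, 1, size=(4, 3)), ["u1", "u2", "d1", "d2"])
        panel = ScorePanel(up_genes=["u1", "u2"], down_genes=["d1", "d2"])
        base = ra_score(m, panel)
        bumped_up = m.copy()
        bumped_up.loc["u1"] += 0.5
        assert (ra_score(bumped_up, panel) > base).all()
        bumped_down = m.copy()
        bumped_down.loc["d2"] += 0.5
        assert (ra_score(bumped_down, panel) < base).all()

    def test_missing_gene_dropped_with_warning(self, rng):
        m = _log2_matrix(rng.normal(size=(2, 3)), ["u1", "d1"])
        panel = ScorePanel(up_genes=["u1", "zz"], down_genes=["d1"])
        with pytest.warns(UserWarning, match="missing"):
            out = ra_score(m, panel)
        assert np.isfinite(out).all()

    def test_no_down_genes_present_rejected(self, rng):
        m = _log2_matrix(rng.normal(size=(1, 2)), ["u1"])
        with pytest.raises(ValueError):
            ra_score(m, ScorePanel(up_genes=["u1"], down_genes=["nope"]))

    def test_overlapping_panel_rejected(self):
        with pytest.raises(ValueError):
            ScorePanel(up_genes=["a"], down_genes=["a"])


class TestGroupEffect:
    def test_identical_groups_ratio_one(self, rng):
        scores = pd.Series(np.tile(rng.normal(10, 1, 20), 2))
        scores.index = [f"s{i}" for i in range(40)]
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=scores.index)
        out = score_group_effect(scores, groups)
        assert out["ratio"] == pytest.approx(1.0)
        assert out["p"] > 0.9

    def test_known_shift_recovered(self, rng):
        a = rng.normal(100, 5, 500)
        b = rng.normal(50, 5, 500)
        scores = pd.Series(
            np.concatenate([a, b]), index=[f"s{i}" for i in range(1000)]
        )
        groups = pd.Series(["a"] * 500 + ["b"] * 500, index=scores.index)
        out = score_group_effect(scores, groups)
        assert out["ratio"] == pytest.approx(2.0, rel=0.01)

    def test_paired_contrast_uses_pairing(self, rng):
        subject = rng.normal(100, 20, 30)
        pre = subject + rng.normal(5, 1, 30)
        post = subject + rng.normal(0, 1, 30)
        scores = pd.Series(
            np.concatenate([pre, post]),
            index=[f"pre{i}" for i in range(30)] + [f"post{i}" for i in range(30)],
        )
        groups = pd.Series(["pre"] * 30 + ["post"] * 30, index=scores.index)
        pairs = pd.Series(
            [f"p{i}" for i in range(30)] * 2, index=scores.index
        )
        paired = score_group_effect(scores, groups, paired=pairs)
        unpaired = score_group_effect(scores, groups)
        assert paired["p"] < 1e-6  # pairing removes the subject variance
        assert paired["p"] < unpaired["p"]


class TestFisherCombine:
    def test_single_p_unchanged(self):
        assert fisher_combine([0.37]) == pytest.approx(0.37, rel=1e-12)

    def test_all_ones_combine_to_one(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_two_tenths_closed_form(self):
        # closed form for k=2: exp(-X/2) * (1 + X/2) with X = -2*2*ln(0.1)
        x = -2 * np.log(0.1) * 2
        expected = np.exp(-x / 2) * (1 + x / 2)
        assert fisher_combine([0.1, 0.1]) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.056052, abs=1e-6)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


class TestDas28Correlation:
    def test_affine_outcome_gives_unit_correlation(self, rng):
        scores = pd.Series(rng.normal(size=60), index=[f"s{i}" for i in range(60)])
        das = scores * 3 + 2
        ds = pd.Series(["d1"] * 30 + ["d2"] * 30, index=scores.index)
        out = score_das28_correlation(scores, das, ds, n_boot=50, seed=0)
        assert out["pooled_r"] == pytest.approx(1.0)

    def test_independent_outcome_near_zero(self, rng):
        scores = pd.Series(rng.normal(size=100), index=[f"s{i}" for i in range(100)])
        das = pd.Series(rng.normal(size=100), index=scores.index)
        ds = pd.Series(["d1"] * 100, index=scores.index)
        out = score_das28_correlation(scores, das, ds, n_boot=50, seed=0)
        assert abs(out["pooled_r"]) < 0.2

    def test_constant_outcome_dataset_skipped(self, rng):
        scores = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        das = pd.Series(
            np.concatenate([np.full(20, 4.0), rng.normal(size=20)]),
            index=scores.index,
        )
        ds = pd.Series(["flat"] * 20 + ["ok"] * 20, index=scores.index)
        with pytest.warns(UserWarning, match="constant"):
            out = score_das28_correlation(scores, das, ds, n_boot=20, seed=0)
        assert list(out["per_dataset"]) == ["ok"]


class TestBootstrapOR:
    def test_null_ci_covers_one(self, rng):
        cover = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            scores = pd.Series(r.normal(size=120), index=[f"s{i}" for i in range(120)])
            labels = pd.Series(
                ["case"] * 60 + ["control"] * 60, index=scores.index
            )
            out = bootstrap_or(
                scores, labels, ("case", "control"), n_boot=200, seed=seed
            )
            if out["ci95"][0] <= 1.0 <= out["ci95"][1]:
                cover += 1
        assert cover >= 16

    def test_direction_and_analytic_agreement(self, rng):
        labels = pd.Series(
            ["case"] * 100 + ["control"] * 100,
            index=[f"s{i}" for i in range(200)],
        )
        flips = rng.random(200) < 0.1
        raw = np.where((labels == "case") ^ flips, 1.0, -1.0)
        scores = pd.Series(raw + rng.normal(0, 0.05, 200), index=labels.index)
        out = bootstrap_or(
            scores, labels, ("case", "control"), n_boot=200, seed=1
        )
        assert out["or"] > 1.0
        assert out["ci95"][0] > 1.0
        # analytic logistic fit on the same standardized data as the oracle
        import statsmodels.api as sm

        z = (scores - scores.mean()) / scores.std(ddof=1)
        res = sm.Logit(
            (labels == "case").astype(float), sm.add_constant(z.to_numpy())
        ).fit(disp=0)
        assert np.log(out["or"]) == pytest.approx(res.params[1], rel=1e-6)

    def test_separation_capped(self):
        scores = pd.Series(
            np.concatenate([np.ones(30), -np.ones(30)]),
            index=[f"s{i}" for i in range(60)],
        )
        labels = pd.Series(["case"] * 30 + ["control"] * 30, index=scores.index)
        out = bootstrap_or(scores, labels, ("case", "control"), n_boot=20, seed=0)
        assert out["capped"]


class TestValidateGenes:
    @pytest.fixture(scope="class")
    def validation_setting(self):
        import warnings

        from rascore.pipeline import preprocess_tissue
        from rascore.simulate import generate_compendium

        cfg = small_config()
        studies, truth = generate_compendium(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, blood, _ = preprocess_tissue(studies["blood"], "blood", truth.y_genes)
        vsets = generate_validation_sets(truth, n_sets=3, seed=99)
        return blood, vsets, truth

    def test_planted_genes_validate_with_high_auc(self, validation_setting):
        blood, vsets, truth = validation_setting
        candidates = truth.planted_up[:5] + truth.planted_down[:5]
        panel = validate_genes(blood, vsets, candidates, auc_min=2 / 3)
        assert set(panel.up_genes) <= set(truth.planted_up)
        assert set(panel.down_genes) <= set(truth.planted_down)
        assert len(panel.genes) >= 7
        assert all(a > 2 / 3 for a in panel.validation_auc.values())

    def test_missing_gene_excluded_with_warning(self, validation_setting):
        blood, vsets, truth = validation_setting
        trimmed = [
            type(v)(
                values=v.values.drop(index=truth.planted_up[0]),
                annotations=v.annotations,
                name=v.name,
            )
            for v in vsets
        ]
        with pytest.warns(UserWarning, match="missing"):
            panel = validate_genes(
                blood, trimmed, truth.planted_up[:3], auc_min=0.5
            )
        assert truth.planted_up[0] not in panel.genes

    def test_impossible_threshold_empties_panel(self, validation_setting):
        blood, vsets, truth = validation_setting
        panel = validate_genes(
            blood, vsets, truth.planted_up[:3], auc_min=1.0
        )
        assert panel.genes == []


class TestCompareGeneSets:
    def test_planted_set_beats_random_set(self, rng):
        import warnings

        from rascore.pipeline import preprocess_tissue
        from rascore.simulate import generate_compendium

        cfg = small_config(seed=5)
        studies, truth = generate_compendium(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, blood, _ = preprocess_tissue(studies["blood"], "blood", truth.y_genes)
        vsets = generate_validation_sets(truth, n_sets=3, seed=55)
        planted = truth.planted_up + truth.planted_down
        null_pool = [
            g for g in blood.genes
            if g not in set(truth.signal_genes) and g not in set(truth.y_genes)
        ]
        random_set = list(rng.choice(null_pool, len(planted), replace=False))
        table = compare_gene_sets(
            blood, vsets,
            {"planted": planted, "random": random_set},
            models=("logistic", "random_forest"),
            seed=1,
        )
        for model in ("logistic", "random_forest"):
            sub = table[table["model"] == model].set_index("gene_set")
            assert sub.loc["planted", "mean_auc"] > sub.loc["random", "mean_auc"]

    def test_sample_overlap_guard(self, validation_overlap_fixture=None):
        import warnings

        from rascore.pipeline import preprocess_tissue
        from rascore.simulate import generate_compendium

        cfg = small_config(seed=6)
        studies, truth = generate_compendium(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, blood, _ = preprocess_tissue(studies["blood"], "blood", truth.y_genes)
        with pytest.raises(ValueError, match="overlap"):
            compare_gene_sets(
                blood, [blood], {"set": truth.planted_up[:3]}, models=("logistic",)
            )


class TestRandomPanelNull:
    def test_informative_panel_beats_null(self):
        import warnings

        from rascore.simulate import generate_compendium

        cfg = small_config(seed=9)
        studies, truth = generate_compendium(cfg)
        from rascore.preprocess import merge_studies

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            blood = merge_studies(studies["blood"], tissue="blood")
        clin = generate_clinical_annotations(truth)
        das28 = clin.table["das28"].reindex(blood.samples)
        panel = ScorePanel(
            up_genes=truth.planted_up[:8], down_genes=truth.planted_down[:5]
        )
        out = random_panel_null(blood.values, panel, das28, n_iter=50, seed=3)
        assert out["true_r"] > out["null_mean_r"]
        assert out["p"] < 0.01

    def test_same_seed_reproduces_null(self, rng):
        m = pd.DataFrame(
            rng.normal(7, 1, size=(60, 40)),
            index=[f"g{i}" for i in range(60)],
            columns=[f"s{j}" for j in range(40)],
        )
        outcome = pd.Series(rng.normal(size=40), index=m.columns)
        panel = ScorePanel(up_genes=["g0", "g1"], down_genes=["g2"])
        a = random_panel_null(m, panel, outcome, n_iter=20, seed=4)
        b = random_panel_null(m, panel, outcome, n_iter=20, seed=4)
        np.testing.assert_array_equal(a["null_rs"], b["null_rs"])

    def test_insufficient_pool_rejected(self, rng):
        m = pd.DataFrame(
            rng.normal(size=(3, 10)),
            index=["g0", "g1", "g2"], columns=[f"s{j}" for j in range(10)],
        )
        panel = ScorePanel(up_genes=["g0", "g1"], down_genes=["g2"])
        with pytest.raises(ValueError):
            random_panel_null(m, panel, pd.Series(rng.normal(size=10), index=m.columns))
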