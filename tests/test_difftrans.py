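import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ribodelta.config import PipelineConfig
from ribodelta.difftrans import (
    ZERO_VARIANCE_P,
    EnrichmentTable,
    band_classifier,
    condition_pvalues,
    enrichment_scores,
    run_diff_translation,
    selection_counts,
    storey_qvalues,
)
from ribodelta.io import CountMatrix, SampleMeta, ValidationError
from ribodelta.simulate import SimConfig, simulate_polysome_experiment

COND = ("MCF10A", "treated")


def table_from_scores(e_rows):
    """Minimal one-condition table with given per-gene replicate scores."""
    e = np.asarray(e_rows, dtype=float)
    genes = [f"g{i}" for i in range(e.shape[0])]
    summary = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    summary["E_mean.MCF10A.treated"] = e.mean(axis=1)
    return EnrichmentTable(gene_ids=genes, conditions=[COND], E={COND: e}, summary=summary)


def band_table(d_values, q_min):
    genes = [f"g{i}" for i in range(len(d_values))]
    summary = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    summary["dE.MCF10A"] = np.asarray(d_values, dtype=float)
    summary["dE.MCF7"] = 0.0
    summary["q_min"] = q_min
    return EnrichmentTable(gene_ids=genes, conditions=[COND], E={}, summary=summary)


class TestEnrichmentScores:
    def setup_method(self):
        samples = []
        for fraction in ("total", "polysome"):
            for rep in (1, 2):
                samples.append(SampleMeta(f"{fraction}{rep}", "MCF10A", "treated",
                                          fraction, rep))
        self.samples = samples

    def scores(self, total, polysome, pseudocount):
        counts = np.array([[total, total, polysome, polysome]])
        cm = CountMatrix(gene_ids=["g1"], samples=self.samples, counts=counts)
        t = enrichment_scores(cm.counts.astype(float), cm, pseudocount=pseudocount)
        return t.E[COND][0]

    def test_equal_fractions_score_zero(self):
        assert self.scores(10, 10, 0.5) == pytest.approx([0.0, 0.0])

    def test_fourfold_enrichment_without_pseudocount(self):
        assert self.scores(10, 40, 0.0) == pytest.approx([2.0, 2.0])

    def test_pseudocount_shrinks_ratio(self):
        expected = np.log2(40.5 / 10.5)  # ~1.9475
        assert self.scores(10, 40, 0.5) == pytest.approx([expected, expected])

    def test_unpaired_replicates_rejected(self):
        samples = [
            SampleMeta("t1", "MCF10A", "treated", "total", 1),
            SampleMeta("t2", "MCF10A", "treated", "total", 2),
            SampleMeta("p2", "MCF10A", "treated", "polysome", 2),
            SampleMeta("p3", "MCF10A", "treated", "polysome", 3),
        ]
        cm = CountMatrix(gene_ids=["g1"], samples=samples, counts=np.ones((1, 4), dtype=int))
        with pytest.raises(ValidationError, match="unpaired"):
            enrichment_scores(cm.counts.astype(float), cm)

    def test_spike_rows_excluded(self, small_counts):
        t = enrichment_scores(small_counts.counts.astype(float), small_counts)
        assert t.gene_ids == ["geneA", "geneB", "geneC"]


class TestConditionPvalues:
    def test_all_zero_scores_give_p_one(self):
        t = condition_pvalues(table_from_scores([[0.0, 0.0, 0.0]]), moderated=False)
        assert t.summary["p.MCF10A.treated"].iloc[0] == 1.0

    def test_zero_variance_nonzero_mean_sentinel(self):
        t = condition_pvalues(table_from_scores([[1.0, 1.0, 1.0]]), moderated=False)
        assert t.summary["p.MCF10A.treated"].iloc[0] == ZERO_VARIANCE_P

    def test_matches_closed_form_t(self):
        # replicates (0.9, 1.1, 1.0): t = 1.0/(0.1/sqrt(3)) ~ 17.32, df 2
        t = condition_pvalues(table_from_scores([[0.9, 1.1, 1.0]]), moderated=False)
        expected = 2 * stats.t.sf(1.0 / (0.1 / np.sqrt(3)), df=2)
        assert t.summary["p.MCF10A.treated"].iloc[0] == pytest.approx(expected)
        assert expected == pytest.approx(0.00332, abs=5e-5)

    def test_moderated_orders_by_signal(self):
        rng = np.random.default_rng(0)
        e = rng.normal(0, 0.2, size=(200, 3))
        e[0] += 3.0
        t = condition_pvalues(table_from_scores(e), moderated=True)
        p = t.summary["p.MCF10A.treated"]
        assert p.iloc[0] == p.min()
        assert p.iloc[0] < 1e-6


def storey_brute_force(p, pi0):
    """Independent oracle: exhaustive tail minimum on sorted p."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for i in range(m):
        q[order[i]] = min(
            pi0 * m * p[order[j]] / (j + 1) for j in range(i, m)
        )
    return np.minimum(q, 1.0)


class TestStoreyQvalues:
    def test_step_up_hand_example(self):
        q, fit = storey_qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert fit.pi0 == 1.0

    def test_single_pvalue(self):
        q, _ = storey_qvalues([0.05], pi0=1.0)
        assert q == pytest.approx([0.05])

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("m", [2, 5, 10])
    def test_matches_brute_force_oracle(self, seed, m):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=m)
        q, fit = storey_qvalues(p, lambda_=0.5)
        np.testing.assert_allclose(q, storey_brute_force(p, fit.pi0), atol=1e-12)

    def test_pi0_one_reduces_to_bh(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=100) ** 2
        q, _ = storey_qvalues(p, pi0=1.0)
        _, q_bh, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_bh, atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        q, _ = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([])
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.2])


class TestBandClassifier:
    def test_hand_evaluated_band(self):
        # d = (0,0,0,0,20): median 0, sample sd sqrt(80) ~ 8.944, band ~ 17.89
        t = band_classifier(band_table([0, 0, 0, 0, 20], q_min=0.001), PipelineConfig())
        assert t.band_center == 0.0
        assert t.band_spread == pytest.approx(np.sqrt(80))
        assert list(t.summary["class"]) == ["none"] * 4 + ["positive"]

    def test_q_gate_dominates_large_d(self):
        t = band_classifier(band_table([0, 0, 0, 0, 20], q_min=0.05), PipelineConfig())
        assert not t.summary["selected"].any()

    def test_zero_spread_selects_nothing(self):
        with pytest.warns(UserWarning, match="zero spread"):
            t = band_classifier(band_table([1.0, 1.0, 1.0], q_min=0.001), PipelineConfig())
        assert not t.summary["selected"].any()

    def test_selection_counts_combine(self):
        t = band_classifier(
            band_table([0] * 6 + [20, 21, -20], q_min=0.001), PipelineConfig()
        )
        c = selection_counts(t.summary)
        assert c["total"] == c["positive"] + c["negative"]


def swap_treatment(cm, line):
    flip = {"treated": "untreated", "untreated": "treated"}
    samples = [
        SampleMeta(s.sample_id, s.cell_line,
                   flip[s.treatment] if s.cell_line == line else s.treatment,
                   s.fraction, s.replicate, s.spike_mix)
        for s in cm.samples
    ]
    return CountMatrix(cm.gene_ids, samples, cm.counts.copy(), cm.spike_ids)


@pytest.fixture(scope="module")
def sim():
    cfg = SimConfig(n_genes=600, n_positive=10, n_negative=10, depth=4e5, rng_seed=5)
    return simulate_polysome_experiment(cfg)


class TestRunDiffTranslation:

    def test_deterministic_rerun(self, sim):
        cm, _ = sim
        cfg = PipelineConfig()
        a = run_diff_translation(cm, cfg).to_frame()
        b = run_diff_translation(cm, cfg).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_null_dataset_selects_almost_nothing(self):
        cfg = SimConfig(n_genes=400, n_positive=0, n_negative=0, effect_size=0.0,
                        depth=3e5, rng_seed=11)
        cm, _ = simulate_polysome_experiment(cfg)
        t = run_diff_translation(cm, PipelineConfig(pi0=1.0))
        assert t.summary["selected"].mean() <= 0.01

    def test_implanted_effects_recovered_with_sign(self, sim):
        cm, truth = sim
        t = run_diff_translation(cm, PipelineConfig())
        s = t.summary
        hits = 0
        for cls in ("positive", "negative"):
            for g in truth.ids_of_class(cls):
                hits += s.loc[g, "class"] == cls
        assert hits >= 18  # >= 90% of the 20 implanted genes

    def test_sensitivity_increases_with_effect_size(self):
        recoveries = []
        for effect in (0.5, 2.0, 4.0):
            cfg = SimConfig(n_genes=400, n_positive=8, n_negative=8,
                            effect_size=effect, depth=3e5, rng_seed=13)
            cm, truth = simulate_polysome_experiment(cfg)
            s = run_diff_translation(cm, PipelineConfig()).summary
            rec = sum(
                s.loc[g, "class"] == cls
                for cls in ("positive", "negative")
                for g in truth.ids_of_class(cls)
            )
            recoveries.append(rec)
        assert recoveries == sorted(recoveries)

    def test_label_swap_negates_responsive_shift_and_flips_classes(self, sim):
        cm, truth = sim
        cfg = PipelineConfig()
        t1 = run_diff_translation(cm, cfg).summary
        t2 = run_diff_translation(swap_treatment(cm, cfg.responsive_line), cfg).summary
        np.testing.assert_allclose(t2["dE.MCF10A"], -t1["dE.MCF10A"], atol=1e-12)
        flip = {"positive": "negative", "negative": "positive"}
        for cls in ("positive", "negative"):
            for g in truth.ids_of_class(cls):
                if t1.loc[g, "selected"] and t2.loc[g, "selected"]:
                    assert t2.loc[g, "class"] == flip[t1.loc[g, "class"]]


# ---------------------------------------------------------------------
# generative properties

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=50)
@given(p=st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                  min_size=1, max_size=30))
def test_storey_q_bounded_and_monotone(p):
    """q-values stay in [0, 1] and are non-decreasing in p."""
    q, fit = storey_qvalues(p, lambda_=0.5)
    assert np.all((q >= 0) & (q <= 1))
    assert 0 < fit.pi0 <= 1
    order = np.argsort(np.asarray(p), kind="mergesort")
    assert np.all(np.diff(q[order]) >= -1e-12)
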