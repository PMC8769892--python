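import numpy as np
import pytest
from scipy import stats

from csgcn.context_tests import (
    ContextThresholds,
    annotate_clusters,
    categorical_association,
    confound_variance_test,
    missingness_similarity,
    quantitative_association,
)
from csgcn.synthetic_data import SyntheticConfig, generate_dataset
from csgcn.workflow import PipelineConfig, run_pipeline


def proportion_z_oracle(count, n, p0, alternative):
    z = (count / n - p0) / np.sqrt(p0 * (1 - p0) / n)
    return stats.norm.sf(z) if alternative == "greater" else stats.norm.cdf(z)


class TestCategoricalAssociation:
    def test_pure_category_cluster_strongly_retained(self):
        labels = np.array(["heat"] * 25 + ["other"] * 75, object)
        in_mask = labels == "heat"
        res = categorical_association(in_mask, labels, "heat")
        assert res.retained
        assert res.p_in < 1e-6 and res.p_out < 1e-6
        assert res.p_in == pytest.approx(
            proportion_z_oracle(25, 25, 0.25, "greater"))
        assert res.p_out == pytest.approx(
            proportion_z_oracle(0, 75, 0.25, "less"))

    def test_statsmodels_cross_check(self):
        sm = pytest.importorskip("statsmodels.stats.proportion")
        labels = np.array(["heat"] * 40 + ["other"] * 60, object)
        in_mask = np.zeros(100, bool)
        in_mask[:30] = True          # 30-sample cluster, all heat
        res = categorical_association(in_mask, labels, "heat")
        z_ref, p_ref = sm.proportions_ztest(
            30, 30, value=0.4, alternative="larger", prop_var=0.4)
        assert res.p_in == pytest.approx(p_ref)

    def test_null_membership_calibrated(self, rng):
        """Retention of label-independent clusters stays at the alpha level."""
        alpha = 0.001
        n, prevalence = 400, 0.25
        labels = np.array(["heat"] * int(n * prevalence)
                          + ["other"] * int(n * (1 - prevalence)), object)
        hits = 0
        reps = 1000
        for _ in range(reps):
            in_mask = np.zeros(n, bool)
            in_mask[rng.choice(n, 60, replace=False)] = True
            res = categorical_association(in_mask, labels, "heat", alpha)
            hits += res.retained
        # both one-sided tests must reject: strictly rarer than alpha
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert hits / reps <= alpha + 3 * se

    def test_degenerate_prevalence_untestable(self):
        labels = np.array(["heat"] * 50, object)
        res = categorical_association(np.ones(50, bool), labels, "heat")
        assert res.untestable and not res.retained


class TestQuantitativeAssociation:
    def test_exact_linear_dependence_retained(self):
        t = np.linspace(0, 8, 40)
        res = quantitative_association(np.ones(40, bool), t,
                                       2 * t + 1, -0.5 * t + 3)
        assert res.retained
        assert res.r2_i == pytest.approx(1.0)
        assert res.r2_j == pytest.approx(1.0)

    def test_constant_covariate_untestable(self, rng):
        res = quantitative_association(np.ones(20, bool), np.full(20, 2.0),
                                       rng.normal(size=20), rng.normal(size=20))
        assert res.untestable

    def test_one_time_independent_gene_blocks_annotation(self, rng):
        """Both genes must pass: one time-flat gene blocks the pair."""
        t = np.linspace(0, 8, 60)
        x = 1.5 * t + rng.normal(0, 0.3, 60)     # time-driven
        y = rng.normal(5, 0.5, 60)               # flat
        res = quantitative_association(np.ones(60, bool), t, x, y)
        assert res.r2_i > 0.9
        assert res.r2_j < 0.3
        assert not res.retained


class TestMissingnessSimilarity:
    def test_identical_patterns_similar(self, rng):
        m = rng.random(100) < 0.3
        assert missingness_similarity(m, m) == 1.0

    def test_fully_observed_pair_similar(self):
        z = np.zeros(100, bool)
        assert missingness_similarity(z, z) == 1.0

    def test_disjoint_patterns_strongly_dissimilar(self):
        """The 'spoke' case: one gene missing in 80/100, the other in 0."""
        miss_x = np.r_[np.ones(80, bool), np.zeros(20, bool)]
        miss_z = np.zeros(100, bool)
        p = missingness_similarity(miss_x, miss_z)
        assert p < 1e-10
        ref = stats.ttest_ind(miss_x.astype(float), miss_z.astype(float),
                              equal_var=True).pvalue
        assert p == pytest.approx(ref)


class TestConfoundVarianceTest:
    def test_shifted_in_group_detected(self, rng):
        expr = np.r_[rng.normal(5, 1, 100), rng.normal(0, 1, 100)]
        in_mask = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        p = confound_variance_test(expr, in_mask, ~in_mask)
        assert p < 1e-6

    def test_matches_welch_ttest(self, rng):
        expr = rng.normal(0, 1, 60)
        in_mask = np.zeros(60, bool)
        in_mask[:25] = True
        p = confound_variance_test(expr, in_mask, ~in_mask)
        ref = stats.ttest_ind(expr[:25], expr[25:], equal_var=False).pvalue
        assert p == pytest.approx(ref)

    def test_empty_out_group_is_error(self, rng):
        expr = rng.normal(0, 1, 30)
        with pytest.raises(ValueError):
            confound_variance_test(expr, np.ones(30, bool), np.zeros(30, bool))

    def test_zero_variance_group_uses_floor(self, rng):
        expr = np.r_[np.full(10, 5.0), rng.normal(0, 1, 30)]
        in_mask = np.r_[np.ones(10, bool), np.zeros(30, bool)]
        p = confound_variance_test(expr, in_mask, ~in_mask)
        assert 0.0 <= p < 1e-4


class TestSpokeScenario:
    """End-to-end check of the missingness bias screen.

    Genes expressed only under control and driven by time correlate both
    with each other and with ubiquitously expressed time-driven (basal)
    genes. The former is a genuine control-specific relationship; the
    latter would create an artifactual spoke and must be filtered.
    """

    @pytest.fixture(scope="class")
    @staticmethod
    def spoke_run(tmp_path_factory):
        cfg = SyntheticConfig(n_bimodal=0, n_category=0, n_spoke=2,
                              n_confounded=0, n_basal=2, n_null=1,
                              spoke_time_driven=True, seed=5)
        gem, ann, truth = generate_dataset(cfg)
        out = tmp_path_factory.mktemp("spoke") / "run"
        stats_out: dict = {}
        run = run_pipeline(
            PipelineConfig(out_prefix=str(out), quantitative_vars=["Time"],
                           seed=5),
            gem=gem, annotations=ann)
        return gem, truth, run

    def test_control_specific_pairs_recovered(self, spoke_run):
        _, truth, run = spoke_run
        planted = {frozenset((t.gene_i, t.gene_j)) for t in truth
                   if t.archetype == "category-specific"}
        got = {frozenset((e.gene_i, e.gene_j)) for e in run.edges
               if e.kind == "categorical" and e.label == "control"}
        assert planted <= got

    def test_spoke_edges_to_basal_genes_filtered(self, spoke_run):
        _, _, run = spoke_run
        for e in run.edges:
            genes = {e.gene_i.split("_")[0][:-2], e.gene_j.split("_")[0][:-2]}
            assert genes != {"spoke", "basal"}, \
                f"spoke edge leaked: {e.gene_i}-{e.gene_j} {e.context}"

    def test_spoke_clusters_reach_but_fail_missingness_screen(self, spoke_run):
        gem, _, run = spoke_run
        # the screen itself: spoke vs basal missingness patterns differ
        p = missingness_similarity(gem.missing_mask("spoke00_a"),
                                   gem.missing_mask("basal00_a"))
        assert p < 1e-10
        p_same = missingness_similarity(gem.missing_mask("spoke00_a"),
                                        gem.missing_mask("spoke00_b"))
        assert p_same > 0.001


class TestAnnotateClusterPolicies:
    def test_miss_retain_switch_flips_behaviour(self, rng):
        """The opposite reading of the missingness screen is available but
        must be selected explicitly."""
        cfg = SyntheticConfig(n_bimodal=1, n_category=0, n_spoke=0,
                              n_confounded=0, n_basal=0, n_null=1, seed=3)
        gem, ann, _ = generate_dataset(cfg)
        from csgcn.pairwise_engine import SimilarityParams, similarity_pass
        from csgcn.power_filter import apply_power_filter

        clusters = list(apply_power_filter(
            similarity_pass(gem, SimilarityParams(seed=3))))
        default = list(annotate_clusters(clusters, gem, ann,
                                         ContextThresholds()))
        flipped = list(annotate_clusters(clusters, gem, ann,
                                         ContextThresholds(miss_retain="different")))
        # fully observed genes have identical missingness: retained under
        # the similarity reading, dropped under the flipped one
        assert len(default) > 0
        assert len(flipped) == 0
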