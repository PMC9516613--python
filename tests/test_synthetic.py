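"""Synthetic-cohort generator: determinism, moments, and recovery chains."""

import numpy as np
import pytest
from scipy.special import logit

from caripheno.clusters import score_subject, summarize_cohort
from caripheno.metareg import CohortPoint, fit_meta_regression
from caripheno.phenotypes import index_counts
from caripheno.simulate import (
    SyntheticCohortParams,
    consortium_age_spread,
    generate_cohort,
    generate_consortium,
)

NO_TOOTH_LOSS = (-50.0, 0.0)


class TestGeneration:
    def test_same_seed_reproduces_bit_identical_cohorts(self):
        p = SyntheticCohortParams(n=40, seed=77)
        a, truth_a = generate_cohort(p)
        b, truth_b = generate_cohort(SyntheticCohortParams(n=40, seed=77))
        assert truth_a == truth_b
        for ra, rb in zip(a, b):
            assert ra.subject_id == rb.subject_id
            assert ra.age == rb.age and ra.sex == rb.sex
            assert ra.surfaces == rb.surfaces

    def test_different_seeds_differ(self):
        a, _ = generate_cohort(SyntheticCohortParams(n=40, seed=1))
        b, _ = generate_cohort(SyntheticCohortParams(n=40, seed=2))
        assert any(ra.surfaces != rb.surfaces for ra, rb in zip(a, b))

    def test_suppressed_caries_and_tooth_loss_give_all_sound_cohort(self):
        p = SyntheticCohortParams(
            n=30, cluster_logits=(-50.0,) * 5, tooth_loss=NO_TOOTH_LOSS,
            frailty_sd=0.0, seed=5)
        records, _ = generate_cohort(p)
        for rec in records:
            assert index_counts(rec).dmfs_morbidity == 0

    def test_ages_respect_truncation(self):
        p = SyntheticCohortParams(n=200, age_mean=20.0, age_sd=15.0, seed=3)
        records, _ = generate_cohort(p)
        assert all(18.0 <= r.age <= 100.0 for r in records)

    def test_truth_echoes_parameters(self):
        p = SyntheticCohortParams(n=10, seed=9, age_slope=0.05)
        _, truth = generate_cohort(p)
        assert truth["age_slope"] == 0.05
        assert truth["n"] == 10 and truth["seed"] == 9

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortParams(n=0)
        with pytest.raises(ValueError):
            SyntheticCohortParams(frailty_sd=-1.0)
        with pytest.raises(ValueError):
            SyntheticCohortParams(cluster_logits=(0.0, 0.0))


class TestMoments:
    def test_cluster_means_match_binomial_expectation(self, default_map):
        """With no frailty, no age effect, and no tooth loss, every surface
        is Bernoulli(0.3): each cluster's cohort mean must fall within 3
        binomial standard errors of 0.3."""
        p = SyntheticCohortParams(
            n=2000, cluster_logits=(float(logit(0.3)),) * 5, age_slope=0.0,
            frailty_sd=0.0, tooth_loss=NO_TOOTH_LOSS, seed=314)
        records, _ = generate_cohort(p)
        summary = summarize_cohort(records, default_map)
        sizes = [default_map.sizes()[c] for c in default_map.cluster_ids]
        for mean, size in zip(summary.cluster_means, sizes):
            se = np.sqrt(0.3 * 0.7 / (2000 * size))
            assert abs(mean - 0.3) < 3 * se

    def test_susceptibility_ordering_is_reproduced(self, default_map):
        """Default logits order clusters 1 > 3 > 5 > 4 > 2; at n=2000 the
        cohort summary must rank the cluster means the same way."""
        p = SyntheticCohortParams(n=2000, seed=271)
        records, _ = generate_cohort(p)
        summary = summarize_cohort(records, default_map)
        m = summary.cluster_means
        assert m[0] > m[2] > m[4] > m[3] > m[1]


class TestConsortium:
    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            generate_consortium([])

    def test_single_cohort_without_master_seed_equals_generate_cohort(self):
        p = SyntheticCohortParams(n=25, seed=4)
        [(records, truth)] = generate_consortium([p])
        direct, _ = generate_cohort(SyntheticCohortParams(n=25, seed=4))
        assert [r.surfaces for r in records] == [r.surfaces for r in direct]

    def test_master_seed_derives_deterministic_child_seeds(self):
        params = [SyntheticCohortParams(n=10, name=f"c{i}") for i in range(3)]
        a = generate_consortium(params, master_seed=5)
        params2 = [SyntheticCohortParams(n=10, name=f"c{i}") for i in range(3)]
        b = generate_consortium(params2, master_seed=5)
        for (ra, ta), (rb, tb) in zip(a, b):
            assert ta["seed"] == tb["seed"] < 2**31
            assert [r.surfaces for r in ra] == [r.surfaces for r in rb]

    def test_age_effect_sign_recovered_by_meta_regression(self, default_map):
        """Cohorts spanning mean ages 23-74 with a positive generating age
        slope: the fitted meta-regression slope is positive for every
        cluster (mirroring the rise of cluster caries experience with age)."""
        cohorts = generate_consortium(
            consortium_age_spread(n_cohorts=8, cohort_n=200, master_seed=60))
        for j, c in enumerate(default_map.cluster_ids):
            points = []
            for records, _ in cohorts:
                scores = [score_subject(r, default_map)[j] for r in records]
                mean = float(np.mean(scores))
                se = float(np.std(scores, ddof=1) / np.sqrt(len(scores)))
                age = float(np.mean([r.age for r in records]))
                points.append(CohortPoint(estimate=mean, se=se, covariate=age))
            fit = fit_meta_regression(points)
            assert fit.slope > 0, f"cluster {c}"

    def test_logit_scale_slope_magnitude_recovered_without_frailty(
            self, default_map):
        """With zero frailty and no tooth loss, a cohort's expected cluster
        score is logistic(a_c + b * age); regressing the logit of the cohort
        mean on cohort mean age therefore recovers b itself, within 20%."""
        b_true = 0.03
        cohorts = generate_consortium(
            consortium_age_spread(
                n_cohorts=8, cohort_n=400, master_seed=90,
                frailty_sd=0.0, tooth_loss=NO_TOOTH_LOSS, age_slope=b_true))
        j = 2  # cluster 3, 48 surfaces: tightest cohort means
        points = []
        for records, _ in cohorts:
            scores = np.array([score_subject(r, default_map)[j]
                               for r in records])
            m = scores.mean()
            se = scores.std(ddof=1) / np.sqrt(len(scores))
            # delta method onto the logit scale
            points.append(CohortPoint(
                estimate=float(logit(m)), se=float(se / (m * (1 - m))),
                covariate=float(np.mean([r.age for r in records]))))
        fit = fit_meta_regression(points)
        assert fit.slope == pytest.approx(b_true, rel=0.2)
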