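"""Evaluation harness: AUROC oracle, subsampling, t-tests, replicate logic."""

import numpy as np
import pytest
from scipy import stats

from swarmpath.classifier import Hyperparams, PatientBag
from swarmpath.evaluate import (
    ExperimentResult,
    ExperimentSpec,
    compare_auroc,
    patient_auroc,
    replicate_experiment,
    stratified_subsample,
    train_model_suite,
)
from swarmpath.synthetic import SyntheticConfig, generate_feature_cohorts


def brute_force_auroc(labels, scores):
    """Pair-counting oracle: P(score_pos > score_neg), ties half-credited."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestPatientAUROC:
    def test_perfect_separation(self):
        assert patient_auroc([0, 1], [0.2, 0.8]) == 1.0

    def test_constant_scores_give_half(self):
        assert patient_auroc([0, 1, 0, 1], [0.4] * 4) == 0.5

    def test_worked_example(self):
        # 4 pos-neg pairs: (.5>.1)+(.5<.6=0)+(.9>.1)+(.9>.6) = 3/4
        assert patient_auroc([0, 0, 1, 1], [0.1, 0.6, 0.5, 0.9]) == 0.75

    def test_matches_pair_counting_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 20))
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                labels[0], labels[1] = 0, 1
            # discrete scores force ties into the comparison
            scores = rng.integers(0, 5, n) / 4.0
            assert patient_auroc(labels, scores) == pytest.approx(
                brute_force_auroc(labels, scores)
            )

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        a = patient_auroc(labels, scores)
        assert patient_auroc(labels, np.exp(3 * scores)) == pytest.approx(a)
        assert patient_auroc(labels, scores**3) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            patient_auroc([1, 1, 1], [0.1, 0.2, 0.3])


def _bags(labels):
    return [
        PatientBag(f"p{i}", "c", int(l), np.zeros((2, 3)) + i) for i, l in enumerate(labels)
    ]


class TestStratifiedSubsample:
    def test_exact_proportions(self):
        bags = _bags([1] * 30 + [0] * 270)
        sub = stratified_subsample(bags, 100, seed=0)
        labels = [b.label for b in sub]
        assert sum(labels) == 10 and len(labels) == 100

    def test_n_equal_total_is_identity(self):
        bags = _bags([0, 1, 0, 1])
        assert stratified_subsample(bags, 4, seed=0) == bags

    def test_largest_remainder_example(self):
        # 97 patients, 13 positive, n=50: 50*13/97 = 6.70 -> 7 positives
        bags = _bags([1] * 13 + [0] * 84)
        sub = stratified_subsample(bags, 50, seed=1)
        assert sum(b.label for b in sub) == 7
        assert len(sub) == 50

    def test_quotas_always_sum_to_n(self, rng):
        # enumeration over many (n_pos, n, k) combinations
        for _ in range(50):
            n_pos = int(rng.integers(2, 40))
            n_neg = int(rng.integers(2, 60))
            bags = _bags([1] * n_pos + [0] * n_neg)
            k = int(rng.integers(2, n_pos + n_neg))
            sub = stratified_subsample(bags, k, seed=int(rng.integers(1000)))
            assert len(sub) == k

    def test_deterministic_under_seed(self):
        bags = _bags([1] * 20 + [0] * 40)
        a = stratified_subsample(bags, 30, seed=7)
        b = stratified_subsample(bags, 30, seed=7)
        assert [x.patient_id for x in a] == [x.patient_id for x in b]

    def test_oversized_and_degenerate_requests_rejected(self):
        bags = _bags([0, 1, 0])
        with pytest.raises(ValueError):
            stratified_subsample(bags, 4, seed=0)
        with pytest.raises(ValueError):
            stratified_subsample(bags, 1, seed=0)


class TestCompareAUROC:
    def _res(self, aurocs):
        return ExperimentResult("m", "pool", tuple(aurocs), tuple(range(len(aurocs))))

    def test_identical_lists_give_p_one(self):
        a = self._res([0.70, 0.72, 0.74])
        assert compare_auroc(a, a) == pytest.approx(1.0)

    def test_shifted_lists_match_closed_form(self):
        # classical equal-variance two-sample t with 8 degrees of freedom
        xa = np.array([0.70, 0.71, 0.72, 0.73, 0.74])
        xb = xa + 0.10
        a, b = self._res(xa), self._res(xb)
        p = compare_auroc(a, b)
        sp = np.sqrt((xa.var(ddof=1) + xb.var(ddof=1)) / 2)
        t = (xa.mean() - xb.mean()) / (sp * np.sqrt(2 / 5))
        p_closed = 2 * stats.t.sf(abs(t), df=8)
        assert p == pytest.approx(p_closed, rel=1e-12)
        assert p < 0.001

    def test_symmetric_in_arguments(self):
        a = self._res([0.6, 0.65, 0.7])
        b = self._res([0.75, 0.8, 0.85])
        assert compare_auroc(a, b) == pytest.approx(compare_auroc(b, a))

    def test_zero_variance_convention(self):
        a = self._res([0.7, 0.7, 0.7])
        b = self._res([0.7, 0.7, 0.7])
        with pytest.warns(UserWarning):
            assert compare_auroc(a, b) == 1.0
        c = self._res([0.8, 0.8, 0.8])
        with pytest.warns(UserWarning):
            assert compare_auroc(a, c) == 0.0

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            compare_auroc(self._res([0.7]), self._res([0.8, 0.9]))


@pytest.fixture(scope="module")
def small_spec():
    cfg = SyntheticConfig(
        patients_per_cohort=(16, 30, 20),
        tiles_per_patient=8,
        feature_dim=24,
        seed=21,
    )
    return ExperimentSpec(
        config=cfg,
        model_types=("local", "w-chkpt"),
        hp=Hyperparams(batch_size=16, learning_rate=0.05),
        test_patients_per_cohort=12,
    )


class TestReplicateExperiment:

    def test_replicates_recorded_with_mean_sd(self, small_spec):
        res = replicate_experiment(small_spec, seeds=[0, 1])
        for r in res.values():
            assert len(r.aurocs) == 2
            assert r.mean == pytest.approx(np.mean(r.aurocs))
            assert r.sd == pytest.approx(np.std(r.aurocs, ddof=1))

    def test_rerun_is_identical(self, small_spec):
        a = replicate_experiment(small_spec, seeds=[0, 1])
        b = replicate_experiment(small_spec, seeds=[0, 1])
        for k in a:
            assert a[k].aurocs == b[k].aurocs

    def test_duplicate_seeds_rejected(self, small_spec):
        with pytest.raises(ValueError):
            replicate_experiment(small_spec, seeds=[3, 3])

    def test_cache_round_trip(self, small_spec, tmp_path):
        a = replicate_experiment(small_spec, seeds=[0], cache_dir=tmp_path)
        assert any(tmp_path.iterdir())
        b = replicate_experiment(small_spec, seeds=[0], cache_dir=tmp_path)
        for k in a:
            assert a[k].aurocs == b[k].aurocs

    def test_no_signal_data_scores_near_chance(self):
        cfg = SyntheticConfig(
            patients_per_cohort=(20, 20, 20),
            tiles_per_patient=6,
            feature_dim=16,
            effect_size=0.0,
            site_shift=0.0,
            seed=5,
        )
        spec = ExperimentSpec(
            config=cfg,
            model_types=("merged",),
            hp=Hyperparams(batch_size=16, learning_rate=0.05),
            test_patients_per_cohort=40,
        )
        res = replicate_experiment(spec, seeds=[0, 1, 2])["merged"]
        # mean within 3 sd-of-mean of chance (sd floor avoids a degenerate test)
        spread = max(res.sd, 0.02)
        assert abs(res.mean - 0.5) < 3 * spread


def test_train_test_patient_overlap_rejected(tiny_config):
    bags, _ = generate_feature_cohorts(tiny_config)
    hp = Hyperparams(batch_size=16, learning_rate=0.05)
    suite = train_model_suite(bags, hp, seed=0, model_types=("merged",))
    from swarmpath.evaluate import _check_no_overlap

    test_pool = [b for c in bags.values() for b in c][:5]  # overlapping on purpose
    with pytest.raises(ValueError):
        _check_no_overlap(bags, test_pool)


def test_box_plot_export_writes_png(tmp_path):
    import pandas as pd

    from swarmpath.evaluate import plot_results_box

    rows = [
        {"test_cohort": "pool", "model_type": m, "subset_size": s, "seed": k,
         "auroc": 0.7 + 0.01 * k}
        for m in ("local:cohortA", "w-chkpt")
        for s in (0, 100)
        for k in range(3)
    ]
    out = tmp_path / "results.png"
    plot_results_box(pd.DataFrame(rows), out, title="demo")
    assert out.stat().st_size > 0
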