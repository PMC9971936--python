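"""Forward stepwise mechanics with a fast pixel-logistic model factory.

The CNN-based planted-lead recovery is exercised in the acceptance suite;
here a regularized logistic regression on pixels stands in as the
classifier so the search mechanics (fold pairing, greedy acceptance,
stopping, tie-breaks, reporting) can be tested in seconds.
"""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from rpaf.dataset import LeadImageDataset
from rpaf.evaluation import stratified_folds
from rpaf.lead_selection import (
    SelectionConfig,
    forward_stepwise,
    score_subset,
    two_sample_t_test,
)


class PixelLogistic:
    def __init__(self, C=1.0):
        self.clf = LogisticRegression(max_iter=2000, C=C)

    def fit(self, X, y):
        self.clf.fit(X.reshape(len(X), -1), y)
        return self

    def predict(self, X):
        return self.clf.predict(X.reshape(len(X), -1))


def logistic_factory(in_channels):
    return PixelLogistic()


def make_planted_dataset(
    n=60,
    size=8,
    coarse_frac=0.6,
    noise=1.0,
    seed=0,
    leads=("I", "II", "V1", "V5", "aVR"),
):
    """Synthetic per-lead images with complementary planted information.

    AF rows of one subtype imprint a fixed pattern on the V1 image, the
    complementary subtype imprints a different pattern on the II image;
    remaining leads are pure noise.  So V1 alone sees ``coarse_frac`` of AF,
    II the rest, and only the pair approaches perfect detection.
    """
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    pattern_v1 = rng.standard_normal((3, size, size))
    pattern_ii = rng.standard_normal((3, size, size))
    images = {l: rng.normal(0, noise, (n, 3, size, size)).astype(np.float32) for l in leads}
    for i in np.flatnonzero(y == 1):
        if rng.random() < coarse_frac:
            images["V1"][i] += pattern_v1
        else:
            images["II"][i] += pattern_ii
    return LeadImageDataset(
        images=images,
        labels=y,
        record_ids=[f"r{i:03d}" for i in range(n)],
    )


class TestTwoSampleTTest:
    def test_identical_lists_p_one(self):
        assert two_sample_t_test([0.9, 0.8, 0.85], [0.9, 0.8, 0.85]) == pytest.approx(1.0)

    def test_textbook_welch_oracle(self):
        """Hand-computed Welch statistic on the two clearly separated score
        groups gives p << 0.001."""
        a = np.array([0.9, 0.91, 0.92, 0.89, 0.9])
        b = np.array([0.5, 0.52, 0.48, 0.51, 0.49])
        # manual Welch computation as the independent oracle
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        from scipy import stats

        p_oracle = 2 * stats.t.sf(abs(t), df)
        p = two_sample_t_test(a, b)
        assert p == pytest.approx(p_oracle, rel=1e-10)
        assert p < 0.001

    def test_symmetry(self):
        a, b = [0.7, 0.8, 0.75], [0.6, 0.65, 0.55]
        assert two_sample_t_test(a, b) == pytest.approx(two_sample_t_test(b, a))

    def test_degenerate_zero_variance(self):
        assert two_sample_t_test([1.0, 1.0], [1.0, 1.0]) == 1.0
        assert two_sample_t_test([1.0, 1.0], [0.5, 0.5]) == 0.0

    def test_too_few_scores(self):
        with pytest.raises(ValueError):
            two_sample_t_test([1.0], [0.5, 0.6])


class TestScoreSubset:
    def test_deterministic_per_seed(self):
        ds = make_planted_dataset()
        cfg = SelectionConfig(seed=3)
        s1 = score_subset(["V1"], ds, logistic_factory, cfg)
        s2 = score_subset(["V1"], ds, logistic_factory, cfg)
        assert s1 == s2

    def test_fold_partitions_shared_across_subsets(self):
        """Fairness: every candidate subset is scored on identical folds."""
        ds = make_planted_dataset()
        cfg = SelectionConfig(seed=9)
        f1 = stratified_folds(ds.labels, cfg.k_folds, cfg.seed)
        f2 = stratified_folds(ds.labels, cfg.k_folds, cfg.seed)
        for (tr1, te1), (tr2, te2) in zip(f1, f2):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)

    def test_perfectly_separable_gives_all_ones(self):
        ds = make_planted_dataset(coarse_frac=1.0, noise=0.05)
        scores = score_subset(["V1"], ds, logistic_factory, SelectionConfig(seed=0))
        assert scores == [1.0] * 5

    def test_pure_noise_lead_scores_near_chance(self):
        """Over 10 repeats, a noise lead's mean F1 sits near the 0.5 chance
        level on balanced data."""
        means = []
        for rep in range(10):
            ds = make_planted_dataset(seed=100 + rep)
            scores = score_subset(["aVR"], ds, logistic_factory, SelectionConfig(seed=rep))
            means.append(np.mean(scores))
        assert abs(np.mean(means) - 0.5) < 0.12

    def test_empty_subset_rejected(self):
        ds = make_planted_dataset()
        with pytest.raises(ValueError):
            score_subset([], ds, logistic_factory, SelectionConfig())


class TestForwardStepwise:
    def test_planted_two_lead_recovery(self):
        """Complementary planted information: the search recovers exactly
        {V1, II}, V1 first, in >= 4/5 seeded replicates."""
        hits = 0
        for rep in range(5):
            ds = make_planted_dataset(n=80, coarse_frac=0.6, noise=1.2, seed=rep)
            cfg = SelectionConfig(seed=rep)
            report = forward_stepwise(ds, logistic_factory, cfg)
            hits += report.chosen_subset == ("V1", "II")
        assert hits >= 4

    def test_single_perfect_lead_stops_at_one(self):
        ds = make_planted_dataset(coarse_frac=1.0, noise=0.05)
        report = forward_stepwise(ds, logistic_factory, SelectionConfig(seed=1))
        assert report.chosen_subset == ("V1",)
        assert report.stopped_reason == "no_improvement"

    def test_max_subset_one_limits_to_phase_one(self):
        ds = make_planted_dataset()
        report = forward_stepwise(ds, logistic_factory, SelectionConfig(seed=2, max_subset=1))
        assert len(report.phases) == 1
        assert len(report.chosen_subset) == 1
        assert report.stopped_reason == "max_subset"

    def test_accepted_phases_strictly_increase(self):
        ds = make_planted_dataset(n=80, seed=5)
        report = forward_stepwise(ds, logistic_factory, SelectionConfig(seed=5))
        means = [p.best.mean_f1 for p in report.phases if p.accepted]
        assert all(b > a for a, b in zip(means, means[1:]))
        # each accepted phase extends the previous subset by one lead
        accepted = [p.best.subset for p in report.phases if p.accepted]
        for prev, cur in zip(accepted, accepted[1:]):
            assert cur[:-1] == prev

    def test_report_serialization(self, tmp_path):
        ds = make_planted_dataset()
        report = forward_stepwise(ds, logistic_factory, SelectionConfig(seed=0, max_subset=2))
        path = report.save(tmp_path / "report.json")
        import json

        data = json.loads(path.read_text())
        assert data["chosen_subset"] == list(report.chosen_subset)
        assert data["phases"][0]["candidates"]
        best0 = data["phases"][0]["best"]
        assert best0["p_value_vs_best"] == 1.0

    def test_p_values_reported_per_candidate(self):
        ds = make_planted_dataset()
        report = forward_stepwise(ds, logistic_factory, SelectionConfig(seed=0, max_subset=1))
        for cand in report.phases[0].candidates:
            assert 0.0 <= cand.p_value_vs_best <= 1.0
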