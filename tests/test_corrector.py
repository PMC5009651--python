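import numpy as np
import pytest

from harman import (
    BatchComposition,
    correct_pc,
    decompose_scores,
    find_k,
    harman,
    likelihood,
    null_std,
    batch_probability,
)
from harman.corrector import _confidence_at


def grid_find_k(pc_scores, design, limit, step=1e-4):
    """Reference oracle: walk k from 1 toward 0 in fixed steps and keep the
    smallest k whose confidence still meets the limit (the plain discrete
    search the bisection optimises).  Vectorised over the grid."""
    batch_means, _ = decompose_scores(pc_scores, design)
    nulls = {b: null_std(pc_scores, design, BatchComposition.of_batch(design, b))
             for b in design.batches}
    if any(n.degenerate for n in nulls.values()):
        return 1.0
    if _confidence_at(1.0, batch_means, nulls) <= limit:
        return 1.0
    ks = np.arange(1.0, -step / 2, -step)
    labels = list(batch_means)
    from scipy.stats import norm
    z = np.column_stack([
        norm.cdf(-np.abs(ks * batch_means[b]) / nulls[b].std) for b in labels
    ])
    z = np.maximum(z, 1e-300)
    b = len(labels)
    loo = np.zeros_like(ks)
    for i in range(b):
        loo += np.prod(np.delete(z, i, axis=1), axis=1)
    conf = 1.0 - np.minimum(2.0 ** (b - 1) / b * loo, 1.0)
    ok = np.nonzero(conf <= limit)[0]
    return float(ks[ok[0]]) if ok.size else 0.0


class TestDecomposeScores:
    def test_arithmetic(self, four_batch_design):
        bm, r = decompose_scores(np.array([-3.0, -1.0, 1.0, 3.0]), four_batch_design)
        assert bm == {"1": -2.0, "2": 2.0}
        assert [r[s] for s in four_batch_design.sample_ids] == [-1.0, 1.0, -1.0, 1.0]

    def test_zero_scores(self, four_batch_design):
        bm, r = decompose_scores(np.zeros(4), four_batch_design)
        assert all(v == 0.0 for v in bm.values())
        assert all(v == 0.0 for v in r.values())

    def test_size_weighted_means_vanish_on_centred_scores(self, rng, null_study):
        from harman import decompose

        design = null_study.design
        scores = decompose(null_study.matrix).scores[:, 0]
        bm, _ = decompose_scores(scores, design)
        total = sum(len(design.samples_in_batch(b)) * bm[b] for b in design.batches)
        assert abs(total) < 1e-10

    def test_reassembly_exact(self, rng, four_batch_design):
        scores = rng.normal(size=4)
        bm, r = decompose_scores(scores, four_batch_design)
        rebuilt = [bm[four_batch_design.batch_of[s]] + r[s]
                   for s in four_batch_design.sample_ids]
        np.testing.assert_allclose(rebuilt, scores, rtol=0, atol=1e-12)


class TestCorrectPC:
    @pytest.mark.parametrize(
        "k,expected",
        [
            (0.0, [-1.0, 1.0, -1.0, 1.0]),
            (1.0, [-3.0, -1.0, 1.0, 3.0]),
            (0.5, [-2.0, 0.0, 0.0, 2.0]),
        ],
    )
    def test_shrinkage(self, four_batch_design, k, expected):
        out = correct_pc(np.array([-3.0, -1.0, 1.0, 3.0]), four_batch_design, k)
        np.testing.assert_allclose(out, expected)

    def test_within_batch_differences_exact(self, rng, four_batch_design):
        scores = rng.normal(size=4)
        out = correct_pc(scores, four_batch_design, 0.3)
        assert out[1] - out[0] == pytest.approx(scores[1] - scores[0], abs=0)
        assert out[3] - out[2] == pytest.approx(scores[3] - scores[2], abs=0)

    def test_invalid_k_rejected(self, four_batch_design):
        with pytest.raises(Exception, match="k must lie"):
            correct_pc(np.zeros(4), four_batch_design, 1.5)


class TestFindK:
    def test_zero_batch_means_untouched(self, null_study):
        design = null_study.design
        n = len(design.sample_ids)
        scores = np.tile([-1.0, 1.0], n // 2)  # same pattern in every batch
        bm, _ = decompose_scores(scores, design)
        if all(abs(v) < 1e-12 for v in bm.values()):
            assert find_k(scores, design, 0.5) == 1.0

    def test_confident_pc_shrunk_to_limit(self, batchy_study):
        study, _ = batchy_study
        from harman import decompose

        scores = decompose(study.matrix).scores[:, 0]
        design = study.design
        nulls = {b: null_std(scores, design, BatchComposition.of_batch(design, b))
                 for b in design.batches}
        bm, _ = decompose_scores(scores, design)
        assert _confidence_at(1.0, bm, nulls) > 0.99
        k = find_k(scores, design, 0.95)
        assert 0.0 < k < 1.0
        # recomputed L at the returned k sits at 1 - limit within tolerance
        conf = _confidence_at(k, bm, nulls)
        conf_up = _confidence_at(min(1.0, k + 2e-4), bm, nulls)
        assert conf <= 0.95 <= conf_up + 1e-12

    def test_matches_grid_oracle(self, rng):
        from tests.conftest import random_design

        agree = 0
        for trial in range(100):
            design = random_design(rng, n_treat=2, max_rep=4, n_batch=2)
            scores = rng.normal(size=len(design.sample_ids))
            scores -= scores.mean()
            limit = float(rng.uniform(0.3, 0.99))
            k_bis = find_k(scores, design, limit)
            k_grid = grid_find_k(scores, design, limit)
            assert k_bis == pytest.approx(k_grid, abs=2e-4)
            agree += 1
        assert agree == 100

    def test_k_non_increasing_in_limit(self, batchy_study):
        study, _ = batchy_study
        from harman import decompose

        scores = decompose(study.matrix).scores[:, 0]
        ks = [find_k(scores, study.design, lim) for lim in (0.5, 0.8, 0.95, 0.99)]
        assert all(a <= b + 2e-4 for a, b in zip(ks, ks[1:]))


class TestConfidenceCalibration:
    """How the normalized likelihood behaves on data with no batch effect."""

    @staticmethod
    def _exceedance_rate(batches, treatments, seeds, p=250):
        from harman import SimulationConfig, decompose, generate_study

        hits = total = 0
        for seed in seeds:
            cfg = SimulationConfig(p=p, treatments=treatments, batches=batches,
                                   batch_sd=0.0, seed=seed)
            matrix, design, _ = generate_study(cfg)
            decomp = decompose(matrix)
            comps = {b: BatchComposition.of_batch(design, b)
                     for b in design.batches}
            for j in range(decomp.n_components):
                s = decomp.scores[:, j]
                nulls = {b: null_std(s, design, comps[b]) for b in design.batches}
                bm, _ = decompose_scores(s, design)
                total += 1
                hits += _confidence_at(1.0, bm, nulls) > 0.95
        return hits / total

    def test_two_equal_batches_are_exactly_calibrated(self):
        """For b = 2 equal batches L = z1 + z2 is uniform under the null, so
        the confidence exceeds 0.95 on ~5% of components."""
        treatments = {f"T{a}": 2 for a in range(7)}
        batches = {f"B{j}": {f"T{a}": 1 for a in range(7)} for j in range(2)}
        rate = self._exceedance_rate(batches, treatments, range(40))
        assert 0.01 <= rate <= 0.10, rate

    def test_four_batches_are_anticonservative(self):
        """For b > 2 the likelihood concentrates near zero (E[L] = 2^(1-b)
        under the null), so the 0.95 threshold is crossed far more often
        than 5% — the confidence is a trade-off score, not a p-value."""
        treatments = {f"T{a}": 4 for a in range(7)}
        batches = {f"B{j}": {f"T{a}": 1 for a in range(7)} for j in range(4)}
        rate = self._exceedance_rate(batches, treatments, range(10))
        assert rate > 0.2, rate


class TestHarman:
    def test_null_data_barely_changes(self, null_study):
        res = harman(null_study, limit=0.95)
        raw = null_study.matrix.values
        centred = raw - raw.mean(axis=1, keepdims=True)
        rel = np.linalg.norm(res.corrected_matrix.values - raw) / np.linalg.norm(centred)
        assert rel < 0.10  # a few percent change under the null
        assert res.corrected_matrix.feature_ids == null_study.matrix.feature_ids

    def test_uncorrected_pcs_bit_identical(self, null_study):
        res = harman(null_study, limit=0.95)
        untouched = res.correction_vector == 1.0
        assert untouched.any()
        np.testing.assert_array_equal(
            res.corrected_scores[:, untouched],
            res.decomposition.scores[:, untouched],
        )

    def test_injected_effect_concentrates_correction(self, batchy_study):
        study, _ = batchy_study
        res = harman(study, limit=0.95)
        # leading PCs carry the batch offsets and are corrected
        assert res.correction_vector[0] < 1.0
        assert res.confidence_before[0] > 0.99
        # sparse pattern: plenty of PCs left untouched
        assert np.mean(res.correction_vector == 1.0) > 0.3

    def test_within_batch_geometry_preserved(self, batchy_study):
        study, _ = batchy_study
        res = harman(study, limit=0.5)
        design = study.design
        raw, cor = study.matrix.values, res.corrected_matrix.values
        ids = design.sample_ids
        for b in design.batches:
            idx = [ids.index(s) for s in design.samples_in_batch(b)]
            for i, j in zip(idx, idx[1:]):
                np.testing.assert_allclose(
                    cor[:, i] - cor[:, j], raw[:, i] - raw[:, j], atol=1e-8
                )

    def test_more_conservative_limit_corrects_less(self, batchy_study):
        study, _ = batchy_study
        res_low = harman(study, limit=0.5)
        res_high = harman(study, limit=0.99)
        assert np.all(res_high.correction_vector >= res_low.correction_vector - 2e-4)

    def test_second_pass_changes_less(self, batchy_study):
        study, _ = batchy_study
        first = harman(study, limit=0.95)
        from harman import validate_study

        second = harman(
            validate_study(first.corrected_matrix, study.design), limit=0.95
        )
        d1 = np.linalg.norm(first.corrected_matrix.values - study.matrix.values)
        d2 = np.linalg.norm(second.corrected_matrix.values - first.corrected_matrix.values)
        assert d2 < d1

    def test_report_frame_layout(self, batchy_study):
        study, _ = batchy_study
        res = harman(study, limit=0.95)
        frame = res.report_frame()
        assert list(frame.columns) == ["pc_index", "var_fraction",
                                       "confidence_before", "k"]
        assert len(frame) == res.decomposition.n_components
        assert (frame["k"] * 100 == (frame["k"] * 100).round()).all()
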