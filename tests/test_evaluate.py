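"""Cross-validation statistics, treatment search and accuracy bands."""

import numpy as np
import pandas as pd
import pytest

import faecalnirs as fn
from faecalnirs.evaluate import evaluate, make_cv_splits
from faecalnirs.mpls import MPLS


class TestMakeCvSplits:
    def test_four_groups_of_223_are_balanced(self):
        scheme = fn.CvScheme("random_groups", 4, seed=11)
        splits = make_cv_splits(223, scheme)
        sizes = sorted(len(test) for _, test in splits)
        assert sizes == [55, 56, 56, 56]

    def test_each_sample_held_out_exactly_once(self):
        scheme = fn.CvScheme("random_groups", 4, seed=3)
        splits = make_cv_splits(50, scheme)
        held = np.concatenate([test for _, test in splits])
        assert sorted(held) == list(range(50))
        for train, test in splits:
            assert np.intersect1d(train, test).size == 0

    def test_leave_one_out_definition(self):
        splits = make_cv_splits(10, fn.CvScheme("leave_one_out"))
        assert len(splits) == 10
        assert all(test.size == 1 for _, test in splits)

    def test_same_seed_same_partition(self):
        a = make_cv_splits(40, fn.CvScheme("random_groups", 4, seed=9))
        b = make_cv_splits(40, fn.CvScheme("random_groups", 4, seed=9))
        for (_, ta), (_, tb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            make_cv_splits(3, fn.CvScheme("random_groups", 4))


def _band_problem(rng, n=40, p=30, noise=0.0):
    grid = np.linspace(0, 1, p)
    conc = rng.uniform(1.0, 3.0, n)
    X = np.outer(conc, np.exp(-0.5 * ((grid - 0.5) / 0.1) ** 2))
    return X + noise * rng.standard_normal((n, p)), 2.0 * conc


class TestEvaluate:
    @pytest.mark.parametrize("method", ["random_groups", "leave_one_out"])
    def test_perfect_model_statistics(self, rng, method):
        X, y = _band_problem(rng)
        stats = evaluate(X, y, scheme=fn.CvScheme(method), max_factors=5)
        assert stats.secv <= 1e-6
        assert stats.r2cv >= 1 - 1e-9
        assert stats.n_factors == 1

    def test_pure_noise_gives_nonpositive_r2cv_on_average(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 20))
            y = rng.standard_normal(40)  # independent of X
            stats = evaluate(X, y, scheme=fn.CvScheme("random_groups", 4, seed=seed),
                             max_factors=5)
            vals.append(stats.r2cv)
        assert np.mean(vals) <= 0.0

    def test_rpd_identity_against_printed_statistics(self):
        """SD 16.30 with SECV 5.70 prints RPD 2.86."""
        assert round(16.30 / 5.70, 2) == 2.86

    def test_rpd_secv_sd_identity(self, rng):
        X, y = _band_problem(rng, noise=0.05)
        stats = evaluate(X, y, max_factors=5)
        assert stats.rpd * stats.secv == pytest.approx(stats.sd, rel=1e-12)

    def test_loo_press_matches_brute_force_refits(self, rng):
        """Leave-one-out PRESS equals an explicit n-refit loop (20 x 30)."""
        X, y = _band_problem(rng, n=20, p=30, noise=0.1)
        k = 3
        stats = evaluate(X, y, scheme=fn.CvScheme("leave_one_out"), max_factors=k)
        press = np.zeros(k)
        for i in range(20):
            mask = np.arange(20) != i
            res = MPLS(y[mask], X[mask], n_factors=k).fit()
            for kk in range(1, k + 1):
                press[kk - 1] += (y[i] - res.predict(X[i][None, :], n_factors=kk)[0]) ** 2
        np.testing.assert_allclose(stats.secv_curve, np.sqrt(press / 20), atol=1e-9)

    def test_secv_curve_reproducible(self, rng):
        X, y = _band_problem(rng, noise=0.1)
        scheme = fn.CvScheme("random_groups", 4, seed=5)
        a = evaluate(X, y, scheme=scheme, max_factors=6)
        b = evaluate(X, y, scheme=scheme, max_factors=6)
        np.testing.assert_array_equal(a.secv_curve, b.secv_curve)

    def test_group_cv_approaches_loo_over_seeds(self, rng):
        """Averaged over partitions, 4-group SECV tracks the leave-one-out
        SECV on a well-conditioned problem."""
        X, y = _band_problem(rng, n=60, noise=0.08)
        loo = evaluate(X, y, scheme=fn.CvScheme("leave_one_out"), max_factors=3)
        group = [
            evaluate(X, y, scheme=fn.CvScheme("random_groups", 4, seed=s), max_factors=3).secv
            for s in range(20)
        ]
        assert np.mean(group) == pytest.approx(loo.secv, rel=0.15)

    def test_zero_sst_rejected(self, rng):
        X = rng.standard_normal((20, 10))
        with pytest.raises(ValueError, match="zero-variance"):
            evaluate(X, np.ones(20), max_factors=3)

    def test_fit_cv_method_on_model(self, rng):
        X, y = _band_problem(rng, noise=0.05)
        stats = MPLS(y, X, n_factors=5, constituent="cp").fit_cv(fn.CvScheme("leave_one_out"))
        assert stats.constituent == "cp"
        assert 0 < stats.secv < stats.sd


class TestSearchTreatments:
    def _make_set(self, rng, y_noise=0.0):
        wl = fn.DEFAULT_GRID.wavelengths
        n = 24
        conc = rng.uniform(1, 3, n)
        band = np.exp(-0.5 * ((wl - 1900) / 40) ** 2)
        A = np.outer(conc, band) + 0.003 * rng.standard_normal((n, wl.size)) + 0.2
        meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                             "replicate_id": ["1"] * n})
        refs = pd.Series(2 * conc + y_noise * rng.standard_normal(n),
                         index=[f"s{i}" for i in range(n)])
        return fn.SpectraSet(fn.DEFAULT_GRID, A, meta), refs

    def test_single_code_returned(self, rng):
        sset, refs = self._make_set(rng)
        code = fn.parse_treatment_code("1,5,5,1")
        best, table = fn.search_treatments(sset, refs, [code], max_factors=3)
        assert best.treatment == code
        assert len(table) == 1

    def test_lower_secv_code_wins(self, rng):
        sset, refs = self._make_set(rng, y_noise=0.05)
        codes = [fn.parse_treatment_code(c) for c in ("1,5,5,1", "2,10,5,1")]
        best, table = fn.search_treatments(sset, refs, codes, max_factors=3,
                                           scheme=fn.CvScheme("random_groups", 4, seed=2))
        assert best.secv == table["secv"].min()

    def test_duplicate_codes_tie_break_to_first(self, rng):
        sset, refs = self._make_set(rng)
        code = fn.parse_treatment_code("1,5,5,1")
        best, table = fn.search_treatments(sset, refs, [code, code], max_factors=3)
        assert len(table) == 2
        assert best is not None and best.treatment == code


class TestClassifyAccuracy:
    @pytest.mark.parametrize(
        "r2cv, rpd, band, discordant",
        [
            (0.95, 4.45, "excellent", False),
            (0.75, 2.21, "good", False),
            (0.60, 1.7, "moderate", False),
            (0.30, 1.2, "poor", False),
            (0.95, 1.6, "moderate", True),   # weaker criterion rules
            (0.55, 3.5, "moderate", True),
            (float("nan"), 2.0, "unclassified", False),
            (0.8, -1.0, "unclassified", False),
        ],
    )
    def test_bands(self, r2cv, rpd, band, discordant):
        result = fn.classify_accuracy(r2cv, rpd)
        assert result.band == band
        assert result.discordant is discordant
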