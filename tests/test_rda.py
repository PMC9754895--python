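"""RDA ordination, predictor filtering, LD pruning and Mantel tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from divland import SimulationConfig, simulate
from divland.rda import (
    filter_predictors,
    ld_prune,
    fit_rda,
    test_axes as run_axis_tests,
    assign_predictors,
    call_outlier_variants,
    haversine_km,
    mantel_test,
    pairwise_population_fst,
    mantel_ibd_ibe,
)

from conftest import toy_table


class TestFilterPredictors:
    def _env(self, cols):
        return pd.DataFrame(cols)

    def test_strongly_correlated_pair_one_survives(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        env = self._env({"a": x, "b": 0.98 * x + 0.05 * rng.normal(size=100),
                         "c": rng.normal(size=100)})
        kept = filter_predictors(env, threshold=0.7)
        assert ("a" in kept.columns) != ("b" in kept.columns)
        assert "c" in kept.columns

    def test_uncorrelated_table_unchanged(self):
        rng = np.random.default_rng(1)
        env = self._env({c: rng.normal(size=200) for c in "abcd"})
        kept = filter_predictors(env, threshold=0.7)
        assert list(kept.columns) == list("abcd")

    def test_correlated_star_matches_minimal_removal_oracle(self):
        """Hub predictor correlated with two others: dropping the hub is
        the unique minimal solution; the greedy finds it."""
        rng = np.random.default_rng(2)
        b = rng.normal(size=500)
        # spokes modestly correlated (r ~ 0.4) so the hub can clear 0.7 to both
        c = 0.4 * b + np.sqrt(1 - 0.16) * rng.normal(size=500)
        hub = (b + c) / np.sqrt(2.8) + 0.1 * rng.normal(size=500)
        env = self._env({"b": b, "c": c, "hub": hub,
                         "d": rng.normal(size=500)})
        corr = env.corr().abs()
        assert corr.loc["hub", "b"] >= 0.7 and corr.loc["hub", "c"] >= 0.7
        assert corr.loc["b", "c"] < 0.7

        # brute-force oracle: largest subset with all pairwise |r| < 0.7
        best = max(
            (s for k in range(len(env.columns), 0, -1)
             for s in itertools.combinations(env.columns, k)
             if (corr.loc[list(s), list(s)].to_numpy()
                 [~np.eye(len(s), dtype=bool)] < 0.7).all()),
            key=len,
        )
        kept = filter_predictors(env, threshold=0.7)
        assert set(kept.columns) == set(best) == {"b", "c", "d"}

    def test_constant_predictor_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        env = self._env({"a": rng.normal(size=50), "k": np.ones(50)})
        with pytest.warns(UserWarning, match="constant"):
            kept = filter_predictors(env)
        assert list(kept.columns) == ["a"]


class TestLdPrune:
    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 20).astype(float)
        other = rng.integers(0, 3, 20).astype(float)
        gt = toy_table(np.vstack([col, col, other]), pos=[100, 1100, 1200])
        kept = ld_prune(gt, r2_threshold=0.4)
        assert 0 in kept and 1 not in kept

    def test_orthogonal_snps_kept(self):
        a = np.array([0, 0, 1, 1, 2, 2, 0, 1] * 2, dtype=float)
        b = np.array([0, 2, 1, 0, 2, 0, 1, 1] * 2, dtype=float)
        assert abs(np.corrcoef(a, b)[0, 1]) ** 2 < 0.4
        gt = toy_table(np.vstack([a, b]), pos=[100, 200])
        kept = ld_prune(gt)
        assert list(kept) == [0, 1]

    def test_matches_hand_greedy_on_toy_window(self):
        """Six SNPs in one window: compare with an explicitly coded
        pairwise greedy (remove later member, rescan)."""
        rng = np.random.default_rng(5)
        base = rng.integers(0, 3, 30).astype(float)
        snps = [base]
        for k in range(5):
            x = base.copy() if k % 2 == 0 else rng.integers(0, 3, 30).astype(float)
            flip = rng.random(30) < 0.15
            x[flip] = rng.integers(0, 3, flip.sum())
            snps.append(x)
        X = np.vstack(snps)
        gt = toy_table(X, pos=[100, 200, 300, 400, 500, 600])

        removed = set()
        for j in range(6):
            for i in range(j):
                if i in removed or j in removed:
                    continue
                xi, xj = X[i], X[j]
                if xi.std() == 0 or xj.std() == 0:
                    continue
                if np.corrcoef(xi, xj)[0, 1] ** 2 > 0.4:
                    removed.add(j)
                    break
        kept = ld_prune(gt, r2_threshold=0.4, window_bp=20_000, step_markers=2)
        assert set(kept) == set(range(6)) - removed

    def test_snps_beyond_window_not_compared(self):
        rng = np.random.default_rng(6)
        col = rng.integers(0, 3, 20).astype(float)
        gt = toy_table(np.vstack([col, col]), pos=[100, 50_000])
        kept = ld_prune(gt, window_bp=20_000)
        assert list(kept) == [0, 1]


def rda_oracle(Y, X):
    """Normal equations + eigendecomposition, coded independently."""
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Yc = Y - Y.mean(0)
    B = np.linalg.inv(Xs.T @ Xs) @ Xs.T @ Yc
    F = Xs @ B
    eig = np.sort(np.linalg.eigvalsh(F.T @ F))[::-1] / (len(Y) - 1)
    total = (Yc**2).sum() / (len(Y) - 1)
    return eig[: X.shape[1]], total


class TestFitRda:
    def test_noise_free_rank_one_fully_explained(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        env = pd.DataFrame({"ap": x, "o": rng.normal(size=30)})
        Y = np.outer(x, rng.normal(size=50))
        res = fit_rda(Y, env)
        assert res.proportion_explained == pytest.approx(1.0, abs=1e-10)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_env_explains_nothing(self):
        n = 40
        x = np.concatenate([np.ones(20), -np.ones(20)])
        env = pd.DataFrame({"x": x})
        rng = np.random.default_rng(1)
        y0 = rng.normal(size=n)
        y0 -= y0.mean()
        y0 -= x * (y0 @ x) / (x @ x)  # project out the predictor
        res = fit_rda(y0[:, None], env)
        assert res.proportion_explained == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(6, 4))
        X = rng.normal(size=(6, 2))
        res = fit_rda(Y, pd.DataFrame(X, columns=["a", "b"]))
        eig, total = rda_oracle(Y, X)
        assert np.allclose(res.eigenvalues, eig, atol=1e-10)
        assert res.total_variance == pytest.approx(total)

    def test_eigenvalues_non_increasing_and_proportions_bounded(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(25, 60))
        X = rng.normal(size=(25, 4))
        res = fit_rda(Y, pd.DataFrame(X, columns=list("abcd")))
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert 0 <= res.proportion_explained <= 1

    def test_scale_and_rotation_invariance(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(30, 40))
        X = rng.normal(size=(30, 3))
        env = pd.DataFrame(X, columns=list("abc"))
        base = fit_rda(Y, env).proportion_explained
        assert fit_rda(5.0 * Y, env).proportion_explained == pytest.approx(base)
        # rotate the standardized predictors: same column space
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        rot = pd.DataFrame(Xs @ Q, columns=list("abc"))
        assert fit_rda(Y, rot).proportion_explained == pytest.approx(base)

    def test_rank_deficient_env_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        env = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            fit_rda(rng.normal(size=(20, 5)), env)

    def test_vegan_cross_check(self, tmp_path):
        """Eigenvalues and proportion explained agree with vegan::rda."""
        import json
        import subprocess

        rng = np.random.default_rng(6)
        Y = rng.normal(size=(12, 6))
        X = rng.normal(size=(12, 2))
        np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        script = tmp_path / "rda.R"
        script.write_text(
            'suppressMessages(library(vegan))\n'
            f'Y <- as.matrix(read.csv("{tmp_path}/Y.csv", header=FALSE))\n'
            f'X <- scale(as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE)))\n'
            'fit <- rda(Y ~ X)\n'
            'cat(jsonlite::toJSON(list(eig=unname(fit$CCA$eig),\n'
            '  prop=fit$CCA$tot.chi/fit$tot.chi), digits=12))\n'
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        res = fit_rda(Y, pd.DataFrame(X, columns=["a", "b"]))
        assert np.allclose(res.eigenvalues, ref["eig"], rtol=1e-8)
        assert res.proportion_explained == pytest.approx(ref["prop"][0], rel=1e-8)


class TestTestAxes:
    def test_planted_signal_hits_p_floor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        env = pd.DataFrame({"ap": x, "o": rng.normal(size=30)})
        Y = np.outer(x, rng.normal(size=40)) + 0.01 * rng.normal(size=(30, 40))
        rda, p = run_axis_tests(Y, env, n_perm=199, seed=1)
        assert p[0] == pytest.approx(1 / 200)

    def test_sequential_stop_leaves_later_axes_untested(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(25, 30))
        env = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        rda, p = run_axis_tests(Y, env, n_perm=99, alpha=0.01, seed=2)
        first_ns = next(i for i, v in enumerate(p) if not np.isnan(v) and v >= 0.01)
        assert np.isnan(p[first_ns + 1:]).all()

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(2)
        env = pd.DataFrame(rng.normal(size=(4, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            run_axis_tests(rng.normal(size=(4, 5)), env, n_perm=9, seed=0)

    def test_null_distribution_stable_across_seeds(self):
        from scipy import stats as sstats

        rng = np.random.default_rng(3)
        Y = rng.normal(size=(20, 25))
        env = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])

        def null_eigs(seed):
            r = np.random.default_rng(seed)
            X = (env - env.mean()) / env.std(ddof=1)
            out = []
            for _ in range(300):
                perm = r.permutation(20)
                Q, _ = np.linalg.qr(X.to_numpy()[perm])
                Yc = Y - Y.mean(0)
                s = np.linalg.svd(Q.T @ Yc, compute_uv=False)
                out.append(s[0] ** 2 / 19)
            return np.array(out)

        ks = sstats.ks_2samp(null_eigs(11), null_eigs(22))
        assert ks.pvalue > 0.01


class TestOutlierVariants:
    def _fitted(self, seed=0, n=60, m=400):
        rng = np.random.default_rng(seed)
        x = np.concatenate([np.ones(n // 2), -np.ones(n - n // 2)])
        x = x + 0.3 * rng.normal(size=n)
        env = pd.DataFrame({"ap": x, "o": rng.normal(size=n)})
        Y = 0.1 * rng.normal(size=(n, m))
        Y[:, :5] += np.outer(x, np.ones(5))  # five env-driven variants
        rda, p = run_axis_tests(Y, env, n_perm=199, seed=seed)
        return rda, Y, env

    def test_planted_variants_are_outliers_assigned_to_driver(self):
        rda, Y, env = self._fitted()
        out = call_outlier_variants(rda, Y, env)
        assert set(range(5)) <= set(out["variant_index"])
        planted = out[out["variant_index"] < 5]
        assert (planted["predictor"] == "ap").all()
        assert planted["strong"].all()

    def test_strict_three_sd_boundary(self):
        from scipy.optimize import brentq

        base = np.concatenate([np.full(50, -1.0), np.full(50, 1.0)])

        def z_of(a):
            v = np.append(base, a)
            return (a - v.mean()) / v.std()

        a3 = brentq(lambda a: z_of(a) - 3.0, 1.0, 50.0)
        loadings = np.append(base, a3)[:, None]
        rda_stub = type("R", (), {})()
        from divland.rda import RdaResult

        rda = RdaResult(
            eigenvalues=np.array([1.0]), proportion=np.array([0.5]),
            variant_scores=loadings, sample_scores=np.zeros((2, 1)),
            total_variance=2.0, predictors=["ap"],
            axis_p=np.array([0.001]),
        )
        resp = np.random.default_rng(0).normal(size=(10, 101))
        env = pd.DataFrame({"ap": np.random.default_rng(1).normal(size=10)})
        at3 = call_outlier_variants(rda, resp, env, sd_mult=3.0)
        assert 100 not in set(at3["variant_index"])  # z == 3 exactly: strict >
        below = call_outlier_variants(rda, resp, env, sd_mult=2.999)
        assert 100 in set(below["variant_index"])

    def test_sign_flip_invariance(self):
        rda, Y, env = self._fitted(seed=3)
        out1 = call_outlier_variants(rda, Y, env)
        rda.variant_scores = -rda.variant_scores
        out2 = call_outlier_variants(rda, Y, env)
        assert list(out1["variant_index"]) == list(out2["variant_index"])

    def test_assign_predictors_recovers_noisy_copy(self):
        rng = np.random.default_rng(4)
        ap = rng.normal(size=80)
        env = pd.DataFrame({"ap": ap, "o1": rng.normal(size=80),
                            "o2": rng.normal(size=80)})
        y = 0.8 * (ap - ap.mean()) / ap.std() + 0.6 * rng.normal(size=80)
        out = assign_predictors(y[:, None], env)
        assert out.loc[0, "predictor"] == "ap"


class TestMantel:
    def test_haversine_closed_forms(self):
        assert haversine_km(10.0, 20.0, 10.0, 20.0) == 0.0
        assert haversine_km(0.0, 0.0, 90.0, 0.0) == pytest.approx(
            6371.0 * np.pi / 2.0, abs=1e-6
        )

    def test_identical_matrices_exact_enumeration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(4, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        r, p = mantel_test(D, D, exact=True)
        assert r == pytest.approx(1.0)

        # independent enumeration oracle
        il = np.tril_indices(4, -1)
        x = D[il]
        hits = 0
        for perm in itertools.permutations(range(4)):
            y = D[np.ix_(perm, perm)][il]
            hits += np.corrcoef(x, y)[0, 1] >= 1.0 - 1e-12
        assert p == pytest.approx(hits / 24.0)

    def test_exact_equals_enumeration_for_five_units(self):
        rng = np.random.default_rng(1)
        A = rng.random((5, 5)); A = (A + A.T) / 2; np.fill_diagonal(A, 0)
        B = rng.random((5, 5)); B = (B + B.T) / 2; np.fill_diagonal(B, 0)
        r, p = mantel_test(A, B, exact=True)
        il = np.tril_indices(5, -1)
        x = A[il]
        rs = []
        for perm in itertools.permutations(range(5)):
            y = B[np.ix_(perm, perm)][il]
            rs.append(np.corrcoef(x, y)[0, 1])
        assert r == pytest.approx(rs[0])
        assert p == pytest.approx(np.mean(np.array(rs) >= r - 1e-12))

    def test_permutation_p_for_larger_matrices(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        noisy = D + 0.1 * rng.random((8, 8))
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        r, p = mantel_test(D, noisy, n_perm=499, seed=3, exact=False)
        assert r > 0.9 and p <= 0.01


class TestPopulationFst:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.4, size=(300, 12)).astype(float)
        pops = np.repeat(["p1", "p2", "p3"], 4)
        gt = toy_table(dos, species=["X"] * 6 + ["Y"] * 6, populations=pops)
        fst = pairwise_population_fst(gt)
        assert abs(fst.loc["p1", "p2"]) < 0.05
        assert np.allclose(fst, fst.T)

    def test_mantel_ibd_pipeline_on_separated_populations(self):
        rng = np.random.default_rng(1)
        # four populations on a line; frequency cline -> IBD
        freqs = [0.1, 0.3, 0.6, 0.9]
        dos = np.hstack(
            [rng.binomial(2, f, size=(400, 4)).astype(float) for f in freqs]
        )
        pops = np.repeat([f"p{i}" for i in range(4)], 4)
        gt = toy_table(dos, species=["X"] * 8 + ["Y"] * 8, populations=pops)
        fst = pairwise_population_fst(gt)
        coords = pd.DataFrame(
            {"lat": [0.0, 1.0, 2.0, 3.0], "lon": [0.0] * 4},
            index=[f"p{i}" for i in range(4)],
        )
        env = pd.DataFrame(
            {"ap": [0.0, 1.0, 2.0, 3.0]}, index=[f"p{i}" for i in range(4)]
        )
        out = mantel_ibd_ibe(fst, coords, env, n_perm=200, seed=2)
        assert out["r_geo"] > 0.8
        assert out["p_geo"] <= 0.2  # only 24 distinct permutations at n=4
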