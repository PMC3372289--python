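"""RDA against brute-force least squares, permutation tests, forward/backward
selection and variation partitioning (including an R/vegan cross-check)."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from tfstability import ordination as o


def brute_force_fit(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Normal-equations projection of centered Y onto centered X."""
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    return Xc @ np.linalg.solve(Xc.T @ Xc, Xc.T @ Yc)


def random_case(rng, n=None, p=None, q=None):
    n = n or int(rng.integers(6, 9))
    p = p or int(rng.integers(2, 6))
    q = q or int(rng.integers(1, min(3, n - 2)))
    Y = pd.DataFrame(rng.normal(size=(n, p)))
    X = pd.DataFrame(rng.normal(size=(n, q)), columns=[f"x{i}" for i in range(q)])
    return Y, X


class TestRDAFit:
    def test_matches_bruteforce_projection_on_random_cases(self, rng):
        for _ in range(25):
            Y, X = random_case(rng)
            model = o.rda_fit(Y, X)
            np.testing.assert_allclose(
                model.fitted.to_numpy(),
                brute_force_fit(Y.to_numpy(), X.to_numpy()),
                atol=1e-9,
            )
            assert 0.0 <= model.r_squared <= 1.0
            assert model.adj_r_squared <= model.r_squared + 1e-12

    def test_orthogonal_predictor_explains_nothing(self, rng):
        Y, _ = random_case(rng, n=20, p=3, q=1)
        Yc = Y - Y.mean(axis=0)
        x = rng.normal(size=20)
        x -= x.mean()
        # orthogonalize x against every response column
        q_y, _ = np.linalg.qr(Yc.to_numpy())
        x -= q_y @ (q_y.T @ x)
        model = o.rda_fit(Y, pd.DataFrame({"x": x}))
        assert model.r_squared == pytest.approx(0.0, abs=1e-9)

    def test_univariate_r2_equals_squared_pearson(self, rng):
        x = rng.normal(size=30)
        y = 2.0 * x + rng.normal(size=30)
        model = o.rda_fit(pd.DataFrame({"y": y}), pd.DataFrame({"x": x}))
        assert model.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_canonical_eigenvalue_sum_identity(self, rng):
        for _ in range(5):
            Y, X = random_case(rng)
            m = o.rda_fit(Y, X)
            ss_fit = float((m.fitted.to_numpy() ** 2).sum())
            assert m.eigenvalues.sum() == pytest.approx(ss_fit / (m.n - 1), rel=1e-9)

    def test_rank_deficient_and_undersized_inputs_rejected(self, rng):
        Y, X = random_case(rng, n=8, p=2, q=2)
        X["dup"] = X.iloc[:, 0] * 2.0
        with pytest.raises(ValueError, match="rank-deficient"):
            o.rda_fit(Y, X)
        with pytest.raises(ValueError, match="n > m"):
            o.rda_fit(Y.iloc[:3], X.iloc[:3])
        Y2 = Y.copy()
        Y2.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            o.rda_fit(Y2, X[["x0", "x1"]])

    def test_scores_shapes_and_scalings(self, rng):
        Y, X = random_case(rng, n=10, p=4, q=2)
        m = o.rda_fit(Y, X)
        site1, spec1 = m.scores(scaling=1)
        site2, spec2 = m.scores(scaling=2)
        assert site1.shape == (10, 2) and spec2.shape == (4, 2)
        # scaling 1 scales sites, scaling 2 scales species, by the same factors
        np.testing.assert_allclose(
            np.abs(site1.to_numpy() * spec1.to_numpy()[0, :]).sum(),
            np.abs(site2.to_numpy() * spec2.to_numpy()[0, :]).sum(),
            rtol=1e-6,
        )


class TestPermutation:
    def test_p_value_bounds_and_determinism(self, rng):
        Y, X = random_case(rng, n=15, p=3, q=2)
        m = o.rda_fit(Y, X)
        p1 = o.permutation_test(m, n_perm=99, seed=5)
        p2 = o.permutation_test(m, n_perm=99, seed=5)
        assert p1 == p2
        assert 1 / 100 <= p1 <= 1.0

    def test_invariant_to_response_scaling(self, rng):
        Y, X = random_case(rng, n=15, p=3, q=2)
        p1 = o.permutation_test(o.rda_fit(Y, X), n_perm=99, seed=7)
        p2 = o.permutation_test(o.rda_fit(Y * 37.5, X), n_perm=99, seed=7)
        assert p1 == p2

    def test_planted_strong_effect_reaches_minimum_p(self, rng):
        n = 44
        x = rng.normal(size=n)
        Y = pd.DataFrame(rng.normal(size=(n, 10), scale=1.0))
        Y = Y.add(x, axis=0)  # strong shared predictor signal
        m = o.rda_fit(Y, pd.DataFrame({"x": x}))
        p = o.permutation_test(m, n_perm=199, seed=0)
        assert p == pytest.approx(1.0 / 200.0)

    def test_partial_test_detects_conditional_effect(self, rng):
        n = 40
        z = rng.normal(size=n)
        x = rng.normal(size=n)
        Y = pd.DataFrame({"a": 2 * z + x + 0.3 * rng.normal(size=n), "b": z + 0.5 * x})
        f, p = o.partial_permutation_test(Y, pd.DataFrame({"x": x}), pd.DataFrame({"z": z}),
                                          n_perm=199, seed=1)
        assert p <= 0.01
        junk = rng.normal(size=n)
        _, p_null = o.partial_permutation_test(Y, pd.DataFrame({"j": junk}),
                                               pd.DataFrame({"z": z, "x": x}),
                                               n_perm=199, seed=2)
        assert p_null > 0.05


class TestSelectModel:
    def test_planted_predictor_found_among_decoys(self, rng):
        n = 44
        X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"c{i}" for i in range(10)])
        signal = X["c4"].to_numpy()
        Y = pd.DataFrame(
            signal[:, None] * rng.uniform(0.8, 1.2, size=8)[None, :]
            + rng.normal(size=(n, 8))
        )
        selected, trace = o.select_model(Y, X, n_perm=199, seed=0)
        assert selected == ["c4"]
        assert trace.steps[0]["action"] == "add"

    def test_pure_noise_rarely_selects_anything(self, rng):
        """Under the null the forward entry test at alpha = 0.05 plus the
        adjusted-R^2 scope guard leaves the model empty in the large
        majority of datasets (the exact rate depends on the stopping rule)."""
        X = pd.DataFrame(rng.normal(size=(30, 8)), columns=[f"c{i}" for i in range(8)])
        empty = 0
        n_sets = 25
        for i in range(n_sets):
            Y = pd.DataFrame(rng.normal(size=(30, 6)))
            sel, _ = o.select_model(Y, X, n_perm=99, seed=i)
            empty += not sel
        assert empty / n_sets >= 0.75

    def test_needs_candidates(self, rng):
        Y, _ = random_case(rng, n=10, p=2, q=1)
        with pytest.raises(ValueError):
            o.select_model(Y, pd.DataFrame(index=Y.index), seed=0)


class TestVariationPartition:
    def test_adjusted_fraction_identity_holds_exactly(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 16))
            Y = pd.DataFrame(rng.normal(size=(n, 4)))
            A = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a1", "a2"])
            B = pd.DataFrame(rng.normal(size=(n, 2)), columns=["b1", "b2"])
            part = o.variation_partition(Y, A, B, n_perm=0)
            total = part.env_only + part.shared + part.space_only + part.residual
            assert total == pytest.approx(1.0, abs=1e-9)
            combined = o.rda_fit(Y, pd.concat([A, B], axis=1)).adj_r_squared
            assert part.env_only + part.shared + part.space_only == pytest.approx(
                combined, abs=1e-9
            )

    def test_empty_space_set_degenerates_to_single_model(self, rng):
        n = 12
        Y = pd.DataFrame(rng.normal(size=(n, 3)))
        A = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a1", "a2"])
        part = o.variation_partition(Y, A, pd.DataFrame(index=Y.index), n_perm=0)
        assert part.env_only == pytest.approx(o.rda_fit(Y, A).adj_r_squared, abs=1e-12)
        assert part.shared == 0.0 and part.space_only == 0.0

    def test_orthogonal_sets_share_nothing(self, rng):
        """With strictly orthogonal predictor sets the shared fraction
        averages ~0 at moderate effect sizes (the small-sample ratio bias
        of adjusted R^2 grows with the explained fraction, so the check is
        run at a study-like total R^2 of ~0.4)."""
        shared = []
        for i in range(20):
            n = 44
            A = rng.normal(size=(n, 2))
            B = rng.normal(size=(n, 1))
            A -= A.mean(axis=0)
            B -= B.mean(axis=0)
            B -= A @ np.linalg.lstsq(A, B, rcond=None)[0]  # B strictly orthogonal to A
            Y = pd.DataFrame(
                0.5 * (A @ rng.normal(size=(2, 5)) + B @ rng.normal(size=(1, 5)))
                + 1.2 * rng.normal(size=(n, 5))
            )
            part = o.variation_partition(
                Y, pd.DataFrame(A, columns=["a1", "a2"]), pd.DataFrame(B, columns=["b1"]),
                n_perm=0,
            )
            shared.append(part.shared)
        assert abs(np.mean(shared)) < 0.02

    def test_overlapping_sets_rejected(self, rng):
        Y = pd.DataFrame(rng.normal(size=(10, 2)))
        A = pd.DataFrame(rng.normal(size=(10, 1)), columns=["t"])
        with pytest.raises(ValueError, match="share"):
            o.variation_partition(Y, A, A.copy(), n_perm=0)

    def test_conditioned_partition_identity_includes_covariable_share(self, rng):
        n = 25
        Y = pd.DataFrame(rng.normal(size=(n, 4)))
        A = pd.DataFrame(rng.normal(size=(n, 1)), columns=["a"])
        B = pd.DataFrame(rng.normal(size=(n, 1)), columns=["b"])
        C = pd.DataFrame(rng.normal(size=(n, 1)), columns=["c"])
        part = o.variation_partition(Y, A, B, n_perm=0, condition=C)
        total = part.env_only + part.shared + part.space_only + part.residual + part.conditioned
        assert total == pytest.approx(1.0, abs=1e-9)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestVeganCrossCheck:
    def test_fractions_match_vegan_varpart(self, rng, tmp_path):
        n = 12
        Y = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        A = pd.DataFrame(rng.normal(size=(n, 2)), columns=["e1", "e2"])
        B = pd.DataFrame(rng.normal(size=(n, 1)), columns=["s1"])
        Y["a"] += 1.5 * A["e1"]
        Y["b"] += B["s1"]
        for name, df in (("Y", Y), ("A", A), ("B", B)):
            df.to_csv(tmp_path / f"{name}.csv", index=False)
        script = f"""
        suppressMessages(library(vegan))
        Y <- read.csv("{tmp_path}/Y.csv"); A <- read.csv("{tmp_path}/A.csv"); B <- read.csv("{tmp_path}/B.csv")
        m <- rda(Y ~ e1 + e2 + s1, data = cbind(A, B))
        v <- varpart(Y, A, B)$part$indfract$Adj.R.squared
        cat(RsquareAdj(m)$r.squared, RsquareAdj(m)$adj.r.squared, v, sep = "\\n")
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout.split()
        r2_ref, adj_ref, a_ref, c_ref, b_ref, d_ref = map(float, out)
        model = o.rda_fit(Y, pd.concat([A, B], axis=1))
        part = o.variation_partition(Y, A, B, n_perm=0)
        assert model.r_squared == pytest.approx(r2_ref, abs=1e-6)
        assert model.adj_r_squared == pytest.approx(adj_ref, abs=1e-6)
        assert part.env_only == pytest.approx(a_ref, abs=1e-6)
        assert part.space_only == pytest.approx(c_ref, abs=1e-6)
        assert part.shared == pytest.approx(b_ref, abs=1e-6)
        assert part.residual == pytest.approx(d_ref, abs=1e-6)
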