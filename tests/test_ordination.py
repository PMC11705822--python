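import re
import subprocess

import numpy as np
import pandas as pd
import pytest

from ciliateco.core import AbundanceTable
from ciliateco.ordination import (
    build_predictor_sets,
    cca,
    ezekiel_adjusted,
    forward_select,
    haversine_matrix,
    hellinger,
    pcnm,
    rda,
    varpart,
)


def _counts(n, p, seed, scale=20):
    rng = np.random.default_rng(seed)
    data = rng.poisson(rng.uniform(1, scale, size=p), size=(n, p)).astype(float) + 1.0
    return AbundanceTable(pd.DataFrame(
        data, index=[f"s{i}" for i in range(n)],
        columns=[f"t{j}" for j in range(p)]))


def _predictors(n, m, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, m)),
                        index=[f"s{i}" for i in range(n)],
                        columns=[f"x{j}" for j in range(m)])


class TestRDA:
    def test_exact_linear_response_r2_one(self):
        rng = np.random.default_rng(0)
        X = _predictors(15, 2, 1)
        B = rng.normal(size=(2, 4))
        Y = pd.DataFrame(X.to_numpy() @ B, index=X.index,
                         columns=[f"t{j}" for j in range(4)])
        fit = rda(Y, X)
        assert fit.constrained_r2 == pytest.approx(1.0)
        assert fit.rank == 2

    def test_unconstrained_is_pca(self):
        Y = _counts(12, 5, 2)
        fit = rda(Y)
        assert fit.constrained_r2 == 0.0
        Yc = Y.values - Y.values.mean(axis=0)
        expected = np.sort(np.linalg.svd(Yc, compute_uv=False) ** 2 / 11)[::-1]
        np.testing.assert_allclose(fit.eigenvalues, expected[:len(fit.eigenvalues)],
                                   rtol=1e-9)
        # PCA eigenvalues sum to the total variance
        assert fit.eigenvalues.sum() == pytest.approx((Yc ** 2).sum() / 11)

    def test_collinear_column_dropped(self):
        X = _predictors(15, 2, 3)
        X["x_dup"] = 2.0 * X["x0"] - X["x1"]
        Y = _counts(15, 4, 4)
        fit = rda(Y, X)
        assert len(fit.dropped_columns) == 1
        assert fit.rank == 2
        # the span is unchanged, so R2 equals the two-predictor fit
        assert fit.constrained_r2 == pytest.approx(
            rda(Y, X[["x0", "x1"]]).constrained_r2)

    def test_adjusted_matches_ezekiel(self):
        Y, X = _counts(25, 6, 5), _predictors(25, 3, 6)
        fit = rda(Y, X, transform="hellinger")
        assert fit.adjusted_r2 == pytest.approx(
            ezekiel_adjusted(fit.constrained_r2, 25, 3))

    def test_noise_predictors_adjusted_near_zero(self):
        # E[adjusted R2] = 0 under independence: average over replicates
        vals = [rda(_counts(30, 8, 10 + s), _predictors(30, 3, 50 + s)).adjusted_r2
                for s in range(40)]
        assert abs(np.mean(vals)) < 0.03

    def test_hellinger_rows(self):
        t = AbundanceTable(pd.DataFrame([[1.0, 3.0], [2.0, 2.0]],
                                        index=["a", "b"], columns=["x", "y"]))
        h = hellinger(t)
        np.testing.assert_allclose(h.loc["a"], [0.5, np.sqrt(0.75)])
        np.testing.assert_allclose((h ** 2).sum(axis=1), 1.0)


class TestCCA:
    def test_total_inertia_is_chi_square_statistic(self):
        Y = _counts(10, 5, 7)
        A = Y.values
        P = A / A.sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        expected = ((P - np.outer(r, c)) ** 2 / np.outer(r, c)).sum()
        fit = cca(Y)
        assert fit.total_inertia == pytest.approx(expected, rel=1e-12)

    def test_two_group_profiles_fully_constrained(self):
        # identical rows within each of two groups: a group indicator
        # explains the full inertia
        row1 = [5.0, 1.0, 2.0, 1.0]
        row2 = [1.0, 4.0, 1.0, 3.0]
        Y = AbundanceTable(pd.DataFrame(
            [row1] * 4 + [row2] * 4, index=[f"s{i}" for i in range(8)],
            columns=list("abcd")))
        X = pd.DataFrame({"grp": [0.0] * 4 + [1.0] * 4}, index=Y.samples)
        fit = cca(Y, X, n_perm=49, seed=0)
        assert fit.constrained_r2 == pytest.approx(1.0)

    def test_noise_predictors_adjusted_near_zero(self):
        vals = [cca(_counts(30, 8, 20 + s), _predictors(30, 3, 80 + s),
                    n_perm=199, seed=s).adjusted_r2 for s in range(12)]
        assert abs(np.mean(vals)) < 0.05

    def test_zero_margin_guards(self):
        df = pd.DataFrame([[1.0, 0.0], [2.0, 0.0]], index=["a", "b"],
                          columns=["x", "y"])
        with pytest.raises(ValueError, match="column sums"):
            cca(AbundanceTable(df))


class TestPCNM:
    def _transect(self, n=10):
        lon = np.linspace(113.0, 113.0 + 0.2 * (n - 1), n)
        lat = np.full(n, 20.0)
        return pd.DataFrame({"longitude": lon, "latitude": lat},
                            index=[f"s{i}" for i in range(n)])

    def test_axes_orthonormal(self):
        sp = pcnm(self._transect())
        V = sp.scores.to_numpy()
        gram = V.T @ V
        np.testing.assert_allclose(gram, np.eye(V.shape[1]), atol=1e-8)

    def test_transect_axes_are_wavelike(self):
        # along an equidistant transect, axis k oscillates with k sign
        # changes (coarse -> fine spatial scales)
        sp = pcnm(self._transect(10))
        for k in range(min(4, sp.n_axes)):
            v = sp.scores.iloc[:, k].to_numpy()
            changes = int((np.diff(np.sign(v)) != 0).sum())
            assert changes == k + 1

    def test_matches_direct_eigendecomposition(self):
        coords = self._transect(8)
        sp = pcnm(coords)
        d = haversine_matrix(coords["longitude"].to_numpy(),
                             coords["latitude"].to_numpy())
        from ciliateco.ordination import _mst_max_edge
        t = _mst_max_edge(d)
        dt = np.where(d > t, 4 * t, d)
        np.fill_diagonal(dt, 0.0)
        a = -0.5 * dt ** 2
        a = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
        ev = np.sort(np.linalg.eigvalsh(a))[::-1]
        np.testing.assert_allclose(sp.eigenvalues, ev[:sp.n_axes], rtol=1e-9)
        assert sp.truncation == pytest.approx(t)

    def test_leading_axis_separates_two_clusters(self):
        lon = np.r_[np.full(5, 113.0) + np.arange(5) * 0.01,
                    np.full(5, 118.0) + np.arange(5) * 0.01]
        lat = np.full(10, 20.0)
        sp = pcnm(pd.DataFrame({"longitude": lon, "latitude": lat}))
        v = sp.scores.iloc[:, 0].to_numpy()
        assert len(set(np.sign(v[:5]))) == 1
        assert len(set(np.sign(v[5:]))) == 1
        assert np.sign(v[0]) != np.sign(v[-1])

    def test_repeated_visits_share_station_scores(self):
        # two samples at the same station (e.g. seasons) get equal scores
        coords = pd.concat([self._transect(6)] * 2)
        coords.index = [f"s{i}" for i in range(12)]
        sp = pcnm(coords)
        np.testing.assert_allclose(sp.scores.iloc[:6].to_numpy(),
                                   sp.scores.iloc[6:].to_numpy(), atol=1e-9)

    def test_single_site_yields_no_axes(self):
        coords = pd.DataFrame({"longitude": [113.0] * 4, "latitude": [20.0] * 4})
        sp = pcnm(coords)
        assert sp.n_axes == 0


class TestForwardSelect:
    def test_alpha_one_no_cap_selects_everything_greedily(self):
        rng = np.random.default_rng(1)
        X = _predictors(30, 4, 9)
        Y = pd.DataFrame(
            X.to_numpy() @ rng.normal(size=(4, 5)) + rng.normal(0, .5, (30, 5)),
            index=X.index, columns=[f"t{j}" for j in range(5)])
        res = forward_select(Y, X, alpha=0.9999, n_perm=99, seed=0,
                             global_test=False, r2_cap=False)
        assert sorted(res.selected) == sorted(X.columns)
        # first pick must be the single best predictor by R2
        singles = {c: rda(Y, X[[c]]).constrained_r2 for c in X.columns}
        assert res.selected[0] == max(singles, key=singles.get)
        assert (res.trace["entered"]).all()

    def test_pure_noise_usually_selects_nothing(self):
        Y = _counts(25, 6, 30)
        X = _predictors(25, 5, 31)
        res = forward_select(Y, X, alpha=0.05, n_perm=199, seed=0,
                             transform="hellinger")
        assert res.selected == []
        assert res.global_p is not None and res.global_p >= 0.05

    def test_strong_driver_recovered(self):
        rng = np.random.default_rng(3)
        X = _predictors(40, 5, 12)
        signal = X["x2"].to_numpy()[:, None] * rng.normal(size=(1, 6))
        Y = pd.DataFrame(signal + rng.normal(0, 0.4, (40, 6)),
                         index=X.index, columns=[f"t{j}" for j in range(6)])
        res = forward_select(Y, X, alpha=0.05, n_perm=299, seed=0)
        assert "x2" in res.selected

    def test_deterministic_given_seed(self):
        Y = _counts(20, 5, 40)
        X = _predictors(20, 4, 41)
        a = forward_select(Y, X, n_perm=99, seed=5, transform="hellinger")
        b = forward_select(Y, X, n_perm=99, seed=5, transform="hellinger")
        assert a.selected == b.selected
        pd.testing.assert_frame_equal(a.trace, b.trace)


class TestVarpart:
    def test_two_set_identities(self):
        Y = _counts(30, 8, 50)
        sets = {"env": _predictors(30, 3, 51), "space": _predictors(30, 2, 52)}
        vp = varpart(Y, sets, n_perm=0, seed=0)
        f = vp.fractions
        u = vp.union_adjusted_r2
        # unique + shared must reassemble each single-set adjusted R2
        assert f["unique[env]"] + f["shared[env&space]"] == pytest.approx(u["env"])
        assert f["unique[space]"] + f["shared[env&space]"] == pytest.approx(u["space"])
        assert sum(f.values()) + vp.residual == pytest.approx(1.0)

    def test_duplicated_set_has_no_unique_fraction(self):
        Y = _counts(25, 6, 60)
        X = _predictors(25, 3, 61)
        vp = varpart(Y, {"a": X, "b": X.copy()}, n_perm=0, seed=0)
        assert vp.fractions["unique[a]"] == pytest.approx(0.0, abs=1e-9)
        assert vp.fractions["unique[b]"] == pytest.approx(0.0, abs=1e-9)
        assert vp.fractions["shared[a&b]"] == pytest.approx(
            vp.union_adjusted_r2["a"])

    def test_three_set_identities(self):
        Y = _counts(40, 8, 70)
        sets = {"a": _predictors(40, 2, 71), "b": _predictors(40, 2, 72),
                "c": _predictors(40, 2, 73)}
        vp = varpart(Y, sets, n_perm=0, seed=0)
        f, u = vp.fractions, vp.union_adjusted_r2
        total = sum(f.values())
        assert total == pytest.approx(u["a+b+c"])
        assert vp.residual == pytest.approx(1.0 - u["a+b+c"])
        # each set's marginal adjusted R2 decomposes into its fractions
        assert (f["unique[a]"] + f["shared[a&b]"] + f["shared[a&c]"]
                + f["shared[a&b&c]"]) == pytest.approx(u["a"], abs=1e-9)

    def test_set_count_guard(self):
        Y = _counts(10, 4, 80)
        with pytest.raises(ValueError):
            varpart(Y, {"only": _predictors(10, 2, 81)})


class TestBuildPredictorSets:
    def test_expected_sets_and_shapes(self, toy_frame, toy_env):
        scores = pd.DataFrame({"PCNM1": [0.5, 0.5, -0.5, -0.5]},
                              index=toy_frame.samples)
        sets = build_predictor_sets(toy_frame, toy_env, scores)
        assert set(sets) == {"season", "vertical", "horizontal",
                             "physical", "chemical", "food"}
        assert list(sets["season"].columns) == ["season_summer"]
        assert sets["physical"].shape == (4, 4)
        # Chla total is excluded from the food set (size fractions only)
        assert "Chla" not in sets["food"].columns
        assert {"Syn", "Peuk", "Pro"}.issubset(sets["food"].columns)

    def test_depth_log_option(self, toy_frame):
        sets = build_predictor_sets(toy_frame, depth_log=True)
        assert list(sets["vertical"].columns) == ["depth", "log_depth"]


R_SCRIPT = """
suppressMessages(library(vegan))
args <- commandArgs(trailingOnly = TRUE)
Y <- read.csv(args[1], row.names = 1)
X <- read.csv(args[2], row.names = 1)
Yh <- decostand(Y, "hellinger")
m <- rda(Yh ~ ., data = X)
cat(sprintf("rda_r2=%.12f\\n", RsquareAdj(m)$r.squared))
cat(sprintf("rda_adj=%.12f\\n", RsquareAdj(m)$adj.r.squared))
vp <- varpart(Yh, X[, 1:2], X[, 3:4])
ind <- vp$part$indfract$Adj.R.square
cat(sprintf("vp_a=%.12f\\nvp_b=%.12f\\nvp_c=%.12f\\n", ind[1], ind[2], ind[3]))
m2 <- cca(Y ~ ., data = X)
cat(sprintf("cca_r2=%.12f\\n", m2$CCA$tot.chi / m2$tot.chi))
"""


def test_matches_vegan_reference(tmp_path):
    """RDA/CCA explained fractions and varpart unique/shared fractions agree
    with the vegan implementations on the same data."""
    Y = _counts(24, 7, 90)
    X = _predictors(24, 4, 91)
    Y.data.to_csv(tmp_path / "Y.csv")
    X.to_csv(tmp_path / "X.csv")
    script = tmp_path / "check.R"
    script.write_text(R_SCRIPT)
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script),
         str(tmp_path / "Y.csv"), str(tmp_path / "X.csv")],
        capture_output=True, text=True, check=True).stdout
    ref = dict(re.findall(r"(\w+)=(-?\d+\.\d+)", out))
    ref = {k: float(v) for k, v in ref.items()}

    fit = rda(Y, X, transform="hellinger")
    assert fit.constrained_r2 == pytest.approx(ref["rda_r2"], abs=1e-9)
    assert fit.adjusted_r2 == pytest.approx(ref["rda_adj"], abs=1e-9)

    vp = varpart(Y, {"e": X[["x0", "x1"]], "s": X[["x2", "x3"]]},
                 n_perm=0, seed=0)
    # vegan indfract rows: [a] = X1|X2, [b] = X2|X1, [c] = shared
    assert vp.fractions["unique[e]"] == pytest.approx(ref["vp_a"], abs=1e-9)
    assert vp.fractions["unique[s]"] == pytest.approx(ref["vp_b"], abs=1e-9)
    assert vp.fractions["shared[e&s]"] == pytest.approx(ref["vp_c"], abs=1e-9)

    fit2 = cca(Y, X, n_perm=49, seed=0)
    assert fit2.constrained_r2 == pytest.approx(ref["cca_r2"], abs=1e-9)
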