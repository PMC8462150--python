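import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from floradisc.catalog import GrowthForm, ProvinceTable, SpeciesRecord
from floradisc.spatial import (
    fit_beta_step,
    fit_ols_step,
    morans_i,
    standardized_discovery_time,
    summarize_provinces,
)


def _sp(sid, year, provs, genus="Carex", form=GrowthForm.HERB):
    return SpeciesRecord(sid, genus, year, form, frozenset(provs))


class TestSummaries:
    def test_mean_is_plain_average(self, toy_provinces):
        recs = [_sp("s1", 1853, {"A"}), _sp("s2", 1953, {"A"})]
        out = summarize_provinces(recs, toy_provinces)
        assert out.loc["A", "mean_discovery_year"] == pytest.approx(1903.0)
        assert out.loc["A", "n_species"] == 2

    def test_all_species_everywhere_gives_identical_means(self, toy_provinces):
        recs = [_sp(f"s{i}", 1800 + 10 * i, {"A", "B", "C", "D"}) for i in range(5)]
        out = summarize_provinces(recs, toy_provinces)
        assert out["mean_discovery_year"].nunique() == 1
        assert out["weighted_mean_discovery_year"].nunique() == 1

    def test_equal_ranges_make_weighting_a_no_op(self, toy_provinces):
        recs = [_sp("s1", 1800, {"A", "B"}), _sp("s2", 1900, {"A", "C"})]
        out = summarize_provinces(recs, toy_provinces)
        assert out.loc["A", "weighted_mean_discovery_year"] == pytest.approx(
            out.loc["A", "mean_discovery_year"]
        )

    def test_empty_province_flagged(self, toy_provinces):
        recs = [_sp("s1", 1800, {"A"})]
        with pytest.warns(RuntimeWarning, match="no species"):
            out = summarize_provinces(recs, toy_provinces)
        assert np.isnan(out.loc["D", "mean_discovery_year"])
        assert out.loc["D", "n_species"] == 0


class TestStandardizedDiscoveryTime:
    def test_exact_mode_matches_hand_enumeration(self, toy_provinces):
        recs = [
            _sp("s1", 1800, {"A", "B"}),
            _sp("s2", 1900, {"B"}),
            _sp("s3", 1990, {"A"}),
        ]
        res = standardized_discovery_time(recs, toy_provinces, method="exact")
        years = np.array([1800.0, 1900.0, 1990.0])
        w = np.array([0.5, 1.0, 1.0])
        occ = {"A": [0, 2], "B": [0, 1]}
        for code, members in occ.items():
            obs = sum(w[i] * years[i] for i in members) / sum(w[i] for i in members)
            nulls = []
            for perm in itertools.permutations(years):
                p = np.array(perm)
                nulls.append(
                    sum(w[i] * p[i] for i in members) / sum(w[i] for i in members)
                )
            nulls = np.array(nulls)
            z = (obs - nulls.mean()) / nulls.std()
            assert res.loc[code, "z"] == pytest.approx(z, abs=1e-12)
            assert res.loc[code, "observed"] == pytest.approx(obs, abs=1e-12)

    def test_invariant_to_constant_year_shift(self, toy_provinces):
        recs = [
            _sp("s1", 1800, {"A", "B"}),
            _sp("s2", 1900, {"B", "C"}),
            _sp("s3", 1990, {"A", "D"}),
            _sp("s4", 1850, {"C"}),
        ]
        shifted = [
            SpeciesRecord(r.species_id, r.genus, r.description_year + 13,
                          r.growth_form, r.provinces)
            for r in recs
        ]
        r1 = standardized_discovery_time(recs, toy_provinces, n_shuffles=200, seed=5)
        r2 = standardized_discovery_time(shifted, toy_provinces, n_shuffles=200, seed=5)
        pd.testing.assert_series_equal(r1["z"], r2["z"], atol=1e-9, rtol=0)

    def test_identical_years_degenerate(self, toy_provinces):
        recs = [_sp(f"s{i}", 1900, {"A", "B"}) for i in range(4)]
        with pytest.warns(RuntimeWarning, match="zero null SD"):
            res = standardized_discovery_time(
                recs, toy_provinces, n_shuffles=50, seed=0
            )
        assert res["z"].isna().all()
        occupied = res["observed"].notna()
        assert occupied.loc[["A", "B"]].all()
        assert (res.loc[occupied, "observed"] == res.loc[occupied, "null_mean"]).all()

    def test_reproducible_under_seed(self, toy_provinces):
        recs = [
            _sp("s1", 1800, {"A", "B"}),
            _sp("s2", 1900, {"B", "C"}),
            _sp("s3", 1990, {"A", "D"}),
        ]
        a = standardized_discovery_time(recs, toy_provinces, n_shuffles=100, seed=3)
        b = standardized_discovery_time(recs, toy_provinces, n_shuffles=100, seed=3)
        pd.testing.assert_frame_equal(a, b)


def _grid_provinces(n=5):
    """Chain of n provinces for Moran tests."""
    frame = pd.DataFrame(
        {
            "code": [f"P{i}" for i in range(n)],
            "area_km2": 1000.0,
            "pop_density": 10.0,
            "coastal": False,
            "centroid_lat": 30.0 + np.arange(n),
            "centroid_lon": 100.0,
        }
    ).set_index("code")
    neighbors = {f"P{i}": {f"P{i+1}"} for i in range(n - 1)}
    return ProvinceTable(frame, neighbors)


class TestMoransI:
    def test_coordinate_on_chain_is_positively_autocorrelated(self):
        prov = _grid_provinces(8)
        vals = pd.Series(np.arange(8.0), index=prov.frame.index)
        res = morans_i(vals, prov, permutations=0)
        assert res.I > 0

    def test_four_node_hand_computation(self):
        # chain P0-P1-P2-P3, binary weights, x = (1, 2, 4, 8)
        prov = _grid_provinces(4)
        x = np.array([1.0, 2.0, 4.0, 8.0])
        z = x - x.mean()
        num = 2 * (z[0] * z[1] + z[1] * z[2] + z[2] * z[3])
        I_hand = (4 / 6.0) * num / (z @ z)
        res = morans_i(
            pd.Series(x, index=prov.frame.index), prov,
            permutations=0, standardize="binary",
        )
        assert res.I == pytest.approx(I_hand, abs=1e-12)
        assert res.expected == pytest.approx(-1 / 3)

    def test_null_mean_matches_minus_one_over_n_minus_one(self):
        prov = _grid_provinces(10)
        rng = np.random.default_rng(0)
        vals = [
            morans_i(
                pd.Series(rng.normal(size=10), index=prov.frame.index),
                prov, permutations=0,
            ).I
            for _ in range(200)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(200)
        assert abs(np.mean(vals) - (-1 / 9)) < 3 * se

    def test_constant_values_rejected(self):
        prov = _grid_provinces(4)
        with pytest.raises(ValueError, match="constant"):
            morans_i(pd.Series(1.0, index=prov.frame.index), prov)

    def test_permutation_p_flags_strong_gradient(self):
        prov = _grid_provinces(12)
        vals = pd.Series(np.arange(12.0), index=prov.frame.index)
        res = morans_i(vals, prov, permutations=499, seed=1)
        assert res.p_permutation < 0.05


def _summary_frame(n=24, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "n_species": rng.integers(50, 500, n).astype(float),
            "coastal": rng.binomial(1, 0.4, n).astype(float),
            "pop_density": rng.lognormal(4, 0.5, n),
            "area_km2": rng.lognormal(11, 0.4, n),
            "centroid_lon": rng.uniform(98, 122, n),
            "centroid_lat": rng.uniform(21, 41, n),
        },
        index=[f"P{i}" for i in range(n)],
    )


class TestOlsStep:
    def test_noiseless_construction_recovers_coefficients_exactly(self):
        df = _summary_frame()
        lon01 = (df.centroid_lon - df.centroid_lon.min()) / np.ptp(df.centroid_lon)
        nsp01 = (df.n_species - df.n_species.min()) / np.ptp(df.n_species)
        df["mean_discovery_year"] = 1900.0 + 30.0 * nsp01 - 12.0 * lon01
        fit = fit_ols_step(df, terms=("n_species", "centroid_lon"))
        assert fit.summary.loc["const", "coefficient"] == pytest.approx(1900.0, abs=1e-8)
        assert fit.summary.loc["n_species", "coefficient"] == pytest.approx(30.0, abs=1e-8)
        assert fit.summary.loc["centroid_lon", "coefficient"] == pytest.approx(-12.0, abs=1e-8)

    def test_superfluous_term_eliminated(self):
        # a whisper of noise keeps the Gaussian log-likelihood finite; an
        # exactly-interpolated response makes AIC comparisons degenerate
        df = _summary_frame()
        rng = np.random.default_rng(9)
        lon01 = (df.centroid_lon - df.centroid_lon.min()) / np.ptp(df.centroid_lon)
        nsp01 = (df.n_species - df.n_species.min()) / np.ptp(df.n_species)
        df["mean_discovery_year"] = (
            1900.0 + 30.0 * nsp01 - 12.0 * lon01 + rng.normal(scale=1e-3, size=len(df))
        )
        fit = fit_ols_step(df, terms=("n_species", "centroid_lon", "pop_density"))
        assert set(fit.selected_terms) == {"n_species", "centroid_lon"}
        assert fit.summary.loc["n_species", "coefficient"] == pytest.approx(30.0, abs=1e-2)

    def test_no_terms_returns_intercept_as_mean(self):
        df = _summary_frame()
        df["mean_discovery_year"] = np.linspace(1850, 1950, len(df))
        fit = fit_ols_step(df, terms=())
        assert fit.selected_terms == []
        assert fit.summary.loc["const", "coefficient"] == pytest.approx(
            df["mean_discovery_year"].mean()
        )

    def test_full_model_kept_when_all_terms_matter(self):
        df = _summary_frame(seed=3)
        lat01 = (df.centroid_lat - df.centroid_lat.min()) / np.ptp(df.centroid_lat)
        df["mean_discovery_year"] = 1880 + 40 * lat01 - 15 * df.coastal
        fit = fit_ols_step(df, terms=("centroid_lat", "coastal"))
        assert set(fit.selected_terms) == {"centroid_lat", "coastal"}
        assert len(fit.aic_trace) == 1

    def test_residuals_align_with_index(self):
        df = _summary_frame(seed=4)
        df["mean_discovery_year"] = 1900 + np.random.default_rng(4).normal(size=len(df))
        fit = fit_ols_step(df, terms=("centroid_lat",))
        assert list(fit.residuals.index) == list(df.index)


def _beta_loglik(mu, phi, y):
    from scipy.special import gammaln

    p, q = mu * phi, (1 - mu) * phi
    return np.sum(
        gammaln(phi) - gammaln(p) - gammaln(q)
        + (p - 1) * np.log(y) + (q - 1) * np.log(1 - y)
    )


class TestBetaStep:
    def test_intercept_only_matches_direct_ml_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.beta(2.0, 5.0, size=200)
        df = pd.DataFrame({"completeness": y, "dummy": rng.normal(size=200)},
                          index=[f"P{i}" for i in range(200)])
        fit = fit_beta_step(df, terms=())
        # independent 2-D maximum-likelihood solve on (logit mu, log phi)
        def nll(theta):
            mu = 1 / (1 + np.exp(-theta[0]))
            phi = np.exp(theta[1])
            return -_beta_loglik(mu, phi, y)

        opt = optimize.minimize(nll, [0.0, 1.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        mu_hat = 1 / (1 + np.exp(-fit.summary.loc["const", "coefficient"]))
        mu_oracle = 1 / (1 + np.exp(-opt.x[0]))
        assert mu_hat == pytest.approx(mu_oracle, abs=1e-5)
        assert fit.phi == pytest.approx(np.exp(opt.x[1]), rel=1e-3)

    def test_constant_response_rejected(self):
        df = pd.DataFrame(
            {"completeness": 0.7, "n_species": np.arange(20.0)},
            index=[f"P{i}" for i in range(20)],
        )
        with pytest.raises(ValueError, match="constant response"):
            fit_beta_step(df, terms=("n_species",))

    def test_boundary_responses_are_compressed_not_fatal(self):
        rng = np.random.default_rng(5)
        n = 40
        df = pd.DataFrame(
            {
                "completeness": np.concatenate([[1.0, 1.0], rng.beta(5, 2, n - 2)]),
                "n_species": rng.integers(10, 100, n).astype(float),
            },
            index=[f"P{i}" for i in range(n)],
        )
        fit = fit_beta_step(df, terms=("n_species",))
        assert np.isfinite(fit.aic)

    def test_fitted_optimum_is_local_maximum(self):
        rng = np.random.default_rng(8)
        n = 150
        x = rng.uniform(size=n)
        mu = 1 / (1 + np.exp(-(0.5 + 1.2 * x)))
        y = rng.beta(mu * 30, (1 - mu) * 30)
        df = pd.DataFrame({"completeness": y, "x": x},
                          index=[f"P{i}" for i in range(n)])
        fit = fit_beta_step(df, terms=("x",))
        res = fit.model_result
        ll_hat = float(res.llf)
        params = np.asarray(res.params)
        for k in range(100):
            pert = params + rng.normal(scale=0.05, size=len(params))
            assert res.model.loglike(pert) <= ll_hat + 1e-8
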