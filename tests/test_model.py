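import numpy as np
import pandas as pd
import pytest

from tmtd.errors import ConfigurationError
from tmtd.model import (
    DesignRow,
    build_design,
    compute_eil,
    decompose_signal,
    fit_robust,
)

from .oracles import oracle_irls_bisquare


def metrics_frame(layout, n=40, classes=("a", "b"), charges=(2, 3), seed=0):
    rng = np.random.default_rng(seed)
    rows = {
        "ppf": rng.uniform(0.4, 0.95, n),
        "pic": np.exp(rng.normal(10, 1, n)),
        "tiw": np.exp(rng.normal(11, 1, n)),
        "noise_estimate": np.exp(rng.normal(3, 1, n)),
        "charge": rng.choice(charges, n),
        "pep_class": rng.choice(classes, n),
    }
    df = pd.DataFrame(rows)
    for c in layout.peptide_channels:
        df[f"reporter_{c}"] = rng.uniform(10, 100, n)
    return df


class TestBuildDesign:
    def test_general_model_column_count(self, layout):
        df = metrics_frame(layout, n=120)
        rows = build_design(df, model="general", layout=layout)
        y_total = df[[f"reporter_{c}" for c in layout.peptide_channels]].sum(axis=1)
        assert len(rows) == len(df)
        assert rows[0].y == pytest.approx(y_total.iloc[0])
        # 2 classes + 2 charges + noise = 5 coefficients
        from tmtd.model import _design_matrix

        X, _, columns, precursor_names, _ = _design_matrix(rows, "general")
        assert X.shape[1] == 5
        assert len(precursor_names) == 2

    def test_pure_psm_has_zero_nonprecursor_term(self, layout):
        df = metrics_frame(layout, n=5)
        df.loc[0, "ppf"] = 1.0
        rows = build_design(df, model="general", layout=layout)
        assert rows[0].nonprecursor_term == 0.0

    def test_ground_truth_response_sums_interference_channels(self, layout):
        df = metrics_frame(layout, n=3)
        for i, c in enumerate(sorted(layout.interference_only_channels)):
            df.loc[0, f"reporter_{c}"] = float(i + 1)
        rows = build_design(df, model="ground_truth", layout=layout)
        assert rows[0].y == pytest.approx(6.0)
        assert rows[0].precursor_term == 0.0

    def test_missing_metrics_excluded_with_warning(self, layout):
        df = metrics_frame(layout, n=6)
        df.loc[2, "noise_estimate"] = np.nan
        with pytest.warns(UserWarning, match="excluded 1"):
            rows = build_design(df, model="general", layout=layout)
        assert len(rows) == 5


def synthetic_rows(n, beta_by_class, beta_by_charge, beta_noise, seed, noise_sd=0.0, outlier_frac=0.0):
    rng = np.random.default_rng(seed)
    classes = sorted(beta_by_class)
    charges = sorted(beta_by_charge)
    rows = []
    for i in range(n):
        k = classes[rng.integers(len(classes))]
        c = charges[rng.integers(len(charges))]
        prec = float(np.exp(rng.normal(9, 0.8)))
        nonp = prec * float(rng.uniform(0.05, 0.8))
        noise = float(np.exp(rng.normal(4, 1.0)))
        y = beta_by_class[k] * prec + beta_by_charge[c] * nonp + beta_noise * noise
        if noise_sd:
            y *= float(np.exp(rng.normal(0, noise_sd)))
        if outlier_frac and rng.random() < outlier_frac:
            y *= 100.0
        rows.append(
            DesignRow(
                psm_index=i, y=y, precursor_term=prec, nonprecursor_term=nonp,
                noise_term=noise, charge_cat=c, pep_class=k,
            )
        )
    return rows


class TestFitRobust:
    def test_noiseless_data_recovers_beta_exactly(self):
        truth_c = {"a": 0.12, "b": 0.05}
        truth_g = {2: 0.08, 3: 0.11}
        rows = synthetic_rows(400, truth_c, truth_g, 60.0, seed=0)
        fit = fit_robust(rows, model="general")
        for k, v in truth_c.items():
            assert fit.coef[f"precursor:pepClass={k}"] == pytest.approx(v, rel=1e-6)
        for c, v in truth_g.items():
            assert fit.coef[f"nonprecursor:charge={c}"] == pytest.approx(v, rel=1e-6)
        assert fit.coef["noiseEstimate"] == pytest.approx(60.0, rel=1e-6)

    def test_bisquare_resists_gross_outliers_where_ols_fails(self):
        truth_c = {"a": 0.1}
        truth_g = {2: 0.09}
        rows = synthetic_rows(5000, truth_c, truth_g, 50.0, seed=1, outlier_frac=0.05)
        fit = fit_robust(rows, model="general")
        assert fit.coef["precursor:pepClass=a"] == pytest.approx(0.1, rel=0.05)
        # plain least squares on the same rows misses badly
        X = np.array([[r.precursor_term, r.nonprecursor_term, r.noise_term] for r in rows])
        y = np.array([r.y for r in rows])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert abs(ols[0] / 0.1 - 1) > 0.20

    def test_matches_textbook_irls_oracle(self):
        rows = synthetic_rows(50, {"a": 0.1}, {2: 0.09}, 40.0, seed=2, noise_sd=0.2)
        fit = fit_robust(rows, model="general")
        X = [[r.precursor_term, r.nonprecursor_term, r.noise_term] for r in rows]
        y = [r.y for r in rows]
        expected = oracle_irls_bisquare(X, y)
        got = [
            fit.coef["precursor:pepClass=a"],
            fit.coef["nonprecursor:charge=2"],
            fit.coef["noiseEstimate"],
        ]
        np.testing.assert_allclose(got, expected, rtol=1e-4)

    def test_scale_equivariance(self):
        rows = synthetic_rows(300, {"a": 0.1, "b": 0.2}, {2: 0.09}, 40.0, seed=3, noise_sd=0.1)
        fit1 = fit_robust(rows, model="general")
        scaled = [
            DesignRow(r.psm_index, r.y * 7.0, r.precursor_term, r.nonprecursor_term,
                      r.noise_term, r.charge_cat, r.pep_class)
            for r in rows
        ]
        fit2 = fit_robust(scaled, model="general")
        for k in fit1.coef:
            assert fit2.coef[k] == pytest.approx(7.0 * fit1.coef[k], rel=1e-6)
        # EIL is invariant to the rescaling
        for r, s in zip(rows[:20], scaled[:20]):
            assert compute_eil(fit1, r) == pytest.approx(compute_eil(fit2, s), abs=1e-6)

    def test_rare_charge_categories_merged(self):
        rows = synthetic_rows(300, {"a": 0.1}, {2: 0.09}, 40.0, seed=4)
        rows[0] = DesignRow(0, rows[0].y, rows[0].precursor_term, rows[0].nonprecursor_term,
                            rows[0].noise_term, 1, "a")  # single charge-1 row
        fit = fit_robust(rows, model="general")
        assert fit.charge_merges == {1: 2}
        assert compute_eil(fit, rows[0]) is not None

    def test_underdetermined_design_rejected(self):
        rows = synthetic_rows(4, {"a": 0.1, "b": 0.2}, {2: 0.09, 3: 0.1}, 40.0, seed=5)
        with pytest.raises(ConfigurationError, match="identify"):
            fit_robust(rows, model="general")


class TestEil:
    @pytest.fixture()
    def fit(self):
        return fit_robust(
            synthetic_rows(400, {"a": 0.1}, {2: 0.08}, 50.0, seed=6), model="general"
        )

    def test_zero_interference_terms_give_zero(self, fit):
        row = DesignRow(0, 1.0, 100.0, 0.0, 0.0, 2, "a")
        assert compute_eil(fit, row) == pytest.approx(0.0, abs=1e-9)

    def test_ratio_by_hand(self, fit):
        # engineer precursor contribution 80 and total 100
        prec = 80.0 / fit.coef["precursor:pepClass=a"]
        noise = 20.0 / fit.coef["noiseEstimate"]
        row = DesignRow(0, 1.0, prec, 0.0, noise, 2, "a")
        assert compute_eil(fit, row) == pytest.approx(0.2, abs=1e-9)

    def test_zero_precursor_gives_one(self, fit):
        row = DesignRow(0, 1.0, 0.0, 10.0, 5.0, 2, "a")
        assert compute_eil(fit, row) == pytest.approx(1.0)

    def test_ground_truth_model_refuses_eil(self):
        rows = synthetic_rows(100, {"a": 0.1}, {2: 0.08}, 50.0, seed=7)
        fit = fit_robust(rows, model="ground_truth")
        with pytest.raises(ConfigurationError, match="general"):
            compute_eil(fit, rows[0])

    def test_eil_always_in_unit_interval(self, fit):
        rng = np.random.default_rng(8)
        for _ in range(200):
            row = DesignRow(
                0, 1.0, float(rng.uniform(0, 1e4)), float(rng.uniform(0, 1e4)),
                float(rng.uniform(0, 100)), 2, "a",
            )
            eil = compute_eil(fit, row)
            if eil is not None:
                assert 0.0 <= eil <= 1.0


class TestDecompose:
    def test_shares_sum_to_one(self):
        rows = synthetic_rows(500, {"a": 0.1, "b": 0.2}, {2: 0.08, 3: 0.1}, 50.0, seed=9)
        fit = fit_robust(rows, model="general")
        shares = decompose_signal(fit, rows)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_noise_coefficient_gives_zero_share(self):
        rows = synthetic_rows(400, {"a": 0.1}, {2: 0.08}, 0.0, seed=10)
        fit = fit_robust(rows, model="general")
        shares = decompose_signal(fit, rows)
        assert shares["noise"] == pytest.approx(0.0, abs=1e-3)

    def test_all_precursor_data_gives_share_one(self):
        rows = [
            DesignRow(i, 0.1 * x, x, 0.0, 0.0, 2, "a")
            for i, x in enumerate(np.linspace(10, 1000, 200))
        ]
        fit = fit_robust(rows, model="general")
        assert decompose_signal(fit, rows)["precursor"] == pytest.approx(1.0, abs=1e-9)
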