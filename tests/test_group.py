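"""Group statistics: Fisher z, regional averaging, OLS contrasts, FDR,
partial Spearman — each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cvrpipe.config import ParcellationVolume
from cvrpipe.exceptions import DataError
from cvrpipe.group import (bh_fdr, fisher_z, fit_region_models,
                           inverse_fisher_z, partial_spearman,
                           regional_average)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_odd_symmetry(self, rng):
        r = rng.uniform(-0.99, 0.99, 50)
        assert np.allclose(fisher_z(r), -fisher_z(-r))

    def test_closed_form_value(self):
        assert fisher_z(0.4621171573) == pytest.approx(0.5, abs=1e-9)

    def test_round_trip_to_1e12(self, rng):
        r = rng.uniform(-0.999999, 0.999999, 200)
        assert np.max(np.abs(inverse_fisher_z(fisher_z(r)) - r)) < 1e-12

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    def test_near_unit_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            z = fisher_z(1 - 1e-9)
        assert np.isfinite(z)


class TestRegionalAverage:
    def _parc(self):
        labels = np.zeros((4, 2, 1), dtype=np.int32)
        labels[:2] = 1
        labels[2:] = 2
        return ParcellationVolume(labels, {1: "a", 2: "b"}, (1.0, 1.0, 1.0))

    def test_constant_map(self):
        out = regional_average(np.full((4, 2, 1), 3.5), self._parc())
        assert out["a"] == 3.5 and out["b"] == 3.5

    def test_two_region_toy(self):
        zmap = np.zeros((4, 2, 1))
        zmap[:2] = 1.0
        zmap[2:] = 3.0
        out = regional_average(zmap, self._parc())
        assert out["a"] == 1.0 and out["b"] == 3.0

    def test_label_permutation_leaves_named_means_unchanged(self):
        zmap = np.zeros((4, 2, 1))
        zmap[:2] = 1.0
        zmap[2:] = 3.0
        parc = self._parc()
        permuted = ParcellationVolume(3 - parc.labels.copy(),
                                      {2: "a", 1: "b"}, (1.0, 1.0, 1.0))
        a = regional_average(zmap, parc)
        b = regional_average(zmap, permuted)
        assert a["a"] == b["a"] and a["b"] == b["b"]

    def test_nan_voxels_ignored(self):
        zmap = np.full((4, 2, 1), 2.0)
        zmap[0, 0, 0] = np.nan
        out = regional_average(zmap, self._parc())
        assert out["a"] == 2.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(DataError):
            regional_average(np.zeros((3, 3, 3)), self._parc())


def _meta(n_hd=6, n_c=6, rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n_hd + n_c)],
        "group": ["control"] * n_c + ["HD"] * n_hd,
        "age": np.concatenate([rng.uniform(25, 50, n_c),
                               rng.uniform(40, 60, n_hd)]),
        "sex": ["M"] * (n_hd + n_c),
    })


class TestRegionModels:
    def test_matches_normal_equations_oracle(self, rng):
        meta = _meta(rng=rng)
        z = rng.normal(0.5, 0.1, 12)
        table = pd.DataFrame({"roi": z}, index=meta["subject_id"])
        res = fit_region_models(table, meta).table.loc["roi"]
        # oracle via explicit pseudoinverse
        hd = (meta["group"] == "HD").to_numpy(float)
        X = np.column_stack([np.ones(12), hd, meta["age"]])
        beta = np.linalg.pinv(X) @ z
        resid = z - X @ beta
        s2 = resid @ resid / (12 - 3)
        cov = s2 * np.linalg.inv(X.T @ X)
        l_c = np.array([1.0, 0.0, 50.0])
        l_h = np.array([1.0, 1.0, 50.0])
        tcrit = stats.t.ppf(0.975, 9)
        assert res["control_est"] == pytest.approx(l_c @ beta, abs=1e-10)
        assert res["hd_est"] == pytest.approx(l_h @ beta, abs=1e-10)
        assert res["diff_est"] == pytest.approx(beta[1], abs=1e-10)
        se = np.sqrt(l_c @ cov @ l_c)
        assert res["control_lo"] == pytest.approx(l_c @ beta - tcrit * se,
                                                  abs=1e-10)
        tstat = beta[1] / np.sqrt(cov[1, 1])
        p = 2 * stats.t.sf(abs(tstat), 9)
        assert res["p"] == pytest.approx(p, abs=1e-10)

    def test_no_effect_no_noise_gives_zero_difference(self):
        meta = _meta()
        table = pd.DataFrame({"roi": np.full(12, 0.6)},
                             index=meta["subject_id"])
        res = fit_region_models(table, meta).table.loc["roi"]
        assert res["diff_est"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] > 0.99

    def test_difference_equals_hd_minus_control(self, rng):
        meta = _meta(rng=rng)
        table = pd.DataFrame(
            rng.normal(0.5, 0.1, (12, 4)),
            index=meta["subject_id"], columns=list("abcd"))
        tab = fit_region_models(table, meta).table
        assert np.allclose(tab["diff_est"],
                           tab["hd_est"] - tab["control_est"], atol=1e-12)
        assert (tab["control_lo"] <= tab["control_est"]).all()
        assert (tab["control_est"] <= tab["control_hi"]).all()
        assert (tab["p_fdr"] >= tab["p"] - 1e-15).all()

    def test_coverage_of_known_difference(self):
        """95% CI covers a true -0.25 difference in >= 93/100 replicates
        (12 HD vs 11 controls, residual SD 0.1)."""
        rng = np.random.default_rng(2024)
        covered = 0
        for _ in range(100):
            meta = _meta(n_hd=12, n_c=11, rng=rng)
            z = np.where(meta["group"] == "HD", 0.35, 0.60) \
                + rng.normal(0, 0.1, 23)
            table = pd.DataFrame({"roi": z}, index=meta["subject_id"])
            res = fit_region_models(table, meta).table.loc["roi"]
            covered += res["diff_lo"] <= -0.25 <= res["diff_hi"]
        assert covered >= 93

    def test_too_few_subjects_rejected(self):
        meta = _meta(n_hd=2, n_c=6)
        table = pd.DataFrame({"roi": np.zeros(8)}, index=meta["subject_id"])
        with pytest.raises(DataError):
            fit_region_models(table, meta)


class TestBhFdr:
    def test_hand_example(self):
        adj = bh_fdr([0.001, 0.02, 0.9])
        assert np.allclose(adj, [0.003, 0.03, 0.9])

    def test_equal_pvalues_unchanged(self):
        assert np.allclose(bh_fdr([0.04] * 5), 0.04)

    def test_matches_brute_force_step_up(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(3, 40))
            adj = bh_fdr(p)
            # brute-force step-up oracle
            m = p.size
            order = np.argsort(p)
            oracle = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                oracle[i] = running
            assert np.allclose(adj, oracle, atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 30)
        assert np.all(bh_fdr(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])


class TestPartialSpearman:
    def _oracle(self, z, tfc, age):
        rz, rt, ra = (stats.rankdata(v) for v in (z, tfc, age))
        X = np.column_stack([np.ones(ra.size), ra])
        res_z = rz - X @ np.linalg.pinv(X) @ rz
        res_t = rt - X @ np.linalg.pinv(X) @ rt
        return res_z @ res_t / (np.linalg.norm(res_z)
                                * np.linalg.norm(res_t))

    def test_monotone_relation_gives_rho_one(self, rng):
        tfc = np.array([9.0, 10, 11, 12, 13, 13.5])
        z = tfc ** 2  # monotone in tfc
        age = rng.uniform(30, 60, 6)
        rho, p = partial_spearman(z, tfc, age)
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_matches_rank_residual_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 30))
            z = rng.normal(size=n)
            tfc = rng.integers(9, 14, n).astype(float)
            age = rng.uniform(25, 65, n)
            if np.ptp(tfc) == 0:
                continue
            rho, _ = partial_spearman(z, tfc, age)
            assert rho == pytest.approx(self._oracle(z, tfc, age),
                                        abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 20
        z = rng.normal(size=n)
        tfc = rng.integers(9, 14, n).astype(float)
        age = rng.uniform(25, 65, n)
        rho, p = partial_spearman(z, tfc, age)
        df = pd.DataFrame({"z": z, "tfc": tfc, "age": age})
        ref = pingouin.partial_corr(df, x="z", y="tfc", covar="age",
                                    method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert p == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-6)

    def test_age_only_signal_gives_null_rho(self, rng):
        n = 40
        age = rng.uniform(25, 65, n)
        z = 0.02 * age + rng.normal(0, 0.01, n)
        tfc = rng.integers(9, 14, n).astype(float)
        rho, p = partial_spearman(z, tfc, age)
        assert abs(rho) < 0.4

    def test_constant_tfc_flagged_not_fatal(self):
        with pytest.warns(UserWarning):
            rho, p = partial_spearman(np.arange(6.0), np.full(6, 13.0),
                                      np.arange(6.0) + 30)
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_triples_rejected(self):
        with pytest.raises(DataError):
            partial_spearman([1, 2, 3], [9, 10, 11], [30, 40, 50])


def test_null_fdr_rate_controlled(rng):
    """Under a global null the fraction of FDR-significant regions stays
    near zero on average (simulation over 200 cohorts, 70 regions)."""
    frac = []
    for _ in range(200):
        p = rng.uniform(0, 1, 70)
        frac.append(np.mean(bh_fdr(p) < 0.05))
    assert np.mean(frac) <= 0.05
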