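"""Reef index unit and property tests with independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import linalg

from reefheat.indices import (
    CATEGORIES,
    FunctionalCoefficientTable,
    SurveyObservation,
    bleaching_severity,
    dca_axis1,
    hill_n1,
    reef_index_set,
    rfi,
    richness,
    si_reef,
    species_bsi_table,
)


def make_obs(colonies, site_id="s", date="2016-10-01", depth=5.0):
    return SurveyObservation(
        site_id=site_id,
        date=date,
        latitude=16.0,
        longitude=-88.0,
        depth=depth,
        colonies=colonies,
    )


# ---------------------------------------------------------------------------
# Bleaching severity (reef level)
# ---------------------------------------------------------------------------


class TestBleachingSeverity:
    def test_known_values(self):
        # 28% fully bleached, rest normal -> 28.0
        assert bleaching_severity(100, 0, 0, 28) == pytest.approx(28.0)
        assert bleaching_severity(100, 0, 0, 0) == 0.0
        assert bleaching_severity(100, 0, 0, 100) == 100.0
        # all pale scores a third of all fully bleached
        assert bleaching_severity(90, 90, 0, 0) == pytest.approx(100.0 / 3.0)

    def test_bounds_exhaustive_small_tables(self):
        for n in range(1, 13):
            for c2 in range(n + 1):
                for c3 in range(n - c2 + 1):
                    for c4 in range(n - c2 - c3 + 1):
                        b = bleaching_severity(n, c2, c3, c4)
                        assert 0.0 <= b <= 100.0

    def test_monotone_in_category_upgrades(self):
        # moving a colony to a more severe category never lowers the index
        base = bleaching_severity(100, 10, 10, 10)
        assert bleaching_severity(100, 9, 11, 10) > base
        assert bleaching_severity(100, 10, 9, 11) > base
        assert bleaching_severity(100, 11, 10, 10) > base  # normal -> pale

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            bleaching_severity(0, 0, 0, 0)
        with pytest.raises(ValueError, match="non-negative"):
            bleaching_severity(10, -1, 0, 0)
        with pytest.raises(ValueError, match="only 10 colonies"):
            bleaching_severity(10, 5, 5, 5)

    @given(
        st.integers(1, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
    )
    def test_scale_linearity(self, n, c2, c3, c4):
        if c2 + c3 + c4 > n:
            return
        full = bleaching_severity(n, c2, c3, c4, scale=100.0)
        unit = bleaching_severity(n, c2, c3, c4, scale=1.0)
        assert full == pytest.approx(100.0 * unit)


# ---------------------------------------------------------------------------
# Survey observations
# ---------------------------------------------------------------------------


class TestSurveyObservation:
    def test_category_counts(self, survey_obs):
        assert survey_obs.category_counts() == (160, 20, 30, 10)

    def test_colony_count_warning_outside_protocol(self):
        with pytest.warns(UserWarning, match="150-200"):
            make_obs([("Sp a", "normal", 10)])

    def test_invalid_category_rejected(self):
        with pytest.raises(ValueError, match="unknown category"):
            make_obs([("Sp a", "bleached", 160)])

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            make_obs([("Sp a", "normal", 160)], depth=0.0)


# ---------------------------------------------------------------------------
# Species sensitivity table and SI_reef
# ---------------------------------------------------------------------------


class TestSpeciesTableAndSI:
    def test_pooled_not_averaged(self):
        # two surveys with very different colony counts: pooling weights the
        # larger survey, per-survey averaging would not
        a = make_obs([("Sp a", "fully_bleached", 150)], site_id="s1")
        b = make_obs([("Sp a", "normal", 49), ("Sp b", "normal", 111)], site_id="s2")
        table = species_bsi_table([a, b], min_colonies=50)
        # Sp a pooled: 199 colonies, 150 fully bleached
        assert table.bsi_sp("Sp a") == pytest.approx((150 * 3 / 3) / 199)
        assert table.bsi_sp("Sp b") == 0.0

    def test_min_colonies_floor(self):
        a = make_obs(
            [("Sp a", "normal", 120), ("Sp b", "pale", 40)], site_id="s1"
        )
        table = species_bsi_table([a], min_colonies=50)
        assert table.species == ["Sp a"]

    def test_no_species_reaches_floor(self):
        with pytest.warns(UserWarning):
            a = make_obs([("Sp a", "normal", 10)])
        with pytest.raises(ValueError, match="colony floor"):
            species_bsi_table([a], min_colonies=50)

    def test_si_reef_is_convex_combination(self, survey_obs):
        table = species_bsi_table([survey_obs], min_colonies=1)
        si = si_reef(survey_obs, table)
        vals = table.table["bsi_sp"]
        assert vals.min() - 1e-12 <= si <= vals.max() + 1e-12

    def test_si_reef_manual_oracle(self):
        obs = make_obs(
            [("Sp a", "normal", 100), ("Sp b", "fully_bleached", 60)]
        )
        table = species_bsi_table([obs], min_colonies=1)
        # Sp a bsi 0, Sp b bsi 1; relative abundances 100/160 and 60/160
        assert si_reef(obs, table) == pytest.approx(60.0 / 160.0)

    def test_unknown_species_excluded_from_si(self):
        obs = make_obs(
            [("Sp a", "normal", 100), ("Sp b", "fully_bleached", 60)]
        )
        table = species_bsi_table(
            [make_obs([("Sp a", "pale", 150)])], min_colonies=1
        )
        # Sp b absent from the table: SI over Sp a alone
        assert si_reef(obs, table) == pytest.approx(1.0 / 3.0)


# ---------------------------------------------------------------------------
# Functional coefficients and RFI
# ---------------------------------------------------------------------------


class TestFunctionalIndex:
    @pytest.fixture
    def fc(self):
        df = pd.DataFrame(
            {"fc": [0.5, 0.7, 0.2], "source_species": ["", "", ""]},
            index=pd.Index(
                ["Acropora palmata", "Acropora cervicornis", "Porites astreoides"],
                name="species",
            ),
        )
        return FunctionalCoefficientTable(table=df)

    def test_direct_lookup(self, fc):
        assert fc.lookup("Acropora palmata") == (0.5, "Acropora palmata")

    def test_congener_fallback_alphabetical(self, fc):
        # missing Acropora species falls back to the alphabetically first congener
        val, src = fc.lookup("Acropora prolifera")
        assert (val, src) == (0.7, "Acropora cervicornis")

    def test_no_congener_returns_none(self, fc):
        assert fc.lookup("Orbicella annularis") is None

    def test_rfi_weighted_mean(self, fc):
        obs = make_obs(
            [("Acropora palmata", "normal", 120), ("Porites astreoides", "pale", 40)]
        )
        expected = (120 * 0.5 + 40 * 0.2) / 160
        assert rfi(obs, fc) == pytest.approx(expected)

    def test_rfi_drops_unassignable_colonies(self, fc):
        obs = make_obs(
            [("Acropora palmata", "normal", 100), ("Orbicella annularis", "pale", 60)]
        )
        assert rfi(obs, fc) == pytest.approx(0.5)

    def test_rfi_all_unassignable_raises(self, fc):
        obs = make_obs([("Orbicella annularis", "pale", 160)])
        with pytest.raises(ValueError, match="functional coefficient"):
            rfi(obs, fc)

    def test_nonpositive_coefficient_rejected(self):
        df = pd.DataFrame(
            {"fc": [0.0], "source_species": [""]},
            index=pd.Index(["Sp a"], name="species"),
        )
        with pytest.raises(ValueError, match="positive"):
            FunctionalCoefficientTable(table=df)


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------


class TestDiversity:
    @given(st.integers(1, 40))
    def test_hill_uniform_identity(self, k):
        assert hill_n1(np.full(k, 5.0)) == pytest.approx(k, rel=1e-12)

    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=30))
    def test_hill_scale_invariance_and_bounds(self, vals):
        a = np.asarray(vals)
        n1 = hill_n1(a)
        assert n1 == pytest.approx(hill_n1(3.7 * a), rel=1e-9)
        assert 1.0 - 1e-9 <= n1 <= len(a) + 1e-9

    def test_hill_zero_species_ignored(self):
        assert hill_n1([2.0, 2.0, 0.0]) == pytest.approx(2.0)

    def test_hill_empty_raises(self):
        with pytest.raises(ValueError, match="positive"):
            hill_n1([0.0, 0.0])

    def test_richness(self):
        assert richness([1.0, 0.0, 3.0]) == 2
        with pytest.warns(UserWarning, match="no species"):
            assert richness([0.0]) == 0


# ---------------------------------------------------------------------------
# Correspondence analysis (DCA axis 1)
# ---------------------------------------------------------------------------


def ca_axis1_oracle(A: np.ndarray) -> np.ndarray:
    """Eigen-decomposition correspondence analysis, first non-trivial axis.

    Site scores with weighted (row-mass) unit variance times sqrt(eigenvalue),
    matching the reciprocal-averaging scaling.
    """
    r = A.sum(axis=1)
    c = A.sum(axis=0)
    total = A.sum()
    S = np.diag(r**-0.5) @ (A - np.outer(r, c) / total) @ np.diag(c**-0.5)
    U, sv, _ = linalg.svd(S, full_matrices=False)
    x = U[:, 0] / np.sqrt(r)
    x = x - np.average(x, weights=r)
    x = x / np.sqrt(np.average(x**2, weights=r))
    return x * sv[0]  # first eigenvalue is sv^2; scores scale by its root


class TestDCA:
    def rand_matrix(self, seed, n=12, m=8):
        rng = np.random.default_rng(seed)
        g = np.sort(rng.uniform(0, 10, n))
        u = rng.uniform(0, 10, m)
        A = np.exp(-((g[:, None] - u[None, :]) ** 2) / 8.0) + 0.01
        return pd.DataFrame(
            A,
            index=[f"site{i}" for i in range(n)],
            columns=[f"sp{j}" for j in range(m)],
        )

    @given(st.integers(0, 10_000))
    def test_matches_svd_oracle_up_to_sign(self, seed):
        M = self.rand_matrix(seed)
        scores = dca_axis1(M).to_numpy()
        oracle = ca_axis1_oracle(M.to_numpy())
        # scale both to weighted unit variance and compare up to sign
        r = M.to_numpy().sum(axis=1)
        a = scores / np.sqrt(np.average(scores**2, weights=r))
        b = oracle / np.sqrt(np.average(oracle**2, weights=r))
        err = min(np.abs(a - b).max(), np.abs(a + b).max())
        assert err < 1e-6

    def test_eigenvalue_scaling(self):
        # weighted variance of the scores equals the first CA eigenvalue
        M = self.rand_matrix(3)
        A = M.to_numpy()
        scores = dca_axis1(M).to_numpy()
        r = A.sum(axis=1)
        c = A.sum(axis=0)
        total = A.sum()
        S = (
            np.diag(1 / np.sqrt(r))
            @ (A - np.outer(r, c) / total)
            @ np.diag(1 / np.sqrt(c))
        )
        lam = linalg.svd(S, compute_uv=False)[0] ** 2
        assert np.average(scores**2, weights=r) == pytest.approx(lam, rel=1e-8)

    def test_row_permutation_equivariance(self):
        M = self.rand_matrix(7)
        perm = np.random.default_rng(1).permutation(len(M))
        s1 = dca_axis1(M)
        s2 = dca_axis1(M.iloc[perm])
        pd.testing.assert_series_equal(s1.loc[s2.index], s2, atol=1e-9, rtol=0)

    def test_orientation_deterministic(self):
        M = self.rand_matrix(9)
        dominant = M.sum(axis=0).idxmax()
        scores = dca_axis1(M)
        rel = M[dominant] / M.sum(axis=1)
        assert np.corrcoef(scores, rel)[0, 1] > 0

    def test_all_zero_rows_dropped_with_warning(self):
        M = self.rand_matrix(2)
        M.iloc[4] = 0.0
        with pytest.warns(UserWarning, match="all-zero"):
            scores = dca_axis1(M)
        assert "site4" not in scores.index

    def test_too_small_matrix_rejected(self):
        M = pd.DataFrame(np.ones((2, 2)))
        with pytest.raises(ValueError, match=">= 3 sites"):
            dca_axis1(M)

    def test_rank_deficient_rejected(self):
        # identical rows carry no gradient
        M = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (5, 1)))
        with pytest.raises(ValueError, match="rank < 2"):
            dca_axis1(M)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


class TestReefIndexSet:
    def test_bundle_values(self, survey_obs):
        table = species_bsi_table([survey_obs], min_colonies=1)
        rec = reef_index_set(survey_obs, table)
        n, c2, c3, c4 = survey_obs.category_counts()
        assert rec.bsi == pytest.approx(bleaching_severity(n, c2, c3, c4))
        assert rec.richness == 3
        assert rec.rfi is None and rec.dca1 is None
        assert 1.0 <= rec.diversity_n1 <= 3.0
        d = rec.as_dict()
        assert set(d) == {
            "site_id", "date", "depth", "bsi", "si_reef", "rfi",
            "richness", "diversity_n1", "dca1",
        }
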