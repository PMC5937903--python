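"""Tests for the per-analyte screen, q-values and correlation matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from carotenome.abundance import CarotenoidTable, filter_detection, median_center
from carotenome.errors import InvalidPValueError
from carotenome.screening import (
    carotenoid_correlations,
    estimate_pi0,
    proteome_correlation_matrix,
    qvalues,
    screen,
)
from carotenome.synthdata import (
    TruthTable,
    generate_carotenoids,
    generate_design,
    generate_proteome,
)

from conftest import brute_force_qvalues


class TestQValues:
    def test_step_up_hand_example(self):
        """p = (.01, .02, .03, .04) with pi0 = 1 all collapse to 0.04."""
        q = qvalues(np.array([0.01, 0.02, 0.03, 0.04]), pi0=1.0)
        assert np.allclose(q, 0.04)

    def test_all_ones(self):
        q = qvalues(np.ones(10), pi0=1.0)
        assert np.allclose(q, 1.0)
        q = qvalues(np.ones(10), pi0=0.6)
        assert np.allclose(q, 0.6)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_tail_scan(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 40))
        q = qvalues(p, pi0=1.0)
        assert np.allclose(q, brute_force_qvalues(p, pi0=1.0), atol=1e-12)

    def test_order_preserving(self, rng):
        p = np.sort(rng.random(200))
        q = qvalues(p, pi0=1.0)
        assert (np.diff(q) >= -1e-15).all()

    def test_invalid_inputs(self):
        with pytest.raises(InvalidPValueError):
            qvalues(np.array([0.5, 1.5]))
        with pytest.raises(InvalidPValueError):
            qvalues(np.array([0.5, -0.1]))
        with pytest.raises(InvalidPValueError):
            qvalues(np.array([0.5, np.nan]))

    def test_pi0_smoother_on_enriched_nulls(self, rng):
        """A mixture with a signal spike near zero yields pi0 < 1; a pure
        uniform sample yields pi0 near 1."""
        null = rng.random(900)
        signal = rng.random(100) * 1e-4
        pi0 = estimate_pi0(np.concatenate([null, signal]))
        assert 0.5 < pi0 <= 1.0
        pi0_null = estimate_pi0(rng.random(2000))
        assert pi0_null > 0.8

    def test_small_m_falls_back_to_bh(self, rng):
        p = rng.random(30)
        assert np.allclose(qvalues(p), qvalues(p, pi0=1.0))


def simulate_screen_inputs(seed, n_plexes=12, per_plex=7, n_proteins=30,
                           slopes=None, sigma_B=0.4, sigma_e=0.5):
    """Small fully detected study with planted slopes."""
    slopes = slopes or {}
    design = generate_design(n_plexes, per_plex, seed=seed)
    m = generate_proteome(design, n_proteins, n_proteins, 0, 1.0, seed=seed + 1)
    named = {m.proteins[i]: s for i, s in slopes.items()}
    truth = TruthTable(slopes=named, b0_true=-3.0, sigma_B=sigma_B,
                       sigma_e=sigma_e, detection_limit=1e-9)
    caro = generate_carotenoids(m, {"beta_carotene": truth}, design, seed=seed + 2)
    return m, caro, named


class TestScreen:
    def test_true_protein_ranks_first(self):
        """A strong planted slope attains the smallest q among nulls."""
        m, caro, named = simulate_screen_inputs(100, slopes={0: 1.0})
        res = screen("beta_carotene", m, caro)
        assert res.audit.iloc[0]["protein_id"] == list(named)[0]
        assert res.audit.iloc[0]["q"] == res.audit["q"].min()
        assert len(res.records) >= 1

    def test_nested_q_strata(self):
        m, caro, _ = simulate_screen_inputs(101, slopes={0: 1.0, 1: 0.5})
        res10 = screen("beta_carotene", m, caro, q_threshold=0.10)
        res01 = screen("beta_carotene", m, caro, q_threshold=0.01)
        assert set(res01.records["protein_id"]) <= set(res10.records["protein_id"])

    def test_sign_fidelity(self):
        """Planted positive and negative slopes give matching signs of r
        and the percent-change effect in every detected record."""
        m, caro, named = simulate_screen_inputs(
            102, slopes={0: 0.8, 1: -0.8})
        res = screen("beta_carotene", m, caro)
        for pid, s in named.items():
            row = res.records[res.records["protein_id"] == pid]
            assert len(row) == 1
            assert np.sign(row["r"].iloc[0]) == np.sign(s)
            assert np.sign(row["b1_pct"].iloc[0]) == np.sign(s)
        assert (res.records["R2"] == res.records["r"] ** 2).all()

    def test_empty_protein_set(self):
        m, caro, _ = simulate_screen_inputs(103)
        empty = m.subset(m.proteins[:0])
        res = screen("beta_carotene", empty, caro)
        assert len(res.records) == 0 and len(res.audit) == 0

    def test_all_below_lod_analyte_skipped(self):
        m, caro, _ = simulate_screen_inputs(104)
        caro.below_lod.loc[:, "beta_carotene"] = True
        res = screen("beta_carotene", m, caro)
        assert len(res.audit) == 0
        assert len(res.excluded_samples) == len(caro.concentrations)

    def test_audit_counts_complete(self):
        """#audit records + #skips = #proteins offered to the screen."""
        m, caro, _ = simulate_screen_inputs(105, n_proteins=25)
        # make one protein constant so it is skipped
        m.values.iloc[:, 3] = 0.0
        res = screen("beta_carotene", m, caro)
        assert len(res.audit) + len(res.skipped) == 25
        assert (res.skipped["protein_id"] == m.proteins[3]).any()

    def test_null_screen_p_calibration(self):
        """All-null screen: fraction of p < 0.05 inside the binomial band
        (200 independent proteins)."""
        m, caro, _ = simulate_screen_inputs(106, n_proteins=200)
        res = screen("beta_carotene", m, caro)
        frac = (res.audit["p"] < 0.05).mean()
        half = 1.96 * np.sqrt(0.05 * 0.95 / 200)
        assert 0.05 - half <= frac <= 0.05 + half


class TestCarotenoidCorrelations:
    def test_structure_and_extremes(self, rng):
        idx = [f"s{i}" for i in range(30)]
        a = np.exp2(rng.normal(size=30))
        t = CarotenoidTable(concentrations=pd.DataFrame(
            {"a": a, "b": 1.0 / a, "c": np.exp2(rng.normal(size=30))}, index=idx))
        cm = carotenoid_correlations(t)
        assert np.allclose(np.diag(cm.r), 1.0)
        assert cm.r.loc["a", "b"] == pytest.approx(-1.0)
        pd.testing.assert_frame_equal(cm.r, cm.r.T)
        assert cm.p.loc["a", "b"] < 1e-10

    def test_pairwise_complete_hand_check(self):
        """Missingness pattern: the pair correlation uses only intersecting
        samples, verified against the direct formula."""
        conc = pd.DataFrame({
            "a": [0.1, 0.2, 0.4, 0.8, np.nan, 0.3],
            "b": [0.2, 0.1, 0.8, np.nan, 0.5, 0.9],
        }, index=[f"s{i}" for i in range(6)])
        flags = pd.DataFrame(False, index=conc.index, columns=conc.columns)
        flags.loc["s0", "b"] = True  # below LOD: excluded for b only
        t = CarotenoidTable(concentrations=conc, below_lod=flags)
        cm = carotenoid_correlations(t)
        # complete pairs: s1, s2, s5
        xa = np.log2([0.2, 0.4, 0.3])
        xb = np.log2([0.1, 0.8, 0.9])
        expect = np.corrcoef(xa, xb)[0, 1]
        assert cm.r.loc["a", "b"] == pytest.approx(expect, abs=1e-12)
        assert cm.n.loc["a", "b"] == 3

    def test_insufficient_pairs_flagged(self):
        conc = pd.DataFrame({
            "a": [0.1, 0.2, np.nan, np.nan],
            "b": [np.nan, 0.1, 0.5, 0.4],
        }, index=list("wxyz"))
        t = CarotenoidTable(concentrations=conc)
        cm = carotenoid_correlations(t)
        assert np.isnan(cm.r.loc["a", "b"])

    def test_needs_two_analytes(self):
        t = CarotenoidTable(concentrations=pd.DataFrame({"a": [0.1, 0.2]}))
        with pytest.raises(ValueError):
            carotenoid_correlations(t)


class TestProteomeCorrelationMatrix:
    def test_toy_matrix_and_ordering(self):
        m, caro, named = simulate_screen_inputs(
            107, slopes={0: 0.9, 1: -0.9, 2: 0.6})
        res = screen("beta_carotene", m, caro)
        mat = proteome_correlation_matrix(res.audit, m, q_cut=0.05)
        pids = list(mat.index)
        planted = list(named)
        assert set(planted) <= set(pids)
        # positives (ascending q) come before negatives
        rs = {row["protein_id"]: row["r"] for _, row in res.audit.iterrows()}
        signs = [rs[p] >= 0 for p in pids]
        assert signs == sorted(signs, reverse=True)
        assert np.allclose(np.diag(mat), 1.0)
        # hand check one off-diagonal entry
        a, b = pids[0], pids[1]
        sub = m.analytic_values[[a, b]].dropna()
        expect = np.corrcoef(sub[a], sub[b])[0, 1]
        assert mat.loc[a, b] == pytest.approx(expect, abs=1e-12)

    def test_duplicated_protein_correlates_perfectly(self):
        m, caro, _ = simulate_screen_inputs(108, slopes={0: 0.9})
        m.values["dup"] = m.values[m.proteins[0]]
        res = screen("beta_carotene", m, caro)
        mat = proteome_correlation_matrix(res.audit, m, q_cut=0.05)
        p0 = m.proteins[0]
        assert mat.loc[p0, "dup"] == pytest.approx(1.0)
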