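"""Normalization, BH, DE, %CV and concordance — checked against independent
brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from evrna.simulate import PlantedEffect, SimulationDesign, choose_expressed_rows, \
    simulate_cohort, simulate_reference
from evrna.stats import (
    DEResult,
    bh_adjust,
    concordance_overlap,
    detection_overlap,
    filter_expressed,
    nb_wald_de,
    normalize,
    percent_cv,
    percent_cv_comparison,
    size_factors,
)

from conftest import small_design, seq_to_gene_id


def brute_force_size_factors(counts: np.ndarray) -> np.ndarray:
    """Independent median-of-ratios oracle: plain loops, no shared code."""
    genes, samples = counts.shape
    ref = []
    for g in range(genes):
        if all(counts[g, j] > 0 for j in range(samples)):
            prod = 1.0
            for j in range(samples):
                prod *= counts[g, j]
            ref.append((g, prod ** (1.0 / samples)))
    out = []
    for j in range(samples):
        ratios = sorted(counts[g, j] / gm for g, gm in ref)
        k = len(ratios)
        med = ratios[k // 2] if k % 2 else 0.5 * (ratios[k // 2 - 1] + ratios[k // 2])
        out.append(med)
    return np.array(out)


def brute_force_bh(p: list[float]) -> list[float]:
    """Step-up BH by direct definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank, 1.0)
        adj[i] = val
        prev = val
    return adj


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        c = pd.DataFrame(np.tile([[5], [10], [100]], (1, 4)))
        assert np.allclose(size_factors(c), 1.0)

    def test_doubled_column_gets_double_factor(self):
        a = np.array([[5, 10], [10, 20], [50, 100]])
        sf = size_factors(pd.DataFrame(a))
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(42)
        c = rng.integers(0, 50, size=(50, 10))
        c[0] += 1  # ensure at least one all-nonzero gene
        got = size_factors(pd.DataFrame(c)).to_numpy()
        want = brute_force_size_factors(c.astype(float))
        assert np.allclose(got, want, rtol=0, atol=1e-12)

    def test_no_reference_gene_raises(self):
        c = pd.DataFrame([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="filter"):
            size_factors(c)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_nan_passthrough_excluded_from_denominator(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(0.02)  # m = 2, not 3

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_brute_force_and_is_monotone(self, p):
        got = bh_adjust(p)
        want = brute_force_bh(p)
        assert np.allclose(got, want, atol=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(np.asarray(got)[order]) >= -1e-12)
        assert np.all(np.asarray(got) >= np.asarray(p) - 1e-12)


class TestFilterExpressed:
    def test_count_11_in_half_of_samples_kept(self):
        c = pd.DataFrame([[11, 11, 0, 0]])
        assert 0 in filter_expressed(c)

    def test_count_10_everywhere_dropped(self):
        c = pd.DataFrame([[10, 10, 10, 10]])
        assert 0 not in filter_expressed(c)

    def test_zero_thresholds_keep_all(self):
        c = pd.DataFrame([[0, 1], [5, 0]])
        assert len(filter_expressed(c, min_count=-1, min_frac=0)) == 2


class TestNBWaldDE:
    def test_identical_constant_groups_give_zero_lfc(self):
        c = pd.DataFrame(np.full((5, 8), 50), columns=[f"s{i}" for i in range(8)])
        de = nb_wald_de(c, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        assert np.allclose(de.table["log2fc"], 0.0)

    def test_lfc_sign_matches_normalized_mean_difference(self):
        d = small_design(seed=37, n_per_group={"control": 10, "AD": 10})
        ref = simulate_reference(d)
        md, mat = simulate_cohort(d, ref)
        g1 = list(md.index[md["group"] == "control"])
        g2 = list(md.index[md["group"] == "AD"])
        de = nb_wald_de(mat.counts, g1, g2)
        q = mat.counts[g1 + g2] / size_factors(mat.counts[g1 + g2])
        diff = q[g2].mean(axis=1) - q[g1].mean(axis=1)
        nonzero = diff.abs() > 1e-9
        assert np.all(np.sign(de.table.loc[nonzero, "log2fc"])
                      == np.sign(diff[nonzero]))

    def test_planted_effect_is_detected(self):
        d0 = small_design(seed=41, n_per_group={"control": 15, "AD": 15})
        ref = simulate_reference(d0)
        rows = choose_expressed_rows(d0, ref)[:5]
        d = SimulationDesign(**{**vars(d0),
                                "planted_effects": [PlantedEffect(rows, "AD", 2.0)]})
        md, mat = simulate_cohort(d, ref)
        de = nb_wald_de(mat.counts,
                        list(md.index[md["group"] == "control"]),
                        list(md.index[md["group"] == "AD"]))
        gids = seq_to_gene_id(mat, ref, rows)
        assert (de.table.loc[gids, "padj"] < 0.05).all()

    def test_padj_at_least_p(self):
        d = small_design(seed=43)
        ref = simulate_reference(d)
        md, mat = simulate_cohort(d, ref)
        de = nb_wald_de(mat.counts,
                        list(md.index[md["group"] == "control"]),
                        list(md.index[md["group"] == "AD"]))
        t = de.table.dropna(subset=["p"])
        assert (t["padj"] >= t["p"] - 1e-12).all()

    def test_small_groups_rejected(self):
        c = pd.DataFrame(np.ones((3, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            nb_wald_de(c, ["a"], ["b", "c"])


class TestPercentCV:
    def test_constant_gene_has_zero_cv(self):
        v = pd.DataFrame([[5.0, 5.0, 5.0]])
        assert percent_cv(v)[0] == pytest.approx(0.0)

    def test_one_two_three_gives_fifty_percent(self):
        v = pd.DataFrame([[1.0, 2.0, 3.0]])
        assert percent_cv(v)[0] == pytest.approx(50.0)

    def test_zero_mean_gene_excluded(self):
        v = pd.DataFrame([[0.0, 0.0, 0.0]])
        assert np.isnan(percent_cv(v)[0])

    def test_comparison_requires_enough_genes(self):
        a = pd.DataFrame(np.ones((1, 3)))
        with pytest.raises(ValueError):
            percent_cv_comparison(a, a)

    def test_welch_statistic_matches_manual_computation(self):
        rng = np.random.default_rng(7)
        a = pd.DataFrame(rng.uniform(50, 200, size=(30, 6)))
        b = pd.DataFrame(rng.uniform(50, 400, size=(30, 6)))
        res = percent_cv_comparison(a, b, min_count=0, min_frac=0)
        x, y = res.cv_a.to_numpy(), res.cv_b.to_numpy()
        # Welch t by its textbook formula
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = 2 * sps.t.sf(abs(t), df)
        assert res.t_stat == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)


class TestOverlap:
    def _matrix(self, cols, tiny_reference):
        table = pd.DataFrame(cols)
        table.index.name = "sequence"
        from evrna.containers import build_count_matrix

        return build_count_matrix(table.fillna(0).astype(int), tiny_reference)

    def test_disjoint_and_identical(self, tiny_reference):
        s = [e.sequence for e in tiny_reference.entries]
        a = self._matrix({"A": {s[0]: 5, s[3]: 0}}, tiny_reference)
        b = self._matrix({"B": {s[0]: 0, s[3]: 7}}, tiny_reference)
        ov = detection_overlap(a, b)
        assert ov.n_both == 0 and ov.n_a_only == 1 and ov.n_b_only == 1
        ov2 = detection_overlap(a, a)
        assert ov2.n_a_only == ov2.n_b_only == 0 and ov2.n_both == 1

    def test_partition_is_exhaustive_per_biotype(self, tiny_reference):
        s = [e.sequence for e in tiny_reference.entries]
        a = self._matrix({"A": {x: 1 for x in s[:5]}}, tiny_reference)
        b = self._matrix({"B": {x: 1 for x in s[3:]}}, tiny_reference)
        ov = detection_overlap(a, b)
        total = ov.per_biotype.to_numpy().sum()
        assert total == ov.n_both + ov.n_a_only + ov.n_b_only == len(set(s))


def _de(table: dict) -> DEResult:
    df = pd.DataFrame(table).T
    df.columns = ["log2fc", "p"]
    df["padj"] = bh_adjust(df["p"])
    return DEResult(table=df)


class TestConcordance:
    def test_identical_results_fully_concordant(self):
        de = _de({"g1": [1.0, 0.01], "g2": [-2.0, 0.001], "g3": [0.5, 0.2]})
        c = concordance_overlap(de, de)
        assert c.shared == ["g1", "g2"]
        assert c.n_concordant == 2 and c.n_discordant == 0
        assert c.fraction_concordant == 1.0

    def test_flipped_sign_is_discordant(self):
        a = _de({"g1": [1.0, 0.01]})
        b = _de({"g1": [-1.0, 0.01]})
        assert concordance_overlap(a, b).n_discordant == 1

    def test_toy_sets_match_enumeration(self):
        a = _de({"g1": [1, 0.01], "g2": [-1, 0.02], "g3": [1, 0.3],
                 "g4": [1, 0.04], "g5": [-1, 0.9]})
        b = _de({"g1": [2, 0.03], "g2": [1, 0.01], "g3": [1, 0.01],
                 "g4": [-1, 0.5], "g5": [-2, 0.02]})
        c = concordance_overlap(a, b)
        # significant in a: g1, g2, g4; in b: g1, g2, g3, g5
        # shared: g1 (+/+ concordant), g2 (-/+ discordant)
        assert set(c.shared) == {"g1", "g2"}
        assert c.n_concordant == 1 and c.n_discordant == 1
        assert c.a_only == ["g4"] and sorted(c.b_only) == ["g3", "g5"]
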