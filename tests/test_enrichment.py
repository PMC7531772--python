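"""Permutation tests, FDR and the depletion contrast."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repevo import (
    CladePartition,
    CountMatrix,
    bh_fdr,
    clade_enrichment_scan,
    depletion_contrast,
    fisher_pitman,
)
from repevo.enrichment import enrichment_table


class TestFisherPitman:
    def test_identical_groups_p_one(self):
        stat, p = fisher_pitman([1, 2, 3], [1, 2, 3])
        assert stat == 0.0
        assert p == 1.0

    def test_extreme_separation_exact_p(self):
        # only the observed split and its mirror reach |T|: p = 2/C(6,3)
        stat, p = fisher_pitman([10, 11, 12], [1, 2, 3])
        assert stat == pytest.approx(9.0)
        assert p == pytest.approx(2 / 20)

    def test_exact_matches_own_enumeration(self):
        """Independent oracle: direct enumeration of all splits."""
        rng = np.random.default_rng(2)
        a = rng.poisson(5, size=4).astype(float)
        b = rng.poisson(3, size=5).astype(float)
        _, p = fisher_pitman(a, b)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        hits = 0
        total = 0
        for ix in combinations(range(9), 4):
            ga = pooled[list(ix)]
            gb = np.delete(pooled, list(ix))
            total += 1
            if abs(ga.mean() - gb.mean()) >= obs - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / total)

    def test_exact_within_3se_of_monte_carlo_oracle(self):
        """The package's exact p agrees with an independent MC estimate."""
        rng = np.random.default_rng(7)
        a = rng.normal(0.8, 1, size=7)
        b = rng.normal(0.0, 1, size=7)
        assert comb(14, 7) <= 20_000  # exact path taken
        _, p_exact = fisher_pitman(a, b)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        B = 10_000
        hits = 0
        for _ in range(B):
            perm = rng.permutation(pooled)
            if abs(perm[:7].mean() - perm[7:].mean()) >= obs - 1e-12:
                hits += 1
        p_mc = hits / B
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / B)
        assert abs(p_exact - p_mc) <= 3 * se

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            fisher_pitman([1.0], [1.0, 2.0])

    def test_n_perm_floor(self):
        with pytest.raises(ValueError):
            fisher_pitman([1, 2], [3, 4], n_perm=10)


class TestBhFdr:
    def test_textbook_sequence(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equal_p_fixed_point(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_matches_step_up_formula(self):
        """Cross-check against the direct step-up definition."""
        rng = np.random.default_rng(9)
        p = rng.uniform(size=25)
        q = bh_fdr(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            expected[i] = running
        assert np.allclose(q, expected)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_permutation_equivariance_and_bounds(self, p, rnd):
        q = bh_fdr(p)
        assert (q <= 1 + 1e-12).all() and (q >= 0).all()
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q2 = bh_fdr([p[i] for i in perm])
        assert sorted(np.round(q, 12)) == sorted(np.round(q2, 12))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def two_clade_matrix(counts: np.ndarray, n_a: int, tags=None):
    n, m = counts.shape
    taxa = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n - n_a)]
    data = pd.DataFrame(counts, index=taxa, columns=[f"og{j}" for j in range(m)])
    part = CladePartition(
        {"A": frozenset(taxa[:n_a]), "B": frozenset(taxa[n_a:])}
    )
    return CountMatrix(data, tags=tags), part


class TestEnrichmentScan:
    def test_identical_rows_nothing_significant(self):
        counts = np.tile([3, 1, 4, 1, 5], (8, 1))
        matrix, part = two_clade_matrix(counts, 4)
        res = clade_enrichment_scan(matrix, part, "A", "B", seed=0)
        assert all(r.direction == "none" for r in res)
        assert all(r.p == 1.0 for r in res)

    def test_swapping_clades_flips_direction_only(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson([8, 2, 5], size=(10, 3))
        matrix, part = two_clade_matrix(counts, 5)
        counts[:5, 0] += 8  # enrich og0 in clade A
        matrix, part = two_clade_matrix(counts, 5)
        ab = clade_enrichment_scan(matrix, part, "A", "B", seed=0)
        ba = clade_enrichment_scan(matrix, part, "B", "A", seed=0)
        for r1, r2 in zip(ab, ba):
            assert r1.p == pytest.approx(r2.p, abs=1e-12)
            assert r1.statistic == pytest.approx(-r2.statistic)
            if r1.direction == "enriched_in_a":
                assert r2.direction == "depleted_in_a"

    def test_all_zero_orthogroup_flagged_p_one(self):
        counts = np.array([[1, 0], [2, 0], [3, 0], [4, 0]])
        matrix, part = two_clade_matrix(counts, 2)
        res = clade_enrichment_scan(matrix, part, "A", "B", seed=0)
        assert res[1].all_zero and res[1].p == 1.0

    def test_depleted_orthogroups_recovered(self):
        """Strong clade depletion (Poisson 10 vs 1) is detected at q < 0.1."""
        rng = np.random.default_rng(42)
        n_og, n_dep = 50, 5
        lam = np.full((16, n_og), 10.0)
        lam[8:, :n_dep] = 1.0  # clade B depleted on first five orthogroups
        counts = rng.poisson(lam)
        matrix, part = two_clade_matrix(counts, 8)
        res = clade_enrichment_scan(matrix, part, "A", "B", seed=1)
        table = enrichment_table(res)
        dep = table.iloc[:n_dep]
        assert (dep.q < 0.1).all()
        assert (dep.direction == "enriched_in_a").all()

    def test_overlapping_clades_rejected(self):
        counts = np.ones((6, 2), dtype=int)
        matrix, part = two_clade_matrix(counts, 3)
        with pytest.raises(ValueError):
            clade_enrichment_scan(matrix, part, ["A", "B"], "B", seed=0)


class TestDepletionContrast:
    def make(self, totals_a, totals_b, focal_idx, n_a=2, n_b=2):
        m = len(totals_a)
        rows_a = [np.array(totals_a) - np.array(totals_a) // 2]
        rows_a.append(np.array(totals_a) - rows_a[0])
        rows_b = [np.array(totals_b) - np.array(totals_b) // 2]
        rows_b.append(np.array(totals_b) - rows_b[0])
        counts = np.vstack(rows_a + rows_b)
        ogs = [f"og{j}" for j in range(m)]
        tags = {"focal": [ogs[i] for i in focal_idx]}
        return two_clade_matrix(counts, 2, tags=tags)

    def test_equal_totals_give_zero_log_ratio(self):
        matrix, part = self.make([10, 6], [10, 4], [0])
        dep = depletion_contrast(matrix, part, "A", "B")
        assert dep.ratios.loc[0, "d"] == pytest.approx(0.0)

    def test_pseudocount_formula(self):
        matrix, part = self.make([10, 2], [5, 2], [0])
        dep = depletion_contrast(matrix, part, "A", "B", pseudocount=1.0)
        assert dep.ratios.loc[0, "d"] == pytest.approx(np.log(11 / 6))

    def test_exact_wilcoxon_worked_example(self):
        """Focal d below all background d: W = 6, exact two-sided p = 0.1."""
        # totals chosen so focal d = ln(2/12), ln(3/12), ln(4/12) and
        # background d = ln(12/2), ln(13/2), ln(14/2): complete separation
        matrix, part = self.make(
            [1, 2, 3, 11, 12, 13], [11, 11, 11, 1, 1, 1], [0, 1, 2]
        )
        dep = depletion_contrast(matrix, part, "A", "B")
        assert dep.exact
        assert dep.w_statistic == 6.0
        assert dep.p == pytest.approx(0.1)

    def test_exact_matches_enumeration_oracle(self):
        """Exhaustive rank-sum null for tie-free groups of size <= 5."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            d = rng.normal(size=na + nb)
            if len(np.unique(d)) < na + nb:
                continue
            focal, back = d[:na], d[na:]
            ranks = pd.Series(d).rank().to_numpy()
            w_obs = ranks[:na].sum()
            mean_w = na * (na + nb + 1) / 2
            hits = sum(
                abs(ranks[list(ix)].sum() - mean_w) >= abs(w_obs - mean_w) - 1e-12
                for ix in combinations(range(na + nb), na)
            )
            expected_p = hits / comb(na + nb, na)
            matrix_rows = np.concatenate([focal, back])
            # feed the d values through the contrast by constructing totals
            ta = np.round(1000 * np.exp(matrix_rows)).astype(int)
            tb = np.full_like(ta, 1000)
            matrix, part = self.make(ta, tb, list(range(na)))
            dep = depletion_contrast(matrix, part, "A", "B", pseudocount=1e-9)
            assert dep.p == pytest.approx(expected_p, abs=5e-3)

    def test_empty_focal_rejected(self):
        matrix, part = self.make([1, 2], [3, 4], [])
        with pytest.raises(ValueError, match="focal"):
            depletion_contrast(matrix, part, "A", "B")
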