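"""QC cascade: per-locus stats, HWE exact test, Mendel filter, LD pruning."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsfparentage.qcfilter import (FilterConfig, TrioSet, build_subsets,
                                   hwe_exact_pvalue, ld_r2, marker_stats,
                                   mendel_error_rate, prune_ld, run_cascade)

from conftest import make_matrix


class TestMarkerStats:
    def test_direct_counts(self):
        m = make_matrix(np.array([[0], [1], [1], [2]]))
        s = marker_stats(m)
        assert s.loc[0, "maf"] == pytest.approx(0.5)
        assert s.loc[0, "obs_het"] == pytest.approx(0.5)

    def test_call_rate_with_missing(self):
        m = make_matrix(np.array([[0], [1], [-1]]))
        assert marker_stats(m).loc[0, "call_rate"] == pytest.approx(2 / 3)

    def test_maf_one_sixth(self):
        m = make_matrix(np.array([[0], [0], [1]]))
        assert marker_stats(m).loc[0, "maf"] == pytest.approx(1 / 6)

    def test_zero_calls_flagged(self):
        m = make_matrix(np.array([[-1], [-1]]))
        s = marker_stats(m)
        assert s.loc[0, "call_rate"] == 0.0
        assert np.isnan(s.loc[0, "maf"])


def hwe_pvalue_oracle(naa, nab, nbb):
    """Exact conditional HWE p-value via the multinomial pairing distribution.

    Independent of the implementation: probabilities from integer
    combinatorics, P(nab) = [n! / (naa! nab! nbb!)] 2^nab / C(2n, na).
    """
    n = naa + nab + nbb
    na = 2 * naa + nab
    nminor = min(na, 2 * n - na)
    if nminor == 0:
        return 1.0
    probs = {}
    for h in range(nminor % 2, nminor + 1, 2):
        a = (nminor - h) // 2
        b = n - h - a
        probs[h] = (math.factorial(n) // (math.factorial(a) * math.factorial(h)
                                          * math.factorial(b))) * 2**h
    total = sum(probs.values())
    obs_h = nab if na == nminor else nab  # het count is symmetric in allele label
    obs = probs[obs_h]
    return sum(v for v in probs.values() if v <= obs) / total


def hwe_pvalue_brute(naa, nab, nbb):
    """Tiny-n oracle: enumerate every distinct assignment of the allele
    multiset into ordered genotype pairs."""
    n = naa + nab + nbb
    alleles = [0] * (2 * naa + nab) + [1] * (2 * nbb + nab)
    counts = {}
    for perm in set(itertools.permutations(alleles)):
        het = sum(perm[2 * i] != perm[2 * i + 1] for i in range(n))
        counts[het] = counts.get(het, 0) + 1
    total = sum(counts.values())
    obs = counts[nab]
    return sum(v for v in counts.values() if v <= obs) / total


class TestHWE:
    def test_extreme_het_excess(self):
        assert hwe_exact_pvalue(0, 50, 0) < 1e-10

    def test_two_configuration_case(self):
        assert hwe_exact_pvalue(1, 0, 1) == pytest.approx(1 / 3)

    def test_monomorphic_returns_one(self):
        assert hwe_exact_pvalue(7, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [(4, 0, 4), (3, 3, 2), (2, 5, 1),
                                        (10, 0, 10), (5, 10, 5), (1, 1, 18),
                                        (0, 20, 0), (7, 6, 7)])
    def test_matches_combinatorial_oracle(self, counts):
        assert hwe_exact_pvalue(*counts) == pytest.approx(
            hwe_pvalue_oracle(*counts), abs=1e-12)

    @given(st.tuples(st.integers(0, 2), st.integers(0, 2), st.integers(0, 2))
           .filter(lambda t: 1 <= sum(t) <= 4))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_brute_force_enumeration(self, counts):
        assert hwe_exact_pvalue(*counts) == pytest.approx(
            hwe_pvalue_brute(*counts), abs=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue(-1, 0, 1)
        with pytest.raises(ValueError):
            hwe_exact_pvalue(0, 0, 0)


class TestMendel:
    def _matrix(self, trio_calls):
        m = make_matrix(np.asarray(trio_calls).T,
                        parents={"s2": ("s0", "s1")})
        return m, TrioSet.from_samples(m.samples)

    def test_homref_parents_het_child_is_error(self):
        m, trios = self._matrix([[0, 0, 1]])
        assert mendel_error_rate(m, trios)[0] == 1.0

    def test_het_parents_any_child_consistent(self):
        for child in (0, 1, 2):
            m, trios = self._matrix([[1, 1, child]])
            assert mendel_error_rate(m, trios)[0] == 0.0

    def test_missing_call_excludes_trio(self):
        m, trios = self._matrix([[0, -1, 2]])
        assert np.isnan(mendel_error_rate(m, trios)[0])

    def test_rate_arithmetic(self):
        # 25 trios at one locus, one error -> rate 0.04
        calls = np.zeros((75, 1), dtype=np.int8)
        calls[2] = 2  # child of first trio is an opposing homozygote
        parents = {f"s{3 * k + 2}": (f"s{3 * k}", f"s{3 * k + 1}")
                   for k in range(25)}
        m = make_matrix(calls, parents=parents)
        trios = TrioSet.from_samples(m.samples)
        assert len(trios) == 25
        assert mendel_error_rate(m, trios)[0] == pytest.approx(0.04)


class TestLdR2:
    def test_identical_vectors(self):
        x = np.array([0, 1, 2, 1, 0])
        assert ld_r2(x, x) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert ld_r2(np.array([0, 0, 2, 2]),
                     np.array([0, 2, 0, 2])) == pytest.approx(0.0)

    def test_hand_computed_case(self):
        # hand Pearson: r = 1/2, r^2 = 1/4
        assert ld_r2(np.array([0, 1, 2, 1]),
                     np.array([0, 1, 1, 2])) == pytest.approx(0.25)

    def test_zero_variance_undefined(self):
        assert np.isnan(ld_r2(np.array([1, 1, 1]), np.array([0, 1, 2])))

    def test_pairwise_complete(self):
        x = np.array([0, 1, 2, 1, -1])
        y = np.array([0, 1, 2, -1, 2])
        assert ld_r2(x, y) == pytest.approx(1.0)  # complete pairs are identical


def greedy_prune_oracle(dose, positions, r2_max):
    """Independent re-implementation of the windowed greedy walk (one
    window covering everything, which holds for these small fixtures)."""
    kept = list(np.argsort(positions, kind="stable"))
    while True:
        worst, worst_r2 = None, r2_max
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                r2 = ld_r2(dose[:, kept[i]], dose[:, kept[j]])
                if not np.isnan(r2) and r2 > worst_r2:
                    worst_r2, worst = r2, j
        if worst is None:
            return sorted(kept)
        kept.pop(worst)


class TestPruneLd:
    def test_duplicated_locus_keeps_one(self):
        col = np.array([0, 1, 2, 1, 0, 2])
        m = make_matrix(np.stack([col, col], axis=1))
        assert len(prune_ld(m)) == 1

    def test_independent_loci_all_retained(self):
        rng = np.random.default_rng(17)
        calls = rng.integers(0, 3, (60, 8)).astype(np.int8)
        m = make_matrix(calls)
        r2 = np.array([[ld_r2(calls[:, a], calls[:, b]) for b in range(8)]
                       for a in range(8)])
        np.fill_diagonal(r2, 0)
        assert np.nanmax(r2) <= 0.5  # precondition of the scenario
        assert len(prune_ld(m)) == 8

    def test_correlated_chain_matches_manual_walk(self):
        rng = np.random.default_rng(23)
        base = rng.integers(0, 3, 40)
        # x2 ~ x1 (high r2), x3 mostly independent
        x2 = base.copy()
        x2[:4] = (x2[:4] + 1) % 3
        x3 = rng.integers(0, 3, 40)
        calls = np.stack([base, x2, x3], axis=1).astype(np.int8)
        m = make_matrix(calls)
        expected = greedy_prune_oracle(
            np.asarray(calls, dtype=float), m.loci["pos"].to_numpy(), 0.5)
        assert sorted(prune_ld(m)) == expected
        assert len(expected) == 2


# ---------------------------------------------------------------------------
# planted-failure cascade fixture: 10 samples x 12 loci, one planted
# violation per (enabled) filter step, trio-consistent everywhere except the
# planted Mendelian error.
# ---------------------------------------------------------------------------

def planted_matrix():
    #        L0 L1  L2  L3 L4  L5  L6 L7 L8 L9 L10 L11
    calls = [
        [0,  0,  0,  1, -1,  0,  0, 1, 0, 0, 0, 0],   # A0 (sire of A2)
        [0,  1,  0,  1,  0,  1,  1, 1, 0, 0, 1, 1],   # A1 (dam of A2)
        [0,  1,  0,  1,  0,  1,  1, 0, 0, 2, 1, 1],   # A2 (L9: Mendel error)
        [0,  2,  0,  1,  1,  2,  2, 2, 2, 1, 2, 2],   # A3
        [0,  0, -1, -1,  0, -1, -1, 0, 0, 0, 0, 0],   # A4 (40% missing)
        [0, -1,  0,  1,  2,  0,  0, 1, 2, 1, 0, 0],   # B0 (sire of B2)
        [0, -1,  0,  1,  2,  1,  1, 0, 2, 2, 1, 1],   # B1 (dam of B2)
        [0, -1,  0,  1,  2,  0,  0, 0, 2, 1, 0, 0],   # B2
        [0, -1,  1,  1,  1,  2,  2, 2, 0, 0, 2, 2],   # B3
        [0, -1,  1,  1,  1,  1,  1, 1, 1, 1, 1, 1],   # B4 (all-het sample)
    ]
    pos = [100, 200, 300, 400, 500, 600, 701, 700, 800, 900, 1000, 1100]
    rad = [f"rad{j}" for j in range(12)]
    rad[6] = rad[7] = "rad6"  # L6/L7 share a RAD locus; L7 is first by pos
    pos_in = [50] * 12
    pos_in[5] = 80  # L5 outside the 40-70 bp window
    loci = pd.DataFrame({"id": [f"L{j}" for j in range(12)], "chrom": "chr1",
                         "pos": pos, "rad_locus": rad, "pos_in_locus": pos_in})
    colonies = ["A"] * 5 + ["B"] * 5
    m = make_matrix(calls, colonies=colonies, loci=loci,
                    parents={"s2": ("s0", "s1"), "s7": ("s5", "s6")})
    return m


PLANTED_REMOVALS = {
    "monomorphic": 1,             # L0
    "shared_across_colonies": 1,  # L1 (missing in colony B)
    "sample_missingness": 1,      # A4
    "sample_heterozygosity": 1,   # B4 (all het)
    "maf": 1,                     # L2 (MAF 1/16)
    "mac": 0,                     # implied by the MAF filter at this n
    "obs_het": 1,                 # L3 (Ho = 1)
    "marker_missingness": 1,      # L4
    "rad_position_window": 1,     # L5
    "one_snp_per_rad_locus": 1,   # L6 (second SNP on rad6)
    "hwe": 1,                     # L8 (4/0/4, p ~ 0.025)
    "mendel_error": 1,            # L9 (opposing homozygote in trio A)
    "ld_prune": 1,                # L11 (duplicate of L10)
}


class TestCascade:
    def test_disabled_config_is_identity(self, truth_matrix):
        out, report = run_cascade(truth_matrix, config=FilterConfig.disabled())
        assert out.n_samples == truth_matrix.n_samples
        assert out.n_loci == truth_matrix.n_loci
        assert all(s.removed == 0 for s in report.steps)

    def test_each_planted_item_removed_by_its_step(self):
        m = planted_matrix()
        out, report = run_cascade(m)
        removed = {s.name: s.removed for s in report.steps}
        for step, n in PLANTED_REMOVALS.items():
            assert removed.get(step, 0) == n, step
        assert out.n_samples == 8
        assert sorted(out.locus_ids) == ["L10", "L7"]

    def test_report_telescopes(self):
        m = planted_matrix()
        _, report = run_cascade(m)
        ns, nl = m.n_samples, m.n_loci
        for s in report.steps:
            if s.axis == "samples":
                ns -= s.removed
            else:
                nl -= s.removed
            assert s.samples_remaining == ns
            assert s.markers_remaining == nl

    def test_idempotence_on_simulated_data(self, truth_matrix):
        # sample outlier screens are one-shot (their statistics are defined
        # against the full marker set), so idempotence is a marker-side
        # property: re-running the marker cascade on its output is a no-op
        cfg = FilterConfig(sample_median_depth_range=None,
                           marker_mean_depth_range=None,
                           sample_het_range=None, sample_max_missing=None)
        once, _ = run_cascade(truth_matrix, config=cfg)
        twice, report2 = run_cascade(once, config=cfg)
        assert twice.n_loci == once.n_loci
        assert twice.n_samples == once.n_samples
        assert all(s.removed == 0 for s in report2.steps)

    def test_tightening_maf_never_increases_survivors(self, truth_matrix):
        base = FilterConfig(sample_median_depth_range=None,
                            marker_mean_depth_range=None, ld_r2_max=None)
        loose, _ = run_cascade(truth_matrix, config=base)
        tight_cfg = FilterConfig(sample_median_depth_range=None,
                                 marker_mean_depth_range=None, ld_r2_max=None,
                                 marker_min_maf=0.42)
        tight, _ = run_cascade(truth_matrix, config=tight_cfg)
        assert set(tight.locus_ids) <= set(loose.locus_ids)

    def test_error_free_input_passes_mendel(self, truth_matrix):
        _, report = run_cascade(truth_matrix)
        mendel = [s for s in report.steps if s.name == "mendel_error"]
        assert mendel and mendel[0].removed == 0


class TestSubsets:
    def test_nested_and_strict(self):
        rng = np.random.default_rng(5)
        # genotype columns engineered to span the MAF tiers
        n = 200
        freqs = rng.uniform(0.35, 0.5, 120)
        calls = (rng.random((n, 120)) < freqs).astype(np.int8) + \
                (rng.random((n, 120)) < freqs).astype(np.int8)
        m = make_matrix(calls)
        panels = build_subsets(m, (0.40, 0.45, 0.47, 0.48))
        sizes = [p.n_loci for p in panels.values()]
        assert sizes == sorted(sizes, reverse=True)
        ids = [set(p.locus_ids) for p in panels.values()]
        assert ids[3] <= ids[2] <= ids[1] <= ids[0]
        maf = marker_stats(m)["maf"].to_numpy()
        # strict inequality at the boundary
        at_tier = np.flatnonzero(np.isclose(maf, 0.45))
        for j in at_tier:
            assert m.locus_ids[j] not in ids[1]

    def test_unsorted_tiers_rejected(self):
        m = make_matrix(np.array([[0], [1]]))
        with pytest.raises(ValueError):
            build_subsets(m, (0.45, 0.40))
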