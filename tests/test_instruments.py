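"""Instrument selection: PVE, F statistic, clumping, cis filtering, pleiotropy."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pqtlmr.gwas_io import LDMatrix
from pqtlmr.instruments import (
    GeneAnnotation,
    TraitCatalog,
    clump,
    compute_f_stat,
    compute_pve,
    flag_pleiotropy,
    select_instruments,
)
from pqtlmr.simulate import scenario_config, simulate_region

from conftest import make_stats, make_variant


class TestPVE:
    @pytest.mark.parametrize(
        "beta, se, n, expected",
        [
            (0.0, 0.1, 100, 0.0),
            (0.5, 0.05, 1000, 0.25 / 2.75),  # hand: 0.25/(0.25+1000*0.0025)
            (0.1, 0.1, 100, 0.01 / 1.01),  # hand: 0.01/(0.01+100*0.01)
        ],
    )
    def test_hand_values(self, beta, se, n, expected):
        assert compute_pve(beta, se, n) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_pve(0.1, 0.0, 100)
        with pytest.raises(ValueError):
            compute_pve(0.1, 0.1, 0)

    @given(
        beta=st.floats(-5, 5),
        se=st.floats(1e-4, 10),
        n=st.integers(1, 10**7),
    )
    def test_always_a_fraction(self, beta, se, n):
        assert 0 <= compute_pve(beta, se, n) < 1


class TestFStat:
    def test_zero_pve_gives_zero(self):
        assert compute_f_stat(0.0, 1000) == 0.0

    def test_hand_value(self):
        # pve = 1/11 from the (0.5, 0.05, 1000) example; F = (1/11)*998/(10/11)
        assert compute_f_stat(0.25 / 2.75, 1000) == pytest.approx(99.8, rel=1e-9)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            compute_f_stat(0.1, 2)

    @given(pve=st.floats(0, 0.99), n=st.integers(10, 10**6))
    def test_threshold_identity(self, pve, n):
        """F > 10 is algebraically equivalent to PVE > 10/(n+8) at k=1
        (solve pve*(n-2)/(1-pve) > 10 for pve)."""
        f = compute_f_stat(pve, n)
        assert f >= 0
        if abs(pve - 10 / (n + 8)) > 1e-12:  # away from the exact boundary
            assert (f > 10) == (pve > 10 / (n + 8))

    def test_monotone_in_pve(self):
        fs = [compute_f_stat(p, 5000) for p in np.linspace(0, 0.5, 20)]
        assert all(b > a for a, b in zip(fs, fs[1:]))


def _ld_from(ids, r2_pairs):
    """Build a small LD matrix from r² specs (everything else ~0)."""
    m = len(ids)
    r = np.eye(m)
    for (a, b), r2 in r2_pairs.items():
        i, j = ids.index(a), ids.index(b)
        r[i, j] = r[j, i] = np.sqrt(r2)
    return LDMatrix(list(ids), r)


class TestClump:
    def test_greedy_hand_example(self):
        a = make_variant("A", pvalue=1e-10, pos=100)
        b = make_variant("B", pvalue=1e-9, pos=200)
        c = make_variant("C", pvalue=1e-8, pos=300)
        ld = _ld_from(["A", "B", "C"], {("A", "B"): 0.5, ("A", "C"): 0.0005, ("B", "C"): 0.0005})
        kept = clump([a, b, c], ld, 0.001)
        assert [v.variant_id for v in kept] == ["A", "C"]

    def test_single_candidate_kept(self):
        v = make_variant("A")
        assert clump([v], _ld_from(["A"], {}), 0.001) == [v]

    def test_empty_input(self):
        assert clump([], _ld_from(["A"], {}), 0.001) == []

    def test_missing_variant_named_in_error(self):
        v = make_variant("B")
        with pytest.raises(ValueError, match="B"):
            clump([v], _ld_from(["A"], {}), 0.001)

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        """Greedy clumping equals the lexicographically-first (by p-rank)
        maximal independent set, found by full subset enumeration."""
        for _ in range(60):
            n = int(rng.integers(2, 11))
            ids = [f"v{i}" for i in range(n)]
            r = rng.uniform(-1, 1, (n, n))
            r = (r + r.T) / 2
            np.fill_diagonal(r, 1.0)
            ld = LDMatrix(ids, r)
            pvals = rng.uniform(1e-12, 1e-4, n)
            variants = [make_variant(ids[i], pvalue=pvals[i], pos=100 + i) for i in range(n)]
            kept = {v.variant_id for v in clump(variants, ld, 0.05)}
            assert kept == exhaustive_clump_oracle(variants, ld, 0.05)


def exhaustive_clump_oracle(variants, ld, r2_threshold):
    """Independent oracle: among all maximal pairwise-independent subsets,
    return the lexicographically smallest by p-value rank."""
    order = sorted(range(len(variants)), key=lambda i: variants[i].pvalue)
    rank = {variants[i].variant_id: k for k, i in enumerate(order)}
    ids = [v.variant_id for v in variants]

    def valid(subset):
        return all(
            ld.r2(a, b) < r2_threshold for a, b in itertools.combinations(subset, 2)
        )

    valid_sets = [s for k in range(1, len(ids) + 1)
                  for s in itertools.combinations(ids, k) if valid(s)]
    maximal = [
        set(s)
        for s in valid_sets
        if all(
            any(ld.r2(a, x) >= r2_threshold for a in s) for x in ids if x not in s
        )
    ]
    best = min(maximal, key=lambda s: tuple(sorted(rank[i] for i in s)))
    return best


class TestSelectInstruments:
    def _region(self, seed=0):
        return simulate_region(scenario_config("causal", seed=seed))

    def test_variant_outside_cis_window_excluded(self):
        far = make_variant("far", pos=3_000_000, pvalue=1e-20)
        near = make_variant("near", pos=1_500_000, pvalue=1e-20)
        stats = make_stats([far, near])
        ld = _ld_from(["far", "near"], {})
        gene = GeneAnnotation("G", "1", 1_000_000)
        inst = select_instruments(stats, gene, ld, cis_window_bp=1_000_000)
        assert [i.variant.variant_id for i in inst.instruments] == ["near"]

    def test_subthreshold_pvalue_excluded(self):
        v = make_variant("rs1", pvalue=1e-7)
        inst = select_instruments(
            make_stats([v]), GeneAnnotation("G", "1", 1_000_000), _ld_from(["rs1"], {})
        )
        assert len(inst) == 0 and inst.stage_counts["pvalue"] == 0

    def test_three_independent_signals_recovered(self):
        ds = self._region(seed=12)
        inst = select_instruments(ds.protein_stats, ds.gene, ds.ld)
        assert len(inst) == 3
        # every retained instrument satisfies all filters (brute-force check)
        for i in inst.instruments:
            assert i.variant.pvalue < 5e-8
            assert i.f_stat > 10
            assert i.variant.chrom == ds.gene.chrom
            assert abs(i.variant.pos - ds.gene.tss) <= 1_000_000
        for a in inst.variants():
            for b in inst.variants():
                if a.variant_id != b.variant_id:
                    assert ds.ld.r2(a.variant_id, b.variant_id) < 0.001

    def test_row_order_invariance(self):
        ds = self._region(seed=4)
        inst1 = select_instruments(ds.protein_stats, ds.gene, ds.ld)
        shuffled = make_stats(list(reversed(ds.protein_stats.variants())), "PROT")
        inst2 = select_instruments(shuffled, ds.gene, ds.ld)
        assert [v.variant_id for v in inst1.variants()] == [
            v.variant_id for v in inst2.variants()
        ]


class TestFlagPleiotropy:
    def _inst(self):
        ds = simulate_region(scenario_config("causal", seed=2))
        return select_instruments(ds.protein_stats, ds.gene, ds.ld)

    def test_genome_wide_catalog_hit_flagged(self):
        inst = self._inst()
        vid = inst.instruments[0].variant.variant_id
        catalog = TraitCatalog([(vid, "waist circumference", 1e-12)])
        flagged = flag_pleiotropy(inst, catalog)
        assert flagged.pleiotropic
        assert flagged.instruments[0].pleiotropy_flags == ("waist circumference",)

    def test_subthreshold_hit_not_flagged(self):
        inst = self._inst()
        vid = inst.instruments[0].variant.variant_id
        flagged = flag_pleiotropy(inst, TraitCatalog([(vid, "height", 1e-6)]))
        assert not flagged.pleiotropic

    def test_empty_catalog_no_flags(self):
        flagged = flag_pleiotropy(self._inst(), TraitCatalog([]))
        assert not flagged.pleiotropic
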