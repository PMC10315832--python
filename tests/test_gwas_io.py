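"""Summary-statistics I/O, validation, harmonization and LD-matrix handling."""

import numpy as np
import pytest

from pqtlmr.gwas_io import (
    LDMatrix,
    harmonize,
    read_ld_matrix,
    read_summary_stats,
    usable_pairs,
    write_ld_matrix,
    write_summary_stats,
)
from pqtlmr.simulate import scenario_config, simulate_region

from conftest import make_stats, make_variant

HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"


def _write(tmp_path, rows, header=HEADER, name="stats.tsv"):
    path = tmp_path / name
    path.write_text(header + "".join(rows))
    return path


class TestReadSummaryStats:
    def test_well_formed_file_parses_all_rows(self, tmp_path):
        path = _write(
            tmp_path,
            [
                "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-9\t5000\n",
                "rs2\t1\t200\tC\tT\t0.4\t-0.2\t0.03\t1e-12\t5000\n",
                "rs3\t2\t300\tG\tA\t0.1\t0.05\t0.02\t0.01\t5000\n",
            ],
        )
        stats = read_summary_stats(path, "prot")
        assert len(stats) == 3
        assert stats.records["rs2"].beta == -0.2

    def test_invalid_rows_dropped_not_fatal(self, tmp_path):
        path = _write(
            tmp_path,
            [
                "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-9\t5000\n",
                "rs2\t1\t200\tC\tT\t0.4\t-0.2\t0.0\t1e-12\t5000\n",  # se = 0
            ],
        )
        stats = read_summary_stats(path, "prot")
        assert len(stats) == 1 and "rs2" not in stats

    def test_lowercase_alleles_normalized(self, tmp_path):
        path = _write(tmp_path, ["rs1\t1\t100\ta\tg\t0.3\t0.1\t0.02\t1e-9\t5000\n"])
        rec = read_summary_stats(path, "prot").records["rs1"]
        assert (rec.effect_allele, rec.other_allele) == ("A", "G")

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tEA\tOA\tBETA\tP\tN\nrs1\tA\tG\t0.1\t1e-9\t5000\n")
        with pytest.raises(ValueError, match="se"):
            read_summary_stats(path, "prot")

    def test_all_rows_invalid_is_hard_error(self, tmp_path):
        path = _write(tmp_path, ["rs1\t1\t100\tA\tA\t0.3\t0.1\t0.02\t1e-9\t5000\n"])
        with pytest.raises(ValueError, match="no valid"):
            read_summary_stats(path, "prot")

    def test_column_synonyms_resolved(self, tmp_path):
        path = tmp_path / "syn.csv"
        path.write_text(
            "rsid,effect_allele,other_allele,Effect,standard_error,pval,sample_size\n"
            "rs1,A,G,0.1,0.02,1e-9,5000\n"
        )
        stats = read_summary_stats(path, "prot")
        assert stats.records["rs1"].se == 0.02


class TestRoundTrip:
    def test_simulated_trait_round_trips_exactly(self, tmp_path):
        ds = simulate_region(
            scenario_config("causal", seed=3, n_variants=100, causal_variants=((50, 0.3),))
        )
        path = tmp_path / "prot.tsv"
        write_summary_stats(ds.protein_stats, path)
        back = read_summary_stats(path, "PROT")
        assert back.records == ds.protein_stats.records

    def test_binary_trait_keeps_case_control_columns(self, tmp_path):
        ds = simulate_region(
            scenario_config("causal", seed=3, n_variants=20, causal_variants=((10, 0.3),))
        )
        path = tmp_path / "dis.tsv"
        write_summary_stats(ds.disease_stats, path)
        assert "N_CASES" in path.read_text().splitlines()[0]
        back = read_summary_stats(path, "DISEASE", "binary")
        assert back.records == ds.disease_stats.records

    def test_empty_container_refused(self, tmp_path):
        empty = make_stats([])
        with pytest.raises(ValueError):
            write_summary_stats(empty, tmp_path / "x.tsv")


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = make_variant(effect_allele="A", other_allele="G", beta=0.1)
        out = make_variant(effect_allele="G", other_allele="A", beta=-0.05, eaf=0.7)
        (pair,) = harmonize([exp], make_stats([out]))
        assert pair.status == "flipped"
        assert pair.beta_out == pytest.approx(0.05)
        assert pair.eaf_out == pytest.approx(0.3)

    def test_aligned_pair_unchanged(self):
        exp = make_variant(beta=0.1)
        out = make_variant(beta=-0.05)
        (pair,) = harmonize([exp], make_stats([out]))
        assert pair.status == "ok" and pair.beta_out == -0.05

    def test_palindromic_ambiguous_frequency_dropped(self):
        exp = make_variant(effect_allele="A", other_allele="T", eaf=0.50)
        out = make_variant(effect_allele="A", other_allele="T", eaf=0.50)
        (pair,) = harmonize([exp], make_stats([out]), palindrome_eaf_window=0.08)
        assert pair.status == "dropped_palindromic"

    def test_palindromic_missing_eaf_dropped(self):
        exp = make_variant(effect_allele="C", other_allele="G", eaf=None)
        out = make_variant(effect_allele="C", other_allele="G", eaf=0.2)
        (pair,) = harmonize([exp], make_stats([out]))
        assert pair.status == "dropped_palindromic"

    def test_palindromic_clear_frequency_aligned_by_eaf(self):
        # outcome reports the other strand: EAF disagreement implies a flip
        exp = make_variant(effect_allele="A", other_allele="T", eaf=0.2, beta=0.1)
        out = make_variant(effect_allele="A", other_allele="T", eaf=0.8, beta=0.05)
        (pair,) = harmonize([exp], make_stats([out]))
        assert pair.status == "flipped" and pair.beta_out == pytest.approx(-0.05)

    def test_incompatible_alleles_dropped(self):
        exp = make_variant(effect_allele="A", other_allele="G")
        out = make_variant(effect_allele="A", other_allele="C")
        (pair,) = harmonize([exp], make_stats([out]))
        assert pair.status == "dropped_mismatch"

    def test_strand_complement_resolved(self):
        exp = make_variant(effect_allele="A", other_allele="G", beta=0.1)
        out = make_variant(effect_allele="T", other_allele="C", beta=0.05)
        (pair,) = harmonize([exp], make_stats([out]))
        assert pair.status == "ok" and pair.beta_out == 0.05

    def test_no_overlap_is_hard_error(self):
        exp = make_variant(variant_id="rs1")
        out = make_variant(variant_id="rs2")
        with pytest.raises(ValueError, match="overlap"):
            harmonize([exp], make_stats([out]))

    def test_harmonization_is_involution_safe(self):
        ds = simulate_region(
            scenario_config("causal", seed=7, n_variants=50, causal_variants=((25, 0.3),))
        )
        pairs = harmonize(ds.protein_stats.variants(), ds.disease_stats)
        assert all(p.status == "ok" for p in pairs)
        for pair, out in zip(pairs, ds.disease_stats.variants()):
            assert pair.beta_out == out.beta and pair.eaf_out == out.eaf


class TestLDMatrix:
    def test_identity_matrix_parses(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("\trs1\trs2\nrs1\t1\t0\nrs2\t0\t1\n")
        ld = read_ld_matrix(path)
        assert ld.variant_ids == ["rs1", "rs2"] and ld.r2("rs1", "rs2") == 0.0

    def test_out_of_range_entry_rejected(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("\trs1\trs2\nrs1\t1\t1.2\nrs2\t1.2\t1\n")
        with pytest.raises(ValueError, match=r"\|r\| > 1"):
            read_ld_matrix(path)

    def test_tiny_asymmetry_symmetrized(self):
        r = np.array([[1.0, 0.5], [0.5 + 1e-12, 1.0]])
        ld = LDMatrix(["a", "b"], r)
        assert ld.r[0, 1] == ld.r[1, 0]

    def test_large_asymmetry_rejected(self):
        r = np.array([[1.0, 0.5], [0.6, 1.0]])
        with pytest.raises(ValueError, match="asymmetry"):
            LDMatrix(["a", "b"], r)

    def test_non_square_rejected(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("\trs1\trs2\nrs1\t1\t0\n")
        with pytest.raises(ValueError, match="square"):
            read_ld_matrix(path)

    def test_round_trip(self, tmp_path):
        ds = simulate_region(scenario_config("causal", seed=1, n_variants=10,
                                             causal_variants=((5, 0.3),),
                                             disease_loci=(), n_background_variants=0))
        path = tmp_path / "ld.tsv"
        write_ld_matrix(ds.ld, path)
        back = read_ld_matrix(path)
        assert back.variant_ids == ds.ld.variant_ids
        np.testing.assert_allclose(back.r, ds.ld.r, atol=1e-12)


def test_allele_recoding_leaves_mr_estimate_unchanged():
    """Swapping an exposure's allele encoding (swap alleles, negate beta,
    reflect EAF) must leave the downstream causal estimate untouched."""
    from dataclasses import replace

    from pqtlmr.mr import mr_estimate

    ds = simulate_region(scenario_config("causal", seed=9))
    from pqtlmr.instruments import select_instruments

    inst = select_instruments(ds.protein_stats, ds.gene, ds.ld)
    pairs = usable_pairs(harmonize(inst.variants(), ds.disease_stats))
    ref = mr_estimate(pairs)

    recoded = [
        replace(
            v,
            effect_allele=v.other_allele,
            other_allele=v.effect_allele,
            beta=-v.beta,
            eaf=1 - v.eaf,
        )
        for v in inst.variants()
    ]
    pairs2 = usable_pairs(harmonize(recoded, ds.disease_stats))
    res = mr_estimate(pairs2)
    assert res.beta == pytest.approx(ref.beta)
    assert res.se == pytest.approx(ref.se)
    assert res.pvalue == pytest.approx(ref.pvalue)
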