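"""Codon arithmetic, translation and coding-effect classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selfseg.annotation import (
    CdsModel,
    ReferenceMismatchError,
    annotate_substitution,
    cds_position_to_codon,
    partition_by_coding,
    translate_codon,
)


def make_cds(codons, gene="g"):
    return CdsModel(gene, "".join(codons))


@pytest.fixture(scope="module")
def arg192_cds():
    """CDS whose 192nd codon is CGT (Arg), so position 574 is its first base."""
    codons = ["ATG"] + ["AAA"] * 190 + ["CGT"] + ["GGC"] * 8
    return make_cds(codons)


class TestCodonArithmetic:
    @pytest.mark.parametrize(
        "pos, expected", [(574, (192, 1)), (1, (1, 1)), (6, (2, 3)), (575, (192, 2))]
    )
    def test_position_to_codon(self, pos, expected):
        assert cds_position_to_codon(pos) == expected

    @given(pos=st.integers(1, 10_000))
    @settings(derandomize=True, max_examples=80)
    def test_round_trip_recovers_the_position(self, pos):
        codon_index, pos_in_codon = cds_position_to_codon(pos)
        assert (codon_index - 1) * 3 + pos_in_codon == pos
        assert 1 <= pos_in_codon <= 3

    def test_position_beyond_cds_rejected(self, arg192_cds):
        with pytest.raises(IndexError):
            cds_position_to_codon(len(arg192_cds) + 1, arg192_cds)

    def test_nonpositive_position_rejected(self):
        with pytest.raises(ValueError):
            cds_position_to_codon(0)


class TestTranslateCodon:
    @pytest.mark.parametrize(
        "codon, aa", [("CGT", "R"), ("TGT", "C"), ("TGA", "*"), ("ATG", "M")]
    )
    def test_standard_code(self, codon, aa):
        assert translate_codon(codon) == aa

    @pytest.mark.parametrize("codon", ["CG", "CGTA", "CNT", "cgx"])
    def test_ambiguous_or_malformed_codons_rejected(self, codon):
        with pytest.raises(ValueError):
            translate_codon(codon)


class TestAnnotateSubstitution:
    def test_c574t_yields_arg192cys(self, arg192_cds):
        eff = annotate_substitution(arg192_cds, 574, "C", "T")
        assert (eff.codon_index, eff.pos_in_codon) == (192, 1)
        assert (eff.ref_codon, eff.alt_codon) == ("CGT", "TGT")
        assert (eff.ref_aa, eff.alt_aa) == ("R", "C")
        assert eff.effect_class == "missense"

    def test_third_position_wobble_is_synonymous(self, arg192_cds):
        eff = annotate_substitution(arg192_cds, 576, "T", "C")
        assert (eff.ref_aa, eff.alt_aa) == ("R", "R")
        assert eff.effect_class == "synonymous"

    def test_stop_gain_is_nonsense(self):
        cds = make_cds(["ATG", "CGA", "AAA"])
        eff = annotate_substitution(cds, 4, "C", "T")  # CGA -> TGA
        assert eff.alt_aa == "*"
        assert eff.effect_class == "nonsense"

    def test_stop_codon_losing_its_stop_is_stop_loss(self):
        cds = make_cds(["ATG", "AAA", "TGA"])
        eff = annotate_substitution(cds, 8, "G", "T")  # TGA -> TTA (Leu)
        assert eff.effect_class == "stop_loss"

    def test_reference_mismatch_is_a_hard_error_naming_the_site(self, arg192_cds):
        with pytest.raises(ReferenceMismatchError, match="574"):
            annotate_substitution(arg192_cds, 574, "G", "T")

    def test_indels_and_mnvs_rejected(self, arg192_cds):
        with pytest.raises(ValueError, match="indel"):
            annotate_substitution(arg192_cds, 574, "CG", "T")

    def test_minus_strand_input_must_be_reverse_complemented_upstream(self):
        # the documented contract: genomic minus-strand variants are handed
        # over already on the coding strand; doing so reproduces the direct call
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        cds = make_cds(["ATG", "CGT", "AAA"])
        genomic = "".join(comp[b] for b in reversed(cds.cds_sequence))
        genomic_pos, g_ref, g_alt = len(cds) - 4 + 1, "G", "A"  # minus strand
        assert genomic[genomic_pos - 1] == g_ref
        cds_pos = len(cds) - genomic_pos + 1
        eff = annotate_substitution(cds, cds_pos, comp[g_ref], comp[g_alt])
        direct = annotate_substitution(cds, 4, "C", "T")
        assert eff == direct


class TestTranslationOracle:
    def test_annotation_path_agrees_with_full_cds_translation(self):
        # independent oracle: translate whole random coding sequences with
        # Biopython and compare residue-by-residue with the annotation path
        rng = np.random.default_rng(7)
        bases = "ACGT"
        for _ in range(10):
            n_codons = int(rng.integers(2, 333))
            seq = "ATG" + "".join(
                bases[i] for i in rng.integers(0, 4, size=3 * (n_codons - 1))
            )
            cds = CdsModel("g", seq)
            protein = cds.protein  # Biopython translation
            for pos in range(1, len(seq) + 1, 7):
                ref = seq[pos - 1]
                alt = bases[(bases.index(ref) + 1) % 4]
                eff = annotate_substitution(cds, pos, ref, alt)
                assert eff.ref_aa == protein[eff.codon_index - 1]
                assert eff.alt_aa == translate_codon(eff.alt_codon)


class TestCdsModelValidation:
    def test_length_must_be_multiple_of_three(self):
        with pytest.raises(ValueError):
            CdsModel("g", "ATGC")

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError):
            CdsModel("g", "ATGNNN")

    def test_missing_start_codon_only_warns(self):
        with pytest.warns(UserWarning, match="ATG"):
            CdsModel("g", "CCCAAA")


class TestPartitionByCoding:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["variant_id", "ref", "alt", "gene_id", "cds_pos"],
        )

    def test_coding_and_noncoding_counted_separately(self):
        cds = make_cds(["ATG", "CGT", "AAA"], gene="g1")
        table = self._table(
            [
                ("v1", "C", "T", "g1", 4),
                ("v2", "T", "C", "g1", 6),
                ("v3", "A", "G", "", np.nan),
                ("v4", "G", "C", "", np.nan),
            ]
        )
        out = partition_by_coding(table, {"g1": cds})
        assert out.counts["coding"] == 2
        assert out.counts["noncoding"] == 2
        assert out.counts["missense"] == 1
        assert out.counts["synonymous"] == 1
        assert out.counts["non_synonymous"] == 1

    def test_effect_classes_conserve_the_coding_count(self, small_dataset):
        out = partition_by_coding(small_dataset.variants, small_dataset.cds)
        assert (
            out.counts["synonymous"] + out.counts["missense"]
            + out.counts["nonsense"] + out.counts["stop_loss"]
        ) == out.counts["coding"]
        assert out.counts["coding"] + out.counts["noncoding"] == len(
            small_dataset.variants
        )

    def test_planted_causal_is_exactly_one_missense_at_the_planted_residue(
        self, small_dataset
    ):
        out = partition_by_coding(small_dataset.variants, small_dataset.cds)
        causal = out.effects[
            out.effects["variant_id"] == small_dataset.causal_variant_id
        ]
        assert len(causal) == 1
        row = causal.iloc[0]
        truth = next(t for t in small_dataset.truth_records if t.is_causal)
        assert row["effect_class"] == "missense"
        assert row["codon_index"] == truth.planted_effect.codon_index
        assert (row["ref_aa"], row["alt_aa"]) == (
            truth.planted_effect.ref_aa, truth.planted_effect.alt_aa,
        )

    def test_variant_mapping_to_multiple_genes_is_flagged(self):
        g1 = make_cds(["ATG", "CGT", "AAA"], gene="g1")
        g2 = make_cds(["ATG", "CGT", "AAA"], gene="g2")
        table = self._table(
            [("v1", "C", "T", "g1", 4), ("v1", "C", "T", "g2", 4)]
        )
        out = partition_by_coding(table, {"g1": g1, "g2": g2})
        assert len(out.effects) == 2
        assert out.effects["multi_mapped"].all()
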