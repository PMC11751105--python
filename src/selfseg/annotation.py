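"""Codon-level consequence annotation of point substitutions on CDS sequences.

Coordinates are 1-based positions on the coding strand, counted from the A
of the ATG.  A substitution at CDS position ``p`` falls in codon
``ceil(p / 3)`` at within-codon position ``((p - 1) mod 3) + 1``; e.g.
position 574 is the first base of codon 192.  Translation uses the standard
nuclear genetic code.  Inputs from the genomic minus strand must be
reverse-complemented upstream — annotation never sees genomic strand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "STOP",
    "EFFECT_CLASSES",
    "CdsModel",
    "CodingEffect",
    "EffectTable",
    "ReferenceMismatchError",
    "cds_position_to_codon",
    "translate_codon",
    "annotate_substitution",
    "partition_by_coding",
]

STOP = "*"
EFFECT_CLASSES = ("synonymous", "missense", "nonsense", "stop_loss", "noncoding")

_BASES = frozenset("ACGT")

# standard nuclear code (translation table 1), with explicit stops
_TABLE = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
for _stop in CodonTable.unambiguous_dna_by_id[1].stop_codons:
    _TABLE[_stop] = STOP


class ReferenceMismatchError(ValueError):
    """The stated reference base disagrees with the CDS sequence.

    Raised as a hard error: a silent mismatch almost always means a strand
    or coordinate-offset bug upstream, which would corrupt every downstream
    effect call.
    """


@dataclass(frozen=True)
class CdsModel:
    """An in-frame coding sequence (ATG-first, coding strand, 1-based)."""

    gene_id: str
    cds_sequence: str

    def __post_init__(self) -> None:
        seq = self.cds_sequence
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {len(seq)} is not a positive "
                "multiple of 3"
            )
        if not set(seq) <= _BASES:
            bad = sorted(set(seq) - _BASES)
            raise ValueError(
                f"{self.gene_id}: CDS contains non-ACGT characters {bad} "
                "(ambiguity codes are rejected)"
            )
        if seq[:3] != "ATG":
            warnings.warn(
                f"{self.gene_id}: CDS does not begin with ATG", stacklevel=2
            )

    def __len__(self) -> int:
        return len(self.cds_sequence)

    @property
    def protein(self) -> str:
        """Translation of the full CDS (stop rendered as '*')."""
        return str(Seq(self.cds_sequence).translate())

    def codon(self, codon_index: int) -> str:
        """The 1-based `codon_index`-th codon."""
        if not 1 <= codon_index <= len(self) // 3:
            raise IndexError(
                f"{self.gene_id}: codon {codon_index} outside 1..{len(self) // 3}"
            )
        return self.cds_sequence[3 * (codon_index - 1): 3 * codon_index]


@dataclass(frozen=True)
class CodingEffect:
    """Codon-level consequence of a single-nucleotide substitution."""

    gene_id: str
    cds_pos: int
    ref_base: str
    alt_base: str
    codon_index: int
    pos_in_codon: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect_class: str


def cds_position_to_codon(
    cds_pos: int, cds: CdsModel | None = None
) -> tuple[int, int]:
    """Map a 1-based CDS position to ``(codon_index, pos_in_codon)``.

    ``codon_index = ceil(cds_pos / 3)``; ``pos_in_codon`` is 1..3.  When a
    :class:`CdsModel` is supplied, positions beyond its length raise.
    """
    if cds_pos < 1:
        raise ValueError(f"cds_pos must be >= 1, got {cds_pos}")
    if cds is not None and cds_pos > len(cds):
        raise IndexError(
            f"{cds.gene_id}: cds_pos {cds_pos} beyond CDS length {len(cds)}"
        )
    codon_index = math.ceil(cds_pos / 3)
    pos_in_codon = (cds_pos - 1) % 3 + 1
    return codon_index, pos_in_codon


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard genetic code ('*' for stop)."""
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= _BASES:
        raise ValueError(
            f"codon must be 3 unambiguous bases (A/C/G/T), got {codon!r}"
        )
    return _TABLE[codon]


def annotate_substitution(
    cds: CdsModel, cds_pos: int, ref_base: str, alt_base: str
) -> CodingEffect:
    """Annotate a single-base substitution on `cds`.

    The effect class is ``synonymous`` when the amino acid is unchanged,
    ``nonsense`` when a stop is gained, ``stop_loss`` when the reference
    codon is a stop and the alternate is not, otherwise ``missense``.
    Multi-nucleotide or indel alleles are rejected — the screen concerns
    point substitutions.
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    for name, base in (("ref", ref_base), ("alt", alt_base)):
        if len(base) != 1 or base not in _BASES:
            raise ValueError(
                f"{cds.gene_id}:{cds_pos}: {name} allele {base!r} is not a "
                "single A/C/G/T base (indels and MNVs are not supported)"
            )
    if ref_base == alt_base:
        raise ValueError(f"{cds.gene_id}:{cds_pos}: ref and alt are both {ref_base!r}")
    codon_index, pos_in_codon = cds_position_to_codon(cds_pos, cds)
    found = cds.cds_sequence[cds_pos - 1]
    if found != ref_base:
        raise ReferenceMismatchError(
            f"{cds.gene_id}: CDS position {cds_pos} holds {found!r}, but the "
            f"variant states ref {ref_base!r} (alt {alt_base!r}); check strand "
            "and coordinate offset"
        )
    ref_codon = cds.codon(codon_index)
    alt_codon = (
        ref_codon[: pos_in_codon - 1] + alt_base + ref_codon[pos_in_codon:]
    )
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == STOP:
        effect = "nonsense"
    elif ref_aa == STOP:
        effect = "stop_loss"
    else:
        effect = "missense"
    return CodingEffect(
        gene_id=cds.gene_id,
        cds_pos=cds_pos,
        ref_base=ref_base,
        alt_base=alt_base,
        codon_index=codon_index,
        pos_in_codon=pos_in_codon,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect_class=effect,
    )


@dataclass
class EffectTable:
    """Annotated effects plus per-class counts."""

    effects: pd.DataFrame
    counts: dict[str, int]


_EFFECT_COLUMNS = [
    "variant_id", "gene_id", "cds_pos", "codon_index", "pos_in_codon",
    "ref_codon", "alt_codon", "ref_aa", "alt_aa", "effect_class",
    "multi_mapped",
]


def partition_by_coding(
    variants: pd.DataFrame,
    cds_catalogue: Mapping[str, CdsModel] | Iterable[CdsModel],
) -> EffectTable:
    """Annotate coding variants and pass noncoding ones through.

    `variants` needs columns ``variant_id, ref, alt`` and the gene mapping
    columns ``gene_id, cds_pos`` (empty/NaN for noncoding variants).  A
    variant mapped to several CDS records (several rows with the same
    ``variant_id``) is annotated against each and flagged ``multi_mapped``.
    """
    if not isinstance(cds_catalogue, Mapping):
        cds_catalogue = {c.gene_id: c for c in cds_catalogue}
    has_gene = "gene_id" in variants.columns and "cds_pos" in variants.columns
    rows: list[dict] = []
    id_counts = variants["variant_id"].value_counts() if len(variants) else {}
    for r in variants.itertuples(index=False):
        gene = getattr(r, "gene_id", None) if has_gene else None
        cds_pos = getattr(r, "cds_pos", None) if has_gene else None
        coding = (
            gene is not None
            and isinstance(gene, str)
            and gene != ""
            and cds_pos is not None
            and not (isinstance(cds_pos, float) and math.isnan(cds_pos))
        )
        multi = bool(id_counts[r.variant_id] > 1) if coding else False
        if not coding:
            rows.append(
                {
                    "variant_id": r.variant_id,
                    "gene_id": "",
                    "cds_pos": pd.NA,
                    "codon_index": pd.NA,
                    "pos_in_codon": pd.NA,
                    "ref_codon": "",
                    "alt_codon": "",
                    "ref_aa": "",
                    "alt_aa": "",
                    "effect_class": "noncoding",
                    "multi_mapped": False,
                }
            )
            continue
        if gene not in cds_catalogue:
            raise KeyError(
                f"variant {r.variant_id} maps to unknown gene {gene!r}"
            )
        eff = annotate_substitution(
            cds_catalogue[gene], int(cds_pos), str(r.ref), str(r.alt)
        )
        rows.append(
            {
                "variant_id": r.variant_id,
                "gene_id": eff.gene_id,
                "cds_pos": eff.cds_pos,
                "codon_index": eff.codon_index,
                "pos_in_codon": eff.pos_in_codon,
                "ref_codon": eff.ref_codon,
                "alt_codon": eff.alt_codon,
                "ref_aa": eff.ref_aa,
                "alt_aa": eff.alt_aa,
                "effect_class": eff.effect_class,
                "multi_mapped": multi,
            }
        )
    effects = pd.DataFrame(rows, columns=_EFFECT_COLUMNS)
    counts = {c: int((effects["effect_class"] == c).sum()) for c in EFFECT_CLASSES}
    counts["coding"] = len(effects) - counts["noncoding"]
    counts["non_synonymous"] = (
        counts["missense"] + counts["nonsense"] + counts["stop_loss"]
    )
    return EffectTable(effects=effects, counts=counts)
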