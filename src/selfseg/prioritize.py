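"""Candidate ranking by substitution severity, residue conservation and domain overlap.

A screen that ends with a handful of non-synonymous candidates needs an
evidence chain to pick one: how drastic is the amino-acid exchange
(Grantham distance), is the affected residue conserved across orthologs,
and does it sit inside an annotated functional domain.  A radical exchange
of an invariant residue inside a signalling domain outranks a conservative
exchange of an unconstrained residue.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Sequence

from Bio.Align import MultipleSeqAlignment

from .annotation import CodingEffect
from .grantham import grantham_distance, severity_class

__all__ = [
    "SubstitutionSeverity",
    "ConservationProfile",
    "CandidateReport",
    "score_substitution",
    "conservation_at_residue",
    "domain_overlap",
    "rank_candidates",
]

_EFFECT_ORDER = {
    "nonsense": 4,
    "stop_loss": 3,
    "missense": 2,
    "synonymous": 1,
    "noncoding": 0,
}
_SEVERITY_ORDER = {"radical": 2, "moderate": 1, "conservative": 0, None: -1}


@dataclass(frozen=True)
class SubstitutionSeverity:
    """Grantham distance of an amino-acid exchange plus its severity bin."""

    ref_aa: str
    alt_aa: str
    grantham_distance: int
    severity_class: str


def score_substitution(
    ref_aa: str,
    alt_aa: str,
    conservative_below: float = 100.0,
    radical_above: float = 150.0,
) -> SubstitutionSeverity:
    """Look up the Grantham distance and bin it."""
    d = grantham_distance(ref_aa, alt_aa)
    return SubstitutionSeverity(
        ref_aa=ref_aa.upper(),
        alt_aa=alt_aa.upper(),
        grantham_distance=d,
        severity_class=severity_class(d, conservative_below, radical_above),
    )


class ConservationProfile:
    """Match-to-reference conservation from an ortholog protein alignment.

    The per-column score is the fraction of non-reference sequences whose
    residue equals the reference residue at that column; gaps count as
    mismatches.  With the small ortholog panels typical of this kind of
    screen (a handful of species) this is more informative than entropy.
    The reference record is identified by ID and must occur exactly once.
    """

    def __init__(
        self,
        gene_id: str,
        alignment: MultipleSeqAlignment | Sequence[tuple[str, str]],
        reference_id: str | None = None,
    ):
        self.gene_id = gene_id
        self.reference_id = reference_id if reference_id is not None else gene_id
        records = [
            rec if isinstance(rec, tuple) else (rec.id, str(rec.seq))
            for rec in alignment
        ]
        refs = [seq for rid, seq in records if rid == self.reference_id]
        if len(refs) != 1:
            raise ValueError(
                f"{gene_id}: reference {self.reference_id!r} occurs "
                f"{len(refs)} times in the alignment (need exactly once)"
            )
        others = [seq for rid, seq in records if rid != self.reference_id]
        if not others:
            raise ValueError(f"{gene_id}: alignment has no non-reference sequences")
        if len({len(seq) for _, seq in records}) != 1:
            raise ValueError(f"{gene_id}: alignment rows have unequal lengths")
        self._ref = refs[0].upper()
        self._others = [seq.upper() for seq in others]
        # map reference residue index -> alignment column (skip reference gaps)
        self._columns = [i for i, c in enumerate(self._ref) if c != "-"]
        self.column_scores = [
            self._column_score(col) for col in range(len(self._ref))
        ]

    def _column_score(self, col: int) -> float:
        ref = self._ref[col]
        if ref == "-":
            return 0.0
        matches = sum(1 for s in self._others if s[col] == ref)
        return matches / len(self._others)

    @property
    def n_orthologs(self) -> int:
        return len(self._others)

    @property
    def reference_length(self) -> int:
        """Ungapped length of the reference sequence."""
        return len(self._columns)

    def column_of_residue(self, residue_index: int) -> int:
        """Alignment column (0-based) holding reference residue `residue_index` (1-based)."""
        if not 1 <= residue_index <= self.reference_length:
            raise IndexError(
                f"{self.gene_id}: residue {residue_index} outside the "
                f"reference's ungapped length {self.reference_length}"
            )
        return self._columns[residue_index - 1]

    def score_at_residue(self, residue_index: int) -> float:
        return self.column_scores[self.column_of_residue(residue_index)]


def conservation_at_residue(
    profile: ConservationProfile, residue_index: int
) -> float:
    """Fraction of orthologs matching the reference residue at `residue_index`."""
    return profile.score_at_residue(residue_index)


def highly_conserved(profile: ConservationProfile, residue_index: int) -> bool:
    """Whether the residue clears the reporting threshold for 'highly conserved'.

    With ≤ 5 aligned sequences every ortholog must match (threshold 1.0);
    larger panels tolerate one-off divergence (threshold 0.9).
    """
    threshold = 1.0 if profile.n_orthologs + 1 <= 5 else 0.9
    return conservation_at_residue(profile, residue_index) >= threshold


def domain_overlap(
    residue_index: int, domains: Sequence[tuple[str, int, int]]
) -> tuple[bool, list[str]]:
    """Does `residue_index` fall in any (name, start, end) interval (inclusive)?"""
    if residue_index < 1:
        raise ValueError(f"residue_index must be >= 1, got {residue_index}")
    hits = []
    for name, start, end in domains:
        if start > end or start < 1:
            raise ValueError(
                f"malformed domain interval {name!r}: [{start}, {end}]"
            )
        if start <= residue_index <= end:
            hits.append(name)
    return bool(hits), hits


@dataclass(frozen=True)
class CandidateReport:
    """One ranked candidate with its full evidence chain."""

    variant_id: str
    gene_id: str
    effect: CodingEffect | None
    severity: SubstitutionSeverity | None
    conservation_score: float | None
    in_domain: bool
    domain_names: tuple[str, ...] = ()
    rank: int = 0
    extras: dict = field(default_factory=dict, compare=False)


def _sort_key(r: CandidateReport):
    effect_class = r.effect.effect_class if r.effect is not None else "noncoding"
    sev = r.severity.severity_class if r.severity is not None else None
    cons = r.conservation_score if r.conservation_score is not None else -1.0
    return (
        -_EFFECT_ORDER.get(effect_class, 0),
        -_SEVERITY_ORDER[sev],
        -cons,
        0 if r.in_domain else 1,
        r.variant_id,
    )


def rank_candidates(reports: Sequence[CandidateReport]) -> list[CandidateReport]:
    """Totally order candidates and assign ranks 1..n.

    Lexicographic: effect class (nonsense > stop-loss > missense >
    synonymous > noncoding), then severity bin (radical > moderate >
    conservative), then conservation descending, then in-domain first, then
    variant_id ascending as the deterministic tie-break.  The order is
    invariant to the input order.
    """
    ordered = sorted(reports, key=_sort_key)
    return [replace(r, rank=i + 1) for i, r in enumerate(ordered)]


def _shuffle_invariant_check(reports: Sequence[CandidateReport], seed: int = 0) -> bool:
    """Internal helper used by tests: ranking is independent of input order."""
    rng = random.Random(seed)
    shuffled = list(reports)
    rng.shuffle(shuffled)
    return [r.variant_id for r in rank_candidates(shuffled)] == [
        r.variant_id for r in rank_candidates(reports)
    ]
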