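"""Three-pool segregation-signature classification for bulk segregant screens.

A recessive causal variant in a selfed brood has a fixed allele-frequency
signature across the three pools sequenced in this design:

* mutant pool (homozygous affected embryos): mutant-allele frequency 1,
* wild-type strain pool: frequency 0,
* sibling pool (phenotypically normal sibs of the mutants): frequency 1/3,
  because normal offspring of a selfed heterozygote are 1/3 homozygous
  reference and 2/3 heterozygous, so the wild-type allele is expected to be
  twice as abundant as the mutant allele.

The classifier applies depth-tolerant versions of these three fixed points
and an exact test of the sibling 2:1 ratio.  Variants whose sibling counts
are incompatible with 1/3 (e.g. mutations fixed in the mutagenized line) are
rejected even when they are perfectly enriched in the mutant pool and absent
from the wild type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "POOLS",
    "CLASSIFICATIONS",
    "PooledVariant",
    "SegregationCall",
    "FilterThresholds",
    "FilterResult",
    "expected_pool_frequency",
    "sibling_ratio_test",
    "sibling_pool_test",
    "classify_segregation",
    "classify_table",
    "filter_candidates",
]

#: Pool labels, in canonical order.
POOLS = ("mutant", "sibling", "wt")

#: Classification labels emitted by the filter (a partition: every variant
#: receives exactly one).
CLASSIFICATIONS = (
    "candidate",
    "strain_fixed",
    "wt_contaminated",
    "non_segregating",
    "sibling_ratio_inconsistent",
    "low_depth",
)

#: Expected mutant-allele frequency per pool for a fully penetrant recessive
#: causal variant (the noiseless, infinite-depth fixed points).
_EXPECTED = {"mutant": 1.0, "sibling": 1.0 / 3.0, "wt": 0.0}


def expected_pool_frequency(pool: str) -> float:
    """Expected mutant-allele frequency of `pool` for the causal variant.

    mutant → 1.0, wt → 0.0, sibling → 1/3 (the 2:1 wild-type:mutant allele
    ratio among phenotypically normal selfed offspring).
    """
    try:
        return _EXPECTED[pool]
    except KeyError:
        raise ValueError(
            f"unknown pool label {pool!r}; expected one of {POOLS}"
        ) from None


@dataclass(frozen=True)
class PooledVariant:
    """One variant site with per-pool allele-depth counts.

    ``counts`` maps each pool label in :data:`POOLS` to an
    ``(alt_count, depth)`` pair, where ``depth`` is the number of reads
    supporting either the reference or the listed alternate allele.
    """

    variant_id: str
    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    counts: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"{self.variant_id}: ref and alt alleles are identical "
                f"({self.ref_allele!r})"
            )
        for pool in POOLS:
            if pool not in self.counts:
                raise ValueError(f"{self.variant_id}: missing counts for pool {pool!r}")
            alt, depth = self.counts[pool]
            if not (0 <= alt <= depth):
                raise ValueError(
                    f"{self.variant_id}: pool {pool!r} has alt_count={alt} "
                    f"outside [0, depth={depth}]"
                )

    def frequency(self, pool: str) -> float:
        """Observed alt-allele frequency in `pool` (NaN at zero depth)."""
        alt, depth = self.counts[pool]
        return alt / depth if depth > 0 else float("nan")


@dataclass(frozen=True)
class SegregationCall:
    """The filter's verdict on one variant's three-pool signature."""

    variant_id: str
    classification: str
    observed_frequencies: Mapping[str, float]
    sibling_test_p: float | None = None


@dataclass(frozen=True)
class FilterThresholds:
    """Depth-tolerant operationalization of the 100% / intermediate / 0% signature.

    The literal fixed points hold only at infinite depth with error-free
    reads; ``min_mutant_freq`` and ``max_wt_freq`` relax them for finite
    noisy counts.  ``sibling_expected_freq`` is the Mendelian 1/3.

    ``sibling_pool_size`` selects the null used for the sibling consistency
    test.  ``None`` tests the read counts directly against
    ``sibling_expected_freq`` with the exact binomial test.  An integer *n*
    instead uses the exact compound null that first draws the pool's
    composition (the number of heterozygous embryos among *n* phenotypically
    normal sibs) and then the reads; with small pools this is the calibrated
    choice, because pool-composition sampling overdisperses read counts
    relative to a plain binomial.
    """

    min_mutant_freq: float = 0.95
    max_wt_freq: float = 0.05
    min_depth: int = 10
    sibling_alpha: float = 0.05
    sibling_expected_freq: float = 1.0 / 3.0
    sibling_pool_size: int | None = None

    def __post_init__(self) -> None:
        for name in ("min_mutant_freq", "max_wt_freq", "sibling_alpha",
                     "sibling_expected_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.min_mutant_freq > self.max_wt_freq:
            raise ValueError(
                "min_mutant_freq must exceed max_wt_freq "
                f"({self.min_mutant_freq} <= {self.max_wt_freq})"
            )
        if not self.max_wt_freq < self.sibling_expected_freq < self.min_mutant_freq:
            raise ValueError(
                "sibling_expected_freq must lie strictly between max_wt_freq "
                "and min_mutant_freq"
            )
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")
        if self.sibling_pool_size is not None and self.sibling_pool_size < 1:
            raise ValueError("sibling_pool_size must be >= 1 when given")


@dataclass
class FilterResult:
    """Output of :func:`filter_candidates`: calls, candidates and the funnel."""

    calls: list[SegregationCall]
    candidates: list[SegregationCall]
    funnel: dict[str, int] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Sibling-ratio consistency tests


def sibling_ratio_test(
    alt_count: int,
    depth: int,
    expected_freq: float = 1.0 / 3.0,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Exact two-sided binomial test of sibling allele counts against `expected_freq`.

    Two-sidedness follows the minimum-likelihood convention: the p-value sums
    the probabilities of all outcomes whose point probability does not exceed
    that of the observed one.  Returns ``(p_value, consistent)`` where
    ``consistent`` means ``p_value >= alpha``.
    """
    if depth < 1:
        raise ValueError("sibling depth is zero; no ratio test possible (low_depth)")
    if not 0 <= alt_count <= depth:
        raise ValueError(f"alt_count={alt_count} outside [0, depth={depth}]")
    if not 0.0 <= expected_freq <= 1.0:
        raise ValueError(f"expected_freq must be in [0, 1], got {expected_freq}")
    p = stats.binomtest(alt_count, depth, expected_freq).pvalue
    return float(p), bool(p >= alpha)


@lru_cache(maxsize=None)
def _compound_null_pmf(depth: int, pool_size: int, expected_freq: float) -> np.ndarray:
    """Null pmf of sibling alt counts, marginalized over pool composition.

    Among phenotypically normal offspring of a selfed heterozygote the
    heterozygote fraction is ``2 * expected_freq`` (2/3 for the Mendelian
    1/3); a pool of n embryos with k heterozygotes has true allele frequency
    k / (2n).  The read counts are binomial given that frequency, so the
    marginal null is a binomial mixture.
    """
    p_het = 2.0 * expected_freq
    if not 0.0 <= p_het <= 1.0:
        raise ValueError(
            "pool-aware sibling null requires expected_freq <= 0.5 "
            f"(got {expected_freq})"
        )
    k = np.arange(pool_size + 1)
    weights = stats.binom.pmf(k, pool_size, p_het)
    x = np.arange(depth + 1)
    pmf = np.zeros(depth + 1)
    for ki, w in zip(k, weights):
        pmf += w * stats.binom.pmf(x, depth, ki / (2.0 * pool_size))
    return pmf


@lru_cache(maxsize=None)
def _compound_pvalue(alt: int, depth: int, pool_size: int, expected_freq: float) -> float:
    pmf = _compound_null_pmf(depth, pool_size, expected_freq)
    # relative tolerance guards against ties broken by floating-point noise
    return float(pmf[pmf <= pmf[alt] * (1.0 + 1e-12)].sum())


def sibling_pool_test(
    alt_count: int,
    depth: int,
    pool_size: int,
    expected_freq: float = 1.0 / 3.0,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Exact sibling consistency test accounting for finite pool size.

    Same minimum-likelihood two-sided convention as
    :func:`sibling_ratio_test`, but the null mixes the binomial read model
    over the embryo composition of a pool of ``pool_size`` phenotypically
    normal sibs.  Converges to the read-level test as ``pool_size`` grows.
    """
    if depth < 1:
        raise ValueError("sibling depth is zero; no ratio test possible (low_depth)")
    if not 0 <= alt_count <= depth:
        raise ValueError(f"alt_count={alt_count} outside [0, depth={depth}]")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    p = _compound_pvalue(alt_count, depth, pool_size, float(expected_freq))
    return p, bool(p >= alpha)


@lru_cache(maxsize=None)
def _cached_sibling_pvalue(
    alt: int, depth: int, expected_freq: float, pool_size: int | None
) -> float:
    if pool_size is None:
        return float(stats.binomtest(alt, depth, expected_freq).pvalue)
    return _compound_pvalue(alt, depth, pool_size, expected_freq)


# --------------------------------------------------------------------------
# Classification


def classify_segregation(
    v: PooledVariant, t: FilterThresholds | None = None
) -> SegregationCall:
    """Assign `v` to exactly one segregation class.

    Decision order: ``low_depth`` (any pool below ``min_depth``) →
    ``strain_fixed`` (all three pools at high frequency: a line-vs-reference
    difference, phenotype-uninformative) → ``wt_contaminated`` (alt allele
    present in the wild-type strain) → ``non_segregating`` (not enriched in
    the mutant pool) → ``sibling_ratio_inconsistent`` (sibling counts reject
    the Mendelian 1/3) → ``candidate``.
    """
    t = t or FilterThresholds()
    freqs = {pool: v.frequency(pool) for pool in POOLS}
    if any(v.counts[pool][1] < t.min_depth for pool in POOLS):
        return SegregationCall(v.variant_id, "low_depth", freqs)
    if all(freqs[pool] >= t.min_mutant_freq for pool in POOLS):
        return SegregationCall(v.variant_id, "strain_fixed", freqs)
    if freqs["wt"] > t.max_wt_freq:
        return SegregationCall(v.variant_id, "wt_contaminated", freqs)
    if freqs["mutant"] < t.min_mutant_freq:
        return SegregationCall(v.variant_id, "non_segregating", freqs)
    alt, depth = v.counts["sibling"]
    p = _cached_sibling_pvalue(
        alt, depth, float(t.sibling_expected_freq), t.sibling_pool_size
    )
    if p < t.sibling_alpha:
        return SegregationCall(v.variant_id, "sibling_ratio_inconsistent", freqs, p)
    return SegregationCall(v.variant_id, "candidate", freqs, p)


_COUNT_COLS = (
    "mut_alt", "mut_depth", "sib_alt", "sib_depth", "wt_alt", "wt_depth",
)


def classify_table(
    variants: pd.DataFrame, t: FilterThresholds | None = None
) -> pd.DataFrame:
    """Vectorized :func:`classify_segregation` over a variant table.

    `variants` must carry the count columns ``mut_alt, mut_depth, sib_alt,
    sib_depth, wt_alt, wt_depth`` (and ``variant_id``).  Returns a calls
    frame with observed frequencies, classification and the sibling test
    p-value (NaN where the decision was reached before the sibling stage).
    """
    t = t or FilterThresholds()
    for col in _COUNT_COLS:
        if col not in variants.columns:
            raise ValueError(f"variant table lacks required column {col!r}")
    n = len(variants)
    mut_alt = variants["mut_alt"].to_numpy(dtype=np.int64)
    mut_dep = variants["mut_depth"].to_numpy(dtype=np.int64)
    sib_alt = variants["sib_alt"].to_numpy(dtype=np.int64)
    sib_dep = variants["sib_depth"].to_numpy(dtype=np.int64)
    wt_alt = variants["wt_alt"].to_numpy(dtype=np.int64)
    wt_dep = variants["wt_depth"].to_numpy(dtype=np.int64)

    with np.errstate(invalid="ignore", divide="ignore"):
        f_mut = np.where(mut_dep > 0, mut_alt / np.maximum(mut_dep, 1), np.nan)
        f_sib = np.where(sib_dep > 0, sib_alt / np.maximum(sib_dep, 1), np.nan)
        f_wt = np.where(wt_dep > 0, wt_alt / np.maximum(wt_dep, 1), np.nan)

    cls = np.full(n, "", dtype=object)
    p_sib = np.full(n, np.nan)

    low = (mut_dep < t.min_depth) | (sib_dep < t.min_depth) | (wt_dep < t.min_depth)
    cls[low] = "low_depth"
    undecided = ~low

    fixed = undecided & (f_mut >= t.min_mutant_freq) & (f_sib >= t.min_mutant_freq) \
        & (f_wt >= t.min_mutant_freq)
    cls[fixed] = "strain_fixed"
    undecided &= ~fixed

    contaminated = undecided & (f_wt > t.max_wt_freq)
    cls[contaminated] = "wt_contaminated"
    undecided &= ~contaminated

    nonseg = undecided & (f_mut < t.min_mutant_freq)
    cls[nonseg] = "non_segregating"
    undecided &= ~nonseg

    exp = float(t.sibling_expected_freq)
    for i in np.flatnonzero(undecided):
        p = _cached_sibling_pvalue(
            int(sib_alt[i]), int(sib_dep[i]), exp, t.sibling_pool_size
        )
        p_sib[i] = p
        cls[i] = "candidate" if p >= t.sibling_alpha else "sibling_ratio_inconsistent"

    out = pd.DataFrame(
        {
            "variant_id": variants["variant_id"].to_numpy()
            if "variant_id" in variants.columns
            else np.arange(n).astype(str),
            "classification": cls,
            "freq_mut": f_mut,
            "freq_sib": f_sib,
            "freq_wt": f_wt,
            "sibling_p": p_sib,
        }
    )
    return out


def _as_table(variants: Iterable[PooledVariant] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(variants, pd.DataFrame):
        return variants
    rows = []
    for v in variants:
        row = {
            "variant_id": v.variant_id,
            "mut_alt": v.counts["mutant"][0],
            "mut_depth": v.counts["mutant"][1],
            "sib_alt": v.counts["sibling"][0],
            "sib_depth": v.counts["sibling"][1],
            "wt_alt": v.counts["wt"][0],
            "wt_depth": v.counts["wt"][1],
        }
        rows.append(row)
    return pd.DataFrame(rows)


def filter_candidates(
    variants: Sequence[PooledVariant] | pd.DataFrame,
    t: FilterThresholds | None = None,
) -> FilterResult:
    """Classify every variant and return the candidates plus a funnel summary.

    Candidates are returned in input order.  The funnel counts every
    classification and the number of sibling tests performed, so downstream
    users can apply a multiplicity correction if they wish (none is applied
    here: the filter is a screen).
    """
    t = t or FilterThresholds()
    table = _as_table(variants)
    if len(table) == 0:
        warnings.warn("empty variant table: no candidates", stacklevel=2)
        funnel = {"total": 0, "tested_sibling_ratio": 0}
        funnel.update({c: 0 for c in CLASSIFICATIONS})
        return FilterResult(calls=[], candidates=[], funnel=funnel)
    calls_df = classify_table(table, t)
    calls = [
        SegregationCall(
            variant_id=str(r.variant_id),
            classification=str(r.classification),
            observed_frequencies={
                "mutant": float(r.freq_mut),
                "sibling": float(r.freq_sib),
                "wt": float(r.freq_wt),
            },
            sibling_test_p=None if np.isnan(r.sibling_p) else float(r.sibling_p),
        )
        for r in calls_df.itertuples(index=False)
    ]
    candidates = [c for c in calls if c.classification == "candidate"]
    funnel = {"total": len(calls)}
    counts = calls_df["classification"].value_counts()
    for c in CLASSIFICATIONS:
        funnel[c] = int(counts.get(c, 0))
    funnel["tested_sibling_ratio"] = int(calls_df["sibling_p"].notna().sum())
    return FilterResult(calls=calls, candidates=candidates, funnel=funnel)
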