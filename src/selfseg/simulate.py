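"""Synthetic pooled-sequencing data from a mutagenized, self-fertilizing pedigree.

The generator emulates the three-pool bulk-segregant design used to map a
recessive mutation in an isogenic, self-fertilizing line: RNA from mutant
embryos, their phenotypically normal siblings, and the parental wild-type
strain is pooled and sequenced, and per-variant allele depths are compared
across the pools.

Model, in brief:

* A mutagenized founder carries one causal mutation plus background
  mutations, all heterozygous when they arise.  The line is maintained by
  self-fertilisation, under which the heterozygote fraction halves each
  generation (h_g = h0 · 2^-g); background sites therefore either still
  segregate or have drifted to fixation in the line by the time the mapped
  brood is produced.
* The brood parent is heterozygous at the causal locus.  Mutant-pool
  embryos are homozygous mutant (frequency 1), the wild-type strain carries
  no mutant allele (frequency 0), and phenotypically normal siblings are
  1/3 homozygous reference + 2/3 heterozygous, so the sibling pool's
  expected mutant-allele frequency is 1/3.
* Pools mix embryos with equal mass; a pool's true allele frequency is the
  mean of its embryos' genotype dosages (0, 1/2, 1).  Reads are then drawn
  per pool: depth ~ Poisson(mean_depth), alt count ~ Binomial(depth,
  f·(1−e) + (1−f)·e) with per-read miscall probability e.

Every dataset ships with ground truth (which variant is causal, true pool
frequencies, planted coding effects) so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import CdsModel, CodingEffect, annotate_substitution, translate_codon

__all__ = [
    "PedigreeConfig",
    "GenotypeDistribution",
    "TruthRecord",
    "SimulatedDataset",
    "genotype_distribution_after_selfing",
    "residual_heterozygosity",
    "sample_pool_counts",
    "selfed_offspring_dosages",
    "simulate_dataset",
]


@dataclass(frozen=True)
class GenotypeDistribution:
    """Proportions of the three diallelic genotypes at one locus."""

    p_homozygous_ref: float
    p_heterozygous: float
    p_homozygous_alt: float

    def __post_init__(self) -> None:
        for name in ("p_homozygous_ref", "p_heterozygous", "p_homozygous_alt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = self.p_homozygous_ref + self.p_heterozygous + self.p_homozygous_alt
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"genotype probabilities sum to {total}, not 1")

    @property
    def allele_frequency(self) -> float:
        """Alt-allele frequency implied by the genotype proportions."""
        return self.p_homozygous_alt + 0.5 * self.p_heterozygous


def genotype_distribution_after_selfing(
    parent: GenotypeDistribution, generations: int
) -> GenotypeDistribution:
    """Apply the selfing transition `generations` times.

    Each generation the heterozygote proportion halves; each half of the
    lost heterozygosity moves to one homozygote class.  The allele
    frequency is preserved exactly.
    """
    if generations < 0:
        raise ValueError(f"generations must be >= 0, got {generations}")
    het = parent.p_heterozygous
    hom_ref = parent.p_homozygous_ref
    hom_alt = parent.p_homozygous_alt
    for _ in range(generations):
        lost = het / 2.0
        het -= lost
        hom_ref += lost / 2.0
        hom_alt += lost / 2.0
    return GenotypeDistribution(hom_ref, het, hom_alt)


def residual_heterozygosity(h0: float, generations: int) -> float:
    """Heterozygosity after `generations` rounds of selfing: h0 · 2^-g."""
    if not 0.0 <= h0 <= 1.0:
        raise ValueError(f"h0 must be in [0, 1], got {h0}")
    if generations < 0:
        raise ValueError(f"generations must be >= 0, got {generations}")
    return h0 * 0.5 ** generations


def sample_pool_counts(
    true_frequency: float,
    depth: int,
    error_rate: float,
    seed: int | np.random.Generator | None = None,
) -> tuple[int, int]:
    """Draw (alt_count, total_depth) for one pool at one variant.

    A read reports the alt allele with probability
    ``f·(1−e) + (1−f)·e``: either it samples a mutant molecule and is read
    correctly, or it samples a wild-type molecule and is miscalled.
    """
    if not 0.0 <= true_frequency <= 1.0:
        raise ValueError(f"true_frequency must be in [0, 1], got {true_frequency}")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError(f"error_rate must be in [0, 1], got {error_rate}")
    if depth < 0:
        raise ValueError(f"depth must be >= 0, got {depth}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = true_frequency * (1.0 - error_rate) + (1.0 - true_frequency) * error_rate
    return int(rng.binomial(depth, p)), int(depth)


def selfed_offspring_dosages(
    parent_genotype: str, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Alt-allele dosages (0, 1 or 2) of `n` selfed offspring of one parent.

    Homozygous parents breed true; a heterozygote's offspring receive two
    independent Bernoulli(1/2) gametes (the 1:2:1 Mendelian ratio).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if parent_genotype == "hom_ref":
        return np.zeros(n, dtype=np.int64)
    if parent_genotype == "hom_alt":
        return np.full(n, 2, dtype=np.int64)
    if parent_genotype == "het":
        return rng.binomial(2, 0.5, size=n).astype(np.int64)
    raise ValueError(
        f"unknown parent genotype {parent_genotype!r}; "
        "expected hom_ref, het or hom_alt"
    )


@dataclass(frozen=True)
class PedigreeConfig:
    """Parameters of the simulated mutagenesis + selfing pedigree.

    Defaults describe the study design this generator emulates: pools of 12
    embryos, one recessive fully penetrant causal substitution at CDS
    position 574 of its gene, a few hundred phenotype-independent background
    mutations (a fraction 7/19 of them coding), Poisson read depth around
    100 and a post-trimming Illumina miscall rate of 1e-3.
    """

    n_background_variants: int = 500
    residual_het_fraction: float = 1.0
    selfing_generations: int = 3
    n_mutant_embryos: int = 12
    n_sibling_embryos: int = 12
    n_wt_embryos: int = 12
    mean_depth: float = 100.0
    error_rate: float = 0.001
    causal_cds_position: int = 574
    coding_fraction: float = 7.0 / 19.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_variants < 0:
            raise ValueError("n_background_variants must be >= 0")
        for name in ("n_mutant_embryos", "n_sibling_embryos", "n_wt_embryos"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("residual_het_fraction", "error_rate", "coding_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if self.causal_cds_position < 1:
            raise ValueError("causal_cds_position must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated variant."""

    variant_id: str
    is_causal: bool
    true_pool_allele_frequency: Mapping[str, float]
    coding_status: str
    planted_effect: CodingEffect | None = None


@dataclass
class SimulatedDataset:
    """One simulated screen: variant table, truth, sequences and annotations.

    ``variants`` carries the pooled counts plus the variant→gene mapping
    (``gene_id``/``cds_pos`` empty for noncoding sites).  ``alignments``
    maps each coding gene to a gap-free ortholog protein alignment as
    ``(record_id, sequence)`` pairs with the reference named after the gene.
    """

    config: PedigreeConfig
    variants: pd.DataFrame
    truth: pd.DataFrame
    truth_records: list[TruthRecord]
    cds: dict[str, CdsModel]
    alignments: dict[str, list[tuple[str, str]]]
    domains: pd.DataFrame
    causal_variant_id: str = ""

    def __post_init__(self) -> None:
        if not self.causal_variant_id:
            causal = self.truth.loc[self.truth["is_causal"], "variant_id"]
            self.causal_variant_id = str(causal.iloc[0])


# --------------------------------------------------------------------------
# gene construction

# planted causal codon and alt base for each within-codon position, chosen so
# the causal change is always a radical missense: R→C (180), C→F (205), C→W (215)
_CAUSAL_PLANT = {1: ("CGT", "T"), 2: ("TGT", "T"), 3: ("TGT", "G")}

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = np.array(
    sorted(
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in _STOPS
    )
)
_AA_LETTERS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_cds(rng: np.random.Generator, n_codons: int,
                planted: dict[int, str]) -> str:
    """Random stop-free CDS with an ATG start and codons forced at `planted` (1-based)."""
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    codons = _NONSTOP_CODONS[idx].tolist()
    codons[0] = "ATG"
    for ci, codon in planted.items():
        codons[ci - 1] = codon
    return "".join(codons)


def _make_ortholog(
    rng: np.random.Generator,
    protein: str,
    conserved: tuple[int, int] | None = None,
    force_mismatch_at: int | None = None,
    divergence: float = 0.1,
) -> str:
    """Mutate ~`divergence` of residues; optionally protect a conserved
    1-based interval or force a mismatch at one residue."""
    arr = np.array(list(protein))
    mask = rng.random(len(arr)) < divergence
    if conserved is not None:
        mask[conserved[0] - 1: conserved[1]] = False
    if force_mismatch_at is not None:
        mask[force_mismatch_at - 1] = True
    pos = np.flatnonzero(mask)
    if pos.size:
        repl = _AA_LETTERS[rng.integers(0, len(_AA_LETTERS), size=pos.size)]
        same = repl == arr[pos]
        if same.any():
            shift = _AA_LETTERS[
                (np.searchsorted(_AA_LETTERS, repl[same]) + 1) % len(_AA_LETTERS)
            ]
            repl[same] = shift
        arr[pos] = repl
    return "".join(arr.tolist())


def _translate(cds: str) -> str:
    return "".join(translate_codon(cds[i: i + 3]) for i in range(0, len(cds), 3))


# --------------------------------------------------------------------------


def simulate_dataset(config: PedigreeConfig | None = None) -> SimulatedDataset:
    """Simulate one three-pool screen with exactly one planted causal variant.

    The causal variant is a fully penetrant recessive radical missense
    substitution inside a planted functional domain of its gene; background
    variants are phenotype-independent, a configurable fraction of them
    coding (planted as synonymous or conservative-missense changes).  Same
    config (including seed) reproduces the same dataset byte for byte.
    """
    cfg = config or PedigreeConfig()
    rng = np.random.default_rng(cfg.seed)
    n_bg = cfg.n_background_variants

    # --- causal gene -------------------------------------------------------
    causal_gene = "gene_causal"
    ci = (cfg.causal_cds_position - 1) // 3 + 1
    pic = (cfg.causal_cds_position - 1) % 3 + 1
    codon, alt_base = _CAUSAL_PLANT[pic]
    n_codons = max(210, ci + 18)
    causal_cds = CdsModel(causal_gene, _random_cds(rng, n_codons, {ci: codon}))
    ref_base = codon[pic - 1]
    causal_effect = annotate_substitution(
        causal_cds, cfg.causal_cds_position, ref_base, alt_base
    )
    domain_rows = [
        {
            "gene_id": causal_gene,
            "name": "death_domain",
            "start": max(1, ci - 39),
            "end": min(n_codons, ci + 16),
        }
    ]
    cds_catalogue = {causal_gene: causal_cds}
    causal_protein = _translate(causal_cds.cds_sequence)
    alignments = {
        causal_gene: [
            (causal_gene, causal_protein),
            (f"{causal_gene}_ortholog1",
             _make_ortholog(rng, causal_protein,
                            conserved=(domain_rows[0]["start"], domain_rows[0]["end"]))),
            (f"{causal_gene}_ortholog2",
             _make_ortholog(rng, causal_protein,
                            conserved=(domain_rows[0]["start"], domain_rows[0]["end"]))),
        ]
    }

    # --- background variant composition ------------------------------------
    is_coding = rng.random(n_bg) < cfg.coding_fraction
    is_synonymous = rng.random(n_bg) < 0.5  # among the coding ones
    # parent genotype at each background locus after g maintenance generations
    p_het = residual_heterozygosity(
        cfg.residual_het_fraction, cfg.selfing_generations
    )
    p_fixed_alt = cfg.residual_het_fraction * (1.0 - 0.5 ** cfg.selfing_generations) / 2.0
    u = rng.random(n_bg)
    state = np.where(u < p_het, 0, np.where(u < p_het + p_fixed_alt, 1, 2))
    # 0 = parent heterozygous, 1 = fixed alt in the line, 2 = fixed ref

    # pool frequencies: for a het parent, each pool of n embryos carries
    # 2n independent Bernoulli(1/2) gametes
    n_mut, n_sib = cfg.n_mutant_embryos, cfg.n_sibling_embryos
    het_mask = state == 0
    mut_f_bg = np.where(state == 1, 1.0, 0.0)
    sib_f_bg = mut_f_bg.copy()
    n_het = int(het_mask.sum())
    mut_f_bg[het_mask] = rng.binomial(2 * n_mut, 0.5, size=n_het) / (2 * n_mut)
    sib_f_bg[het_mask] = rng.binomial(2 * n_sib, 0.5, size=n_het) / (2 * n_sib)
    wt_f_bg = np.zeros(n_bg)

    # causal locus: mutants homozygous, normal sibs 1/3 RR : 2/3 Rr
    k_het_sibs = rng.binomial(n_sib, 2.0 / 3.0)
    causal_freqs = (1.0, k_het_sibs / (2.0 * n_sib), 0.0)

    # --- per-variant metadata ----------------------------------------------
    causal_row = int(rng.integers(0, n_bg + 1))
    meta: list[dict] = []
    truth_records: list[TruthRecord] = []
    noncoding_pos = 0
    for i in range(n_bg + 1):
        vid = f"v{i:05d}"
        if i == causal_row:
            meta.append(
                {
                    "variant_id": vid,
                    "contig": causal_gene,
                    "pos": cfg.causal_cds_position,
                    "ref": ref_base,
                    "alt": alt_base,
                    "gene_id": causal_gene,
                    "cds_pos": cfg.causal_cds_position,
                }
            )
            truth_records.append(
                TruthRecord(
                    variant_id=vid,
                    is_causal=True,
                    true_pool_allele_frequency={
                        "mutant": causal_freqs[0],
                        "sibling": causal_freqs[1],
                        "wt": causal_freqs[2],
                    },
                    coding_status="coding",
                    planted_effect=causal_effect,
                )
            )
            continue
        j = i if i < causal_row else i - 1  # background index
        freqs = {
            "mutant": float(mut_f_bg[j]),
            "sibling": float(sib_f_bg[j]),
            "wt": float(wt_f_bg[j]),
        }
        if is_coding[j]:
            gid = f"gene_bg{j:05d}"
            bg_ci = int(rng.integers(2, 100))
            if is_synonymous[j]:
                planted, cds_pos, b_ref, b_alt = "GCT", 3 * bg_ci, "T", "C"
            else:
                planted, cds_pos, b_ref, b_alt = "TCT", 3 * bg_ci - 2, "T", "A"
            cds = CdsModel(gid, _random_cds(rng, 100, {bg_ci: planted}))
            cds_catalogue[gid] = cds
            effect = annotate_substitution(cds, cds_pos, b_ref, b_alt)
            prot = _translate(cds.cds_sequence)
            force = bg_ci if rng.random() < 0.8 else None
            alignments[gid] = [
                (gid, prot),
                (f"{gid}_ortholog1",
                 _make_ortholog(rng, prot, force_mismatch_at=force)),
                (f"{gid}_ortholog2",
                 _make_ortholog(rng, prot, force_mismatch_at=force)),
            ]
            if rng.random() < 0.3:
                a = int(rng.integers(1, 90))
                domain_rows.append(
                    {"gene_id": gid, "name": "domain",
                     "start": a, "end": a + int(rng.integers(5, 11))}
                )
            meta.append(
                {
                    "variant_id": vid,
                    "contig": gid,
                    "pos": cds_pos,
                    "ref": b_ref,
                    "alt": b_alt,
                    "gene_id": gid,
                    "cds_pos": cds_pos,
                }
            )
            truth_records.append(
                TruthRecord(vid, False, freqs, "coding", effect)
            )
        else:
            noncoding_pos += 997  # arbitrary spacing on an unplaced scaffold
            bases = "ACGT"
            rb = bases[int(rng.integers(0, 4))]
            ab = bases[(bases.index(rb) + 1 + int(rng.integers(0, 3))) % 4]
            meta.append(
                {
                    "variant_id": vid,
                    "contig": "noncoding_scaffold",
                    "pos": noncoding_pos,
                    "ref": rb,
                    "alt": ab,
                    "gene_id": "",
                    "cds_pos": np.nan,
                }
            )
            truth_records.append(TruthRecord(vid, False, freqs, "noncoding", None))

    # --- read counts --------------------------------------------------------
    freq_matrix = np.empty((n_bg + 1, 3))
    for row, rec in enumerate(truth_records):
        freq_matrix[row, 0] = rec.true_pool_allele_frequency["mutant"]
        freq_matrix[row, 1] = rec.true_pool_allele_frequency["sibling"]
        freq_matrix[row, 2] = rec.true_pool_allele_frequency["wt"]
    e = cfg.error_rate
    p_read = freq_matrix * (1.0 - e) + (1.0 - freq_matrix) * e
    depths = rng.poisson(cfg.mean_depth, size=freq_matrix.shape)
    alts = rng.binomial(depths, p_read)

    variants = pd.DataFrame(meta)
    variants["mut_alt"] = alts[:, 0]
    variants["mut_depth"] = depths[:, 0]
    variants["sib_alt"] = alts[:, 1]
    variants["sib_depth"] = depths[:, 1]
    variants["wt_alt"] = alts[:, 2]
    variants["wt_depth"] = depths[:, 2]

    truth = pd.DataFrame(
        {
            "variant_id": [t.variant_id for t in truth_records],
            "is_causal": [t.is_causal for t in truth_records],
            "true_freq_mutant": freq_matrix[:, 0],
            "true_freq_sibling": freq_matrix[:, 1],
            "true_freq_wt": freq_matrix[:, 2],
            "coding_status": [t.coding_status for t in truth_records],
        }
    )
    domains = pd.DataFrame(domain_rows, columns=["gene_id", "name", "start", "end"])
    return SimulatedDataset(
        config=cfg,
        variants=variants,
        truth=truth,
        truth_records=truth_records,
        cds=cds_catalogue,
        alignments=alignments,
        domains=domains,
        causal_variant_id=truth_records[causal_row].variant_id,
    )
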