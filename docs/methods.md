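# Methods

## The mapping design

`selfseg` targets screens in self-fertilizing, highly isogenic lines. A
mutagenized founder carries induced point mutations heterozygously; because
the animal selfs, a carrier line can be maintained without crosses, and any
brood from a heterozygous parent contains homozygous mutant embryos at the
Mendelian 1/4. Pooled sequencing of three groups — mutant embryos,
phenotypically normal siblings, and the parental wild-type strain — then
separates the causal variant from everything else by allele frequency
alone:

| pool | expected mutant-allele frequency |
|---|---|
| mutant | 1 |
| sibling (normal phenotype) | 1/3 |
| wild-type strain | 0 |

The sibling value follows from conditioning the selfed 1:2:1 genotype
ratio on the non-mutant phenotype: 1/3 `+/+` + 2/3 `+/m`, so the wild-type
allele is exactly twice as abundant as the mutant allele. This 2:1 ratio is
the decisive check: mutations that drifted to fixation in the line are also
100% in the mutant pool and 0% in the wild type, but sit near 100% in the
siblings and are rejected by the ratio test.

## Segregation filter

Classification is a fixed decision cascade, so every variant receives
exactly one label: `low_depth` (any pool under `min_depth`) →
`strain_fixed` (all pools ≥ `min_mutant_freq`) → `wt_contaminated`
(wild-type frequency > `max_wt_freq`) → `non_segregating` (mutant frequency
< `min_mutant_freq`) → sibling ratio test → `candidate`.

Defaults: `min_mutant_freq = 0.95`, `max_wt_freq = 0.05`, `min_depth = 10`,
`sibling_alpha = 0.05`, `sibling_expected_freq = 1/3`. The literal 100%/0%
signature is attainable only at infinite depth with error-free reads; the
5% tolerances make the filter robust to finite noisy counts and are
configurable. No multiplicity correction is applied — the filter is a
screen — but the funnel reports how many sibling tests were run so users
can Bonferroni downstream.

### Sibling ratio test and the pool-size effect

`sibling_ratio_test` is the exact two-sided binomial test of the sibling
alt count against 1/3, with the minimum-likelihood two-sidedness
convention (the p-value sums all outcomes whose point probability does not
exceed the observed one). It is implemented with `scipy.stats.binomtest`
and verified in the tests against an independent enumeration oracle at
every depth up to 200.

For small pools the read-level binomial is the wrong null: the pool's true
allele frequency is itself a random draw (with 12 normal siblings, the
number of heterozygous embryos is Binomial(12, 2/3), so the pool frequency
is k/24 with standard deviation ≈ 0.068). Read counts are therefore
overdispersed relative to Binomial(depth, 1/3), and the read-level test
rejects a genuinely causal variant ~14% of the time at depth 50 (worse at
higher depth). `sibling_pool_test` fixes this with the exact compound
null — the binomial mixed over the pool composition — which is calibrated
at any depth and converges to the read-level test for large pools. The
classifier uses it whenever `FilterThresholds.sibling_pool_size` is set;
the pipeline sets it from the known pool size. With unknown pool sizes the
read-level test remains the default.

## Effect annotation

Coordinates are 1-based CDS positions counted from the A of ATG, on the
coding strand only (minus-strand inputs must be reverse-complemented
upstream; this contract is tested). `codon_index = ceil(p/3)`,
`pos_in_codon = ((p−1) mod 3) + 1` — position 574 is the first base of
codon 192. Translation uses the standard nuclear genetic code (table 1)
via Biopython's codon table. Reference mismatches are hard errors, not
warnings, because silent strand/offset bugs are the dominant failure mode
of effect annotation. Only single-nucleotide substitutions are supported;
indels and MNVs are rejected explicitly.

## Prioritization

The verbal judgement "Ser→Thr occurs freely in natural variation, Arg→Cys
is drastic" is operationalized with the Grantham (1974) physicochemical
distance, embedded as the full symmetric 20×20 matrix and binned as
conservative < 100 ≤ moderate ≤ 150 < radical (boundaries configurable).
This places S/T (58) in the conservative bin and R/C (180) in the radical
bin, reproducing both judgements with one citable scale.

Conservation is the match-to-reference fraction at the aligned column
(reference gaps skipped when mapping residue → column; ortholog gaps count
as mismatch). With ortholog panels of a handful of species, column entropy
is uninformative; match fraction is not. The "highly conserved" reporting
flag requires 1.0 for alignments of ≤ 5 sequences and 0.9 otherwise.
Domain intervals are user-supplied annotations (1-based, inclusive), never
computed.

Ranking is lexicographic and total: effect class (nonsense > stop-loss >
missense > synonymous > noncoding), severity bin, conservation descending,
in-domain first, variant id ascending. Missing evidence (no alignment, no
domains) sorts below any present value of the same key.

## Simulator

The generator's defaults describe the study conditions it emulates:

| parameter | default | rationale |
|---|---|---|
| `n_mutant/sibling/wt_embryos` | 12 | embryos pooled per group in the emulated design |
| `n_background_variants` | 500 | desk-scale screen size |
| `coding_fraction` | 7/19 | coding share of the emulated variant funnel |
| `residual_het_fraction` (h₀) | 1.0 | induced mutations arise heterozygous in the founder |
| `selfing_generations` (g) | 3 | line maintenance between mutagenesis and the mapped brood |
| `mean_depth` | 100 | moderate-expression transcript in a pooled RNA-seq lane |
| `error_rate` | 0.001 | post-Q20-trimming Illumina miscall rate |
| `causal_cds_position` | 574 | first base of codon 192 of the causal gene |

Mechanics: a background site's brood-parent genotype is heterozygous with
probability h₀·2⁻ᵍ, else fixed (alt or ref with equal probability — the
selfing limit). A pool's true allele frequency is the equal-mass mean of
its embryos' genotype dosages; for a heterozygous parent each pool of n
embryos receives 2n independent Bernoulli(1/2) gametes. The causal locus
is conditioned: mutant-pool embryos homozygous mutant (frequency exactly
1), siblings 1/3 `+/+` : 2/3 `+/m`, wild-type strain 0. Reads are then
depth ~ Poisson(`mean_depth`) and alt ~ Binomial(depth, f·(1−e)+(1−f)·e)
per pool. Background coding variants are planted as synonymous or
conservative-missense (Ser→Thr) substitutions, each on its own synthetic
gene with a three-sequence ortholog alignment; the causal gene carries a
radical missense substitution inside a planted "death domain" interval
whose residues are conserved across its orthologs.

One `numpy` Generator seeded from `PedigreeConfig.seed` drives the whole
dataset; the same config reproduces the dataset byte for byte (tested).

**What the generator does not model** — and hence what passing tests do
not show about real data: read-level artifacts (mapping error, strand
bias, duplicates), allele-specific expression and expression-linked depth
(depth is Poisson, independent of genotype), linkage between variants
(sites segregate independently), shared polymorphism between the line and
the wild-type strain (the `strain_fixed` and `wt_contaminated` classes
arise only from real data or sequencing error here), and any de novo
assembly or variant-calling stage upstream of the allele-count table.

## Operating characteristics

With the defaults above, the pool-aware sibling test rejects the true
causal variant ≈ 4–5% of the time (it is an exact 5%-level test under the
true generating mechanism; this is the irreducible screening loss at
α = 0.05), and the mutant/wild-type gates lose ≈ 0.4%. The acceptance
tests measure a causal filter-recovery and rank-1 rate ≥ 95% over 2000
simulated screens, and the read-level test's type-I rate ≤ 5% at the
read-level null. The test suite sizes (2000 screens, 4000 null variants,
full enumeration at depths ≤ 200) were chosen to keep Monte-Carlo noise
well below the margins being asserted while running in a couple of minutes
on one CPU.

## Limitations

* The funnel counts of a real screen depend on upstream assembly and
  variant discovery, which are out of scope; `selfseg` starts from a
  per-variant allele-count table (TSV or VCF with `AD`).
* The sibling compound null assumes equal-mass pooling and independent
  embryos; severe expression imbalance between embryos would overdisperse
  beyond it.
* Severity, conservation and domain evidence are combined
  lexicographically, not as a learned score; with rich ortholog panels a
  quantitative model could do better.
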