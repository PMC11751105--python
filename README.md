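# selfseg

Mutant-gene identification from pooled sequencing of **self-fertilizing
isogenic lines**.

Forward-genetic screens in selfing hermaphrodite models (e.g. the mangrove
killifish *Kryptolebias marmoratus*) have an unusual luxury: a mutagenized
founder selfs into a nearly isogenic line, so a recessive mutation can be
mapped by a single sequencing run of three phenotype-defined pools — mutant
embryos, their phenotypically normal siblings, and the parental wild-type
strain — without any genetic mapping cross. `selfseg` implements that
mapping as a reusable, tested pipeline:

1. **Segregation filter** — a fully penetrant recessive causal variant must
   show mutant-pool allele frequency ≈ 1, wild-type-pool frequency ≈ 0, and
   an intermediate sibling frequency consistent with the Mendelian
   expectation **1/3** (phenotypically normal offspring of a selfed
   heterozygote are 1/3 `+/+` and 2/3 `+/m`, so the wild-type allele is
   exactly twice as abundant as the mutant allele). The sibling check is an
   exact two-sided binomial test; an optional pool-size-aware compound null
   keeps the test calibrated for small embryo pools.
2. **Effect annotation** — maps each candidate onto its CDS, with
   `codon_index = ceil(p/3)`, translates reference and alternate codons
   under the standard genetic code, and classifies synonymous / missense /
   nonsense / stop-loss changes (e.g. C→T at CDS position 574 of an
   arginine `CGT` codon → **R192C**).
3. **Prioritization** — ranks candidates by Grantham substitution severity
   (Ser→Thr = 58, conservative; Arg→Cys = 180, radical), ortholog
   conservation of the affected residue, and overlap with annotated
   functional domains.
4. **Simulator** — a synthetic ENU-mutagenesis + selfing pedigree generator
   that emulates the three-pool design with known ground truth (heterozygote
   fraction halves each selfed generation, h_g = h₀·2⁻ᵍ), so the whole
   pipeline can be exercised and power-checked at desk scale.

## Worked example

Simulate a screen (200 background variants plus one planted recessive
causal missense variant) and run the full pipeline:

```bash
selfseg simulate --seed 7 --out data --n-background 200
cat > run.yaml <<EOF
variants: data/variants.tsv
cds_fasta: data/cds.fasta
alignments_dir: data/alignments
domains: data/domains.tsv
out_dir: out
thresholds:
  sibling_pool_size: 12
EOF
selfseg run-all --config run.yaml
```

prints

```
{"candidates": 1, "ranked": 1, "total": 201}
 rank variant_id     gene_id effect_class substitution  grantham severity  conservation  in_domain      domains
    1     v00033 gene_causal     missense        R192C       180  radical           1.0       True death_domain
```

Of 201 variants, exactly one survives the segregation filter, and it is the
planted causal variant (`data/truth.tsv` confirms `v00033` is the planted
truth): a missense substitution replacing arginine 192 with cysteine —
Grantham distance 180 (radical), affected residue conserved in every
ortholog, inside the annotated death domain. The funnel in
`out/funnel.json` shows where the other 200 variants fell: 111 were not
enriched in the mutant pool (`non_segregating`) and 89 were perfectly
enriched but failed the sibling 2:1 ratio test
(`sibling_ratio_inconsistent` — mutations fixed in the line, the classic
false-positive class of this design).

The stages also run separately (`selfseg filter`, `selfseg annotate`,
`selfseg prioritize`) and read/write plain TSV, VCFv4.2 (samples
`MUT/SIB/WT` with `AD`), FASTA and aligned FASTA; see
`selfseg <cmd> --help`.

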