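"""Readers and writers for the formats the pipeline touches.

Variant tables travel as TSV (columns ``variant_id, contig, pos, ref, alt,
mut_alt, mut_depth, sib_alt, sib_depth, wt_alt, wt_depth`` plus the optional
gene mapping ``gene_id, cds_pos``) or as VCFv4.2 with three sample columns
``MUT, SIB, WT`` carrying per-sample allele depths (``AD``); the gene
mapping rides in the ``GENE``/``CDSPOS`` INFO fields so the two dialects
round-trip losslessly.  Sequences use FASTA, ortholog panels aligned FASTA
(one file per gene, reference record named after the gene), domains a
4-column TSV, configuration YAML.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO

from .annotation import CdsModel
from .segregation import FilterThresholds
from .simulate import PedigreeConfig, SimulatedDataset

__all__ = [
    "FormatError",
    "ConfigError",
    "PipelineConfig",
    "read_variants",
    "read_variants_tsv",
    "read_variants_vcf",
    "write_variants_tsv",
    "write_variants_vcf",
    "read_cds_fasta",
    "write_cds_fasta",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_domains_tsv",
    "write_domains_tsv",
    "write_dataset",
    "load_config",
]

VCF_SAMPLES = ("MUT", "SIB", "WT")

_REQUIRED_COLS = [
    "variant_id", "contig", "pos", "ref", "alt",
    "mut_alt", "mut_depth", "sib_alt", "sib_depth", "wt_alt", "wt_depth",
]
_COUNT_PAIRS = [("mut_alt", "mut_depth"), ("sib_alt", "sib_depth"),
                ("wt_alt", "wt_depth")]


class FormatError(ValueError):
    """A file does not parse under the named dialect."""


class ConfigError(ValueError):
    """The run configuration is inconsistent or incomplete."""


# --------------------------------------------------------------------------
# variant tables


def _validate_variants(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing required column(s) {missing}")
    problems = []
    for alt_col, dep_col in _COUNT_PAIRS:
        bad = df.index[(df[alt_col] < 0) | (df[alt_col] > df[dep_col])]
        problems.extend(
            f"row {i + 2}: {alt_col}={df.at[i, alt_col]} outside "
            f"[0, {dep_col}={df.at[i, dep_col]}]"
            for i in bad
        )
    if (df["pos"] < 1).any():
        problems.extend(
            f"row {i + 2}: pos={df.at[i, 'pos']} < 1"
            for i in df.index[df["pos"] < 1]
        )
    same = df.index[df["ref"] == df["alt"]]
    problems.extend(f"row {i + 2}: ref equals alt" for i in same)
    if problems:
        raise FormatError(f"{source}: " + "; ".join(problems[:10]))
    if "gene_id" not in df.columns:
        df = df.assign(gene_id="", cds_pos=np.nan)
    df["gene_id"] = df["gene_id"].fillna("")
    return df


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    """Read a pooled-variant TSV, validating counts row by row."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "contig": str})
    return _validate_variants(df, str(path))


def write_variants_tsv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "cds_pos" in out.columns:
        out["cds_pos"] = out["cds_pos"].astype("Int64")
    out.to_csv(path, sep="\t", index=False)


def write_variants_vcf(df: pd.DataFrame, path: str | Path) -> None:
    """Write the table as VCFv4.2 with AD-carrying samples MUT, SIB, WT."""
    header = pysam.VariantHeader()
    for contig in pd.unique(df["contig"]):
        header.contigs.add(str(contig))
    header.formats.add("AD", "R", "Integer",
                       "Allelic depths for the ref and alt alleles")
    header.info.add("GENE", 1, "String", "Gene the variant maps to")
    header.info.add("CDSPOS", 1, "Integer", "1-based CDS position in GENE")
    for sample in VCF_SAMPLES:
        header.add_sample(sample)
    pools = [("MUT", "mut_alt", "mut_depth"), ("SIB", "sib_alt", "sib_depth"),
             ("WT", "wt_alt", "wt_depth")]
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in df.itertuples(index=False):
            rec = vcf.new_record(
                contig=str(row.contig),
                start=int(row.pos) - 1,
                alleles=(str(row.ref), str(row.alt)),
                id=str(row.variant_id),
            )
            gene = getattr(row, "gene_id", "")
            if isinstance(gene, str) and gene:
                rec.info["GENE"] = gene
                cds_pos = getattr(row, "cds_pos", None)
                if cds_pos is not None and not pd.isna(cds_pos):
                    rec.info["CDSPOS"] = int(cds_pos)
            for sample, alt_col, dep_col in pools:
                alt = int(getattr(row, alt_col))
                dep = int(getattr(row, dep_col))
                rec.samples[sample]["AD"] = (dep - alt, alt)
            vcf.write(rec)


def read_variants_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF with samples MUT, SIB, WT carrying AD fields.

    Frequencies downstream use alt/(ref+alt), ignoring any other alleles;
    multi-allelic records are split with a warning, keeping each listed alt
    against the reference depth.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        missing = [s for s in VCF_SAMPLES if s not in samples]
        if missing:
            raise ConfigError(
                f"{path}: VCF lacks required sample(s) {missing}; found {samples}"
            )
        if "AD" not in vcf.header.formats:
            raise FormatError(f"{path}: VCF header lacks the AD FORMAT field")
        has_gene = "GENE" in vcf.header.info
        has_cdspos = "CDSPOS" in vcf.header.info
        for n, rec in enumerate(vcf, start=1):
            alts = rec.alts or ()
            if len(alts) > 1:
                warnings.warn(
                    f"{path}: record {rec.id or n} is multi-allelic; "
                    "splitting per alt allele",
                    stacklevel=2,
                )
            for ai, alt in enumerate(alts, start=1):
                row = {
                    "variant_id": rec.id or f"{rec.contig}_{rec.pos}_{alt}",
                    "contig": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                    "gene_id": rec.info.get("GENE", "") if has_gene else "",
                    "cds_pos": float(rec.info["CDSPOS"])
                    if has_cdspos and "CDSPOS" in rec.info else np.nan,
                }
                for sample, prefix in zip(VCF_SAMPLES, ("mut", "sib", "wt")):
                    ad = rec.samples[sample].get("AD")
                    if ad is None or ad[0] is None:
                        raise FormatError(
                            f"{path}: record {rec.id or n} sample {sample} "
                            "has no AD field"
                        )
                    ref_d, alt_d = int(ad[0]), int(ad[ai])
                    row[f"{prefix}_alt"] = alt_d
                    row[f"{prefix}_depth"] = ref_d + alt_d
                rows.append(row)
    df = pd.DataFrame(rows, columns=_REQUIRED_COLS + ["gene_id", "cds_pos"])
    return _validate_variants(df, str(path))


def read_variants(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a variant table, inferring TSV vs VCF from the suffix if needed."""
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "tsv":
        return read_variants_tsv(path)
    if format == "vcf":
        return read_variants_vcf(path)
    raise ConfigError(f"unknown variant-table format {format!r}")


# --------------------------------------------------------------------------
# sequences, alignments, domains


def read_cds_fasta(path: str | Path) -> dict[str, CdsModel]:
    """Read a CDS catalogue: record IDs are gene IDs."""
    catalogue = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        catalogue[rec.id] = CdsModel(rec.id, str(rec.seq).upper())
    if not catalogue:
        raise FormatError(f"{path}: no FASTA records found")
    return catalogue


def write_cds_fasta(catalogue: Mapping[str, CdsModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id, cds in catalogue.items():
            fh.write(f">{gene_id}\n")
            seq = cds.cds_sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")


def read_alignment_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA as (id, sequence) pairs."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if len({len(s) for _, s in records}) != 1:
        raise FormatError(f"{path}: aligned FASTA rows have unequal lengths")
    return records


def write_alignment_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_domains_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "name", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: domain TSV missing column(s) {missing}")
    bad = df.index[(df["start"] > df["end"]) | (df["start"] < 1)]
    if len(bad):
        raise FormatError(
            f"{path}: malformed domain interval(s) at row(s) "
            f"{[int(i) + 2 for i in bad]}"
        )
    return df


def write_domains_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset: variants (TSV + VCF), truth, CDS, alignments, domains."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants_tsv": outdir / "variants.tsv",
        "variants_vcf": outdir / "variants.vcf",
        "truth": outdir / "truth.tsv",
        "cds_fasta": outdir / "cds.fasta",
        "domains": outdir / "domains.tsv",
        "alignments_dir": outdir / "alignments",
    }
    write_variants_tsv(ds.variants, paths["variants_tsv"])
    write_variants_vcf(ds.variants, paths["variants_vcf"])
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    write_cds_fasta(ds.cds, paths["cds_fasta"])
    write_domains_tsv(ds.domains, paths["domains"])
    paths["alignments_dir"].mkdir(exist_ok=True)
    for gene_id, records in ds.alignments.items():
        write_alignment_fasta(records, paths["alignments_dir"] / f"{gene_id}.afa")
    return paths


# --------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs: paths, thresholds, severity bins, simulator."""

    variants: str | None = None
    format: str | None = None
    cds_fasta: str | None = None
    alignments_dir: str | None = None
    domains: str | None = None
    out_dir: str = "selfseg_out"
    seed: int = 0
    log_level: str = "INFO"
    thresholds: FilterThresholds = dataclasses.field(default_factory=FilterThresholds)
    severity_conservative_below: float = 100.0
    severity_radical_above: float = 150.0
    simulate: PedigreeConfig = dataclasses.field(default_factory=PedigreeConfig)

    def require_inputs(self) -> None:
        if self.variants is None:
            raise ConfigError("no variant table configured")
        for name in ("variants", "cds_fasta", "domains"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured {name} path does not exist: {p}")
        if self.alignments_dir is not None and not Path(self.alignments_dir).is_dir():
            raise ConfigError(
                f"configured alignments_dir is not a directory: {self.alignments_dir}"
            )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML run configuration (unknown keys are rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown configuration key(s) {sorted(unknown)}")
    kwargs = dict(raw)
    try:
        if "thresholds" in kwargs:
            kwargs["thresholds"] = FilterThresholds(**kwargs["thresholds"])
        if "simulate" in kwargs:
            kwargs["simulate"] = PedigreeConfig(**kwargs["simulate"])
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
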