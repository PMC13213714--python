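"""Pyrimidine-collapsed 96-channel trinucleotide mutational spectra.

A somatic single-nucleotide variant is classified by its substitution type
and its immediate 5'/3' flanking bases. Substitutions with a purine
reference (A or G) are mapped to the reverse-complement strand so that
every variant is expressed with a pyrimidine (C or T) reference, giving
6 substitution classes x 4 x 4 flanks = 96 channels. The channel order is
the COSMIC convention: substitution class major (C>A, C>G, C>T, T>A, T>C,
T>G), then 5' flank (A, C, G, T), then 3' flank (A, C, G, T); downstream
loaders always align by label, never by row position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sigsubtype.errors import (
    FormatError,
    InconsistentContextError,
    MalformedRecordError,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"
PYRIMIDINE_SUBS = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical channel labels, e.g. ``A[C>A]A``; fixed order, length 96.
CHANNEL_LABELS: list[str] = [
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in PYRIMIDINE_SUBS
    for five in BASES
    for three in BASES
]

_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNEL_LABELS)}

#: Default MAF-dialect column names.
DEFAULT_MAF_COLUMNS = {
    "sample": "Tumor_Sample_Barcode",
    "chromosome": "Chromosome",
    "position": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "context": "ref_context",
}


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise MalformedRecordError(f"non-ACGT base in {seq!r}") from exc


@dataclass(frozen=True)
class MutationRecord:
    """A validated somatic SNV with its trinucleotide context.

    ``position`` is 1-based (MAF convention); VCF input is converted on
    read. ``context`` is the 3-mer centered on the variant with the middle
    base equal to ``ref_allele`` (as written in the input, i.e. possibly
    purine-referenced; strand collapse happens at channel assignment).
    """

    sample_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    context: str

    def __post_init__(self) -> None:
        for b in (self.ref_allele, self.alt_allele):
            if b not in _COMPLEMENT:
                raise MalformedRecordError(f"allele {b!r} is not a single ACGT base")
        if self.ref_allele == self.alt_allele:
            raise MalformedRecordError("ref and alt alleles are identical")
        if len(self.context) != 3 or any(b not in _COMPLEMENT for b in self.context):
            raise MalformedRecordError(f"context {self.context!r} is not an ACGT 3-mer")
        if self.context[1] != self.ref_allele:
            raise InconsistentContextError(
                f"context {self.context!r} middle base != ref allele {self.ref_allele!r}"
            )

    @property
    def channel(self) -> int:
        return collapse_substitution(self.ref_allele, self.alt_allele, self.context)


def collapse_substitution(ref: str, alt: str, context: str) -> int:
    """Map a raw (ref, alt, context) substitution class to its channel index.

    Purine-referenced mutations are reverse-complemented to the pyrimidine
    representation first, so the map is an exact 2-to-1 surjection from the
    192 raw classes onto the 96 channels.
    """
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise MalformedRecordError(f"alleles ({ref!r}, {alt!r}) must be single ACGT bases")
    if ref == alt:
        raise MalformedRecordError("ref and alt alleles are identical")
    if len(context) != 3:
        raise MalformedRecordError(f"context {context!r} must be a 3-mer")
    if context[1] != ref:
        raise InconsistentContextError(
            f"context {context!r} middle base != ref allele {ref!r}"
        )
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = reverse_complement(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    try:
        return _CHANNEL_INDEX[label]
    except KeyError as exc:  # non-ACGT flank
        raise MalformedRecordError(f"context {context!r} contains a non-ACGT base") from exc


@dataclass
class ReadReport:
    """Per-file accounting of accepted and skipped variant rows."""

    n_accepted: int = 0
    n_skipped_indel_mnv: int = 0
    n_skipped_non_acgt: int = 0
    n_skipped_duplicate: int = 0
    n_skipped_other: int = 0
    skipped_rows: list[int] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return (
            self.n_skipped_indel_mnv
            + self.n_skipped_non_acgt
            + self.n_skipped_duplicate
            + self.n_skipped_other
        )


def _context_from_fasta(fasta, chromosome: str, position: int) -> str | None:
    """1-based trinucleotide lookup around ``position`` via a pyfaidx handle."""
    try:
        seq = str(fasta[chromosome][position - 2 : position + 1]).upper()
    except (KeyError, ValueError):
        return None
    return seq if len(seq) == 3 else None


def _validate_row(
    sample: str,
    chromosome: str,
    position: int,
    ref: str,
    alt: str,
    context: str | None,
    fasta,
    report: ReadReport,
) -> MutationRecord | None:
    ref, alt = str(ref).strip().upper(), str(alt).strip().upper()
    if len(ref) != 1 or len(alt) != 1 or "-" in (ref, alt):
        report.n_skipped_indel_mnv += 1
        return None
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        report.n_skipped_non_acgt += 1
        return None
    if context is None and fasta is not None:
        context = _context_from_fasta(fasta, chromosome, position)
    if context is None:
        report.n_skipped_other += 1
        return None
    context = str(context).strip().upper()
    if len(context) != 3 or any(b not in _COMPLEMENT for b in context):
        report.n_skipped_non_acgt += 1
        return None
    if context[1] != ref:
        report.n_skipped_other += 1
        return None
    return MutationRecord(sample, str(chromosome), int(position), ref, alt, context)


def read_maf(
    path,
    columns: dict[str, str] | None = None,
    fasta_path=None,
    deduplicate: bool = True,
) -> tuple[list[MutationRecord], ReadReport]:
    """Read a MAF-dialect TSV and return validated SNV records plus a report.

    Indels, MNVs, and rows with ambiguous bases are dropped with logged
    counts. When the context column is absent, ``fasta_path`` (an indexed
    FASTA) supplies the trinucleotide contexts. Duplicate records (same
    sample, chromosome, position, ref, alt) are counted once unless
    ``deduplicate=False``.
    """
    cols = dict(DEFAULT_MAF_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["sample", "chromosome", "position", "ref", "alt"]
    missing = [cols[key] for key in required if cols[key] not in df.columns]
    if missing:
        raise FormatError(f"MAF file {path} is missing required column(s): {missing}")
    has_context = cols["context"] in df.columns
    fasta = None
    if not has_context:
        if fasta_path is None and len(df) > 0:
            raise FormatError(
                f"MAF file {path} has no {cols['context']!r} column and no reference "
                "FASTA was supplied for context lookup"
            )
        if fasta_path is not None:
            from pyfaidx import Fasta

            fasta = Fasta(str(fasta_path))

    report = ReadReport()
    records: list[MutationRecord] = []
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        rec = _validate_row(
            row[cols["sample"]],
            row[cols["chromosome"]],
            int(float(row[cols["position"]])),
            row[cols["ref"]],
            row[cols["alt"]],
            row[cols["context"]] if has_context else None,
            fasta,
            report,
        )
        if rec is None:
            continue
        key = (rec.sample_id, rec.chromosome, rec.position, rec.ref_allele, rec.alt_allele)
        if deduplicate and key in seen:
            report.n_skipped_duplicate += 1
            continue
        seen.add(key)
        records.append(rec)
        report.n_accepted += 1
    if len(df) == 0:
        logger.warning("MAF file %s contains a header but no variant rows", path)
    if report.n_skipped:
        logger.info(
            "MAF %s: accepted %d SNVs, skipped %d rows (%d indel/MNV, %d non-ACGT, "
            "%d duplicate, %d other)",
            path,
            report.n_accepted,
            report.n_skipped,
            report.n_skipped_indel_mnv,
            report.n_skipped_non_acgt,
            report.n_skipped_duplicate,
            report.n_skipped_other,
        )
    return records, report


def read_vcf(
    path,
    sample_id: str | None = None,
    fasta_path=None,
    deduplicate: bool = True,
) -> tuple[list[MutationRecord], ReadReport]:
    """Read SNVs from a (plain-text or bgzipped) VCF.

    Positions are already 1-based in VCF. For a single-sample file the
    sample column name is used unless ``sample_id`` overrides it; a
    site-only VCF requires ``sample_id``. Contexts are resolved from
    ``fasta_path``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample_id is None:
        if len(vcf.samples) == 1:
            sample_id = vcf.samples[0]
        else:
            raise FormatError(
                f"VCF {path} has {len(vcf.samples)} sample columns; pass sample_id"
            )
    fasta = None
    if fasta_path is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(fasta_path))
    report = ReadReport()
    records: list[MutationRecord] = []
    seen: set[tuple] = set()
    for variant in vcf:
        for alt in variant.ALT:
            rec = _validate_row(
                sample_id,
                variant.CHROM,
                variant.POS,
                variant.REF,
                alt,
                None,
                fasta,
                report,
            )
            if rec is None:
                continue
            key = (rec.sample_id, rec.chromosome, rec.position, rec.ref_allele, rec.alt_allele)
            if deduplicate and key in seen:
                report.n_skipped_duplicate += 1
                continue
            seen.add(key)
            records.append(rec)
            report.n_accepted += 1
    return records, report


def build_spectrum_matrix(
    records: list[MutationRecord],
    sample_order: list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate records into a samples x 96 count matrix.

    Row sums equal per-sample accepted-record counts; samples listed in
    ``sample_order`` but absent from ``records`` yield all-zero rows with
    a warning. Output columns carry the canonical channel labels.
    """
    if sample_order is None:
        sample_order = sorted({r.sample_id for r in records})
    index = {s: i for i, s in enumerate(sample_order)}
    counts = np.zeros((len(sample_order), 96), dtype=np.int64)
    for rec in records:
        if rec.sample_id not in index:
            raise FormatError(
                f"record sample {rec.sample_id!r} not present in sample_order"
            )
        counts[index[rec.sample_id], rec.channel] += 1
    empty = [s for s in sample_order if counts[index[s]].sum() == 0]
    if empty:
        logger.warning("%d sample(s) have zero accepted SNVs: %s", len(empty), empty[:10])
    return pd.DataFrame(counts, index=pd.Index(sample_order, name="sample"), columns=CHANNEL_LABELS)


def write_spectrum_matrix(spectra: pd.DataFrame, path) -> None:
    spectra.to_csv(path, sep="\t")


def read_spectrum_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in CHANNEL_LABELS if c not in df.columns]
    if missing:
        raise FormatError(f"spectrum matrix {path} lacks channel(s) {missing[:5]}...")
    return df[CHANNEL_LABELS]
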