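"""SNP-index mutant mapping: read QC, substituted reference, candidate scan.

A recessive mutation is mapped by resequencing the mutant, writing the
wild-type parent line's known SNPs into the public reference genome (so
only mutant-specific variants stand out), and computing for every SNP
site the SNP-index = alt reads / total reads.  With adequate depth, a
homozygous mutant variant has SNP-index near 1; sites with depth > 5 and
SNP-index > 0.9 (both strict) are extracted as homozygous candidates.
Alignment itself is out of scope: allele counts enter as VCF (AD fields)
or a 4-column table.  Coordinates are 1-based throughout (VCF
convention); FASTQ qualities are Phred+33 and Phred+64-looking input is
rejected rather than guessed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

__all__ = [
    "passes_quality",
    "fastq_quality_filter",
    "substitute_reference",
    "compute_snp_index",
    "extract_homozygous",
    "read_allele_counts_tsv",
    "read_allele_counts_vcf",
]

_BASES = frozenset("ACGT")


def passes_quality(
    qualities: Sequence[int], q_threshold: int = 30, max_fraction: float = 0.10
) -> bool:
    """Keep a read unless MORE than ``max_fraction`` of its bases fall
    below ``q_threshold`` (strict: exactly 10% sub-Q30 is kept).

    Depends only on the multiset of quality scores, not their order.
    """
    q = np.asarray(qualities)
    if q.size == 0:
        return False
    return (q < q_threshold).sum() / q.size <= max_fraction


def fastq_quality_filter(
    reads: str | Path | Iterable[SeqRecord],
    q_threshold: int = 30,
    max_fraction: float = 0.10,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Partition FASTQ reads into (kept, discarded) by base quality.

    A read is discarded iff the fraction of bases with quality below
    ``q_threshold`` strictly exceeds ``max_fraction``.  ``reads`` may be
    a FASTQ path (Phred+33) or an iterable of Biopython records carrying
    ``phred_quality`` annotations.  Paired-end data is handled per read;
    callers wanting pair dropping can intersect kept IDs.
    """
    if isinstance(reads, (str, Path)):
        records = SeqIO.parse(str(reads), "fastq")
    else:
        records = reads
    kept: list[SeqRecord] = []
    discarded: list[SeqRecord] = []
    for i, rec in enumerate(records):
        try:
            quals = rec.letter_annotations["phred_quality"]
        except KeyError as exc:
            raise ValueError(f"record {i} ({rec.id}): no quality scores") from exc
        if len(quals) != len(rec.seq):
            raise ValueError(f"record {i} ({rec.id}): quality/sequence length mismatch")
        if max(quals, default=0) > 60:
            raise ValueError(
                f"record {i} ({rec.id}): quality {max(quals)} implausible for "
                "Phred+33 - input looks Phred+64 encoded; re-encode it"
            )
        (kept if passes_quality(quals, q_threshold, max_fraction)
         else discarded).append(rec)
    return kept, discarded


def _as_records(reference) -> list[SeqRecord]:
    if isinstance(reference, (str, Path)):
        return list(SeqIO.parse(str(reference), "fasta"))
    if isinstance(reference, dict):
        return [SeqRecord(Seq(s), id=c, description="") for c, s in reference.items()]
    return list(reference)


def substitute_reference(
    reference,
    table: pd.DataFrame,
    strict: bool = True,
) -> tuple[list[SeqRecord], int]:
    """Write tabled SNP substitutions into a reference sequence.

    ``table`` needs columns chrom, position (1-based), ref_base,
    sub_base.  In strict mode, the sequence must carry ``ref_base`` at
    every tabled position; in lenient mode mismatches are skipped with a
    warning, which makes re-application idempotent (positions already
    carrying the substitute are left alone).  Returns the modified
    records and the number of effective substitutions; lengths are always
    preserved.
    """
    records = _as_records(reference)
    by_chrom = {rec.id: bytearray(str(rec.seq).upper(), "ascii") for rec in records}
    required = {"chrom", "position", "ref_base", "sub_base"}
    if not required.issubset(table.columns):
        raise ValueError(f"substitution table needs columns {sorted(required)}")
    if table.duplicated(["chrom", "position"]).any():
        raise ValueError("duplicate (chrom, position) rows in substitution table")

    n_sub = 0
    for row in table.itertuples(index=False):
        chrom, pos = row.chrom, int(row.position)
        ref_b, sub_b = row.ref_base.upper(), row.sub_base.upper()
        if ref_b not in _BASES or sub_b not in _BASES:
            raise ValueError(f"{chrom}:{pos}: bases must be A/C/G/T")
        if chrom not in by_chrom:
            raise ValueError(f"chromosome {chrom!r} not in reference")
        seq = by_chrom[chrom]
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"{chrom}:{pos}: position outside sequence "
                             f"of length {len(seq)}")
        current = chr(seq[pos - 1])
        if current != ref_b:
            if strict:
                raise ValueError(
                    f"{chrom}:{pos}: reference base is {current}, expected {ref_b}"
                )
            log.warning("%s:%d: reference base %s != expected %s; skipped",
                        chrom, pos, current, ref_b)
            continue
        if current != sub_b:
            seq[pos - 1] = ord(sub_b)
            n_sub += 1
    out = [
        SeqRecord(Seq(by_chrom[rec.id].decode("ascii")), id=rec.id,
                  description=rec.description)
        for rec in records
    ]
    return out, n_sub


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write FASTA wrapped at 60 columns (Biopython default)."""
    SeqIO.write(list(records), str(path), "fasta")


def compute_snp_index(counts: pd.DataFrame) -> pd.DataFrame:
    """Add the SNP-index (alt / depth) column to an allele-count table.

    Sites with zero depth get ``snp_index = NaN`` (flagged undefined,
    never coerced to 0) so downstream totals reconcile.
    """
    required = {"chrom", "position", "ref_count", "alt_count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    if (counts["ref_count"] < 0).any() or (counts["alt_count"] < 0).any():
        raise ValueError("negative read counts")
    out = counts.copy()
    depth = out["ref_count"] + out["alt_count"]
    out["depth"] = depth
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = out["alt_count"] / depth
    out["snp_index"] = idx.where(depth > 0, np.nan)
    return out


def extract_homozygous(
    rows: pd.DataFrame, min_depth: int = 5, min_index: float = 0.9
) -> pd.DataFrame:
    """Extract homozygous-candidate sites: depth > min_depth AND
    snp_index > min_index, both inequalities strict; output sorted by
    (chrom, position)."""
    if "snp_index" not in rows.columns:
        rows = compute_snp_index(rows)
    keep = (rows["depth"] > min_depth) & (rows["snp_index"] > min_index)
    return (rows[keep.fillna(False)]
            .sort_values(["chrom", "position"], kind="stable")
            .reset_index(drop=True))


def read_allele_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a (chrom, position, ref_count, alt_count) TSV, with or
    without a header row."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    try:
        int(first.iloc[0, 1])
        has_header = False
    except (TypeError, ValueError):
        has_header = True
    names = ["chrom", "position", "ref_count", "alt_count"]
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None,
                     names=names, usecols=range(4))
    return df.astype({"position": int, "ref_count": int, "alt_count": int})


def read_allele_counts_vcf(path: str | Path) -> pd.DataFrame:
    """Read biallelic allele counts from a VCF's AD genotype field.

    Multiallelic records are skipped with a warning; the first sample's
    AD is used.
    """
    import pysam

    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            sample = rec.samples[0]
            ad = sample.get("AD")
            if ad is None or len(ad) < 2:
                skipped += 1
                continue
            rows.append((rec.chrom, rec.pos, int(ad[0]), int(ad[1])))
    if skipped:
        log.warning("skipped %d multiallelic or AD-less VCF records", skipped)
    return pd.DataFrame(rows, columns=["chrom", "position",
                                       "ref_count", "alt_count"])
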