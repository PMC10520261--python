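"""Readers, interval arithmetic and codon-level mutation annotation.

This module owns the plumbing the rest of the pipeline sits on: FASTA coding
sequences (with optional one-base flanks encoded in the header), BED3 exon
intervals, and MAF-like mutation tables.  Coordinates follow each format's
ecosystem norm: BED is 0-based half-open, the mutation TSV is serialized
1-based and converted to 0-based internally.

All CDS are taken in coding orientation; no strand flipping happens here
(pyrimidine collapsing is the spectrum module's job).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "CodingSequence",
    "MutationRecord",
    "FormatError",
    "read_fasta",
    "read_bed",
    "merge_intervals",
    "annotate_mutation",
    "read_mutations",
]

DNA = set("ACGT")
DNA_N = set("ACGTN")

_FLANK_RE = re.compile(r"\|flank5=([ACGTN])\|flank3=([ACGTN])", re.IGNORECASE)


class FormatError(ValueError):
    """Malformed input file (names the record/line at fault)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open 0-based interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CodingSequence:
    """A complete CDS in coding orientation with one-base genomic flanks.

    The flanks supply trinucleotide context for the first and last base; ``N``
    means unknown and is later spread uniformly over the four bases.
    """

    gene: str
    seq: str
    flank5: str = "N"
    flank3: str = "N"

    def __post_init__(self) -> None:
        if set(self.seq) - DNA:
            bad = sorted(set(self.seq) - DNA)
            raise ValueError(f"{self.gene}: non-ACGT characters {bad} in CDS")
        if len(self.seq) % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length {len(self.seq)} not a multiple of 3")
        if self.flank5 not in DNA_N or self.flank3 not in DNA_N:
            raise ValueError(f"{self.gene}: flanks must be single bases in ACGTN")
        aa = str(Seq(self.seq).translate())
        if "*" in aa[:-1]:
            raise ValueError(f"{self.gene}: internal stop codon at residue {aa.index('*') + 1}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_residues(self) -> int:
        return len(self.seq) // 3

    def codon(self, codon_index: int) -> str:
        return self.seq[3 * codon_index : 3 * codon_index + 3]

    def context(self, cds_pos: int) -> str:
        """Trinucleotide context of a base, using flanks at the ends."""
        left = self.seq[cds_pos - 1] if cds_pos > 0 else self.flank5
        right = self.seq[cds_pos + 1] if cds_pos < len(self.seq) - 1 else self.flank3
        return left + self.seq[cds_pos] + right


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV on a CDS, annotated with consequence and context."""

    sample: str
    gene: str
    cds_pos: int  # 0-based index into the CDS
    ref: str
    alt: str
    consequence: str  # synonymous | missense | nonsense
    context: str  # trinucleotide, ref-centered, coding strand

    @property
    def residue(self) -> int:
        """1-based protein residue index."""
        return self.cds_pos // 3 + 1


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read coding sequences from FASTA.

    Records are keyed by the first whitespace-delimited header token; flanks
    default to N unless the header carries a ``|flank5=X|flank3=Y`` suffix.
    Sequences are uppercased; non-ACGTN characters raise :class:`FormatError`
    naming the record and offset (N in the body is rejected too — a CDS must
    be fully resolved).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    out = []
    for rec in records:
        name = rec.id
        flank5, flank3 = "N", "N"
        m = _FLANK_RE.search(name)
        if m:
            flank5, flank3 = m.group(1).upper(), m.group(2).upper()
            name = name[: m.start()]
        seq = str(rec.seq).upper()
        for off, ch in enumerate(seq):
            if ch not in DNA:
                raise FormatError(f"{path}: record {name!r} has invalid base {ch!r} at offset {off}")
        out.append(CodingSequence(gene=name, seq=seq, flank5=flank5, flank3=flank3))
    return out


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3 intervals (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >=3 tab-separated fields")
            try:
                intervals.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return intervals


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals per chromosome.

    Output is sorted by (chrom, start), pairwise disjoint, and covers exactly
    the union of input bases.  Idempotent.
    """
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def annotate_mutation(cds: CodingSequence, cds_pos: int, alt: str) -> tuple[str, str]:
    """Classify a single-base substitution and report its context.

    Returns ``(consequence, context)`` where consequence is derived from the
    standard genetic code applied to the mutated codon: a substitution that
    creates a stop is ``nonsense``; stop-loss is treated as ``missense`` (the
    downstream analyses only distinguish synonymous / missense / truncating).
    """
    if not (0 <= cds_pos < len(cds.seq)):
        raise ValueError(f"cds_pos {cds_pos} out of range for {cds.gene} (length {len(cds.seq)})")
    alt = alt.upper()
    ref = cds.seq[cds_pos]
    if alt == ref:
        raise ValueError(f"alt equals ref ({ref}) at cds_pos {cds_pos}")
    if alt not in DNA:
        raise ValueError(f"invalid alt base {alt!r}")
    ci, within = divmod(cds_pos, 3)
    codon = cds.codon(ci)
    mutated = codon[:within] + alt + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_alt == "*" and aa_ref != "*":
        consequence = "nonsense"
    elif aa_alt == aa_ref:
        consequence = "synonymous"
    else:
        # includes stop-loss (ref '*', alt amino acid)
        consequence = "missense"
    return consequence, cds.context(cds_pos)


MUTATION_COLUMNS = ["sample", "gene", "cds_pos", "ref", "alt"]


def read_mutations(
    path: str | Path,
    cds_index: dict[str, CodingSequence],
    strict: bool = False,
) -> tuple[list[MutationRecord], list[tuple[int, str]]]:
    """Read a mutation TSV (sample, gene, cds_pos 1-based, ref, alt).

    Every row is validated against its CDS (the stated ref must match the
    sequence) and annotated.  Returns ``(records, rejects)`` where rejects are
    ``(line_number, reason)`` pairs; with ``strict=True`` the first bad row
    raises instead.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records: list[MutationRecord] = []
    rejects: list[tuple[int, str]] = []

    def reject(line_no: int, reason: str) -> None:
        if strict:
            raise FormatError(f"{path}:{line_no}: {reason}")
        rejects.append((line_no, reason))

    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        gene = row.gene
        cds = cds_index.get(gene)
        if cds is None:
            reject(line_no, f"unknown gene {gene!r}")
            continue
        try:
            pos = int(row.cds_pos) - 1
        except (TypeError, ValueError):
            reject(line_no, f"non-integer cds_pos {row.cds_pos!r}")
            continue
        if not (0 <= pos < len(cds.seq)):
            reject(line_no, f"cds_pos {pos + 1} outside CDS of length {len(cds.seq)}")
            continue
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if ref != cds.seq[pos]:
            reject(line_no, f"ref mismatch: table says {ref}, CDS has {cds.seq[pos]}")
            continue
        try:
            consequence, context = annotate_mutation(cds, pos, alt)
        except ValueError as exc:
            reject(line_no, str(exc))
            continue
        records.append(
            MutationRecord(
                sample=str(row.sample),
                gene=gene,
                cds_pos=pos,
                ref=ref,
                alt=alt,
                consequence=consequence,
                context=context,
            )
        )
    return records, rejects
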