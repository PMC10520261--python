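"""Copy-number alteration calls and the patients x genes alteration matrix.

A gene's copy-number state in a tumour sample is judged against the sample's
own average ploidy: ``rel = log2(total_cn / ploidy)``.  A gene is *deleted*
when its total copy number is exactly zero or ``rel < -1``, and *amplified*
when ``rel > 1``; both inequalities are strict, so ``rel == -1`` or
``rel == 1`` is neutral, and an exact-zero copy number wins over everything.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .sequence_io import MutationRecord

__all__ = [
    "CopyNumberRecord",
    "AlterationMatrix",
    "relative_copy_number",
    "classify_cn",
    "build_alteration_matrix",
    "read_cn_table",
]

CALL_TYPES = ("missense", "truncating", "amplified", "deleted")


@dataclass(frozen=True)
class CopyNumberRecord:
    sample: str
    gene: str
    total_cn: float  # absolute copies of the gene
    ploidy: float  # sample average ploidy

    def __post_init__(self) -> None:
        if self.total_cn < 0:
            raise ValueError(f"total_cn must be >= 0, got {self.total_cn}")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be > 0, got {self.ploidy}")


def relative_copy_number(total_cn: float, ploidy: float) -> float:
    """log2 ratio of gene copy number to sample ploidy.

    ``total_cn == 0`` returns ``-inf`` (the deletion sentinel).
    """
    if ploidy <= 0:
        raise ValueError(f"ploidy must be > 0, got {ploidy}")
    if total_cn < 0:
        raise ValueError(f"total_cn must be >= 0, got {total_cn}")
    if total_cn == 0:
        return -math.inf
    return math.log2(total_cn / ploidy)


def classify_cn(total_cn: float, ploidy: float) -> str:
    """Call deleted / amplified / neutral from total copy number and ploidy."""
    if total_cn == 0:
        return "deleted"
    rel = relative_copy_number(total_cn, ploidy)
    if rel < -1:
        return "deleted"
    if rel > 1:
        return "amplified"
    return "neutral"


class AlterationMatrix:
    """Per-(sample, gene) sets of alteration calls plus summary fractions.

    A cell may carry several calls at once (e.g. a missense mutation in an
    amplified gene); ``deleted`` and ``amplified`` are mutually exclusive by
    construction of the classification rule.  Pairs absent from the inputs
    are wild-type, not missing: the sample and gene universes are explicit.
    """

    def __init__(self, samples: list[str], genes: list[str]) -> None:
        self.samples = list(samples)
        self.genes = list(genes)
        self.calls: dict[tuple[str, str], set[str]] = {}

    def add_call(self, sample: str, gene: str, call: str) -> None:
        if call not in CALL_TYPES:
            raise ValueError(f"unknown call type {call!r}")
        cell = self.calls.setdefault((sample, gene), set())
        cell.add(call)
        if {"deleted", "amplified"} <= cell:
            raise ValueError(f"({sample}, {gene}): deleted and amplified cannot co-occur")

    def cell(self, sample: str, gene: str) -> set[str]:
        return self.calls.get((sample, gene), set())

    def gene_fraction(self, gene: str) -> float:
        """Fraction of samples with any alteration in *gene*."""
        n = sum(1 for s in self.samples if self.cell(s, gene))
        return n / len(self.samples)

    def cohort_fraction(self, genes: list[str] | None = None) -> float:
        """Fraction of samples altered in at least one of the listed genes."""
        genes = self.genes if genes is None else genes
        n = sum(1 for s in self.samples if any(self.cell(s, g) for g in genes))
        return n / len(self.samples)

    def to_binary(self) -> pd.DataFrame:
        """Samples x genes 0/1 incidence (1 = any alteration call)."""
        data = {
            g: [1 if self.cell(s, g) else 0 for s in self.samples] for g in self.genes
        }
        return pd.DataFrame(data, index=self.samples, columns=self.genes)

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"sample": s, "gene": g, "call": c}
            for (s, g), cell in sorted(self.calls.items())
            for c in sorted(cell)
        ]
        return pd.DataFrame(rows, columns=["sample", "gene", "call"])

    def summary(self) -> dict:
        return {
            "n_samples": len(self.samples),
            "n_genes": len(self.genes),
            "gene_fractions": {g: self.gene_fraction(g) for g in self.genes},
            "cohort_fraction": self.cohort_fraction(),
        }

    def write(self, tsv_path: str | Path, summary_path: str | Path | None = None) -> None:
        self.to_long().to_csv(tsv_path, sep="\t", index=False)
        if summary_path is not None:
            Path(summary_path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def build_alteration_matrix(
    mutations: list[MutationRecord],
    cn: list[CopyNumberRecord],
    genes: list[str],
    samples: list[str],
) -> AlterationMatrix:
    """Assemble the alteration matrix from mutation and copy-number records.

    Missense records yield ``missense`` calls, nonsense records ``truncating``;
    copy-number records are classified with :func:`classify_cn`.  Synonymous
    mutations are not alterations.  A record whose sample or gene is outside
    the declared universe is an error (the universes define wild-type cells).
    """
    sample_set, gene_set = set(samples), set(genes)
    offenders = sorted(
        {(r.sample, r.gene) for r in mutations if r.sample not in sample_set or r.gene not in gene_set}
        | {(r.sample, r.gene) for r in cn if r.sample not in sample_set or r.gene not in gene_set}
    )
    if offenders:
        raise ValueError(f"records outside declared sample/gene universe: {offenders[:10]}")

    matrix = AlterationMatrix(samples, genes)
    for rec in mutations:
        if rec.consequence == "missense":
            matrix.add_call(rec.sample, rec.gene, "missense")
        elif rec.consequence == "nonsense":
            matrix.add_call(rec.sample, rec.gene, "truncating")
    for rec in cn:
        state = classify_cn(rec.total_cn, rec.ploidy)
        if state != "neutral":
            matrix.add_call(rec.sample, rec.gene, state)
    return matrix


def read_cn_table(path: str | Path) -> list[CopyNumberRecord]:
    """Read a copy-number TSV (sample, gene, total_cn, ploidy)."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample", "gene", "total_cn", "ploidy"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        CopyNumberRecord(str(r.sample), str(r.gene), float(r.total_cn), float(r.ploidy))
        for r in df.itertuples(index=False)
    ]
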