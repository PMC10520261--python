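"""Synthetic cohort generator with known ground truth.

Every input the pipeline consumes can be produced here: a coding sequence at
a requested GC content, a signature-driven somatic mutation catalog with
optional positional hotspots and nonsynonymous enrichment, per-sample
copy-number tables with planted amplifications/deletions, binary alteration
matrices with planted mutually exclusive gene pairs, and an idealized
alpha-helix structure for the 3D clustering test.

Each generator is a pure function of :class:`SimConfig`: reruns with the
same seed are bit-identical, and every generator draws from its own seed
substream so the outputs are independent of call order.  Hotspot and
selection enrichment act multiplicatively on the per-site rates before
renormalization, so an enriched catalog is still a proper probability
distribution over sites.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .copy_number import CopyNumberRecord
from .sequence_io import CodingSequence, MutationRecord, annotate_mutation
from .signatures import BASES, Signature, SiteRateTable, site_rates
from .spatial3d import StructureCoords

__all__ = [
    "SimConfig",
    "gen_cds",
    "gen_mutations",
    "gen_cn_table",
    "gen_alteration_matrix",
    "gen_helix_coords",
    "write_simulation",
]

STOP_CODONS = ("TAA", "TAG", "TGA")

# substream tags so each generator has its own independent stream per seed
_STREAM = {"cds": 1, "mutations": 2, "cn": 3, "alterations": 4}


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort in one place.

    Defaults emulate a mid-sized untargeted tumour-sequencing cohort: one
    ~500-codon gene, a few hundred SNVs spread over ~100 patients, near-
    diploid samples, and modest background alteration rates.
    """

    seed: int = 0
    # coding sequence
    gene: str = "GENE1"
    cds_length_codons: int = 500
    gc_fraction: float = 0.5
    # mutation catalog
    signature: str | Signature = "uniform"  # "uniform", "cpg" or a Signature
    n_mutations: int = 200
    hotspot: tuple[int, int, float] | None = None  # (start_res, end_res, multiplier)
    omega_true: float = 1.0  # nonsynonymous rate multiplier
    n_samples: int = 100
    # copy number
    cn_genes: tuple[str, ...] = ("GENE1", "GENE2", "GENE3")
    ploidy_mean: float = 2.0
    ploidy_sd: float = 0.15
    amplified_fractions: dict = field(default_factory=dict)  # gene -> fraction
    deleted_fractions: dict = field(default_factory=dict)
    # alteration matrix
    alt_genes: tuple[str, ...] = tuple(f"G{i}" for i in range(1, 9))
    background_rate: float = 0.2
    exclusivity_pairs: tuple[tuple[str, str], ...] = ()
    # idealized helix
    helix_n_residues: int = 200

    def __post_init__(self) -> None:
        if self.cds_length_codons < 2:
            raise ValueError("need at least 2 codons (start + stop)")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.omega_true <= 0:
            raise ValueError("omega_true must be > 0")
        if self.hotspot is not None:
            start, end, mult = self.hotspot
            if mult <= 0:
                raise ValueError("hotspot multiplier must be > 0")
            if not (1 <= start <= end <= self.cds_length_codons):
                raise ValueError("hotspot span must lie inside the CDS")
        both = set(self.amplified_fractions) & set(self.deleted_fractions)
        if both:
            raise ValueError(f"genes cannot be both amplified and deleted: {sorted(both)}")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream]])


def resolve_signature(sig: str | Signature) -> Signature:
    if isinstance(sig, Signature):
        return sig
    if sig == "uniform":
        return Signature.uniform()
    if sig in ("cpg", "CpG-heavy", "cpg-heavy"):
        return Signature.cpg_heavy()
    raise ValueError(f"unknown signature preset {sig!r}")


def gen_cds(config: SimConfig) -> CodingSequence:
    """Random CDS: ATG start, stop end, no internal stops, target GC.

    Internal codons are drawn base-by-base at the requested GC fraction and
    redrawn whenever a stop codon appears, so the realized GC tracks the
    target up to the (small) stop-rejection bias.
    """
    rng = config.rng("cds")
    gc = config.gc_fraction
    if config.cds_length_codons > 2 and gc in (0.0, 1.0):
        # all-AT codons are stop-prone but feasible; all-GC is fine; both allowed
        pass
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    n_internal = config.cds_length_codons - 2
    codons = []
    for _ in range(n_internal):
        while True:
            codon = "".join(rng.choice(list(BASES), size=3, p=p))
            if codon not in STOP_CODONS:
                break
        codons.append(codon)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    seq = "ATG" + "".join(codons) + stop
    flank5, flank3 = rng.choice(list(BASES), size=2)
    return CodingSequence(gene=config.gene, seq=seq, flank5=str(flank5), flank3=str(flank3))


def gen_mutations(
    cds: CodingSequence,
    config: SimConfig,
    rates: "SiteRateTable | None" = None,
) -> tuple[list[MutationRecord], dict]:
    """Sample a mutation catalog from the CDS's signature-driven site rates.

    Site rates come from ``site_rates(cds, signature)``; nonsynonymous rates
    are multiplied by ``omega_true`` and rates inside the hotspot residue
    span by its multiplier, then the whole table is renormalized and
    ``n_mutations`` (position, alt) draws are taken iid.  Each mutation is
    assigned to a uniformly random patient.  Returns the records plus a
    ground-truth dict.
    """
    rng = config.rng("mutations")
    signature = resolve_signature(config.signature)
    if rates is None:
        rates = site_rates(cds, signature)  # recomputable; pass it in when simulating repeatedly
    w = rates.rate.copy()
    if config.omega_true != 1.0:
        nonsyn = (rates.cons == 1) | (rates.cons == 2)
        w[nonsyn] *= config.omega_true
    if config.hotspot is not None:
        start, end, mult = config.hotspot
        w[3 * (start - 1) : 3 * end, :] *= mult
    flat = w.ravel()
    prob = flat / flat.sum()
    draws = rng.choice(len(flat), size=config.n_mutations, p=prob)
    sample_ids = rng.integers(config.n_samples, size=config.n_mutations)
    records = []
    for d, s in zip(draws, sample_ids):
        pos, alt_idx = divmod(int(d), 4)
        alt = BASES[alt_idx]
        consequence, context = annotate_mutation(cds, pos, alt)
        records.append(
            MutationRecord(
                sample=f"S{int(s):04d}",
                gene=cds.gene,
                cds_pos=pos,
                ref=cds.seq[pos],
                alt=alt,
                consequence=consequence,
                context=context,
            )
        )
    truth = {
        "gene": cds.gene,
        "signature": signature.name,
        "n_mutations": config.n_mutations,
        "omega_true": config.omega_true,
        "hotspot": list(config.hotspot) if config.hotspot else None,
        "seed": config.seed,
    }
    return records, truth


def gen_cn_table(config: SimConfig) -> tuple[list[CopyNumberRecord], pd.DataFrame]:
    """Copy-number table with planted amplified/deleted sample fractions.

    Per sample a ploidy is drawn around ``ploidy_mean``; a planted amplified
    gene gets total_cn = ploidy * 2^u with u in [1.2, 2.5] (safely past the
    rel > 1 rule), a planted deletion is total_cn = 0 half the time and
    ploidy * 2^-u otherwise; everything else sits exactly at ploidy
    (rel = 0).  Returns the records and a truth table of planted states.
    """
    rng = config.rng("cn")
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    ploidies = np.clip(
        rng.normal(config.ploidy_mean, config.ploidy_sd, size=config.n_samples), 1.0, None
    )
    records, truth_rows = [], []
    for gene in config.cn_genes:
        amp_frac = config.amplified_fractions.get(gene, 0.0)
        del_frac = config.deleted_fractions.get(gene, 0.0)
        u = rng.random(config.n_samples)
        for i, sample in enumerate(samples):
            ploidy = float(ploidies[i])
            if u[i] < amp_frac:
                state = "amplified"
                total_cn = ploidy * 2 ** rng.uniform(1.2, 2.5)
            elif u[i] < amp_frac + del_frac:
                state = "deleted"
                total_cn = 0.0 if rng.random() < 0.5 else ploidy * 2 ** -rng.uniform(1.2, 2.5)
            else:
                state = "neutral"
                total_cn = ploidy
            records.append(CopyNumberRecord(sample, gene, total_cn, ploidy))
            truth_rows.append({"sample": sample, "gene": gene, "state": state})
    return records, pd.DataFrame(truth_rows)


def gen_alteration_matrix(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Binary samples x genes matrix with planted mutually exclusive pairs.

    Background genes are independent Bernoulli(``background_rate``) columns;
    for every pair in ``exclusivity_pairs`` each sample is altered in exactly
    one of the two genes (fair coin), the XOR pattern the exclusivity test
    should flag.  Returns the matrix and the truth dict.
    """
    rng = config.rng("alterations")
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    genes = list(config.alt_genes)
    for a, b in config.exclusivity_pairs:
        for g in (a, b):
            if g not in genes:
                genes.append(g)
    M = (rng.random((config.n_samples, len(genes))) < config.background_rate).astype(int)
    df = pd.DataFrame(M, index=samples, columns=genes)
    for a, b in config.exclusivity_pairs:
        pick_a = rng.random(config.n_samples) < 0.5
        df[a] = pick_a.astype(int)
        df[b] = (~pick_a).astype(int)
    truth = {
        "background_rate": config.background_rate,
        "exclusivity_pairs": [list(p) for p in config.exclusivity_pairs],
        "seed": config.seed,
    }
    return df, truth


def gen_helix_coords(n_residues: int, chain: str = "A") -> StructureCoords:
    """Idealized alpha-helix C-alpha trace.

    Residue i sits at angle 100 degrees * i on a 2.3 A radius with a 1.5 A
    rise per residue — the textbook helix geometry (consecutive C-alphas
    ~3.8 A apart).  Deterministic; no randomness involved.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    i = np.arange(n_residues)
    theta = np.deg2rad(100.0 * i)
    xyz = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
    return StructureCoords(residues=i + 1, xyz=xyz, chain=chain)


def write_pdb(coords: StructureCoords, path: str | Path) -> None:
    """Write minimal CA-only ATOM records (fixed-column PDB)."""
    with open(path, "w") as fh:
        for serial, (res, (x, y, z)) in enumerate(zip(coords.residues, coords.xyz), start=1):
            fh.write(
                f"ATOM  {serial:5d}  CA  ALA {coords.chain}{res:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def write_fasta(cds: CodingSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{cds.gene}|flank5={cds.flank5}|flank3={cds.flank3}\n")
        for i in range(0, len(cds.seq), 60):
            fh.write(cds.seq[i : i + 60] + "\n")


def write_mutations_tsv(records: list[MutationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample": r.sample,
                "gene": r.gene,
                "cds_pos": r.cds_pos + 1,  # serialized 1-based
                "ref": r.ref,
                "alt": r.alt,
            }
            for r in records
        ],
        columns=["sample", "gene", "cds_pos", "ref", "alt"],
    ).to_csv(path, sep="\t", index=False)


def write_cn_tsv(records: list[CopyNumberRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample": r.sample, "gene": r.gene, "total_cn": r.total_cn, "ploidy": r.ploidy}
            for r in records
        ],
        columns=["sample", "gene", "total_cn", "ploidy"],
    ).to_csv(path, sep="\t", index=False)


def write_simulation(config: SimConfig, outdir: str | Path) -> dict:
    """Generate and write the full synthetic input set plus truth JSON.

    Produces cds.fasta, mutations.tsv, cn.tsv, alterations.tsv, helix.pdb
    and truth.json under ``outdir``; returns the truth dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cds = gen_cds(config)
    write_fasta(cds, outdir / "cds.fasta")
    mutations, mut_truth = gen_mutations(cds, config)
    write_mutations_tsv(mutations, outdir / "mutations.tsv")
    cn_records, cn_truth = gen_cn_table(config)
    write_cn_tsv(cn_records, outdir / "cn.tsv")
    alt_matrix, alt_truth = gen_alteration_matrix(config)
    alt_matrix.to_csv(outdir / "alterations.tsv", sep="\t", index_label="sample")
    helix = gen_helix_coords(config.helix_n_residues)
    write_pdb(helix, outdir / "helix.pdb")
    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, Signature)
        },
        "mutations": mut_truth,
        "cn_states": cn_truth.to_dict(orient="records"),
        "alterations": alt_truth,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth
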