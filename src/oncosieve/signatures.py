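"""Trinucleotide mutational spectra, signature refitting, and per-site
expected mutation rates.

The 96 channels follow the COSMIC pyrimidine-centered convention:
substitution classes C>A, C>G, C>T, T>A, T>C, T>G (in that order), each with
16 flanking contexts ordered A/C/G/T on the 5' side (outer) and A/C/G/T on
the 3' side (inner), i.e. A[C>A]A, A[C>A]C, ... T[T>G]T.  A substitution
observed with a purine reference is reverse-complemented into its pyrimidine
channel, so the spectrum is strand-symmetric by construction.

From a signature, every possible single-base substitution in a CDS gets a
relative rate (the signature probability of its channel), which drives the
expected per-residue mutation profile and the sliding-window
observed/expected track.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .sequence_io import CodingSequence, MutationRecord, annotate_mutation

__all__ = [
    "CHANNELS",
    "channel_index",
    "collapse_channel",
    "Spectrum",
    "Signature",
    "SiteRateTable",
    "ExpectedProfile",
    "ObsExpTrack",
    "mutation_spectrum",
    "refit_signature",
    "site_rates",
    "expected_profile",
    "obs_exp_track",
]

BASES = "ACGT"
PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CHANNELS: tuple[str, ...] = tuple(
    f"{l}[{sub}]{r}" for sub in PYRIMIDINE_SUBS for l in BASES for r in BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

# consequence codes used by SiteRateTable
CLASS_CODES = {"synonymous": 0, "missense": 1, "nonsense": 2}
CODE_CLASSES = {v: k for k, v in CLASS_CODES.items()}


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def channel_index(label: str) -> int:
    return _CHANNEL_INDEX[label]


def collapse_channel(context: str, alt: str) -> list[tuple[int, float]]:
    """Map a (trinucleotide context, alt) pair to weighted channel indices.

    Purine references are reverse-complemented into the pyrimidine channel.
    An ``N`` flank is spread uniformly over the four bases (weight 1/4 each).
    Returns an empty list when the substitution is unresolvable (N at the
    mutated base, or alt == ref).
    """
    left, ref, right = context[0], context[1], context[2]
    if ref == "N" or alt == "N" or alt == ref:
        return []
    if ref in "AG":  # purine: flip strand
        left, ref, right = _revcomp(right), _revcomp(ref)[0], _revcomp(left)
        alt = alt.translate(_COMPLEMENT)
    sub = f"{ref}>{alt}"
    lefts = BASES if left == "N" else left
    rights = BASES if right == "N" else right
    w = 1.0 / (len(lefts) * len(rights))
    return [(_CHANNEL_INDEX[f"{l}[{sub}]{r}"], w) for l in lefts for r in rights]


@dataclass
class Spectrum:
    """96-channel substitution counts.

    Counts may be fractional where an unknown flank spread a mutation over
    several channels; total mass always equals the number of contributing
    SNVs (``sum(counts) == n_input - n_skipped``).
    """

    counts: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have 96 channels")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": CHANNELS, "count": self.counts})

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class Signature:
    """96-channel substitution probability vector (sums to one)."""

    probs: np.ndarray
    name: str = "signature"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (96,):
            raise ValueError("signature must have 96 channels")
        if (self.probs < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"signature must sum to 1, got {self.probs.sum()!r}")

    @classmethod
    def uniform(cls) -> "Signature":
        return cls(np.full(96, 1.0 / 96), name="uniform")

    @classmethod
    def cpg_heavy(cls, boost: float = 10.0) -> "Signature":
        """C>T at NpCpG contexts boosted *boost*-fold, then renormalized.

        A crude stand-in for deamination-driven processes concentrated at CpG
        dinucleotides; useful for stressing context handling.
        """
        probs = np.full(96, 1.0)
        for l in BASES:
            probs[_CHANNEL_INDEX[f"{l}[C>T]G"]] *= boost
        return cls(probs / probs.sum(), name="CpG-heavy")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": CHANNELS, "probability": self.probs})

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, name: str | None = None) -> "Signature":
        df = pd.read_csv(path, sep="\t")
        if list(df["channel"]) != list(CHANNELS):
            raise ValueError(f"{path}: channels not in COSMIC order")
        return cls(df["probability"].to_numpy(), name=name or str(path))


def mutation_spectrum(mutations: list[MutationRecord]) -> Spectrum:
    """Accumulate annotated mutations into a 96-channel spectrum.

    Records whose substitution cannot be resolved to any channel are skipped
    and tallied in ``n_skipped``.
    """
    counts = np.zeros(96)
    skipped = 0
    for rec in mutations:
        entries = collapse_channel(rec.context, rec.alt)
        if not entries:
            skipped += 1
            continue
        for idx, w in entries:
            counts[idx] += w
    return Spectrum(counts=counts, n_skipped=skipped)


def refit_signature(
    spectrum: Spectrum,
    reference: np.ndarray | None = None,
    pseudocount: float = 0.5,
) -> tuple[Signature, np.ndarray | None]:
    """Turn an observed spectrum into a signature.

    Without a reference catalog the spectrum is pseudocount-smoothed
    (``pseudocount`` added per channel) and normalized.  With a 96 x K
    reference matrix, non-negative least squares fits exposure weights over
    the reference columns; the returned signature is the reconstruction
    ``reference @ weights`` renormalized, and the (renormalized) weights are
    returned alongside it.
    """
    counts = spectrum.counts
    if counts.sum() <= 0:
        raise ValueError("cannot refit an all-zero spectrum")
    if reference is None:
        probs = counts + pseudocount
        return Signature(probs / probs.sum(), name="empirical"), None
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 2 or ref.shape[0] != 96:
        raise ValueError(f"reference must be 96 x K, got {ref.shape}")
    target = counts / counts.sum()
    weights, _ = nnls(ref, target)
    if weights.sum() <= 0:
        raise ValueError("NNLS fit degenerate: all weights zero")
    recon = ref @ weights
    weights = weights / weights.sum()
    return Signature(recon / recon.sum(), name="refit"), weights


class SiteRateTable:
    """Relative mutation rate and consequence class for every possible SNV.

    For a CDS of length L this holds an (L, 4) rate array over alternate
    bases (the reference base's own column is zero) and a parallel class-code
    array (0 synonymous, 1 missense, 2 nonsense, -1 at the reference base).
    Rates are the signature probabilities of each substitution's channel;
    they are relative, and every consumer uses them only through ratios.
    """

    def __init__(self, cds: CodingSequence, rate: np.ndarray, cons: np.ndarray) -> None:
        self.cds = cds
        self.rate = rate
        self.cons = cons

    @property
    def length(self) -> int:
        return len(self.cds.seq)

    def class_rate_by_base(self, classes: set[str] | str) -> np.ndarray:
        """Per-base sum of rates over substitutions of the given class(es)."""
        if isinstance(classes, str):
            classes = {classes}
        codes = [CLASS_CODES[c] for c in classes]
        mask = np.isin(self.cons, codes)
        return (self.rate * mask).sum(axis=1)

    def class_rate_by_residue(self, classes: set[str] | str) -> np.ndarray:
        per_base = self.class_rate_by_base(classes)
        return per_base.reshape(-1, 3).sum(axis=1)

    def total_class_rate(self, classes: set[str] | str) -> float:
        return float(self.class_rate_by_base(classes).sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in range(self.length):
            for b_idx, alt in enumerate(BASES):
                if self.cons[pos, b_idx] < 0:
                    continue
                rows.append(
                    {
                        "cds_pos": pos,
                        "alt": alt,
                        "rate": self.rate[pos, b_idx],
                        "class": CODE_CLASSES[int(self.cons[pos, b_idx])],
                    }
                )
        return pd.DataFrame(rows)


def site_rates(cds: CodingSequence, signature: Signature) -> SiteRateTable:
    """Enumerate the relative rate of every possible substitution in a CDS."""
    L = len(cds.seq)
    rate = np.zeros((L, 4))
    cons = np.full((L, 4), -1, dtype=np.int8)
    for pos in range(L):
        ref = cds.seq[pos]
        context = cds.context(pos)
        for b_idx, alt in enumerate(BASES):
            if alt == ref:
                continue
            consequence, _ = annotate_mutation(cds, pos, alt)
            cons[pos, b_idx] = CLASS_CODES[consequence]
            rate[pos, b_idx] = sum(
                signature.probs[i] * w for i, w in collapse_channel(context, alt)
            )
    return SiteRateTable(cds, rate, cons)


@dataclass
class ExpectedProfile:
    """Expected per-residue mutation counts for one consequence class.

    Per-residue expectations are the class-matching site-rate mass of each
    codon, normalized over the gene and scaled by the observed total, so the
    profile always sums to ``total_observed``.
    """

    gene: str
    consequence_class: str
    per_residue: np.ndarray
    total_observed: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": np.arange(1, len(self.per_residue) + 1),
                "expected": self.per_residue,
            }
        )


def expected_profile(
    rates: SiteRateTable, consequence_class: str, total_observed: float
) -> ExpectedProfile:
    """Distribute an observed mutation total along the gene by site rates."""
    if total_observed < 0:
        raise ValueError("total_observed must be >= 0")
    per_residue = rates.class_rate_by_residue(consequence_class)
    mass = per_residue.sum()
    if mass <= 0:
        raise ValueError(
            f"{rates.cds.gene}: no {consequence_class} rate mass; cannot build profile"
        )
    return ExpectedProfile(
        gene=rates.cds.gene,
        consequence_class=consequence_class,
        per_residue=per_residue / mass * total_observed,
        total_observed=float(total_observed),
    )


@dataclass
class ObsExpTrack:
    """Sliding-window observed/expected mutation ratio along a CDS.

    The ratio in each window is (sum of observed) / (sum of expected), with
    expected scaled so the gene-wide totals agree; windows with zero expected
    mass are flagged undefined rather than given a value.
    """

    gene: str
    window_bases: int
    center: np.ndarray  # 0-based CDS coordinate of each window center
    residue: np.ndarray  # 1-based residue of the center base
    observed: np.ndarray  # windowed observed sums
    expected: np.ndarray  # windowed (rescaled) expected sums
    ratio: np.ndarray  # NaN where undefined
    defined: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "base_center": self.center,
                "residue": self.residue,
                "observed": self.observed,
                "expected": self.expected,
                "ratio": self.ratio,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def obs_exp_track(
    observed: np.ndarray,
    rates: SiteRateTable,
    consequence_class: str = "missense",
    window_bases: int = 50,
) -> ObsExpTrack:
    """Windowed observed/expected ratio track (stride 1, windows inside CDS)."""
    observed = np.asarray(observed, dtype=float)
    L = rates.length
    if observed.shape != (L,):
        raise ValueError(f"observed vector length {observed.shape} != CDS length {L}")
    if window_bases > L:
        raise ValueError(f"window_bases {window_bases} exceeds CDS length {L}")
    if window_bases < 1:
        raise ValueError("window_bases must be >= 1")
    exp_base = rates.class_rate_by_base(consequence_class)
    mass = exp_base.sum()
    if mass <= 0:
        raise ValueError(f"no {consequence_class} rate mass in {rates.cds.gene}")
    # scale expected to the observed total; with nothing observed keep the
    # relative expectation so empty windows read 0 rather than undefined
    exp_base = exp_base / mass * (observed.sum() if observed.sum() > 0 else 1.0)

    kernel = np.ones(window_bases)
    obs_win = np.convolve(observed, kernel, mode="valid")
    exp_win = np.convolve(exp_base, kernel, mode="valid")
    defined = exp_win > 0
    ratio = np.full_like(obs_win, np.nan)
    np.divide(obs_win, exp_win, out=ratio, where=defined)
    starts = np.arange(L - window_bases + 1)
    centers = starts + (window_bases - 1) // 2
    return ObsExpTrack(
        gene=rates.cds.gene,
        window_bases=window_bases,
        center=centers,
        residue=centers // 3 + 1,
        observed=obs_win,
        expected=exp_win,
        ratio=ratio,
        defined=defined,
    )


def observed_base_counts(mutations: list[MutationRecord], cds: CodingSequence,
                         consequence_class: str | None = None) -> np.ndarray:
    """Per-base observed mutation counts for one gene (optionally one class)."""
    counts = np.zeros(len(cds.seq))
    for rec in mutations:
        if rec.gene != cds.gene:
            continue
        if consequence_class is not None and rec.consequence != consequence_class:
            continue
        counts[rec.cds_pos] += 1
    return counts
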