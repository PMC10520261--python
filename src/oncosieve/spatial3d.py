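"""Permutation test for 3D clustering of mutated residues on a structure.

The statistic is a weighted-average-proximity (WAP) score: a Gaussian-kernel
sum over pairs of distinct mutated residues,

    score = sum_{i<j} n_i n_j exp(-d_ij^2 / (2 t^2)),

with n_i the mutation count at residue i, d_ij the C-alpha distance and t a
length scale (default 6 A, about 1.5 C-alpha steps along a helix).  The null
reassigns the observed multiset of counts to residues drawn uniformly
without replacement from all residues with coordinates; the p-value uses the
add-one estimator, so it is never below 1 / (n_permutations + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "StructureCoords",
    "PermTestResult",
    "read_ca_coords",
    "wap_score",
    "spatial_permutation_test",
]


@dataclass
class StructureCoords:
    """C-alpha coordinates: one (x, y, z) in Angstrom per residue index."""

    residues: np.ndarray  # int residue indices, unique, sorted
    xyz: np.ndarray  # (n, 3) float
    chain: str = "A"

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (len(self.residues), 3):
            raise ValueError("xyz must be (n_residues, 3)")
        if not np.isfinite(self.xyz).all():
            raise ValueError("coordinates must be finite")
        if len(np.unique(self.residues)) != len(self.residues):
            raise ValueError("duplicate residue indices")

    def __len__(self) -> int:
        return len(self.residues)

    def index_of(self, residue: int) -> int:
        hits = np.nonzero(self.residues == residue)[0]
        if len(hits) == 0:
            raise KeyError(f"residue {residue} has no coordinates")
        return int(hits[0])


@dataclass(frozen=True)
class PermTestResult:
    observed_score: float
    n_permutations: int
    p: float
    seed: int | None
    t: float

    def to_dict(self) -> dict:
        return {
            "score": self.observed_score,
            "p": self.p,
            "t": self.t,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def read_ca_coords(path: str | Path, chain: str | None = None) -> StructureCoords:
    """Extract one C-alpha coordinate per residue from PDB ATOM records.

    Fixed-column parse; only ``ATOM`` records with atom name ``CA`` are used.
    Where altloc conformers duplicate a CA, the first one encountered is
    kept.  Residues lacking a CA are skipped with a warning.  A file with no
    usable CA atoms is an error.
    """
    seen: dict[int, tuple[float, float, float]] = {}
    residues_with_atoms: set[int] = set()
    file_chain = chain
    with open(path) as fh:
        for line in fh:
            if not line.startswith("ATOM"):
                continue
            line_chain = line[21].strip() or "A"
            if chain is not None and line_chain != chain:
                continue
            if file_chain is None:
                file_chain = line_chain
            elif chain is None and line_chain != file_chain:
                continue  # single-chain analysis by default: keep first chain
            resseq = int(line[22:26])
            residues_with_atoms.add(resseq)
            atom_name = line[12:16].strip()
            if atom_name != "CA":
                continue
            if resseq in seen:  # later altloc (or duplicate): first wins
                continue
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            seen[resseq] = (x, y, z)
    if not seen:
        raise ValueError(f"{path}: no CA atoms found" + (f" in chain {chain}" if chain else ""))
    missing = residues_with_atoms - set(seen)
    if missing:
        warnings.warn(f"{path}: {len(missing)} residue(s) without a CA atom skipped")
    residues = np.array(sorted(seen))
    xyz = np.array([seen[r] for r in residues])
    return StructureCoords(residues=residues, xyz=xyz, chain=file_chain or "A")


def _kernel_matrix(coords: StructureCoords, t: float) -> np.ndarray:
    d2 = squareform(pdist(coords.xyz, metric="sqeuclidean"))
    K = np.exp(-d2 / (2.0 * t * t))
    np.fill_diagonal(K, 0.0)  # pairs are over distinct residues
    return K


def _score_from_kernel(K: np.ndarray, counts_vec: np.ndarray) -> float:
    return float(counts_vec @ K @ counts_vec) / 2.0


def wap_score(coords: StructureCoords, counts: dict[int, float], t: float = 6.0) -> float:
    """Weighted-average-proximity score of a residue -> count mapping."""
    if t <= 0:
        raise ValueError("kernel length scale t must be > 0")
    vec = np.zeros(len(coords))
    for residue, n in counts.items():
        vec[coords.index_of(residue)] = n  # KeyError names missing residues
    K = _kernel_matrix(coords, t)
    return _score_from_kernel(K, vec)


def spatial_permutation_test(
    coords: StructureCoords,
    counts: dict[int, float],
    n_permutations: int = 10000,
    seed: int | None = None,
    t: float = 6.0,
) -> PermTestResult:
    """Permutation p-value for spatial clustering of mutated residues.

    Null: the multiset of per-residue mutation counts is reassigned to
    residues drawn uniformly without replacement from all residues with
    coordinates.  p = (1 + #{null score >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if n_permutations < 100:
        warnings.warn(f"n_permutations={n_permutations} is very low; p resolution is coarse")
    nonzero = {r: c for r, c in counts.items() if c > 0}
    total = sum(nonzero.values())
    if total < 2:
        raise ValueError("need at least 2 mutations")
    r = len(nonzero)
    n_res = len(coords)
    if n_res < r:
        raise ValueError("fewer residues with coordinates than distinct mutated residues")

    K = _kernel_matrix(coords, t)
    obs_vec = np.zeros(n_res)
    for residue, n in nonzero.items():
        obs_vec[coords.index_of(residue)] = n
    observed = _score_from_kernel(K, obs_vec)

    count_values = np.array(list(nonzero.values()), dtype=float)
    rng = np.random.default_rng(seed)
    n_ge = 0
    vec = np.zeros(n_res)
    for _ in range(n_permutations):
        idx = rng.choice(n_res, size=r, replace=False)
        vec[:] = 0.0
        vec[idx] = count_values
        if _score_from_kernel(K, vec) >= observed - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return PermTestResult(
        observed_score=observed,
        n_permutations=n_permutations,
        p=p,
        seed=seed,
        t=t,
    )
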