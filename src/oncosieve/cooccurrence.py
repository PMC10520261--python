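"""Margin-preserving permutation tests for mutual exclusivity and
co-occurrence of gene alterations across patients.

The null model holds every patient's alteration burden and every gene's
alteration frequency fixed: randomized matrices share the observed row and
column sums exactly.  Sampling uses curveball trades — repeatedly pick two
patients and shuffle the genes unique to either between them — which walks
uniformly over the set of binary matrices with the given margins.  For each
gene pair the observed overlap (patients altered in both) is compared with
its null distribution; a left tail supports mutual exclusivity, a right tail
co-occurrence, and both use add-one estimators (so p_mutex + p_cooc >= 1).
BH adjustment runs separately per direction, mirroring how exclusivity and
co-occurrence are reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["PairAssociationResult", "curveball_null", "pair_association"]


@dataclass(frozen=True)
class PairAssociationResult:
    gene_a: str
    gene_b: str
    observed_overlap: int
    p_mutex: float
    p_cooc: float
    q_mutex: float = float("nan")
    q_cooc: float = float("nan")


def _as_matrix(matrix) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(matrix, pd.DataFrame):
        M = matrix.to_numpy()
        samples = [str(s) for s in matrix.index]
        genes = [str(g) for g in matrix.columns]
    else:
        M = np.asarray(matrix)
        samples = [f"s{i}" for i in range(M.shape[0])]
        genes = [f"g{j}" for j in range(M.shape[1])]
    if M.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    if not np.isin(M, (0, 1)).all():
        raise ValueError("matrix entries must be 0/1")
    return M.astype(np.int8), samples, genes


def _trade(rows: list[set[int]], rng: np.random.Generator) -> None:
    """One curveball trade between two random rows."""
    i, j = rng.choice(len(rows), size=2, replace=False)
    a, b = rows[i], rows[j]
    a_only = list(a - b)
    b_only = list(b - a)
    pool = a_only + b_only
    if not a_only or not b_only:
        return  # nothing tradable
    perm = rng.permutation(len(pool))
    new_a = {pool[k] for k in perm[: len(a_only)]}
    shared = a & b
    rows[i] = shared | new_a
    rows[j] = shared | ({pool[k] for k in perm[len(a_only):]})


def curveball_null(
    matrix,
    n_samples: int,
    seed: int | None = None,
    burn_in_factor: int = 20,
    thin_factor: int = 5,
) -> Iterator[np.ndarray]:
    """Yield ``n_samples`` randomized matrices with the input's exact margins.

    The chain burns in for ``burn_in_factor * n_rows`` trades and separates
    successive emissions by ``thin_factor * n_rows`` trades.  Deterministic
    given ``seed``.
    """
    M, _, _ = _as_matrix(matrix)
    n_rows, n_cols = M.shape
    if n_rows < 2 or n_cols < 2:
        raise ValueError("matrix must have at least 2 rows and 2 columns")
    total = int(M.sum())
    if total == 0 or total == n_rows * n_cols:
        raise ValueError("all-zero or all-one matrix cannot be randomized")
    rng = np.random.default_rng(seed)
    rows = [set(np.nonzero(M[i])[0].tolist()) for i in range(n_rows)]
    for _ in range(burn_in_factor * n_rows):
        _trade(rows, rng)
    for _ in range(n_samples):
        for _ in range(thin_factor * n_rows):
            _trade(rows, rng)
        out = np.zeros_like(M)
        for i, cols in enumerate(rows):
            out[i, list(cols)] = 1
        yield out


def pair_association(
    matrix,
    n_null: int = 10000,
    seed: int | None = None,
    check_margins: bool = True,
) -> pd.DataFrame:
    """Test every gene pair for mutual exclusivity and co-occurrence.

    ``matrix`` is a samples x genes 0/1 incidence (DataFrame or array).
    Degenerate genes (altered in no or in all samples) are skipped with a
    warning — their overlap is fixed by the margins and carries no signal.
    Returns a DataFrame with columns gene_a, gene_b, overlap, p_mutex,
    p_cooc, q_mutex, q_cooc.
    """
    M, _, genes = _as_matrix(matrix)
    n_rows, n_cols = M.shape
    if n_cols < 2:
        raise ValueError("need at least 2 genes")
    col_sums = M.sum(axis=0)
    degenerate = (col_sums == 0) | (col_sums == n_rows)
    if degenerate.any():
        bad = [genes[j] for j in np.nonzero(degenerate)[0]]
        warnings.warn(f"degenerate gene(s) skipped: {bad}")
    keep = np.nonzero(~degenerate)[0]
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-degenerate genes")

    obs_overlap = (M.T.astype(np.int32) @ M.astype(np.int32))
    row_sums = M.sum(axis=1)
    n_le = np.zeros((n_cols, n_cols), dtype=np.int64)
    n_ge = np.zeros((n_cols, n_cols), dtype=np.int64)
    for null_M in curveball_null(M, n_null, seed=seed):
        if check_margins:
            assert (null_M.sum(axis=0) == col_sums).all()
            assert (null_M.sum(axis=1) == row_sums).all()
        null_overlap = null_M.T.astype(np.int32) @ null_M.astype(np.int32)
        n_le += null_overlap <= obs_overlap
        n_ge += null_overlap >= obs_overlap

    rows = []
    for ia, a in enumerate(keep):
        for b in keep[ia + 1 :]:
            rows.append(
                {
                    "gene_a": genes[a],
                    "gene_b": genes[b],
                    "overlap": int(obs_overlap[a, b]),
                    "p_mutex": (1 + int(n_le[a, b])) / (1 + n_null),
                    "p_cooc": (1 + int(n_ge[a, b])) / (1 + n_null),
                }
            )
    df = pd.DataFrame(rows)
    _, df["q_mutex"], _, _ = multipletests(df["p_mutex"], method="fdr_bh")
    _, df["q_cooc"], _, _ = multipletests(df["p_cooc"], method="fdr_bh")
    return df
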