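"""Context-aware dN/dS selection inference with a conditional exact test.

The expected nonsynonymous-to-synonymous balance of a gene is read off its
site-rate table: e_N is the total relative rate of nonsynonymous sites
(missense, optionally plus nonsense) and e_S the synonymous rate mass, both
driven by the mutational signature, so the trinucleotide composition of the
gene is accounted for.  Conditioning on the observed total n + s, the number
of nonsynonymous mutations is Binomial(n + s, pi) with pi = e_N / (e_N + e_S)
under neutrality; a two-sided exact binomial test gives the per-gene p, and

    omega = (n_obs / e_N) / (s_obs / e_S)

is the selection ratio (omega > 1: nonsynonymous excess).  Because rates
enter only through ratios, omega is invariant to any uniform rescaling of
the signature.  BH adjustment runs across genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .sequence_io import MutationRecord
from .signatures import SiteRateTable

__all__ = ["SelectionResult", "context_dnds", "cohort_dnds"]

DEFAULT_CLASS_SET = frozenset({"missense", "nonsense"})


@dataclass(frozen=True)
class SelectionResult:
    gene: str
    n_obs: int  # nonsynonymous observed (class_set)
    s_obs: int  # synonymous observed
    e_n: float  # expected nonsynonymous rate mass
    e_s: float  # expected synonymous rate mass
    n_exp_frac: float  # pi = e_n / (e_n + e_s)
    omega: float  # may be inf (s_obs == 0, n_obs > 0)
    omega_haldane: float  # +0.5 in both observed cells, for plotting
    p: float

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "n_obs": self.n_obs,
            "s_obs": self.s_obs,
            "e_N": self.e_n,
            "e_S": self.e_s,
            "omega": self.omega,
            "omega_haldane": self.omega_haldane,
            "p": self.p,
        }


def context_dnds(
    mutations: list[MutationRecord],
    rates: SiteRateTable,
    class_set: frozenset[str] | set[str] = DEFAULT_CLASS_SET,
) -> SelectionResult:
    """Per-gene selection test conditional on the observed mutation total.

    ``class_set`` chooses which nonsynonymous classes count toward n_obs
    ({"missense"} or {"missense", "nonsense"}); mutations of classes outside
    ``class_set | {"synonymous"}`` are ignored.
    """
    class_set = frozenset(class_set)
    if not class_set <= {"missense", "nonsense"}:
        raise ValueError(f"class_set must be a subset of missense/nonsense, got {set(class_set)}")
    gene = rates.cds.gene
    relevant = [m for m in mutations if m.gene == gene]
    if not relevant:
        raise ValueError(f"no mutations in gene {gene}")
    n_obs = sum(1 for m in relevant if m.consequence in class_set)
    s_obs = sum(1 for m in relevant if m.consequence == "synonymous")

    e_n = rates.total_class_rate(class_set)
    e_s = rates.total_class_rate("synonymous")
    if e_n <= 0 or e_s <= 0:
        raise ValueError(f"{gene}: degenerate rate masses e_N={e_n}, e_S={e_s}")
    pi = e_n / (e_n + e_s)

    if s_obs > 0:
        omega = (n_obs / e_n) / (s_obs / e_s)
    elif n_obs > 0:
        omega = math.inf
    else:
        omega = float("nan")  # no informative mutations at all
    omega_haldane = ((n_obs + 0.5) / e_n) / ((s_obs + 0.5) / e_s)

    total = n_obs + s_obs
    p = binomtest(n_obs, total, pi, alternative="two-sided").pvalue if total > 0 else 1.0
    return SelectionResult(
        gene=gene,
        n_obs=n_obs,
        s_obs=s_obs,
        e_n=e_n,
        e_s=e_s,
        n_exp_frac=pi,
        omega=omega,
        omega_haldane=omega_haldane,
        p=float(p),
    )


def cohort_dnds(results: list[SelectionResult], alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust per-gene selection tests and flag positively selected genes.

    A gene is flagged when omega > 1 and q < alpha.  Returns a DataFrame with
    one row per gene (columns: gene, n_obs, s_obs, e_N, e_S, omega,
    omega_haldane, p, q, flag).
    """
    if not results:
        raise ValueError("need at least one gene")
    df = pd.DataFrame([r.to_dict() for r in results])
    _, qvals, _, _ = multipletests(df["p"], method="fdr_bh")
    df["q"] = qvals
    df["flag"] = (df["omega"] > 1) & (df["q"] < alpha)
    return df.sort_values("q", kind="stable").reset_index(drop=True)
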