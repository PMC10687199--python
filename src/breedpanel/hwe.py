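"""Exact Hardy–Weinberg equilibrium testing and de Finetti (ternary) coordinates.

The exact test conditions on the observed allele counts and enumerates every
heterozygote count h compatible with them (same parity as the rare-allele
count, 0 <= h <= n_rare).  Under HWE the conditional probability of h is

    P(h) = 2^h * n! / (n_AA(h)! h! n_BB(h)!) * n_A! n_B! / (2n)!

evaluated here by a recurrence in log space so counts in the hundreds pose
no overflow risk.  The exact p-value sums P over all outcomes no more
probable than the observed one; the mid-p variant counts only half the
observed outcome's mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .genotypes import GenotypeTable

_SQRT3_2 = math.sqrt(3.0) / 2.0


def _het_log_probs(n_aa: int, n_ab: int, n_bb: int) -> tuple[np.ndarray, np.ndarray]:
    """Support (het counts) and normalized log-probabilities of the exact null."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    n_rare = min(n_a, n_b)
    support = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.empty(support.size)
    logp[0] = 0.0
    for i in range(support.size - 1):
        h = support[i]
        hom_rare = (n_rare - h) // 2
        hom_common = (2 * n - n_rare - h) // 2
        # P(h+2)/P(h) = 4 * hom_rare * hom_common / ((h+1)(h+2))
        logp[i + 1] = logp[i] + math.log(4.0 * hom_rare * hom_common) - math.log(
            (h + 1.0) * (h + 2.0)
        )
    logp -= logsumexp(logp)
    return support, logp


def hwe_exact(n_aa: int, n_ab: int, n_bb: int, midp: bool = False) -> float:
    """Exact HWE p-value for one locus from its three genotype counts.

    Invariant under swapping the homozygote classes (allele relabelling).
    A monomorphic locus (single possible outcome) returns 1.0.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    if n_aa + n_ab + n_bb < 1:
        raise ValueError("need at least one genotyped individual")
    support, logp = _het_log_probs(n_aa, n_ab, n_bb)
    obs = int(np.flatnonzero(support == n_ab)[0])
    # outcomes no more probable than observed (tolerance guards float ties)
    mask = logp <= logp[obs] + 1e-9
    p = float(np.exp(logsumexp(logp[mask])))
    if midp:
        p -= 0.5 * float(np.exp(logp[obs]))
    return min(p, 1.0)


@dataclass
class HWETestResult:
    locus_id: str
    population: str
    n_aa: int
    n_ab: int
    n_bb: int
    p_exact: float
    p_mid: float
    significant: bool
    ternary_xy: tuple[float, float]


def genotype_counts(table: GenotypeTable, per_population: bool = True) -> pd.DataFrame:
    """Genotype counts (AA/AB/BB by alt-dosage 0/1/2) per locus and group."""
    d = table.dosages
    groups = (
        [(pop, np.flatnonzero(table.population_labels == pop)) for pop in table.populations]
        if per_population
        else [("pooled", np.arange(table.n_samples))]
    )
    rows = []
    for name, idx in groups:
        sub = d[idx]
        rows.append(
            pd.DataFrame(
                {
                    "locus_id": table.locus_ids,
                    "population": name,
                    "n_AA": (sub == 0).sum(axis=0),
                    "n_AB": (sub == 1).sum(axis=0),
                    "n_BB": (sub == 2).sum(axis=0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def hwe_scan(
    table: GenotypeTable,
    per_population: bool = True,
    alpha: float = 0.05,
    midp: bool = False,
    correction: str | None = None,
) -> tuple[pd.DataFrame, int]:
    """Exact HWE test at every locus, within each population by default.

    Returns the tidy result table and the number of deviating loci — loci
    significant at ``alpha`` in at least one group.  No multiple-testing
    correction is applied by default; ``correction`` may be "bonferroni"
    or "bh" (Benjamini–Hochberg).
    """
    counts = genotype_counts(table, per_population=per_population)
    p_exact = np.ones(len(counts))
    p_mid = np.ones(len(counts))
    xs = np.zeros(len(counts))
    ys = np.zeros(len(counts))
    for i, row in enumerate(counts.itertuples(index=False)):
        n = row.n_AA + row.n_AB + row.n_BB
        if n == 0:
            p_exact[i] = p_mid[i] = np.nan
            xs[i] = ys[i] = np.nan
            continue
        support, logp = _het_log_probs(row.n_AA, row.n_AB, row.n_BB)
        obs = int(np.flatnonzero(support == row.n_AB)[0])
        mask = logp <= logp[obs] + 1e-9
        p_exact[i] = min(float(np.exp(logsumexp(logp[mask]))), 1.0)
        p_mid[i] = max(p_exact[i] - 0.5 * float(np.exp(logp[obs])), 0.0)
        xs[i], ys[i] = ternary_coordinates(row.n_AA, row.n_AB, row.n_BB)

    out = counts.copy()
    out["p_exact"] = p_exact
    out["p_mid"] = p_mid
    out["ternary_x"] = xs
    out["ternary_y"] = ys
    p_used = out["p_mid"] if midp else out["p_exact"]
    p_adj = _adjust(p_used.to_numpy(), correction)
    out["p_adj"] = p_adj
    out["significant"] = p_adj < alpha
    n_deviating = int(out.loc[out["significant"], "locus_id"].nunique())
    return out, n_deviating


def _adjust(p: np.ndarray, correction: str | None) -> np.ndarray:
    if correction is None:
        return p
    if correction == "bonferroni":
        return np.minimum(p * np.isfinite(p).sum(), 1.0)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        ok = np.isfinite(p)
        out = p.copy()
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
        return out
    raise ValueError(f"unknown correction {correction!r}")


def ternary_coordinates(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """Cartesian position of a genotype-frequency point in the de Finetti
    triangle with vertices AA=(0,0), BB=(1,0), AB=(1/2, sqrt(3)/2)."""
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    f_ab = n_ab / n
    f_bb = n_bb / n
    return (f_bb + f_ab / 2.0, f_ab * _SQRT3_2)


def hwe_parabola(n_points: int = 201) -> np.ndarray:
    """The HWE locus inside the de Finetti triangle as an (n_points, 2) array.

    At allele frequency p the expected genotype frequencies ((1-p)^2,
    2p(1-p), p^2) map to x = p, y = sqrt(3) p (1-p).
    """
    p = np.linspace(0.0, 1.0, n_points)
    return np.column_stack([p, 2.0 * _SQRT3_2 * p * (1.0 - p)])
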