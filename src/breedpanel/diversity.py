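"""Within-population diversity: allele frequencies, heterozygosity, F_IS,
and Hill-number q-profiles.

All statistics are per locus, computed either pooled over every sample or
within each population.  Expected heterozygosity is Nei's gene diversity
H_E = 2p(1-p) (plug-in by default; the small-sample 2n/(2n-1) correction is
available behind a flag).  The fixation index is F_IS = 1 - H_O/H_E, with
the multilocus value combined as a ratio of sums (sum H_O over loci divided
by sum H_E), which is stable when low-diversity loci are present.

Hill numbers give the effective number of alleles at order q:

    qD = (sum_i p_i^q)^(1/(1-q)),   1D = exp(-sum_i p_i ln p_i)  (q -> 1)

For a biallelic locus 0D is the number of segregating alleles (1 or 2),
1D the exponential of Shannon entropy, and 2D the inverse Simpson index,
linked to gene diversity by 2D = 1/(1 - H_E).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

POOLED = "pooled"


def _freq_ho(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """alt-allele frequency, observed het proportion, and n typed per column."""
    typed = ~np.isnan(d)
    n_typed = typed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.nansum(d, axis=0) / (2.0 * n_typed)
        h_o = np.nansum(d == 1, axis=0) / n_typed
    p_alt = np.where(n_typed == 0, np.nan, p_alt)
    h_o = np.where(n_typed == 0, np.nan, h_o)
    return p_alt, h_o, n_typed


def _groups(table: GenotypeTable, by_population: bool) -> list[tuple[str, np.ndarray]]:
    if not by_population:
        return [(POOLED, np.arange(table.n_samples))]
    labels = table.population_labels
    return [(pop, np.flatnonzero(labels == pop)) for pop in table.populations]


def allele_frequencies(table: GenotypeTable, by_population: bool = False) -> pd.DataFrame:
    """Per-locus alt/ref allele frequencies, missing genotypes excluded.

    Loci with zero typed samples in a group get NaN frequencies.
    """
    if table.n_loci == 0:
        raise ValueError("empty genotype table")
    d = table.dosages_float()
    rows = []
    for name, idx in _groups(table, by_population):
        p_alt, _, n_typed = _freq_ho(d[idx])
        rows.append(
            pd.DataFrame(
                {
                    "locus_id": table.locus_ids,
                    "population": name,
                    "p_alt": p_alt,
                    "p_ref": 1.0 - p_alt,
                    "n_typed": n_typed,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def heterozygosity(
    table: GenotypeTable, by_population: bool = False, unbiased: bool = False
) -> pd.DataFrame:
    """Per-locus observed and expected heterozygosity plus F_IS.

    H_O is the proportion of heterozygotes among typed individuals; H_E is
    2p(1-p), multiplied by 2n/(2n-1) when ``unbiased`` is set.  Per-locus
    F_IS = 1 - H_O/H_E is NaN where H_E = 0.
    """
    d = table.dosages_float()
    rows = []
    for name, idx in _groups(table, by_population):
        p, h_o, n_typed = _freq_ho(d[idx])
        h_e = 2.0 * p * (1.0 - p)
        if unbiased:
            with np.errstate(invalid="ignore", divide="ignore"):
                h_e = h_e * (2.0 * n_typed) / (2.0 * n_typed - 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            fis_l = np.where(h_e > 0, 1.0 - h_o / h_e, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "locus_id": table.locus_ids,
                    "population": name,
                    "p_alt": p,
                    "n_typed": n_typed,
                    "H_O": h_o,
                    "H_E": h_e,
                    "F_IS": fis_l,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def fis(
    table: GenotypeTable,
    by_population: bool = False,
    unbiased: bool = False,
    method: str = "ratio-of-sums",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-locus F_IS table and an overall F_IS per group.

    The multilocus value is 1 - (sum_l H_O,l)/(sum_l H_E,l) by default
    ("ratio-of-sums"); ``method="mean-of-ratios"`` averages per-locus F_IS
    over loci with H_E > 0 instead.
    """
    if method not in ("ratio-of-sums", "mean-of-ratios"):
        raise ValueError(f"unknown method {method!r}")
    het = heterozygosity(table, by_population=by_population, unbiased=unbiased)
    overall: dict[str, float] = {}
    for name, grp in het.groupby("population", sort=False):
        ok = grp["H_E"] > 0
        if method == "ratio-of-sums":
            num, den = grp.loc[ok, "H_O"].sum(), grp.loc[ok, "H_E"].sum()
            overall[name] = 1.0 - num / den if den > 0 else float("nan")
        else:
            overall[name] = float(grp.loc[ok, "F_IS"].mean())
    return het, overall


def hill_number(p_alt: np.ndarray, q: float) -> np.ndarray:
    """Hill number of order q for biallelic loci given alt-allele frequency."""
    p_alt = np.asarray(p_alt, dtype=float)
    freqs = np.stack([p_alt, 1.0 - p_alt])  # (2, L)
    if q == 0:
        return np.sum(freqs > 0, axis=0).astype(float)
    if q == 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            plogp = np.where(freqs > 0, freqs * np.log(freqs), 0.0)
        return np.exp(-plogp.sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(freqs > 0, freqs**q, 0.0).sum(axis=0)
    return s ** (1.0 / (1.0 - q))


def hill_profile(
    table: GenotypeTable,
    q_list: list[float] = (0.0, 1.0, 2.0),
    by_population: bool = False,
) -> pd.DataFrame:
    """Per-locus Hill numbers and their mean over loci, per group and order q.

    Returns a tidy frame with columns (population, q, locus_id, qD) plus a
    ``mean_qD`` attached per (population, q) via groupby in callers; use
    :func:`hill_means` for the summary.
    """
    q_list = list(q_list)
    if not q_list:
        raise ValueError("q_list must not be empty")
    d = table.dosages_float()
    rows = []
    for name, idx in _groups(table, by_population):
        p, _, _ = _freq_ho(d[idx])
        for q in q_list:
            rows.append(
                pd.DataFrame(
                    {
                        "locus_id": table.locus_ids,
                        "population": name,
                        "q": float(q),
                        "qD": hill_number(p, q),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def hill_means(
    table: GenotypeTable,
    q_list: list[float] = (0.0, 1.0, 2.0),
    by_population: bool = False,
) -> pd.DataFrame:
    """Arithmetic mean of per-locus qD over loci, per group and order."""
    prof = hill_profile(table, q_list=q_list, by_population=by_population)
    return (
        prof.groupby(["population", "q"], sort=False)["qD"]
        .mean()
        .rename("mean_qD")
        .reset_index()
    )
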