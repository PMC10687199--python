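"""Between-population differentiation and an F_ST-outlier scan.

Three pairwise distances are provided on the same genotype table:

* **Weir–Cockerham theta** — the moment estimator of F_ST built from three
  variance components per locus: ``a`` (among populations), ``b`` (among
  individuals within populations) and ``c`` (within individuals), with
  multilocus values combined as ratio of sums, sum(a)/sum(a+b+c).
* **Nei G_ST** — (H_T - H_S)/H_T from within-population and total gene
  diversity, unweighted across the pair, combined as ratio of sums.
* **Euclidean distance** — sqrt(sum_l (p_j,l - p_k,l)^2) on alt-allele
  frequencies (0–1 scale, one coordinate per locus; a ``scale`` multiplier
  accommodates percent-scale conventions).

The outlier scan fits a scaled chi-square to the trimmed distribution of
per-locus uncorrected theta values (low-heterozygosity loci excluded) and
flags loci in the fitted right tail as candidates for divergent selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeTable


# ---------------------------------------------------------------------------
# Weir–Cockerham variance components
# ---------------------------------------------------------------------------

@dataclass
class FstComponents:
    """Per-locus variance components of the Weir–Cockerham F_ST estimator."""

    locus_id: str
    a: float
    b: float
    c: float
    theta: float  # a/(a+b+c); NaN where the locus is monomorphic overall
    theta_nocorr: float  # finite-sample-correction terms dropped


def _wc_from_stats(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized a, b, c (+ no-correction a0, b0) from per-pop summaries.

    Parameters are (r, L) arrays of sample sizes, alt-allele frequencies and
    observed heterozygote proportions.  Populations with n=0 at a locus are
    ignored for that locus.
    """
    n = n.astype(float)
    valid = n > 0
    r = valid.sum(axis=0).astype(float)  # populations informative per locus
    n_sum = np.where(valid, n, 0.0).sum(axis=0)
    nbar = n_sum / r
    n2_sum = np.where(valid, n**2, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_sum - n2_sum / n_sum) / (r - 1.0)
        pbar = np.where(valid, n * p, 0.0).sum(axis=0) / n_sum
        s2 = np.where(valid, n * (p - pbar) ** 2, 0.0).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = np.where(valid, n * h, 0.0).sum(axis=0) / n_sum

        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
        c = hbar / 2.0
        a0 = (nbar / nc) * s2
        b0 = inner - hbar / 2.0
    return a, b, c, a0, b0


def _pop_stats(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """(r, L) arrays of n typed, alt frequency and het proportion per pop."""
    pops = table.populations
    d = table.dosages_float()
    labels = table.population_labels
    n = np.zeros((len(pops), table.n_loci))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for k, pop in enumerate(pops):
        sub = d[labels == pop]
        typed = ~np.isnan(sub)
        n[k] = typed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.nansum(sub, axis=0) / (2.0 * n[k])
            h[k] = np.nansum(sub == 1, axis=0) / n[k]
    return n, p, h, pops


def wc_components(genotype_counts: list[tuple[int, int, int]], locus_id: str = "") -> FstComponents:
    """Weir–Cockerham components for one locus from per-population counts.

    ``genotype_counts`` holds one (n_AA, n_AB, n_BB) triple per population
    (counts of alt-dosage 0/1/2).  At least two populations with a typed
    individual each are required.
    """
    counts = np.asarray(genotype_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 3:
        raise ValueError("expected one (n_AA, n_AB, n_BB) triple per population")
    n = counts.sum(axis=1)
    if (n > 0).sum() < 2:
        raise ValueError("need >=2 populations with at least one typed individual")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2.0 * counts[:, 2] + counts[:, 1]) / (2.0 * n)
        h = counts[:, 1] / n
    a, b, c, a0, b0 = _wc_from_stats(n[:, None], p[:, None], h[:, None])
    a, b, c, a0, b0 = (float(x[0]) for x in (a, b, c, a0, b0))
    denom = a + b + c
    theta = a / denom if denom != 0.0 else float("nan")
    denom0 = a0 + b0 + c
    theta_nocorr = a0 / denom0 if denom0 != 0.0 else float("nan")
    return FstComponents(locus_id=locus_id, a=a, b=b, c=c, theta=theta, theta_nocorr=theta_nocorr)


def wc_components_table(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus Weir–Cockerham components across all populations at once."""
    n, p, h, _ = _pop_stats(table)
    if n.shape[0] < 2:
        raise ValueError("need at least two populations")
    a, b, c, a0, b0 = _wc_from_stats(n, p, h)
    denom = a + b + c
    denom0 = a0 + b0 + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0.0, a / denom, np.nan)
        theta_nocorr = np.where(denom0 != 0.0, a0 / denom0, np.nan)
    return pd.DataFrame(
        {
            "locus_id": table.locus_ids,
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
            "theta_nocorr": theta_nocorr,
        }
    )


# ---------------------------------------------------------------------------
# Pairwise distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceSet:
    populations: list[str]
    fst: np.ndarray
    gst: np.ndarray
    euclidean: np.ndarray

    def to_frame(self, which: str) -> pd.DataFrame:
        m = getattr(self, which)
        return pd.DataFrame(m, index=self.populations, columns=self.populations)


def pairwise_fst(table: GenotypeTable, method: str = "ratio-of-sums") -> pd.DataFrame:
    """K x K matrix of multilocus Weir–Cockerham theta for each pair."""
    n, p, h, pops = _pop_stats(table)
    K = len(pops)
    if K < 2:
        raise ValueError("need at least two populations")
    if (n.sum(axis=1) == 0).any():
        empty = [pops[k] for k in np.flatnonzero(n.sum(axis=1) == 0)]
        raise ValueError(f"population(s) with zero typed samples: {empty}")
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            idx = [i, j]
            a, b, c, _, _ = _wc_from_stats(n[idx], p[idx], h[idx])
            ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
            if method == "ratio-of-sums":
                out[i, j] = out[j, i] = a[ok].sum() / (a[ok] + b[ok] + c[ok]).sum()
            elif method == "mean-of-ratios":
                denom = a + b + c
                keep = ok & (denom != 0)
                out[i, j] = out[j, i] = float(np.mean(a[keep] / denom[keep]))
            else:
                raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(out, index=pops, columns=pops)


def nei_gst_pairwise(table: GenotypeTable, method: str = "ratio-of-sums") -> pd.DataFrame:
    """K x K matrix of multilocus Nei G_ST, unweighted across each pair."""
    n, p, _, pops = _pop_stats(table)
    K = len(pops)
    if K < 2:
        raise ValueError("need at least two populations")
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            ok = (n[i] > 0) & (n[j] > 0)
            pi, pj = p[i, ok], p[j, ok]
            hs = 0.5 * (2.0 * pi * (1.0 - pi) + 2.0 * pj * (1.0 - pj))
            pbar = 0.5 * (pi + pj)
            ht = 2.0 * pbar * (1.0 - pbar)
            if method == "ratio-of-sums":
                if ht.sum() == 0.0:
                    raise ValueError(f"total gene diversity is zero for pair {pops[i]}, {pops[j]}")
                out[i, j] = out[j, i] = (ht - hs).sum() / ht.sum()
            elif method == "mean-of-ratios":
                keep = ht > 0
                out[i, j] = out[j, i] = float(np.mean((ht[keep] - hs[keep]) / ht[keep]))
            else:
                raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(out, index=pops, columns=pops)


def euclidean_pairwise(table: GenotypeTable, scale: float = 1.0) -> pd.DataFrame:
    """K x K Euclidean distance between population allele-frequency vectors.

    Loci untyped in either member of a pair are excluded pairwise; ``scale``
    multiplies frequencies (e.g. 100 for a percent-scale convention).
    """
    n, p, _, pops = _pop_stats(table)
    K = len(pops)
    if K < 2:
        raise ValueError("need at least two populations")
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            ok = (n[i] > 0) & (n[j] > 0)
            if not ok.any():
                raise ValueError(f"no shared typed loci for pair {pops[i]}, {pops[j]}")
            diff = (p[i, ok] - p[j, ok]) * scale
            out[i, j] = out[j, i] = float(np.sqrt(np.sum(diff**2)))
    return pd.DataFrame(out, index=pops, columns=pops)


def distance_set(table: GenotypeTable) -> DistanceSet:
    """All three pairwise distance matrices on one table."""
    return DistanceSet(
        populations=table.populations,
        fst=pairwise_fst(table).to_numpy(),
        gst=nei_gst_pairwise(table).to_numpy(),
        euclidean=euclidean_pairwise(table).to_numpy(),
    )


# ---------------------------------------------------------------------------
# F_ST-outlier scan
# ---------------------------------------------------------------------------

@dataclass
class OutlierScan:
    trim_fractions: tuple[float, float]
    h_min: float
    df_inferred: float
    fst_bar: float
    table: pd.DataFrame  # locus_id, theta_nocorr, H_E, included, p_value, outlier
    alpha: float

    @property
    def n_outliers(self) -> int:
        return int(self.table["outlier"].sum())


def _trunc_chi2_nll(params: np.ndarray, x: np.ndarray, lo: float, hi: float) -> float:
    log_df, log_bar = params
    df, bar = np.exp(log_df), np.exp(log_bar)
    scale = bar / df  # x ~ scale * chi2(df)
    logpdf = stats.chi2.logpdf(x / scale, df) - np.log(scale)
    mass = stats.chi2.cdf(hi / scale, df) - stats.chi2.cdf(lo / scale, df)
    if mass <= 0 or not np.isfinite(mass):
        return 1e12
    return float(-(logpdf.sum() - x.size * np.log(mass)))


def outflank_scan(
    table: GenotypeTable,
    trim: tuple[float, float] = (0.05, 0.05),
    h_min: float = 0.1,
    alpha: float = 0.05,
) -> OutlierScan:
    """Chi-square-calibrated F_ST outlier scan over all populations.

    Per-locus uncorrected theta values are the test statistic.  Loci with
    expected heterozygosity (at the weighted mean frequency) below ``h_min``
    are excluded from both fitting and testing; the lowest and highest
    ``trim`` quantiles are removed and (df, mean F_ST) fitted by maximum
    likelihood of the chi-square model truncated to the kept range.  Each
    included locus then gets a right-tail p-value from the fitted
    (untruncated) distribution; p < alpha flags an outlier.
    """
    comp = wc_components_table(table)
    n, p, _, _ = _pop_stats(table)
    with np.errstate(invalid="ignore"):
        pbar = np.where(n > 0, n * p, 0.0).sum(axis=0) / np.where(n > 0, n, 0.0).sum(axis=0)
    he = 2.0 * pbar * (1.0 - pbar)

    theta0 = comp["theta_nocorr"].to_numpy()
    included = np.isfinite(theta0) & (he >= h_min) & (theta0 > 0)
    if included.sum() < 20:
        raise ValueError(
            f"only {int(included.sum())} loci pass h_min={h_min}; too few to fit the null"
        )

    x_all = theta0[included]
    lo_q, hi_q = np.quantile(x_all, [trim[0], 1.0 - trim[1]])
    kept = x_all[(x_all >= lo_q) & (x_all <= hi_q)]
    if np.ptp(kept) < 1e-12:
        raise ValueError("trimmed theta distribution is degenerate (all values identical)")

    # log-grid over df with the scale fitted per candidate, then local refinement
    best = None
    for df0 in np.exp(np.linspace(np.log(0.2), np.log(50.0), 25)):
        res = optimize.minimize_scalar(
            lambda lb: _trunc_chi2_nll(np.array([np.log(df0), lb]), kept, lo_q, hi_q),
            bounds=(np.log(kept.mean()) - 4.0, np.log(kept.mean()) + 4.0),
            method="bounded",
        )
        if best is None or res.fun < best[0]:
            best = (res.fun, np.log(df0), res.x)
    refine = optimize.minimize(
        _trunc_chi2_nll,
        x0=np.array([best[1], best[2]]),
        args=(kept, lo_q, hi_q),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
    )
    if not refine.success and refine.fun > best[0] + 1e-6:
        raise RuntimeError(f"chi-square null fit did not converge: {refine.message}")
    df_hat = float(np.exp(refine.x[0]))
    bar_hat = float(np.exp(refine.x[1]))

    scale = bar_hat / df_hat
    pvals = np.full(table.n_loci, np.nan)
    test_idx = np.isfinite(theta0) & (he >= h_min)
    pvals[test_idx] = stats.chi2.sf(np.maximum(theta0[test_idx], 0.0) / scale, df_hat)
    outlier = np.zeros(table.n_loci, dtype=bool)
    outlier[test_idx] = pvals[test_idx] < alpha

    out = pd.DataFrame(
        {
            "locus_id": table.locus_ids,
            "theta_nocorr": theta0,
            "H_E": he,
            "included": test_idx,
            "p_value": pvals,
            "outlier": outlier,
        }
    )
    return OutlierScan(
        trim_fractions=trim,
        h_min=h_min,
        df_inferred=df_hat,
        fst_bar=bar_hat,
        table=out,
        alpha=alpha,
    )
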