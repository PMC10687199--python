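"""Discriminant Analysis of Principal Components (DAPC) for breed assignment.

The genotype matrix (samples x loci, alt-allele dosage, missing entries
mean-imputed) is first reduced by PCA; a linear discriminant analysis on the
retained principal components then finds K-1 axes maximizing between-group
relative to within-group variance.  Because the discriminant axes are linear
in the PCs, and the PCs linear in the SNPs, each SNP receives a squared,
column-normalized *contribution* to every discriminant axis; thresholding
these contributions selects a reduced breed-informative marker panel.

The number of retained PCs is chosen by the a-score: observed reassignment
success minus the reassignment success expected under randomly permuted
group labels, which penalizes overfitting from retaining too many PCs.

Group membership probabilities use a Gaussian model in discriminant space
with axis-wise pooled within-group variances.

The module follows a model/results layout: build :class:`DAPC` from a
genotype table, call :meth:`DAPC.fit` to obtain a :class:`DAPCResults`
carrying coefficients, contributions and diagnostics, and hang assignment
and panel selection off the results object.  Thin functional wrappers
(:func:`fit_dapc`, :func:`assign`, ...) mirror the same surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .genotypes import GenotypeTable

_RIDGE = 1e-8


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Centered (optionally scaled) PCA of the mean-imputed dosage matrix."""

    means: np.ndarray  # (L,) locus means used for imputation and centering
    scales: np.ndarray | None  # (L,) or None
    loadings: np.ndarray  # (L, n_pc), orthonormal columns
    eigenvalues: np.ndarray  # (n_pc,), non-increasing
    locus_ids: list[str] = field(default_factory=list)

    @property
    def var_fractions(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues

    @property
    def cum_var_fractions(self) -> np.ndarray:
        return np.cumsum(self.var_fractions)

    def transform(self, table: GenotypeTable, n_pc: int | None = None) -> np.ndarray:
        """Project a table into PC space using the stored imputation/centering."""
        if table.locus_ids != self.locus_ids:
            missing = set(self.locus_ids) - set(table.locus_ids)
            raise ValueError(
                f"table loci do not match the model's loci"
                + (f"; missing: {sorted(missing)[:5]}..." if missing else " (order differs)")
            )
        X = table.dosages_float()
        X = np.where(np.isnan(X), self.means, X) - self.means
        if self.scales is not None:
            X = X / self.scales
        k = self.loadings.shape[1] if n_pc is None else n_pc
        return X @ self.loadings[:, :k]


def fit_pca(table: GenotypeTable, scale: bool = False) -> tuple[PCAModel, np.ndarray]:
    """PCA by SVD of the centered, mean-imputed dosage matrix.

    Returns the model and the (n_samples, n_pc) score matrix; eigenvalues
    are squared singular values / (n-1).
    """
    if table.n_samples < 2 or table.n_loci < 1:
        raise ValueError("PCA needs >=2 samples and >=1 locus")
    X = table.dosages_float()
    means = np.nanmean(X, axis=0)
    means = np.where(np.isnan(means), 0.0, means)  # all-missing column
    X = np.where(np.isnan(X), means, X) - means
    scales = None
    if scale:
        scales = X.std(axis=0, ddof=1)
        scales[scales == 0] = 1.0
        X = X / scales
    if not np.any(X):
        raise ValueError("zero-variance genotype matrix; PCA undefined")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = s > s[0] * 1e-12
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    model = PCAModel(
        means=means,
        scales=scales,
        loadings=Vt.T,
        eigenvalues=s**2 / (table.n_samples - 1),
        locus_ids=table.locus_ids,
    )
    return model, U * s


# ---------------------------------------------------------------------------
# DAPC model / results
# ---------------------------------------------------------------------------

@dataclass
class SNPPanel:
    threshold: float
    axis_policy: str
    table: pd.DataFrame  # locus_id, contribution, axis

    @property
    def locus_ids(self) -> list[str]:
        return list(self.table["locus_id"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class AssignmentReport:
    groups: list[str]
    confusion: pd.DataFrame  # true x assigned counts
    per_population: dict[str, float]
    overall: float
    mean_posterior_true: float
    posteriors: pd.DataFrame  # sample_id x group
    assigned: pd.Series  # sample_id -> group

    def summary(self) -> str:
        lines = ["Assignment report", "=" * 17]
        for g in self.groups:
            lines.append(f"  {g:>10s}: {self.per_population[g]:6.1%} correct")
        lines.append(f"  {'overall':>10s}: {self.overall:6.1%} correct")
        lines.append(f"  mean posterior of true group: {self.mean_posterior_true:.3f}")
        return "\n".join(lines)


class DAPC:
    """Discriminant analysis of principal components of a genotype table.

    Parameters
    ----------
    table : GenotypeTable
        Training genotypes.
    labels : sequence of str, optional
        Group labels; defaults to the table's population labels.
    scale : bool
        Scale loci to unit variance before PCA (default off: centering only).
    """

    def __init__(
        self,
        table: GenotypeTable,
        labels: Sequence[str] | None = None,
        scale: bool = False,
    ) -> None:
        self.table = table
        self.labels = np.asarray(labels if labels is not None else table.population_labels)
        if len(self.labels) != table.n_samples:
            raise ValueError("labels length must equal number of samples")
        self.groups = list(dict.fromkeys(self.labels))
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        self.scale = scale
        self._pca, self._pc_scores = fit_pca(table, scale=scale)

    @property
    def max_n_pca(self) -> int:
        return min(self._pc_scores.shape[1], self.table.n_samples - len(self.groups))

    def fit(self, n_pca: int | None = None, **a_score_kwargs) -> "DAPCResults":
        """Fit the discriminant step on ``n_pca`` retained PCs.

        When ``n_pca`` is None it is chosen by a-score optimization
        (``a_score_kwargs`` forwarded to :meth:`a_score`).
        """
        if n_pca is None:
            n_pca = self.a_score(**a_score_kwargs).best_n_pca
        if not 1 <= n_pca <= self.max_n_pca:
            raise ValueError(f"n_pca must be in [1, {self.max_n_pca}], got {n_pca}")
        return self._fit_on(self._pc_scores[:, :n_pca], n_pca, self.labels)

    def _fit_on(self, S: np.ndarray, n_pca: int, labels: np.ndarray) -> "DAPCResults":
        groups = list(dict.fromkeys(labels))
        K = len(groups)
        n = S.shape[0]
        mu = S.mean(axis=0)
        W = np.zeros((n_pca, n_pca))
        B = np.zeros((n_pca, n_pca))
        centroids_pc = np.zeros((K, n_pca))
        for k, g in enumerate(groups):
            Sg = S[labels == g]
            centroids_pc[k] = Sg.mean(axis=0)
            dev = Sg - centroids_pc[k]
            W += dev.T @ dev
            dg = centroids_pc[k] - mu
            B += len(Sg) * np.outer(dg, dg)
        W /= max(n - K, 1)
        B /= max(K - 1, 1)
        W_reg = W + _RIDGE * np.eye(n_pca) * max(np.trace(W) / n_pca, 1.0)
        evals, evecs = linalg.eigh(B, W_reg)
        order = np.argsort(evals)[::-1][: K - 1]
        coef = evecs[:, order]  # (n_pca, K-1), W-orthonormal
        disc_eig = np.maximum(evals[order], 0.0)

        Y = S @ coef
        centroids = centroids_pc @ coef
        within_var = np.zeros(K - 1)
        for k, g in enumerate(groups):
            dev = Y[labels == g] - centroids[k]
            within_var += (dev**2).sum(axis=0)
        within_var /= max(n - K, 1)
        within_var = np.maximum(within_var, 1e-12)

        # contributions of original SNPs: squared loading->axis weight, per-axis sum 1
        raw = (self._pca.loadings[:, :n_pca] @ coef) ** 2
        colsum = raw.sum(axis=0)
        contributions = raw / np.where(colsum > 0, colsum, 1.0)

        return DAPCResults(
            model=self,
            pca=self._pca,
            n_pca=n_pca,
            groups=groups,
            coef=coef,
            disc_eigenvalues=disc_eig,
            centroids=centroids,
            within_var=within_var,
            contributions=contributions,
            scores=Y,
        )

    # -- a-score ---------------------------------------------------------
    def a_score(
        self,
        candidate_grid: Sequence[int] | None = None,
        n_sim: int = 10,
        seed: int | None = None,
    ) -> "AScoreResult":
        """Choose the number of retained PCs by the permutation a-score.

        For each candidate the a-score is the observed self-reassignment
        proportion minus the mean reassignment proportion over ``n_sim``
        fits with permuted labels; the argmax wins, smaller n_pca on ties.
        """
        if candidate_grid is None:
            candidate_grid = range(1, min(100, self.max_n_pca) + 1)
        grid = [int(c) for c in candidate_grid]
        if not grid or min(grid) < 1 or max(grid) > self.max_n_pca:
            raise ValueError(f"candidate grid must be within [1, {self.max_n_pca}]")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(self.labels) for _ in range(n_sim)]
        rows = []
        for c in grid:
            S = self._pc_scores[:, :c]
            p_t = self._reassignment(S, c, self.labels)
            p_r = [self._reassignment(S, c, pl) for pl in perms]
            rows.append((c, p_t, float(np.mean(p_r)), p_t - float(np.mean(p_r))))
        df = pd.DataFrame(rows, columns=["n_pca", "P_t", "P_r", "a_score"])
        best = int(df.loc[df["a_score"].idxmax(), "n_pca"])  # idxmax -> first max
        return AScoreResult(table=df, best_n_pca=best)

    def _reassignment(self, S: np.ndarray, n_pca: int, labels: np.ndarray) -> float:
        res = self._fit_on(S, n_pca, labels)
        post = res._posteriors(res.scores, np.asarray(res.groups))
        assigned = np.asarray(res.groups)[post.argmax(axis=1)]
        return float(np.mean(assigned == labels))


@dataclass
class AScoreResult:
    table: pd.DataFrame
    best_n_pca: int


@dataclass
class DAPCResults:
    """Fitted DAPC: discriminant coefficients, contributions, diagnostics."""

    model: DAPC
    pca: PCAModel
    n_pca: int
    groups: list[str]
    coef: np.ndarray  # (n_pca, K-1)
    disc_eigenvalues: np.ndarray
    centroids: np.ndarray  # (K, K-1)
    within_var: np.ndarray  # (K-1,)
    contributions: np.ndarray  # (L, K-1), columns sum to 1
    scores: np.ndarray  # training samples in discriminant space

    @property
    def n_da(self) -> int:
        return self.coef.shape[1]

    def summary(self) -> str:
        pca_var = self.pca.cum_var_fractions[self.n_pca - 1]
        lines = [
            "DAPC results",
            "============",
            f"groups: {', '.join(self.groups)} (K={len(self.groups)})",
            f"retained PCs: {self.n_pca} (cumulative variance {pca_var:.1%})",
            f"discriminant axes: {self.n_da}",
            "discriminant eigenvalues: "
            + ", ".join(f"{e:.3g}" for e in self.disc_eigenvalues),
        ]
        return "\n".join(lines)

    # -- membership probabilities ---------------------------------------
    def _posteriors(self, Y: np.ndarray, groups: np.ndarray) -> np.ndarray:
        d2 = ((Y[:, None, :] - self.centroids[None, :, :]) ** 2) / self.within_var
        loglik = -0.5 * d2.sum(axis=2)
        loglik -= loglik.max(axis=1, keepdims=True)
        post = np.exp(loglik)
        return post / post.sum(axis=1, keepdims=True)

    def transform(self, table: GenotypeTable) -> np.ndarray:
        """Project genotypes into discriminant space."""
        return self.pca.transform(table, self.n_pca) @ self.coef

    def assign(self, table: GenotypeTable | None = None) -> AssignmentReport:
        """Assign individuals to groups by highest Gaussian posterior.

        Defaults to reassigning the training table; the report's accuracy
        entries compare against the table's population labels.
        """
        table = table if table is not None else self.model.table
        Y = self.transform(table)
        garr = np.asarray(self.groups)
        post = self._posteriors(Y, garr)
        assigned = garr[post.argmax(axis=1)]
        true = table.population_labels

        confusion = pd.DataFrame(0, index=self.groups, columns=self.groups)
        for t, a in zip(true, assigned):
            if t in confusion.index:
                confusion.loc[t, a] += 1
        per_pop = {}
        post_true = []
        for k, g in enumerate(garr):
            mask = true == g
            if mask.any():
                per_pop[g] = float(np.mean(assigned[mask] == g))
                post_true.append(post[mask, k])
        overall = float(np.mean(assigned == true))
        mean_post_true = float(np.concatenate(post_true).mean()) if post_true else float("nan")
        return AssignmentReport(
            groups=self.groups,
            confusion=confusion,
            per_population=per_pop,
            overall=overall,
            mean_posterior_true=mean_post_true,
            posteriors=pd.DataFrame(post, index=table.sample_ids, columns=self.groups),
            assigned=pd.Series(assigned, index=table.sample_ids),
        )

    # -- informative panel ----------------------------------------------
    def select_informative(self, threshold: float = 0.01, axis_policy: str = "max") -> SNPPanel:
        """Select SNPs whose discriminant contribution reaches ``threshold``.

        ``axis_policy``: "max" (default) scores each SNP by its maximum
        contribution over axes; "axis1" uses the first axis only;
        "eigen-weighted" weights axes by their discriminant eigenvalues.
        """
        if not 0.0 <= threshold <= 1.0:
            raise ValueError(f"threshold must be in [0,1], got {threshold}")
        C = self.contributions
        if axis_policy == "max":
            score = C.max(axis=1)
            axis = C.argmax(axis=1)
        elif axis_policy == "axis1":
            score = C[:, 0]
            axis = np.zeros(C.shape[0], dtype=int)
        elif axis_policy == "eigen-weighted":
            w = self.disc_eigenvalues / max(self.disc_eigenvalues.sum(), 1e-300)
            score = C @ w
            axis = C.argmax(axis=1)
        else:
            raise ValueError(f"unknown axis_policy {axis_policy!r}")
        sel = score >= threshold
        df = pd.DataFrame(
            {
                "locus_id": np.asarray(self.pca.locus_ids)[sel],
                "contribution": score[sel],
                "axis": axis[sel] + 1,
            }
        ).sort_values("contribution", ascending=False, ignore_index=True)
        return SNPPanel(threshold=threshold, axis_policy=axis_policy, table=df)

    def to_json_dict(self) -> dict:
        return {
            "groups": self.groups,
            "n_pca": self.n_pca,
            "means": self.pca.means.tolist(),
            "loadings": self.pca.loadings[:, : self.n_pca].tolist(),
            "coef": self.coef.tolist(),
            "centroids": self.centroids.tolist(),
            "within_var": self.within_var.tolist(),
            "locus_ids": self.pca.locus_ids,
        }


# ---------------------------------------------------------------------------
# Functional wrappers and the full-vs-reduced panel comparison
# ---------------------------------------------------------------------------

def a_score_optimize(
    table: GenotypeTable,
    labels: Sequence[str] | None = None,
    candidate_grid: Sequence[int] | None = None,
    n_sim: int = 10,
    seed: int | None = None,
) -> AScoreResult:
    return DAPC(table, labels).a_score(candidate_grid=candidate_grid, n_sim=n_sim, seed=seed)


def fit_dapc(
    table: GenotypeTable, labels: Sequence[str] | None = None, n_pca: int | None = None, **kw
) -> DAPCResults:
    return DAPC(table, labels).fit(n_pca=n_pca, **kw)


def select_informative(
    results: DAPCResults, threshold: float = 0.01, axis_policy: str = "max"
) -> SNPPanel:
    return results.select_informative(threshold=threshold, axis_policy=axis_policy)


def assign(results: DAPCResults, table: GenotypeTable | None = None) -> AssignmentReport:
    return results.assign(table)


@dataclass
class PanelComparison:
    full: AssignmentReport
    reduced: AssignmentReport
    panel: SNPPanel
    full_results: DAPCResults
    reduced_results: DAPCResults


def compare_panels(
    table: GenotypeTable,
    labels: Sequence[str] | None = None,
    threshold: float = 0.01,
    axis_policy: str = "max",
    seed: int | None = None,
    n_sim: int = 10,
    candidate_grid: Sequence[int] | None = None,
) -> PanelComparison:
    """Full pipeline: a-score, fit, panel selection, refit on the reduced
    panel, and self-assignment reports for both panels.

    The reduced panel is refitted from scratch (its own a-score run with the
    same seed), mirroring how a laboratory would genotype only the reduced
    marker set.
    """
    model = DAPC(table, labels)
    full_res = model.fit(n_pca=None, candidate_grid=candidate_grid, n_sim=n_sim, seed=seed)
    panel = full_res.select_informative(threshold=threshold, axis_policy=axis_policy)
    full_report = full_res.assign()

    reduced_table = table.subset_loci_by_id(panel.locus_ids)
    red_model = DAPC(reduced_table, labels)
    red_grid = None
    if candidate_grid is not None:
        red_grid = [c for c in candidate_grid if c <= red_model.max_n_pca]
    red_res = red_model.fit(n_pca=None, candidate_grid=red_grid, n_sim=n_sim, seed=seed)
    red_report = red_res.assign()
    return PanelComparison(
        full=full_report,
        reduced=red_report,
        panel=panel,
        full_results=full_res,
        reduced_results=red_res,
    )
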