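"""Principal-interaction extraction from a centered energy matrix.

Procedure, applied to the column-centered n x p matrix U (p = 210 pair types
for the full alphabet):

1. covariance  Sigma = U^T U / (n - 1), eigendecomposed as Sigma = V L V^T
   with eigenvalues in decreasing order;
2. variance proportions  t_j = 100 * lambda_j / sum(lambda), and the smallest
   m with t_1 + ... + t_m >= 80;
3. per-component contributions  C_kj = 100 * V_j(k)^2 / sum_k V_j(k)^2 (each
   column of C sums to 100, and is invariant to eigenvector sign);
4. total contribution of variable k:  sum_{j<=m} C_kj * lambda_j, compared to
   the uniform-contribution threshold  tau = sum_{j<=m} (100/p) * lambda_j
   (at p = 210 this is sum (1/2.1) * lambda_j).  tau is identically the mean
   of the total contributions over all p variables.

Variables whose total contribution strictly exceeds tau form the principal
set.  The selection is invariant to positive rescaling of the energies, row
permutation, and eigenvector sign flips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .energy_vectors import EnergyMatrix

_CENTER_TOL = 1e-8


@dataclass
class EigenSpectrum:
    """Sorted (non-increasing) eigenvalues with paired unit eigenvectors."""

    eigenvalues: np.ndarray    # (p,), clipped at 0
    eigenvectors: np.ndarray   # (p, p), column j pairs with eigenvalue j

    @property
    def p(self) -> int:
        return len(self.eigenvalues)


@dataclass
class SelectionResult:
    labels: list[str]
    spectrum: EigenSpectrum
    t: np.ndarray                   # (p,) variance proportions, percent
    m: int                          # retained components
    contributions: np.ndarray       # (p, m), percent, columns sum to 100
    total_contribution: np.ndarray  # (p,)
    tau: float
    principal_set: list[str]
    ranked_variables: list[str]     # all p labels, total contribution descending
    threshold_percent: float = 80.0

    @property
    def support(self) -> np.ndarray:
        return self.total_contribution > self.tau

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.total_contribution, kind="stable")
        rank = np.empty(len(self.labels), dtype=int)
        rank[order] = np.arange(1, len(self.labels) + 1)
        return pd.DataFrame(
            {
                "pair_label": self.labels,
                "total_contribution": self.total_contribution,
                "tau": self.tau,
                "selected": self.support,
                "rank": rank,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "n_variables": len(self.labels),
            "m": self.m,
            "threshold_percent": self.threshold_percent,
            "tau": self.tau,
            "eigenvalues": self.spectrum.eigenvalues.tolist(),
            "variance_proportions": self.t.tolist(),
            "principal_set": self.principal_set,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1)


def _as_centered_array(cte) -> tuple[np.ndarray, list[str]]:
    if isinstance(cte, EnergyMatrix):
        if not cte.centered:
            raise ValueError("energy matrix is not column-centered (call center_columns)")
        x, labels = cte.values, list(cte.column_labels)
    else:
        x = np.asarray(cte, dtype=float)
        labels = [str(i) for i in range(x.shape[1])]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    col_means = x.mean(axis=0)
    scale = max(1.0, float(np.abs(x).max()))
    if np.abs(col_means).max() > _CENTER_TOL * scale:
        raise ValueError("input matrix is not column-centered")
    return x, labels


def covariance(cte) -> np.ndarray:
    """Sample covariance U^T U / (n - 1) of a column-centered matrix."""
    x, _ = _as_centered_array(cte)
    return x.T @ x / (x.shape[0] - 1)


def eigendecompose(cov: np.ndarray) -> EigenSpectrum:
    """Sorted eigendecomposition of a symmetric (covariance) matrix."""
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    asym = np.abs(cov - cov.T).max()
    if asym > 1e-8 * max(1.0, np.abs(cov).max()):
        raise ValueError(f"matrix is not symmetric (max asymmetry {asym:g})")
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals.min() < -1e-9 * max(1.0, vals.max()):
        raise ValueError("covariance has significantly negative eigenvalues")
    return EigenSpectrum(np.clip(vals, 0.0, None), vecs)


def variance_proportions(spec: EigenSpectrum) -> np.ndarray:
    """t_j = 100 * lambda_j / sum(lambda); non-increasing, sums to 100."""
    total = spec.eigenvalues.sum()
    if total <= 0:
        raise ValueError("zero total variance: nothing to explain")
    return 100.0 * spec.eigenvalues / total


def select_components(t: np.ndarray, threshold_percent: float = 80.0) -> int:
    """Smallest m whose cumulative variance proportion reaches the threshold."""
    csum = np.cumsum(t)
    hit = np.nonzero(csum >= threshold_percent - 1e-12)[0]
    return int(hit[0]) + 1 if len(hit) else len(t)


def contributions(spec: EigenSpectrum, m: int) -> np.ndarray:
    """C_kj = 100 * V_j(k)^2 / sum_k V_j(k)^2 for the first m components."""
    if not (1 <= m <= spec.p):
        raise ValueError(f"m must be in [1, {spec.p}]")
    v = spec.eigenvectors[:, :m]
    sq = v ** 2
    return 100.0 * sq / sq.sum(axis=0, keepdims=True)


def total_contributions(c: np.ndarray, spec: EigenSpectrum, m: int) -> np.ndarray:
    """Eigenvalue-weighted contribution of each variable over the m components."""
    return c[:, :m] @ spec.eigenvalues[:m]


def uniform_threshold(spec: EigenSpectrum, m: int, p: int | None = None) -> float:
    """tau = sum_{j<=m} (100/p) * lambda_j, the uniform-contribution baseline.

    Equals the mean of the total contributions over all p variables.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    p = p if p is not None else spec.p
    return float((100.0 / p) * spec.eigenvalues[:m].sum())


def select_principal(cte, threshold_percent: float = 80.0) -> SelectionResult:
    """Run the full extraction chain on a centered energy matrix."""
    x, labels = _as_centered_array(cte)
    spec = eigendecompose(x.T @ x / (x.shape[0] - 1))
    t = variance_proportions(spec)
    m = select_components(t, threshold_percent)
    c = contributions(spec, m)
    totals = total_contributions(c, spec, m)
    tau = uniform_threshold(spec, m)
    assert abs(totals.mean() - tau) <= 1e-8 * max(1.0, tau), "tau/mean identity violated"
    support = totals > tau
    order = np.argsort(-totals, kind="stable")
    return SelectionResult(
        labels=labels,
        spectrum=spec,
        t=t,
        m=m,
        contributions=c,
        total_contribution=totals,
        tau=tau,
        principal_set=[labels[i] for i in np.nonzero(support)[0]],
        ranked_variables=[labels[i] for i in order],
        threshold_percent=threshold_percent,
    )


class PrincipalInteractionSelector(SelectorMixin, BaseEstimator):
    """Feature selector keeping variables whose eigenvalue-weighted PCA
    contribution exceeds the uniform-contribution threshold tau.

    Parameters
    ----------
    variance_threshold : float, default 80.0
        Percent of total variance the retained leading components must reach.
    center : bool, default True
        Column-center X before the covariance analysis.  Set False if X is
        already centered (it is then validated).

    Attributes
    ----------
    means_ : column means subtracted (zeros when center=False)
    eigenvalues_, components_ : sorted covariance spectrum
    variance_ratio_ : per-component variance proportions (percent)
    n_components_ : retained component count m
    contributions_ : (p, m) per-component contributions (percent)
    total_contribution_ : (p,) eigenvalue-weighted totals
    tau_ : selection threshold
    support_ : boolean mask of selected variables
    ranking_ : indices of variables by descending total contribution
    """

    def __init__(self, variance_threshold: float = 80.0, center: bool = True):
        self.variance_threshold = variance_threshold
        self.center = center

    def fit(self, X, y=None) -> "PrincipalInteractionSelector":
        labels = None
        if isinstance(X, EnergyMatrix):
            labels = list(X.column_labels)
            X = X.values
        X = check_array(X, dtype=float, ensure_min_samples=2)
        self.n_features_in_ = X.shape[1]
        if self.center:
            self.means_ = X.mean(axis=0)
            X = X - self.means_
        else:
            self.means_ = np.zeros(X.shape[1])
        result = select_principal(X, self.variance_threshold)
        if labels is not None:
            result.labels = labels
            self.feature_labels_ = labels
            order = np.argsort(-result.total_contribution, kind="stable")
            result.principal_set = [labels[i] for i in np.nonzero(result.support)[0]]
            result.ranked_variables = [labels[i] for i in order]
        self.result_ = result
        self.eigenvalues_ = result.spectrum.eigenvalues
        self.components_ = result.spectrum.eigenvectors
        self.variance_ratio_ = result.t
        self.n_components_ = result.m
        self.contributions_ = result.contributions
        self.total_contribution_ = result.total_contribution
        self.tau_ = result.tau
        self.support_ = result.support
        self.ranking_ = np.argsort(-result.total_contribution, kind="stable")
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
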