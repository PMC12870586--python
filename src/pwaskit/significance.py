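"""Multiple-testing correction for correlated signals.

The family-wise threshold for the marginal scans divides alpha by an
effective number of tests: the number of principal components of the
signal correlation matrix needed to explain a target fraction (default
80%) of the total variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EffectiveTests", "effective_tests", "effective_tests_from_correlation", "bonferroni_threshold"]


@dataclass
class EffectiveTests:
    """Effective number of tests and the resulting Bonferroni threshold."""

    M: int
    variance_fraction_target: float
    cumulative_variance_at_M: float
    eigenvalue_shares: np.ndarray
    alpha: float | None = None
    threshold: float | None = None

    def display_threshold(self) -> str:
        """Threshold rounded to 2 significant figures, e.g. '3.1e-04'."""
        if self.threshold is None:
            raise ValueError("threshold not set; call bonferroni_threshold first")
        return np.format_float_scientific(self.threshold, precision=1)


def effective_tests_from_correlation(
    corr: np.ndarray, target: float = 0.80
) -> EffectiveTests:
    """Effective tests from an explicit correlation (or covariance) matrix."""
    if not (0.0 < target <= 1.0):
        raise ValueError("target must lie in (0, 1]")
    C = np.asarray(corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    eig = np.linalg.eigvalsh(C)[::-1]
    eig = np.clip(eig, 0.0, None)
    shares = eig / eig.sum()
    cum = np.cumsum(shares)
    M = int(np.searchsorted(cum, target - 1e-12) + 1)
    return EffectiveTests(
        M=M,
        variance_fraction_target=target,
        cumulative_variance_at_M=float(cum[M - 1]),
        eigenvalue_shares=shares,
    )


def effective_tests(proteins: pd.DataFrame | np.ndarray, target: float = 0.80) -> EffectiveTests:
    """Number of principal components explaining ``target`` of the variance.

    PCA is taken on the column correlation matrix (columns standardized),
    and M is the smallest component count whose cumulative eigenvalue
    share reaches the target (first crossing, inclusive).
    """
    X = proteins.to_numpy() if isinstance(proteins, pd.DataFrame) else np.asarray(proteins, dtype=float)
    if np.isnan(X).any():
        raise ValueError("protein matrix contains missing values; complete it upstream")
    if X.shape[1] < 2:
        raise ValueError("need >= 2 signal columns")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance signal column(s) present")
    corr = np.corrcoef(X, rowvar=False)
    return effective_tests_from_correlation(corr, target=target)


def bonferroni_threshold(alpha: float = 0.05, M: int | EffectiveTests = 1) -> float:
    """Family-wise threshold alpha / M (exact quotient).

    When given an :class:`EffectiveTests`, the threshold and alpha are
    stored on it and the quotient returned.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if isinstance(M, EffectiveTests):
        M.alpha = alpha
        M.threshold = alpha / M.M
        return M.threshold
    if int(M) < 1:
        raise ValueError("M must be >= 1")
    return alpha / int(M)
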