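"""Linear mixed models with a kinship-structured random effect.

The model is ``y = X b + g + e`` with ``g ~ N(0, sigma2_g K)`` and
``e ~ N(0, sigma2_e I)`` for a symmetric PSD relatedness matrix ``K``
(diagonal 1, full siblings 0.5 — i.e. twice the kinship coefficient).
REML estimation uses a single spectral decomposition ``K = U D U'``:
after rotating ``y`` and ``X`` by ``U'`` the covariance is diagonal in
the variance ratio ``delta = sigma2_e / sigma2_g``, which is profiled
out on a log-spaced grid refined by bounded scalar minimization.  The
decomposition can be shared across many responses (e.g. a full proteome
residualization against one covariate design).

Two applications are provided as module functions: residualizing protein
signals on covariates (conditional, BLUP-subtracted residuals, then
scaled), and the marginal association of each signal with APOE e4 allele
count coded as a 3-level factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = [
    "KinshipDecomposition",
    "KinshipLMM",
    "KinshipLMMResults",
    "fit_lmm",
    "residualize_protein",
    "residualize_proteins",
    "apoe_association",
    "apoe_scan",
    "BASIC_ADJUSTMENT",
    "FULL_ADJUSTMENT",
]

BASIC_ADJUSTMENT = ["age", "sex"]
FULL_ADJUSTMENT = BASIC_ADJUSTMENT + [
    "simd",
    "bmi",
    "alcohol",
    "smoking_score",
    "depression",
    "education",
    "high_blood_pressure",
]
# diabetes is collected but absent from some model descriptions; it can be
# added to the full tier explicitly (include_diabetes switch in apoe_scan).

_DELTA_GRID = np.logspace(-4, 4, 81)


class KinshipDecomposition:
    """Cached eigendecomposition of a kinship matrix.

    Reused across responses sharing the same individuals; building it is
    the only O(n^3) step of a proteome-wide scan.
    """

    def __init__(self, K: pd.DataFrame | np.ndarray):
        A = K.to_numpy() if isinstance(K, pd.DataFrame) else np.asarray(K, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(A, A.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        d, U = np.linalg.eigh(A)
        if d.min() < -1e-8:
            raise ValueError(
                f"kinship matrix is not PSD (min eigenvalue {d.min():.3e})"
            )
        self.eigenvalues = np.clip(d, 0.0, None)
        self.U = U
        self.n = A.shape[0]

    def rotate(self, M: np.ndarray) -> np.ndarray:
        return self.U.T @ M


@dataclass
class KinshipLMMResults:
    """REML fit of the kinship LMM.

    ``params``/``bse`` are the GLS fixed effects and standard errors at
    the REML variance estimates; ``sigma2_g`` scales the kinship
    covariance and ``sigma2_e`` the independent residual.
    """

    params: np.ndarray
    bse: np.ndarray
    sigma2_g: float
    sigma2_e: float
    llf_reml: float
    converged: bool
    model: "KinshipLMM"
    exog_names: list[str]

    @property
    def heritable_fraction(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.tvalues))

    def resid_conditional(self) -> np.ndarray:
        """Residuals with both fixed effects and the BLUP removed."""
        m = self.model
        delta = self.sigma2_e / self.sigma2_g if self.sigma2_g > 0 else np.inf
        r_rot = m._y_rot - m._X_rot @ self.params
        if np.isinf(delta):
            shrink = np.ones_like(m._eig)
        else:
            shrink = delta / (m._eig + delta)
        return m.decomposition.U @ (shrink * r_rot)

    def resid_marginal(self) -> np.ndarray:
        return np.asarray(self.model.endog) - self.model.exog @ self.params

    def summary(self) -> str:
        lines = [
            "Kinship linear mixed model (REML)",
            f"  n = {self.model.nobs}, sigma2_g = {self.sigma2_g:.4f}, "
            f"sigma2_e = {self.sigma2_e:.4f} "
            f"(heritable fraction {self.heritable_fraction:.3f})",
            f"  REML loglik = {self.llf_reml:.3f}  converged = {self.converged}",
            f"  {'term':<24}{'coef':>10}{'se':>10}{'z':>8}{'p':>10}",
        ]
        for name, b, s, z, p in zip(
            self.exog_names, self.params, self.bse, self.tvalues, self.pvalues
        ):
            lines.append(f"  {name:<24}{b:>10.4f}{s:>10.4f}{z:>8.2f}{p:>10.2e}")
        return "\n".join(lines)


class KinshipLMM:
    """Model object for ``y = X b + g + e`` with kinship covariance.

    Parameters
    ----------
    endog : response vector (n,)
    exog : fixed-effect design (n, p), full column rank
    kinship : relatedness matrix or a precomputed KinshipDecomposition
    """

    def __init__(
        self,
        endog,
        exog,
        kinship: pd.DataFrame | np.ndarray | KinshipDecomposition,
        exog_names: list[str] | None = None,
    ):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if np.isnan(y).any() or np.isnan(X).any():
            raise ValueError("endog/exog contain missing values")
        if isinstance(kinship, KinshipDecomposition):
            dec = kinship
        else:
            dec = KinshipDecomposition(kinship)
        if dec.n != len(y) or X.shape[0] != len(y):
            raise ValueError("dimension mismatch between endog, exog and kinship")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            aliased = _aliased_columns(X)
            names = exog_names or [f"x{i}" for i in range(X.shape[1])]
            raise ValueError(
                f"exog is rank deficient; aliased columns: {[names[i] for i in aliased]}"
            )
        self.endog = y
        self.exog = X
        self.nobs = len(y)
        self.decomposition = dec
        self.exog_names = exog_names or [f"x{i}" for i in range(X.shape[1])]
        self._eig = dec.eigenvalues
        self._y_rot = dec.rotate(y)
        self._X_rot = dec.rotate(X)

    def _profile_reml(self, delta: float):
        """GLS profile quantities at a fixed variance ratio delta."""
        d = self._eig
        w = 1.0 / (d + delta)
        Xw = self._X_rot * w[:, None]
        XtWX = self._X_rot.T @ Xw
        XtWy = Xw.T @ self._y_rot
        beta = np.linalg.solve(XtWX, XtWy)
        r = self._y_rot - self._X_rot @ beta
        rss = float(np.sum(w * r * r))
        return beta, XtWX, rss, w

    def _reml_loglik(self, delta: float) -> float:
        n, p = self.nobs, self.exog.shape[1]
        _, XtWX, rss, w = self._profile_reml(delta)
        df = n - p
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign <= 0 or rss <= 0:
            return -np.inf
        return -0.5 * (
            df * np.log(2.0 * np.pi * rss / df)
            + df
            - np.sum(np.log(w))
            + logdet_xwx
        )

    def _ols_reml_loglik(self) -> float:
        # delta -> inf limit: plain OLS with sigma2_g = 0
        n, p = self.nobs, self.exog.shape[1]
        beta = np.linalg.lstsq(self.exog, self.endog, rcond=None)[0]
        r = self.endog - self.exog @ beta
        rss = float(r @ r)
        df = n - p
        sign, logdet = np.linalg.slogdet(self.exog.T @ self.exog)
        if rss <= 0:
            return np.inf  # degenerate, handled by caller
        return -0.5 * (df * np.log(2.0 * np.pi * rss / df) + df + logdet)

    def fit(self) -> KinshipLMMResults:
        """REML: grid search over log delta, then bounded refinement."""
        grid_ll = np.array([self._reml_loglik(d) for d in _DELTA_GRID])
        i = int(np.argmax(grid_ll))
        lo = _DELTA_GRID[max(i - 1, 0)]
        hi = _DELTA_GRID[min(i + 1, len(_DELTA_GRID) - 1)]
        res = minimize_scalar(
            lambda t: -self._reml_loglik(np.exp(t)),
            bounds=(np.log(lo), np.log(hi)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        delta = float(np.exp(res.x))
        ll = -res.fun
        converged = bool(res.success)

        ols_ll = self._ols_reml_loglik()
        n, p = self.nobs, self.exog.shape[1]
        if np.isfinite(ols_ll) and ols_ll > ll:
            # boundary solution: no kinship variance
            beta, *_ = np.linalg.lstsq(self.exog, self.endog, rcond=None)
            r = self.endog - self.exog @ beta
            s2e = float(r @ r) / (n - p)
            cov = s2e * np.linalg.inv(self.exog.T @ self.exog)
            return KinshipLMMResults(
                params=beta,
                bse=np.sqrt(np.diag(cov)),
                sigma2_g=0.0,
                sigma2_e=s2e,
                llf_reml=ols_ll,
                converged=True,
                model=self,
                exog_names=self.exog_names,
            )

        beta, XtWX, rss, _ = self._profile_reml(delta)
        s2g = rss / (n - p)
        s2e = s2g * delta
        cov = s2g * np.linalg.inv(XtWX)
        return KinshipLMMResults(
            params=beta,
            bse=np.sqrt(np.diag(cov)),
            sigma2_g=s2g,
            sigma2_e=s2e,
            llf_reml=ll,
            converged=converged,
            model=self,
            exog_names=self.exog_names,
        )


def _aliased_columns(X: np.ndarray) -> list[int]:
    """Columns linearly dependent on earlier ones (QR pivot heuristic)."""
    aliased = []
    cols: list[np.ndarray] = []
    for j in range(X.shape[1]):
        trial = np.column_stack(cols + [X[:, j]]) if cols else X[:, [j]]
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            aliased.append(j)
        else:
            cols.append(X[:, j])
    return aliased


def fit_lmm(y, X, K, exog_names: list[str] | None = None) -> KinshipLMMResults:
    """Functional wrapper: REML fit of the kinship LMM."""
    return KinshipLMM(y, X, K, exog_names=exog_names).fit()


def _design(covariates: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, list[str]]:
    missing = [c for c in columns if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate columns absent: {missing}")
    X = np.column_stack(
        [np.ones(len(covariates))] + [covariates[c].to_numpy(dtype=float) for c in columns]
    )
    return X, ["intercept"] + columns


def residualize_protein(
    y,
    covariates: pd.DataFrame,
    K: pd.DataFrame | np.ndarray | KinshipDecomposition,
    adjustment: list[str] | None = None,
) -> np.ndarray:
    """Kinship-aware residualization of one (transformed) signal.

    The signal is regressed on the covariates with a kinship random
    effect; the conditional residual (fixed effects and BLUP subtracted)
    is returned scaled to mean 0 and unit sample variance.
    """
    cols = adjustment if adjustment is not None else BASIC_ADJUSTMENT
    X, names = _design(covariates, cols)
    fit = KinshipLMM(y, X, K, exog_names=names).fit()
    r = fit.resid_conditional()
    sd = r.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("residuals have (near) zero variance; response is degenerate")
    return (r - r.mean()) / sd


def residualize_proteins(
    proteins: pd.DataFrame,
    covariates: pd.DataFrame,
    K: pd.DataFrame | np.ndarray | KinshipDecomposition,
    adjustment: list[str] | None = None,
) -> pd.DataFrame:
    """Residualize every signal column, reusing one kinship decomposition."""
    dec = K if isinstance(K, KinshipDecomposition) else KinshipDecomposition(K)
    out = {}
    for col in proteins.columns:
        out[col] = residualize_protein(
            proteins[col].to_numpy(), covariates, dec, adjustment=adjustment
        )
    return pd.DataFrame(out, index=proteins.index)


def apoe_association(
    protein,
    apoe_counts,
    covariates: pd.DataFrame,
    K: pd.DataFrame | np.ndarray | KinshipDecomposition,
    adjustment: str = "basic",
    include_diabetes: bool = False,
    signal: str = "signal",
) -> pd.DataFrame:
    """Association of one signal with APOE e4 count as a 3-level factor.

    The (transformed) signal is the outcome; allele count enters as two
    indicator contrasts against the 0-copy reference, adjusted for the
    chosen covariate tier plus the kinship random effect.  Returns one
    row per contrast with Wald z-test results.
    """
    counts = np.asarray(apoe_counts, dtype=float)
    levels, n_per = np.unique(counts, return_counts=True)
    if not set(levels).issubset({0.0, 1.0, 2.0}):
        raise ValueError("apoe counts must be 0, 1 or 2")
    if set(levels) != {0.0, 1.0, 2.0} or (n_per < 2).any():
        raise ValueError("need >= 2 individuals at each allele count 0/1/2")
    if adjustment == "basic":
        cols = list(BASIC_ADJUSTMENT)
    elif adjustment == "full":
        cols = list(FULL_ADJUSTMENT) + (["diabetes"] if include_diabetes else [])
    else:
        raise ValueError("adjustment must be 'basic' or 'full'")
    Xc, names = _design(covariates, cols)
    X = np.column_stack([Xc[:, :1], (counts == 1).astype(float), (counts == 2).astype(float), Xc[:, 1:]])
    names = [names[0], "apoe_1_vs_0", "apoe_2_vs_0"] + names[1:]
    fit = KinshipLMM(protein, X, K, exog_names=names).fit()
    rows = []
    for idx, label in ((1, "1 vs 0 copies"), (2, "2 vs 0 copies")):
        rows.append(
            {
                "signal": signal,
                "contrast": label,
                "beta": fit.params[idx],
                "se": fit.bse[idx],
                "p": fit.pvalues[idx],
                "n": len(counts),
                "adjustment": adjustment,
            }
        )
    return pd.DataFrame(rows)


def apoe_scan(
    proteins: pd.DataFrame,
    apoe_counts,
    covariates: pd.DataFrame,
    K: pd.DataFrame | np.ndarray | KinshipDecomposition,
    adjustment: str = "basic",
    include_diabetes: bool = False,
) -> pd.DataFrame:
    """APOE e4 association for every signal column (shared decomposition)."""
    dec = K if isinstance(K, KinshipDecomposition) else KinshipDecomposition(K)
    frames = [
        apoe_association(
            proteins[col].to_numpy(),
            apoe_counts,
            covariates,
            dec,
            adjustment=adjustment,
            include_diabetes=include_diabetes,
            signal=col,
        )
        for col in proteins.columns
    ]
    return pd.concat(frames, ignore_index=True)
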