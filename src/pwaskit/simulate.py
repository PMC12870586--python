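"""Synthetic family-structured cohort generation.

This module produces cohorts with the statistical structure that the
downstream models assume: block-family relatedness, a correlated proteome
with a heritable (kinship-structured) variance component, sparse
protein->outcome effects across correlated continuous outcomes,
Hardy-Weinberg APOE e4 genotypes with additive per-copy protein shifts,
mixed-type covariates with configurable missing-completely-at-random
rates, and proportional-hazards ages at dementia onset with
administrative censoring.

Every generator takes an explicit seed (or inherits one from its spec)
and is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeSpec",
    "ProteomeSpec",
    "EffectPlan",
    "SurvivalSpec",
    "simulate_kinship",
    "simulate_proteome",
    "simulate_outcomes",
    "simulate_covariates",
    "simulate_apoe",
    "simulate_survival",
    "DEFAULT_MISSINGNESS",
    "COVARIATE_ROLES",
]

# Per-covariate missing fractions used as generator defaults; age and sex
# are always complete.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "alcohol": 0.09,
    "simd": 0.06,
    "smoking_score": 0.03,
    "education": 0.05,
    "depression": 0.02,
    "diabetes": 0.02,
    "high_blood_pressure": 0.02,
    "bmi": 0.01,
}

#: role of each generated covariate column, consumed by the KNN imputer
COVARIATE_ROLES: dict[str, str] = {
    "age": "continuous",
    "sex": "binary",
    "bmi": "continuous",
    "alcohol": "continuous",
    "smoking_score": "continuous",
    "simd": "continuous",
    "education": "ordinal",
    "depression": "binary",
    "diabetes": "binary",
    "high_blood_pressure": "binary",
}


@dataclass
class PedigreeSpec:
    """Family-block pedigree for a compound-symmetric kinship matrix.

    ``relatedness_within`` is the expected genetic relatedness (twice the
    kinship coefficient): 0.5 for full siblings.  The resulting matrix has
    unit diagonal, ``relatedness_within`` within families and zero between
    families, and is positive semi-definite for relatedness in [0, 1).
    """

    n_families: int = 400
    family_size_weights: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.07, 5: 0.03}
    )
    relatedness_within: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not (0.0 <= self.relatedness_within < 1.0):
            raise ValueError(
                "relatedness_within must lie in [0, 1); a compound-symmetric "
                "block with relatedness >= 1 is not positive semi-definite"
            )
        w = np.asarray(list(self.family_size_weights.values()), dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("family_size_weights must be non-negative and sum > 0")


@dataclass
class ProteomeSpec:
    """Latent-factor + kinship-component proteome generator settings.

    Each signal is built as

        x_j = sqrt(h2) * g_j + sqrt(v_f) * (loadings_j . factors) + noise_sd * e

    with g_j ~ N(0, K) a kinship-structured genetic component,
    ``h2 = genetic_variance_fraction``, shared latent factors inducing
    cross-signal correlation, and v_f = 1 - h2 - noise_sd**2 the factor
    variance share (so the population variance of every signal is 1).
    """

    n_signals: int = 439
    n_factors: int = 15
    genetic_variance_fraction: float = 0.3
    noise_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signals < 1:
            raise ValueError("n_signals must be >= 1")
        if self.n_factors < 0:
            raise ValueError("n_factors must be >= 0")
        if not (0.0 <= self.genetic_variance_fraction < 1.0):
            raise ValueError("genetic_variance_fraction must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.factor_variance < -1e-12:
            raise ValueError(
                "genetic_variance_fraction + noise_sd**2 exceeds 1; "
                "no variance left for the factor component"
            )
        if self.n_factors == 0 and self.factor_variance > 1e-12:
            raise ValueError(
                "n_factors=0 requires genetic_variance_fraction + noise_sd**2 == 1"
            )

    @property
    def factor_variance(self) -> float:
        return 1.0 - self.genetic_variance_fraction - self.noise_sd**2


@dataclass
class EffectPlan:
    """Sparse true protein->outcome effects and outcome residual correlation.

    ``true_effects`` maps (signal index, outcome index) -> standardized
    effect size; ``residual_outcome_correlation`` is the q x q correlation
    of the outcome noise (unit diagonal, symmetric PSD).
    """

    n_outcomes: int = 5
    true_effects: Mapping[tuple[int, int], float] = field(default_factory=dict)
    residual_outcome_correlation: np.ndarray | None = None

    def correlation(self) -> np.ndarray:
        q = self.n_outcomes
        if self.residual_outcome_correlation is None:
            return np.eye(q)
        C = np.asarray(self.residual_outcome_correlation, dtype=float)
        if C.shape != (q, q):
            raise ValueError(f"residual correlation must be {q}x{q}")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("residual correlation must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("residual correlation must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("residual correlation must be positive semi-definite")
        return C

    def coefficient_matrix(self, n_signals: int) -> np.ndarray:
        B = np.zeros((n_signals, self.n_outcomes))
        for (j, k), beta in self.true_effects.items():
            if not (0 <= j < n_signals and 0 <= k < self.n_outcomes):
                raise ValueError(f"effect key ({j}, {k}) out of bounds")
            B[j, k] = beta
        return B


@dataclass
class SurvivalSpec:
    """Weibull proportional-hazards onset ages with administrative censoring.

    The cumulative hazard is ``(age / baseline_hazard_scale)**shape *
    exp(linear predictor)``; shape 4 gives the steep age increase typical
    of late-life dementia incidence.  Follow-up ends at the administrative
    cut-off ``entry_age + (1 - admin_censor_fraction) * max_follow_up``
    (capped at ``censor_age_cap``), independent of onset, so
    ``admin_censor_fraction = 1`` shrinks the observation window to zero
    and yields no events.
    """

    baseline_hazard_scale: float = 140.0
    shape: float = 4.0
    log_hr: Mapping[int, float] = field(default_factory=dict)
    entry_age_range: tuple[float, float] = (40.0, 80.0)
    censor_age_cap: float = 100.0
    admin_censor_fraction: float = 0.0
    max_follow_up: float = 17.0
    frailty_variance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard_scale <= 0:
            raise ValueError("baseline_hazard_scale must be positive")
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        lo, hi = self.entry_age_range
        if not (0 < lo < hi):
            raise ValueError("entry_age_range must satisfy 0 < min < max")
        if not (0.0 <= self.admin_censor_fraction <= 1.0):
            raise ValueError("admin_censor_fraction must lie in [0, 1]")
        if self.max_follow_up <= 0:
            raise ValueError("max_follow_up must be positive")
        if self.frailty_variance < 0:
            raise ValueError("frailty_variance must be >= 0")


def _family_sizes(spec: PedigreeSpec, rng: np.random.Generator) -> np.ndarray:
    sizes = np.asarray(list(spec.family_size_weights.keys()), dtype=int)
    probs = np.asarray(list(spec.family_size_weights.values()), dtype=float)
    probs = probs / probs.sum()
    return rng.choice(sizes, size=spec.n_families, p=probs)


def simulate_kinship(spec: PedigreeSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw family sizes and build the block-diagonal relatedness matrix.

    Returns ``(K, family_index)`` where ``K`` is a square DataFrame indexed
    by individual id and ``family_index`` maps each individual to their
    family number.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _family_sizes(spec, rng)
    n = int(sizes.sum())
    K = np.zeros((n, n))
    family_index = np.zeros(n, dtype=int)
    pos = 0
    for fam, s in enumerate(sizes):
        block = np.full((s, s), spec.relatedness_within)
        np.fill_diagonal(block, 1.0)
        K[pos : pos + s, pos : pos + s] = block
        family_index[pos : pos + s] = fam
        pos += s
    ids = [f"ID{i:06d}" for i in range(1, n + 1)]
    return pd.DataFrame(K, index=ids, columns=ids), family_index


def _kinship_cholesky(K: np.ndarray) -> np.ndarray:
    # jittered Cholesky; kinship matrices are PSD but may be numerically singular
    jitter = 0.0
    for _ in range(6):
        try:
            return np.linalg.cholesky(K + jitter * np.eye(K.shape[0]))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10)
    raise np.linalg.LinAlgError("kinship matrix is not positive semi-definite")


def simulate_proteome(
    n: int, spec: ProteomeSpec, kinship: pd.DataFrame | np.ndarray
) -> pd.DataFrame:
    """Generate an n x n_signals protein-signal matrix.

    Columns are correlated through shared latent factors; rows of related
    individuals are correlated through the kinship-structured component
    (expected within-pair signal correlation = genetic_variance_fraction *
    relatedness).
    """
    ids = None
    if isinstance(kinship, pd.DataFrame):
        ids = list(kinship.index)
        K = kinship.to_numpy()
    else:
        K = np.asarray(kinship, dtype=float)
    if K.shape != (n, n):
        raise ValueError(f"kinship must be {n}x{n}, got {K.shape}")

    rng = np.random.default_rng(spec.seed)
    p = spec.n_signals
    X = np.zeros((n, p))

    h2 = spec.genetic_variance_fraction
    if h2 > 0:
        L = _kinship_cholesky(K)
        X += np.sqrt(h2) * (L @ rng.standard_normal((n, p)))
    vf = max(spec.factor_variance, 0.0)
    if spec.n_factors > 0 and vf > 0:
        F = rng.standard_normal((n, spec.n_factors))
        loadings = rng.standard_normal((spec.n_factors, p))
        # normalise each signal's loading vector so its factor variance is vf
        norms = np.linalg.norm(loadings, axis=0)
        norms[norms == 0] = 1.0
        loadings = loadings / norms * np.sqrt(vf)
        X += F @ loadings
    X += spec.noise_sd * rng.standard_normal((n, p))

    cols = [f"signal_{j + 1:03d}" for j in range(p)]
    if ids is None:
        ids = [f"ID{i:06d}" for i in range(1, n + 1)]
    return pd.DataFrame(X, index=ids, columns=cols)


def simulate_outcomes(
    proteins: pd.DataFrame, plan: EffectPlan, seed: int = 0
) -> pd.DataFrame:
    """Draw q continuous outcomes Y = X B + E with correlated residuals.

    Residual rows are multivariate normal with the plan's outcome
    correlation; each outcome column is standardized (mean 0, sample
    variance 1) after generation.
    """
    X = proteins.to_numpy()
    n = X.shape[0]
    B = plan.coefficient_matrix(X.shape[1])
    C = plan.correlation()
    rng = np.random.default_rng(seed)
    # PSD (possibly singular) correlation: factor via eigendecomposition
    vals, vecs = np.linalg.eigh(C)
    vals = np.clip(vals, 0.0, None)
    Lc = vecs * np.sqrt(vals)
    E = rng.standard_normal((n, plan.n_outcomes)) @ Lc.T
    Y = X @ B + E
    Y = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    cols = [f"outcome_{k + 1}" for k in range(plan.n_outcomes)]
    return pd.DataFrame(Y, index=proteins.index, columns=cols)


def simulate_covariates(
    n: int,
    missingness_rates: Mapping[str, float] | None = None,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate the mixed-type covariate table with MCAR missingness.

    Continuous: age, bmi, alcohol (units/week), smoking_score,
    simd (deprivation index); ordinal: education (11 categories, 0-10);
    binary: sex, depression, diabetes, high_blood_pressure.  Entries are
    masked missing completely at random at the configured per-column
    rates; age and sex are never masked.
    """
    rates = dict(DEFAULT_MISSINGNESS)
    if missingness_rates is not None:
        for key, rate in missingness_rates.items():
            if key not in COVARIATE_ROLES:
                raise ValueError(f"unknown covariate {key!r}")
            rates[key] = float(rate)
    for key, rate in rates.items():
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"missingness rate for {key!r} must lie in [0, 1)")
    if rates.get("age", 0.0) != 0.0 or rates.get("sex", 0.0) != 0.0:
        raise ValueError("age and sex are always fully observed")

    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {
            "age": np.clip(rng.normal(50, 12, n), 18, 95),
            "sex": rng.binomial(1, 0.55, n).astype(float),
            "bmi": np.clip(rng.normal(27, 4.5, n), 15, 55),
            "alcohol": rng.gamma(1.5, 6.0, n),
            "smoking_score": rng.normal(0, 1, n),
            "simd": rng.uniform(0, 10, n),
            "education": rng.integers(0, 11, n).astype(float),
            "depression": rng.binomial(1, 0.10, n).astype(float),
            "diabetes": rng.binomial(1, 0.05, n).astype(float),
            "high_blood_pressure": rng.binomial(1, 0.25, n).astype(float),
        }
    )
    for col, rate in rates.items():
        if rate > 0 and col not in ("age", "sex"):
            mask = rng.random(n) < rate
            table.loc[mask, col] = np.nan
    if ids is None:
        ids = [f"ID{i:06d}" for i in range(1, n + 1)]
    table.index = pd.Index(ids, name="id")
    return table


def simulate_apoe(
    n: int,
    e4_allele_frequency: float = 0.15,
    protein_shift_map: Mapping[str, float] | None = None,
    proteins: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Draw APOE e4 allele counts under Hardy-Weinberg and shift proteins.

    Each designated signal is shifted additively by ``shift * count``
    standard deviations.  Returns (counts, shifted protein matrix); the
    matrix is None when no proteins are supplied.
    """
    if not (0.0 < e4_allele_frequency < 1.0):
        raise ValueError("e4_allele_frequency must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    counts = rng.binomial(2, e4_allele_frequency, n)
    shifted = None
    if proteins is not None:
        if len(proteins) != n:
            raise ValueError("proteins row count must equal n")
        shifted = proteins.copy()
        if protein_shift_map:
            for col, shift in protein_shift_map.items():
                if col not in shifted.columns:
                    raise KeyError(f"protein_shift_map references unknown signal {col!r}")
                shifted[col] = shifted[col] + shift * counts
        index = proteins.index
    else:
        if protein_shift_map:
            raise ValueError("protein_shift_map given without a protein matrix")
        index = pd.Index([f"ID{i:06d}" for i in range(1, n + 1)], name="id")
    return pd.Series(counts, index=index, name="apoe_e4_count"), shifted


def simulate_survival(
    n: int,
    proteins: pd.DataFrame,
    spec: SurvivalSpec,
    kinship: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate ages at dementia onset / censoring.

    Event ages follow a Weibull proportional-hazards model on the age
    scale with linear predictor ``X . log_hr`` (signals standardized by
    column) plus an optional kinship-structured Gaussian log-frailty.
    Returns a DataFrame with entry_age, exit_age and event columns.
    """
    if len(proteins) != n:
        raise ValueError("proteins row count must equal n")
    rng = np.random.default_rng(spec.seed)

    X = proteins.to_numpy()
    lp = np.zeros(n)
    for j, loghr in spec.log_hr.items():
        if not (0 <= j < X.shape[1]):
            raise ValueError(f"log_hr signal index {j} out of bounds")
        col = X[:, j]
        lp += loghr * (col - col.mean()) / col.std(ddof=1)
    if spec.frailty_variance > 0:
        if kinship is None:
            raise ValueError("frailty_variance > 0 requires a kinship matrix")
        K = kinship.to_numpy() if isinstance(kinship, pd.DataFrame) else np.asarray(kinship)
        L = _kinship_cholesky(K)
        lp += np.sqrt(spec.frailty_variance) * (L @ rng.standard_normal(n))

    lo, hi = spec.entry_age_range
    entry = rng.uniform(lo, hi, n)
    # inverse-transform sample of the Weibull PH onset age, conditioned on
    # being event-free at entry (cohort participants are sampled alive)
    E = rng.standard_exponential(n)
    b, k = spec.baseline_hazard_scale, spec.shape
    onset = b * ((entry / b) ** k + E * np.exp(-lp)) ** (1.0 / k)

    # administrative censoring age: calendar cut-off independent of onset
    censor_age = np.minimum(
        entry + (1.0 - spec.admin_censor_fraction) * spec.max_follow_up,
        spec.censor_age_cap,
    )
    event = (onset <= censor_age).astype(int)
    exit_age = np.minimum(onset, censor_age)
    exit_age = np.maximum(exit_age, entry + 1e-9)
    return pd.DataFrame(
        {
            "entry_age": entry,
            "exit_age": exit_age,
            "event": event.astype(int),
        },
        index=proteins.index,
    )
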