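"""Run configuration: a single nested YAML file drives the pipeline.

``validate_config`` parses and range-checks the file, rejecting unknown
keys, and returns a typed :class:`RunConfig` with documented defaults
filled in (joint model: 5000 iterations, 1000 burn-in; PIP threshold
0.95; CI level 0.95; alpha 0.05; variance target 0.80; minimum exit age
65; minimum measured covariate fraction 0.40).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .simulate import (
    DEFAULT_MISSINGNESS,
    EffectPlan,
    PedigreeSpec,
    ProteomeSpec,
    SurvivalSpec,
)
from .spikeslab import SpikeSlabConfig

__all__ = ["RunConfig", "ConfigError", "validate_config"]


class ConfigError(ValueError):
    """Configuration problems, one message per violated key path."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass
class RunConfig:
    seed: int
    pedigree: PedigreeSpec
    proteome: ProteomeSpec
    effects: EffectPlan
    survival: SurvivalSpec
    joint: SpikeSlabConfig
    missingness: dict[str, float] = field(default_factory=dict)
    apoe_frequency: float = 0.15
    apoe_shifts: dict[str, float] = field(default_factory=dict)
    knn_k: int = 5
    min_measured_fraction: float = 0.40
    chains: int = 2
    pip_threshold: float = 0.95
    ci_level: float = 0.95
    alpha: float = 0.05
    variance_target: float = 0.80
    min_age: float = 65.0
    include_diabetes: bool = False
    use_entry: bool = False
    ties: str = "efron"

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        tag = zlib.crc32(stage.encode("utf-8"))
        ss = np.random.SeedSequence([self.seed, tag])
        return int(ss.generate_state(1)[0] % (2**31))


_KNOWN = {
    None: {
        "seed",
        "cohort",
        "proteome",
        "effects",
        "covariates",
        "apoe",
        "survival",
        "preprocess",
        "joint",
        "analysis",
    },
    "cohort": {"n_families", "family_size_weights", "relatedness_within"},
    "proteome": {"n_signals", "n_factors", "genetic_variance_fraction", "noise_sd"},
    "effects": {"n_outcomes", "true_effects", "residual_outcome_correlation"},
    "covariates": {"missingness"},
    "apoe": {"frequency", "shifts"},
    "survival": {
        "baseline_hazard_scale",
        "shape",
        "log_hr",
        "entry_age_range",
        "censor_age_cap",
        "admin_censor_fraction",
        "max_follow_up",
        "frailty_variance",
    },
    "preprocess": {"k", "min_measured_fraction"},
    "joint": {"n_iter", "burn_in", "thin", "chains", "pip_threshold", "ci_level",
              "a_tau", "b_tau", "a_pi", "b_pi"},
    "analysis": {"alpha", "variance_target", "min_age", "include_diabetes",
                 "use_entry", "ties"},
}


def _check_keys(section: str | None, d: dict, errors: list[str]) -> None:
    label = section or "<top level>"
    for k in d:
        if k not in _KNOWN[section]:
            errors.append(f"{label}: unknown key {k!r}")


def validate_config(path: str | Path | dict) -> RunConfig:
    """Parse, type and range-check a YAML pipeline configuration."""
    if isinstance(path, dict):
        raw = path
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigError([f"config file not found: {p}"])
        raw = yaml.safe_load(p.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    errors: list[str] = []
    _check_keys(None, raw, errors)
    for sec in ("cohort", "proteome", "effects", "covariates", "apoe", "survival",
                "preprocess", "joint", "analysis"):
        val = raw.get(sec, {})
        if not isinstance(val, dict):
            errors.append(f"{sec}: must be a mapping")
            raw[sec] = {}
        elif sec in _KNOWN:
            _check_keys(sec, val, errors)
    if errors:
        raise ConfigError(errors)

    seed = int(raw.get("seed", 0))

    def build(section: str, factory, **kwargs):
        try:
            return factory(**kwargs)
        except (ValueError, TypeError) as exc:
            errors.append(f"{section}: {exc}")
            return None

    coh = raw.get("cohort", {})
    weights = coh.get("family_size_weights", {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.07, 5: 0.03})
    pedigree = build(
        "cohort",
        PedigreeSpec,
        n_families=int(coh.get("n_families", 400)),
        family_size_weights={int(k): float(v) for k, v in weights.items()},
        relatedness_within=float(coh.get("relatedness_within", 0.5)),
        seed=seed,
    )

    pr = raw.get("proteome", {})
    proteome = build(
        "proteome",
        ProteomeSpec,
        n_signals=int(pr.get("n_signals", 439)),
        n_factors=int(pr.get("n_factors", 15)),
        genetic_variance_fraction=float(pr.get("genetic_variance_fraction", 0.3)),
        noise_sd=float(pr.get("noise_sd", 0.6)),
        seed=seed,
    )

    ef = raw.get("effects", {})
    q = int(ef.get("n_outcomes", 5))
    true_effects = {}
    for item in ef.get("true_effects", []):
        try:
            j, k, beta = item
            true_effects[(int(j), int(k))] = float(beta)
        except (ValueError, TypeError):
            errors.append(f"effects.true_effects: bad entry {item!r} (want [signal, outcome, beta])")
    rc = ef.get("residual_outcome_correlation", 0.0)
    if isinstance(rc, (int, float)):
        C = np.full((q, q), float(rc))
        np.fill_diagonal(C, 1.0)
    else:
        C = np.asarray(rc, dtype=float)
    effects = build(
        "effects",
        EffectPlan,
        n_outcomes=q,
        true_effects=true_effects,
        residual_outcome_correlation=C,
    )
    if effects is not None:
        try:
            effects.correlation()
        except ValueError as exc:
            errors.append(f"effects.residual_outcome_correlation: {exc}")

    cv = raw.get("covariates", {})
    missingness = dict(DEFAULT_MISSINGNESS)
    for k, v in cv.get("missingness", {}).items():
        if k not in DEFAULT_MISSINGNESS and k not in ("age", "sex"):
            errors.append(f"covariates.missingness: unknown covariate {k!r}")
        elif not (0.0 <= float(v) < 1.0):
            errors.append(f"covariates.missingness.{k}: rate must lie in [0, 1)")
        else:
            missingness[k] = float(v)

    ap = raw.get("apoe", {})
    apoe_frequency = float(ap.get("frequency", 0.15))
    if not (0.0 < apoe_frequency < 1.0):
        errors.append("apoe.frequency: must lie in (0, 1)")
    apoe_shifts = {str(k): float(v) for k, v in ap.get("shifts", {}).items()}

    sv = raw.get("survival", {})
    survival = build(
        "survival",
        SurvivalSpec,
        baseline_hazard_scale=float(sv.get("baseline_hazard_scale", 140.0)),
        shape=float(sv.get("shape", 4.0)),
        log_hr={int(k): float(v) for k, v in sv.get("log_hr", {}).items()},
        entry_age_range=tuple(sv.get("entry_age_range", (40.0, 80.0))),
        censor_age_cap=float(sv.get("censor_age_cap", 100.0)),
        admin_censor_fraction=float(sv.get("admin_censor_fraction", 0.0)),
        max_follow_up=float(sv.get("max_follow_up", 17.0)),
        frailty_variance=float(sv.get("frailty_variance", 0.0)),
        seed=seed,
    )

    jt = raw.get("joint", {})
    joint = SpikeSlabConfig(
        n_iter=int(jt.get("n_iter", 5000)),
        burn_in=int(jt.get("burn_in", 1000)),
        thin=int(jt.get("thin", 1)),
        a_tau=float(jt.get("a_tau", 0.01)),
        b_tau=float(jt.get("b_tau", 0.01)),
        a_pi=float(jt.get("a_pi", 1.0)),
        b_pi=jt.get("b_pi"),
        seed=seed,
    )
    if joint.burn_in >= joint.n_iter:
        errors.append("joint: burn_in must be < n_iter")
    chains = int(jt.get("chains", 2))
    if chains < 1:
        errors.append("joint.chains: must be >= 1")
    pip_threshold = float(jt.get("pip_threshold", 0.95))
    if not (0.0 < pip_threshold <= 1.0):
        errors.append("joint.pip_threshold: must lie in (0, 1]")
    ci_level = float(jt.get("ci_level", 0.95))
    if not (0.0 < ci_level < 1.0):
        errors.append("joint.ci_level: must lie in (0, 1)")

    pp = raw.get("preprocess", {})
    knn_k = int(pp.get("k", 5))
    if knn_k < 1:
        errors.append("preprocess.k: must be >= 1")
    mmf = float(pp.get("min_measured_fraction", 0.40))
    if not (0.0 < mmf <= 1.0):
        errors.append("preprocess.min_measured_fraction: must lie in (0, 1]")

    an = raw.get("analysis", {})
    alpha = float(an.get("alpha", 0.05))
    if not (0.0 < alpha < 1.0):
        errors.append("analysis.alpha: must lie in (0, 1)")
    variance_target = float(an.get("variance_target", 0.80))
    if not (0.0 < variance_target <= 1.0):
        errors.append("analysis.variance_target: must lie in (0, 1]")
    min_age = float(an.get("min_age", 65.0))
    ties = str(an.get("ties", "efron"))
    if ties not in ("efron", "breslow"):
        errors.append("analysis.ties: must be 'efron' or 'breslow'")

    if errors or pedigree is None or proteome is None or effects is None or survival is None:
        raise ConfigError(errors or ["invalid configuration"])

    # cross-section dependency checks
    for (j, _k) in effects.true_effects:
        if j >= proteome.n_signals:
            errors.append(f"effects.true_effects: signal index {j} >= n_signals")
    for j in survival.log_hr:
        if j >= proteome.n_signals:
            errors.append(f"survival.log_hr: signal index {j} >= n_signals")
    if errors:
        raise ConfigError(errors)

    return RunConfig(
        seed=seed,
        pedigree=pedigree,
        proteome=proteome,
        effects=effects,
        survival=survival,
        joint=joint,
        missingness=missingness,
        apoe_frequency=apoe_frequency,
        apoe_shifts=apoe_shifts,
        knn_k=knn_k,
        min_measured_fraction=mmf,
        chains=chains,
        pip_threshold=pip_threshold,
        ci_level=ci_level,
        alpha=alpha,
        variance_target=variance_target,
        min_age=min_age,
        include_diabetes=bool(an.get("include_diabetes", False)),
        use_entry=bool(an.get("use_entry", False)),
        ties=ties,
    )
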