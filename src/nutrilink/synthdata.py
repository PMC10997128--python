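"""Seeded synthetic DHS-like child records.

Real child-level survey microdata (the DHS Kid Record files) are
access-restricted, so every downstream stage of this package is exercised on
synthetic data that reproduces the statistical structure the analysis
assumes:

* trivariate anthropometric z-scores (HAZ, WAZ, WHZ) drawn multivariate
  normal with a target correlation matrix;
* DHS-like categorical covariates drawn from stated marginal frequencies;
* two binary outcomes (anemia, undernutrition) whose margins follow
  user-specified logistic models on those covariates and whose dependence is
  a user-specified global odds ratio psi, sampled from the Plackett joint
  cell probabilities.

Default parameter values are the published Rwanda 2019/20 summary statistics
in :mod:`nutrilink.reference`: n = 3206 children, z-score correlations
(0.42, 0.44, 0.62), psi = 1.729, covariate marginals from the frequency
table, and covariate effects equal to the published adjusted odds ratios.
Default intercepts are calibrated (by exact enumeration over covariate
patterns) so the population-average outcome prevalences equal the published
46.2% (anemia) and 20.5% (undernutrition).

A single master seed drives everything; per-stage sub-streams are derived
deterministically with ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from . import reference
from .bivlogit import DesignMatrix
from .plackett import joint_cell_probabilities

__all__ = [
    "SyntheticConfig",
    "default_config",
    "generate_covariates",
    "generate_zscores",
    "generate_outcomes",
    "generate_dataset",
    "calibrate_intercept",
]


def _default_covariate_spec():
    spec = []
    for name, counts in reference.COVARIATE_COUNTS.items():
        labels = list(counts)
        total = sum(counts.values())
        probs = [c / total for c in counts.values()]
        spec.append((name, labels, probs))
    return spec


def _default_betas():
    """Published adjusted odds ratios, on the log-odds scale, per margin."""
    aor_anemia = {
        "residence=urban": 0.751,
        "water_source=improved": 0.681,
        "mother_anemia=anemic": 1.160,
        "twin=multiple": 1.727,
        "child_age=12_59_months": 1.697,
        "birth_size=average": 0.567,
        "birth_size=large": 0.823,
    }
    aor_under = {
        "residence=urban": 0.663,
        "water_source=improved": 0.581,
        "mother_anemia=anemic": 1.663,
        "twin=multiple": 1.278,
        "child_age=12_59_months": 1.054,
        "birth_size=average": 0.856,
        "birth_size=large": 0.822,
    }
    b1 = {k: float(np.log(v)) for k, v in aor_anemia.items()}
    b2 = {k: float(np.log(v)) for k, v in aor_under.items()}
    return b1, b2


def _pattern_distribution(covariate_spec, terms):
    """Exact distribution of the design row over independent covariates.

    Returns (probabilities, eta_contributions) over the cartesian product of
    covariate levels, where each eta contribution sums the term coefficients
    active for that pattern.  Used for intercept calibration.
    """
    probs = np.array([1.0])
    eta = np.array([0.0])
    for name, labels, p in covariate_spec:
        p = np.asarray(p, dtype=float)
        contrib = np.array([terms.get(f"{name}={lab}", 0.0) for lab in labels])
        probs = np.outer(probs, p).ravel()
        eta = (eta[:, None] + contrib[None, :]).ravel()
    return probs, eta


def calibrate_intercept(covariate_spec, beta_terms: dict, target_prevalence: float) -> float:
    """Intercept making the population-average outcome prevalence exact.

    Solves E[expit(b0 + x.beta)] = target over the exact covariate-pattern
    distribution (covariates independent), by bracketing on b0.
    """
    if not 0 < target_prevalence < 1:
        raise ValueError("target prevalence must be in (0, 1)")
    probs, eta = _pattern_distribution(covariate_spec, beta_terms)

    def mean_prev(b0):
        return float(probs @ expit(b0 + eta)) - target_prevalence

    return brentq(mean_prev, -30.0, 30.0, xtol=1e-12)


@dataclass
class SyntheticConfig:
    """Conditions of a synthetic study; defaults emulate the published one."""

    n_children: int = reference.N_CHILDREN
    zscore_corr: np.ndarray = field(
        default_factory=lambda: reference.ZSCORE_CORR_MATRIX.copy()
    )
    zscore_means: np.ndarray = field(
        default_factory=lambda: np.array([-1.0, -0.5, 0.0])
    )
    beta_anemia: dict = field(default_factory=lambda: _default_betas()[0])
    beta_undernutrition: dict = field(default_factory=lambda: _default_betas()[1])
    psi: float = reference.ASSOCIATION_OR
    covariate_spec: list = field(default_factory=_default_covariate_spec)
    weight_model: str = "uniform"
    seed: int = 0
    anemia_mode: str = "binary"        # "binary" | "hemoglobin"
    hemoglobin_cutoff: float = 11.0    # g/dL

    def __post_init__(self):
        if self.n_children < 0:
            raise ValueError("n_children must be nonnegative")
        self.zscore_corr = np.asarray(self.zscore_corr, dtype=float)
        self.zscore_means = np.asarray(self.zscore_means, dtype=float)
        c = self.zscore_corr
        if c.shape != (3, 3) or not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("zscore_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ValueError("zscore_corr must have unit diagonal")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("zscore_corr must be positive definite")
        if self.zscore_means.shape != (3,):
            raise ValueError("zscore_means must have length 3")
        if self.psi <= 0:
            raise ValueError("psi must be > 0")
        for name, labels, probs in self.covariate_spec:
            probs = np.asarray(probs, dtype=float)
            if len(labels) != len(probs):
                raise ValueError(f"covariate {name!r}: labels/probabilities mismatch")
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
                raise ValueError(
                    f"covariate {name!r}: category probabilities must be "
                    "nonnegative and sum to 1"
                )
        if self.weight_model != "uniform" and not re.fullmatch(
            r"gamma\(\s*[\d.eE+-]+\s*,\s*[\d.eE+-]+\s*\)", self.weight_model
        ):
            raise ValueError("weight_model must be 'uniform' or 'gamma(shape,rate)'")
        if self.anemia_mode not in ("binary", "hemoglobin"):
            raise ValueError("anemia_mode must be 'binary' or 'hemoglobin'")
        # intercepts default to the calibrated values reproducing the
        # published prevalences in expectation
        for beta, target in (
            (self.beta_anemia, reference.ANEMIA_COUNTS["anemic"] / reference.N_CHILDREN),
            (
                self.beta_undernutrition,
                reference.UNDERNUTRITION_COUNTS["undernourished"] / reference.N_CHILDREN,
            ),
        ):
            if "intercept" not in beta:
                beta["intercept"] = calibrate_intercept(
                    self.covariate_spec, beta, target
                )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_children": int(self.n_children),
            "zscore_corr": self.zscore_corr.tolist(),
            "zscore_means": self.zscore_means.tolist(),
            "beta_anemia": dict(self.beta_anemia),
            "beta_undernutrition": dict(self.beta_undernutrition),
            "psi": float(self.psi),
            "covariate_spec": [
                [name, list(labels), list(map(float, probs))]
                for name, labels, probs in self.covariate_spec
            ],
            "weight_model": self.weight_model,
            "seed": int(self.seed),
            "anemia_mode": self.anemia_mode,
            "hemoglobin_cutoff": float(self.hemoglobin_cutoff),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "covariate_spec" in d:
            d["covariate_spec"] = [
                (name, list(labels), list(probs))
                for name, labels, probs in d["covariate_spec"]
            ]
        return cls(**d)


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The study-emulating default configuration with a chosen seed."""
    return SyntheticConfig(seed=seed, **overrides)


def _substreams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_covariates(config: SyntheticConfig) -> pd.DataFrame:
    """Draw the categorical covariates and sampling weights.

    Covariates are sampled independently of each other from their stated
    category distributions; deterministic given the config seed.
    """
    rng_cov, rng_w = _substreams(config.seed, 5)[:2]
    n = config.n_children
    data = {}
    for name, labels, probs in config.covariate_spec:
        idx = rng_cov.choice(len(labels), size=n, p=np.asarray(probs, dtype=float))
        data[name] = pd.Categorical.from_codes(idx, categories=list(labels))
    if config.weight_model == "uniform":
        weights = np.ones(n)
    else:
        shape, rate = map(
            float, re.findall(r"[\d.eE+-]+", config.weight_model.split("(")[1])[:2]
        )
        weights = rng_w.gamma(shape=shape, scale=1.0 / rate, size=n)
    out = pd.DataFrame(data)
    out["weight"] = weights
    return out


def generate_zscores(n: int, corr, means, seed: int) -> pd.DataFrame:
    """Multivariate-normal (haz, waz, whz) with unit variances.

    ``corr`` must be positive definite; the Cholesky factor is applied to
    i.i.d. standard normals, then the means are added.
    """
    corr = np.asarray(corr, dtype=float)
    means = np.asarray(means, dtype=float)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("z-score correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 3)) @ chol.T + means
    return pd.DataFrame(z, columns=["haz", "waz", "whz"])


def _beta_vector(beta, column_names) -> np.ndarray:
    if isinstance(beta, dict):
        missing = set(beta) - set(column_names)
        if missing:
            raise ValueError(f"coefficient names not in design: {sorted(missing)}")
        return np.array([float(beta.get(c, 0.0)) for c in column_names])
    vec = np.asarray(beta, dtype=float)
    if vec.shape[0] != len(column_names):
        raise ValueError("coefficient vector length does not match design")
    return vec


def generate_outcomes(
    design: DesignMatrix, beta1, beta2, psi: float, seed: int
) -> pd.DataFrame:
    """Draw the (anemia, undernutrition) pair per row of a design matrix.

    For each row the marginal probabilities come from the two logistic
    models; the four Plackett joint cell probabilities at odds ratio ``psi``
    define a categorical draw.  Deterministic given seed.
    """
    if psi <= 0:
        raise ValueError("psi must be > 0")
    b1 = _beta_vector(beta1, design.column_names)
    b2 = _beta_vector(beta2, design.column_names)
    pi1 = expit(design.matrix @ b1)
    pi2 = expit(design.matrix @ b2)
    p11, p10, p01, p00 = joint_cell_probabilities(pi1, pi2, psi)
    cum = np.cumsum(np.column_stack([p11, p10, p01, p00]), axis=1)
    rng = np.random.default_rng(seed)
    u = rng.random(design.n)
    cell = (u[:, None] > cum).sum(axis=1)  # 0:11, 1:10, 2:01, 3:00
    anemia = (cell <= 1).astype(int)
    undernutrition = ((cell == 0) | (cell == 2)).astype(int)
    return pd.DataFrame({"anemia": anemia, "undernutrition": undernutrition})


def generate_dataset(
    config: SyntheticConfig,
    csv_path: str | Path | None = None,
) -> pd.DataFrame:
    """Compose covariates, z-scores and outcomes into one child-record table.

    Column order: haz, waz, whz, [hemoglobin,] anemia, undernutrition,
    covariates..., weight.  When ``csv_path`` is given the table is written
    as CSV and a JSON sidecar ``<csv_path>.meta.json`` records the full
    config (including the seed).
    """
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    covariates = generate_covariates(config)
    zscores = generate_zscores(
        config.n_children,
        config.zscore_corr,
        config.zscore_means,
        seed=seeds[2],
    )
    design = DesignMatrix.from_dataframe(
        covariates,
        covariates=[name for name, _, _ in config.covariate_spec],
        reference_levels={
            name: str(labels[0]) for name, labels, _ in config.covariate_spec
        },
        weight_column="weight",
    )
    outcomes = generate_outcomes(
        design,
        config.beta_anemia,
        config.beta_undernutrition,
        config.psi,
        seed=seeds[3],
    )
    table = pd.concat([zscores, outcomes, covariates], axis=1)
    if config.anemia_mode == "hemoglobin":
        rng = np.random.default_rng(seeds[4])
        cut = config.hemoglobin_cutoff
        hb = np.empty(config.n_children)
        anemic = outcomes["anemia"].to_numpy() == 1
        # truncated normals on either side of the cutoff, consistent with
        # the drawn anemia indicator
        hb[anemic] = truncnorm.rvs(
            -np.inf, (cut - 9.9) / 1.2, loc=9.9, scale=1.2,
            size=int(anemic.sum()), random_state=rng,
        )
        hb[~anemic] = truncnorm.rvs(
            (cut - 12.6) / 1.2, np.inf, loc=12.6, scale=1.2,
            size=int((~anemic).sum()), random_state=rng,
        )
        table.insert(3, "hemoglobin", hb)
    if csv_path is not None:
        csv_path = Path(csv_path)
        try:
            table.to_csv(csv_path, index=False, float_format="%.10g")
            meta = {"config": config.to_dict(), "generator": "nutrilink.synthdata"}
            csv_path.with_suffix(csv_path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=2, sort_keys=True) + "\n"
            )
        except OSError as exc:
            raise OSError(f"failed to write synthetic dataset: {exc}") from exc
    return table
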