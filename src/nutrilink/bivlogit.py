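"""Bivariate binary logistic regression linked by a global odds ratio.

Two binary outcomes per child — anemia (Y1) and undernutrition (Y2) — are
modelled jointly.  Each margin follows an ordinary logistic regression,

    logit P(Yj = 1 | x) = x . beta_j,   j = 1, 2,

and the dependence between the two outcomes is a single cross-product
(global odds) ratio psi, constant across covariate patterns, so that each
observation contributes a multinomial likelihood over the four joint cells

    p11(x), p10(x), p01(x), p00(x)

given by the Plackett construction (see :mod:`nutrilink.plackett`).  The full
parameter vector (beta1, beta2, log psi) is estimated by maximising the joint
(pseudo-)log-likelihood with a Newton-type ascent; sampling weights, when
supplied, are normalised to mean one and enter as frequency weights.  Reported
variances are inverse-information (model-based); design-based variance
estimation for complex surveys is out of scope and flagged in the output.

A hook allows covariates on log psi via ``psi_design``; by default the
association is intercept-only, matching the single dependence odds ratio the
model is built around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .plackett import joint_cell_derivatives, joint_cell_probabilities

__all__ = [
    "DesignMatrix",
    "BivariateFit",
    "marginal_probability",
    "log_likelihood",
    "fit",
    "adjusted_odds_ratios",
    "predict_joint",
]

_PROB_FLOOR = 1e-12
_LIK_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    """Dummy-coded design with named columns and declared reference levels.

    The first column is always an all-ones intercept.  Each categorical
    covariate contributes one indicator column per non-reference level, named
    ``"<covariate>=<level>"``; the reference level is recorded but gets no
    column.  Weights are stored normalised to mean one (pseudo-likelihood
    convention).
    """

    matrix: np.ndarray
    column_names: list[str]
    reference_levels: dict[str, str] = field(default_factory=dict)
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-dimensional")
        if len(self.column_names) != self.matrix.shape[1]:
            raise ValueError("column_names length does not match matrix width")
        if not np.allclose(self.matrix[:, 0], 1.0):
            raise ValueError("first design column must be an all-ones intercept")
        if self.weights is None:
            self.weights = np.ones(self.matrix.shape[0])
        else:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            if len(w) != self.matrix.shape[0]:
                raise ValueError("weights length does not match number of rows")
            if len(w) > 0:
                if w.sum() <= 0:
                    raise ValueError("weights must not all be zero")
                w = w * (len(w) / w.sum())
            self.weights = w

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        covariates: list[str],
        reference_levels: dict[str, str] | None = None,
        weight_column: str | None = None,
    ) -> "DesignMatrix":
        """Build an intercept + dummy-coded design from categorical columns.

        The reference level of each covariate defaults to its first level in
        order of appearance; ``reference_levels`` overrides per covariate.
        """
        reference_levels = dict(reference_levels or {})
        n = len(data)
        cols = [np.ones(n)]
        names = ["intercept"]
        refs: dict[str, str] = {}
        for cov in covariates:
            if cov not in data.columns:
                raise KeyError(f"covariate column not found: {cov!r}")
            if isinstance(data[cov].dtype, pd.CategoricalDtype):
                levels = [str(c) for c in data[cov].cat.categories]
            else:
                levels = list(dict.fromkeys(data[cov].astype(str)))  # appearance order
            values = data[cov].astype(str)
            ref = str(reference_levels.get(cov, levels[0]))
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} not observed for covariate {cov!r}"
                )
            refs[cov] = ref
            for level in levels:
                if level == ref:
                    continue
                cols.append((values == level).to_numpy(dtype=float))
                names.append(f"{cov}={level}")
        weights = data[weight_column].to_numpy(dtype=float) if weight_column else None
        return cls(
            matrix=np.column_stack(cols),
            column_names=names,
            reference_levels=refs,
            weights=weights,
        )


# ---------------------------------------------------------------------------
# probabilities and likelihood


def marginal_probability(x_row, beta):
    """Logistic marginal probability ``expit(x . beta)``.

    Numerically stable over the full double range of the linear predictor:
    large negative predictors give tiny positive probabilities rather than
    underflowing to exactly zero (until ~ -745, far beyond the |eta| <= 700
    contract).
    """
    eta = np.dot(np.asarray(x_row, dtype=float), np.asarray(beta, dtype=float))
    return expit(eta)


def _unpack(params, p, q):
    params = np.asarray(params, dtype=float)
    if params.shape[0] != 2 * p + q:
        raise ValueError(f"expected {2 * p + q} parameters, got {params.shape[0]}")
    return params[:p], params[p : 2 * p], params[2 * p :]


def _as_outcomes(y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(y, pd.DataFrame):
        arr = y.to_numpy()
    else:
        arr = np.asarray(y)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("outcomes must be an (n, 2) table of binary values")
    arr = arr.astype(float)
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("outcomes must be coded 0/1")
    return arr[:, 0].astype(int), arr[:, 1].astype(int)


def _cell_probs(params, design: DesignMatrix, psi_design: np.ndarray):
    p = design.p
    q = psi_design.shape[1]
    b1, b2, gamma = _unpack(params, p, q)
    pi1 = expit(design.matrix @ b1)
    pi2 = expit(design.matrix @ b2)
    pi1 = np.clip(pi1, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    pi2 = np.clip(pi2, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    psi = np.exp(psi_design @ gamma)
    return pi1, pi2, psi


def _psi_design_for(design: DesignMatrix, psi_design) -> np.ndarray:
    if psi_design is None:
        return np.ones((design.n, 1))
    z = np.asarray(psi_design, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[0] != design.n:
        raise ValueError("psi_design row count does not match design")
    return z


def log_likelihood(params, design: DesignMatrix, y, psi_design=None) -> float:
    """Joint weighted log-likelihood of the bivariate model.

    ``params`` is the concatenation (beta1, beta2, log psi coefficients).
    Each row contributes ``w_i * log p_cell(x_i)`` for its observed joint
    cell; fitted cell probabilities are floored at 1e-300 (with a warning)
    so the value stays finite under degenerate parameters.
    """
    z = _psi_design_for(design, psi_design)
    y1, y2 = _as_outcomes(y)
    pi1, pi2, psi = _cell_probs(params, design, z)
    p11, p10, p01, p00 = joint_cell_probabilities(pi1, pi2, psi)
    pcell = np.choose(y1 * 2 + y2, [p00, p01, p10, p11])
    if np.any(pcell < _LIK_FLOOR):
        warnings.warn(
            "fitted cell probability underflow; likelihood floored", RuntimeWarning
        )
        pcell = np.maximum(pcell, _LIK_FLOOR)
    return float(np.sum(design.weights * np.log(pcell)))


def _score(params, design: DesignMatrix, y1, y2, z) -> np.ndarray:
    """Analytic gradient of :func:`log_likelihood` in (beta1, beta2, gamma)."""
    pi1, pi2, psi = _cell_probs(params, design, z)
    (p11, p10, p01, p00), d1, d2, dpsi = joint_cell_derivatives(pi1, pi2, psi)
    cells = np.stack([p00, p01, p10, p11])
    idx = y1 * 2 + y2
    pcell = np.maximum(np.choose(idx, cells), _LIK_FLOOR)

    # d p_cell / d pi1, pi2, psi by cell identity (p10 = pi1 - p11, ...)
    dcell_dpi1 = np.choose(idx, [d1 - 1.0, -d1, 1.0 - d1, d1])
    dcell_dpi2 = np.choose(idx, [d2 - 1.0, 1.0 - d2, -d2, d2])
    dcell_dpsi = np.choose(idx, [dpsi, -dpsi, -dpsi, dpsi])

    w = design.weights
    u1 = w * dcell_dpi1 / pcell * pi1 * (1.0 - pi1)
    u2 = w * dcell_dpi2 / pcell * pi2 * (1.0 - pi2)
    ug = w * dcell_dpsi / pcell * psi  # chain through psi = exp(z . gamma)
    return np.concatenate(
        [design.matrix.T @ u1, design.matrix.T @ u2, z.T @ ug]
    )


def _numeric_hessian(params, design, y1, y2, z, h=1e-5) -> np.ndarray:
    """Central-difference Jacobian of the analytic score."""
    k = len(params)
    hess = np.empty((k, k))
    for j in range(k):
        step = h * max(1.0, abs(params[j]))
        up = params.copy()
        dn = params.copy()
        up[j] += step
        dn[j] -= step
        hess[:, j] = (_score(up, design, y1, y2, z) - _score(dn, design, y1, y2, z)) / (
            2.0 * step
        )
    return 0.5 * (hess + hess.T)


def _irls_logistic(x, yvec, w, max_iter=50, tol=1e-10) -> np.ndarray:
    """Weighted univariate logistic MLE by iteratively reweighted least squares."""
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        mu = np.clip(expit(x @ beta), 1e-10, 1 - 1e-10)
        wls = w * mu * (1.0 - mu)
        grad = x.T @ (w * (yvec - mu))
        hess = x.T @ (x * wls[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


# ---------------------------------------------------------------------------
# fit result


@dataclass
class BivariateFit:
    """Maximum-likelihood fit of the bivariate logistic / global-OR model."""

    beta1: np.ndarray
    beta2: np.ndarray
    log_psi: float
    gamma: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    column_names: list[str]
    psi_column_names: list[str]
    reference_levels: dict[str, str]
    n_obs: int
    aor_table: pd.DataFrame | None = None
    variance_note: str = (
        "model-based (inverse information) variances; "
        "no design-based survey adjustment"
    )

    @property
    def psi(self) -> float:
        return float(np.exp(self.log_psi))

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta1, self.beta2, self.gamma])

    def se(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.vcov), 0.0))


def fit(
    design: DesignMatrix,
    y,
    psi_design=None,
    max_iter: int = 100,
    tol_loglik: float = 1e-10,
    tol_score: float = 1e-6,
    fix_log_psi: float | None = None,
    compute_aor: bool = True,
) -> BivariateFit:
    """Fit the bivariate model by Newton ascent with step-halving.

    Initialisation: two separate univariate logistic IRLS fits for the
    margins, and log psi set to the log of the (continuity-corrected, if any
    cell is empty) sample 2x2 odds ratio.  Iterations use the analytic score
    and a finite-differenced Hessian; step-halving enforces likelihood
    ascent.  Convergence requires both a relative log-likelihood change
    below ``tol_loglik`` and a maximum absolute score below ``tol_score``.

    ``fix_log_psi`` freezes the association at a given value (e.g. 0 for
    independence), in which case only the betas are estimated.
    """
    z = _psi_design_for(design, psi_design)
    q = z.shape[1]
    y1, y2 = _as_outcomes(y)
    if not (0 < y1.mean() < 1) or not (0 < y2.mean() < 1):
        raise ValueError("both outcomes must have both levels present")
    p = design.p
    if design.n <= 2 * p + q:
        raise ValueError("need more observations than parameters")
    w = design.weights

    b1 = _irls_logistic(design.matrix, y1, w)
    b2 = _irls_logistic(design.matrix, y2, w)
    counts = np.array(
        [
            np.sum(w[(y1 == 1) & (y2 == 1)]),
            np.sum(w[(y1 == 1) & (y2 == 0)]),
            np.sum(w[(y1 == 0) & (y2 == 1)]),
            np.sum(w[(y1 == 0) & (y2 == 0)]),
        ]
    )
    if np.any(counts == 0):
        counts = counts + 0.5
    gamma0 = np.zeros(q)
    gamma0[0] = np.log(counts[0] * counts[3] / (counts[1] * counts[2]))
    if fix_log_psi is not None:
        gamma0 = np.zeros(q)
        gamma0[0] = fix_log_psi
    params = np.concatenate([b1, b2, gamma0])

    free = np.ones(len(params), dtype=bool)
    if fix_log_psi is not None:
        free[2 * p :] = False

    ll = log_likelihood(params, design, np.column_stack([y1, y2]), psi_design=z)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        g = _score(params, design, y1, y2, z)
        if np.max(np.abs(g[free])) < tol_score:
            converged = True  # already at a stationary point (e.g. exact init)
            break
        hess = _numeric_hessian(params, design, y1, y2, z)
        gf = g[free]
        hf = hess[np.ix_(free, free)]
        try:
            direction = np.linalg.solve(hf, -gf)
        except np.linalg.LinAlgError:
            direction = gf  # fall back to steepest ascent
        if direction @ gf < 0:
            direction = gf
        # step-halving line search enforcing ascent
        step = 1.0
        new_ll = -np.inf
        for _ in range(40):
            trial = params.copy()
            trial[free] = params[free] + step * direction
            new_ll = log_likelihood(
                trial, design, np.column_stack([y1, y2]), psi_design=z
            )
            if new_ll >= ll - 1e-13 * max(1.0, abs(ll)):
                break
            step *= 0.5
        if new_ll < ll:
            break  # no ascent direction left
        rel_change = abs(new_ll - ll) / max(1.0, abs(new_ll))
        params[free] = params[free] + step * direction
        ll = new_ll
        g = _score(params, design, y1, y2, z)
        if rel_change < tol_loglik and np.max(np.abs(g[free])) < tol_score:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"bivariate fit did not converge in {n_iter} iterations", RuntimeWarning
        )
    if np.max(np.abs(params[: 2 * p])) > 15:
        warnings.warn(
            "large coefficient magnitude: possible quasi-complete separation",
            RuntimeWarning,
        )

    hess = _numeric_hessian(params, design, y1, y2, z)
    vcov = np.full((len(params), len(params)), np.nan)
    try:
        vcov_free = np.linalg.inv(-hess[np.ix_(free, free)])
        vcov_free = 0.5 * (vcov_free + vcov_free.T)
        vcov[np.ix_(free, free)] = vcov_free
    except np.linalg.LinAlgError:
        warnings.warn("Hessian not invertible; vcov unavailable", RuntimeWarning)
    if fix_log_psi is not None:
        vcov[2 * p :, :] = 0.0
        vcov[:, 2 * p :] = 0.0

    result = BivariateFit(
        beta1=params[:p].copy(),
        beta2=params[p : 2 * p].copy(),
        log_psi=float(params[2 * p]),
        gamma=params[2 * p :].copy(),
        vcov=vcov,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        column_names=list(design.column_names),
        psi_column_names=[f"log_psi:{j}" for j in range(q)],
        reference_levels=dict(design.reference_levels),
        n_obs=design.n,
    )
    if compute_aor and converged and np.isfinite(vcov).all():
        result.aor_table = adjusted_odds_ratios(result)
    return result


def adjusted_odds_ratios(fit_result: BivariateFit, level: float = 0.95) -> pd.DataFrame:
    """Per-coefficient adjusted odds ratios with Wald confidence intervals.

    AOR = exp(beta); CI = exp(beta +/- z * SE); two-sided Wald p-values, no
    multiplicity adjustment.  The association rows report psi = exp(gamma).
    """
    if fit_result.vcov is None or not np.isfinite(fit_result.vcov).all():
        raise ValueError("fit has no valid covariance matrix")
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    se = fit_result.se()
    p = len(fit_result.beta1)
    rows = []
    labels = (
        [("anemia", name) for name in fit_result.column_names]
        + [("undernutrition", name) for name in fit_result.column_names]
        + [("association", name) for name in fit_result.psi_column_names]
    )
    for k, (outcome, term) in enumerate(labels):
        est = fit_result.params[k]
        s = se[k]
        zstat = est / s if s > 0 else np.inf * np.sign(est) if est else 0.0
        rows.append(
            {
                "outcome": outcome,
                "term": term,
                "estimate": est,
                "se": s,
                "aor": np.exp(est),
                "ci_low": np.exp(est - zcrit * s),
                "ci_high": np.exp(est + zcrit * s),
                "p_value": 2.0 * stats.norm.sf(abs(zstat)) if np.isfinite(zstat) else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    _ = p  # kept for clarity of the layout above
    return table


def predict_joint(fit_result: BivariateFit, design: DesignMatrix, psi_design=None):
    """Per-row fitted joint cell probabilities (p11, p10, p01, p00)."""
    if list(design.column_names) != list(fit_result.column_names):
        raise ValueError("design columns do not match the fitted model")
    z = _psi_design_for(design, psi_design)
    if z.shape[1] != len(fit_result.gamma):
        raise ValueError("psi_design columns do not match the fitted model")
    pi1 = expit(design.matrix @ fit_result.beta1)
    pi2 = expit(design.matrix @ fit_result.beta2)
    psi = np.exp(z @ fit_result.gamma)
    p11, p10, p01, p00 = joint_cell_probabilities(pi1, pi2, psi)
    return np.column_stack([p11, p10, p01, p00])
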