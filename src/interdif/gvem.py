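"""Regularized Gaussian variational EM for random-item-effect 2PL models.

The marginal likelihood of a random-item 2PL model involves an integral
over one ability per person plus one random intercept (and optionally
slope) per item × group, which is intractable.  The algorithm bounds
each Bernoulli log-likelihood term with the local quadratic (Jaakkola–
Jordan) lower bound on the log-sigmoid, governed by a per-response
variational parameter ξ, and approximates the latent posterior by a
mean-field product of per-latent factors.  Every E-step factor is then
conjugate: normals for abilities, random intercepts and impact
deviations, and a left-truncated normal for random slopes.  The M-step
has closed forms for everything except the slope fixed effects and
slope variances of the ``Ris``/``RisM`` variants, which are updated by
bounded one-dimensional maximization.

A log penalty η·log σ² on each DIF variance shrinks the variances of
items free of intersectional DIF toward zero; the penalized objective
(ELBO − η·Σ log σ², with near-zero variances floored at δ inside the
objective only) increases monotonically under the coordinate updates.

E-step sweep order is θ → u → b → a → ξ, one sweep per EM iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, log_expit, log_ndtr

from .model_core import (
    ModelSpec,
    Parameters,
    ResponseData,
    truncnorm_moments,
)

__all__ = [
    "VariationalState",
    "FitConfig",
    "FitResult",
    "IterationError",
    "bound_lambda",
    "log_sigmoid_lower_bound",
    "e_step",
    "m_step",
    "elbo",
    "penalized_objective",
    "fit",
]

logger = logging.getLogger("interdif.gvem")

_LOG_2PI = np.log(2.0 * np.pi)
_VAR_TINY = 1e-12  # guard divisor for structurally/numerically zero variances


class IterationError(RuntimeError):
    """A variational update produced a nonfinite moment."""


def bound_lambda(xi):
    """Jaakkola–Jordan coefficient λ(ξ) = (sigmoid(ξ) − 1/2) / (2ξ).

    Even in ξ with removable singularity λ(0) = 1/8; evaluated by a
    series for |ξ| below 1e-4.
    """
    xi = np.asarray(xi, dtype=float)
    if (xi < 0).any():
        raise ValueError("xi must be nonnegative")
    small = xi < 1e-4
    safe = np.where(small, 1.0, xi)
    lam = (expit(safe) - 0.5) / (2.0 * safe)
    out = np.where(small, 0.125 - xi**2 / 192.0, lam)
    return out[()] if out.ndim == 0 else out


def log_sigmoid_lower_bound(x, xi):
    """Local quadratic lower bound on log sigmoid(x), tight at |x| = ξ.

    log σ(x) ≥ log σ(ξ) + (x − ξ)/2 − λ(ξ)(x² − ξ²) for every ξ ≥ 0.
    """
    x = np.asarray(x, dtype=float)
    xi = np.asarray(xi, dtype=float)
    out = log_expit(xi) + 0.5 * (x - xi) - bound_lambda(xi) * (x * x - xi * xi)
    return out[()] if out.ndim == 0 else out


@dataclass
class VariationalState:
    """Mean-field variational moments for one model fit.

    ``b_mean``/``b_var`` are J×S normal moments of the group-specific
    intercepts.  ``a_mean``/``a_second`` are first and second moments of
    the group-specific slopes; for ``Ri``/``RiM`` they simply replicate
    the fixed slope across groups.  ``a_under_*`` hold the underlying
    (pre-truncation) normal parameters of the truncated-normal slope
    factors and ``a_log_z`` their log normalizers (Ris/RisM only).
    ``xi`` is the N×J matrix of local-bound parameters.
    """

    theta_mean: np.ndarray
    theta_var: np.ndarray
    b_mean: np.ndarray
    b_var: np.ndarray
    a_mean: np.ndarray
    a_second: np.ndarray
    a_under_mean: np.ndarray
    a_under_var: np.ndarray
    a_log_z: np.ndarray
    u_mean: np.ndarray
    u_var: np.ndarray
    xi: np.ndarray

    def copy(self) -> "VariationalState":
        return VariationalState(
            *(getattr(self, f).copy() for f in self.__dataclass_fields__)
        )


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs of the regularized GVEM fit.

    ``penalty_eta`` is the log-penalty weight (0 = unpenalized);
    ``variance_floor`` is the δ replacing near-zero variances inside
    objective/GIC evaluation only, never inside updates.  With
    ``init_strategy="unpenalized_warm_start"`` a penalized fit first
    converges at η = 0 and continues from there.
    """

    penalty_eta: float = 0.0
    max_iters: int = 500
    elbo_rel_tol: float = 1e-5
    seed: int = 0
    variance_floor: float = 1e-6
    init_strategy: str = "unpenalized_warm_start"

    def __post_init__(self) -> None:
        if self.penalty_eta < 0:
            raise ValueError("penalty_eta must be nonnegative")
        if self.elbo_rel_tol <= 0 or self.variance_floor <= 0:
            raise ValueError("elbo_rel_tol and variance_floor must be positive")
        if self.init_strategy not in ("random", "unpenalized_warm_start"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")


@dataclass
class FitResult:
    """Converged (or truncated) state of one regularized GVEM run.

    ``elbo_trace`` records the penalized objective per EM iteration —
    the quantity the coordinate updates ascend; it equals the ELBO when
    η = 0.  ``elbo_final`` is the unpenalized ELBO surrogate (with the
    δ floor on variance logs) used by model-selection criteria.
    """

    params: Parameters
    vstate: VariationalState
    elbo_trace: np.ndarray
    penalized_objective: float
    elbo_final: float
    n_iters: int
    converged: bool
    penalty_eta: float

    def dif_flags(self, spec: ModelSpec) -> tuple[set[int], set[int]]:
        """(UDIF items, NUDIF items) by the ε-threshold on DIF variances."""
        eps = spec.dif_flag_threshold
        udif = set(np.flatnonzero(self.params.var_intercept > eps).tolist())
        nudif = set()
        if spec.has_random_slopes:
            nudif = set(np.flatnonzero(self.params.var_slope > eps).tolist())
        return udif, nudif

    def n_dif_parameters(self, spec: ModelSpec) -> int:
        """k of the information criterion: nonzero DIF variance count."""
        udif, nudif = self.dif_flags(spec)
        return len(udif) + len(nudif)


class _Workspace:
    """Data-derived constants shared by E-step, M-step and ELBO."""

    def __init__(self, data: ResponseData, spec: ModelSpec):
        self.g = data.group_of
        self.S = data.design.S
        self.W = data.observed.astype(float)  # N×J observation mask
        self.Yhalf = np.nan_to_num(data.Y - 0.5) * self.W  # (y − 1/2), 0 if missing
        self.n_s = data.n_s.astype(float)
        # dense group indicator: group sums become one matmul
        self.G = np.zeros((self.S, data.N))
        self.G[self.g, np.arange(data.N)] = 1.0
        self.Xt = data.design.X_tilde
        self.X = data.design.X
        if np.linalg.matrix_rank(self.Xt) < self.Xt.shape[1]:
            raise np.linalg.LinAlgError(
                "group design matrix is rank deficient; item fixed effects "
                "are not identified"
            )
        self.pinv_Xt = np.linalg.pinv(self.Xt)

    def group_sum(self, M: np.ndarray) -> np.ndarray:
        """Sum an N×J array within groups → S×J."""
        return self.G @ M


def _slope_moment_matrices(spec: ModelSpec, params: Parameters, vstate, S: int):
    """E[a_js] and E[a_js²] as J×S matrices for any variant."""
    if spec.has_random_slopes:
        return vstate.a_mean, vstate.a_second
    a = np.repeat(params.slope_base[:, None], S, axis=1)
    return a, a * a


def e_step(
    data: ResponseData,
    spec: ModelSpec,
    params: Parameters,
    vstate: VariationalState,
    _ws: _Workspace | None = None,
) -> VariationalState:
    """One mean-field sweep over all variational factors (θ → u → b → a → ξ).

    Each block update is the exact maximizer of the ELBO over that
    factor holding the others fixed; items whose DIF variance has
    collapsed are handled continuously (their factors concentrate on
    the fixed-effect prior mean).
    """
    ws = _ws or _Workspace(data, spec)
    g, S = ws.g, ws.S
    v0 = spec.fixed_theta_variance
    new = vstate.copy()

    lam = bound_lambda(vstate.xi) * ws.W
    a_mean, a_second = _slope_moment_matrices(spec, params, vstate, S)
    new.a_mean, new.a_second = a_mean, a_second
    Ea_p = a_mean[:, g].T  # N×J person-expanded slope moments
    Ea2_p = a_second[:, g].T
    Eb_p = vstate.b_mean[:, g].T

    mu_grp = params.group_ability_mean(data.design)

    # --- q(theta_i): normal ---
    prior_mean = mu_grp[g] + new.u_mean[g]
    prec = 1.0 / v0 + 2.0 * (lam * Ea2_p).sum(axis=1)
    num = prior_mean / v0 + (ws.Yhalf * Ea_p - 2.0 * lam * Ea_p * Eb_p).sum(axis=1)
    new.theta_var = 1.0 / prec
    new.theta_mean = num * new.theta_var

    # --- q(u_s): normal (multilevel variants) ---
    if spec.has_multilevel_ability:
        tau2 = max(params.impact_var, _VAR_TINY)
        prec_u = 1.0 / tau2 + ws.n_s / v0
        num_u = (ws.G @ new.theta_mean - ws.n_s * mu_grp) / v0
        new.u_var = 1.0 / prec_u
        new.u_mean = num_u * new.u_var

    theta2 = new.theta_mean**2 + new.theta_var

    # --- q(b_js): normal; zero-variance items are fixed effects (point mass) ---
    Bprior = params.intercept_prior_mean(data.design)
    fixed_b = params.var_intercept == 0.0
    vb = np.maximum(params.var_intercept, _VAR_TINY)[:, None]
    S_lam = ws.group_sum(lam).T  # J×S
    S_lam_th = ws.group_sum(lam * new.theta_mean[:, None]).T
    S_y = ws.group_sum(ws.Yhalf).T
    prec_b = 1.0 / vb + 2.0 * S_lam
    num_b = Bprior / vb + S_y - 2.0 * a_mean * S_lam_th
    new.b_var = 1.0 / prec_b
    new.b_mean = num_b * new.b_var
    if fixed_b.any():
        new.b_mean[fixed_b] = Bprior[fixed_b]
        new.b_var[fixed_b] = 0.0

    # --- q(a_js): left-truncated normal (Ris/RisM) ---
    if spec.has_random_slopes:
        Aprior = params.slope_prior_mean(data.design)
        va = np.maximum(params.var_slope, _VAR_TINY)[:, None]
        S_lam_th2 = ws.group_sum(lam * theta2[:, None]).T
        S_y_th = ws.group_sum(ws.Yhalf * new.theta_mean[:, None]).T
        prec_a = 1.0 / va + 2.0 * S_lam_th2
        num_a = Aprior / va + S_y_th - 2.0 * new.b_mean * S_lam_th
        new.a_under_var = 1.0 / prec_a
        new.a_under_mean = num_a * new.a_under_var
        mom = truncnorm_moments(new.a_under_mean, new.a_under_var)
        new.a_mean = mom.mean
        new.a_second = mom.variance + mom.mean**2
        new.a_log_z = mom.log_normalizer

    # --- xi_ij = sqrt(E[(a θ + b)²]) under mean-field independence ---
    Ea_p = new.a_mean[:, g].T
    Ea2_p = new.a_second[:, g].T
    Eb_p = new.b_mean[:, g].T
    Eb2_p = (new.b_mean**2 + new.b_var)[:, g].T
    ex2 = Ea2_p * theta2[:, None] + 2.0 * Ea_p * new.theta_mean[:, None] * Eb_p + Eb2_p
    new.xi = np.sqrt(np.clip(ex2, 0.0, None))

    for name in ("theta_mean", "b_mean", "a_mean", "u_mean", "xi"):
        arr = getattr(new, name)
        if not np.isfinite(arr).all():
            idx = np.unravel_index(int(np.argmin(np.isfinite(arr))), arr.shape)
            raise IterationError(f"nonfinite {name} at index {idx}")
    return new


def _slope_term_value(Ea2, Ea, mu, s2):
    """Expected log truncated-normal prior for one item's slopes, up to const."""
    sd = np.sqrt(s2)
    quad = (Ea2 - 2.0 * Ea * mu + mu * mu).sum() / (2.0 * s2)
    return -0.5 * len(Ea) * np.log(s2) - quad - log_ndtr(mu / sd).sum()


def m_step(
    data: ResponseData,
    spec: ModelSpec,
    vstate: VariationalState,
    config: FitConfig,
    params: Parameters | None = None,
    _ws: _Workspace | None = None,
) -> Parameters:
    """Maximize the penalized expected complete-data bound over parameters.

    Closed forms: fixed slopes (Ri/RiM), intercept fixed effects (least
    squares of b means on the group design, anchors restricted to the
    base column), impact main effects (group-size-weighted least
    squares), impact variance, and the penalized DIF-variance update
    R_j/(S + 2η).  Slope fixed effects and slope variances of Ris/RisM
    have no closed form and use bounded scalar maximization per
    coordinate (brackets (−5, 5) and (1e-4, 10)); ``params`` supplies
    their current values and is required for those variants.
    """
    ws = _ws or _Workspace(data, spec)
    S = ws.S
    eta = config.penalty_eta
    theta_m, theta_v = vstate.theta_mean, vstate.theta_var
    theta2 = theta_m**2 + theta_v
    lam = bound_lambda(vstate.xi) * ws.W
    S_lam_th = ws.group_sum(lam * theta_m[:, None]).T  # J×S

    J, P = spec.J, data.design.P
    anchor = spec.anchor_mask

    # slopes
    if spec.has_random_slopes:
        if params is None:
            raise ValueError("m_step for Ris/RisM needs current params")
        alpha = params.slope_alpha().copy()
        var_slope = params.var_slope.copy()
        for j in range(J):
            Ea, Ea2 = vstate.a_mean[j], vstate.a_second[j]
            coords = [0] if anchor[j] else range(P + 1)
            for p in coords:

                def neg(t, j=j, p=p):
                    vec = alpha[j].copy()
                    vec[p] = t
                    return -_slope_term_value(Ea2, Ea, ws.Xt @ vec, var_slope[j])

                res = minimize_scalar(
                    neg, bounds=(-5.0, 5.0), method="bounded",
                    options={"xatol": 1e-8},
                )
                alpha[j, p] = res.x
            mu_j = ws.Xt @ alpha[j]

            def neg_var(s2, mu_j=mu_j):
                return -(_slope_term_value(Ea2, Ea, mu_j, s2) - eta * np.log(s2))

            res = minimize_scalar(
                neg_var, bounds=(1e-4, 10.0), method="bounded",
                options={"xatol": 1e-8},
            )
            var_slope[j] = res.x
        slope_base = alpha[:, 0]
        slope_main = alpha[:, 1:]
    else:
        num = (ws.Yhalf * theta_m[:, None]).sum(axis=0)
        num -= 2.0 * (vstate.b_mean * S_lam_th).sum(axis=1)
        den = 2.0 * (lam * theta2[:, None]).sum(axis=0)
        slope_base = num / np.maximum(den, _VAR_TINY)
        slope_main = np.zeros((J, P))
        var_slope = np.zeros(J)

    # intercept fixed effects: LS of b_mean rows on X_tilde
    beta = (ws.pinv_Xt @ vstate.b_mean.T).T  # J×(P+1)
    if anchor.any():
        beta[anchor, 1:] = 0.0
        beta[anchor, 0] = vstate.b_mean[anchor].mean(axis=1)
    # items whose DIF variance collapsed are fixed effects: their intercept
    # coefficients enter the bound-weighted likelihood directly
    fixed_b = (
        np.flatnonzero(params.var_intercept == 0.0)
        if params is not None
        else np.array([], dtype=int)
    )
    S_lam = ws.group_sum(lam).T  # J×S
    rhs_all = ws.group_sum(ws.Yhalf).T - 2.0 * vstate.a_mean * S_lam_th  # J×S
    for j in fixed_b:
        if anchor[j]:
            beta[j, 0] = rhs_all[j].sum() / (2.0 * S_lam[j].sum())
            beta[j, 1:] = 0.0
        else:
            M = (ws.Xt.T * S_lam[j]) @ ws.Xt
            beta[j] = np.linalg.solve(2.0 * M, rhs_all[j] @ ws.Xt)
    Bhat = beta @ ws.Xt.T  # J×S fitted prior means
    resid = (vstate.b_mean - Bhat) ** 2 + vstate.b_var
    var_intercept = resid.sum(axis=1) / (S + 2.0 * eta)
    # collapse: a variance shrunk below the floor is an exact structural zero,
    # and a collapsed item stays a fixed effect
    var_intercept[var_intercept < config.variance_floor] = 0.0
    var_intercept[fixed_b] = 0.0

    # impact main effects: group-size-weighted LS of ability means on X
    if P > 0:
        theta_bar = (ws.G @ theta_m) / np.maximum(ws.n_s, 1.0)
        target = theta_bar - vstate.u_mean
        w = np.sqrt(ws.n_s)
        gamma, *_ = np.linalg.lstsq(ws.X * w[:, None], target * w, rcond=None)
    else:
        gamma = np.zeros(0)

    impact_var = 0.0
    if spec.has_multilevel_ability:
        impact_var = float(np.mean(vstate.u_mean**2 + vstate.u_var))

    return Parameters(
        intercept_base=beta[:, 0],
        intercept_main=beta[:, 1:],
        slope_base=slope_base,
        slope_main=slope_main,
        var_intercept=var_intercept,
        var_slope=var_slope,
        impact_main=gamma,
        impact_var=impact_var,
    )


def _flog(v, floor):
    """log of a variance with the Remark-style δ floor (floor=None → raw log)."""
    if floor is None:
        return np.log(v)
    return np.log(np.maximum(v, floor))


def elbo(
    data: ResponseData,
    spec: ModelSpec,
    params: Parameters,
    vstate: VariationalState,
    log_floor: float | None = None,
    _ws: _Workspace | None = None,
) -> float:
    """Evidence lower bound under the local sigmoid bound.

    Expected bounded Bernoulli log-likelihood plus expected latent
    log-densities plus variational entropies.  ``log_floor`` applies
    the δ replacement to every log of a variance (priors and entropies
    consistently), as used inside objective and GIC evaluation.
    """
    ws = _ws or _Workspace(data, spec)
    g, S = ws.g, ws.S
    v0 = spec.fixed_theta_variance
    th_m, th_v = vstate.theta_mean, vstate.theta_var
    theta2 = th_m**2 + th_v
    a_mean, a_second = _slope_moment_matrices(spec, params, vstate, S)

    Ea_p = a_mean[:, g].T
    Ea2_p = a_second[:, g].T
    Eb_p = vstate.b_mean[:, g].T
    Eb2_p = (vstate.b_mean**2 + vstate.b_var)[:, g].T
    ex = Ea_p * th_m[:, None] + Eb_p
    ex2 = Ea2_p * theta2[:, None] + 2.0 * Ea_p * th_m[:, None] * Eb_p + Eb2_p

    xi = vstate.xi
    lam = bound_lambda(xi)
    lik = ws.W * (log_expit(xi) - 0.5 * xi - lam * (ex2 - xi * xi)) + ws.Yhalf * ex
    total = float(lik.sum())

    # theta prior
    mu_grp = params.group_ability_mean(data.design)
    mu_i = mu_grp[g] + vstate.u_mean[g]
    e_mu2 = mu_i**2 + vstate.u_var[g] * (1.0 if spec.has_multilevel_ability else 0.0)
    quad = theta2 - 2.0 * th_m * mu_i + e_mu2
    total += float((-0.5 * (_LOG_2PI + np.log(v0)) - quad / (2.0 * v0)).sum())
    # theta entropy
    total += float(0.5 * (_LOG_2PI + 1.0 + _flog(th_v, log_floor)).sum())

    # random intercept prior + entropy; collapsed items are fixed effects
    # (their b is no longer latent, so they contribute no such terms)
    Bprior = params.intercept_prior_mean(data.design)
    live_b = (params.var_intercept > 0.0)[:, None]
    vb = np.maximum(params.var_intercept, _VAR_TINY)[:, None]
    rb = (vstate.b_mean - Bprior) ** 2 + vstate.b_var
    prior_b = -0.5 * (_LOG_2PI + _flog(vb, log_floor)) - rb / (2.0 * vb)
    ent_b = 0.5 * (_LOG_2PI + 1.0 + _flog(np.maximum(vstate.b_var, _VAR_TINY), log_floor))
    total += float(((prior_b + ent_b) * live_b).sum())

    if spec.has_random_slopes:
        Aprior = params.slope_prior_mean(data.design)
        va = np.maximum(params.var_slope, _VAR_TINY)[:, None]
        ra = a_second - 2.0 * a_mean * Aprior + Aprior**2
        logz_prior = log_ndtr(Aprior / np.sqrt(va))
        total += float(
            (-0.5 * (_LOG_2PI + _flog(va, log_floor)) - ra / (2.0 * va) - logz_prior).sum()
        )
        # entropy of the truncated-normal factors, from stored moments
        m, v = vstate.a_under_mean, vstate.a_under_var
        e_dev2 = a_second - 2.0 * m * a_mean + m * m
        total += float(
            (0.5 * (_LOG_2PI + _flog(v, log_floor)) + e_dev2 / (2.0 * v)
             + vstate.a_log_z).sum()
        )

    if spec.has_multilevel_ability:
        tau2 = max(params.impact_var, _VAR_TINY)
        eu2 = vstate.u_mean**2 + vstate.u_var
        total += float(
            (-0.5 * (_LOG_2PI + _flog(np.full(S, tau2), log_floor)) - eu2 / (2.0 * tau2)).sum()
        )
        total += float(0.5 * (_LOG_2PI + 1.0 + _flog(vstate.u_var, log_floor)).sum())

    return total


def penalized_objective(
    data: ResponseData,
    spec: ModelSpec,
    params: Parameters,
    vstate: VariationalState,
    config: FitConfig,
    _ws: _Workspace | None = None,
) -> float:
    """ELBO − η·Σ log(DIF variances), with the δ floor inside the logs."""
    val = elbo(data, spec, params, vstate, log_floor=config.variance_floor, _ws=_ws)
    if config.penalty_eta > 0:
        pen = _flog(params.var_intercept, config.variance_floor).sum()
        if spec.has_random_slopes:
            pen += _flog(params.var_slope, config.variance_floor).sum()
        val -= config.penalty_eta * float(pen)
    return val


def _cold_start(
    data: ResponseData, spec: ModelSpec, config: FitConfig
) -> tuple[Parameters, VariationalState]:
    """Moment-based starting point: unit slopes, logit item means, variances 0.1."""
    J, S, P = spec.J, data.design.S, data.design.P
    with np.errstate(invalid="ignore"):
        pbar = np.nanmean(data.Y, axis=0)
    pbar = np.clip(np.nan_to_num(pbar, nan=0.5), 0.02, 0.98)
    params = Parameters(
        intercept_base=np.log(pbar / (1.0 - pbar)),
        intercept_main=np.zeros((J, P)),
        slope_base=np.ones(J),
        slope_main=np.zeros((J, P)),
        var_intercept=np.full(J, 0.1),
        var_slope=np.full(J, 0.1) if spec.has_random_slopes else np.zeros(J),
        impact_main=np.zeros(P),
        impact_var=0.1 if spec.has_multilevel_ability else 0.0,
    )
    if config.init_strategy == "random":
        rng = np.random.default_rng(config.seed)
        params.intercept_base = params.intercept_base + rng.normal(0, 0.3, J)
        params.slope_base = np.abs(params.slope_base + rng.normal(0, 0.3, J))

    Bprior = params.intercept_prior_mean(data.design)
    if spec.has_random_slopes:
        mom = truncnorm_moments(params.slope_prior_mean(data.design), np.full((J, S), 0.1))
        a_mean, a_sec = mom.mean, mom.variance + mom.mean**2
        a_um, a_uv, a_lz = params.slope_prior_mean(data.design), np.full((J, S), 0.1), mom.log_normalizer
    else:
        a_mean = np.repeat(params.slope_base[:, None], S, axis=1)
        a_sec = a_mean**2
        a_um, a_uv, a_lz = a_mean.copy(), np.ones((J, S)), np.zeros((J, S))
    vstate = VariationalState(
        theta_mean=np.zeros(data.N),
        theta_var=np.ones(data.N),
        b_mean=Bprior.copy(),
        b_var=np.full((J, S), 0.1),
        a_mean=a_mean,
        a_second=a_sec,
        a_under_mean=a_um,
        a_under_var=a_uv,
        a_log_z=a_lz,
        u_mean=np.zeros(S),
        u_var=np.full(S, 0.1 if spec.has_multilevel_ability else 1.0),
        xi=np.ones((data.N, spec.J)),
    )
    return params, vstate


def fit(
    data: ResponseData,
    spec: ModelSpec,
    config: FitConfig | None = None,
    init: FitResult | tuple[Parameters, VariationalState] | None = None,
) -> FitResult:
    """Run the regularized GVEM loop to convergence.

    Alternates one E-step sweep and one M-step until the relative
    change of the penalized objective drops below ``elbo_rel_tol`` or
    ``max_iters`` is reached (non-convergence is reported, not raised).
    ``init`` warm-starts from an earlier fit, e.g. the previous point
    of a regularization path.
    """
    config = config or FitConfig()
    ws = _Workspace(data, spec)
    if init is not None:
        if isinstance(init, FitResult):
            params, vstate = init.params.copy(), init.vstate.copy()
        else:
            params, vstate = init[0].copy(), init[1].copy()
    elif config.penalty_eta > 0 and config.init_strategy == "unpenalized_warm_start":
        base = fit(data, spec, replace(config, penalty_eta=0.0))
        params, vstate = base.params, base.vstate
    else:
        params, vstate = _cold_start(data, spec, config)

    trace: list[float] = []
    prev = None
    converged = False
    for it in range(config.max_iters):
        vstate = e_step(data, spec, params, vstate, _ws=ws)
        params = m_step(data, spec, vstate, config, params=params, _ws=ws)
        obj = penalized_objective(data, spec, params, vstate, config, _ws=ws)
        trace.append(obj)
        logger.debug(
            "iter %d: objective %.6f, active variances %d",
            it, obj, int((params.var_intercept > spec.dif_flag_threshold).sum()),
        )
        if prev is not None and abs(obj - prev) <= config.elbo_rel_tol * (
            abs(prev) + 1e-12
        ):
            converged = True
            break
        prev = obj

    surrogate = elbo(data, spec, params, vstate, log_floor=config.variance_floor, _ws=ws)
    return FitResult(
        params=params,
        vstate=vstate,
        elbo_trace=np.asarray(trace),
        penalized_objective=trace[-1],
        elbo_final=surrogate,
        n_iters=len(trace),
        converged=converged,
        penalty_eta=config.penalty_eta,
    )
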