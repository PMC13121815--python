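"""Data model for random-item-effect 2PL models of intersectional DIF.

Persons are nested in intersectional groups — the cells of the full
cross-classification of ``D`` categorical demographic variables.  A 2PL
item response function

    P(Y_isj = 1 | theta_is) = sigmoid(a_js * theta_is + b_js)

is extended with group-specific item intercepts ``b_js`` (and optionally
slopes ``a_js``) whose means are linear in the dummy-coded demographic
main effects (traditional uniform / non-uniform DIF) and whose variances
capture interaction-driven deviations (intersectional DIF).  A multilevel
ability structure adds a group-level random intercept on mean ability
(intersectional impact).  Four variants arise:

==========  ==============  ============  ==================
variant     random b_js     random a_js   multilevel ability
==========  ==============  ============  ==================
``Ri``      yes             no            no
``RiM``     yes             no            yes
``Ris``     yes             yes           no
``RisM``    yes             yes           yes
==========  ==============  ============  ==================

Group-specific slopes follow a normal distribution left-truncated at
zero; "untruncated" (bar) quantities refer to the latent normal before
truncation.  All indices are 0-based in memory; file formats are 1-based.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit, log_ndtr

__all__ = [
    "GroupDesign",
    "ResponseData",
    "ModelSpec",
    "Parameters",
    "TruncNormMoments",
    "VARIANTS",
    "build_group_design",
    "response_probability",
    "truncnorm_moments",
    "log_joint",
]

VARIANTS = ("Ri", "RiM", "Ris", "RisM")

_SQRT_2PI = np.sqrt(2.0 * np.pi)


class InvalidDesignError(ValueError):
    """Raised for demographic designs that cannot define a group structure."""


@dataclass(frozen=True)
class GroupDesign:
    """Full cross-classification of demographic variables into S groups.

    ``X`` is the S×P coded main-effect design (P = sum of levels − 1 per
    variable); ``X_tilde`` prepends a constant-1 column for item-parameter
    regressions.  Under dummy coding the all-first-levels cell is the
    reference group (all-zero row); under effect coding no group is a
    reference and effects are relative to the grand mean.
    """

    levels_per_variable: tuple[int, ...]
    coding: str
    X: np.ndarray
    group_labels: tuple[tuple[int, ...], ...]

    @property
    def S(self) -> int:
        return self.X.shape[0]

    @property
    def P(self) -> int:
        return self.X.shape[1]

    @property
    def X_tilde(self) -> np.ndarray:
        return np.hstack([np.ones((self.S, 1)), self.X])

    def __post_init__(self) -> None:
        S = int(np.prod(self.levels_per_variable)) if self.levels_per_variable else 1
        if self.X.shape[0] != S:
            raise InvalidDesignError(
                f"design matrix has {self.X.shape[0]} rows, expected {S}"
            )


def build_group_design(
    levels_per_variable: Sequence[int], coding: str = "dummy"
) -> GroupDesign:
    """Enumerate intersectional groups for the given level counts.

    Groups are enumerated lexicographically over variables in input
    order (last variable varies fastest), so group 0 is the
    all-first-levels cell — the reference group under dummy coding.
    An empty level list yields the degenerate single-group design
    (S = 1, P = 0) used when no demographic structure is modeled.

    Parameters
    ----------
    levels_per_variable
        Number of levels L_d (each ≥ 2) for each demographic variable.
    coding
        ``"dummy"`` (reference cell) or ``"effect"`` (grand-mean) coding.
    """
    levels = tuple(int(L) for L in levels_per_variable)
    if any(L < 2 for L in levels):
        raise InvalidDesignError(f"every variable needs ≥ 2 levels, got {levels}")
    if coding not in ("dummy", "effect"):
        raise InvalidDesignError(f"unknown coding {coding!r}")
    labels = tuple(itertools.product(*(range(L) for L in levels)))
    P = sum(L - 1 for L in levels)
    X = np.zeros((len(labels), P))
    for s, combo in enumerate(labels):
        col = 0
        for d, L in enumerate(levels):
            cat = combo[d]
            if cat > 0:
                X[s, col + cat - 1] = 1.0
            elif coding == "effect":
                X[s, col : col + L - 1] = -1.0
            col += L - 1
    return GroupDesign(levels, coding, X, labels)


@dataclass
class ResponseData:
    """Binary item responses with intersectional group membership.

    ``Y`` is N×J with entries 0.0, 1.0 or NaN (missing, skipped in all
    sums); ``group_of`` maps each person to a group index in ``0..S-1``.
    """

    Y: np.ndarray
    group_of: np.ndarray
    design: GroupDesign

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.group_of = np.asarray(self.group_of, dtype=int)
        if self.Y.ndim != 2:
            raise ValueError("Y must be a 2-D persons × items array")
        if self.group_of.shape != (self.Y.shape[0],):
            raise ValueError("group_of must have one entry per person")
        if self.group_of.min(initial=0) < 0 or (
            self.Y.shape[0] > 0 and self.group_of.max() >= self.design.S
        ):
            raise ValueError("group index out of range")
        observed = ~np.isnan(self.Y)
        vals = self.Y[observed]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("responses must be 0, 1 or missing (NaN)")

    @property
    def N(self) -> int:
        return self.Y.shape[0]

    @property
    def J(self) -> int:
        return self.Y.shape[1]

    @property
    def n_s(self) -> np.ndarray:
        """Per-group person counts (length S, sums to N)."""
        return np.bincount(self.group_of, minlength=self.design.S)

    @property
    def observed(self) -> np.ndarray:
        """Boolean N×J mask of non-missing responses."""
        return ~np.isnan(self.Y)

    def n_missing(self) -> int:
        return int(np.isnan(self.Y).sum())


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit and how it is identified.

    ``anchors`` are items whose demographic *main* effects are fixed to
    zero; their random effects remain free (they are not anchored with
    respect to intersectional DIF).  ``dif_flag_threshold`` is the ε
    below which an estimated DIF variance is reported as zero.  The
    within-group ability variance is fixed (default 1) for
    identification.
    """

    variant: str
    J: int
    anchors: frozenset[int]
    dif_flag_threshold: float = 1e-3
    fixed_theta_variance: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        anchors = frozenset(int(a) for a in self.anchors)
        object.__setattr__(self, "anchors", anchors)
        if not anchors or not anchors < set(range(self.J)):
            raise ValueError("anchors must be a nonempty strict subset of items")
        if self.dif_flag_threshold <= 0:
            raise ValueError("dif_flag_threshold must be positive")

    @property
    def has_random_slopes(self) -> bool:
        return self.variant in ("Ris", "RisM")

    @property
    def has_multilevel_ability(self) -> bool:
        return self.variant in ("RiM", "RisM")

    @property
    def anchor_mask(self) -> np.ndarray:
        m = np.zeros(self.J, dtype=bool)
        m[list(self.anchors)] = True
        return m


@dataclass
class Parameters:
    """Fixed effects and variance components of a random-item 2PL model.

    Item intercept prior means are ``X_tilde @ [intercept_base_j,
    intercept_main_j]``; analogously for slopes.  ``var_intercept[j]``
    and ``var_slope[j]`` are the intersectional UDIF / NUDIF variances:
    item j is free of intersectional NUDIF when ``var_slope[j] = 0`` and
    additionally free of intersectional UDIF when ``var_intercept[j] =
    0``.  ``impact_main`` acts on group mean ability through ``X`` (no
    constant column, so the reference group mean is 0) and
    ``impact_var`` is the intersectional impact variance.
    """

    intercept_base: np.ndarray
    intercept_main: np.ndarray
    slope_base: np.ndarray
    slope_main: np.ndarray
    var_intercept: np.ndarray
    var_slope: np.ndarray
    impact_main: np.ndarray
    impact_var: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "intercept_base",
            "intercept_main",
            "slope_base",
            "slope_main",
            "var_intercept",
            "var_slope",
            "impact_main",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if (self.var_intercept < 0).any() or (self.var_slope < 0).any():
            raise ValueError("DIF variances must be nonnegative")
        if self.impact_var < 0:
            raise ValueError("impact_var must be nonnegative")

    @property
    def J(self) -> int:
        return self.intercept_base.shape[0]

    def intercept_beta(self) -> np.ndarray:
        """J×(P+1) intercept coefficient matrix [base | main effects]."""
        return np.column_stack([self.intercept_base, self.intercept_main])

    def slope_alpha(self) -> np.ndarray:
        """J×(P+1) slope coefficient matrix [base | main effects]."""
        return np.column_stack([self.slope_base, self.slope_main])

    def intercept_prior_mean(self, design: GroupDesign) -> np.ndarray:
        """J×S matrix of group-specific item intercept means."""
        return self.intercept_beta() @ design.X_tilde.T

    def slope_prior_mean(self, design: GroupDesign) -> np.ndarray:
        """J×S matrix of group-specific pre-truncation slope means."""
        return self.slope_alpha() @ design.X_tilde.T

    def group_ability_mean(self, design: GroupDesign) -> np.ndarray:
        """Length-S fixed part of group mean ability (X @ impact_main)."""
        if design.P == 0:
            return np.zeros(design.S)
        return design.X @ self.impact_main

    def copy(self) -> "Parameters":
        return Parameters(
            self.intercept_base.copy(),
            self.intercept_main.copy(),
            self.slope_base.copy(),
            self.slope_main.copy(),
            self.var_intercept.copy(),
            self.var_slope.copy(),
            self.impact_main.copy(),
            float(self.impact_var),
        )


@dataclass(frozen=True)
class TruncNormMoments:
    """Moments of a normal distribution left-truncated at zero."""

    mean: np.ndarray
    variance: np.ndarray
    log_normalizer: np.ndarray


def response_probability(theta, slope, intercept):
    """2PL item response function sigmoid(slope·theta + intercept)."""
    return expit(np.asarray(slope) * np.asarray(theta) + np.asarray(intercept))


def truncnorm_moments(untruncated_mean, untruncated_variance) -> TruncNormMoments:
    """Moments of N(mean, variance) conditioned on the positive half-line.

    Uses the Mills-ratio form r = φ(z)/Φ(z) with z = mean/sd evaluated in
    log space, which stays accurate for untruncated means down to tens
    of standard deviations below zero.
    """
    mu = np.asarray(untruncated_mean, dtype=float)
    var = np.asarray(untruncated_variance, dtype=float)
    if (var <= 0).any():
        raise ValueError("untruncated_variance must be positive")
    sd = np.sqrt(var)
    z = mu / sd
    log_z_norm = log_ndtr(z)
    # r = phi(z)/Phi(z), computed as exp(log phi − log Phi) for tail stability
    r = np.exp(-0.5 * z * z - np.log(_SQRT_2PI) - log_z_norm)
    mean = mu + sd * r
    variance = var * (1.0 - z * r - r * r)
    # guard the deep-tail residual cancellation; variance is tiny but positive
    variance = np.maximum(variance, np.finfo(float).tiny)
    return TruncNormMoments(mean=mean, variance=variance, log_normalizer=log_z_norm)


def _norm_logpdf(x, mean, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def log_joint(
    data: ResponseData,
    spec: ModelSpec,
    params: Parameters,
    theta: np.ndarray,
    b: np.ndarray,
    a: np.ndarray | None = None,
    u: np.ndarray | None = None,
) -> float:
    """Log joint density of responses and a full latent configuration.

    ``theta`` is length N, ``b`` (and ``a`` when slopes are random) are
    J×S group-specific item parameters, ``u`` is the length-S impact
    deviation for multilevel variants.  Bernoulli terms for missing
    responses are skipped.  Latent densities: θ ~ N(group mean, fixed
    variance), b ~ N(prior mean, var_intercept), a ~ left-truncated
    N(prior mean, var_slope), u ~ N(0, impact_var).
    """
    design = data.design
    g = data.group_of
    if u is None:
        u = np.zeros(design.S)
    if a is None:
        a = np.broadcast_to(params.slope_base[:, None], (spec.J, design.S))

    total = 0.0
    # Bernoulli responses under the 2PL with group-specific parameters
    eta_lin = a[:, g].T * theta[:, None] + b[:, g].T  # N×J linear predictor
    obs = data.observed
    yc = np.nan_to_num(data.Y)
    sgn = np.where(yc > 0.5, 1.0, -1.0)
    from scipy.special import log_expit

    total += float((log_expit(sgn * eta_lin) * obs).sum())

    # ability: theta_i ~ N(group mean + u, fixed variance)
    mu_theta = params.group_ability_mean(design)[g] + u[g]
    v0 = spec.fixed_theta_variance
    total += float(_norm_logpdf(theta, mu_theta, v0).sum())

    # random intercepts
    Bprior = params.intercept_prior_mean(design)
    vb = params.var_intercept[:, None]
    if (vb <= 0).any():
        raise ValueError("var_intercept must be positive to evaluate log_joint")
    total += float(_norm_logpdf(b, Bprior, vb).sum())

    if spec.has_random_slopes:
        va = params.var_slope[:, None]
        if (va <= 0).any():
            raise ValueError("var_slope must be positive to evaluate log_joint")
        Aprior = params.slope_prior_mean(design)
        if (a <= 0).any():
            return -np.inf
        log_z = log_ndtr(Aprior / np.sqrt(va))
        total += float((_norm_logpdf(a, Aprior, va) - log_z).sum())

    if spec.has_multilevel_ability:
        if params.impact_var <= 0:
            raise ValueError("impact_var must be positive to evaluate log_joint")
        total += float(_norm_logpdf(u, 0.0, params.impact_var).sum())
    return total
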