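"""Conditional logistic regression (CLR) over matched family sets.

The conditional likelihood for strata with one case each is

    l(beta) = sum_sets [ x_case . beta - log sum_{j in set} exp(x_j . beta) ],

which eliminates the stratum-specific baseline risk.  The fit is by
Newton-Raphson with exact derivatives and step-halving; standard errors come
from the inverse observed information and 95% CIs are exp(b +/- 1.96 SE).

Coding rules for the interaction models:

* categorical risk factors are *saturated* for the main effect (one
  indicator per non-reference level) so the model stays correctly specified
  under a no-interaction null;
* the PRS x factor interaction uses a single linear-trend product column
  with integer scores 0,1,2,... over the ordered levels — except smoking,
  the one unordered factor, which gets one product column per non-reference
  level;
* the centered PRS main effect is always present in interaction models;
* every model adjusts for birth order (indicator for being the elder
  sister) because the sampling design makes control sisters more often the
  elder one.

The interaction parameter exponentiated is the ROR: the PRS odds ratio in
the exposed category divided by that in the category one unit below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .exposures import FACTORS, Factor
from .sets import MatchedSet

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "FitResult",
    "EstimationError",
    "UnidentifiableTermError",
    "default_model_specs",
    "build_design_matrix",
    "conditional_loglik",
    "fit_design",
    "fit_clr",
    "compose_exposed_or",
    "wald_interaction_test",
]

Z975 = 1.959963984540054  # standard normal 97.5% quantile


class EstimationError(RuntimeError):
    pass


class UnidentifiableTermError(KeyError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """One Table-style model: a target risk factor with optional PRS interaction.

    ``confounders`` defaults to the factor registry's confounder set; birth
    order is always added.  ``subset`` restricts the families used
    ("all", "invasive_only", "er_positive_only"); ``ethnicity`` of None
    means every ethnic group, otherwise families are restricted to that
    label.
    """

    target_factor: str
    interaction: bool = True
    confounders: Optional[tuple[str, ...]] = None
    subset: str = "all"
    ethnicity: Optional[str] = None
    # "saturated" (default for interaction models) or "trend": how ordered
    # categorical main effects are coded.  Nominal factors are always
    # saturated; the trend option exists for presentation fits.
    main_effect_coding: str = "saturated"

    def factor(self) -> Factor:
        try:
            return FACTORS[self.target_factor]
        except KeyError:
            raise KeyError(f"unknown risk factor {self.target_factor!r}") from None

    def resolved_confounders(self) -> tuple[str, ...]:
        if self.confounders is not None:
            return self.confounders
        return self.factor().confounders


def default_model_specs(interaction: bool = True) -> list[ModelSpec]:
    """The 14 default models, one per risk factor, in reporting order."""
    order = [
        "ever_hbc", "hbc_within_5y", "last_birth_within_5y", "breastfeeding",
        "premenopausal", "height", "bmi_at_30", "age_menarche",
        "age_first_birth_cont", "smoking", "alcohol", "years_hbc",
        "parity", "age_first_birth_cat",
    ]
    return [ModelSpec(target_factor=f, interaction=interaction) for f in order]


# ---------------------------------------------------------------------------
# Design matrix construction
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    X: np.ndarray                 # (n_rows, n_cols)
    starts: np.ndarray            # set offsets, length n_sets + 1; case row first
    names: list[str]
    interaction_terms: tuple[str, ...]
    target_terms: tuple[str, ...]
    set_ids: list[str]
    dropped_sets: list[tuple[str, str]]  # (family_id, reason)

    @property
    def n_sets(self) -> int:
        return len(self.starts) - 1

    @property
    def case_rows(self) -> np.ndarray:
        return self.starts[:-1]


def _member_value(factor: Factor, member) -> object:
    return factor.accessor(member.exposure)


def _main_columns(factor: Factor, saturated: bool) -> list[str]:
    if factor.kind in ("continuous", "binary"):
        return [factor.name]
    if factor.kind == "nominal" or saturated:
        return [f"{factor.name}[{lv}]" for lv in factor.levels[1:]]
    return [f"{factor.name}_trend"]


def _encode_main(factor: Factor, value, saturated: bool, center: float) -> list[float]:
    if factor.kind == "continuous":
        return [float(value) - center]
    if factor.kind == "binary":
        return [1.0 if value else 0.0]
    idx = factor.level_score(value)
    if factor.kind == "nominal" or saturated:
        return [1.0 if idx == k else 0.0 for k in range(1, len(factor.levels))]
    return [float(idx)]


def _interaction_columns(factor: Factor) -> list[str]:
    if factor.kind == "nominal":
        return [f"prs_x_{factor.name}[{lv}]" for lv in factor.levels[1:]]
    return [f"prs_x_{factor.name}"]


def _encode_interaction(factor: Factor, value, prs: float, center: float) -> list[float]:
    if factor.kind == "continuous":
        return [prs * (float(value) - center)]
    if factor.kind == "binary":
        return [prs * (1.0 if value else 0.0)]
    idx = factor.level_score(value)
    if factor.kind == "nominal":
        return [prs * (1.0 if idx == k else 0.0) for k in range(1, len(factor.levels))]
    return [prs * float(idx)]


def build_design_matrix(
    sets: Iterable[MatchedSet],
    spec: ModelSpec,
    control_means: Optional[Mapping[str, float]] = None,
) -> DesignMatrix:
    """Expand matched sets into CLR rows for one model.

    Complete-case per model: a set any of whose members lacks the target
    factor or a confounder is dropped whole and logged.  Continuous target
    factors are centered by the control mean when one is supplied, so the
    PRS main effect refers to the factor's control mean (this does not
    change the interaction estimate).
    """
    factor = spec.factor()
    confounders = [FACTORS[c] for c in spec.resolved_confounders()]
    control_means = control_means or {}

    def centering(f: Factor) -> float:
        if f.kind == "continuous" and f.center_by_controls:
            return float(control_means.get(f.name, 0.0))
        return 0.0

    saturated = spec.interaction and spec.main_effect_coding != "trend"
    names: list[str] = []
    names += _main_columns(factor, saturated=saturated)
    target_terms = tuple(names)
    interaction_terms: tuple[str, ...] = ()
    if spec.interaction:
        names.append("prs")
        inter = _interaction_columns(factor)
        names += inter
        interaction_terms = tuple(inter)
    names.append("elder")
    for conf in confounders:
        # confounders enter with their presentation coding (trend for
        # ordered, indicators for nominal)
        names += _main_columns(conf, saturated=False)

    rows: list[list[float]] = []
    starts = [0]
    set_ids: list[str] = []
    dropped: list[tuple[str, str]] = []

    for mset in sets:
        encoded: list[list[float]] = []
        reason = None
        for member in mset.members:
            value = _member_value(factor, member)
            if value is None:
                reason = f"missing {factor.name}"
                break
            row = _encode_main(factor, value, saturated, centering(factor))
            if spec.interaction:
                row.append(member.prs)
                row += _encode_interaction(factor, value, member.prs, centering(factor))
            row.append(1.0 if member.exposure.is_elder else 0.0)
            for conf in confounders:
                cval = _member_value(conf, member)
                if cval is None:
                    reason = f"missing confounder {conf.name}"
                    break
                row += _encode_main(conf, cval, False, centering(conf))
            if reason:
                break
            encoded.append(row)
        if reason:
            dropped.append((mset.family_id, reason))
            continue
        # case member first (build_matched_set guarantees it, but be safe)
        case_idx = next(i for i, m in enumerate(mset.members) if m.is_case_member)
        encoded.insert(0, encoded.pop(case_idx))
        rows.extend(encoded)
        starts.append(len(rows))
        set_ids.append(mset.family_id)

    X = np.asarray(rows, dtype=float) if rows else np.zeros((0, len(names)))
    return DesignMatrix(
        X=X,
        starts=np.asarray(starts, dtype=np.intp),
        names=names,
        interaction_terms=interaction_terms,
        target_terms=target_terms,
        set_ids=set_ids,
        dropped_sets=dropped,
    )


# ---------------------------------------------------------------------------
# Likelihood and Newton-Raphson fit
# ---------------------------------------------------------------------------

def _loglik_parts(beta: np.ndarray, X: np.ndarray, starts: np.ndarray):
    eta = X @ beta
    heads = starts[:-1]
    reps = np.diff(starts)
    m = np.maximum.reduceat(eta, heads)
    ex = np.exp(eta - np.repeat(m, reps))
    denom = np.add.reduceat(ex, heads)
    lse = m + np.log(denom)
    ll = float(np.sum(eta[heads] - lse))
    w = ex / np.repeat(denom, reps)
    return ll, w, heads


def conditional_loglik(beta, X, starts) -> float:
    """l(beta) = sum_sets [eta_case - log sum_j exp(eta_j)], case row first."""
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    starts = np.asarray(starts, dtype=np.intp)
    return _loglik_parts(beta, X, starts)[0]


def _score_and_info(w, X, starts, heads):
    grad = X[heads].sum(axis=0) - X.T @ w
    WX = w[:, None] * X
    M = np.add.reduceat(WX, heads, axis=0)
    info = X.T @ WX - M.T @ M
    return grad, info


@dataclass
class FitResult:
    params: dict[str, float]
    se: dict[str, float]
    cov: np.ndarray
    names: list[str]
    loglik: float
    converged: bool
    iterations: int
    separation_flag: bool
    unidentifiable: tuple[str, ...]
    interaction_terms: tuple[str, ...] = ()
    target_terms: tuple[str, ...] = ()
    n_sets: int = 0
    dropped_sets: tuple[tuple[str, str], ...] = ()

    def odds_ratio(self, term: str) -> tuple[float, float, float]:
        """(OR, 95% CI low, 95% CI high) for one coefficient.

        Bounds overflow to inf (or underflow to 0) for separated terms.
        """
        b, s = self._term(term)
        with np.errstate(over="ignore"):
            return (float(np.exp(b)), float(np.exp(b - Z975 * s)),
                    float(np.exp(b + Z975 * s)))

    def p_value(self, term: str) -> float:
        b, s = self._term(term)
        if s == 0:
            return 1.0 if b == 0 else 0.0
        return float(2 * stats.norm.sf(abs(b) / s))

    def _term(self, term: str) -> tuple[float, float]:
        if term in self.unidentifiable:
            raise UnidentifiableTermError(
                f"term {term!r} has no within-set variation and was not estimated"
            )
        if term not in self.params:
            raise KeyError(f"unknown term {term!r}; have {list(self.params)}")
        return self.params[term], self.se[term]


def fit_design(
    X: np.ndarray,
    starts: np.ndarray,
    names: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = 10.0,
) -> FitResult:
    """Newton-Raphson CLR fit on a pre-built design (case row first per set).

    Columns constant within every set carry no conditional information and
    are excluded up front, reported as unidentifiable.  Separation (a
    monotone likelihood) is flagged when a coefficient wanders past
    ``separation_bound`` on the log scale with a non-vanishing gradient.
    """
    X = np.asarray(X, dtype=float)
    starts = np.asarray(starts, dtype=np.intp)
    names = list(names)
    n_sets = len(starts) - 1
    if n_sets < 1 or X.shape[0] == 0:
        raise EstimationError("no matched sets to fit")

    reps = np.diff(starts)
    set_means = np.add.reduceat(X, starts[:-1], axis=0) / reps[:, None]
    Xc = X - np.repeat(set_means, reps, axis=0)
    active = np.max(np.abs(Xc), axis=0) > 1e-10
    unident = tuple(n for n, a in zip(names, active) if not a)
    kept = [n for n, a in zip(names, active) if a]
    Xk = X[:, active]
    if Xk.shape[1] == 0:
        raise EstimationError("every covariate is constant within sets")
    if np.linalg.matrix_rank(Xc[:, active]) < Xk.shape[1]:
        raise EstimationError(
            "within-set design is rank deficient (collinear covariates)"
        )

    p = Xk.shape[1]
    beta = np.zeros(p)
    ll, w, heads = _loglik_parts(beta, Xk, starts)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, info = _score_and_info(w, Xk, starts, heads)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving: never accept a likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, w_new, _ = _loglik_parts(cand, Xk, starts)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll, w = cand, ll_new, w_new
    else:
        grad, info = _score_and_info(w, Xk, starts, heads)
        converged = np.linalg.norm(grad) < tol

    grad, info = _score_and_info(w, Xk, starts, heads)
    # monotone likelihood: a coefficient escaping to +/- infinity; near the
    # boundary the conditional likelihood flattens (the gradient vanishes),
    # so the magnitude of beta itself is the signal
    separation = bool(np.any(np.abs(beta) > separation_bound))
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    return FitResult(
        params=dict(zip(kept, beta.tolist())),
        se=dict(zip(kept, se.tolist())),
        cov=cov,
        names=kept,
        loglik=ll,
        converged=converged and not separation,
        iterations=it,
        separation_flag=separation,
        unidentifiable=unident,
        n_sets=n_sets,
    )


def fit_clr(
    sets: Iterable[MatchedSet],
    spec: ModelSpec,
    tol: float = 1e-8,
    max_iter: int = 100,
    control_means: Optional[Mapping[str, float]] = None,
) -> FitResult:
    """Build the design for ``spec`` and fit it; see fit_design."""
    design = build_design_matrix(sets, spec, control_means=control_means)
    if design.n_sets == 0:
        raise EstimationError(
            f"model {spec.target_factor}: no complete-case sets "
            f"({len(design.dropped_sets)} dropped)"
        )
    result = fit_design(design.X, design.starts, design.names,
                        tol=tol, max_iter=max_iter)
    result.interaction_terms = design.interaction_terms
    result.target_terms = design.target_terms
    result.dropped_sets = tuple(design.dropped_sets)
    return result


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def compose_exposed_or(
    or_unexposed: float, ror: float, round_to: Optional[int] = 2
) -> float:
    """PRS odds ratio in the exposed group: OR_unexposed * ROR.

    The interaction ROR is the PRS effect in the exposed category divided by
    the PRS effect in the unexposed (or one-unit-lower) category, so the
    exposed-group PRS OR is their product.  Rounded to 2 decimals by default
    for report tables; pass round_to=None for the raw product.
    """
    if not (or_unexposed > 0 and ror > 0):
        raise ValueError(
            f"odds ratios must be positive, got ({or_unexposed}, {ror})"
        )
    value = or_unexposed * ror
    return round(value, round_to) if round_to is not None else value


def wald_interaction_test(fit: FitResult, term: str) -> float:
    """Two-sided normal p-value for one interaction coefficient."""
    return fit.p_value(term)
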