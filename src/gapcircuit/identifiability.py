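"""Practical parameter determinability from nonlinear least squares.

After fitting, the question is how reliable each parameter estimate is.
Assuming the fitted optimum is the true solution, the confidence region is
the ellipsoid

    { theta : ||J (theta - theta_hat)||^2 <= Delta },
    Delta = p * s^2 * F_alpha(p, N_d - p),    s^2 = S(theta_hat) / (N_d - p)

where J is the N_d x p Jacobian of the weighted residual vector with respect
to the free parameters and F_alpha is the upper alpha quantile of Fisher's
distribution.  Two per-parameter interval types are derived from the
ellipsoid: the *dependent* interval is the axis slice through the estimate
(all other parameters held at their estimates) and tends to underestimate
the region when parameters are correlated; the *independent* interval is the
ellipsoid's bounding box, computed from the SVD J = U Sigma V^T, and tends
to overestimate it.  The dependent interval is always contained in the
independent one.

A regulatory weight is *determinable* when its independent interval lies
entirely within one regulatory category (repressing below -cutoff, no
interaction within [-cutoff, cutoff], activating above), *weakly
determinable* when the interval excludes exactly one category, and
*non-determinable* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .circuit_model import CircuitParameters

__all__ = [
    "ConfidenceIntervals",
    "DeterminabilityReport",
    "residual_jacobian",
    "confidence_intervals",
    "classify_determinability",
]

#: Relative finite-difference step and absolute floor for the Jacobian.
FD_RELATIVE_STEP = 1e-4
FD_ABSOLUTE_FLOOR = 1e-6

#: Singular values below RANK_TOL * sigma_max are treated as zero.
RANK_TOL = 1e-10

REGULATORY_CUTOFF = 0.005


@dataclass
class ConfidenceIntervals:
    """Per-parameter dependent and independent confidence intervals."""

    labels: list
    estimates: np.ndarray
    dependent: np.ndarray    # (p, 2)
    independent: np.ndarray  # (p, 2)
    delta: float
    s2: float
    p: int
    n_points: int
    alpha: float

    def half_widths(self, kind: str = "independent") -> np.ndarray:
        iv = self.independent if kind == "independent" else self.dependent
        return (iv[:, 1] - iv[:, 0]) / 2.0


@dataclass
class DeterminabilityReport:
    """Determinability classification of the free regulatory weights."""

    categories: dict          # label -> "determinable" / "weakly" / "non"
    interval_category: dict   # label -> regulatory reading, e.g. "activating"
    n_determinable: int
    n_weakly: int
    n_non: int

    @property
    def triplet(self) -> tuple[int, int, int]:
        return (self.n_determinable, self.n_weakly, self.n_non)


def residual_jacobian(params: CircuitParameters, objective, inputs=None,
                      **kwargs) -> np.ndarray:
    """Jacobian of the weighted residual vector w.r.t. the free parameters.

    ``objective`` is a :class:`~gapcircuit.fitting.CircuitObjective` (or any
    object with ``weighted_residuals``/``params_from_vector``); passing an
    :class:`~gapcircuit.dataprep.ExpressionDataset` plus ``inputs`` builds
    one.  Central finite differences with relative step 1e-4 of the
    parameter scale (absolute floor 1e-6); columns for masked parameters are
    omitted by construction (only free entries are differentiated).
    """
    if not hasattr(objective, "weighted_residuals"):
        from .fitting import CircuitObjective
        objective = CircuitObjective(objective, inputs, params, **kwargs)
    theta = params.to_vector()
    p = len(theta)
    r0 = objective.weighted_residuals(params)
    J = np.empty((len(r0), p))
    labels = params.free_labels()
    for j in range(p):
        step = max(FD_RELATIVE_STEP * abs(theta[j]), FD_ABSOLUTE_FLOOR)
        plus, minus = theta.copy(), theta.copy()
        plus[j] += step
        minus[j] -= step
        rp = objective.weighted_residuals(objective.params_from_vector(plus))
        rm = objective.weighted_residuals(objective.params_from_vector(minus))
        col = (rp - rm) / (2.0 * step)
        if not np.all(np.isfinite(col)):
            raise ValueError(
                f"non-finite Jacobian entries for parameter {labels[j]}"
            )
        J[:, j] = col
    return J


def confidence_intervals(J: np.ndarray, S_at_estimate: float, p: int,
                         n_points: int, alpha: float = 0.05,
                         estimates=None, labels=None) -> ConfidenceIntervals:
    """Dependent and independent intervals from the residual Jacobian.

    Rank-deficient Jacobians do not fail: parameters carried by null
    directions receive infinite independent intervals (non-determinable).
    """
    J = np.asarray(J, dtype=float)
    if n_points <= p:
        raise ValueError(f"need n_points > p, got n_points={n_points}, p={p}")
    if J.shape != (n_points, p):
        raise ValueError(f"Jacobian shape {J.shape}, expected {(n_points, p)}")
    s2 = S_at_estimate / (n_points - p)
    delta = p * s2 * stats.f.ppf(1.0 - alpha, p, n_points - p)
    sqrt_delta = np.sqrt(delta)

    estimates = (np.zeros(p) if estimates is None
                 else np.asarray(estimates, dtype=float))
    labels = labels if labels is not None else [f"theta_{j}" for j in range(p)]

    # dependent: slice of the ellipsoid along each axis
    col_norms = np.linalg.norm(J, axis=0)
    with np.errstate(divide="ignore"):
        dep_half = np.where(col_norms > 0, sqrt_delta / col_norms, np.inf)

    # independent: bounding box via SVD J = U Sigma V^T
    U, sigma, Vt = np.linalg.svd(J, full_matrices=False)
    V = Vt.T
    keep = sigma > RANK_TOL * (sigma[0] if sigma.size else 0.0)
    ind_half = np.empty(p)
    for j in range(p):
        if np.any(~keep & (np.abs(V[j, :]) > 1e-12)):
            ind_half[j] = np.inf
        else:
            ind_half[j] = sqrt_delta * np.sqrt(
                np.sum((V[j, keep] / sigma[keep]) ** 2))

    dep = np.column_stack([estimates - dep_half, estimates + dep_half])
    ind = np.column_stack([estimates - ind_half, estimates + ind_half])
    return ConfidenceIntervals(
        labels=list(labels), estimates=estimates, dependent=dep,
        independent=ind, delta=float(delta), s2=float(s2), p=p,
        n_points=n_points, alpha=alpha,
    )


def circuit_confidence_intervals(fit, alpha: float = 0.05
                                 ) -> ConfidenceIntervals:
    """Confidence intervals for a fitted circuit (convenience wrapper)."""
    if fit.objective is None:
        raise ValueError("fit carries no objective context")
    J = residual_jacobian(fit.params, fit.objective)
    theta = fit.params.to_vector()
    return confidence_intervals(
        J, fit.cost, p=len(theta), n_points=fit.objective.n_points,
        alpha=alpha, estimates=theta, labels=fit.params.free_labels(),
    )


def _interval_categories(lo: float, hi: float, cutoff: float) -> set:
    """Regulatory categories intersected by [lo, hi].

    Categories: repressing (-inf, -cutoff), none [-cutoff, cutoff]
    (closed), activating (cutoff, inf).
    """
    cats = set()
    if lo < -cutoff:
        cats.add("repressing")
    if hi > cutoff:
        cats.add("activating")
    if lo <= cutoff and hi >= -cutoff:
        cats.add("none")
    return cats


def classify_determinability(ci: ConfidenceIntervals,
                             cutoff: float = REGULATORY_CUTOFF,
                             weight_labels=None) -> DeterminabilityReport:
    """Classify regulatory weights by their independent intervals.

    A parameter is determinable if its interval lies within one category,
    weakly determinable if it intersects two (excludes the third), and
    non-determinable if it spans all three.  Only W/E regulatory weights are
    classified (selected by label prefix unless ``weight_labels`` is given).
    """
    if weight_labels is None:
        weight_labels = [lb for lb in ci.labels
                         if lb.startswith("W[") or lb.startswith("E[")]
    categories = {}
    readings = {}
    counts = {"determinable": 0, "weakly determinable": 0,
              "non-determinable": 0}
    for lb in weight_labels:
        j = ci.labels.index(lb)
        lo, hi = ci.independent[j]
        cats = _interval_categories(lo, hi, cutoff)
        if len(cats) == 1:
            categories[lb] = "determinable"
            readings[lb] = next(iter(cats))
        elif len(cats) == 2:
            categories[lb] = "weakly determinable"
            excluded = ({"repressing", "none", "activating"} - cats).pop()
            readings[lb] = f"not {excluded}"
        else:
            categories[lb] = "non-determinable"
            readings[lb] = "any"
        counts[categories[lb]] += 1
    return DeterminabilityReport(
        categories=categories,
        interval_category=readings,
        n_determinable=counts["determinable"],
        n_weakly=counts["weakly determinable"],
        n_non=counts["non-determinable"],
    )
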