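"""Curve reconstruction from paired distances.

Only pairwise differences ``f(x_i) − f(x_j)`` are observed, so the curve is
estimated by linear least squares over either

* a piecewise cubic with two interior knots i < j — three local cubics
  ``f1, f2, f3`` with coefficients ``b1..b12`` constrained to agree in value,
  first and second derivative at each knot (a C² cubic spline); or
* a single polynomial of degree 5.

Both objectives are linear in the coefficients and the spline constraints are
linear, so the fit is solved exactly by nullspace elimination + least squares
— deterministic, no iterations, no seed. The additive constant is not
identified by differences (intercepts only enter through within-segment
cancellation); it is fixed by an anchor policy, by default "the mean of f
over the distinct pair endpoints is zero", matching the relative y-liability
scale on which the distances live.

Orientation: a :class:`~genarc.transform.DistanceEstimate` carries
``dy = f(x_case) − f(x_control)`` (the case is the lower bin, coded 1 in the
contrast design, and dy inherits the sign of the genetic correlation). The
``dy_sign`` option accepts ``"case_minus_control"`` (default) or
``"control_minus_case"`` for tables produced under the opposite convention.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import (
    EmptyFitError,
    InsufficientSupportError,
    TransformDomainError,
    UnderdeterminedFitError,
)
from .transform import DistanceEstimate

__all__ = [
    "ShapeCurve",
    "FitReport",
    "default_knots",
    "spline_design",
    "fit_spline",
    "fit_polynomial",
    "evaluate_curve",
]

_RANK_RTOL = 1e-8
_DOMAIN_EPS = 1e-9


@dataclass(frozen=True)
class ShapeCurve:
    """A fitted curve: three constrained local cubics, or one polynomial.

    ``coefficients``: for kind ``cubic_spline``, b1..b12 = the three cubics'
    coefficients highest power first (f1: b1..b4, f2: b5..b8, f3: b9..b12);
    for kind ``polynomial``, degree+1 coefficients highest power first.
    ``anchor`` is the constant subtracted from the raw solution's intercepts
    so that the anchored curve averages zero over the anchor points.
    """

    kind: str  # "cubic_spline" | "polynomial"
    coefficients: tuple[float, ...]
    domain: tuple[float, float]
    knots: tuple[float, float] | None = None
    anchor: float = 0.0
    #: basis offset: polynomials are in powers of (x - x0); fits center the
    #: basis at the domain midpoint for numerical conditioning
    x0: float = 0.0

    def __call__(self, x) -> np.ndarray:
        return evaluate_curve(self, x)

    def derivative(self, x, order: int = 1) -> np.ndarray:
        """Evaluate the order-th derivative on a grid inside the domain."""
        x = _check_domain(np.asarray(x, dtype=float), self.domain)
        u = x - self.x0
        if self.kind == "polynomial":
            c = np.polyder(np.asarray(self.coefficients), order)
            return np.polyval(c, u)
        out = np.empty_like(x)
        for seg, mask in enumerate(_segment_masks(x, self.knots)):
            c = np.asarray(self.coefficients[4 * seg: 4 * seg + 4])
            out[mask] = np.polyval(np.polyder(c, order), u[mask])
        return out


@dataclass(frozen=True)
class FitReport:
    """Diagnostics of one fit."""

    n_pairs_used: int
    objective_value: float  # residual sum of squares on the distances
    condition: float  # condition number of the reduced design
    exclusions: dict  # reason -> count
    kind: str
    fell_back_to_polynomial: bool = False


def default_knots(x_reps) -> tuple[float, float]:
    """Interior knots at the 1/3 and 2/3 points of the representative range."""
    xs = np.unique(np.asarray(x_reps, dtype=float))
    if xs.size < 4:
        raise InsufficientSupportError(
            f"need at least 4 distinct representative values, got {xs.size}"
        )
    lo, hi = float(xs[0]), float(xs[-1])
    return (lo + (hi - lo) / 3.0, lo + 2.0 * (hi - lo) / 3.0)


def _segment_masks(x: np.ndarray, knots) -> list[np.ndarray]:
    i, j = knots
    return [x < i, (x >= i) & (x < j), x >= j]


def _segment_of(x: float, knots) -> int:
    i, j = knots
    return 0 if x < i else (1 if x < j else 2)


def _basis_row(x: float, knots, x0: float = 0.0) -> np.ndarray:
    """Row of b1..b12 coefficients expressing f(x); powers of (x − x0)."""
    row = np.zeros(12)
    seg = _segment_of(x, knots)
    u = x - x0
    row[4 * seg: 4 * seg + 4] = (u ** 3, u ** 2, u, 1.0)
    return row


def spline_design(pairs, knots, x0: float = 0.0) -> np.ndarray:
    """Rows expressing f(x_control) − f(x_case) in terms of b1..b12.

    ``pairs`` is a sequence of (x_case, x_control) tuples. Within a segment
    the shared intercept cancels; pairs straddling segments pick up the
    intercept difference, which the continuity constraints tie down.
    Segment membership is decided on the raw x scale; the cubics' powers are
    taken in (x − x0).
    """
    rows = [
        _basis_row(xb, knots, x0) - _basis_row(xa, knots, x0)
        for xa, xb in pairs
    ]
    return np.asarray(rows)


def _constraint_matrix(knots, x0: float = 0.0) -> np.ndarray:
    """6×12 matrix C with C·b = 0: value, f' and f'' agreement at each knot."""

    def val(t):
        return np.array([t ** 3, t ** 2, t, 1.0])

    def d1(t):
        return np.array([3 * t ** 2, 2 * t, 1.0, 0.0])

    def d2(t):
        return np.array([6 * t, 2.0, 0.0, 0.0])

    i, j = knots[0] - x0, knots[1] - x0
    C = np.zeros((6, 12))
    for r, fn in enumerate((val, d1, d2)):
        C[r, 0:4] = fn(i)
        C[r, 4:8] = -fn(i)
    for r, fn in enumerate((val, d1, d2)):
        C[3 + r, 4:8] = fn(j)
        C[3 + r, 8:12] = -fn(j)
    return C


def _prepare(distances: list[DistanceEstimate], dy_sign: str,
             weights: str | None):
    if dy_sign not in ("case_minus_control", "control_minus_case"):
        raise ValueError(f"unknown dy_sign {dy_sign!r}")
    included = [d for d in distances if d.included]
    exclusions = Counter(
        d.exclusion_reason for d in distances if not d.included
    )
    if not included:
        raise EmptyFitError("all distance estimates were excluded")
    pairs = [(d.x_case, d.x_control) for d in included]
    sign = -1.0 if dy_sign == "case_minus_control" else 1.0
    target = sign * np.array([d.dy for d in included])
    if weights == "inverse_variance":
        se = np.array([d.se for d in included])
        if np.any(~np.isfinite(se)) or np.any(se <= 0):
            raise InsufficientSupportError(
                "inverse-variance weighting needs finite positive se"
            )
        w = 1.0 / se
    else:
        w = np.ones(len(included))
    return included, pairs, target, w, dict(exclusions)


def _anchor_points(pairs) -> np.ndarray:
    return np.unique(np.asarray(pairs, dtype=float).ravel())


def _solve_reduced(M: np.ndarray, target: np.ndarray, w: np.ndarray,
                   expected_rank: int, context: str):
    Mw = M * w[:, None]
    tw = target * w
    sol, _, rank, sv = np.linalg.lstsq(Mw, tw, rcond=_RANK_RTOL)
    if rank < expected_rank:
        raise UnderdeterminedFitError(
            f"{context}: reduced design has rank {rank}, "
            f"expected {expected_rank}; singular values {sv}"
        )
    cond = float(sv[0] / sv[rank - 1]) if rank > 0 else np.inf
    return sol, cond


def fit_spline(distances: list[DistanceEstimate],
               knots: tuple[float, float] | None = None,
               anchor_policy: str = "mean_zero",
               dy_sign: str = "case_minus_control",
               weights: str | None = None) -> tuple[ShapeCurve, FitReport]:
    """Equality-constrained least-squares fit of the three-cubic spline.

    Minimises the sum of squared differences between observed distances and
    model-implied ``f`` differences over b1..b12 subject to the six smoothness
    constraints, via the nullspace of the constraint matrix. If a knot
    segment contains no pair endpoints the corresponding cubic would be
    unidentified; a warning is emitted and the degree-5 polynomial fit is
    returned instead.
    """
    included, pairs, target, w, exclusions = _prepare(
        distances, dy_sign, weights
    )
    xs = _anchor_points(pairs)
    if xs.size < 4:
        raise InsufficientSupportError(
            f"need at least 4 distinct x values, got {xs.size}"
        )
    domain = (float(xs[0]), float(xs[-1]))
    if knots is None:
        knots = default_knots(xs)
    i, j = knots
    if not i < j:
        raise InsufficientSupportError(f"knots must satisfy i < j, got {knots}")
    occupancy = [int(np.sum(m)) for m in _segment_masks(xs, knots)]
    if min(occupancy) == 0:
        warnings.warn(
            f"segment occupancy {occupancy}: a knot interval contains no pair "
            "endpoints; falling back to the degree-5 polynomial fit",
            stacklevel=2,
        )
        curve, report = fit_polynomial(
            distances, degree=5, anchor_policy=anchor_policy,
            dy_sign=dy_sign, weights=weights,
        )
        return curve, FitReport(
            n_pairs_used=report.n_pairs_used,
            objective_value=report.objective_value,
            condition=report.condition,
            exclusions=report.exclusions,
            kind=report.kind,
            fell_back_to_polynomial=True,
        )
    if len(included) < 6:
        raise InsufficientSupportError(
            f"need at least 6 included distances, got {len(included)}"
        )
    x0 = 0.5 * (domain[0] + domain[1])
    A = spline_design(pairs, knots, x0)
    C = _constraint_matrix(knots, x0)
    N = linalg.null_space(C)  # 12 x 6
    M = A @ N
    # the all-intercepts direction satisfies the constraints and is invisible
    # to pairwise differences, so full identified rank is dim(N) - 1
    z, cond = _solve_reduced(M, target, w, N.shape[1] - 1, "spline fit")
    b = N @ z
    resid = target - A @ b
    objective = float(resid @ resid)
    anchor = 0.0
    if anchor_policy == "mean_zero":
        anchor = float(
            np.mean([np.dot(_basis_row(x, knots, x0), b) for x in xs])
        )
        b = b.copy()
        b[[3, 7, 11]] -= anchor
    curve = ShapeCurve(
        kind="cubic_spline",
        coefficients=tuple(float(v) for v in b),
        domain=domain,
        knots=(float(i), float(j)),
        anchor=anchor,
        x0=x0,
    )
    report = FitReport(
        n_pairs_used=len(included),
        objective_value=objective,
        condition=cond,
        exclusions=exclusions,
        kind="cubic_spline",
    )
    return curve, report


def fit_polynomial(distances: list[DistanceEstimate], degree: int = 5,
                   anchor_policy: str = "mean_zero",
                   dy_sign: str = "case_minus_control",
                   weights: str | None = None) -> tuple[ShapeCurve, FitReport]:
    """Least-squares fit of a single degree-``degree`` polynomial."""
    included, pairs, target, w, exclusions = _prepare(
        distances, dy_sign, weights
    )
    if len(included) < degree + 1:
        raise InsufficientSupportError(
            f"need at least {degree + 1} included distances for degree "
            f"{degree}, got {len(included)}"
        )
    xs = _anchor_points(pairs)
    domain = (float(xs[0]), float(xs[-1]))
    x0 = 0.5 * (domain[0] + domain[1])
    powers = np.arange(degree, 0, -1)
    xa = np.array([p[0] for p in pairs]) - x0
    xb = np.array([p[1] for p in pairs]) - x0
    # intercept column omitted: it cancels in every difference
    M = xb[:, None] ** powers - xa[:, None] ** powers
    z, cond = _solve_reduced(M, target, w, degree, "polynomial fit")
    resid = target - M @ z
    objective = float(resid @ resid)
    coef = np.concatenate([z, [0.0]])
    anchor = 0.0
    if anchor_policy == "mean_zero":
        anchor = float(np.mean(np.polyval(coef, xs - x0)))
        coef[-1] -= anchor
    curve = ShapeCurve(
        kind="polynomial",
        coefficients=tuple(float(v) for v in coef),
        domain=domain,
        anchor=anchor,
        x0=x0,
    )
    report = FitReport(
        n_pairs_used=len(included),
        objective_value=objective,
        condition=cond,
        exclusions=exclusions,
        kind="polynomial",
    )
    return curve, report


def _check_domain(x: np.ndarray, domain) -> np.ndarray:
    lo, hi = domain
    span = max(hi - lo, 1.0)
    if np.any(x < lo - _DOMAIN_EPS * span) or np.any(x > hi + _DOMAIN_EPS * span):
        raise TransformDomainError(
            f"evaluation points outside curve domain [{lo}, {hi}]"
        )
    return np.clip(x, lo, hi)


def evaluate_curve(curve: ShapeCurve, grid) -> np.ndarray:
    """Evaluate the curve on grid points inside its domain (no extrapolation)."""
    scalar = np.isscalar(grid)
    x = _check_domain(np.atleast_1d(np.asarray(grid, dtype=float)),
                      curve.domain)
    u = x - curve.x0
    if curve.kind == "polynomial":
        y = np.polyval(np.asarray(curve.coefficients), u)
    else:
        y = np.empty_like(x)
        for seg, mask in enumerate(_segment_masks(x, curve.knots)):
            c = np.asarray(curve.coefficients[4 * seg: 4 * seg + 4])
            y[mask] = np.polyval(c, u[mask])
    return float(y[0]) if scalar else y
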