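"""Correlation-to-distance transform for bin-pair genetic correlations.

Each bin-pair contrast GWAS yields a genetic correlation ``cor`` with the
outcome trait y, and the pair of bins has a known distance ``dx`` on x. The
ratio ``cor / dx`` is read as the cosine of the angle complementary to the
acute angle of a right triangle with adjacent side ``dx``; the opposite side
of that triangle is the estimated distance on y:

    angle = 90 − acos(cor / dx) · 180/π        (degrees)
    dy    = tan(angle · π/180) · dx

which collapses to the closed form ``dy = dx · c / sqrt(1 − c²)`` with
``c = cor / dx``. The transform is applied literally, so it is deliberately
unit-dependent: changing the scale of x changes the recovered shape, and
users should bin x on a natural scale.

Sign convention: the case of each contrast is the *lower* bin and is coded 1
in the contrast GWAS, so a positive ``cor`` means the lower bin's genetics
align with y and ``dy`` (which inherits the sign of ``cor``) estimates
``f(x_case) − f(x_control)``.

Filtering, applied before the transform and never silently clamped:

* missing ``cor`` (upstream estimation failed)      → ``not_estimated``
* |cor| > 1                                         → ``out_of_bounds``
* |cor / dx| > 1 (possible when dx < 1)             → ``ratio_out_of_domain``
* |cor / dx| = 1 exactly (angle of 90°, dy → ∞)     → ``divergent_distance``

All surviving estimates are retained regardless of their significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import (
    DivergentDistanceError,
    EmptyInputError,
    InadmissibleRatioError,
    TransformDomainError,
)

__all__ = [
    "RgRecord",
    "DistanceEstimate",
    "filter_rg",
    "correlation_to_angle",
    "angle_to_distance",
    "distance_to_correlation",
    "transform_table",
]

#: exclusion reason codes
NOT_ESTIMATED = "not_estimated"
OUT_OF_BOUNDS = "out_of_bounds"
RATIO_OUT_OF_DOMAIN = "ratio_out_of_domain"
DIVERGENT_DISTANCE = "divergent_distance"


@dataclass(frozen=True)
class RgRecord:
    """Genetic correlation of one bin-pair contrast with the outcome trait.

    ``rg`` is NaN when the upstream estimator failed; ``se`` may be NaN for
    point-estimate-only workflows (resampling then refuses the record).
    Extra diagnostic columns from the input table ride along in ``extra``.
    """

    case_bin: int
    control_bin: int
    x_case: float
    x_control: float
    rg: float
    se: float = float("nan")
    extra: tuple = ()

    @property
    def dx(self) -> float:
        return self.x_control - self.x_case

    @property
    def missing(self) -> bool:
        return math.isnan(self.rg)


@dataclass(frozen=True)
class DistanceEstimate:
    """Result of the transform for one record; excluded records carry a reason."""

    case_bin: int
    control_bin: int
    x_case: float
    x_control: float
    dx: float
    rg: float
    se: float
    angle: float  # degrees; NaN when excluded
    dy: float  # f(x_case) − f(x_control) estimate; NaN when excluded
    included: bool
    exclusion_reason: str | None = None


def filter_rg(records: list[RgRecord]) -> list[str | None]:
    """Exclusion reason per record (None = retained), preserving order.

    Only missingness and the |rg| > 1 bound exclude a record; estimates are
    never filtered on significance.
    """
    if not records:
        raise EmptyInputError("no rg records to filter")
    reasons: list[str | None] = []
    for rec in records:
        if rec.missing:
            reasons.append(NOT_ESTIMATED)
        elif abs(rec.rg) > 1.0:
            reasons.append(OUT_OF_BOUNDS)
        else:
            reasons.append(None)
    return reasons


def correlation_to_angle(cor: float, dx: float) -> float:
    """90 − acos(cor/dx)·180/π, in degrees; 0 when cor = 0."""
    if dx <= 0:
        raise TransformDomainError(f"dx must be positive, got {dx}")
    c = cor / dx
    if abs(c) > 1.0:
        raise InadmissibleRatioError(
            f"|cor/dx| = {abs(c)} exceeds 1 (cor={cor}, dx={dx})"
        )
    return 90.0 - math.degrees(math.acos(c))


def angle_to_distance(angle: float, dx: float) -> float:
    """tan(angle·π/180)·dx — the opposite side of the triangle."""
    if dx <= 0:
        raise TransformDomainError(f"dx must be positive, got {dx}")
    if abs(angle) >= 90.0:
        raise DivergentDistanceError(
            f"|angle| = {abs(angle)} >= 90 degrees; distance on y diverges"
        )
    return math.tan(math.radians(angle)) * dx


def distance_to_correlation(dy: float, dx: float) -> float:
    """Exact inverse of the two-step transform: the cor giving this dy.

    From dy = dx·c/sqrt(1−c²) with c = cor/dx it follows that
    c = dy / sqrt(dx² + dy²), hence cor = dx·dy / sqrt(dx² + dy²). Useful for
    constructing correlation tables whose transform reproduces a known curve.
    """
    if dx <= 0:
        raise TransformDomainError(f"dx must be positive, got {dx}")
    return dx * dy / math.hypot(dx, dy)


def transform_table(records: list[RgRecord]) -> list[DistanceEstimate]:
    """Filter then transform a batch; output length always equals input length.

    Per-record domain failures become exclusions with a reason code rather
    than aborting the batch.
    """
    reasons = filter_rg(records)
    out: list[DistanceEstimate] = []
    for rec, reason in zip(records, reasons):
        angle = dy = float("nan")
        if reason is None:
            try:
                angle = correlation_to_angle(rec.rg, rec.dx)
                dy = angle_to_distance(angle, rec.dx)
            except InadmissibleRatioError:
                reason = RATIO_OUT_OF_DOMAIN
                angle = dy = float("nan")
            except DivergentDistanceError:
                reason = DIVERGENT_DISTANCE
                dy = float("nan")
        out.append(
            DistanceEstimate(
                case_bin=rec.case_bin,
                control_bin=rec.control_bin,
                x_case=rec.x_case,
                x_control=rec.x_control,
                dx=rec.dx,
                rg=rec.rg,
                se=rec.se,
                angle=angle,
                dy=dy,
                included=reason is None,
                exclusion_reason=reason,
            )
        )
    return out
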