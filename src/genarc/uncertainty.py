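"""Resampling-based uncertainty for the fitted curve.

Genetic correlations come with standard errors; each resampling cycle redraws
every correlation from Normal(rg, se²), pushes the resampled table through the
full filter → transform → fit pipeline, and evaluates the refitted curve on a
common grid. The default 100 cycles give a bundle of curves from which
pointwise percentile bands (2.5% / 50% / 97.5% by default) are computed.
Resampled correlations that land outside [−1, 1] are excluded by the same
filter as point estimates, never truncated; cycles whose refit fails (e.g.
too many exclusions) are recorded and skipped, not retried.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EnvelopeFailureError, MissingSEError
from .fitting import FitReport, ShapeCurve, evaluate_curve, fit_polynomial, fit_spline
from .transform import RgRecord, transform_table

__all__ = ["CurveEnvelope", "resample_rg", "curve_envelope"]


@dataclass
class CurveEnvelope:
    """Bundle of resampled curves plus pointwise bands on a shared grid."""

    grid: np.ndarray
    curves: np.ndarray  # (n_success, len(grid))
    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray
    point_curve: ShapeCurve
    point_report: FitReport
    B: int
    seed: int | None
    n_failed: int
    quantiles: tuple[float, float]

    @property
    def n_curves(self) -> int:
        return self.curves.shape[0]

    @property
    def half_width(self) -> np.ndarray:
        return 0.5 * (self.upper - self.lower)


def resample_rg(records: list[RgRecord],
                rng: np.random.Generator | int) -> list[RgRecord]:
    """Redraw each estimated rg from Normal(rg, se²), independently.

    Records whose rg is missing are passed through unchanged (they stay
    excluded downstream). A record with an estimate but no finite se cannot
    be resampled and raises :class:`MissingSEError`.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: list[RgRecord] = []
    for rec in records:
        if rec.missing:
            out.append(rec)
            continue
        if not math.isfinite(rec.se) or rec.se < 0:
            raise MissingSEError(
                f"record ({rec.case_bin},{rec.control_bin}) has no finite "
                f"standard error (se={rec.se})"
            )
        new_rg = float(rng.normal(rec.rg, rec.se)) if rec.se > 0 else rec.rg
        out.append(
            RgRecord(
                case_bin=rec.case_bin,
                control_bin=rec.control_bin,
                x_case=rec.x_case,
                x_control=rec.x_control,
                rg=new_rg,
                se=rec.se,
                extra=rec.extra,
            )
        )
    return out


def curve_envelope(records: list[RgRecord],
                   B: int = 100,
                   seed: int | None = None,
                   kind: str = "cubic_spline",
                   knots: tuple[float, float] | None = None,
                   degree: int = 5,
                   anchor_policy: str = "mean_zero",
                   dy_sign: str = "case_minus_control",
                   weights: str | None = None,
                   grid_size: int = 200,
                   quantiles: tuple[float, float] = (2.5, 97.5),
                   ) -> CurveEnvelope:
    """Point fit plus ``B`` resample → transform → refit cycles.

    The point-estimate fit fixes the evaluation grid (and, for the spline,
    the knots) so every resampled curve is comparable pointwise. Raises
    :class:`EnvelopeFailureError` when more than half the refits fail.
    """

    def _fit(recs):
        dists = transform_table(recs)
        if kind == "cubic_spline":
            return fit_spline(dists, knots=fit_knots, dy_sign=dy_sign,
                              anchor_policy=anchor_policy, weights=weights)
        return fit_polynomial(dists, degree=degree, dy_sign=dy_sign,
                              anchor_policy=anchor_policy, weights=weights)

    fit_knots = knots
    point_curve, point_report = _fit(records)
    if kind == "cubic_spline" and fit_knots is None:
        fit_knots = point_curve.knots  # may be None after polynomial fallback
    grid = np.linspace(point_curve.domain[0], point_curve.domain[1], grid_size)
    rng = np.random.default_rng(seed)
    curves, failures = [], []
    for b in range(B):
        resampled = resample_rg(records, rng)
        try:
            curve_b, _ = _fit(resampled)
            curves.append(evaluate_curve(curve_b, grid))
        except Exception as exc:  # refit failures are recorded, not retried
            failures.append((b, repr(exc)))
    if len(failures) > B / 2:
        raise EnvelopeFailureError(
            f"{len(failures)} of {B} envelope refits failed; first failures: "
            f"{failures[:5]}"
        )
    stack = np.vstack(curves)
    lo_q, hi_q = quantiles
    return CurveEnvelope(
        grid=grid,
        curves=stack,
        lower=np.percentile(stack, lo_q, axis=0),
        median=np.percentile(stack, 50.0, axis=0),
        upper=np.percentile(stack, hi_q, axis=0),
        point_curve=point_curve,
        point_report=point_report,
        B=B,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
        n_failed=len(failures),
        quantiles=quantiles,
    )
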