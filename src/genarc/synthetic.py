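"""Exact synthetic distance / correlation tables from a known curve.

Given a generating function f on bin representative values, these builders
produce tables whose transform reproduces f's pairwise differences exactly
(using the closed-form inverse cor = dx·dy/sqrt(dx² + dy²)). They are the
noiseless oracles used to validate the fitting stage and to seed resampling
demonstrations without running the cohort simulator.
"""

from __future__ import annotations

import itertools

from .transform import DistanceEstimate, RgRecord, distance_to_correlation

__all__ = ["distances_noiseless", "rg_from_curve"]


def distances_noiseless(fn, xs, dy_sign: str = "case_minus_control",
                        se: float = 0.05) -> list[DistanceEstimate]:
    """All-pairs DistanceEstimates with dy generated exactly from ``fn``."""
    out = []
    for a, b in itertools.combinations(range(len(xs)), 2):
        xa, xb = float(xs[a]), float(xs[b])
        diff = fn(xa) - fn(xb)
        dy = diff if dy_sign == "case_minus_control" else -diff
        out.append(
            DistanceEstimate(
                case_bin=a + 1, control_bin=b + 1, x_case=xa, x_control=xb,
                dx=xb - xa, rg=float("nan"), se=se, angle=0.0, dy=dy,
                included=True, exclusion_reason=None,
            )
        )
    return out


def rg_from_curve(fn, xs, se: float = 0.05) -> list[RgRecord]:
    """All-pairs RgRecords whose transform yields fn's differences exactly."""
    out = []
    for a, b in itertools.combinations(range(len(xs)), 2):
        xa, xb = float(xs[a]), float(xs[b])
        cor = distance_to_correlation(fn(xa) - fn(xb), xb - xa)
        out.append(
            RgRecord(case_bin=a + 1, control_bin=b + 1, x_case=xa,
                     x_control=xb, rg=cor, se=se)
        )
    return out
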