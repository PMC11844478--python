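"""Quantile and value bin schemes for a continuous trait.

A continuous trait x is partitioned into K ordered bins, either by empirical
quantile position (``assign_bins``, e.g. the 30-bin BMI design that emphasises
the distribution tails) or by fixed cut values on the trait's natural scale
(``value_bins``, e.g. hours slept). Each bin carries a representative value
(by default the median of its members), and every ordered pair of bins defines
one case/control contrast whose x-distance ``dx`` feeds the correlation-to-
distance transform downstream.

Conventions, chosen for deterministic, order-independent assignment:

* empirical quantile at level q is the sorted value at rank ``ceil(q * n)``;
* a value falling exactly on a bin edge belongs to the lower bin;
* the lower-x bin of a pair is the case, the higher-x bin the control.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateBinningError,
    InvalidSchemeError,
    OrderingError,
)

__all__ = [
    "BinScheme",
    "BinTable",
    "BinPairContrast",
    "BMI_30_WIDTHS",
    "build_scheme",
    "assign_bins",
    "value_bins",
    "enumerate_contrasts",
    "contrasts_frame",
]

#: Tail-emphasising 30-bin width scheme (percent): 2 half-percentile bins,
#: 4 one-percentile bins, 18 five-percentile bins, then mirrored.
BMI_30_WIDTHS: tuple[float, ...] = (
    0.5, 0.5, 1.0, 1.0, 1.0, 1.0,
    *([5.0] * 18),
    1.0, 1.0, 1.0, 1.0, 0.5, 0.5,
)

_WIDTH_TOL = 1e-9


@dataclass(frozen=True)
class BinScheme:
    """Ordered quantile widths (percent) partitioning 0-100%."""

    widths: tuple[float, ...]

    @property
    def n_bins(self) -> int:
        return len(self.widths)

    @property
    def edges(self) -> np.ndarray:
        """Cumulative quantile edges in percent, length K + 1, from 0 to 100."""
        return np.concatenate([[0.0], np.cumsum(self.widths)])


@dataclass(frozen=True)
class BinPairContrast:
    """One case/control pairing of two bins.

    The case is the lower-x bin, the control the higher-x bin (the higher bin
    serves as the control group in the contrast association design).
    """

    case_bin: int
    control_bin: int
    x_case: float
    x_control: float
    dx: float = field(default=float("nan"))

    def __post_init__(self):
        if self.case_bin >= self.control_bin:
            raise OrderingError(
                f"case_bin {self.case_bin} must be below control_bin {self.control_bin}"
            )
        dx = self.x_control - self.x_case
        if math.isnan(self.dx):
            object.__setattr__(self, "dx", dx)
        if self.dx <= 0:
            raise OrderingError(f"dx must be positive, got {self.dx}")


@dataclass
class BinTable:
    """Per-bin summary plus the per-individual assignment vector.

    ``bins`` columns: bin (1..K), q_lo, q_hi (percent for quantile schemes,
    trait-value bounds for value schemes), n, x_rep, x_min, x_max.
    """

    bins: pd.DataFrame
    assignments: np.ndarray
    scheme: BinScheme | None = None
    edges: tuple[float, ...] | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def x_rep(self) -> np.ndarray:
        return self.bins["x_rep"].to_numpy()


def build_scheme(widths) -> BinScheme:
    """Validate quantile widths (percent) and return a :class:`BinScheme`.

    Raises :class:`InvalidSchemeError` if any width is non-positive or the
    widths do not sum to 100 within 1e-9.
    """
    widths = tuple(float(w) for w in widths)
    if len(widths) < 2:
        raise InvalidSchemeError("a scheme needs at least 2 bins")
    if any(w <= 0 for w in widths):
        raise InvalidSchemeError(f"all widths must be positive, got {widths}")
    total = math.fsum(widths)
    if abs(total - 100.0) > _WIDTH_TOL:
        raise InvalidSchemeError(f"widths sum to {total!r}, expected 100")
    return BinScheme(widths)


def _representative(members: np.ndarray, lo: float, hi: float, index: int,
                    kind: str) -> float:
    if kind == "median":
        return float(np.median(members))
    if kind == "midpoint":
        return 0.5 * (lo + hi)
    if kind == "index":
        return float(index)
    raise ValueError(f"unknown representative kind {kind!r}")


def _summarize(values: np.ndarray, assignment: np.ndarray, k: int,
               lo_bounds, hi_bounds, representative: str,
               min_count: int) -> pd.DataFrame:
    rows = []
    for b in range(1, k + 1):
        members = values[assignment == b]
        if members.size == 0:
            raise DegenerateBinningError(f"bin {b} of {k} received no members")
        if members.size < min_count:
            warnings.warn(
                f"bin {b} has only {members.size} members (< {min_count})",
                stacklevel=3,
            )
        rows.append(
            dict(
                bin=b,
                q_lo=lo_bounds[b - 1],
                q_hi=hi_bounds[b - 1],
                n=int(members.size),
                x_rep=_representative(members, lo_bounds[b - 1],
                                      hi_bounds[b - 1], b, representative),
                x_min=float(members.min()),
                x_max=float(members.max()),
            )
        )
    return pd.DataFrame(rows)


def assign_bins(values, scheme: BinScheme, representative: str = "median",
                min_count: int = 100) -> BinTable:
    """Assign each value to a quantile bin of ``scheme``.

    The cut value for cumulative quantile q (fraction) is the sorted value at
    rank ``ceil(q * n)``; ties on a cut go to the lower bin. Raises
    :class:`DegenerateBinningError` when heavy ties empty a bin.
    """
    values = np.asarray(values, dtype=float)
    k = scheme.n_bins
    if values.ndim != 1 or values.size < k:
        raise DegenerateBinningError(
            f"need at least {k} values for {k} bins, got {values.size}"
        )
    srt = np.sort(values)
    n = values.size
    qs = scheme.edges[1:-1] / 100.0  # interior cumulative quantiles
    ranks = np.ceil(qs * n).astype(int) - 1
    cuts = srt[ranks]
    # value <= cut  ->  lower bin
    assignment = np.searchsorted(cuts, values, side="left") + 1
    edges_pct = scheme.edges
    bins = _summarize(values, assignment, k, edges_pct[:-1], edges_pct[1:],
                      representative, min_count)
    return BinTable(bins=bins, assignments=assignment, scheme=scheme)


def value_bins(values, edges, representative: str = "median",
               min_count: int = 100) -> BinTable:
    """Bin by fixed cut values on the trait's own scale.

    ``edges`` (strictly increasing, length L) induce L + 2 categories: below
    the first edge, one category starting at each edge, and above the last
    edge. E.g. sleep-hour edges 4..10 give the 9 categories
    <4, 4, 5, 6, 7, 8, 9, 10, >10.
    """
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 1:
        raise InvalidSchemeError("need at least one edge value")
    if np.any(np.diff(edges) <= 0):
        raise InvalidSchemeError("edges must be strictly increasing")
    k = edges.size + 2
    assignment = np.searchsorted(edges, values, side="right") + 1
    assignment[values > edges[-1]] = k
    lo = np.concatenate([[-np.inf], edges, [edges[-1]]])
    hi = np.concatenate([edges, [edges[-1]], [np.inf]])
    bins = _summarize(values, assignment, k, lo, hi, representative, min_count)
    return BinTable(bins=bins, assignments=assignment,
                    edges=tuple(float(e) for e in edges))


def enumerate_contrasts(bin_table: BinTable) -> list[BinPairContrast]:
    """All K·(K−1)/2 ordered bin pairs, lower bin as case.

    Raises :class:`OrderingError` when representative values are not strictly
    increasing with bin index (the pairwise distances would be ill-defined).
    """
    reps = bin_table.x_rep
    if bin_table.n_bins < 2:
        raise OrderingError("need at least 2 bins to form a contrast")
    if np.any(np.diff(reps) <= 0):
        raise OrderingError(
            "bin representative values must be strictly increasing"
        )
    idx = bin_table.bins["bin"].to_numpy()
    return [
        BinPairContrast(
            case_bin=int(idx[a]),
            control_bin=int(idx[b]),
            x_case=float(reps[a]),
            x_control=float(reps[b]),
        )
        for a, b in itertools.combinations(range(bin_table.n_bins), 2)
    ]


def contrasts_frame(contrasts: list[BinPairContrast]) -> pd.DataFrame:
    """Contrast manifest: case_bin, control_bin, x_case, x_control, dx."""
    return pd.DataFrame(
        [
            dict(case_bin=c.case_bin, control_bin=c.control_bin,
                 x_case=c.x_case, x_control=c.x_control, dx=c.dx)
            for c in contrasts
        ]
    )
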