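"""Polygenic two-trait simulator for end-to-end validation.

Each of n individuals carries m independent biallelic variants (dosages
0/1/2, allele frequencies uniform on (0.05, 0.95), linkage equilibrium). Both
traits are sums of additive genetic and environmental parts, x = a_x + e_x
and y = a_y + e_y, with var(a_x)/var(x) = h2x and a_y built from standardized
polygenic scores so true per-variant effect vectors on y exist exactly.

Couplings between the genetic components of x and y:

``null``
    a_y is an independent polygenic score; the recovered curve should be flat.
``linear``
    a_y = ρ·ā_x + sqrt(1−ρ²)·u with ρ = ``coupling_strength``; every bin-pair
    contrast shares the same population genetic correlation with y and the
    recovered curve is monotone.
``quadratic`` and ``two_tail``
    Detectable nonlinearity requires genetic effects on x that are
    heterogeneous across x (with fully homogeneous additive effects, every
    bin contrast tags the same effect vector and the method is blind — the
    homogeneity property tested below). Both scenarios therefore couple two
    y-component scores a_s and a_l to x through one-sided hinge
    dose-responses: a_s pushes x *down* only when a_s > 0, a_l pushes x *up*
    only when a_l > 0, and a_y loads on a_s + a_l. Individuals in the low
    tail of x are strongly enriched for a_s but only boundedly depleted of
    a_l (and symmetrically for the high tail), so both tails' contrast GWASs
    correlate with y and the recovered conditional-expectation curve is
    convex / U-shaped. ``two_tail`` assigns a_s and a_l disjoint variant sets
    (two distinct genetic aetiologies, emulating the short-sleep /
    long-sleep structure); ``quadratic`` lets them share the variant panel,
    giving a smooth approximately quadratic E[a_y | a_x].

Genetic correlations are estimated as the Pearson correlation between the
contrast effect vector and the (true, by default) y effect vector across
variants — valid in linkage equilibrium — with a delete-one-block jackknife
standard error, exercising the same (rg, se) interface as summary-statistic
estimators without reference panels.

x is reported on a BMI-like natural scale (mean 25, sd 4 by default): the
correlation-to-distance transform is deliberately scale dependent, and on a
unit-sd scale adjacent decile bins would sit closer than typical correlation
noise (|cor/dx| > 1).

All randomness flows from ``scenario.seed`` through a SeedSequence; identical
seeds reproduce cohorts, rg tables and envelopes bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binning import (
    BinPairContrast,
    BinScheme,
    BinTable,
    assign_bins,
    build_scheme,
    enumerate_contrasts,
)
from .errors import ScenarioError
from .fitting import FitReport, ShapeCurve
from .transform import DistanceEstimate, RgRecord, transform_table
from .uncertainty import CurveEnvelope, curve_envelope

__all__ = [
    "SimScenario",
    "Cohort",
    "ContrastEffects",
    "EndToEndResult",
    "simulate_cohort",
    "contrast_association",
    "estimate_rg",
    "rg_table",
    "run_end_to_end",
]

COUPLINGS = ("linear", "quadratic", "two_tail", "null")

# population moments of the hinge max(a, 0) for standard normal a
_HINGE_MEAN = 1.0 / math.sqrt(2.0 * math.pi)
_HINGE_SD = math.sqrt(0.5 - _HINGE_MEAN ** 2)
#: cor(a, standardized hinge(a)) — the linear share of the hinge channel
HINGE_LINEAR_COR = 0.5 / _HINGE_SD


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for one synthetic cohort."""

    n: int = 20_000
    m: int = 2_000
    h2x: float = 0.5
    coupling: str = "quadratic"
    coupling_strength: float = 0.5
    noise_sd_y: float = 1.0
    seed: int = 0
    bins: int | tuple[float, ...] = 10  # K equal quantile bins, or widths
    x_mean: float = 25.0
    x_sd: float = 4.0
    representative: str = "median"

    def scheme(self) -> BinScheme:
        if isinstance(self.bins, int):
            return build_scheme([100.0 / self.bins] * self.bins)
        return build_scheme(self.bins)

    def validate(self) -> None:
        if not 0.0 < self.h2x < 1.0:
            raise ScenarioError(f"h2x must be in (0,1), got {self.h2x}")
        if self.coupling not in COUPLINGS:
            raise ScenarioError(
                f"coupling must be one of {COUPLINGS}, got {self.coupling!r}"
            )
        if self.m < 200:
            raise ScenarioError(f"m must be at least 200, got {self.m}")
        k = self.scheme().n_bins
        if self.n < 50 * k:
            raise ScenarioError(
                f"n = {self.n} too small for {k} bins (need >= {50 * k})"
            )
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ScenarioError(
                "coupling_strength must be in [0, 1], got "
                f"{self.coupling_strength}"
            )
        if self.noise_sd_y < 0 or self.x_sd <= 0:
            raise ScenarioError("noise_sd_y must be >= 0 and x_sd > 0")


@dataclass
class Cohort:
    """A realized synthetic cohort with its generative bookkeeping."""

    scenario: SimScenario
    genotypes: np.ndarray  # (n, m) int8 dosages
    freqs: np.ndarray
    x: np.ndarray
    y: np.ndarray
    a_x: np.ndarray
    e_x: np.ndarray
    a_y: np.ndarray
    e_y: np.ndarray
    #: additive projection of a_x onto standardized dosages (trait units)
    x_effects: np.ndarray
    #: exact per-variant additive effects on a_y (standardized dosages)
    y_effects: np.ndarray


@dataclass
class ContrastEffects:
    """Per-variant association slopes for one bin-pair contrast."""

    contrast: BinPairContrast
    beta: np.ndarray
    monomorphic: np.ndarray  # bool mask; beta forced to 0 there
    n_case: int
    n_control: int


@dataclass
class EndToEndResult:
    cohort: Cohort
    bin_table: BinTable
    contrasts: list[BinPairContrast]
    records: list[RgRecord]
    distances: list[DistanceEstimate]
    curve: ShapeCurve
    report: FitReport
    envelope: CurveEnvelope


def _seed_children(seed: int) -> tuple[np.random.SeedSequence, ...]:
    return tuple(np.random.SeedSequence(seed).spawn(2))


def _unit_weights(rng: np.random.Generator, m: int,
                  support: slice | None = None) -> np.ndarray:
    w = np.zeros(m)
    sl = support if support is not None else slice(0, m)
    raw = rng.normal(size=sl.stop - sl.start)
    w[sl] = raw / np.linalg.norm(raw)
    return w


def _scores(G: np.ndarray, freqs: np.ndarray, W: np.ndarray,
            chunk: int = 4096) -> np.ndarray:
    """Standardized-genotype polygenic scores, computed in row chunks."""
    center = 2.0 * freqs
    scale = np.sqrt(2.0 * freqs * (1.0 - freqs))
    Ws = W / scale[:, None]
    offset = center @ Ws
    n = G.shape[0]
    out = np.empty((n, W.shape[1]))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        out[lo:hi] = G[lo:hi].astype(np.float64) @ Ws
    return out - offset


def _hinge(a: np.ndarray) -> np.ndarray:
    return (np.maximum(a, 0.0) - _HINGE_MEAN) / _HINGE_SD


def simulate_cohort(scenario: SimScenario) -> Cohort:
    """Draw genotypes, build both traits under the scenario's coupling."""
    scenario.validate()
    rng = np.random.default_rng(_seed_children(scenario.seed)[0])
    n, m = scenario.n, scenario.m
    freqs = rng.uniform(0.05, 0.95, size=m)
    G = rng.binomial(2, freqs, size=(n, m)).astype(np.int8)

    w0 = _unit_weights(rng, m)
    wu = _unit_weights(rng, m)
    cs = scenario.coupling_strength
    h2x = scenario.h2x

    if scenario.coupling in ("quadratic", "two_tail"):
        if scenario.coupling == "two_tail":
            half = m // 2
            ws = _unit_weights(rng, m, slice(0, half))
            wl = _unit_weights(rng, m, slice(half, m))
        else:
            ws = _unit_weights(rng, m)
            wl = _unit_weights(rng, m)
        a0, au, a_s, a_l = _scores(G, freqs, np.column_stack(
            [w0, wu, ws, wl])).T
        ax_std = (math.sqrt(1.0 - cs) * a0
                  + math.sqrt(cs / 2.0) * (_hinge(a_l) - _hinge(a_s)))
        a_y = (math.sqrt(cs / 2.0) * (a_s + a_l)
               + math.sqrt(1.0 - cs) * au)
        y_eff = (math.sqrt(cs / 2.0) * (ws + wl)
                 + math.sqrt(1.0 - cs) * wu)
        x_eff_std = (math.sqrt(1.0 - cs) * w0
                     + math.sqrt(cs / 2.0) * HINGE_LINEAR_COR * (wl - ws))
    elif scenario.coupling == "linear":
        a0, au = _scores(G, freqs, np.column_stack([w0, wu])).T
        ax_std = a0
        a_y = cs * a0 + math.sqrt(1.0 - cs ** 2) * au
        y_eff = cs * w0 + math.sqrt(1.0 - cs ** 2) * wu
        x_eff_std = w0
    else:  # null
        a0, au = _scores(G, freqs, np.column_stack([w0, wu])).T
        ax_std = a0
        a_y = au
        y_eff = wu
        x_eff_std = w0

    gx_scale = scenario.x_sd * math.sqrt(h2x)
    a_x = gx_scale * ax_std
    e_x = scenario.x_sd * math.sqrt(1.0 - h2x) * rng.normal(size=n)
    x = scenario.x_mean + a_x + e_x
    e_y = scenario.noise_sd_y * rng.normal(size=n)
    y = a_y + e_y
    return Cohort(
        scenario=scenario,
        genotypes=G,
        freqs=freqs,
        x=x,
        y=y,
        a_x=a_x,
        e_x=e_x,
        a_y=a_y,
        e_y=e_y,
        x_effects=gx_scale * x_eff_std,
        y_effects=y_eff,
    )


def contrast_association(cohort: Cohort, assignments: np.ndarray,
                         contrast: BinPairContrast) -> ContrastEffects:
    """Per-variant slope of case/control membership regressed on dosage.

    Members of the lower bin are the cases (coded 1), members of the higher
    bin the controls (coded 0); all other individuals are excluded. Variants
    monomorphic within the pair subsample get slope 0 and a flag.
    """
    mask = (assignments == contrast.case_bin) | \
           (assignments == contrast.control_bin)
    if not mask.any():
        raise ScenarioError(
            f"bins {contrast.case_bin}/{contrast.control_bin} are empty"
        )
    Gs = cohort.genotypes[mask].astype(np.float64)
    member = (assignments[mask] == contrast.case_bin).astype(np.float64)
    n_case = int(member.sum())
    n_pair = member.size
    if n_case == 0 or n_case == n_pair:
        raise ScenarioError(
            f"contrast {contrast.case_bin} vs {contrast.control_bin} has an "
            "empty case or control group"
        )
    g_mean = Gs.mean(axis=0)
    y_c = member - member.mean()
    num = y_c @ Gs  # equals sum(y_c * (g - g_mean))
    den = np.einsum("ij,ij->j", Gs, Gs) - n_pair * g_mean ** 2
    mono = den <= 0
    beta = np.zeros(Gs.shape[1])
    np.divide(num, den, out=beta, where=~mono)
    return ContrastEffects(
        contrast=contrast,
        beta=beta,
        monomorphic=mono,
        n_case=n_case,
        n_control=n_pair - n_case,
    )


def estimate_rg(contrast_effects, y_effects, n_blocks: int = 20
                ) -> tuple[float, float]:
    """Correlation of two effect vectors with a block-jackknife SE.

    Valid as a genetic-correlation estimate because simulated variants are in
    linkage equilibrium. Returns (nan, nan) when either vector has zero
    variance (the record is then flagged ``not_estimated`` downstream).
    """
    a = np.asarray(
        contrast_effects.beta
        if isinstance(contrast_effects, ContrastEffects)
        else contrast_effects,
        dtype=float,
    )
    b = np.asarray(y_effects, dtype=float)
    m = a.size
    if m != b.size:
        raise ValueError("effect vectors must have equal length")
    if m < 10 * n_blocks:
        raise ValueError(
            f"m = {m} too small for {n_blocks} jackknife blocks (need >= "
            f"{10 * n_blocks})"
        )

    def _corr(sa, sb, saa, sbb, sab, k):
        va = saa - sa * sa / k
        vb = sbb - sb * sb / k
        if va <= 0 or vb <= 0:
            return float("nan")
        return (sab - sa * sb / k) / math.sqrt(va * vb)

    sa, sb = a.sum(), b.sum()
    saa, sbb, sab = a @ a, b @ b, a @ b
    rg = _corr(sa, sb, saa, sbb, sab, m)
    if math.isnan(rg):
        return float("nan"), float("nan")
    blocks = np.array_split(np.arange(m), n_blocks)
    loo = np.empty(n_blocks)
    for i, idx in enumerate(blocks):
        ab, bb = a[idx], b[idx]
        loo[i] = _corr(sa - ab.sum(), sb - bb.sum(), saa - ab @ ab,
                       sbb - bb @ bb, sab - ab @ bb, m - idx.size)
    if np.any(np.isnan(loo)):
        return float("nan"), float("nan")
    se = math.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2))
    return float(rg), float(se)


def rg_table(cohort: Cohort, bin_table: BinTable,
             contrasts: list[BinPairContrast] | None = None,
             n_blocks: int = 20) -> list[RgRecord]:
    """Contrast associations + rg estimates for every bin pair."""
    if contrasts is None:
        contrasts = enumerate_contrasts(bin_table)
    records = []
    for c in contrasts:
        eff = contrast_association(cohort, bin_table.assignments, c)
        rg, se = estimate_rg(eff, cohort.y_effects, n_blocks=n_blocks)
        records.append(
            RgRecord(case_bin=c.case_bin, control_bin=c.control_bin,
                     x_case=c.x_case, x_control=c.x_control, rg=rg, se=se)
        )
    return records


def run_end_to_end(scenario: SimScenario,
                   kind: str = "cubic_spline",
                   B: int = 100,
                   n_blocks: int = 20,
                   grid_size: int = 200,
                   min_count: int = 100,
                   **fit_options) -> EndToEndResult:
    """simulate → bin → contrast GWAS → rg table → transform → fit → envelope."""
    scenario.validate()
    cohort = simulate_cohort(scenario)
    table = assign_bins(cohort.x, scenario.scheme(),
                        representative=scenario.representative,
                        min_count=min_count)
    contrasts = enumerate_contrasts(table)
    records = rg_table(cohort, table, contrasts, n_blocks=n_blocks)
    distances = transform_table(records)
    env = curve_envelope(records, B=B, kind=kind, grid_size=grid_size,
                         seed=_seed_children(scenario.seed)[1],
                         **fit_options)
    return EndToEndResult(
        cohort=cohort,
        bin_table=table,
        contrasts=contrasts,
        records=records,
        distances=distances,
        curve=env.point_curve,
        report=env.point_report,
        envelope=env,
    )
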