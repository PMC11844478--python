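"""Shared fixtures and oracle helpers.

The distance/record builders construct tables whose transform reproduces a
chosen generating function exactly (via the closed-form inverse
cor = dx·dy/sqrt(dx²+dy²)), so fitting tests have analytically known truth.
Session-scoped end-to-end simulation results are shared between the
scenario-level tests and the acceptance suite.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

import genarc as g
from genarc.transform import DistanceEstimate, RgRecord, distance_to_correlation

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

ACCEPT_SEED = 1  # fixed seed for the simulation-based checks


def make_distances(fn, xs, dy_sign="case_minus_control", se=0.05):
    """Noiseless DistanceEstimates from a generating function fn on points xs."""
    out = []
    for a, b in itertools.combinations(range(len(xs)), 2):
        xa, xb = float(xs[a]), float(xs[b])
        diff = fn(xa) - fn(xb)  # f(case) − f(control)
        dy = diff if dy_sign == "case_minus_control" else -diff
        out.append(
            DistanceEstimate(
                case_bin=a + 1, control_bin=b + 1, x_case=xa, x_control=xb,
                dx=xb - xa, rg=float("nan"), se=se, angle=0.0, dy=dy,
                included=True, exclusion_reason=None,
            )
        )
    return out


def make_rg_records(fn, xs, se=0.05):
    """RgRecords whose transform yields dy = fn(x_case) − fn(x_control) exactly."""
    out = []
    for a, b in itertools.combinations(range(len(xs)), 2):
        xa, xb = float(xs[a]), float(xs[b])
        dy = fn(xa) - fn(xb)
        cor = distance_to_correlation(dy, xb - xa)
        out.append(
            RgRecord(case_bin=a + 1, control_bin=b + 1, x_case=xa,
                     x_control=xb, rg=cor, se=se)
        )
    return out


def _run(coupling, **kw):
    scen = g.SimScenario(coupling=coupling, seed=ACCEPT_SEED, **kw)
    return g.run_end_to_end(scen, min_count=1)


@pytest.fixture(scope="session")
def quadratic_result():
    return _run("quadratic")


@pytest.fixture(scope="session")
def two_tail_result():
    return _run("two_tail")


@pytest.fixture(scope="session")
def null_result():
    return _run("null")


@pytest.fixture(scope="session")
def linear_result():
    return _run("linear")


@pytest.fixture(scope="session")
def homogeneous_contrast_betas():
    """Contrast effect vectors under a fully homogeneous additive architecture.

    Power-adequate configuration (few variants, large bins) so that vector
    correlations are attenuated only negligibly by GWAS sampling noise.
    """
    scen = g.SimScenario(n=40_000, m=200, h2x=0.8, coupling="null", bins=3,
                         seed=ACCEPT_SEED)
    cohort = g.simulate_cohort(scen)
    table = g.assign_bins(cohort.x, scen.scheme(), min_count=1)
    contrasts = g.enumerate_contrasts(table)
    return [
        g.contrast_association(cohort, table.assignments, c).beta
        for c in contrasts
    ]
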