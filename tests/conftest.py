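"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results from first principles
(explicit matrix algebra, step-up enumeration, exhaustive draws) so the
package implementations are checked against an independent route.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import ewaskit as ek

# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def ols_sandwich_oracle(y, X, kind="HC0"):
    """Explicit-matrix OLS + sandwich covariance; returns (coef, cov)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ y
    e = y - X @ coef
    H = X @ xtx_inv @ X.T
    h = np.diag(H)
    if kind == "HC0":
        omega = e**2
    elif kind == "HC1":
        omega = e**2 * n / (n - k)
    elif kind == "HC3":
        omega = e**2 / (1 - h) ** 2
    elif kind == "classical":
        return coef, float(e @ e) / (n - k) * xtx_inv
    else:
        raise ValueError(kind)
    meat = X.T @ np.diag(omega) @ X
    return coef, xtx_inv @ meat @ xtx_inv


def stepup_oracle(p, alpha, cm=1.0):
    """Step-up rejection set by direct enumeration (cm=1: BH; harmonic sum: BY)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    rejected = np.zeros(m, dtype=bool)
    k_max = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * alpha / (m * cm):
            k_max = i
    rejected[order[:k_max]] = True
    return rejected


def qvalues_oracle(p, cm=1.0):
    """Step-up adjusted p-values by direct enumeration."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for i in range(m, 0, -1):
        running = min(running, p[order[i - 1]] * m * cm / i)
        q[order[i - 1]] = min(running, 1.0)
    return q


def cis_pairs_oracle(snp_manifest, cpg_manifest, window):
    """All-pairs filter for the cis window."""
    rows = []
    for snp in snp_manifest.itertuples(index=False):
        for cpg in cpg_manifest.itertuples(index=False):
            if snp.chrom == cpg.chrom and abs(int(snp.pos) - int(cpg.pos)) <= window:
                rows.append((snp.snp_id, cpg.probe_id, abs(int(snp.pos) - int(cpg.pos))))
    return sorted(rows)


def overlap_test_enumeration(query, targets, keep, pool, size):
    """Exact empirical-p: fraction of all same-size pools draws with count >= observed,
    folded through the +1 pseudocount limit (returns the exact tail probability)."""

    def count(snps):
        hit = set()
        for s in snps:
            for c in targets.get(s, ()):
                if keep is None or c in keep:
                    hit.add(c)
        return len(hit)

    observed = count(query)
    draws = list(itertools.combinations(pool, size))
    tail = sum(count(d) >= observed for d in draws)
    return observed, tail / len(draws)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_manifest():
    return ek.simulate_manifest(1200, n_chrom=6, seed=11)


@pytest.fixture(scope="session")
def planted_probe(small_manifest):
    return small_manifest.loc[small_manifest.on_450k, "probe_id"].iloc[12]


@pytest.fixture(scope="session")
def small_cohort(small_manifest, planted_probe):
    spec = ek.CohortSpec(
        "unit", "EA", 250, planted_dmps=((planted_probe, -30.0),), seed=21
    )
    return ek.generate_cohort(spec, small_manifest)


# A fixed 12-observation regression problem: eGFR outcome, one beta predictor,
# two covariates.  Values are printed literals so the sandwich oracle check is
# exactly reproducible.
TWELVE_OBS = dict(
    y=np.array([78.2, 91.5, 66.0, 85.3, 72.9, 95.1, 60.4, 88.8, 70.2, 82.6, 76.4, 93.0]),
    x=np.array([0.61, 0.35, 0.82, 0.44, 0.70, 0.28, 0.91, 0.39, 0.75, 0.52, 0.63, 0.31]),
    w1=np.array([52.0, 61.0, 70.0, 48.0, 66.0, 55.0, 73.0, 50.0, 68.0, 59.0, 63.0, 46.0]),
    w2=np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0]),
)


@pytest.fixture(scope="session")
def twelve_obs():
    return TWELVE_OBS
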