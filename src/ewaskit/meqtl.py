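"""Cis-meQTL scanning on M-values and empirical SNP/CpG/interval overlap tests.

The cis scan regresses each CpG's M-values on SNP dosage (additive coding)
plus covariates within a +/-1 Mb same-chromosome window (boundary inclusive),
reporting the least-squares slope in M-units per allele with its classical
standard error and a two-sided p from the t reference.

The overlap tests mirror the GWAS-integration procedure: given a query SNP
set, count the distinct CpGs that are significant meQTL targets of at least
one query SNP and that (a) belong to an EWAS DMP set, or (b) fall inside a
tissue's open-chromatin intervals; then re-draw equally sized SNP sets from a
background pool and recompute the statistic, yielding an empirical p with a
+1 pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CisWindowSpec:
    """Cis window around each CpG/SNP position; boundary inclusive."""

    window: int = 1_000_000

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("cis window must be positive")


@dataclass
class OverlapTestResult:
    observed: int
    n_background_sets: int
    background_mean: float
    background_sd: float
    empirical_p: float
    statistic: str


# ---------------------------------------------------------------------------
# Cis pairing
# ---------------------------------------------------------------------------


def cis_pairs(
    snp_manifest: pd.DataFrame,
    cpg_manifest: pd.DataFrame,
    window_spec: CisWindowSpec | int = CisWindowSpec(),
) -> pd.DataFrame:
    """All same-chromosome SNP-CpG pairs with |distance| <= window (inclusive)."""
    window = window_spec.window if isinstance(window_spec, CisWindowSpec) else int(window_spec)
    rows = []
    cpg_by_chrom = {c: sub.sort_values("pos") for c, sub in cpg_manifest.groupby("chrom")}
    for snp in snp_manifest.itertuples(index=False):
        sub = cpg_by_chrom.get(snp.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, snp.pos - window, side="left")
        hi = np.searchsorted(pos, snp.pos + window, side="right")
        for cpg_id, cpg_pos in zip(sub["probe_id"].to_numpy()[lo:hi], pos[lo:hi]):
            rows.append((snp.snp_id, cpg_id, int(abs(int(snp.pos) - int(cpg_pos)))))
    return pd.DataFrame(rows, columns=["snp_id", "cpg_id", "distance"])


# ---------------------------------------------------------------------------
# Nominal cis scan
# ---------------------------------------------------------------------------


def meqtl_scan(
    m_matrix: pd.DataFrame,
    genotypes,
    covariate_matrix,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Per-pair OLS of M on dosage with covariates; classical SE, two-sided p.

    ``m_matrix`` is samples x CpGs, ``genotypes`` a GenotypeSet (or a samples
    x SNPs dosage DataFrame) aligned on samples.  Monomorphic SNPs are
    skipped with a log message.  Returns records (snp_id, cpg_id, distance,
    effect, se, p, n).
    """
    dosages = genotypes.dosages if hasattr(genotypes, "dosages") else genotypes
    if len(dosages) != len(m_matrix):
        raise ValueError("sample dimensions of dosages and M-matrix differ")
    w = np.asarray(covariate_matrix, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    n = len(m_matrix)
    if w.shape[0] != n:
        raise ValueError("covariate matrix must align with samples")
    if not (w.shape[1] and np.allclose(w[:, 0], 1.0)):
        w = np.column_stack([np.ones(n), w]) if w.size else np.ones((n, 1))
    k = w.shape[1] + 1  # + dosage term

    q, _ = np.linalg.qr(w)

    def residualize(mat: np.ndarray) -> np.ndarray:
        return mat - q @ (q.T @ mat)

    used_snps = pairs["snp_id"].unique()
    used_cpgs = pairs["cpg_id"].unique()
    d_res = pd.DataFrame(
        residualize(dosages[used_snps].to_numpy(dtype=float)), columns=used_snps
    )
    m_res = pd.DataFrame(
        residualize(m_matrix[used_cpgs].to_numpy(dtype=float)), columns=used_cpgs
    )

    rows = []
    df = n - k
    for pair in pairs.itertuples(index=False):
        d = d_res[pair.snp_id].to_numpy()
        raw = dosages[pair.snp_id].to_numpy()
        if np.ptp(raw) == 0:
            logger.info("skipping monomorphic SNP %s", pair.snp_id)
            continue
        s = float(d @ d)
        if s <= 1e-12 * n:
            logger.info("skipping %s: dosage constant after covariate adjustment", pair.snp_id)
            continue
        mv = m_res[pair.cpg_id].to_numpy()
        effect = float(d @ mv) / s
        resid = mv - effect * d
        sigma2 = float(resid @ resid) / df
        se = float(np.sqrt(sigma2 / s))
        if se == 0:
            p = 1e-300
        else:
            p = float(np.clip(2.0 * stats.t.sf(abs(effect / se), df), 1e-300, 1.0))
        rows.append((pair.snp_id, pair.cpg_id, pair.distance, effect, se, p, n))
    return pd.DataFrame(rows, columns=["snp_id", "cpg_id", "distance", "effect", "se", "p", "n"])


def classify_meqtl_cpgs(
    records: pd.DataFrame,
    assoc_p: float = 0.05,
    nonassoc_p: float = 0.95,
) -> tuple[set[str], set[str]]:
    """Split scanned CpGs into associated (any record p < assoc_p) and
    non-associated (all records p > nonassoc_p); the gap region joins neither."""
    associated, nonassociated = set(), set()
    for cpg_id, sub in records.groupby("cpg_id"):
        p = sub["p"].to_numpy()
        if (p < assoc_p).any():
            associated.add(cpg_id)
        elif (p > nonassoc_p).all():
            nonassociated.add(cpg_id)
    return associated, nonassociated


# ---------------------------------------------------------------------------
# Empirical overlap tests
# ---------------------------------------------------------------------------


def _significant_targets(records: pd.DataFrame, sig_p: float) -> dict[str, np.ndarray]:
    sig = records.loc[records["p"] < sig_p]
    return {snp: sub["cpg_id"].unique() for snp, sub in sig.groupby("snp_id")}


def _distinct_target_count(
    snps: Iterable[str],
    targets: dict[str, np.ndarray],
    keep: set[str] | None,
) -> int:
    hit: set[str] = set()
    for snp in snps:
        for cpg in targets.get(snp, ()):
            if keep is None or cpg in keep:
                hit.add(cpg)
    return len(hit)


def _empirical_overlap_test(
    query_snps: Sequence[str],
    targets: dict[str, np.ndarray],
    keep: set[str] | None,
    background_pool: Sequence[str],
    n_sims: int,
    seed: int,
    statistic: str,
) -> OverlapTestResult:
    pool = np.asarray(background_pool)
    if len(pool) < len(query_snps):
        raise ValueError(f"background pool ({len(pool)}) smaller than query ({len(query_snps)})")
    observed = _distinct_target_count(query_snps, targets, keep)
    rng = np.random.default_rng(seed)
    bg = np.empty(n_sims)
    for s in range(n_sims):
        draw = pool[rng.choice(len(pool), len(query_snps), replace=False)]
        bg[s] = _distinct_target_count(draw, targets, keep)
    p = (float((bg >= observed).sum()) + 1.0) / (n_sims + 1.0)
    return OverlapTestResult(
        observed=observed,
        n_background_sets=n_sims,
        background_mean=float(bg.mean()),
        background_sd=float(bg.std(ddof=0)),
        empirical_p=p,
        statistic=statistic,
    )


def snp_meqtl_dmp_overlap_test(
    query_snps: Sequence[str],
    meqtl_records: pd.DataFrame,
    dmp_cpgs: Iterable[str],
    background_pool: Sequence[str],
    n_sims: int = 1000,
    seed: int = 0,
    sig_p: float = 0.05,
) -> OverlapTestResult:
    """Distinct CpGs that are significant meQTL targets of the query SNPs and
    EWAS DMPs, versus equally sized random SNP draws from the pool."""
    targets = _significant_targets(meqtl_records, sig_p)
    return _empirical_overlap_test(
        query_snps, targets, set(dmp_cpgs), background_pool, n_sims, seed,
        statistic="distinct SNP-meQTL-DMP sites",
    )


def meqtl_hotspot_overlap_test(
    query_snps: Sequence[str],
    meqtl_records: pd.DataFrame,
    intervals: IntervalCollection,
    tissue: str,
    cpg_manifest: pd.DataFrame,
    background_pool: Sequence[str],
    n_sims: int = 1000,
    seed: int = 0,
    sig_p: float = 0.05,
) -> OverlapTestResult:
    """Distinct significant meQTL target CpGs of the query SNPs lying inside
    the tissue's intervals, versus random SNP draws from the pool."""
    targets = _significant_targets(meqtl_records, sig_p)
    chrom = cpg_manifest["chrom"].to_numpy()
    pos = cpg_manifest["pos"].to_numpy()
    inside = intervals.contains_positions(tissue, chrom, pos)
    keep = set(cpg_manifest["probe_id"].to_numpy()[inside])
    return _empirical_overlap_test(
        query_snps, targets, keep, background_pool, n_sims, seed,
        statistic=f"distinct meQTL target CpGs in {tissue} hotspots",
    )


def blood_kidney_overlap_fraction(
    kidney_meqtl_cpgs: Iterable[str],
    blood_meqtl_cpgs: Iterable[str],
) -> float:
    """Percentage of kidney meQTL CpGs also present in blood, to one decimal."""
    kidney = set(kidney_meqtl_cpgs)
    if not kidney:
        raise ValueError("kidney meQTL CpG set must be non-empty")
    blood = set(blood_meqtl_cpgs)
    return round(100.0 * len(kidney & blood) / len(kidney), 1)
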