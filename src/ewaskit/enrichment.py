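"""Tissue-specific open-chromatin overlap enrichment with matched backgrounds.

For a query CpG set (e.g. the top 1000 probes of an EWAS), the observed
overlap with each tissue's DNase I hotspot intervals is compared with the
overlaps of annotation-matched random probe sets: each background set
reproduces the query's island-relation x gene-relation stratum composition
exactly, drawn without replacement from the manifest excluding the query.
The empirical p-value carries a +1 pseudocount,

    p = (#{background >= observed} + 1) / (B + 1),

so B = 1000 backgrounds floor it at ~0.001, and the per-tissue p-values are
adjusted across tissues with Benjamini-Yekutieli.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .intervals import IntervalCollection

logger = logging.getLogger(__name__)

MATCH_STRATA = ("island_relation", "gene_relation")


@dataclass
class ProbeSet:
    """Probe ids ordered by ascending association p-value."""

    probe_ids: tuple[str, ...]
    p_values: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("probe ids must be unique")
        if len(self.p_values) != len(self.probe_ids):
            raise ValueError("p_values must align with probe_ids")
        if any(a > b for a, b in zip(self.p_values[:-1], self.p_values[1:])):
            raise ValueError("probe set must be ordered by ascending p")

    def __len__(self) -> int:
        return len(self.probe_ids)


# ---------------------------------------------------------------------------
# Probe-set construction
# ---------------------------------------------------------------------------


def top_probes(ewas_table: pd.DataFrame, k: int = 1000, label: str = "") -> ProbeSet:
    """The k smallest-p probes; ties at the cut broken by probe id."""
    if len(ewas_table) == 0:
        raise ValueError("EWAS table is empty")
    if len(ewas_table) < k:
        logger.warning("table has only %d rows < k=%d; returning all", len(ewas_table), k)
    ranked = ewas_table.sort_values(["p", "probe_id"], kind="mergesort").head(k)
    return ProbeSet(tuple(ranked["probe_id"]), tuple(ranked["p"]), label)


def ranked_probe_batches(
    ewas_table: pd.DataFrame,
    batch: int = 1000,
    n_batches: int = 5,
    label: str = "",
) -> list[ProbeSet]:
    """Consecutive disjoint rank windows (1..batch, batch+1..2*batch, ...)."""
    if len(ewas_table) < batch:
        raise ValueError(f"table has {len(ewas_table)} rows < one batch of {batch}")
    ranked = ewas_table.sort_values(["p", "probe_id"], kind="mergesort")
    available = min(n_batches, len(ranked) // batch)
    if available < n_batches:
        logger.warning("only %d full batches of %d available (requested %d)", available, batch, n_batches)
    sets = []
    for b in range(available):
        window = ranked.iloc[b * batch : (b + 1) * batch]
        sets.append(ProbeSet(tuple(window["probe_id"]), tuple(window["p"]), f"{label}batch{b + 1}"))
    return sets


# ---------------------------------------------------------------------------
# Overlap counting
# ---------------------------------------------------------------------------


def _probe_positions(probe_ids: Sequence[str], manifest: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    idx = pd.Index(manifest["probe_id"]).get_indexer(list(probe_ids))
    if (idx < 0).any():
        missing = [p for p, k in zip(probe_ids, idx) if k < 0]
        raise KeyError(f"probes absent from manifest: {missing[:5]}")
    return manifest["chrom"].to_numpy()[idx], manifest["pos"].to_numpy()[idx]


def overlap_count(
    probes: ProbeSet | Sequence[str],
    intervals: IntervalCollection,
    tissue: str,
    manifest: pd.DataFrame,
) -> int:
    """Number of probes whose interrogated base lies inside the tissue's intervals."""
    probe_ids = probes.probe_ids if isinstance(probes, ProbeSet) else tuple(probes)
    chrom, pos = _probe_positions(probe_ids, manifest)
    return int(intervals.contains_positions(tissue, chrom, pos).sum())


# ---------------------------------------------------------------------------
# Matched backgrounds
# ---------------------------------------------------------------------------


def matched_background(
    query: ProbeSet | Sequence[str],
    manifest: pd.DataFrame,
    n_sets: int = 1000,
    seed: int = 0,
    strata: Sequence[str] = MATCH_STRATA,
) -> list[np.ndarray]:
    """Random probe sets with the query's exact annotation-stratum composition.

    Sampling is without replacement within each set, excludes the query, and
    is deterministic under ``seed``.  Raises when a stratum's pool is smaller
    than twice the query's demand there.
    """
    query_ids = list(query.probe_ids if isinstance(query, ProbeSet) else query)
    query_set = set(query_ids)
    mani = manifest.set_index("probe_id")
    missing = query_set - set(mani.index)
    if missing:
        raise KeyError(f"query probes absent from manifest: {sorted(missing)[:5]}")

    key = [tuple(row) for row in mani.loc[query_ids, list(strata)].to_numpy()]
    need = pd.Series(key).value_counts().to_dict()
    pool_key = [tuple(row) for row in mani[list(strata)].to_numpy()]
    pools: dict[tuple, np.ndarray] = {}
    ids = mani.index.to_numpy()
    in_query = np.fromiter((p in query_set for p in ids), dtype=bool, count=len(ids))
    for stratum, count in need.items():
        mask = np.fromiter((k == stratum for k in pool_key), dtype=bool, count=len(ids)) & ~in_query
        pool = ids[mask]
        if len(pool) < 2 * count:
            raise ValueError(
                f"stratum {stratum} exhausted: needs {count} probes per set "
                f"but only {len(pool)} candidates remain outside the query"
            )
        pools[stratum] = pool

    rng = np.random.default_rng(seed)
    sets: list[np.ndarray] = [np.empty(0, dtype=ids.dtype) for _ in range(n_sets)]
    for stratum, count in sorted(need.items()):
        pool = pools[stratum]
        keys = rng.random((n_sets, len(pool)))
        picks = np.argpartition(keys, count - 1, axis=1)[:, :count]
        for s in range(n_sets):
            sets[s] = np.concatenate([sets[s], pool[picks[s]]])
    return sets


# ---------------------------------------------------------------------------
# Empirical statistics
# ---------------------------------------------------------------------------


def empirical_enrichment(observed: int, background_counts) -> tuple[float, float, float, float]:
    """(empirical p with +1 pseudocount, z-score, background mean, background sd)."""
    bg = np.asarray(background_counts, dtype=float)
    if bg.size == 0:
        raise ValueError("background counts must be non-empty")
    b = bg.size
    p = (float((bg >= observed).sum()) + 1.0) / (b + 1.0)
    mean = float(bg.mean())
    sd = float(bg.std(ddof=0))
    z = (observed - mean) / sd if sd > 0 else float("nan")
    return p, z, mean, sd


def by_correct(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up q-values (harmonic-sum factor, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_by")
    return q


# ---------------------------------------------------------------------------
# Full enrichment run
# ---------------------------------------------------------------------------


def run_enrichment(
    probe_set: ProbeSet,
    interval_collection: IntervalCollection,
    manifest: pd.DataFrame,
    n_sets: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Matched-background overlap enrichment of one probe set per tissue.

    Returns a table (tissue, observed, background mean/sd, z, empirical p,
    BY q across tissues); deterministic under ``seed``.
    """
    tissues = interval_collection.tissues
    # per-tissue membership for every manifest probe; background counts are
    # then indexed sums, so the B sets cost one pass each
    chrom = manifest["chrom"].to_numpy()
    pos = manifest["pos"].to_numpy()
    membership = {
        t: interval_collection.contains_positions(t, chrom, pos) for t in tissues
    }
    probe_index = pd.Index(manifest["probe_id"])

    query_idx = probe_index.get_indexer(list(probe_set.probe_ids))
    if (query_idx < 0).any():
        missing = [p for p, k in zip(probe_set.probe_ids, query_idx) if k < 0]
        raise KeyError(f"query probes absent from manifest: {missing[:5]}")
    backgrounds = matched_background(probe_set, manifest, n_sets=n_sets, seed=seed)
    bg_idx = np.vstack([probe_index.get_indexer(b) for b in backgrounds])

    rows = []
    for tissue in tissues:
        member = membership[tissue]
        observed = int(member[query_idx].sum())
        bg_counts = member[bg_idx].sum(axis=1)
        p, z, mean, sd = empirical_enrichment(observed, bg_counts)
        rows.append((tissue, observed, mean, sd, z, p, len(bg_counts)))
    out = pd.DataFrame(
        rows, columns=["tissue", "observed", "background_mean", "background_sd", "z", "empirical_p", "n_background_sets"]
    )
    out["by_q"] = by_correct(out["empirical_p"].to_numpy())
    return out
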