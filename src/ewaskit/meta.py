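"""Fixed-effect inverse-variance meta-analysis, FDR discovery and
Bonferroni/direction-concordance replication.

Per-study summaries are combined with weights w_i = 1/SE_i^2:

    effect = sum(w_i b_i) / sum(w_i),   SE = (sum w_i)^-1/2,
    z = effect/SE,  p = 2 Phi(-|z|),
    Q = sum w_i (b_i - effect)^2,  I^2 = max(0, (Q - df)/Q) * 100.

Probes present in fewer than two studies are excluded.  Discovery uses
Benjamini-Hochberg FDR; replication requires p at or below the Bonferroni
cutoff alpha/m (m = number of discovery hits carried forward) and a
concordant direction of effect.  "p <= threshold" counts as passing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudySummary:
    """One study's association statistics at one probe."""

    study_id: str
    probe_id: str
    effect: float
    se: float
    p: float = float("nan")
    n: int = 0
    ethnicity: str = ""
    array: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.study_id}/{self.probe_id}: se must be positive")


@dataclass
class MetaResult:
    probe_id: str
    effect: float
    se: float
    z: float
    p: float
    q_cochran: float
    i_squared: float  # percent
    df: int
    n_studies: int
    n_total: int
    direction: str  # one sign per study, in study_id order


@dataclass
class ReplicationCall:
    probe_id: str
    discovery_effect: float
    discovery_p: float
    replication_effect: float | None
    replication_p: float | None
    threshold: float
    concordant: bool
    replicated: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# Core combination
# ---------------------------------------------------------------------------


def ivw_meta(summaries: Sequence[StudySummary], min_studies: int = 2) -> MetaResult:
    """Inverse-variance weighted fixed-effect combination of one probe."""
    if len(summaries) < min_studies:
        raise ValueError(
            f"{summaries[0].probe_id if summaries else '?'}: "
            f"{len(summaries)} studies < required {min_studies}"
        )
    probe_ids = {s.probe_id for s in summaries}
    if len(probe_ids) != 1:
        raise ValueError(f"summaries mix probes: {sorted(probe_ids)}")
    ordered = sorted(summaries, key=lambda s: s.study_id)
    b = np.array([s.effect for s in ordered])
    w = np.array([1.0 / s.se**2 for s in ordered])
    effect = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = effect / se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), 1e-300, 1.0))
    q = float((w * (b - effect) ** 2).sum())
    df = len(ordered) - 1
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    return MetaResult(
        probe_id=ordered[0].probe_id,
        effect=effect,
        se=se,
        z=z,
        p=p,
        q_cochran=q,
        i_squared=i2,
        df=df,
        n_studies=len(ordered),
        n_total=int(sum(s.n for s in ordered)),
        direction="".join("+" if s.effect >= 0 else "-" for s in ordered),
    )


def min_studies_filter(
    probe_to_summaries: Mapping[str, Sequence[StudySummary]],
    k: int = 2,
) -> dict[str, Sequence[StudySummary]]:
    """Drop probes contributed by fewer than ``k`` studies."""
    kept = {p: s for p, s in probe_to_summaries.items() if len(s) >= k}
    dropped = len(probe_to_summaries) - len(kept)
    if dropped:
        logger.info("min-studies filter dropped %d probes (< %d studies)", dropped, k)
    return kept


def meta_analyze(summaries: pd.DataFrame, min_studies: int = 2) -> pd.DataFrame:
    """Meta-analyze a METAL-like summary table (one row per study x probe).

    Expects columns MARKER, EFFECT, SE, N, STUDY (PVAL/ETHNICITY optional);
    returns one row per probe passing the minimum-studies rule.
    """
    by_probe: dict[str, list[StudySummary]] = {}
    for row in summaries.itertuples(index=False):
        s = StudySummary(
            study_id=str(row.STUDY),
            probe_id=str(row.MARKER),
            effect=float(row.EFFECT),
            se=float(row.SE),
            n=int(row.N) if hasattr(row, "N") else 0,
        )
        by_probe.setdefault(s.probe_id, []).append(s)
    kept = min_studies_filter(by_probe, min_studies)
    rows = [ivw_meta(s, min_studies) for s in kept.values()]
    out = pd.DataFrame(
        [
            (r.probe_id, r.effect, r.se, r.z, r.p, r.q_cochran, r.i_squared, r.df, r.n_studies, r.n_total, r.direction)
            for r in rows
        ],
        columns=["probe_id", "effect", "se", "z", "p", "q_cochran", "i_squared", "df", "n_studies", "n_total", "direction"],
    )
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def se_from_effect_p(effect: float, p: float) -> float:
    """Invert a printed (effect, p) pair to its standard error: |b|/Phi^-1(1-p/2)."""
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    if effect == 0:
        raise ValueError("effect must be nonzero")
    return abs(effect) / stats.norm.isf(p / 2.0)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q-values, boolean rejected at ``alpha``)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Per-test cutoff alpha/m for ``m`` replication tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------


def call_replication(
    discovery: Sequence[MetaResult],
    replication: Sequence[MetaResult],
    alpha: float = 0.05,
    require_concordance: bool = True,
) -> list[ReplicationCall]:
    """Bonferroni + direction-concordance replication of discovery hits.

    The cutoff is alpha divided by the number of discovery probes carried
    forward; ``p <= threshold`` passes.  Probes absent from the replication
    set are called not-replicated with reason "untested".
    """
    threshold = bonferroni_threshold(alpha, len(discovery))
    repl = {r.probe_id: r for r in replication}
    calls = []
    for d in discovery:
        r = repl.get(d.probe_id)
        if r is None:
            calls.append(
                ReplicationCall(d.probe_id, d.effect, d.p, None, None, threshold, False, False, "untested")
            )
            continue
        concordant = np.sign(d.effect) == np.sign(r.effect)
        passed = r.p <= threshold and (concordant or not require_concordance)
        reason = "" if passed else ("discordant direction" if r.p <= threshold else "p above threshold")
        calls.append(
            ReplicationCall(d.probe_id, d.effect, d.p, r.effect, r.p, threshold, bool(concordant), bool(passed), reason)
        )
    return calls


#: which replication ethnicity serves each discovery group: European-ancestry
#: replication samples back EA and H/L discoveries, African-ancestry samples
#: back AA discoveries
DEFAULT_ETHNICITY_MAP = {"EA": "EA", "HL": "EA", "AA": "AA"}


def route_replication(
    discovery_by_group: Mapping[str, Sequence[MetaResult]],
    replication_by_group: Mapping[str, Sequence[MetaResult]],
    ethnicity_map: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> dict[str, list[ReplicationCall]]:
    """Ethnic-specific replication: each discovery group's hits are tested in
    the replication group its ethnicity maps to."""
    ethnicity_map = dict(DEFAULT_ETHNICITY_MAP if ethnicity_map is None else ethnicity_map)
    calls = {}
    for group, discovery in discovery_by_group.items():
        target = ethnicity_map.get(group)
        if target is None:
            raise KeyError(f"no replication group mapped for discovery group {group!r}")
        replication = replication_by_group.get(target, [])
        calls[group] = call_replication(discovery, replication, alpha=alpha)
    return calls


def combine_discovery_replication(discovery: MetaResult, replication: MetaResult) -> MetaResult:
    """Two-entry inverse-variance combination of the two stage estimates."""
    if discovery.probe_id != replication.probe_id:
        raise ValueError("stages refer to different probes")
    stages = [
        StudySummary("discovery", discovery.probe_id, discovery.effect, discovery.se, discovery.p),
        StudySummary("replication", replication.probe_id, replication.effect, replication.se, replication.p),
    ]
    return ivw_meta(stages)


def stage_result_from_effect_p(probe_id: str, effect: float, p: float) -> MetaResult:
    """A one-stage MetaResult from a printed (effect, p) pair, se inverted from p."""
    se = se_from_effect_p(effect, p)
    return MetaResult(
        probe_id=probe_id,
        effect=effect,
        se=se,
        z=effect / se,
        p=p,
        q_cochran=0.0,
        i_squared=0.0,
        df=0,
        n_studies=1,
        n_total=0,
        direction="+" if effect >= 0 else "-",
    )


# ---------------------------------------------------------------------------
# Plot data (QQ / forest)
# ---------------------------------------------------------------------------


def qq_table(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot."""
    p = np.sort(np.asarray(p_values, dtype=float))
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame({"expected_neglog10": -np.log10(expected), "observed_neglog10": -np.log10(p)})


def manhattan_table(results: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Chromosome/position/-log10 p for a Manhattan plot of a results table."""
    pos = manifest.set_index("probe_id")[["chrom", "pos"]]
    merged = results.join(pos, on="probe_id", how="inner")
    return pd.DataFrame(
        {
            "probe_id": merged["probe_id"],
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "neglog10_p": -np.log10(merged["p"]),
        }
    ).reset_index(drop=True)


def forest_table(summaries: Sequence[StudySummary]) -> pd.DataFrame:
    """Per-study effect with 95% CI bounds for a forest plot of one probe."""
    rows = [
        (s.study_id, s.effect, s.se, s.effect - 1.96 * s.se, s.effect + 1.96 * s.se)
        for s in sorted(summaries, key=lambda s: s.study_id)
    ]
    return pd.DataFrame(rows, columns=["study_id", "effect", "se", "ci_low", "ci_high"])
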