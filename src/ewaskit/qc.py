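"""Probe/sample quality filters and the beta <-> M-value transform.

The detection filter removes probes with detection p > ``probe_p`` in a
strict fraction > ``probe_frac`` of samples first, then samples failing in a
strict fraction > ``sample_frac`` of the *retained* probes.  Strict ">"
inequalities throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    probes_removed_detection: list[str] = field(default_factory=list)
    samples_removed_detection: list[str] = field(default_factory=list)
    probes_removed_blacklist: list[str] = field(default_factory=list)
    n_probes_before: int = 0
    n_probes_after: int = 0
    n_samples_before: int = 0
    n_samples_after: int = 0

    def to_dict(self) -> dict:
        return {
            "probes_removed_detection": list(self.probes_removed_detection),
            "samples_removed_detection": list(self.samples_removed_detection),
            "probes_removed_blacklist": list(self.probes_removed_blacklist),
            "n_probes_before": self.n_probes_before,
            "n_probes_after": self.n_probes_after,
            "n_samples_before": self.n_samples_before,
            "n_samples_after": self.n_samples_after,
        }


def filter_by_detection(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    probe_p: float = 0.01,
    probe_frac: float = 0.10,
    sample_frac: float = 0.01,
) -> tuple[pd.DataFrame, QcReport]:
    """Remove failing probes (first) and then failing samples.

    A cell fails when its detection p exceeds ``probe_p``.  A probe is removed
    when it fails in more than ``probe_frac`` of samples; afterwards a sample
    is removed when it fails in more than ``sample_frac`` of the retained
    probes.  Both comparisons are strict.
    """
    if beta.shape != detp.shape:
        raise ValueError(f"beta {beta.shape} and detection-p {detp.shape} shapes differ")
    detp = detp.loc[beta.index, beta.columns]
    failing = detp.to_numpy() > probe_p

    probe_fail_frac = failing.mean(axis=0)
    bad_probes = probe_fail_frac > probe_frac
    kept_probe_mask = ~bad_probes

    if kept_probe_mask.sum() == 0:
        logger.warning("detection filter removed every probe")
        sample_bad = np.zeros(beta.shape[0], dtype=bool)
    else:
        sample_fail_frac = failing[:, kept_probe_mask].mean(axis=1)
        sample_bad = sample_fail_frac > sample_frac
    kept_sample_mask = ~sample_bad

    report = QcReport(
        probes_removed_detection=list(beta.columns[bad_probes]),
        samples_removed_detection=list(beta.index[sample_bad]),
        n_probes_before=beta.shape[1],
        n_probes_after=int(kept_probe_mask.sum()),
        n_samples_before=beta.shape[0],
        n_samples_after=int(kept_sample_mask.sum()),
    )
    filtered = beta.loc[kept_sample_mask, kept_probe_mask]
    if filtered.size == 0:
        logger.warning("detection filter produced an empty matrix")
    return filtered, report


def remove_blacklisted_probes(
    beta: pd.DataFrame,
    blacklist: Iterable[str],
) -> tuple[pd.DataFrame, QcReport]:
    """Drop cross-reactive/polymorphic probes; absent entries are only logged."""
    blacklist = set(blacklist)
    present = [p for p in beta.columns if p in blacklist]
    absent = blacklist - set(present)
    if absent:
        logger.info("%d blacklist entries not present in the matrix", len(absent))
    filtered = beta.drop(columns=present)
    if filtered.shape[1] == 0:
        logger.warning("blacklist removed every probe")
    report = QcReport(
        probes_removed_blacklist=present,
        n_probes_before=beta.shape[1],
        n_probes_after=filtered.shape[1],
        n_samples_before=beta.shape[0],
        n_samples_after=beta.shape[0],
    )
    return filtered, report


def beta_to_m(beta, epsilon: float = 1e-6):
    """M = log2(beta / (1 - beta)) with betas clamped to [epsilon, 1 - epsilon].

    Accepts scalars, arrays, Series or DataFrames; the container type is
    preserved.  Strictly increasing and finite on [0, 1].
    """
    values = np.asarray(beta, dtype=float) if not isinstance(beta, (pd.DataFrame, pd.Series)) else beta
    arr = values.to_numpy() if isinstance(values, (pd.DataFrame, pd.Series)) else values
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("beta values must lie in [0, 1]")
    clamped = np.clip(arr, epsilon, 1.0 - epsilon)
    m = np.log2(clamped / (1.0 - clamped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    return m if m.ndim else float(m)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` on the clamped domain: beta = 2^M / (1 + 2^M)."""
    arr = m.to_numpy() if isinstance(m, (pd.DataFrame, pd.Series)) else np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + 2.0 ** (-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(beta, index=m.index, name=m.name)
    return beta if beta.ndim else float(beta)
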