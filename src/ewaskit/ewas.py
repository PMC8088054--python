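"""Per-cohort EWAS: eGFR regressed on methylation beta with covariates.

Coefficients come from ordinary least squares; standard errors from the
heteroscedasticity-consistent sandwich estimator

    (X'X)^-1 X' diag(w_i e_i^2) X (X'X)^-1

with HC0 (w=1), HC1 (w=n/(n-k)) or HC3 (w=1/(1-h_i)^2) weights, or from the
classical homoscedastic formula.  A family-aware variant fits a
random-intercept-per-family model by profile REML with closed-form per-family
block inverses and reports the GLS fixed effect.  p-values use the standard
normal reference throughout, matching fixed-effect meta-analysis downstream.

``run_ewas`` exploits Frisch-Waugh-Lovell: with a covariate design shared by
all probes, the per-probe coefficient and every HC variant of its sandwich
variance depend only on the covariate-residualized outcome and predictor plus
the covariate leverages, so the whole array is fit with dense linear algebra
rather than one model object per probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

HC_VARIANTS = ("HC0", "HC1", "HC3", "classical")
ESTIMATORS = ("ols_hc", "family_lmm")

#: two-sided p-values are floored here so degenerate (zero-residual) fits
#: report a sentinel rather than 0
P_FLOOR = 1e-300

#: median of the chi-square distribution with 1 df
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))


class FitSkipped(ValueError):
    """A probe could not be fit (too few samples, rank deficiency, ...)."""


@dataclass(frozen=True)
class EwasModelSpec:
    """Model configuration for one cohort's probe-by-probe regressions."""

    covariates: tuple[str, ...] = (
        "age",
        "sex",
        "smoking_status",
        "pack_years",
        "cell_proportions",
        "pcs",
        "batch",
    )
    estimator: str = "ols_hc"
    hc: str = "HC3"
    min_n: int | None = None  # default: number of parameters + 2

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")
        if self.hc not in HC_VARIANTS:
            raise ValueError(f"hc must be one of {HC_VARIANTS}")


@dataclass
class EwasResult:
    probe_id: str
    n: int
    effect: float  # eGFR mL/min/1.73 m^2 per unit beta
    se: float
    z: float
    p: float
    direction: str
    degenerate: bool = False
    cluster_fallback: bool = False
    tau2: float | None = None  # family variance component (family_lmm only)
    sigma2: float | None = None  # residual variance (family_lmm only)


@dataclass
class EwasRunReport:
    lambda_: float
    n_tested: int
    n_skipped: int
    estimator: str
    skipped: dict[str, str] | None = None


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def design_matrix(
    covariates: pd.DataFrame,
    include: Sequence[str],
) -> tuple[np.ndarray, list[str]]:
    """Numeric design (with leading intercept) from a covariate table.

    Logical names expand as the EWAS model expects: ``smoking_status`` to
    current/past dummies (never = reference), ``cell_proportions`` to the
    ``cell_*`` columns minus the last (they sum to 1), ``pcs`` to all ``pc_*``
    columns, ``batch`` to dummies against the first level.  Any other name
    must be a numeric column of the table.
    """
    n = len(covariates)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for name in include:
        if name == "smoking_status":
            status = covariates["smoking_status"].to_numpy()
            for level in ("current", "past"):
                cols.append((status == level).astype(float))
                names.append(f"smoking_{level}")
        elif name == "cell_proportions":
            cells = sorted(c for c in covariates.columns if c.startswith("cell_"))
            for c in cells[:-1]:  # drop one: fractions sum to 1
                cols.append(covariates[c].to_numpy(dtype=float))
                names.append(c)
        elif name == "pcs":
            for c in sorted(c for c in covariates.columns if c.startswith("pc_")):
                cols.append(covariates[c].to_numpy(dtype=float))
                names.append(c)
        elif name == "batch":
            levels = sorted(pd.unique(covariates["batch"]))
            for level in levels[1:]:
                cols.append((covariates["batch"].to_numpy() == level).astype(float))
                names.append(f"batch_{level}")
        elif name in covariates.columns:
            cols.append(covariates[name].to_numpy(dtype=float))
            names.append(name)
        else:
            raise KeyError(f"covariate {name!r} not present in the covariate table")
    return np.column_stack(cols), names


def _as_design(covariate_matrix) -> np.ndarray:
    """Covariate block as ndarray, prepending an intercept if absent."""
    w = np.asarray(
        covariate_matrix.to_numpy() if isinstance(covariate_matrix, pd.DataFrame) else covariate_matrix,
        dtype=float,
    )
    if w.ndim == 1:
        w = w[:, None]
    if w.size == 0:
        return np.ones((w.shape[0], 1))
    has_intercept = np.allclose(w[:, 0], 1.0)
    return w if has_intercept else np.column_stack([np.ones(w.shape[0]), w])


# ---------------------------------------------------------------------------
# Single-probe fits
# ---------------------------------------------------------------------------


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)


def fit_probe(
    egfr,
    beta_probe,
    covariate_matrix,
    spec: EwasModelSpec | None = None,
    probe_id: str = "",
) -> EwasResult:
    """OLS fit of eGFR on one probe's betas with sandwich (or classical) SE.

    Complete cases only; raises :class:`FitSkipped` on rank deficiency or when
    fewer than ``min_n`` samples remain.
    """
    spec = spec or EwasModelSpec()
    y = np.asarray(egfr, dtype=float)
    x = np.asarray(beta_probe, dtype=float)
    w = _as_design(covariate_matrix)
    mask = np.isfinite(y) & np.isfinite(x) & np.all(np.isfinite(w), axis=1)
    y, x, w = y[mask], x[mask], w[mask]
    n = len(y)
    X = np.column_stack([w[:, :1], x, w[:, 1:]])  # intercept, probe, covariates
    k = X.shape[1]
    min_n = spec.min_n if spec.min_n is not None else k + 2
    if n < min_n:
        raise FitSkipped(f"{probe_id or 'probe'}: n={n} < min_n={min_n}")
    if np.linalg.matrix_rank(X) < k:
        raise FitSkipped(f"{probe_id or 'probe'}: design matrix is rank deficient")

    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ (X.T @ y)
    resid = y - X @ coef
    effect = float(coef[1])

    rss = float(resid @ resid)
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        # exact fit: zero residual variance, report the sentinel p
        return EwasResult(probe_id, n, effect, 0.0, np.inf, P_FLOOR, _sign(effect), degenerate=True)

    if spec.hc == "classical":
        var = rss / (n - k) * xtx_inv[1, 1]
    else:
        if spec.hc == "HC3":
            h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
            omega = resid**2 / (1.0 - h) ** 2
        else:
            omega = resid**2
        meat = (X * omega[:, None]).T @ X
        cov = xtx_inv @ meat @ xtx_inv
        var = cov[1, 1]
        if spec.hc == "HC1":
            var *= n / (n - k)
    se = float(np.sqrt(var))
    z = effect / se
    return EwasResult(probe_id, n, effect, se, z, float(_two_sided_p(np.array(z))), _sign(effect))


def _sign(effect: float) -> str:
    return "+" if effect >= 0 else "-"


def fit_probe_family(
    egfr,
    beta_probe,
    covariate_matrix,
    family_ids,
    spec: EwasModelSpec | None = None,
    probe_id: str = "",
) -> EwasResult:
    """Random-intercept-per-family fit by profile REML.

    The covariance is sigma^2 (I + theta Z Z') with Z the family incidence
    matrix; theta = tau^2/sigma^2 is profiled on [0, inf) using closed-form
    per-family block inverses, and the fixed effect and its SE come from GLS
    at the REML estimates.  Falls back to a cluster-flagged OLS sandwich fit
    if the REML solve fails numerically.
    """
    spec = spec or EwasModelSpec()
    y = np.asarray(egfr, dtype=float)
    x = np.asarray(beta_probe, dtype=float)
    w = _as_design(covariate_matrix)
    fam = pd.Categorical(np.asarray(family_ids))
    mask = np.isfinite(y) & np.isfinite(x) & np.all(np.isfinite(w), axis=1)
    y, x, w = y[mask], x[mask], w[mask]
    codes = fam.codes[mask]
    n = len(y)
    X = np.column_stack([w[:, :1], x, w[:, 1:]])
    k = X.shape[1]
    min_n = spec.min_n if spec.min_n is not None else k + 2
    if n < min_n:
        raise FitSkipped(f"{probe_id or 'probe'}: n={n} < min_n={min_n}")
    if np.linalg.matrix_rank(X) < k:
        raise FitSkipped(f"{probe_id or 'probe'}: design matrix is rank deficient")

    codes = pd.factorize(codes)[0]
    n_fam = codes.max() + 1
    sizes = np.bincount(codes).astype(float)
    xtx = X.T @ X
    xty = X.T @ y
    yty = float(y @ y)
    # per-family sums
    sx = np.zeros((n_fam, k))
    np.add.at(sx, codes, X)
    sy = np.bincount(codes, weights=y)

    def gls_parts(theta: float):
        c = theta / (1.0 + theta * sizes)
        xtax = xtx - (sx * c[:, None]).T @ sx
        xtay = xty - sx.T @ (c * sy)
        ytay = yty - float(c @ sy**2)
        coef = np.linalg.solve(xtax, xtay)
        rss = ytay - float(coef @ xtay)
        return xtax, coef, rss

    def neg2_reml(theta: float) -> float:
        xtax, _, rss = gls_parts(theta)
        if rss <= 0:
            return np.inf
        sigma2 = rss / (n - k)
        sign_det, logdet = np.linalg.slogdet(xtax)
        if sign_det <= 0:
            return np.inf
        return (n - k) * np.log(sigma2) + float(np.sum(np.log1p(theta * sizes))) + logdet

    try:
        res = minimize_scalar(neg2_reml, bounds=(0.0, 200.0), method="bounded", options={"xatol": 1e-8})
        theta = float(res.x) if res.fun <= neg2_reml(0.0) else 0.0
        xtax, coef, rss = gls_parts(theta)
        sigma2 = rss / (n - k)
        var = sigma2 * np.linalg.inv(xtax)[1, 1]
        if not np.isfinite(var) or var < 0:
            raise np.linalg.LinAlgError("non-finite GLS variance")
    except np.linalg.LinAlgError as exc:
        logger.warning("%s: family REML failed (%s); falling back to robust OLS", probe_id, exc)
        result = fit_probe(egfr, beta_probe, covariate_matrix, spec, probe_id)
        result.cluster_fallback = True
        return result

    effect = float(coef[1])
    if rss <= 1e-12 * max(1.0, yty):
        return EwasResult(probe_id, n, effect, 0.0, np.inf, P_FLOOR, _sign(effect), degenerate=True)
    se = float(np.sqrt(var))
    z = effect / se
    return EwasResult(
        probe_id, n, effect, se, z, float(_two_sided_p(np.array(z))), _sign(effect),
        tau2=float(theta * sigma2), sigma2=float(sigma2),
    )


# ---------------------------------------------------------------------------
# Whole-array run
# ---------------------------------------------------------------------------


def run_ewas(dataset, spec: EwasModelSpec | None = None) -> tuple[pd.DataFrame, EwasRunReport]:
    """Fit every probe of a cohort and report genomic inflation.

    Returns a table with one row per tested probe (probe_id, n, effect, se,
    z, p, direction) and a run report with the inflation factor lambda over
    all tested probes.
    """
    spec = spec or EwasModelSpec()
    for name in spec.covariates:
        if name in ("smoking_status", "batch", "cell_proportions", "pcs"):
            prefix = {"cell_proportions": "cell_", "pcs": "pc_"}.get(name, name)
            if not any(c.startswith(prefix) or c == name for c in dataset.covariates.columns):
                raise KeyError(f"covariate {name!r} not available in the cohort")
        elif name not in dataset.covariates.columns:
            raise KeyError(f"covariate {name!r} not available in the cohort")

    W, _ = design_matrix(dataset.covariates, spec.covariates)
    y = dataset.egfr.to_numpy(dtype=float)
    B = dataset.beta.to_numpy(dtype=float)
    probe_ids = np.asarray(dataset.beta.columns)
    n, m = B.shape
    k = W.shape[1] + 1
    min_n = spec.min_n if spec.min_n is not None else k + 2
    skipped: dict[str, str] = {}

    if spec.estimator == "family_lmm":
        if dataset.family_id is None:
            raise ValueError("family_lmm estimator requires family ids")
        rows = []
        for j, pid in enumerate(probe_ids):
            try:
                r = fit_probe_family(y, B[:, j], W, dataset.family_id.to_numpy(), spec, pid)
                rows.append((r.probe_id, r.n, r.effect, r.se, r.z, r.p, r.direction))
            except FitSkipped as exc:
                skipped[pid] = str(exc)
        table = pd.DataFrame(rows, columns=["probe_id", "n", "effect", "se", "z", "p", "direction"])
    elif np.isnan(B).any() or np.isnan(y).any():
        rows = []
        for j, pid in enumerate(probe_ids):
            try:
                r = fit_probe(y, B[:, j], W, spec, pid)
                rows.append((r.probe_id, r.n, r.effect, r.se, r.z, r.p, r.direction))
            except FitSkipped as exc:
                skipped[pid] = str(exc)
        table = pd.DataFrame(rows, columns=["probe_id", "n", "effect", "se", "z", "p", "direction"])
    else:
        table = _run_ewas_dense(y, B, W, probe_ids, spec, min_n, skipped)

    lam = genomic_lambda(table["p"].to_numpy()) if len(table) else float("nan")
    report = EwasRunReport(
        lambda_=lam,
        n_tested=len(table),
        n_skipped=m - len(table),
        estimator=f"{spec.estimator}:{spec.hc}" if spec.estimator == "ols_hc" else spec.estimator,
        skipped=skipped or None,
    )
    return table.reset_index(drop=True), report


def _run_ewas_dense(y, B, W, probe_ids, spec, min_n, skipped) -> pd.DataFrame:
    """Vectorized OLS + sandwich across probes via Frisch-Waugh-Lovell."""
    n, m = B.shape
    k = W.shape[1] + 1
    if n < min_n:
        for pid in probe_ids:
            skipped[pid] = f"n={n} < min_n={min_n}"
        return pd.DataFrame(columns=["probe_id", "n", "effect", "se", "z", "p", "direction"])

    q, _ = np.linalg.qr(W)
    y_r = y - q @ (q.T @ y)
    B_r = B - q @ (q.T @ B)
    S = np.einsum("ij,ij->j", B_r, B_r)
    ok = S > 1e-12 * n
    for pid in probe_ids[~ok]:
        skipped[pid] = "predictor constant after covariate adjustment"

    coef = np.zeros(m)
    coef[ok] = (B_r[:, ok].T @ y_r) / S[ok]
    h_w = np.einsum("ij,ij->i", q, q)

    var = np.full(m, np.nan)
    rss_all = np.full(m, np.nan)
    chunk = 2048
    for start in range(0, m, chunk):
        idx = np.arange(start, min(start + chunk, m))
        idx = idx[ok[idx]]
        if idx.size == 0:
            continue
        Bc = B_r[:, idx]
        E = y_r[:, None] - Bc * coef[idx][None, :]
        rss = np.einsum("ij,ij->j", E, E)
        rss_all[idx] = rss
        if spec.hc == "classical":
            var[idx] = rss / (n - k) / S[idx]
        else:
            w2 = Bc**2 * E**2
            if spec.hc == "HC3":
                h = h_w[:, None] + Bc**2 / S[idx][None, :]
                w2 = w2 / (1.0 - h) ** 2
            v = w2.sum(axis=0) / S[idx] ** 2
            if spec.hc == "HC1":
                v = v * n / (n - k)
            var[idx] = v

    sel = ok
    effect = coef[sel]
    se = np.sqrt(var[sel])
    degenerate = rss_all[sel] <= 1e-12 * max(1.0, float(y @ y))
    se = np.where(degenerate, 0.0, se)
    with np.errstate(divide="ignore"):
        z = np.where(se > 0, effect / np.where(se > 0, se, 1.0), np.inf * np.sign(effect))
    p = np.where(se > 0, _two_sided_p(z), P_FLOOR)
    return pd.DataFrame(
        {
            "probe_id": probe_ids[sel],
            "n": n,
            "effect": effect,
            "se": se,
            "z": z,
            "p": p,
            "direction": np.where(effect >= 0, "+", "-"),
        }
    )


# ---------------------------------------------------------------------------
# Genomic inflation
# ---------------------------------------------------------------------------


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median observed chi-square(1) over 0.45494."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("cannot compute lambda from an empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2_obs = stats.chi2.isf(p, 1)
    return float(np.median(chi2_obs) / CHI2_NULL_MEDIAN)


# ---------------------------------------------------------------------------
# Summary-statistics file contract (METAL-like TSV)
# ---------------------------------------------------------------------------

METAL_COLUMNS = ["MARKER", "EFFECT", "SE", "PVAL", "N", "DIRECTION", "STUDY", "ETHNICITY"]


def to_metal_tsv(table: pd.DataFrame, path: str | Path, study: str, ethnicity: str) -> None:
    out = pd.DataFrame(
        {
            "MARKER": table["probe_id"],
            "EFFECT": table["effect"],
            "SE": table["se"],
            "PVAL": table["p"],
            "N": table["n"],
            "DIRECTION": table["direction"],
            "STUDY": study,
            "ETHNICITY": ethnicity,
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_metal_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(METAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary file {path} missing columns {sorted(missing)}")
    return df
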