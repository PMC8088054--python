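"""Synthetic multi-ethnic methylation cohorts with known ground truth.

Emulates the data a blood-based EWAS of kidney function consumes — an array
beta matrix in (0,1), covariates (age, sex, smoking, pack-years, leukocyte
proportions, genotype PCs, batch), serum creatinine with CKD-EPI-derived eGFR,
optional family structure — plus the side fixtures the downstream stages need:
detection p-value matrices, SNP dosage sets with planted cis-meQTL links, and
tissue-labelled open-chromatin interval collections with a planted enriched
tissue.

Association planting runs in the methylation direction: for a planted probe,
logit(beta) gains a slope on standardized eGFR, and the slope is calibrated
numerically (Gauss-Hermite integration over the probe noise) so that the
downstream covariate-adjusted regression of eGFR on beta recovers the target
effect, in eGFR units per unit beta, in expectation.  This keeps betas bounded
while making every planted effect directly comparable to reported EWAS
coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .intervals import IntervalCollection

logger = logging.getLogger(__name__)

ETHNICITIES = ("EA", "AA", "HL")
ARRAYS = ("k450", "epic")

#: covariates every generated cohort carries, in the order the EWAS adjusts for them
DEFAULT_COVARIATES = (
    "age",
    "sex",
    "smoking_status",
    "pack_years",
    "cell_proportions",
    "pcs",
    "batch",
)

CELL_TYPES = ("gran", "cd4t", "cd8t", "bcell", "nk", "mono")
# Dirichlet concentration giving realistic whole-blood mean fractions
# (~55% granulocytes) with moderate inter-individual variation.
_CELL_ALPHA = np.array([16.5, 4.5, 3.0, 2.4, 1.8, 1.8])

_BETA_EPS = 1e-12


class CalibrationError(ValueError):
    """Raised when a planted effect is not attainable under the noise model."""


# ---------------------------------------------------------------------------
# CKD-EPI phenotype
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeParams:
    """Constants of the 2009 CKD-EPI creatinine equation."""

    kappa_female: float = 0.7
    kappa_male: float = 0.9
    alpha_female: float = -0.329
    alpha_male: float = -0.411
    max_exponent: float = -1.209
    base: float = 141.0
    age_factor: float = 0.993
    female_factor: float = 1.018
    black_factor: float = 1.159


def compute_ckd_epi_egfr(
    scr,
    age,
    is_female,
    is_black,
    params: PhenotypeParams | None = None,
):
    """Estimated GFR (mL/min/1.73 m^2) from serum creatinine via CKD-EPI 2009.

    eGFR = 141 * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^-1.209
         * 0.993^age * 1.018[female] * 1.159[black]

    with sex-specific kappa (0.7 female / 0.9 male) and alpha (-0.329 / -0.411).
    Accepts scalars or arrays; strictly decreasing in creatinine and in age.
    """
    params = params or PhenotypeParams()
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    is_female = np.asarray(is_female, dtype=bool)
    is_black = np.asarray(is_black, dtype=bool)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    kappa = np.where(is_female, params.kappa_female, params.kappa_male)
    alpha = np.where(is_female, params.alpha_female, params.alpha_male)
    ratio = scr / kappa
    egfr = (
        params.base
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** params.max_exponent
        * params.age_factor**age
        * np.where(is_female, params.female_factor, 1.0)
        * np.where(is_black, params.black_factor, 1.0)
    )
    return egfr if egfr.ndim else float(egfr)


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "island_relation",
    "gene_relation",
    "on_450k",
    "on_epic",
]

ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
GENE_RELATIONS = ("promoter", "body", "intergenic")


def validate_manifest(manifest: pd.DataFrame) -> None:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if manifest["probe_id"].duplicated().any():
        raise ValueError("manifest probe_ids must be unique")
    if (manifest["pos"] < 1).any():
        raise ValueError("manifest positions must be >= 1")


def simulate_manifest(
    n_probes: int = 10_000,
    n_chrom: int = 22,
    frac_epic_only: float = 0.3,
    max_pos: int = 50_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic array manifest with a 450K subset nested inside the EPIC set.

    A fraction ``frac_epic_only`` of probes is assayed only on the EPIC array,
    mimicking the per-probe sample-size variation of mixed-array meta-analyses.
    """
    rng = np.random.default_rng(seed)
    chrom = np.sort(rng.integers(1, n_chrom + 1, n_probes))
    pos = np.zeros(n_probes, dtype=np.int64)
    for c in np.unique(chrom):
        mask = chrom == c
        pos[mask] = np.sort(rng.choice(np.arange(1, max_pos + 1), mask.sum(), replace=False))
    manifest = pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(n_probes)],
            "chrom": [f"chr{c}" for c in chrom],
            "pos": pos,
            "island_relation": rng.choice(ISLAND_RELATIONS, n_probes, p=[0.31, 0.23, 0.10, 0.36]),
            "gene_relation": rng.choice(GENE_RELATIONS, n_probes, p=[0.28, 0.34, 0.38]),
            "on_450k": rng.random(n_probes) >= frac_epic_only,
            "on_epic": np.ones(n_probes, dtype=bool),
        }
    )
    validate_manifest(manifest)
    return manifest


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t")
    validate_manifest(manifest)
    return manifest


# ---------------------------------------------------------------------------
# Cohort specification and dataset
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfounderConfig:
    """Loadings of the shared confounder score on logit-methylation.

    The per-sample confounder score combines age, sex, smoking, pack-years,
    granulocyte fraction and a per-batch offset, is standardized, and enters
    each probe's logit with a probe-specific random loading of scale
    ``probe_loading_sd`` (logit units).
    """

    age_per_year: float = 0.01
    sex: float = 0.2
    smoking_current: float = 0.4
    smoking_past: float = 0.15
    pack_years_per_year: float = 0.005
    granulocyte: float = 2.0
    batch_sd: float = 0.1
    probe_loading_sd: float = 0.5


@dataclass(frozen=True)
class FamilyConfig:
    """Family structure: per-family random intercepts on phenotype and methylation.

    ``phenotype_corr`` is the within-family correlation of log-creatinine (and
    hence approximately of eGFR) in [0, 1); ``methylation_corr`` the
    within-family correlation of the probe noise.  The two intercepts are
    independent draws, so families induce correlated errors without
    confounding the null probes.
    """

    n_families: int
    phenotype_corr: float
    methylation_corr: float = 0.2

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for name in ("phenotype_corr", "methylation_corr"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Design of one simulated study."""

    cohort_id: str
    ethnicity: str
    n_samples: int
    array: str = "k450"
    planted_dmps: tuple[tuple[str, float], ...] = ()
    confounder_config: ConfounderConfig = field(default_factory=ConfounderConfig)
    family_config: FamilyConfig | None = None
    noise_sd: float = 1.0
    seed: int = 0
    p_female: float = 0.5
    n_pcs: int = 4
    n_batches: int = 2

    def __post_init__(self) -> None:
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"ethnicity must be one of {ETHNICITIES}")
        if self.array not in ARRAYS:
            raise ValueError(f"array must be one of {ARRAYS}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for probe_id, effect in self.planted_dmps:
            if not np.isfinite(effect):
                raise ValueError(f"planted effect for {probe_id} must be finite")


@dataclass
class CohortDataset:
    """One simulated study: beta matrix, covariates, phenotype, ground truth."""

    cohort_id: str
    ethnicity: str
    beta: pd.DataFrame  # samples x probes, entries strictly in (0, 1)
    covariates: pd.DataFrame
    creatinine: pd.Series  # mg/dL
    egfr: pd.Series  # mL/min/1.73 m^2
    truth: pd.Series  # planted eGFR effect per probe (0 for nulls)
    family_id: pd.Series | None = None

    def validate(self) -> None:
        b = self.beta.to_numpy()
        if not ((b > 0).all() and (b < 1).all()):
            raise ValueError("beta entries must lie strictly in (0, 1)")
        cells = self.covariates[[f"cell_{c}" for c in CELL_TYPES]].to_numpy()
        if np.abs(cells.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("cell proportions must sum to 1")
        if (self.egfr <= 0).any():
            raise ValueError("egfr must be positive")
        n = self.beta.shape[0]
        for obj in (self.covariates, self.creatinine, self.egfr):
            if len(obj) != n:
                raise ValueError("inconsistent sample dimensions")
        if len(self.truth) != self.beta.shape[1]:
            raise ValueError("truth must have one entry per probe")

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.columns

    def write(self, directory: str | Path) -> None:
        """Write beta/covariates as gzipped TSV plus phenotype and truth tables."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.beta.to_csv(directory / "beta.tsv.gz", sep="\t")
        cov = self.covariates.copy()
        cov["creatinine"] = self.creatinine
        cov["egfr"] = self.egfr
        if self.family_id is not None:
            cov["family_id"] = self.family_id
        cov.to_csv(directory / "covariates.tsv.gz", sep="\t")
        self.truth.rename("planted_effect").to_csv(directory / "truth.tsv", sep="\t")


# ---------------------------------------------------------------------------
# Planted-slope calibration
# ---------------------------------------------------------------------------


def _gauss_hermite_normal(n_nodes: int = 21) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights integrating against a standard normal density."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    return nodes, weights / weights.sum()


def _expected_ewas_effect(
    slope: float,
    base_logit: np.ndarray,
    z_egfr: np.ndarray,
    egfr_resid: np.ndarray,
    residualize,
    noise_sd: float,
) -> float:
    """Expected covariate-adjusted OLS coefficient of eGFR on beta for a probe
    with logit(beta) = base_logit + slope * z_egfr + Normal(0, noise_sd).

    The noise integral uses Gauss-Hermite quadrature; the between-sample part
    of var(beta) is taken after residualizing on the analysis design, matching
    what the downstream regression adjusts away.
    """
    nodes, weights = _gauss_hermite_normal()
    logits = base_logit[:, None] + slope * z_egfr[:, None] + noise_sd * nodes[None, :]
    s = expit(logits)
    m1 = s @ weights
    m2 = (s * s) @ weights
    r = residualize(m1)
    n = len(m1)
    cov = float(egfr_resid @ r) / n
    var = float(np.mean(m2 - m1 * m1) + np.mean(r * r))
    if var <= 0:
        return 0.0
    return cov / var


def _calibrate_slope(
    target: float,
    base_logit: np.ndarray,
    z_egfr: np.ndarray,
    egfr_resid: np.ndarray,
    residualize,
    noise_sd: float,
) -> float:
    """Logit slope on standardized eGFR yielding the target EWAS effect.

    Scans the monotone (attenuated-signal) branch of the slope -> effect map
    and inverts it by root bracketing; raises CalibrationError when the target
    exceeds the largest attainable effect.
    """
    if target == 0:
        return 0.0
    sign = np.sign(target)
    grid = sign * np.linspace(0.0, 6.0 * noise_sd, 121)

    def gap(b: float) -> float:
        return _expected_ewas_effect(b, base_logit, z_egfr, egfr_resid, residualize, noise_sd) - target

    prev = gap(0.0)
    for b_prev, b_next in zip(grid[:-1], grid[1:]):
        cur = gap(b_next)
        if prev * cur <= 0:
            if b_prev == 0.0 and cur == prev:
                break
            return float(brentq(gap, b_prev, b_next, xtol=1e-10))
        prev = cur
    raise CalibrationError(
        f"target effect {target} is not attainable with noise_sd={noise_sd}; "
        "reduce the target or the noise scale"
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _draw_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_samples
    age = rng.uniform(45.0, 75.0, n)
    sex = rng.binomial(1, spec.p_female, n)  # 1 = female
    smoking = rng.choice(["never", "past", "current"], n, p=[0.55, 0.30, 0.15])
    pack_years = np.where(smoking == "never", 0.0, rng.gamma(2.0, 10.0, n))
    cells = rng.dirichlet(_CELL_ALPHA, n)
    pcs = rng.normal(0.0, 1.0, (n, spec.n_pcs))
    batch = np.array([f"b{k + 1}" for k in rng.integers(0, spec.n_batches, n)])
    cov = pd.DataFrame({"age": age, "sex": sex, "smoking_status": smoking, "pack_years": pack_years})
    for k, cell in enumerate(CELL_TYPES):
        cov[f"cell_{cell}"] = cells[:, k]
    for k in range(spec.n_pcs):
        cov[f"pc_{k + 1}"] = pcs[:, k]
    cov["batch"] = batch
    cov.index = [f"{spec.cohort_id}_s{i:05d}" for i in range(n)]
    return cov


def _confounder_score(cov: pd.DataFrame, cfg: ConfounderConfig, rng: np.random.Generator) -> np.ndarray:
    smoking = cov["smoking_status"].to_numpy()
    batches = pd.unique(cov["batch"])
    batch_offsets = dict(zip(batches, rng.normal(0.0, cfg.batch_sd, len(batches))))
    score = (
        cfg.age_per_year * (cov["age"].to_numpy() - 60.0)
        + cfg.sex * cov["sex"].to_numpy()
        + cfg.smoking_current * (smoking == "current")
        + cfg.smoking_past * (smoking == "past")
        + cfg.pack_years_per_year * cov["pack_years"].to_numpy()
        + cfg.granulocyte * (cov["cell_gran"].to_numpy() - cov["cell_gran"].mean())
        + cov["batch"].map(batch_offsets).to_numpy()
    )
    sd = score.std()
    return (score - score.mean()) / sd if sd > 0 else score - score.mean()


def generate_cohort(spec: CohortSpec, manifest: pd.DataFrame) -> CohortDataset:
    """Simulate one study from its design; identical spec => identical dataset."""
    from .ewas import design_matrix  # local: ewas does not depend on this module

    validate_manifest(manifest)
    array_col = "on_450k" if spec.array == "k450" else "on_epic"
    probes = manifest.loc[manifest[array_col], "probe_id"].to_numpy()
    probe_index = pd.Index(probes)
    for probe_id, _ in spec.planted_dmps:
        if probe_id not in probe_index:
            raise ValueError(f"planted probe {probe_id!r} is absent from the {spec.array} array")

    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, len(probes)
    cov = _draw_covariates(spec, rng)

    # family assignment and phenotype family intercept
    fam_idx = None
    family_id = None
    if spec.family_config is not None:
        fam_idx = rng.permutation(np.arange(n) % spec.family_config.n_families)
        family_id = pd.Series([f"F{k:05d}" for k in fam_idx], index=cov.index, name="family_id")

    # serum creatinine: lognormal with sex/age shifts, sd 0.2 on the log scale
    kappa = np.where(cov["sex"].to_numpy() == 1, 0.7, 0.9)
    mu = np.log(kappa) + 0.10 + 0.004 * (cov["age"].to_numpy() - 60.0)
    log_sd = 0.2
    if fam_idx is not None and spec.family_config.phenotype_corr > 0:
        rho = spec.family_config.phenotype_corr
        fam_eff = rng.normal(0.0, log_sd * np.sqrt(rho), spec.family_config.n_families)
        noise = fam_eff[fam_idx] + rng.normal(0.0, log_sd * np.sqrt(1 - rho), n)
    else:
        noise = rng.normal(0.0, log_sd, n)
    scr = np.exp(mu + noise)
    egfr = compute_ckd_epi_egfr(scr, cov["age"].to_numpy(), cov["sex"].to_numpy() == 1, spec.ethnicity == "AA")

    # analysis design used downstream; needed to calibrate planted slopes
    X, _ = design_matrix(cov, DEFAULT_COVARIATES)
    q, _ = np.linalg.qr(X)

    def residualize(v: np.ndarray) -> np.ndarray:
        return v - q @ (q.T @ v)

    egfr_resid = residualize(egfr)
    z_egfr = (egfr - egfr.mean()) / egfr.std()

    # probe baseline logits; planted probes draw from the intermediate-
    # methylation range (trait-associated CpGs are variably methylated)
    intercepts = rng.uniform(-3.0, 3.0, m)
    score = _confounder_score(cov, spec.confounder_config, rng)
    loadings = rng.normal(0.0, spec.confounder_config.probe_loading_sd, m)

    fam_meth = None
    meth_fam_sd = 0.0
    if fam_idx is not None and spec.family_config.methylation_corr > 0:
        rho_m = spec.family_config.methylation_corr
        meth_fam_sd = spec.noise_sd * np.sqrt(rho_m / (1 - rho_m))
        fam_meth = rng.normal(0.0, meth_fam_sd, (spec.family_config.n_families, m))
    noise_eff = float(np.hypot(spec.noise_sd, meth_fam_sd))

    planted = {probe_id: effect for probe_id, effect in spec.planted_dmps}
    slopes = np.zeros(m)
    for probe_id, effect in planted.items():
        j = probe_index.get_loc(probe_id)
        intercepts[j] = rng.uniform(-1.5, 1.5)
        base = intercepts[j] + loadings[j] * score
        slopes[j] = _calibrate_slope(effect, base, z_egfr, egfr_resid, residualize, noise_eff)

    logits = intercepts[None, :] + np.outer(score, loadings) + np.outer(z_egfr, slopes)
    if fam_meth is not None:
        logits += fam_meth[fam_idx, :]
    logits += rng.normal(0.0, spec.noise_sd, (n, m))
    beta = np.clip(expit(logits), _BETA_EPS, 1.0 - _BETA_EPS)

    truth = pd.Series(0.0, index=probe_index, name="planted_effect")
    for probe_id, effect in planted.items():
        truth[probe_id] = effect

    dataset = CohortDataset(
        cohort_id=spec.cohort_id,
        ethnicity=spec.ethnicity,
        beta=pd.DataFrame(beta, index=cov.index, columns=probe_index),
        covariates=cov,
        creatinine=pd.Series(scr, index=cov.index, name="creatinine"),
        egfr=pd.Series(egfr, index=cov.index, name="egfr"),
        truth=truth,
        family_id=family_id,
    )
    dataset.validate()
    return dataset


# ---------------------------------------------------------------------------
# Detection p-value fixture
# ---------------------------------------------------------------------------


def generate_detection_p(
    dataset: CohortDataset,
    fail_probes: Sequence[tuple[str, float]] = (),
    fail_samples: Sequence[tuple[str, float]] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Detection p-value matrix: background ~ U(0, 0.005), designated failures
    get p in (0.01, 1].

    ``fail_probes`` lists (probe_id, fraction of samples failing); likewise
    ``fail_samples`` lists (sample_id, fraction of probes failing).
    """
    rng = np.random.default_rng(seed)
    n, m = dataset.beta.shape
    detp = rng.uniform(0.0, 0.005, (n, m))
    lo = np.nextafter(0.01, 1.0)

    for probe_id, frac in fail_probes:
        if probe_id not in dataset.beta.columns:
            raise KeyError(f"unknown probe {probe_id!r}")
        j = dataset.beta.columns.get_loc(probe_id)
        k = int(np.ceil(frac * n))
        rows = rng.choice(n, k, replace=False)
        detp[rows, j] = rng.uniform(lo, 1.0, k)
    for sample_id, frac in fail_samples:
        if sample_id not in dataset.beta.index:
            raise KeyError(f"unknown sample {sample_id!r}")
        i = dataset.beta.index.get_loc(sample_id)
        k = int(np.ceil(frac * m))
        cols = rng.choice(m, k, replace=False)
        detp[i, cols] = rng.uniform(lo, 1.0, k)
    return pd.DataFrame(detp, index=dataset.beta.index, columns=dataset.beta.columns)


# ---------------------------------------------------------------------------
# Genotypes with planted cis-meQTL links
# ---------------------------------------------------------------------------


@dataclass
class GenotypeSet:
    """SNP dosages under Hardy-Weinberg with recorded planted meQTL links."""

    manifest: pd.DataFrame  # snp_id, chrom, pos
    dosages: pd.DataFrame  # samples x SNPs, entries in [0, 2]
    maf: pd.Series
    truth_meqtl: tuple[tuple[str, str, float], ...] = ()

    def validate(self) -> None:
        d = self.dosages.to_numpy()
        if d.min() < 0 or d.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")
        if (self.manifest["pos"] < 1).any():
            raise ValueError("SNP positions must be >= 1")


def simulate_snp_manifest(
    n_snps: int = 100,
    n_chrom: int = 22,
    max_pos: int = 50_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    chrom = np.sort(rng.integers(1, n_chrom + 1, n_snps))
    pos = rng.integers(1, max_pos + 1, n_snps)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i:07d}" for i in range(n_snps)],
            "chrom": [f"chr{c}" for c in chrom],
            "pos": pos,
        }
    )


def generate_genotypes(
    n_samples: int,
    snp_manifest: pd.DataFrame,
    maf_range: tuple[float, float] = (0.05, 0.5),
    planted_meqtls: Sequence[tuple[str, str, float]] = (),
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> GenotypeSet:
    """Hardy-Weinberg dosage matrix with planted SNP->CpG effect links.

    Planted links are recorded as ground truth; apply them to an M-value
    matrix with :func:`add_meqtl_effects`.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("MAF range must lie within (0, 0.5]")
    snp_ids = pd.Index(snp_manifest["snp_id"])
    for snp_id, probe_id, _ in planted_meqtls:
        if snp_id not in snp_ids:
            raise KeyError(f"planted link references unknown SNP {snp_id!r}")
    rng = np.random.default_rng(seed)
    s = len(snp_ids)
    maf = rng.uniform(lo, hi, s)
    dosages = rng.binomial(2, maf, (n_samples, s)).astype(float)
    index = list(sample_ids) if sample_ids is not None else [f"s{i:05d}" for i in range(n_samples)]
    gset = GenotypeSet(
        manifest=snp_manifest.reset_index(drop=True),
        dosages=pd.DataFrame(dosages, index=index, columns=snp_ids),
        maf=pd.Series(maf, index=snp_ids, name="maf"),
        truth_meqtl=tuple(planted_meqtls),
    )
    gset.validate()
    return gset


def add_meqtl_effects(m_matrix: pd.DataFrame, genotypes: GenotypeSet) -> pd.DataFrame:
    """Add each planted link's effect * dosage to the target CpG's M-values."""
    out = m_matrix.copy()
    for snp_id, probe_id, effect in genotypes.truth_meqtl:
        if probe_id not in out.columns:
            raise KeyError(f"planted link references unknown CpG {probe_id!r}")
        out[probe_id] = out[probe_id] + effect * genotypes.dosages[snp_id].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Open-chromatin hotspot fixture
# ---------------------------------------------------------------------------


def generate_hotspots(
    manifest: pd.DataFrame,
    tissues: Sequence[str],
    enriched_tissue: str | None = None,
    enriched_probe_set: Sequence[str] = (),
    coverage_fraction: float = 0.5,
    base_rate: float = 0.1,
    halfwidth: int = 150,
    seed: int = 0,
) -> IntervalCollection:
    """Tissue-labelled interval collections covering probes at a base rate,
    with one tissue covering an enriched probe set at ``coverage_fraction``.

    Each covered probe gets an interval of ``2 * halfwidth + 1`` bases centred
    on its interrogated base; intervals are merged per tissue.
    """
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in (0, 1]")
    if enriched_tissue is not None:
        if enriched_tissue not in tissues:
            raise ValueError(f"enriched tissue {enriched_tissue!r} not in tissue list")
        if len(enriched_probe_set) == 0:
            raise ValueError("enriched probe set must be non-empty")
    validate_manifest(manifest)
    probe_index = pd.Index(manifest["probe_id"])
    enriched_pos = probe_index.get_indexer(list(enriched_probe_set))
    if (enriched_pos < 0).any():
        missing = [p for p, k in zip(enriched_probe_set, enriched_pos) if k < 0]
        raise KeyError(f"enriched probes absent from manifest: {missing[:5]}")

    rng = np.random.default_rng(seed)
    n_probes = len(manifest)
    chrom = manifest["chrom"].to_numpy()
    pos = manifest["pos"].to_numpy()
    data = {}
    for tissue in tissues:
        covered = rng.random(n_probes) < base_rate
        if tissue == enriched_tissue:
            covered[enriched_pos] = rng.random(len(enriched_pos)) < coverage_fraction
        idx = np.flatnonzero(covered)
        start = np.maximum(pos[idx] - 1 - halfwidth, 0)
        end = pos[idx] + halfwidth
        data[tissue] = pd.DataFrame({"chrom": chrom[idx], "start": start, "end": end})
    return IntervalCollection(data)
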