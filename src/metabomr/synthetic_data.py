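"""Synthetic GWAS summary statistics, LD reference panels and cohorts.

The real inputs of the study design this package implements — a
metabolome-wide GWAS (7,824 individuals, Metabolon platform), GEFOS bone
mineral density / fracture summary statistics and the UK Biobank cohort —
are access-restricted or very large.  This module generates stand-ins with
the same statistical structure and a known ground truth, so that every
downstream stage (clumping, harmonization, IVW, MR-Egger, MR-PRESSO, GRS
regression, MVMR) can be exercised and its parameter recovery verified.

Generative model
----------------
Per-SNP true exposure effects ``gamma_j`` are drawn uniform on
[0.05, 0.3] with random sign, which makes the instruments strong
(F >> 10) and isolates estimator behaviour from weak-instrument bias.
True outcome effects are ``Gamma_j = true_beta * gamma_j + alpha_j``
where ``alpha_j`` is a direct (horizontally pleiotropic) effect controlled
by ``pleiotropy_mode``.  Observed effects add sampling noise at the
standard GWAS standard error ``1 / sqrt(2 f (1-f) N)`` for allele
frequency ``f`` and sample size ``N``; exposure and outcome noise are
independent (two non-overlapping cohorts).  P-values follow the two-sided
normal approximation ``p = 2 * Phi(-|beta/se|)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import SummaryRecord, ValidationError

# Smallest representable positive p-value; the normal tail underflows for
# |z| > ~38 but records require p > 0.
_P_FLOOR = 5e-324


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-sample MR / cohort study.

    Defaults mirror the study conditions the pipeline is designed for:
    a metabolite GWAS of 7,824 individuals, an outcome GWAS of 50,000,
    a cohort of 20,000, strong instruments and a causal effect of 0.2
    outcome SD per exposure SD.  Fracture prevalence defaults to 12.5%
    (53,184 cases of 426,795 in the consortium fracture GWAS).
    """

    n_snps: int = 50
    n_samples_exposure: int = 7824
    n_samples_outcome: int = 50_000
    n_samples_cohort: int = 20_000
    n_samples_panel: int = 5_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    true_beta: float = 0.2
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    n_outliers: int = 0
    outlier_shift: float = 0.0
    ld_blocks: tuple[tuple[int, float], ...] = ()
    fracture_prevalence: float = 0.125
    metabolite_noise_sd: float = 1.0
    phenotype_noise_sd: float = 1.0
    covariate_effects: bool = True
    snp_spacing_bp: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range must be within (0, 0.5], got {self.maf_range}")
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        if self.n_outliers > self.n_snps:
            raise ValidationError("n_outliers cannot exceed n_snps")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValidationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if sum(size for size, _ in self.ld_blocks) > self.n_snps:
            raise ValidationError("ld_blocks sizes sum exceeds n_snps")
        for size, r in self.ld_blocks:
            if not (0 <= r < 1):
                raise ValidationError(f"within-block r must be in [0,1), got {r}")
            if size < 1:
                raise ValidationError("block size must be >= 1")
        if not (0 < self.fracture_prevalence < 1):
            raise ValidationError("fracture_prevalence must be in (0,1)")


@dataclass(frozen=True)
class Truth:
    """Ground truth behind one simulated dataset."""

    true_beta: float
    gamma: np.ndarray          # per-SNP true exposure effects
    alpha: np.ndarray          # per-SNP direct (pleiotropic) outcome effects
    outlier_indices: tuple[int, ...]
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.gamma) != len(self.alpha):
            raise ValidationError("gamma and alpha lengths differ")


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, _P_FLOOR)


def _gwas_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _positions(config: SimConfig) -> np.ndarray:
    return 1 + np.arange(config.n_snps, dtype=int) * config.snp_spacing_bp


def simulate_two_sample_gwas(
    config: SimConfig,
) -> tuple[list[SummaryRecord], list[SummaryRecord], Truth]:
    """Draw exposure and outcome summary statistics with known truth.

    Returns ``(exposure_records, outcome_records, truth)``.  Outlier SNPs
    (``config.n_outliers`` of them, chosen at random) have their observed
    outcome effect shifted by ``config.outlier_shift``.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snps
    maf = rng.uniform(*config.maf_range, size=J)
    gamma = rng.uniform(0.05, 0.3, size=J) * rng.choice([-1.0, 1.0], size=J)

    if config.pleiotropy_mode == "none":
        alpha = np.zeros(J)
    elif config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_sd, size=J)
    else:
        # directional pleiotropy is defined relative to the
        # exposure-increasing allele: orient the direct effect with
        # sign(gamma) so the planted mean survives re-orientation
        alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd,
                           size=J) * np.sign(gamma)

    se_x = _gwas_se(maf, config.n_samples_exposure)
    se_y = _gwas_se(maf, config.n_samples_outcome)
    gamma_hat = gamma + rng.normal(0.0, se_x)
    big_gamma = config.true_beta * gamma + alpha
    big_gamma_hat = big_gamma + rng.normal(0.0, se_y)

    outliers: tuple[int, ...] = ()
    if config.n_outliers:
        outliers = tuple(sorted(rng.choice(J, size=config.n_outliers, replace=False)))
        big_gamma_hat = big_gamma_hat.copy()
        big_gamma_hat[list(outliers)] += config.outlier_shift

    pos = _positions(config)
    p_x = _two_sided_p(gamma_hat, se_x)
    p_y = _two_sided_p(big_gamma_hat, se_y)

    exposure = [
        SummaryRecord(
            snp_id=f"rs{j + 1}", chrom="1", pos=int(pos[j]),
            effect_allele="A", other_allele="G",
            eaf=float(maf[j]), beta=float(gamma_hat[j]), se=float(se_x[j]),
            pval=float(p_x[j]), n=config.n_samples_exposure,
        )
        for j in range(J)
    ]
    outcome = [
        SummaryRecord(
            snp_id=f"rs{j + 1}", chrom="1", pos=int(pos[j]),
            effect_allele="A", other_allele="G",
            eaf=float(maf[j]), beta=float(big_gamma_hat[j]), se=float(se_y[j]),
            pval=float(p_y[j]), n=config.n_samples_outcome,
        )
        for j in range(J)
    ]
    truth = Truth(true_beta=config.true_beta, gamma=gamma, alpha=alpha,
                  outlier_indices=outliers, maf=maf)
    return exposure, outcome, truth


def simulate_ld_panel(config: SimConfig) -> tuple[list[str], np.ndarray]:
    """Simulate a diploid reference panel with block LD structure.

    Within a block every SNP copies a shared latent haplotype allele with
    probability ``sqrt(r)``, giving pairwise allele correlation exactly
    ``r`` in expectation; blocks share one allele frequency.  SNPs outside
    any block are independent.  Genotypes are the sum of two independent
    haplotypes, hence Hardy-Weinberg at the drawn frequency.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_samples_panel
    J = config.n_snps

    block_of = np.full(J, -1, dtype=int)
    start = 0
    for b, (size, _r) in enumerate(config.ld_blocks):
        block_of[start:start + size] = b
        start += size

    geno = np.zeros((n, J), dtype=float)
    # one maf per block (shared), independent maf elsewhere
    block_maf = {b: rng.uniform(*config.maf_range) for b in range(len(config.ld_blocks))}
    free_maf = rng.uniform(*config.maf_range, size=J)

    for hap in range(2):
        alleles = np.zeros((n, J))
        base = {b: (rng.random(n) < block_maf[b]).astype(float)
                for b in range(len(config.ld_blocks))}
        for j in range(J):
            b = block_of[j]
            if b == -1:
                alleles[:, j] = (rng.random(n) < free_maf[j]).astype(float)
            else:
                r = config.ld_blocks[b][1]
                copy = rng.random(n) < np.sqrt(r)
                fresh = (rng.random(n) < block_maf[b]).astype(float)
                alleles[:, j] = np.where(copy, base[b], fresh)
        geno += alleles

    snp_ids = [f"rs{j + 1}" for j in range(J)]
    return snp_ids, geno


# cohort covariate effects on the continuous bone phenotype (per raw unit);
# magnitudes chosen so covariates explain a realistic minor share of variance
_COVARIATE_BETAS = {
    "age": -0.01, "sex": 0.15, "weight": 0.005, "height": -0.003,
    **{f"pc{k}": 0.05 for k in range(1, 11)},
}


def simulate_cohort(
    config: SimConfig,
    snp_weights: Sequence[float],
    mafs: Sequence[float] | None = None,
):
    """Simulate an individual-level cohort under the GRS study design.

    The latent metabolite is ``X @ snp_weights + noise``; the continuous
    bone phenotype is ``true_beta * metabolite`` plus covariate effects and
    noise; fracture is Bernoulli with a logistic model whose intercept is
    set from ``config.fracture_prevalence`` and whose risk decreases with
    the bone phenotype.  Returns ``(Cohort, Truth)``.
    """
    from .grs_association import Cohort

    weights = np.asarray(snp_weights, dtype=float)
    if len(weights) != config.n_snps:
        raise ValidationError(
            f"snp_weights length {len(weights)} != n_snps {config.n_snps}")
    if config.n_samples_cohort < 2:
        raise ValidationError("n_samples_cohort must be >= 2")

    rng = np.random.default_rng(config.seed + 2)
    n = config.n_samples_cohort
    J = config.n_snps
    maf = (np.asarray(mafs, dtype=float) if mafs is not None
           else rng.uniform(*config.maf_range, size=J))
    X = (rng.random((n, J)) < maf).astype(float) + (rng.random((n, J)) < maf)

    age = rng.normal(57.0, 8.0, size=n)
    sex = (rng.random(n) < 0.5).astype(float)
    height = rng.normal(163.0, 7.0, size=n) + 13.0 * sex
    weight = rng.normal(70.0, 12.0, size=n) + 8.0 * sex
    # orthonormal PC columns, rescaled to unit variance
    pcs, _ = np.linalg.qr(rng.normal(size=(n, 10)))
    pcs *= np.sqrt(n)

    metabolite = X @ weights + rng.normal(0.0, config.metabolite_noise_sd, size=n)

    ebmd = config.true_beta * metabolite
    if config.covariate_effects:
        ebmd = (ebmd
                + _COVARIATE_BETAS["age"] * age
                + _COVARIATE_BETAS["sex"] * sex
                + _COVARIATE_BETAS["weight"] * weight
                + _COVARIATE_BETAS["height"] * height
                + pcs @ np.full(10, _COVARIATE_BETAS["pc1"]))
    ebmd = ebmd + rng.normal(0.0, config.phenotype_noise_sd, size=n)

    prev = config.fracture_prevalence
    logit = np.log(prev / (1.0 - prev)) - 0.3 * (ebmd - ebmd.mean()) / max(ebmd.std(), 1e-12)
    fracture = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    import pandas as pd

    covariates = pd.DataFrame({
        "age": age, "sex": sex, "weight": weight, "height": height,
        **{f"pc{k + 1}": pcs[:, k] for k in range(10)},
    })
    cohort = Cohort(
        sample_ids=[f"id{i + 1}" for i in range(n)],
        snp_ids=[f"rs{j + 1}" for j in range(J)],
        dosages=X,
        covariates=covariates,
        ebmd=ebmd,
        fracture=fracture,
    )
    truth = Truth(true_beta=config.true_beta, gamma=weights,
                  alpha=np.zeros(J), outlier_indices=(), maf=maf)
    return cohort, truth


def plant_outliers(
    outcome_records: Sequence[SummaryRecord],
    indices: Sequence[int],
    shift: float,
) -> list[SummaryRecord]:
    """Shift the outcome beta of the named records by exactly ``shift``.

    All other fields (including the p-value) are left untouched, so the
    planted pleiotropy is visible only through the effect estimate — the
    situation the residual-sum outlier test is built to detect.
    """
    records = list(outcome_records)
    for i in indices:
        if not (0 <= i < len(records)):
            raise ValidationError(f"outlier index {i} out of range [0, {len(records)})")
    out = []
    idx = set(indices)
    for i, rec in enumerate(records):
        out.append(replace(rec, beta=rec.beta + shift) if i in idx else rec)
    return out
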