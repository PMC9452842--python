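"""Multivariable Mendelian randomization.

Joint estimation of the independent causal effects of K exposures on one
outcome by weighted least squares on SNP-level marginal effects:

    lambda_outcome,j = sum_k lambda_k,j * beta_k + eps_j,   eps_j ~ N(0, s2)

with weights 1/se_Yj^2 and no intercept.  Standard errors use the
multiplicative-overdispersion covariance (scaled by max(1, Q/(J-K))),
paralleling the univariable random-effects convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import SummaryRecord, ValidationError
from .mr_core import Z95


@dataclass(frozen=True)
class MultiPanel:
    """J instruments with a K-column exposure effect matrix and outcome effects."""

    snp_ids: tuple[str, ...]
    exposure_names: tuple[str, ...]
    exposure_betas: np.ndarray   # J x K
    exposure_ses: np.ndarray     # J x K
    outcome_betas: np.ndarray    # J
    outcome_ses: np.ndarray      # J
    flipped: np.ndarray          # J x K bool, allele flips during alignment

    def __post_init__(self) -> None:
        J, K = self.exposure_betas.shape
        if len(self.snp_ids) != J or len(set(self.snp_ids)) != J:
            raise ValidationError("snp_ids must be unique and match row count")
        if len(self.exposure_names) != K:
            raise ValidationError("exposure_names length != K")
        if K < 1 or J <= K:
            raise ValidationError(f"need J > K >= 1 instruments, got J={J}, K={K}")
        if np.any(self.outcome_ses <= 0):
            raise ValidationError("outcome SEs must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)


@dataclass(frozen=True)
class MvmrEstimate:
    """Per-exposure adjusted causal effects from one joint WLS fit."""

    exposure_names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    sigma2: float
    n_snp: int

    def ci95(self, k: int) -> tuple[float, float]:
        return (float(self.beta[k] - Z95 * self.se[k]),
                float(self.beta[k] + Z95 * self.se[k]))

    def as_rows(self) -> list[dict]:
        rows = []
        for k, name in enumerate(self.exposure_names):
            lo, hi = self.ci95(k)
            rows.append({
                "exposure": name, "beta": float(self.beta[k]),
                "se": float(self.se[k]), "ci_lo": lo, "ci_hi": hi,
                "pval": float(self.pval[k]), "n_snp": self.n_snp,
                "sigma2": self.sigma2,
            })
        return rows


def build_multi_panel(
    exposure_sets: Sequence[Sequence[SummaryRecord]],
    outcome: Sequence[SummaryRecord],
    exposure_names: Sequence[str] | None = None,
) -> tuple[MultiPanel, dict[str, object]]:
    """Assemble the J x K effect matrix from K exposure tables and one outcome.

    The instrument set is the intersection of SNPs present in every exposure
    table and the outcome table (complete-case).  Alleles align to the first
    exposure's effect allele; swapped records are sign-flipped and flagged,
    full mismatches drop the SNP with a log entry.
    """
    K = len(exposure_sets)
    if K < 1:
        raise ValidationError("need at least one exposure set")
    names = (tuple(exposure_names) if exposure_names is not None
             else tuple(f"exposure{k + 1}" for k in range(K)))
    maps: list[dict[str, SummaryRecord]] = []
    for k, records in enumerate(exposure_sets):
        records = list(records)
        m = {r.snp_id: r for r in records}
        if len(m) != len(records):
            raise ValidationError(f"duplicate snp_id in exposure set {names[k]}")
        maps.append(m)
    outcome = list(outcome)
    out_map = {r.snp_id: r for r in outcome}
    if len(out_map) != len(outcome):
        raise ValidationError("duplicate snp_id in outcome set")

    shared = [s for s in maps[0] if all(s in m for m in maps[1:]) and s in out_map]
    dropped: list[tuple[str, str]] = []
    ids: list[str] = []
    eb, es, ob, os_, flips = [], [], [], [], []
    for s in shared:
        ref = maps[0][s]
        row_b, row_s, row_f = [], [], []
        ok = True
        for m in maps:
            rec = m[s]
            if (rec.effect_allele, rec.other_allele) == (ref.effect_allele, ref.other_allele):
                row_b.append(rec.beta)
                row_f.append(False)
            elif (rec.effect_allele, rec.other_allele) == (ref.other_allele, ref.effect_allele):
                row_b.append(-rec.beta)
                row_f.append(True)
            else:
                dropped.append((s, "allele mismatch (exposure)"))
                ok = False
                break
            row_s.append(rec.se)
        if not ok:
            continue
        orec = out_map[s]
        if (orec.effect_allele, orec.other_allele) == (ref.effect_allele, ref.other_allele):
            o_beta = orec.beta
        elif (orec.effect_allele, orec.other_allele) == (ref.other_allele, ref.effect_allele):
            o_beta = -orec.beta
        else:
            dropped.append((s, "allele mismatch (outcome)"))
            continue
        ids.append(s)
        eb.append(row_b)
        es.append(row_s)
        flips.append(row_f)
        ob.append(o_beta)
        os_.append(orec.se)
    if not ids:
        raise ValidationError(
            "no SNP observed in every exposure table and the outcome table")
    panel = MultiPanel(
        snp_ids=tuple(ids), exposure_names=names,
        exposure_betas=np.asarray(eb), exposure_ses=np.asarray(es),
        outcome_betas=np.asarray(ob), outcome_ses=np.asarray(os_),
        flipped=np.asarray(flips, dtype=bool),
    )
    return panel, {"n_snp": len(ids), "dropped": dropped}


def mvmr_wls(panel: MultiPanel) -> MvmrEstimate:
    """No-intercept weighted least squares of outcome on exposure effects.

    ``beta = (L' W L)^-1 L' W y`` with ``W = diag(1/se_Yj^2)``; the
    coefficient covariance ``(L' W L)^-1`` is inflated by
    ``max(1, Q/(J-K))`` where Q is the weighted residual sum of squares;
    p-values are two-sided normal; the residual variance ``sigma2`` is
    reported as ``Q/(J-K)``.
    """
    L = panel.exposure_betas
    y = panel.outcome_betas
    J, K = L.shape
    w = 1.0 / panel.outcome_ses**2
    WL = L * w[:, None]
    xtwx = L.T @ WL
    rank = np.linalg.matrix_rank(xtwx)
    if rank < K:
        raise ValidationError(
            f"exposure effect matrix rank {rank} < {K}: collinear exposures"
            f" among {panel.exposure_names}")
    beta = np.linalg.solve(xtwx, WL.T @ y)
    resid = y - L @ beta
    Q = float(np.sum(w * resid**2))
    sigma2 = Q / (J - K)
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    se = np.sqrt(np.diag(cov))
    pval = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return MvmrEstimate(
        exposure_names=panel.exposure_names, beta=beta, se=se, pval=pval,
        sigma2=sigma2, n_snp=J,
    )
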