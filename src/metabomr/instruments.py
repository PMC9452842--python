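"""Instrument selection and quality control.

Record-level QC (strand-ambiguous alleles, duplicated rsIDs, low imputation
quality, sex chromosomes), greedy LD clumping against a reference panel,
exposure/outcome allele harmonization, and instrument-strength metrics
(per-SNP F statistic and proportion of variance explained).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import MISSING_DOSAGE, SummaryRecord, ValidationError

DEFAULT_QC_RULES = (
    "palindromic", "missing_rsid", "duplicate_rsid", "duplicate_position",
    "low_info", "sex_chromosome",
)

INFO_THRESHOLD = 0.9  # records with imputation INFO < 0.9 are removed
SEX_CHROMOSOMES = frozenset({"X", "Y", "23", "24", "chrX", "chrY"})


@dataclass(frozen=True)
class HarmonizedPanel:
    """J instruments with exposure and outcome effects on a common allele.

    ``gamma``/``se_x`` are the per-SNP exposure effects and standard errors,
    ``big_gamma``/``se_y`` the outcome effects, all expressed relative to
    the exposure effect allele.  ``flipped`` marks SNPs whose outcome
    alleles were swapped during alignment.
    """

    snp_ids: tuple[str, ...]
    gamma: np.ndarray
    se_x: np.ndarray
    big_gamma: np.ndarray
    se_y: np.ndarray
    flipped: np.ndarray  # bool per SNP

    def __post_init__(self) -> None:
        n = len(self.snp_ids)
        for name in ("gamma", "se_x", "big_gamma", "se_y", "flipped"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length != {n}")
        if len(set(self.snp_ids)) != n:
            raise ValidationError("duplicate snp_id in panel")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValidationError("standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: Sequence[int]) -> "HarmonizedPanel":
        keep = list(keep)
        return HarmonizedPanel(
            snp_ids=tuple(self.snp_ids[i] for i in keep),
            gamma=self.gamma[keep], se_x=self.se_x[keep],
            big_gamma=self.big_gamma[keep], se_y=self.se_y[keep],
            flipped=self.flipped[keep],
        )


@dataclass(frozen=True)
class StrengthReport:
    """Instrument-strength summary: per-SNP F and PVE plus totals."""

    snp_ids: tuple[str, ...]
    f_stat: np.ndarray
    pve: np.ndarray

    @property
    def total_pve(self) -> float:
        return float(np.sum(self.pve))

    @property
    def mean_f(self) -> float:
        return float(np.mean(self.f_stat))


def qc_filter(
    records: Sequence[SummaryRecord],
    rules: Sequence[str] = DEFAULT_QC_RULES,
) -> tuple[list[SummaryRecord], dict[str, int]]:
    """Apply record-level QC; returns kept records and per-rule counts.

    Rules: ``palindromic`` drops A/T and G/C SNPs (strand-ambiguous);
    ``missing_rsid`` drops SNPs without an rs identifier; ``duplicate_rsid``
    and ``duplicate_position`` drop *all* copies of a duplicated rsID or
    (chrom, pos); ``low_info`` drops imputation INFO < 0.9 (INFO = 0.9 is
    kept); ``sex_chromosome`` drops chromosomes X and Y.  A record failing
    several rules counts once, under the first rule that catches it.
    """
    rules = tuple(rules)
    rsid_counts = Counter(r.snp_id for r in records)
    pos_counts = Counter((r.chrom, r.pos) for r in records)
    log = {rule: 0 for rule in rules}
    kept: list[SummaryRecord] = []
    for r in records:
        reason = None
        for rule in rules:
            if rule == "palindromic" and r.is_palindromic():
                reason = rule
            elif rule == "missing_rsid" and not r.snp_id.startswith("rs"):
                reason = rule
            elif rule == "duplicate_rsid" and rsid_counts[r.snp_id] > 1:
                reason = rule
            elif rule == "duplicate_position" and pos_counts[(r.chrom, r.pos)] > 1:
                reason = rule
            elif rule == "low_info" and r.info < INFO_THRESHOLD:
                reason = rule
            elif rule == "sex_chromosome" and r.chrom in SEX_CHROMOSOMES:
                reason = rule
            if reason:
                break
        if reason:
            log[reason] += 1
        else:
            kept.append(r)
    return kept, log


def ld_r2(
    dosages: np.ndarray,
    snp_ids: Sequence[str],
    snp_a: str,
    snp_b: str,
) -> float:
    """Squared Pearson correlation between two SNPs' dosage vectors."""
    ids = list(snp_ids)
    a = np.asarray(dosages[:, ids.index(snp_a)], dtype=float)
    b = np.asarray(dosages[:, ids.index(snp_b)], dtype=float)
    mask = (a != MISSING_DOSAGE) & (b != MISSING_DOSAGE)
    a, b = a[mask], b[mask]
    if len(a) < 2:
        raise ValidationError("need >=2 samples with non-missing dosages")
    if a.std() == 0 or b.std() == 0:
        raise ValidationError(
            f"LD undefined: zero dosage variance for {snp_a if a.std() == 0 else snp_b}")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(
    records: Sequence[SummaryRecord],
    panel_dosages: np.ndarray | None,
    panel_snp_ids: Sequence[str] | None,
    p_thresh: float = 1e-5,
    r2_thresh: float = 0.1,
    window_kb: float = 500.0,
) -> tuple[list[str], dict[str, object]]:
    """Greedy LD clumping of significant SNPs into independent index SNPs.

    Restricts to ``pval < p_thresh``, then repeatedly takes the
    smallest-p remaining SNP as an index and removes every remaining SNP on
    the same chromosome within ``window_kb`` whose r² with the index exceeds
    ``r2_thresh``.  Ties on p break on (chrom, pos), then snp_id.  SNPs
    absent from the panel are treated as unlinked and listed in the log.
    Returns the index snp_ids (selection order) and a log dict.
    """
    window_bp = window_kb * 1000.0
    candidates = [r for r in records if r.pval < p_thresh]
    log: dict[str, object] = {
        "n_input": len(records),
        "n_candidates": len(candidates),
        "missing_from_panel": [],
        "removed": {},
    }
    if not candidates:
        return [], log

    panel_index: dict[str, int] = {}
    if panel_snp_ids is not None:
        panel_index = {s: i for i, s in enumerate(panel_snp_ids)}
    missing = [r.snp_id for r in candidates if r.snp_id not in panel_index]
    log["missing_from_panel"] = missing

    def sort_key(r: SummaryRecord):
        return (r.pval, r.chrom, r.pos, r.snp_id)

    remaining = sorted(candidates, key=sort_key)
    index_snps: list[str] = []
    removed: dict[str, list[str]] = {}
    while remaining:
        index = remaining.pop(0)
        index_snps.append(index.snp_id)
        removed[index.snp_id] = []
        survivors = []
        for r in remaining:
            linked = False
            if (r.chrom == index.chrom
                    and abs(r.pos - index.pos) <= window_bp
                    and r.snp_id in panel_index
                    and index.snp_id in panel_index):
                try:
                    r2 = ld_r2(panel_dosages, list(panel_index), index.snp_id, r.snp_id)
                except ValidationError:
                    r2 = 0.0
                linked = r2 > r2_thresh
            if linked:
                removed[index.snp_id].append(r.snp_id)
            else:
                survivors.append(r)
        remaining = survivors
    log["removed"] = removed
    return index_snps, log


def harmonize(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
) -> tuple[HarmonizedPanel, dict[str, object]]:
    """Align outcome effects to the exposure effect allele per SNP.

    Intersects on snp_id; where the outcome's alleles are swapped relative
    to the exposure, the outcome beta is sign-flipped (and eaf reflected)
    and the SNP flagged; where the allele sets differ entirely the SNP is
    dropped and logged.  Palindromic SNPs are expected to have been removed
    upstream by :func:`qc_filter`.
    """
    out_by_id = {r.snp_id: r for r in outcome}
    ids: list[str] = []
    gamma, se_x, big_gamma, se_y, flipped = [], [], [], [], []
    dropped: list[tuple[str, str]] = []
    for ex in exposure:
        oc = out_by_id.get(ex.snp_id)
        if oc is None:
            dropped.append((ex.snp_id, "absent from outcome"))
            continue
        if (ex.effect_allele, ex.other_allele) == (oc.effect_allele, oc.other_allele):
            flip = False
        elif (ex.effect_allele, ex.other_allele) == (oc.other_allele, oc.effect_allele):
            flip = True
        else:
            dropped.append((ex.snp_id, "allele mismatch"))
            continue
        ids.append(ex.snp_id)
        gamma.append(ex.beta)
        se_x.append(ex.se)
        big_gamma.append(-oc.beta if flip else oc.beta)
        se_y.append(oc.se)
        flipped.append(flip)
    if not ids:
        raise ValidationError(
            "no SNPs shared between exposure and outcome after alignment")
    panel = HarmonizedPanel(
        snp_ids=tuple(ids),
        gamma=np.asarray(gamma), se_x=np.asarray(se_x),
        big_gamma=np.asarray(big_gamma), se_y=np.asarray(se_y),
        flipped=np.asarray(flipped, dtype=bool),
    )
    return panel, {"n_harmonized": len(ids), "dropped": dropped}


def instrument_strength(
    records: Sequence[SummaryRecord] | HarmonizedPanel,
    n: int,
) -> StrengthReport:
    """Per-SNP F statistic and proportion of variance explained.

    ``F_j = (gamma_j / se_j)^2`` and ``PVE_j = gamma_j^2 / (gamma_j^2 +
    n * se_j^2)``, the standard summary-statistic approximations; ``n`` is
    the exposure GWAS sample size.
    """
    if n <= 2:
        raise ValidationError("exposure sample size must exceed 2")
    if isinstance(records, HarmonizedPanel):
        ids = records.snp_ids
        beta, se = records.gamma, records.se_x
    else:
        ids = tuple(r.snp_id for r in records)
        beta = np.asarray([r.beta for r in records])
        se = np.asarray([r.se for r in records])
    f = (beta / se) ** 2
    pve = beta**2 / (beta**2 + n * se**2)
    return StrengthReport(snp_ids=ids, f_stat=f, pve=pve)
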