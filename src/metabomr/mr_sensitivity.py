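"""Robustness machinery around the core MR estimators.

MR-PRESSO (global residual-sum test, per-SNP outlier test, distortion
test), leave-one-out influence analysis, the numeric tables behind funnel
and scatter plots, instrument-selection threshold grids, and
reverse-direction MR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .instruments import HarmonizedPanel, clump, harmonize
from .io_formats import SummaryRecord, ValidationError
from .mr_core import MREstimate, egger, ivw, wald_ratios


@dataclass(frozen=True)
class PressoResult:
    """Outcome of the pleiotropy residual-sum and outlier procedure."""

    rss_obs: float
    global_pval: float
    outlier_pvals: np.ndarray        # per-SNP empirical p (unadjusted)
    outlier_indices: tuple[int, ...]  # after Bonferroni control
    raw_estimate: MREstimate
    corrected_estimate: MREstimate | None
    distortion_pval: float | None
    distortion_skipped: bool

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_indices)


def _loo_ivw_betas(gamma: np.ndarray, big_gamma: np.ndarray, se_y: np.ndarray):
    """Leave-one-out fixed-effect IVW estimates, vectorized.

    ``big_gamma`` may be a (sims, J) matrix; broadcasting then yields the
    LOO estimates for every simulated outcome vector at once.
    """
    wy = gamma / se_y**2          # weight * gamma contribution per SNP
    wg = gamma**2 / se_y**2
    num = big_gamma * wy          # (.., J)
    a = num.sum(axis=-1, keepdims=True) - num
    b = wg.sum() - wg
    return a / b


def mr_presso(
    panel: HarmonizedPanel,
    n_sim: int = 1000,
    seed: int = 0,
    sig_level: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: simulation-based pleiotropy residual-sum and outlier test.

    The observed statistic is the weighted residual sum
    ``RSS = sum_j (Gamma_j - b_{-j} gamma_j)^2 / se_Yj^2`` where ``b_{-j}``
    is the IVW estimate leaving SNP j out.  The null distribution redraws
    both sides, ``gamma*_j ~ N(gamma_j, se_Xj)`` and ``Gamma*_j ~
    N(b_{-j} gamma_j, se_Yj)``, ``n_sim`` times and recomputes RSS
    (including the leave-one-out estimates) on each draw; redrawing the
    exposure effects too is essential because the observed residual
    carries exposure-side noise (variance ``se_Y^2 + b^2 se_X^2``), and a
    null that omitted it would reject far too often.  Per-SNP outlier
    p-values use the same simulated residuals,
    Bonferroni-controlled across the J instruments at ``sig_level``.  The
    distortion test compares the raw-vs-corrected estimate change against
    removal of random SNP subsets of the same size.
    """
    J = panel.n_snp
    if J < 4:
        raise ValidationError("MR-PRESSO needs >= 4 instruments")
    rng = np.random.default_rng(seed)
    g, G, sy = panel.gamma, panel.big_gamma, panel.se_y

    b_loo = _loo_ivw_betas(g, G, sy)                      # (J,)
    resid_obs = (G - b_loo * g) ** 2 / sy**2
    rss_obs = float(resid_obs.sum())

    # parametric null: redraw exposure and outcome effects jointly
    g_star = rng.normal(g, panel.se_x, size=(n_sim, J))
    G_star = rng.normal(b_loo * g, sy, size=(n_sim, J))
    wy_s = g_star / sy**2
    wg_s = g_star**2 / sy**2
    num = G_star * wy_s
    b_star = ((num.sum(axis=1, keepdims=True) - num)
              / (wg_s.sum(axis=1, keepdims=True) - wg_s))  # (n_sim, J)
    resid_star = (G_star - b_star * g_star) ** 2 / sy**2
    rss_star = resid_star.sum(axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    outlier_p = (1 + np.sum(resid_star >= resid_obs[None, :], axis=0)) / (n_sim + 1)
    outliers = tuple(np.flatnonzero(outlier_p * J < sig_level).tolist())

    raw = ivw(panel, model="auto")
    corrected = None
    distortion_p: float | None = None
    skipped = True
    if outliers and len(outliers) < J - 1:
        keep = [j for j in range(J) if j not in outliers]
        corrected = ivw(panel.subset(keep), model="auto")
        d_obs = raw.beta - corrected.beta
        n_out = len(outliers)
        n_sub = 1000
        d_rand = np.empty(n_sub)
        for s in range(n_sub):
            drop = rng.choice(J, size=n_out, replace=False)
            mask = np.ones(J, dtype=bool)
            mask[drop] = False
            w = g[mask] ** 2 / sy[mask] ** 2
            theta = G[mask] / g[mask]
            d_rand[s] = raw.beta - float(np.sum(w * theta) / np.sum(w))
        distortion_p = float((1 + np.sum(np.abs(d_rand) >= abs(d_obs))) / (n_sub + 1))
        skipped = False
    return PressoResult(
        rss_obs=rss_obs, global_pval=global_p, outlier_pvals=outlier_p,
        outlier_indices=outliers, raw_estimate=raw,
        corrected_estimate=corrected, distortion_pval=distortion_p,
        distortion_skipped=skipped,
    )


def leave_one_out(panel: HarmonizedPanel, q_alpha: float = 0.05) -> pd.DataFrame:
    """IVW estimate with each instrument omitted in turn, plus the full-panel
    row (snp_id = 'ALL').  A row is flagged influential when omitting the SNP
    flips the estimate's sign or moves it by more than one full-panel SE."""
    if panel.n_snp < 3:
        raise ValidationError("leave-one-out needs >= 3 instruments")
    full = ivw(panel, model="auto", q_alpha=q_alpha)
    rows = []
    for j in range(panel.n_snp):
        keep = [k for k in range(panel.n_snp) if k != j]
        est = ivw(panel.subset(keep), model="auto", q_alpha=q_alpha)
        shifted = abs(est.beta - full.beta) > full.se
        flipped = np.sign(est.beta) != np.sign(full.beta) and full.beta != 0
        rows.append({
            "omitted": panel.snp_ids[j], "beta": est.beta, "se": est.se,
            "pval": est.pval, "method": est.method,
            "influential": bool(shifted or flipped),
        })
    rows.append({
        "omitted": "ALL", "beta": full.beta, "se": full.se,
        "pval": full.pval, "method": full.method, "influential": False,
    })
    return pd.DataFrame(rows)


def funnel_scatter_data(panel: HarmonizedPanel) -> dict[str, object]:
    """Numeric tables behind the funnel and scatter diagnostics.

    The funnel table holds each SNP's Wald ratio against its precision;
    the scatter table the (exposure, outcome) effect pairs.  Annotated
    slopes equal the IVW and Egger estimates exactly.
    """
    theta, theta_se = wald_ratios(panel)
    ivw_est = ivw(panel, model="auto")
    egger_est = egger(panel) if panel.n_snp >= 3 else None
    funnel = pd.DataFrame({
        "snp_id": panel.snp_ids, "theta": theta, "precision": 1.0 / theta_se,
    })
    scatter = pd.DataFrame({
        "snp_id": panel.snp_ids, "gamma": panel.gamma, "se_x": panel.se_x,
        "big_gamma": panel.big_gamma, "se_y": panel.se_y,
    })
    return {
        "funnel": funnel, "scatter": scatter,
        "ivw_slope": ivw_est.beta,
        "egger_slope": None if egger_est is None else egger_est.beta,
        "egger_intercept": None if egger_est is None else egger_est.egger_intercept,
    }


def threshold_grid(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    panel_dosages: np.ndarray | None,
    panel_snp_ids: Sequence[str] | None,
    p_list: Sequence[float],
    r2_list: Sequence[float],
    window_kb: float = 500.0,
    q_alpha: float = 0.05,
) -> pd.DataFrame:
    """Re-run clump -> harmonize -> IVW over a grid of selection thresholds.

    Cells left with fewer than two instruments are reported as empty rows
    rather than failing, so the grid always has len(p_list) * len(r2_list)
    rows.
    """
    if not p_list or not r2_list:
        raise ValidationError("p_list and r2_list must be non-empty")
    rows = []
    by_id = {r.snp_id: r for r in exposure}
    for p_thresh in p_list:
        for r2_thresh in r2_list:
            index_ids, _ = clump(exposure, panel_dosages, panel_snp_ids,
                                 p_thresh=p_thresh, r2_thresh=r2_thresh,
                                 window_kb=window_kb)
            row = {"p_thresh": p_thresh, "r2_thresh": r2_thresh,
                   "n_snp": 0, "beta": np.nan, "se": np.nan,
                   "pval": np.nan, "method": "empty"}
            if len(index_ids) >= 2:
                sel = [by_id[s] for s in index_ids]
                try:
                    panel, _ = harmonize(sel, outcome)
                except ValidationError:
                    rows.append(row)
                    continue
                if panel.n_snp >= 2:
                    est = ivw(panel, model="auto", q_alpha=q_alpha)
                    row.update(n_snp=panel.n_snp, beta=est.beta, se=est.se,
                               pval=est.pval, method=est.method)
            rows.append(row)
    return pd.DataFrame(rows)


def reverse_mr(
    reverse_exposure: Sequence[SummaryRecord],
    reverse_outcome: Sequence[SummaryRecord],
    panel_dosages: np.ndarray | None,
    panel_snp_ids: Sequence[str] | None,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.1,
    window_kb: float = 500.0,
    q_alpha: float = 0.05,
) -> MREstimate:
    """Forward machinery with the roles swapped: the original outcome trait
    becomes the exposure, instrumented at the genome-wide threshold 5e-8."""
    index_ids, _ = clump(reverse_exposure, panel_dosages, panel_snp_ids,
                         p_thresh=p_thresh, r2_thresh=r2_thresh,
                         window_kb=window_kb)
    if not index_ids:
        raise ValidationError(
            f"no instruments at p < {p_thresh} for the reverse direction")
    by_id = {r.snp_id: r for r in reverse_exposure}
    panel, _ = harmonize([by_id[s] for s in index_ids], reverse_outcome)
    return ivw(panel, model="auto", q_alpha=q_alpha)
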