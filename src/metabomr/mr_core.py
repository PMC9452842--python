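"""Two-sample Mendelian randomization estimators.

Per-SNP Wald ratios are combined by inverse-variance weighting (fixed
effects, or multiplicative random effects when Cochran's Q rejects
homogeneity), by MR-Egger weighted regression with an intercept for
directional pleiotropy, by the weighted median, and by the mode-based
estimator.  All point estimates are invariant to flipping the orientation
of any SNP (negating both its exposure and outcome effect); p-values are
two-sided normal throughout, matching common MR package behaviour at the
instrument counts this design yields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .instruments import HarmonizedPanel
from .io_formats import ValidationError

Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass(frozen=True)
class MREstimate:
    """One causal-effect estimate with its heterogeneity diagnostics."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    Q: float | None = None
    Q_df: int | None = None
    Q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - Z95 * self.se, self.beta + Z95 * self.se)

    def as_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "method": self.method, "beta": self.beta, "se": self.se,
            "ci_lo": lo, "ci_hi": hi, "pval": self.pval, "n_snp": self.n_snp,
            "Q": self.Q, "Q_df": self.Q_df, "Q_pval": self.Q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_pval": self.egger_intercept_pval,
        }


def _norm_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def wald_ratios(panel: HarmonizedPanel) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratio estimates theta_j = Gamma_j / gamma_j.

    The standard error is first-order delta method, se_j = se_Yj/|gamma_j|,
    which ignores exposure-side uncertainty (the convention of the
    estimators built on top of it).
    """
    zero = np.flatnonzero(panel.gamma == 0)
    if zero.size:
        raise ValidationError(
            f"zero exposure effect for {panel.snp_ids[zero[0]]}: Wald ratio undefined")
    theta = panel.big_gamma / panel.gamma
    se = panel.se_y / np.abs(panel.gamma)
    return theta, se


def _ivw_weights(panel: HarmonizedPanel) -> np.ndarray:
    return panel.gamma**2 / panel.se_y**2


def cochran_q(panel: HarmonizedPanel) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic of the Wald ratios around IVW."""
    if panel.n_snp < 2:
        raise ValidationError("Cochran's Q needs >= 2 instruments")
    theta, _ = wald_ratios(panel)
    w = _ivw_weights(panel)
    beta = float(np.sum(w * theta) / np.sum(w))
    Q = float(np.sum(w * (theta - beta) ** 2))
    df = panel.n_snp - 1
    return Q, df, float(stats.chi2.sf(Q, df))


def ivw(
    panel: HarmonizedPanel,
    model: str = "auto",
    q_alpha: float = 0.05,
) -> MREstimate:
    """Inverse-variance-weighted estimate with the fixed/random switch.

    Weights are ``gamma_j^2 / se_Yj^2`` (equivalently a no-intercept WLS of
    outcome on exposure effects).  ``model='auto'`` uses fixed effects
    unless Cochran's Q rejects homogeneity at ``q_alpha``, in which case the
    standard error is inflated by ``sqrt(Q / (J - 1))`` (multiplicative
    random effects, floored at the fixed-effect SE).  A single instrument
    degenerates to its Wald ratio.
    """
    if model not in ("fixed", "random", "auto"):
        raise ValidationError(f"unknown IVW model {model!r}")
    theta, theta_se = wald_ratios(panel)
    if panel.n_snp == 1:
        beta, se = float(theta[0]), float(theta_se[0])
        return MREstimate("wald", beta, se, _norm_p(beta, se), 1)
    w = _ivw_weights(panel)
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    Q = float(np.sum(w * (theta - beta) ** 2))
    df = panel.n_snp - 1
    q_pval = float(stats.chi2.sf(Q, df))
    inflate = max(1.0, np.sqrt(Q / df))
    if model == "fixed":
        use_random = False
    elif model == "random":
        use_random = True
    else:
        use_random = q_pval < q_alpha
    se = se_fixed * inflate if use_random else se_fixed
    method = "ivw_random" if use_random else "ivw_fixed"
    return MREstimate(method, beta, se, _norm_p(beta, se), panel.n_snp,
                      Q=Q, Q_df=df, Q_pval=q_pval)


def egger(panel: HarmonizedPanel) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure effects with
    an intercept estimating average directional pleiotropy.

    Each SNP is oriented so its exposure effect is positive before fitting
    (the estimator is not invariant to orientation otherwise); weights are
    ``1 / se_Yj^2``.
    """
    if panel.n_snp < 3:
        raise ValidationError("MR-Egger needs >= 3 instruments")
    sign = np.where(panel.gamma < 0, -1.0, 1.0)
    x = panel.gamma * sign
    y = panel.big_gamma * sign
    w = 1.0 / panel.se_y**2
    X = np.column_stack([np.ones_like(x), x])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    Q = float(np.sum(w * resid**2))
    df = panel.n_snp - 2
    cov = np.linalg.inv(xtwx) * max(1.0, Q / df)
    inter, slope = float(coef[0]), float(coef[1])
    se_inter, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    return MREstimate(
        "egger", slope, se_slope, _norm_p(slope, se_slope), panel.n_snp,
        Q=Q, Q_df=df, Q_pval=float(stats.chi2.sf(Q, df)),
        egger_intercept=inter, egger_intercept_se=se_inter,
        egger_intercept_pval=_norm_p(inter, se_inter),
    )


def _parametric_bootstrap_se(
    panel: HarmonizedPanel,
    estimator,
    n_boot: int,
    seed: int,
) -> float:
    """SD of the estimator over panels redrawn from N(gamma, se_x),
    N(Gamma, se_y) — the convention for the median and mode estimators."""
    rng = np.random.default_rng(seed)
    J = panel.n_snp
    gam = rng.normal(panel.gamma, panel.se_x, size=(n_boot, J))
    big = rng.normal(panel.big_gamma, panel.se_y, size=(n_boot, J))
    est = np.empty(n_boot)
    for b in range(n_boot):
        est[b] = estimator(gam[b], big[b], panel.se_y)
    return float(np.std(est, ddof=1))


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    theta = theta[order]
    w = w[order] / np.sum(w)
    mid = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, mid, theta))


def weighted_median(
    panel: HarmonizedPanel,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median estimator: consistent if valid instruments carry at
    least half the IVW weight.  SE by seeded parametric bootstrap."""
    if panel.n_snp < 3:
        raise ValidationError("weighted median needs >= 3 instruments")
    theta, _ = wald_ratios(panel)
    w = _ivw_weights(panel)
    beta = _weighted_median_point(theta, w)

    def est(gam, big, se_y):
        mask = gam != 0
        th = big[mask] / gam[mask]
        ww = gam[mask] ** 2 / se_y[mask] ** 2
        return _weighted_median_point(th, ww)

    se = _parametric_bootstrap_se(panel, est, n_boot, seed)
    return MREstimate("weighted_median", beta, se, _norm_p(beta, se), panel.n_snp)


def _mode_point(theta: np.ndarray, se: np.ndarray, phi: float) -> float:
    # modified-Silverman bandwidth on the ratio estimates, using the
    # normalized MAD so a tight majority cluster is not washed out
    s = np.std(theta, ddof=1)
    mad = stats.median_abs_deviation(theta, scale="normal")
    scale = min(s, mad) if mad > 0 else s
    if scale == 0:
        return float(theta[0])
    h = phi * 0.9 * scale * len(theta) ** (-1 / 5)
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 512)
    w = 1.0 / se**2
    dens = np.sum(
        w[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2),
        axis=1)
    return float(grid[int(np.argmax(dens))])  # argmax ties -> smallest grid point


def mode_based(
    panel: HarmonizedPanel,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimator: the mode of an inverse-variance-weighted
    kernel density over the Wald ratios; consistent when the largest group
    of instruments shares the true effect.  SE by seeded parametric
    bootstrap."""
    if panel.n_snp < 3:
        raise ValidationError("mode-based estimator needs >= 3 instruments")
    if phi <= 0:
        raise ValidationError("bandwidth multiplier phi must be positive")
    theta, theta_se = wald_ratios(panel)
    beta = _mode_point(theta, theta_se, phi)

    def est(gam, big, se_y):
        mask = gam != 0
        th = big[mask] / gam[mask]
        tse = se_y[mask] / np.abs(gam[mask])
        return _mode_point(th, tse, phi)

    se = _parametric_bootstrap_se(panel, est, n_boot, seed)
    return MREstimate("mode", beta, se, _norm_p(beta, se), panel.n_snp)


def run_all_methods(
    panel: HarmonizedPanel,
    q_alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median", "mode"),
) -> list[MREstimate]:
    """Run the requested estimators, skipping any the panel is too small for."""
    out: list[MREstimate] = []
    for m in methods:
        try:
            if m == "ivw":
                out.append(ivw(panel, model="auto", q_alpha=q_alpha))
            elif m == "egger":
                out.append(egger(panel))
            elif m == "weighted_median":
                out.append(weighted_median(panel, n_boot=n_boot, seed=seed))
            elif m == "mode":
                out.append(mode_based(panel, n_boot=n_boot, seed=seed + 1))
            else:
                raise ValidationError(f"unknown MR method {m!r}")
        except ValidationError:
            if m in ("ivw",):
                raise
    return out
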