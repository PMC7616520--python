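"""Univariable two-sample MR estimators on a :class:`~proxymr.gwas_io.HarmonizedSet`.

Implements the Wald ratio, inverse-variance weighted (IVW) meta-analysis
of per-SNP ratios, MR-Egger regression, the weighted median, and the
simple/weighted mode estimators.  All estimators take per-SNP exposure
and outcome betas in SD units and return an :class:`MREstimate`.

The IVW estimate is the zero-intercept weighted least-squares slope of
outcome on exposure betas with weights 1/se_y²; its default variance
model is multiplicative random effects (the fixed-effect SE inflated by
√(Q/(n−1)) when Cochran's Q exceeds its degrees of freedom).  Egger adds
an intercept that absorbs directional pleiotropy, at the cost of the
InSIDE assumption.  Median and mode estimators are consistent when,
respectively, a weight-majority or a plurality of instruments is valid;
their SEs come from a parametric bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .gwas_io import HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = 1.96


@dataclass(frozen=True)
class MREstimate:
    """One estimator's result: effect in outcome-SD per exposure-SD."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    q_stat: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("confidence interval must contain the point estimate")


def _normal_estimate(method, beta, se, n_snp, **kw) -> MREstimate:
    pval = 2.0 * sps.norm.sf(abs(beta) / se) if se > 0 else 0.0
    return MREstimate(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
        pval=float(pval), n_snp=n_snp, **kw,
    )


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MREstimate:
    """Single-SNP causal ratio beta_y/beta_x with first-order SE |se_y/beta_x|.

    Exposure uncertainty is ignored (standard first-order approximation,
    accurate for strong instruments).
    """
    if beta_x == 0:
        raise ZeroDivisionError("wald_ratio undefined for beta_x = 0")
    return _normal_estimate("wald_ratio", beta_y / beta_x, abs(se_y / beta_x), n_snp=1)


def ivw(data: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate.

    beta = Σ(beta_x·beta_y/se_y²) / Σ(beta_x²/se_y²); the fixed-effect SE
    is (Σ w)^(−1/2) with w = beta_x²/se_y², and the default
    multiplicative random-effects model scales it by max(1, √(Q/(n−1))).
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    bx, by, sy = data.beta_x, data.beta_y, data.se_y
    zero = [r for r, b in zip(data.rsids, bx) if b == 0]
    if zero:
        raise ZeroDivisionError(f"beta_x is zero for rsid(s): {zero}")
    w = bx**2 / sy**2
    beta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (by / bx - beta) ** 2))
    n = data.n_snp
    if model == "multiplicative_random" and n >= 2:
        se *= max(1.0, np.sqrt(q / (n - 1)))
    return _normal_estimate(f"ivw_{model}", beta, se, n_snp=n, q_stat=q)


def egger(data: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted least squares of beta_y on beta_x with intercept.

    Per-SNP pairs are first oriented so beta_x ≥ 0 (negating both betas
    where needed — the estimate is invariant to this relabelling but the
    intercept is not).  Weights are 1/se_y²; SEs use multiplicative
    overdispersion scaling max(1, residual scale) and t(n−2) p-values.
    """
    n = data.n_snp
    if n < 3:
        raise ValueError(f"egger requires >= 3 SNPs, got {n}")
    sign = np.where(data.beta_x < 0, -1.0, 1.0)
    if np.any(sign < 0):
        logger.info("egger: re-oriented %d SNP(s) to non-negative beta_x", int((sign < 0).sum()))
    bx, by, sy = sign * data.beta_x, sign * data.beta_y, data.se_y
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), bx])
    A = X.T @ (w[:, None] * X)
    b = np.linalg.solve(A, X.T @ (w * by))
    resid = by - X @ b
    scale = max(1.0, float(np.sum(w * resid**2) / (n - 2)))
    cov = np.linalg.inv(A) * scale
    intercept, slope = float(b[0]), float(b[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    tdist = sps.t(df=n - 2)
    return MREstimate(
        method="egger",
        beta=slope, se=se_slope,
        ci_low=slope - Z95 * se_slope, ci_high=slope + Z95 * se_slope,
        pval=float(2.0 * tdist.sf(abs(slope) / se_slope)),
        n_snp=n,
        q_stat=float(np.sum(w * resid**2)),
        intercept=intercept, intercept_se=se_int,
        intercept_pval=float(2.0 * tdist.sf(abs(intercept) / se_int)),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: cumulative-midpoint rule at s = 0.5."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def _bootstrap_se(point_fn, data: HarmonizedSet, n_boot: int, rng) -> float:
    """SD of the estimator over parametric resamples of per-SNP betas."""
    bx = rng.normal(data.beta_x, data.se_x, size=(n_boot, data.n_snp))
    by = rng.normal(data.beta_y, data.se_y, size=(n_boot, data.n_snp))
    ests = np.array([point_fn(bx[i], by[i]) for i in range(n_boot)])
    return float(np.std(ests, ddof=1))


def weighted_median(data: HarmonizedSet, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted median of per-SNP Wald ratios, weights beta_x²/se_y².

    Consistent when valid instruments carry >50% of the weight.  SE from
    a parametric bootstrap (``n_boot`` resamples of per-SNP betas).
    """
    if data.n_snp < 3:
        raise ValueError(f"weighted_median requires >= 3 SNPs, got {data.n_snp}")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if n_boot < 100:
        logger.warning("weighted_median: n_boot=%d is small; SE will be noisy", n_boot)
    rng = np.random.default_rng(seed)
    sy = data.se_y

    def point(bx, by):
        return _weighted_median(by / bx, bx**2 / sy**2)

    beta = point(data.beta_x, data.beta_y)
    se = _bootstrap_se(point, data, n_boot, rng)
    return _normal_estimate("weighted_median", beta, se, n_snp=data.n_snp)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Argmax of a weighted gaussian KDE over a fixed 512-point grid.

    Bandwidth h = phi·0.9·min(sd, IQR/1.349)·n^(−1/5) (modified
    Silverman rule).  If all ratios coincide the common value is
    returned directly.
    """
    n = len(ratios)
    sd = np.std(ratios, ddof=1)
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    h = phi * 0.9 * min(sd, iqr / 1.349) * n ** (-0.2)
    if h <= 0:
        return float(ratios[0])
    grid = np.linspace(ratios.min() - h, ratios.max() + h, 512)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def mode_estimate(
    data: HarmonizedSet,
    variant: str = "simple",
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Simple or weighted mode of per-SNP Wald ratios (ZEMPA estimator).

    Consistent when the largest group of instruments sharing a ratio is
    valid.  ``variant="weighted"`` weights the kernel density by
    beta_x²/se_y²; ``phi`` multiplies the KDE bandwidth.  SE from a
    parametric bootstrap.
    """
    if variant not in ("simple", "weighted"):
        raise ValueError(f"unknown mode variant {variant!r}")
    if data.n_snp < 3:
        raise ValueError(f"mode_estimate requires >= 3 SNPs, got {data.n_snp}")
    if phi <= 0:
        raise ValueError("phi must be positive")
    rng = np.random.default_rng(seed)
    sy = data.se_y

    def point(bx, by):
        w = bx**2 / sy**2 if variant == "weighted" else np.ones_like(bx)
        return _kde_mode(by / bx, w, phi)

    beta = point(data.beta_x, data.beta_y)
    se = _bootstrap_se(point, data, n_boot, rng)
    return _normal_estimate(f"{variant}_mode", beta, se, n_snp=data.n_snp)
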