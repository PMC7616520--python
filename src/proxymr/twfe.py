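"""Two-way fixed-effects panel estimator and the consumption-index builder.

The panel records repeated measures of coffee cups, tea cups and BMI per
individual per assessment visit.  :func:`build_exposure_index` z-scores
each beverage within visit and combines them into a single
caffeine-consumption index in SD units; :func:`twfe_fit` estimates

    outcome_it = β·index_it + α_i + γ_t + ε_it

by alternating within-transformation (iterated demeaning over
individuals and visits, which handles unbalanced panels), with two-way
cluster-robust standard errors by inclusion–exclusion over the one-way
clustered sandwich estimators.  Identification comes from
within-individual changes, so any time-invariant individual confounder
(and any individual-invariant visit shock) is differenced out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("individual_id", "visit", "coffee_cups", "tea_cups", "bmi")


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PanelData:
    """Long-format panel; (individual, visit) pairs unique."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"panel missing column(s): {missing}")
        if self.frame.duplicated(["individual_id", "visit"]).any():
            raise ValueError("duplicate (individual, visit) pairs in panel")

    @property
    def n_individuals(self) -> int:
        return self.frame["individual_id"].nunique()

    @property
    def n_visits(self) -> int:
        return self.frame["visit"].nunique()

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path) -> "PanelData":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class TWFEEstimate:
    """Outcome change per SD of the exposure index, with 2-way clustered SE."""

    beta: float
    se_cluster2: float
    ci_low: float
    ci_high: float
    pval: float
    n_obs: int
    n_individuals: int
    n_visits: int

    def __post_init__(self) -> None:
        if not self.se_cluster2 > 0:
            raise ValueError("se must be positive")


def _zscore(values: pd.Series) -> pd.Series:
    # population (ddof=0) z-score across individuals at one visit
    mu, sd = values.mean(), values.std(ddof=0)
    return (values - mu) / sd


def build_exposure_index(panel: PanelData, scale: str = "per_visit") -> PanelData:
    """Add an ``exposure_index`` column in SD units.

    Within each visit, coffee and tea cups are z-scored separately
    across individuals and summed; the sum is re-standardized within
    visit (``scale="per_visit"``, default) or across the pooled panel
    (``scale="pooled"``).  Rows missing one beverage use the other alone
    (logged).  A visit where either beverage has zero variance among its
    non-missing reporters is an error naming the visit.
    """
    if scale not in ("per_visit", "pooled"):
        raise ValueError(f"unknown scale {scale!r}")
    df = panel.frame.copy()
    parts = []
    for visit, grp in df.groupby("visit", sort=True):
        if len(grp) < 2:
            raise ValueError(f"visit {visit!r}: need >= 2 individuals to standardize")
        zsum = pd.Series(0.0, index=grp.index)
        n_used = pd.Series(0, index=grp.index)
        for col in ("coffee_cups", "tea_cups"):
            obs = grp[col].dropna()
            if len(obs) >= 2 and obs.std(ddof=0) == 0:
                raise ValueError(f"visit {visit!r}: zero variance in {col}")
            z = _zscore(obs)
            zsum.loc[z.index] += z
            n_used.loc[z.index] += 1
        n_missing = int((n_used == 1).sum())
        if n_missing:
            logger.info("visit %r: %d row(s) use a single beverage", visit, n_missing)
        if (n_used == 0).any():
            raise ValueError(f"visit {visit!r}: rows with no beverage data")
        if scale == "per_visit":
            zsum = _zscore(zsum)
        parts.append(zsum)
    index = pd.concat(parts).sort_index()
    if scale == "pooled":
        index = _zscore(index)
    df["exposure_index"] = index
    return PanelData(df)


def _two_way_demean(y, x, dims, tol=1e-10, max_sweeps=10000):
    """Alternating projections onto the group means in ``dims``.

    ``dims`` is a list of (codes, n_groups) pairs.  Convergence is
    declared on the change in the regression coefficient, which is what
    the estimate depends on.
    """
    yd, xd = y.copy(), x.copy()
    beta_prev = np.inf
    for sweep in range(max_sweeps):
        for codes, size in dims:
            counts = np.bincount(codes, minlength=size)
            yd -= (np.bincount(codes, yd, minlength=size) / counts)[codes]
            xd -= (np.bincount(codes, xd, minlength=size) / counts)[codes]
        sxx = float(xd @ xd)
        if sxx == 0:
            raise ValueError("exposure index has no within variation")
        beta = float(xd @ yd) / sxx
        if abs(beta - beta_prev) < tol:
            return yd, xd, beta
        beta_prev = beta
    raise ConvergenceError(f"demeaning did not converge in {max_sweeps} sweeps")


def _cluster_meat(scores: np.ndarray, codes: np.ndarray, n_clusters: int) -> tuple[float, float]:
    """(Σ_g (Σ_{i∈g} score_i)², small-sample correction) for one grouping."""
    sums = np.bincount(codes, scores, minlength=n_clusters)
    meat = float(sums @ sums)
    n = len(scores)
    g = n_clusters
    k = 1  # single slope on the demeaned regression
    corr = (g / (g - 1)) * ((n - 1) / (n - k)) if g > 1 else 1.0
    return meat, corr


def twfe_fit(panel: PanelData) -> TWFEEstimate:
    """Two-way fixed-effects slope of outcome on the exposure index.

    SE is two-way cluster robust: V = V_individual + V_visit −
    V_intersection over one-way clustered sandwich estimators on the
    demeaned regression, with per-component small-sample corrections
    G/(G−1)·(N−1)/(N−k).  With a single visit (or individual) the
    estimator degenerates to a one-way problem and one-way clustering on
    the remaining dimension is reported.  If inclusion–exclusion yields
    a negative variance it is clamped to the individual-clustered
    component with a warning.
    """
    df = panel.frame
    if "exposure_index" not in df.columns:
        raise ValueError("run build_exposure_index first")
    ind_codes, ind_levels = pd.factorize(df["individual_id"], sort=True)
    visit_codes, visit_levels = pd.factorize(df["visit"], sort=True)
    n_ind, n_visit = len(ind_levels), len(visit_levels)
    n_obs = len(df)
    if n_obs < 3 or (n_ind < 2 and n_visit < 2):
        raise ValueError("need >= 2 individuals or >= 2 visits and >= 3 observations")

    y = df["bmi"].to_numpy(dtype=float)
    x = df["exposure_index"].to_numpy(dtype=float)
    # a collapsed dimension (single visit / single individual) would make
    # the other dimension's demeaning degenerate; drop its projection
    dims = []
    if n_visit >= 2:
        dims.append((ind_codes, n_ind))
    if n_ind >= 2:
        dims.append((visit_codes, n_visit))
    yd, xd, beta = _two_way_demean(y, x, dims)

    sxx = float(xd @ xd)
    resid = yd - beta * xd
    scores = xd * resid
    bread = 1.0 / sxx

    meat_ind, c_ind = _cluster_meat(scores, ind_codes, n_ind)
    if n_visit == 1 or n_ind == 1:
        # one cluster dimension collapsed: one-way clustering on the other
        meat, corr = (meat_ind, c_ind) if n_visit == 1 else _cluster_meat(
            scores, visit_codes, n_visit
        )
        var = bread**2 * corr * meat
    else:
        meat_vis, c_vis = _cluster_meat(scores, visit_codes, n_visit)
        cell = scores  # (individual, visit) cells are single observations
        meat_int = float(cell @ cell)
        c_int = n_obs / (n_obs - 1)  # G = N
        var = bread**2 * (c_ind * meat_ind + c_vis * meat_vis - c_int * meat_int)
        if var <= 0 and meat_int > 0:
            logger.warning("two-way clustered variance negative; clamping to V_individual")
            var = bread**2 * c_ind * meat_ind

    # exact-fit panels have zero residual variance; keep the SE positive
    se = float(np.sqrt(max(var, 1e-300)))
    return TWFEEstimate(
        beta=beta,
        se_cluster2=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        pval=float(2.0 * sps.norm.sf(abs(beta) / se)),
        n_obs=n_obs,
        n_individuals=n_ind,
        n_visits=n_visit,
    )


def pooled_fit(panel: PanelData) -> float:
    """Pooled OLS slope of outcome on the index — a biased benchmark when
    individual effects correlate with consumption."""
    df = panel.frame
    x = df["exposure_index"].to_numpy(dtype=float)
    y = df["bmi"].to_numpy(dtype=float)
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))
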