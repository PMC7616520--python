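"""Per-SNP directionality testing and mechanism stratification.

A variant generally explains more variance in the trait it acts on
proximally than in traits downstream of it.  The Steiger test compares
the variance a SNP explains in two traits via Fisher-transformed
correlations; stratifying an instrument set by the winning trait splits
a behavioral-proxy GWAS's instruments into those acting through the
biomarker (metabolism-proximal) and those acting through behavior.

:func:`reweight_exposure` swaps the primary and second exposure of a
two-exposure harmonized set, which is how a consumption-selected
instrument set is "scaled by" the biomarker: IVW on the reweighted set
estimates the biomarker's effect using the same SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

from .gwas_io import HarmonizedSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SteigerRecord:
    """One SNP's variance explained in two traits and the assigned direction."""

    rsid: str
    r2_trait1: float
    r2_trait2: float
    direction: str  # trait1_first | trait2_first | undetermined
    z: float
    pval: float

    def __post_init__(self) -> None:
        expected = (
            "trait1_first" if self.r2_trait1 > self.r2_trait2
            else "trait2_first" if self.r2_trait2 > self.r2_trait1
            else "undetermined"
        )
        if self.direction != expected:
            raise ValueError(
                f"{self.rsid}: direction {self.direction!r} inconsistent with "
                f"r² comparison ({self.r2_trait1} vs {self.r2_trait2})"
            )


class SteigerResult(NamedTuple):
    z: float
    pval: float
    direction: str


def steiger_test(r2_1: float, n_1: float, r2_2: float, n_2: float) -> SteigerResult:
    """Compare variance explained in two traits measured in two samples.

    z = (atanh(√r2_1) − atanh(√r2_2)) / √(1/(n_1−3) + 1/(n_2−3)),
    two-sided normal p; direction by strict r² comparison.
    """
    for r2 in (r2_1, r2_2):
        if not 0 <= r2 < 1:
            raise ValueError(f"r² must be in [0, 1), got {r2}")
    for n in (n_1, n_2):
        if n <= 3:
            raise ValueError(f"sample size must exceed 3, got {n}")
    z = (np.arctanh(np.sqrt(r2_1)) - np.arctanh(np.sqrt(r2_2))) / np.sqrt(
        1.0 / (n_1 - 3) + 1.0 / (n_2 - 3)
    )
    pval = float(2.0 * sps.norm.sf(abs(z)))
    if r2_1 > r2_2:
        direction = "trait1_first"
    elif r2_2 > r2_1:
        direction = "trait2_first"
    else:
        direction = "undetermined"
    return SteigerResult(float(z), pval, direction)


class StratifiedSets(NamedTuple):
    """trait2_first holds SNPs proximal to the second exposure (biomarker)."""

    trait2_first: HarmonizedSet | None
    trait1_first: HarmonizedSet | None
    records: list[SteigerRecord]
    excluded: list[str]


def _per_snp_r2(beta, se, n) -> np.ndarray:
    # t-statistic form: eaf-free, usable when frequencies are unavailable
    t2 = (np.asarray(beta) / np.asarray(se)) ** 2
    return t2 / (t2 + np.asarray(n) - 2.0)


def stratify_instruments(
    data: HarmonizedSet,
    policy: str = "point",
    alpha: float = 0.05,
) -> StratifiedSets:
    """Partition a two-exposure harmonized set by per-SNP Steiger direction.

    Trait 1 is the primary exposure, trait 2 the second exposure.  Under
    ``policy="point"`` each SNP goes to the stratum of the trait with
    strictly larger r² (exact ties are excluded, never assigned
    arbitrarily); ``policy="significant"`` additionally requires the
    Steiger p-value below ``alpha``, excluding indeterminate SNPs.
    """
    if policy not in ("point", "significant"):
        raise ValueError(f"unknown stratification policy {policy!r}")
    if not data.has_second_exposure:
        raise ValueError("stratification requires a second exposure")
    r2_1 = _per_snp_r2(data.beta_x, data.se_x, data.n_x)
    r2_2 = _per_snp_r2(data.beta_x2, data.se_x2, data.n_x2)

    records, excluded = [], []
    mask1 = np.zeros(data.n_snp, dtype=bool)
    mask2 = np.zeros(data.n_snp, dtype=bool)
    for i, rsid in enumerate(data.rsids):
        z, pval, direction = steiger_test(r2_1[i], data.n_x[i], r2_2[i], data.n_x2[i])
        records.append(SteigerRecord(rsid, float(r2_1[i]), float(r2_2[i]), direction, z, pval))
        if direction == "undetermined" or (policy == "significant" and pval >= alpha):
            excluded.append(rsid)
        elif direction == "trait1_first":
            mask1[i] = True
        else:
            mask2[i] = True
    if excluded:
        logger.info("stratify_instruments: excluded %d SNP(s): %s", len(excluded), excluded)
    for name, mask in (("trait1_first", mask1), ("trait2_first", mask2)):
        if not mask.any():
            logger.warning("stratify_instruments: %s stratum is empty", name)
    return StratifiedSets(
        trait2_first=data.subset(mask2) if mask2.any() else None,
        trait1_first=data.subset(mask1) if mask1.any() else None,
        records=records,
        excluded=excluded,
    )


def reweight_exposure(data: HarmonizedSet) -> HarmonizedSet:
    """Swap primary and second exposure so IVW yields the "scaled" estimate.

    An involution: applying it twice restores the original set.
    """
    return data.swap_exposures()
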