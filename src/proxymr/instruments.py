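"""Instrument selection, greedy LD clumping and instrument-strength statistics.

Instruments are chosen by a p-value threshold, then pruned to
approximate pairwise independence by greedy clumping against a supplied
LD matrix (most significant SNP wins within each correlated cluster).
Strength is summarised by the variance a variant explains in its trait
(r², from allele frequency or from the t statistic) and the joint
F statistic of the selected set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import SummaryStats, VariantAssociation

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Symmetric matrix of pairwise squared correlations, unit diagonal."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.rsids)
        if self.r2.shape != (m, m):
            raise ValueError(f"r2 must be {m}x{m}, got {self.r2.shape}")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {r: i for i, r in enumerate(self.rsids)}

    @classmethod
    def identity(cls, rsids) -> "LDMatrix":
        return cls(list(rsids), np.eye(len(rsids)))

    @classmethod
    def block(cls, rsids, block_size: int, r2: float) -> "LDMatrix":
        """Compound-symmetric blocks: r² between SNPs in the same block."""
        rsids = list(rsids)
        m = len(rsids)
        mat = np.eye(m)
        for start in range(0, m, block_size):
            stop = min(start + block_size, m)
            mat[start:stop, start:stop] = r2
        np.fill_diagonal(mat, 1.0)
        return cls(rsids, mat)

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"rsid {exc.args[0]!r} absent from LD matrix") from None

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(
            path, sep="\t", float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(r) for r in df.index], df.to_numpy())


@dataclass
class InstrumentSet:
    """Selected instruments with per-SNP provenance.

    ``provenance`` maps every candidate rsid to "retained" or
    "clumped_out_by:<index rsid>".  ``pvals`` parallels ``rsids`` so
    clumping order can always be re-derived.
    """

    rsids: list[str]
    pvals: np.ndarray
    p_threshold: float
    clump_r2: float | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pvals = np.asarray(self.pvals, dtype=float)
        if len(self.pvals) != len(self.rsids):
            raise ValueError("pvals must parallel rsids")

    def __len__(self) -> int:
        return len(self.rsids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "pval": self.pvals,
                "provenance": [self.provenance.get(r, "retained") for r in self.rsids],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def select_by_pvalue(stats: SummaryStats, p_threshold: float) -> InstrumentSet:
    """Variants with pval strictly below the threshold, sorted ascending.

    Ties are broken lexically by rsid for determinism.
    """
    if not 0 < p_threshold < 1:
        raise ValueError(f"p_threshold must be in (0, 1), got {p_threshold}")
    hits = [(rec.pval, rec.rsid) for rec in stats.records.values() if rec.pval < p_threshold]
    hits.sort()
    if not hits:
        logger.warning(
            "%s: no variants pass P < %g", stats.trait_label, p_threshold
        )
        return InstrumentSet([], np.array([]), p_threshold)
    rsids = [r for _, r in hits]
    return InstrumentSet(
        rsids=rsids,
        pvals=np.array([p for p, _ in hits]),
        p_threshold=p_threshold,
        provenance={r: "retained" for r in rsids},
    )


def greedy_clump(candidates: InstrumentSet, ld: LDMatrix, clump_r2: float) -> InstrumentSet:
    """Greedy p-value-ranked clumping.

    Candidates are visited in ascending p-value order (rsid breaks
    ties); a SNP is retained iff its r² with every previously retained
    SNP is ≤ ``clump_r2``.  Provenance records which index SNP removed
    each casualty.
    """
    missing = [r for r in candidates.rsids if r not in ld]
    if missing:
        raise KeyError(f"candidate rsid(s) absent from LD matrix: {missing}")
    order = sorted(zip(candidates.pvals, candidates.rsids))
    kept: list[tuple[float, str]] = []
    provenance: dict[str, str] = {}
    for pval, rsid in order:
        culprit = next(
            (k for _, k in kept if ld.lookup(rsid, k) > clump_r2), None
        )
        if culprit is None:
            kept.append((pval, rsid))
            provenance[rsid] = "retained"
        else:
            provenance[rsid] = f"clumped_out_by:{culprit}"
    return InstrumentSet(
        rsids=[r for _, r in kept],
        pvals=np.array([p for p, _ in kept]),
        p_threshold=candidates.p_threshold,
        clump_r2=clump_r2,
        provenance=provenance,
    )


def variance_explained(assoc: VariantAssociation, mode: str = "tstat") -> float:
    """Fraction of trait variance explained by one variant.

    mode "eaf": r² = 2·eaf·(1−eaf)·beta² (requires eaf and SD-unit beta);
    mode "tstat": r² = t²/(t² + n − 2) with t = beta/se (requires n > 2).
    """
    if mode == "eaf":
        if assoc.eaf is None:
            raise ValueError(f"{assoc.rsid}: mode 'eaf' requires an effect-allele frequency")
        r2 = 2.0 * assoc.eaf * (1.0 - assoc.eaf) * assoc.beta**2
    elif mode == "tstat":
        if assoc.n <= 2:
            raise ValueError(f"{assoc.rsid}: mode 'tstat' requires n > 2")
        t2 = (assoc.beta / assoc.se) ** 2
        r2 = t2 / (t2 + assoc.n - 2)
    else:
        raise ValueError(f"unknown variance_explained mode {mode!r}")
    return min(float(r2), 1.0 - 1e-15)


def combined_r2(stats: SummaryStats, rsids, mode: str = "tstat") -> float:
    """Sum of per-SNP r² — valid for (quasi-)independent clumped variants."""
    return float(sum(variance_explained(stats[r], mode) for r in rsids))


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Joint F statistic for k instruments explaining r2_total of the trait."""
    if not 0 <= r2_total < 1:
        raise ValueError(f"r2_total must be in [0, 1), got {r2_total}")
    if k < 1 or n <= k + 1:
        raise ValueError(f"need n > k+1 >= 2, got n={n}, k={k}")
    return float(r2_total / (1.0 - r2_total) * (n - k - 1) / k)


def instrument_strength(stats: SummaryStats, rsids, mode: str = "tstat"):
    """(r² total, joint F, n) for a set of instruments from one study."""
    rsids = list(rsids)
    r2 = combined_r2(stats, rsids, mode)
    n = int(np.median([stats[r].n for r in rsids]))
    return r2, f_statistic(r2, n, len(rsids)), n
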