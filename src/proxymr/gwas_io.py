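"""GWAS summary-statistic containers, delimited-file I/O and allele harmonization.

Two-sample Mendelian randomization combines per-variant association
estimates from an exposure study and an outcome study.  Before any
estimation the two studies must report each variant's effect on the same
allele; :func:`harmonize` aligns the outcome study to the exposure
study's effect allele, resolving allele swaps and strand flips, and
handling palindromic (A/T, C/G) variants by allele-frequency inference
or by dropping them.  :func:`merge_second_exposure` aligns a second
exposure onto an already-harmonized set for multivariable analyses.

Betas are assumed to be in trait-SD units per effect allele throughout.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: sentinel SE for second-exposure records filled under missing_policy="zero"
MISSING_SE_SENTINEL = 1e6


class ColumnMappingError(ValueError):
    """A mandatory column is absent from the input file (configuration error)."""


class EmptySummaryError(ValueError):
    """No parseable variant rows were found (input error)."""


class HarmonizationError(ValueError):
    """The exposure and outcome studies share no variants."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association with one trait.

    beta is the per-allele effect of ``effect_allele`` in trait-SD units,
    se its standard error, pval the two-sided association p-value and n
    the study sample size.  eaf (effect-allele frequency) is optional.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(
                f"{self.rsid}: alleles must be single bases A/C/G/T, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.rsid}: se must be positive, got {self.se}")
        if not 0 < self.pval <= 1:
            raise ValueError(f"{self.rsid}: pval must be in (0, 1], got {self.pval}")
        if self.n <= 0:
            raise ValueError(f"{self.rsid}: n must be a positive integer, got {self.n}")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ValueError(f"{self.rsid}: eaf must be in (0, 1), got {self.eaf}")
        self._check_pval_consistency()

    def _check_pval_consistency(self) -> None:
        # |beta/se| should match the z implied by the p-value under the
        # two-sided normal approximation; mismatch warns but never errors,
        # since published p-values may come from other test statistics.
        z_obs = abs(self.beta) / self.se
        if self.pval < 1e-300 or z_obs < 0.5:
            return
        z_imp = -ndtri(self.pval / 2.0)
        if z_imp > 0 and abs(z_obs - z_imp) / z_imp > 0.10:
            warnings.warn(
                f"{self.rsid}: p-value {self.pval:.3g} implies |z|={z_imp:.2f} "
                f"but beta/se gives {z_obs:.2f}",
                stacklevel=3,
            )

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class SummaryStats:
    """A labelled collection of :class:`VariantAssociation`, keyed by rsid."""

    trait_label: str
    records: dict[str, VariantAssociation]
    sd_units: bool = True

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptySummaryError(f"{self.trait_label}: no variant records")
        for rsid, rec in self.records.items():
            if rsid != rec.rsid:
                raise ValueError(f"record key {rsid!r} does not match rsid {rec.rsid!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def __getitem__(self, rsid: str) -> VariantAssociation:
        return self.records[rsid]

    @property
    def rsids(self) -> list[str]:
        return list(self.records)

    def subset(self, rsids) -> "SummaryStats":
        recs = {r: self.records[r] for r in rsids if r in self.records}
        return SummaryStats(self.trait_label, recs, self.sd_units)

    @classmethod
    def from_records(cls, trait_label: str, records, sd_units: bool = True) -> "SummaryStats":
        return cls(trait_label, {rec.rsid: rec for rec in records}, sd_units)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "SNP": r.rsid,
                "EA": r.effect_allele,
                "OA": r.other_allele,
                "EAF": np.nan if r.eaf is None else r.eaf,
                "BETA": r.beta,
                "SE": r.se,
                "P": r.pval,
                "N": r.n,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


DEFAULT_COLUMN_MAP = {
    "rsid": "SNP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

_MANDATORY_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval", "n")


def read_summary_stats(
    path,
    trait_label: str | None = None,
    column_map: dict[str, str] | None = None,
    delimiter: str = "\t",
) -> SummaryStats:
    """Read a delimited summary-statistics file into :class:`SummaryStats`.

    ``column_map`` maps canonical field names (rsid, effect_allele,
    other_allele, eaf, beta, se, pval, n) to the file's header names; it
    is merged over the default SNP/EA/OA/EAF/BETA/SE/P/N dialect.  Rows
    with unparseable beta/se, invalid alleles (including indels and
    multi-allelic records) or other invariant violations are skipped and
    counted.  gzip-compressed files are accepted.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, sep=delimiter, dtype=str)
    missing = [cmap[f] for f in _MANDATORY_FIELDS if cmap[f] not in df.columns]
    if missing:
        raise ColumnMappingError(f"{path}: missing mandatory column(s) {missing}")
    has_eaf = cmap["eaf"] in df.columns

    records: dict[str, VariantAssociation] = {}
    n_dropped = 0
    for _, row in df.iterrows():
        try:
            eaf = None
            if has_eaf:
                raw = row[cmap["eaf"]]
                eaf = None if pd.isna(raw) or raw == "" else float(raw)
            rec = VariantAssociation(
                rsid=str(row[cmap["rsid"]]),
                effect_allele=str(row[cmap["effect_allele"]]).upper(),
                other_allele=str(row[cmap["other_allele"]]).upper(),
                beta=float(row[cmap["beta"]]),
                se=float(row[cmap["se"]]),
                pval=float(row[cmap["pval"]]),
                n=int(float(row[cmap["n"]])),
                eaf=eaf,
            )
        except (ValueError, TypeError):
            n_dropped += 1
            continue
        records[rec.rsid] = rec

    if n_dropped:
        logger.info("%s: skipped %d unparseable/invalid rows", path, n_dropped)
    if not records:
        raise EmptySummaryError(f"{path}: zero parseable variant rows")
    label = trait_label if trait_label is not None else str(path)
    return SummaryStats(label, records)


@dataclass
class HarmonizedSet:
    """Allele-aligned per-SNP effects for one or two exposures plus an outcome.

    Every retained SNP is expressed on the primary exposure's effect
    allele.  This is the unit all MR estimators operate on.
    """

    rsids: list[str]
    effect_allele: list[str]
    other_allele: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    n_x: np.ndarray
    n_y: np.ndarray
    beta_x2: np.ndarray | None = None
    se_x2: np.ndarray | None = None
    n_x2: np.ndarray | None = None
    eaf_x: np.ndarray | None = None
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    exposure2_label: str | None = None
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("beta_x", "se_x", "beta_y", "se_y", "n_x", "n_y",
                     "beta_x2", "se_x2", "n_x2", "eaf_x"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))
        n = len(self.rsids)
        if n < 1:
            raise ValueError("HarmonizedSet must retain at least one SNP")
        for name in ("effect_allele", "other_allele"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        for name in ("beta_x", "se_x", "beta_y", "se_y", "n_x", "n_y",
                     "beta_x2", "se_x2", "n_x2", "eaf_x"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("all standard errors must be positive")
        if self.se_x2 is not None and np.any(self.se_x2 <= 0):
            raise ValueError("all standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.rsids)

    @property
    def has_second_exposure(self) -> bool:
        return self.beta_x2 is not None

    def subset(self, index) -> "HarmonizedSet":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        take = lambda v: None if v is None else v[idx]
        return replace(
            self,
            rsids=[self.rsids[i] for i in idx],
            effect_allele=[self.effect_allele[i] for i in idx],
            other_allele=[self.other_allele[i] for i in idx],
            beta_x=self.beta_x[idx],
            se_x=self.se_x[idx],
            beta_y=self.beta_y[idx],
            se_y=self.se_y[idx],
            n_x=self.n_x[idx],
            n_y=self.n_y[idx],
            beta_x2=take(self.beta_x2),
            se_x2=take(self.se_x2),
            n_x2=take(self.n_x2),
            eaf_x=take(self.eaf_x),
            dropped=list(self.dropped),
        )

    def swap_exposures(self) -> "HarmonizedSet":
        """Exchange primary and second exposure (outcome untouched)."""
        if not self.has_second_exposure:
            raise ValueError("no second exposure to swap with")
        return replace(
            self,
            beta_x=self.beta_x2,
            se_x=self.se_x2,
            n_x=self.n_x2,
            beta_x2=self.beta_x,
            se_x2=self.se_x,
            n_x2=self.n_x,
            exposure_label=self.exposure2_label or "exposure2",
            exposure2_label=self.exposure_label,
        )

    def to_frame(self) -> pd.DataFrame:
        d = {
            "rsid": self.rsids,
            "effect_allele": self.effect_allele,
            "other_allele": self.other_allele,
            "beta_x": self.beta_x,
            "se_x": self.se_x,
            "n_x": self.n_x.astype(int),
            "beta_y": self.beta_y,
            "se_y": self.se_y,
            "n_y": self.n_y.astype(int),
        }
        if self.eaf_x is not None:
            d["eaf_x"] = self.eaf_x
        if self.has_second_exposure:
            d["beta_x2"] = self.beta_x2
            d["se_x2"] = self.se_x2
            d["n_x2"] = self.n_x2.astype(int)
        return pd.DataFrame(d)

    def write_tsv(self, path, drop_log=None) -> None:
        """Write one row per retained SNP; optional sidecar drop-log TSV."""
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        if drop_log is not None:
            pd.DataFrame(self.dropped, columns=["rsid", "reason"]).to_csv(
                drop_log, sep="\t", index=False
            )


def read_harmonized_tsv(path, exposure_label="exposure", outcome_label="outcome",
                        exposure2_label=None) -> HarmonizedSet:
    df = pd.read_csv(path, sep="\t")
    kw = {}
    if "eaf_x" in df.columns:
        kw["eaf_x"] = df["eaf_x"].to_numpy()
    if "beta_x2" in df.columns:
        kw.update(
            beta_x2=df["beta_x2"].to_numpy(),
            se_x2=df["se_x2"].to_numpy(),
            n_x2=df["n_x2"].to_numpy(),
            exposure2_label=exposure2_label or "exposure2",
        )
    return HarmonizedSet(
        rsids=df["rsid"].astype(str).tolist(),
        effect_allele=df["effect_allele"].tolist(),
        other_allele=df["other_allele"].tolist(),
        beta_x=df["beta_x"].to_numpy(),
        se_x=df["se_x"].to_numpy(),
        beta_y=df["beta_y"].to_numpy(),
        se_y=df["se_y"].to_numpy(),
        n_x=df["n_x"].to_numpy(),
        n_y=df["n_y"].to_numpy(),
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        **kw,
    )


def _align_to(ea: str, oa: str, rec: VariantAssociation, eaf_ref: float | None,
              palindrome_policy: str, eaf_window: float):
    """Decide how ``rec`` aligns to the reference allele pair (ea, oa).

    Returns (flip, reason): flip is True if rec's beta must be negated,
    None if the SNP must be dropped, with reason naming why.
    """
    pair = (rec.effect_allele, rec.other_allele)
    comp = (COMPLEMENT[rec.effect_allele], COMPLEMENT[rec.other_allele])
    palindromic = COMPLEMENT[ea] == oa

    if palindromic:
        # strand is unresolvable from allele labels alone
        if palindrome_policy == "drop":
            return None, "palindromic (policy drop)"
        if pair == (ea, oa):
            flip = False
        elif pair == (oa, ea):
            flip = True
        else:
            return None, "allele mismatch"
        if eaf_ref is None or rec.eaf is None:
            return None, "ambiguous palindrome"
        eaf_aln = 1.0 - rec.eaf if flip else rec.eaf
        lo, hi = 0.5 - eaf_window, 0.5 + eaf_window
        if lo <= eaf_ref <= hi or lo <= eaf_aln <= hi:
            return None, "ambiguous palindrome"
        if (eaf_ref - 0.5) * (eaf_aln - 0.5) < 0:
            return None, "palindrome eaf discordant"
        return flip, None

    if pair == (ea, oa) or comp == (ea, oa):
        return False, None
    if pair == (oa, ea) or comp == (oa, ea):
        return True, None
    return None, "allele mismatch"


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_policy: str = "infer",
    eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align the outcome study to the exposure study's effect alleles.

    For each shared rsid the outcome beta is kept as-is when alleles
    match (directly or as strand complements), negated (and eaf
    reflected) when swapped, and palindromic SNPs are resolved by
    ``palindrome_policy``: ``"drop"`` removes them, ``"infer"`` keeps
    them only when both effect-allele frequencies are outside
    ``0.5 ± eaf_window`` and concordant after alignment.  All removals
    are recorded in ``dropped`` with a reason.
    """
    if palindrome_policy not in ("drop", "infer"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    shared = [r for r in exposure.rsids if r in outcome]
    if not shared:
        raise HarmonizationError(
            f"no shared rsids between {exposure.trait_label!r} and {outcome.trait_label!r}"
        )
    kept, dropped = [], []
    for rsid in shared:
        ex, out = exposure[rsid], outcome[rsid]
        flip, reason = _align_to(
            ex.effect_allele, ex.other_allele, out, ex.eaf, palindrome_policy, eaf_window
        )
        if reason is not None:
            dropped.append((rsid, reason))
            continue
        beta_y = -out.beta if flip else out.beta
        kept.append((ex, beta_y, out.se, out.n))
    if not kept:
        raise HarmonizationError(
            f"all {len(shared)} shared SNPs dropped during harmonization: "
            f"{sorted(set(r for _, r in dropped))}"
        )
    if dropped:
        logger.info(
            "harmonize(%s, %s): dropped %d of %d shared SNPs",
            exposure.trait_label, outcome.trait_label, len(dropped), len(shared),
        )
    exs = [k[0] for k in kept]
    return HarmonizedSet(
        rsids=[e.rsid for e in exs],
        effect_allele=[e.effect_allele for e in exs],
        other_allele=[e.other_allele for e in exs],
        beta_x=np.array([e.beta for e in exs]),
        se_x=np.array([e.se for e in exs]),
        beta_y=np.array([k[1] for k in kept]),
        se_y=np.array([k[2] for k in kept]),
        n_x=np.array([e.n for e in exs], dtype=float),
        n_y=np.array([k[3] for k in kept], dtype=float),
        eaf_x=np.array([np.nan if e.eaf is None else e.eaf for e in exs]),
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        dropped=dropped,
    )


def merge_second_exposure(
    base: HarmonizedSet,
    exposure2: SummaryStats,
    missing_policy: str = "drop",
    palindrome_policy: str = "infer",
    eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Populate beta_x2/se_x2 on ``base`` by the same allele-alignment rules.

    SNPs absent from ``exposure2`` are removed under
    ``missing_policy="drop"``, or kept with beta 0 and a large-SE
    sentinel (:data:`MISSING_SE_SENTINEL`) under ``"zero"``.
    """
    if missing_policy not in ("drop", "zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    keep_idx, b2, s2, n2 = [], [], [], []
    dropped = list(base.dropped)
    eaf_x = base.eaf_x if base.eaf_x is not None else [None] * base.n_snp
    for i, rsid in enumerate(base.rsids):
        if rsid not in exposure2:
            if missing_policy == "drop":
                dropped.append((rsid, f"absent from {exposure2.trait_label}"))
                continue
            keep_idx.append(i)
            b2.append(0.0)
            s2.append(MISSING_SE_SENTINEL)
            n2.append(4)
            logger.info("merge_second_exposure: %s missing, filled with zero/sentinel", rsid)
            continue
        rec = exposure2[rsid]
        ref_eaf = None if eaf_x[i] is None or np.isnan(eaf_x[i]) else float(eaf_x[i])
        flip, reason = _align_to(
            base.effect_allele[i], base.other_allele[i], rec, ref_eaf,
            palindrome_policy, eaf_window,
        )
        if reason is not None:
            dropped.append((rsid, f"exposure2 {reason}"))
            continue
        keep_idx.append(i)
        b2.append(-rec.beta if flip else rec.beta)
        s2.append(rec.se)
        n2.append(rec.n)
    if not keep_idx:
        raise HarmonizationError(f"no SNPs retained after merging {exposure2.trait_label}")
    out = base.subset(np.array(keep_idx))
    out.beta_x2 = np.array(b2)
    out.se_x2 = np.array(s2)
    out.n_x2 = np.array(n2, dtype=float)
    out.exposure2_label = exposure2.trait_label
    out.dropped = dropped
    return out
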