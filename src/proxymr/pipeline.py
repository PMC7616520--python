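"""End-to-end workflow orchestration: from three summary-statistic studies
(and optionally a panel) to a tidy results table.

The workflow mirrors the analysis ladder of a behavioral-proxy vs
biomarker drug-target MR study: genome-wide MR on the proxy, MR on the
named biologically-motivated variants, TWFE triangulation, Steiger
mechanism stratification with per-stratum and re-weighted IVW, MVMR-Qhet
direct effects on the union instrument set, and the univariable
pleiotropy-robust suite.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gwas_io, instruments, mr_core, mvmr, steiger, twfe
from .gwas_io import HarmonizedSet, SummaryStats
from .instruments import LDMatrix

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 5e-7
DEFAULT_CLUMP_R2 = 0.001


class WorkflowError(RuntimeError):
    """A stage failed; carries the stage name and the partial report."""

    def __init__(self, stage: str, report: "WorkflowReport", cause: Exception):
        super().__init__(f"workflow stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial_report = report


@dataclass
class ReportRow:
    label: str
    exposure: str
    outcome: str
    method: str
    n_snp: int | None
    f_stat: float | None
    beta: float
    se: float | None
    ci_low: float
    ci_high: float
    pval: float | None = None
    q_stat: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None


@dataclass
class WorkflowReport:
    rows: list[ReportRow] = field(default_factory=list)
    strat_counts: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "label", "exposure", "outcome", "method", "n_snp", "f_stat",
            "beta", "se", "ci_low", "ci_high", "pval", "q_stat",
            "intercept", "intercept_se",
        ]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.rows])

    def row(self, label: str) -> ReportRow:
        hits = [r for r in self.rows if r.label == label]
        if not hits:
            raise KeyError(f"no row labelled {label!r}")
        return hits[0]


def _mr_row(label, est: mr_core.MREstimate, exposure, outcome, f_stat=None) -> ReportRow:
    return ReportRow(
        label=label, exposure=exposure, outcome=outcome, method=est.method,
        n_snp=est.n_snp, f_stat=f_stat, beta=est.beta, se=est.se,
        ci_low=est.ci_low, ci_high=est.ci_high, pval=est.pval, q_stat=est.q_stat,
        intercept=est.intercept, intercept_se=est.intercept_se,
    )


def select_and_clump(stats: SummaryStats, ld: LDMatrix,
                     p_threshold=DEFAULT_P_THRESHOLD, clump_r2=DEFAULT_CLUMP_R2):
    sel = instruments.select_by_pvalue(stats, p_threshold)
    return instruments.greedy_clump(sel, ld, clump_r2)


def build_mvmr_set(
    consumption: SummaryStats,
    biomarker: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix,
    p_threshold=DEFAULT_P_THRESHOLD,
    clump_r2=DEFAULT_CLUMP_R2,
) -> HarmonizedSet:
    """Union instrument set for MVMR: SNPs associated with either
    exposure, ranked by their best p-value and clumped, then harmonized
    against the outcome and merged with the second exposure."""
    sel_d = instruments.select_by_pvalue(consumption, p_threshold)
    sel_p = instruments.select_by_pvalue(biomarker, p_threshold)
    best: dict[str, float] = {}
    for s in (sel_d, sel_p):
        for rsid, pval in zip(s.rsids, s.pvals):
            best[rsid] = min(best.get(rsid, 1.0), float(pval))
    union = instruments.InstrumentSet(
        rsids=list(best), pvals=np.array(list(best.values())), p_threshold=p_threshold
    )
    clumped = instruments.greedy_clump(union, ld, clump_r2)
    h = gwas_io.harmonize(consumption.subset(clumped.rsids), outcome)
    return gwas_io.merge_second_exposure(h, biomarker, missing_policy="drop")


def run_workflow(
    consumption: SummaryStats,
    biomarker: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix,
    panel: twfe.PanelData | None = None,
    bio_variants: list[str] | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    clump_r2: float = DEFAULT_CLUMP_R2,
    seed: int = 0,
    n_boot: int = 1000,
) -> WorkflowReport:
    """Run the full analysis ladder and collect a :class:`WorkflowReport`.

    ``bio_variants`` names the biologically-motivated instruments (lead
    variants of the biomarker's effector gene regions); when omitted,
    the two lowest-p biomarker SNPs stand in.  The TWFE row is emitted
    only when a panel is supplied.  All bootstrap-based estimators are
    seeded from ``seed``.
    """
    report = WorkflowReport(
        provenance={
            "p_threshold": p_threshold,
            "clump_r2": clump_r2,
            "seed": seed,
            "traits": [consumption.trait_label, biomarker.trait_label, outcome.trait_label],
        }
    )
    stage = "setup"
    try:
        # --- genome-wide MR on the behavioral proxy -------------------
        stage = "genome_wide_mr"
        clumped = select_and_clump(consumption, ld, p_threshold, clump_r2)
        if len(clumped) == 0:
            raise ValueError("no genome-wide instruments selected")
        _, f_gw, _ = instruments.instrument_strength(consumption, clumped.rsids)
        h_gw = gwas_io.harmonize(consumption.subset(clumped.rsids), outcome)
        report.rows.append(
            _mr_row("genome_wide_mr", mr_core.ivw(h_gw),
                    consumption.trait_label, outcome.trait_label, f_gw)
        )
        report.provenance["n_genome_wide_instruments"] = h_gw.n_snp

        # --- biologically-motivated MR on the biomarker ---------------
        stage = "biological_mr"
        if bio_variants is None:
            ranked = sorted(biomarker.records.values(), key=lambda r: (r.pval, r.rsid))
            bio_variants = [r.rsid for r in ranked[:2]]
            logger.info("bio_variants not named; using lead biomarker SNPs %s", bio_variants)
        _, f_bio, _ = instruments.instrument_strength(biomarker, bio_variants)
        h_bio = gwas_io.harmonize(biomarker.subset(bio_variants), outcome)
        report.rows.append(
            _mr_row("biological_mr", mr_core.ivw(h_bio),
                    biomarker.trait_label, outcome.trait_label, f_bio)
        )

        # --- TWFE triangulation (optional) ----------------------------
        if panel is not None:
            stage = "twfe"
            est = twfe.twfe_fit(twfe.build_exposure_index(panel))
            report.rows.append(
                ReportRow(
                    label="twfe", exposure="consumption index", outcome="outcome",
                    method="twfe", n_snp=None, f_stat=None, beta=est.beta,
                    se=est.se_cluster2, ci_low=est.ci_low, ci_high=est.ci_high,
                    pval=est.pval,
                )
            )

        # --- Steiger mechanism stratification -------------------------
        stage = "steiger_stratification"
        h2 = gwas_io.merge_second_exposure(h_gw, biomarker, missing_policy="drop")
        strata = steiger.stratify_instruments(h2)
        metab, behav = strata.trait2_first, strata.trait1_first
        report.strat_counts = {
            "biomarker_first": 0 if metab is None else metab.n_snp,
            "consumption_first": 0 if behav is None else behav.n_snp,
            "excluded": len(strata.excluded),
        }

        if metab is not None:
            stage = "metabolism_stratum_mr"
            rsids = metab.rsids
            h_pd = gwas_io.harmonize(biomarker.subset(rsids), consumption)
            _, f_p, _ = instruments.instrument_strength(biomarker, rsids)
            _, f_d, _ = instruments.instrument_strength(consumption, rsids)
            report.rows.append(
                _mr_row("metab_stratum_biomarker_on_consumption", mr_core.ivw(h_pd),
                        biomarker.trait_label, consumption.trait_label, f_p)
            )
            report.rows.append(
                _mr_row("metab_stratum_consumption_weighted", mr_core.ivw(metab),
                        consumption.trait_label, outcome.trait_label, f_d)
            )
            report.rows.append(
                _mr_row("metab_stratum_biomarker_weighted",
                        mr_core.ivw(steiger.reweight_exposure(metab)),
                        biomarker.trait_label, outcome.trait_label, f_p)
            )

        if behav is not None:
            stage = "behavior_stratum_mr"
            rsids = behav.rsids
            _, f_d, _ = instruments.instrument_strength(consumption, rsids)
            report.rows.append(
                _mr_row("behav_stratum_consumption_weighted", mr_core.ivw(behav),
                        consumption.trait_label, outcome.trait_label, f_d)
            )
            h_dp = gwas_io.harmonize(consumption.subset(rsids), biomarker)
            report.rows.append(
                _mr_row("behav_stratum_consumption_on_biomarker", mr_core.ivw(h_dp),
                        consumption.trait_label, biomarker.trait_label, f_d)
            )

        # --- MVMR-Qhet on the union instrument set --------------------
        stage = "mvmr"
        h_mv = build_mvmr_set(consumption, biomarker, outcome, ld, p_threshold, clump_r2)
        fit = mvmr.mvmr_qhet_fit(h_mv, seed=seed)
        report.rows.append(
            ReportRow(
                label="mvmr_direct_consumption", exposure=consumption.trait_label,
                outcome=outcome.trait_label, method="mvmr_qhet", n_snp=fit.n_snp,
                f_stat=None, beta=fit.beta_1, se=None,
                ci_low=fit.ci_1[0], ci_high=fit.ci_1[1], q_stat=fit.q_min,
            )
        )
        report.rows.append(
            ReportRow(
                label="mvmr_direct_biomarker", exposure=biomarker.trait_label,
                outcome=outcome.trait_label, method="mvmr_qhet", n_snp=fit.n_snp,
                f_stat=None, beta=fit.beta_2, se=None,
                ci_low=fit.ci_2[0], ci_high=fit.ci_2[1], q_stat=fit.q_min,
            )
        )

        # --- pleiotropy-robust suite ----------------------------------
        stage = "pleiotropy_robust"
        suites = [("full", h_gw)]
        if behav is not None and behav.n_snp >= 3:
            suites.append(("behav_stratum", behav))
        for tag, hset in suites:
            ests = [
                mr_core.egger(hset),
                mr_core.weighted_median(hset, n_boot=n_boot, seed=seed),
                mr_core.mode_estimate(hset, "simple", n_boot=n_boot, seed=seed),
                mr_core.mode_estimate(hset, "weighted", n_boot=n_boot, seed=seed),
            ]
            for est in ests:
                report.rows.append(
                    _mr_row(f"{tag}_{est.method}", est,
                            consumption.trait_label, outcome.trait_label)
                )
    except Exception as exc:  # preserve the partial report for diagnosis
        raise WorkflowError(stage, report, exc) from exc

    digest = hashlib.sha256(
        json.dumps(report.provenance, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    report.provenance["config_hash"] = digest
    return report


def render_report(report: WorkflowReport, path, fmt: str = "tsv") -> None:
    """Write the report deterministically as TSV or markdown.

    The markdown variant prints one line per analysis with the estimate
    formatted as ``beta (ci_low, ci_high)`` to 3 decimals.
    """
    if fmt == "tsv":
        report.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif fmt == "markdown":
        lines = [
            "| Analysis | Exposure | Outcome | F | n SNPs | Estimate (95% CI) |",
            "|---|---|---|---|---|---|",
        ]
        for r in report.rows:
            f = "" if r.f_stat is None else f"{r.f_stat:.0f}"
            n = "" if r.n_snp is None else str(r.n_snp)
            lines.append(
                f"| {r.label} | {r.exposure} | {r.outcome} | {f} | {n} | "
                f"{r.beta:.3f} ({r.ci_low:.3f}, {r.ci_high:.3f}) |"
            )
        if report.strat_counts:
            lines.append("")
            lines.append(
                "Steiger strata: "
                + ", ".join(f"{k}={v}" for k, v in sorted(report.strat_counts.items()))
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_report_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
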