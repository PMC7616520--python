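"""Structural-equation generator for the caffeine consumption / plasma
caffeine / BMI causal architecture, with analytic ground truth.

The individual-level model is linear-Gaussian.  Genotypes are
independent biallelic SNPs, g_ij ~ Binomial(2, maf_j).  Two variant
panels exist: metabolism variants (allele effects a_j on the biomarker)
and behavioral variants (allele effects c_j on a latent lifestyle
trait).  Phenotypes:

    L = Σ_behav c_j·g_j + ε_L                    (latent lifestyle)
    D = λ_L·L − λ_M·Σ_metab a_j·g_j + ε_D        (caffeine consumption)
    P = π_D·D + Σ_metab a_j·g_j + ε_P            (plasma caffeine)
    B = θ_P·P + θ_L·L + θ_S·D + ε_B              (outcome, BMI)

The −λ_M term is the titration feedback: fast metabolizers (high a_j
score) clear caffeine quickly, hence have *lower* plasma caffeine per
cup and drink *more* — equivalently, alleles that raise the biomarker
make carriers consume less to reach the same physiological effect.
θ_L is behavioral (latent-lifestyle) pleiotropy and θ_S the direct
consumption effect not mediated by plasma caffeine (accompaniments such
as milk and sugar).  Stability requires π_D·λ_M < 1.

Reduced-form per-allele effects (exact, raw scale):

    effect_D = λ_L·c_j − λ_M·a_j
    effect_P = π_D·effect_D + a_j
    effect_B = θ_P·effect_P + θ_L·c_j + θ_S·effect_D

:func:`simulate_gwas_trio` draws three non-overlapping cohorts
(consumption, biomarker, outcome GWAS), standardizes each phenotype
within its cohort and regresses it on every SNP, emulating the
three-study two-sample MR design.  :class:`GroundTruth` carries the
reduced-form effects on the standardized scale (population SDs are
available in closed form) and the true Steiger label of every SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gwas_io import SummaryStats, VariantAssociation
from .instruments import LDMatrix
from .twfe import PanelData

logger = logging.getLogger(__name__)

# non-palindromic allele pairs cycled across variants
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))


@dataclass
class SimulationConfig:
    """Structural coefficients, variant panels, cohort sizes and seed.

    Defaults (see :func:`default_study_config`) are calibrated so
    that all 24 variants reach P < 5e-7 in the consumption GWAS, the
    Steiger split separates the panels cleanly, and the qualitative sign
    pattern of the study design holds: θ_P < 0 (caffeine lowers BMI),
    θ_L > 0 and θ_S > 0 (behavioral pleiotropy and accompaniments raise
    it).
    """

    m_metab: int = 16
    m_behav: int = 8
    maf_range: tuple[float, float] = (0.2, 0.5)
    a: np.ndarray | None = None          # metabolism allele effects on biomarker
    c: np.ndarray | None = None          # behavioral allele effects on lifestyle
    lambda_M: float = 0.4                # titration feedback strength
    lambda_L: float = 0.6                # lifestyle -> consumption loading
    pi_D: float = 0.3                    # consumption -> biomarker transfer
    theta_P: float = -0.15               # biomarker -> outcome
    theta_L: float = 0.15                # lifestyle -> outcome pleiotropy
    theta_S: float = 0.075               # direct consumption -> outcome
    sigma_D: float = 1.0
    sigma_P: float = 1.0
    sigma_B: float = 1.0
    sigma_L: float = 1.0
    n_consumption_gwas: int = 50_000
    n_biomarker_gwas: int = 10_000
    n_outcome_gwas: int = 50_000
    panel_n_individuals: int = 2_000
    panel_n_visits: int = 4
    panel_confounding: float = 0.5       # corr of individual effect with mean consumption
    panel_beta: float = -0.1             # true outcome change per SD consumption
    panel_participation: float = 0.7     # revisit probability (unbalanced panel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a is None:
            self.a = np.linspace(0.20, 0.35, self.m_metab)
        if self.c is None:
            self.c = np.linspace(0.14, 0.26, self.m_behav)
        self.a = np.asarray(self.a, dtype=float)
        self.c = np.asarray(self.c, dtype=float)

    @property
    def m_total(self) -> int:
        return self.m_metab + self.m_behav

    def validate(self) -> None:
        if self.pi_D * self.lambda_M >= 1:
            raise ValueError("unstable titration: require pi_D*lambda_M < 1")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie in (0, 0.5]")
        if len(self.a) != self.m_metab or len(self.c) != self.m_behav:
            raise ValueError("effect vectors must match panel sizes")
        for name in ("n_consumption_gwas", "n_biomarker_gwas", "n_outcome_gwas"):
            if getattr(self, name) < 100:
                raise ValueError(f"{name} must be >= 100")
        if self.panel_n_visits < 2:
            raise ValueError("panel needs >= 2 visits")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["a"] = self.a.tolist()
        d["c"] = self.c.tolist()
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        for key in ("a", "c"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def default_study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The documented default study conditions: 16 metabolism + 8
    behavioral variants (24 instruments), θ_P < 0, θ_L > 0,
    θ_S = |θ_P|/2 > 0, desk-scale cohorts of 50k/10k/50k."""
    cfg = replace(SimulationConfig(seed=seed), **overrides) if overrides else SimulationConfig(seed=seed)
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """Analytic twin of the generator: exact reduced forms and labels."""

    rsids: list[str]
    mafs: np.ndarray
    a_full: np.ndarray                   # per-SNP a_j (0 for behavioral SNPs)
    c_full: np.ndarray                   # per-SNP c_j (0 for metabolism SNPs)
    is_metabolism: np.ndarray
    effect_d: np.ndarray                 # raw per-allele reduced forms
    effect_p: np.ndarray
    effect_b: np.ndarray
    sd_l: float
    sd_d: float
    sd_p: float
    sd_b: float
    theta_p: float
    theta_s: float
    theta_l: float
    steiger_labels: list[str] = field(default_factory=list)

    @property
    def effect_d_sd(self) -> np.ndarray:
        return self.effect_d / self.sd_d

    @property
    def effect_p_sd(self) -> np.ndarray:
        return self.effect_p / self.sd_p

    @property
    def effect_b_sd(self) -> np.ndarray:
        return self.effect_b / self.sd_b

    @property
    def theta_p_sd(self) -> float:
        """Biomarker→outcome effect on the standardized-GWAS scale."""
        return self.theta_p * self.sd_p / self.sd_b

    @property
    def theta_s_sd(self) -> float:
        """Direct consumption→outcome effect on the standardized scale."""
        return self.theta_s * self.sd_d / self.sd_b

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        d["theta_p_sd"] = self.theta_p_sd
        d["theta_s_sd"] = self.theta_s_sd
        return d


def _closed_form_moments(config: SimulationConfig, mafs: np.ndarray) -> dict:
    """Population variances/covariances implied by the structural model."""
    var_g = 2.0 * mafs * (1.0 - mafs)
    var_gl = float(np.sum(config.c**2 * var_g[config.m_metab:]))
    var_sa = float(np.sum(config.a**2 * var_g[: config.m_metab]))
    var_l = var_gl + config.sigma_L**2
    var_d = config.lambda_L**2 * var_l + config.lambda_M**2 * var_sa + config.sigma_D**2
    cov_dl = config.lambda_L * var_l
    cov_dsa = -config.lambda_M * var_sa
    var_p = (
        config.pi_D**2 * var_d + var_sa + 2.0 * config.pi_D * cov_dsa + config.sigma_P**2
    )
    cov_pd = config.pi_D * var_d + cov_dsa
    cov_pl = config.pi_D * cov_dl
    var_b = (
        config.theta_P**2 * var_p
        + config.theta_L**2 * var_l
        + config.theta_S**2 * var_d
        + 2.0 * config.theta_P * config.theta_L * cov_pl
        + 2.0 * config.theta_P * config.theta_S * cov_pd
        + 2.0 * config.theta_L * config.theta_S * cov_dl
        + config.sigma_B**2
    )
    return {
        "var_l": var_l, "var_d": var_d, "var_p": var_p, "var_b": var_b,
        "cov_dl": cov_dl, "cov_pd": cov_pd, "cov_pl": cov_pl, "cov_dsa": cov_dsa,
        "var_sa": var_sa,
    }


def draw_variant_panel(config: SimulationConfig, rng: np.random.Generator):
    """(rsids, mafs, truth) — one variant panel shared by all cohorts."""
    config.validate()
    m = config.m_total
    mafs = rng.uniform(*config.maf_range, size=m)
    rsids = [f"rsM{j + 1:02d}" for j in range(config.m_metab)] + [
        f"rsB{j + 1:02d}" for j in range(config.m_behav)
    ]
    a_full = np.concatenate([config.a, np.zeros(config.m_behav)])
    c_full = np.concatenate([np.zeros(config.m_metab), config.c])

    effect_d = config.lambda_L * c_full - config.lambda_M * a_full
    effect_p = config.pi_D * effect_d + a_full
    effect_b = (
        config.theta_P * effect_p + config.theta_L * c_full + config.theta_S * effect_d
    )
    mom = _closed_form_moments(config, mafs)
    truth = GroundTruth(
        rsids=rsids,
        mafs=mafs,
        a_full=a_full,
        c_full=c_full,
        is_metabolism=np.arange(m) < config.m_metab,
        effect_d=effect_d,
        effect_p=effect_p,
        effect_b=effect_b,
        sd_l=float(np.sqrt(mom["var_l"])),
        sd_d=float(np.sqrt(mom["var_d"])),
        sd_p=float(np.sqrt(mom["var_p"])),
        sd_b=float(np.sqrt(mom["var_b"])),
        theta_p=config.theta_P,
        theta_s=config.theta_S,
        theta_l=config.theta_L,
    )
    # a SNP is biomarker-proximal iff it explains more standardized
    # variance in P than in D; the shared 2·maf·(1−maf) factor cancels
    truth.steiger_labels = [
        "biomarker_first" if abs(p) > abs(d) else "consumption_first"
        for p, d in zip(truth.effect_p_sd, truth.effect_d_sd)
    ]
    return rsids, mafs, truth


def simulate_cohort(config: SimulationConfig, n: int, rng: np.random.Generator,
                    mafs: np.ndarray) -> dict:
    """Individual-level draws: genotypes and the four phenotypes."""
    config.validate()
    g = rng.binomial(2, mafs, size=(n, len(mafs))).astype(float)
    g_metab = g[:, : config.m_metab]
    g_behav = g[:, config.m_metab:]
    score_a = g_metab @ config.a
    L = g_behav @ config.c + rng.normal(0.0, config.sigma_L, n)
    D = config.lambda_L * L - config.lambda_M * score_a + rng.normal(0.0, config.sigma_D, n)
    P = config.pi_D * D + score_a + rng.normal(0.0, config.sigma_P, n)
    B = (
        config.theta_P * P + config.theta_L * L + config.theta_S * D
        + rng.normal(0.0, config.sigma_B, n)
    )
    return {"g": g, "L": L, "D": D, "P": P, "B": B}


def _gwas_scan(g: np.ndarray, pheno: np.ndarray, rsids, trait_label: str,
               alleles, orient_rng: np.random.Generator | None) -> SummaryStats:
    """Per-SNP simple regression of the standardized phenotype on genotype.

    ``orient_rng`` optionally scrambles each record's reported allele
    orientation (swap and/or strand-complement labels), emulating the
    inconsistent conventions of independent studies; harmonization must
    undo this downstream.
    """
    n, m = g.shape
    y = (pheno - pheno.mean()) / pheno.std(ddof=0)
    gc = g - g.mean(axis=0)
    sxx = np.einsum("ij,ij->j", gc, gc)
    beta = gc.T @ y / sxx
    rss = np.sum(y**2) - beta**2 * sxx
    se = np.sqrt(rss / (n - 2) / sxx)
    pval = np.clip(2.0 * sps.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    eaf = g.mean(axis=0) / 2.0

    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    records = []
    for j, rsid in enumerate(rsids):
        ea, oa = alleles[j]
        b, f = float(beta[j]), float(eaf[j])
        if orient_rng is not None:
            if orient_rng.random() < 0.5:  # report the other allele as effect
                ea, oa, b, f = oa, ea, -b, 1.0 - f
            if orient_rng.random() < 0.5:  # report the opposite strand
                ea, oa = comp[ea], comp[oa]
        records.append(
            VariantAssociation(
                rsid=rsid, effect_allele=ea, other_allele=oa,
                beta=b, se=float(se[j]), pval=float(pval[j]), n=n, eaf=f,
            )
        )
    return SummaryStats.from_records(trait_label, records)


@dataclass
class GwasTrio:
    consumption: SummaryStats
    biomarker: SummaryStats
    outcome: SummaryStats
    ld: LDMatrix
    truth: GroundTruth


def simulate_gwas_trio(config: SimulationConfig) -> GwasTrio:
    """Three-cohort summary statistics (consumption, biomarker, outcome).

    Cohorts are simulated independently with distinct sub-seeds,
    phenotypes standardized within cohort so betas are in SD units.
    Variants are in linkage equilibrium; the emitted LD matrix is the
    identity.  The consumption study keeps canonical allele orientation;
    the biomarker and outcome studies report scrambled orientations that
    :func:`proxymr.gwas_io.harmonize` must realign.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_panel, rng_d, rng_p, rng_b, rng_orient = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    rsids, mafs, truth = draw_variant_panel(config, rng_panel)
    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(len(rsids))]

    cohorts = {}
    for label, n, rng, pheno_key, orient in (
        ("consumption", config.n_consumption_gwas, rng_d, "D", None),
        ("biomarker", config.n_biomarker_gwas, rng_p, "P", rng_orient),
        ("outcome", config.n_outcome_gwas, rng_b, "B", rng_orient),
    ):
        sim = simulate_cohort(config, n, rng, mafs)
        cohorts[label] = _gwas_scan(sim["g"], sim[pheno_key], rsids, label, alleles, orient)

    return GwasTrio(
        consumption=cohorts["consumption"],
        biomarker=cohorts["biomarker"],
        outcome=cohorts["outcome"],
        ld=LDMatrix.identity(rsids),
        truth=truth,
    )


def simulate_panel(config: SimulationConfig, seed: int | None = None):
    """Confounded repeated-measures panel for the TWFE triangulation.

    Latent per-visit consumption z_it = μ_i + v_it (unit variance), with
    the individual outcome effect α_i correlated with μ_i at strength
    ``panel_confounding`` — so pooled OLS is biased while the within
    estimator is not.  Cups of coffee and tea are affine in z (1 SD ≈
    2 cups coffee ≈ 3 cups tea) with small beverage-specific noise, kept
    continuous.  Individuals always attend visit 0 and later visits with
    probability ``panel_participation``.

    Returns (PanelData, true beta).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, t = config.panel_n_individuals, config.panel_n_visits
    rho = config.panel_confounding

    mu = rng.normal(0.0, np.sqrt(0.5), n)
    v = rng.normal(0.0, np.sqrt(0.5), (n, t))
    z = mu[:, None] + v
    alpha = rho * mu + rng.normal(0.0, 0.3, n)
    gamma = rng.normal(0.0, 0.2, t)
    eps = rng.normal(0.0, 0.5, (n, t))
    bmi = config.panel_beta * z + alpha[:, None] + gamma[None, :] + eps

    coffee = 3.0 + 2.0 * z + rng.normal(0.0, 0.1, (n, t))
    tea = 4.0 + 3.0 * z + rng.normal(0.0, 0.1, (n, t))

    present = np.ones((n, t), dtype=bool)
    if t > 1:
        present[:, 1:] = rng.random((n, t - 1)) < config.panel_participation

    ii, tt = np.nonzero(present)
    frame = pd.DataFrame(
        {
            "individual_id": ii,
            "visit": tt,
            "coffee_cups": coffee[ii, tt],
            "tea_cups": tea[ii, tt],
            "bmi": bmi[ii, tt],
        }
    )
    return PanelData(frame), config.panel_beta
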