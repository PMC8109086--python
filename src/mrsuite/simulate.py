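"""Synthetic two-sample GWAS summary statistics with known truth.

Emulates the data-generating process the MR estimators assume: true
per-variant exposure effects gamma_j, direct (pleiotropic) outcome
effects alpha_j, true outcome effects Gamma_j = beta * gamma_j +
alpha_j, and observed effects with sampling noise whose standard errors
follow the standard GWAS approximation 1 / sqrt(2 N p (1-p)) for allele
frequency p and study size N.  Defaults are calibrated to the scale of
a large case-control exposure GWAS (N = 76,312) against a biobank-scale
outcome GWAS (N = 1,030,836).

The generator also fabricates the nuisance structure the selection and
harmonization stages must handle: LD blocks of correlated proxies,
palindromic (A/T, C/G) variants, random strand and allele-label
presentation in the outcome study, and a local trait catalog marking a
configurable fraction of variants as confounder-associated.

Effect alleles are labelled as the exposure-increasing allele, the
convention in which "directional" pleiotropy is directional; the
magnitude of gamma_j is half-normal with scale ``gamma_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import TabularLDSource, TraitCatalog
from .summary_io import SummaryDataset, VariantAssociation

__all__ = [
    "ScenarioConfig",
    "Truth",
    "GeneratedStudy",
    "CONFOUNDER_TRAITS",
    "generate",
    "make_trait_catalog",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]

#: trait families screened as potential confounders of an
#: inflammation/arrhythmia analysis
CONFOUNDER_TRAITS = [
    "body mass index",
    "fat-free mass",
    "heart rate",
    "blood pressure",
    "coronary artery disease",
    "diabetes",
    "chronic kidney disease",
]

P_FLOOR = 1e-300


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic two-sample scenario.

    ``pleiotropy`` is one of ``none``, ``balanced`` (zero-mean alpha),
    ``directional`` (mean ``alpha_mean``), or ``outliers``
    (``outlier_count`` variants with direct effects of
    ``outlier_size`` outcome-SE units).  ``inside_violation`` is the
    correlation between alpha_j and gamma_j (0 = InSIDE holds).
    ``ld_blocks = (n_blocks, snps_per_block, r2)`` replaces the
    independent variants with correlated blocks.
    """

    n_snps: int = 80
    true_beta: float = 0.0
    exposure_n: int = 76_312
    outcome_n: int = 1_030_836
    eaf_range: tuple[float, float] = (0.1, 0.9)
    gamma_scale: float = 0.08
    gamma_min: float = 0.03
    pleiotropy: str = "none"
    alpha_mean: float = 0.0
    alpha_sd: float = 0.001
    outlier_count: int = 1
    outlier_size: float = 10.0
    inside_violation: float = 0.0
    ld_blocks: tuple[int, int, float] | None = None
    palindrome_fraction: float = 0.2
    se_model: str = "quantitative"
    exposure_case_fraction: float = 38_565 / 76_312
    outcome_case_fraction: float = 60_620 / 1_030_836
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pleiotropy not in ("none", "balanced", "directional", "outliers"):
            raise ValueError(f"unknown pleiotropy model: {self.pleiotropy!r}")
        if self.se_model not in ("quantitative", "case_control"):
            raise ValueError(f"unknown se_model: {self.se_model!r}")
        if not abs(self.inside_violation) <= 1.0:
            raise ValueError("inside_violation must lie in [-1,1]")
        if self.gamma_scale <= 0 or self.alpha_sd < 0:
            raise ValueError("scales must be positive")
        if not 0.0 <= self.gamma_min < 5 * self.gamma_scale:
            raise ValueError("gamma_min must be small relative to gamma_scale")
        if not 0.0 <= self.palindrome_fraction <= 1.0:
            raise ValueError("palindrome_fraction must lie in [0,1]")
        lo, hi = self.eaf_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("eaf_range must satisfy 0 < lo < hi < 1")


@dataclass
class Truth:
    """Latent quantities behind one generated scenario."""

    true_beta: float
    rsids: list[str]
    gamma: np.ndarray
    alpha: np.ndarray
    big_gamma: np.ndarray
    beta_exp_hat: np.ndarray
    se_exp: np.ndarray
    beta_out_hat: np.ndarray
    se_out: np.ndarray
    eaf: np.ndarray
    block: np.ndarray
    is_block_index: np.ndarray
    palindromic: np.ndarray
    outcome_presentation: list[str]
    outlier_rsids: list[str] = field(default_factory=list)

    def instrument_frame(self) -> pd.DataFrame:
        """Truth-aligned harmonized table (both effects on the exposure
        effect allele), bypassing the harmonization stage."""
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "beta_exp": self.beta_exp_hat,
                "se_exp": self.se_exp,
                "beta_out": self.beta_out_hat,
                "se_out": self.se_out,
                "eaf_exp": self.eaf,
                "eaf_out": self.eaf,
            }
        )


class GeneratedStudy(NamedTuple):
    exposure: SummaryDataset
    outcome: SummaryDataset
    ld: TabularLDSource
    truth: Truth


def _se(n: int, eaf: np.ndarray, model: str, case_fraction: float) -> np.ndarray:
    base = 2.0 * n * eaf * (1.0 - eaf)
    if model == "case_control":
        base = base * case_fraction * (1.0 - case_fraction)
    return 1.0 / np.sqrt(base)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, P_FLOOR, 1.0)


def generate(config: ScenarioConfig) -> GeneratedStudy:
    """Draw one synthetic exposure/outcome study pair with recorded truth."""
    rng = np.random.default_rng(config.seed)

    if config.ld_blocks is not None:
        n_blocks, per_block, block_r2 = config.ld_blocks
        if n_blocks < 1 or per_block < 1 or not 0.0 <= block_r2 <= 1.0:
            raise ValueError("ld_blocks must be (n>=1, m>=1, r2 in [0,1])")
    else:
        n_blocks, per_block, block_r2 = config.n_snps, 1, 0.0
    n_index = n_blocks
    total = n_blocks * per_block

    # latent index-variant effects; effect allele = exposure-increasing.
    # Half-normal magnitudes truncated below at gamma_min, emulating the
    # genome-wide significance selection that precedes estimation: a
    # selected instrument's true effect is bounded away from zero.
    lo_u = stats.halfnorm.cdf(config.gamma_min, scale=config.gamma_scale)
    u = rng.uniform(lo_u, 1.0, n_index)
    gamma_i = stats.halfnorm.ppf(u, scale=config.gamma_scale)
    eaf_i = rng.uniform(*config.eaf_range, n_index)

    # expand LD blocks: proxies carry attenuated (sqrt r2) effects
    expand = np.repeat(np.arange(n_index), per_block)
    within = np.tile(np.arange(per_block), n_index)
    atten = np.where(within == 0, 1.0, np.sqrt(block_r2))
    gamma = gamma_i[expand] * atten
    eaf = eaf_i[expand]

    se_exp = _se(config.exposure_n, eaf, config.se_model,
                 config.exposure_case_fraction)
    se_out = _se(config.outcome_n, eaf, config.se_model,
                 config.outcome_case_fraction)

    # direct (pleiotropic) effects, with optional InSIDE violation
    rho = config.inside_violation
    z = rng.standard_normal(total)
    gz = (gamma - gamma.mean()) / (gamma.std() or 1.0)
    mix = rho * gz + np.sqrt(max(0.0, 1.0 - rho**2)) * z
    outlier_rsids: list[str] = []
    if config.pleiotropy == "none":
        alpha = np.zeros(total)
    elif config.pleiotropy == "balanced":
        alpha = config.alpha_sd * mix
    elif config.pleiotropy == "directional":
        alpha = config.alpha_mean + config.alpha_sd * mix
    else:  # outliers
        alpha = np.zeros(total)
        chosen = rng.choice(total, size=min(config.outlier_count, total),
                            replace=False)
        signs = rng.choice([-1.0, 1.0], size=chosen.size)
        alpha[chosen] = signs * config.outlier_size * se_out[chosen]

    big_gamma = config.true_beta * gamma + alpha

    beta_exp_hat = gamma + se_exp * rng.standard_normal(total)
    beta_out_hat = big_gamma + se_out * rng.standard_normal(total)
    p_exp = _pvals(beta_exp_hat, se_exp)
    p_out = _pvals(beta_out_hat, se_out)

    eaf_exp_obs = np.clip(eaf + rng.normal(0.0, 0.005, total), 0.005, 0.995)
    eaf_out_obs = np.clip(eaf + rng.normal(0.0, 0.005, total), 0.005, 0.995)

    rsids = [f"rs{100000 + i}" for i in range(total)]
    block = expand.copy()
    is_index = within == 0
    chrom = [str(b % 22 + 1) for b in block]
    pos = [10_000_000 + (b // 22) * 1_000_000 + w * 1_000
           for b, w in zip(block, within)]

    palindromic = rng.random(total) < config.palindrome_fraction
    alleles = []
    for j in range(total):
        pairs = PALINDROMIC_PAIRS if palindromic[j] else NON_PALINDROMIC_PAIRS
        alleles.append(pairs[rng.integers(len(pairs))])

    if config.pleiotropy == "outliers":
        outlier_rsids = [rsids[i] for i in sorted(chosen)]

    exp_records = [
        VariantAssociation(
            rsid=rsids[j], chrom=chrom[j], pos=pos[j],
            effect_allele=alleles[j][0], other_allele=alleles[j][1],
            eaf=float(eaf_exp_obs[j]), beta=float(beta_exp_hat[j]),
            se=float(se_exp[j]), pval=float(p_exp[j]),
        )
        for j in range(total)
    ]

    # outcome presentation: random strand / allele-label arrangement
    presentations: list[str] = []
    out_records = []
    for j in range(total):
        if palindromic[j]:
            op = ("same", "swap")[rng.integers(2)]
        else:
            op = ("same", "swap", "comp", "comp_swap")[rng.integers(4)]
        presentations.append(op)
        ea, oa = alleles[j]
        beta, frq = float(beta_out_hat[j]), float(eaf_out_obs[j])
        if "comp" in op:
            ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        if "swap" in op:
            ea, oa = oa, ea
            beta, frq = -beta, 1.0 - frq
        out_records.append(
            VariantAssociation(
                rsid=rsids[j], chrom=chrom[j], pos=pos[j],
                effect_allele=ea, other_allele=oa,
                eaf=frq, beta=beta, se=float(se_out[j]),
                pval=float(p_out[j]),
            )
        )

    ld = TabularLDSource()
    if per_block > 1:
        for b in range(n_blocks):
            members = [rsids[b * per_block + i] for i in range(per_block)]
            for i in range(per_block):
                for k in range(i + 1, per_block):
                    ld.add(members[i], members[k], block_r2)

    truth = Truth(
        true_beta=config.true_beta,
        rsids=rsids,
        gamma=gamma,
        alpha=alpha,
        big_gamma=big_gamma,
        beta_exp_hat=beta_exp_hat,
        se_exp=se_exp,
        beta_out_hat=beta_out_hat,
        se_out=se_out,
        eaf=eaf,
        block=block,
        is_block_index=is_index,
        palindromic=palindromic,
        outcome_presentation=presentations,
        outlier_rsids=outlier_rsids,
    )
    exposure = SummaryDataset(records=exp_records, trait="exposure",
                              ancestry="European",
                              n_cases=int(config.exposure_n
                                          * config.exposure_case_fraction),
                              n_controls=int(config.exposure_n
                                             * (1 - config.exposure_case_fraction)))
    outcome = SummaryDataset(records=out_records, trait="outcome",
                             ancestry="European",
                             n_cases=int(config.outcome_n
                                         * config.outcome_case_fraction),
                             n_controls=int(config.outcome_n
                                            * (1 - config.outcome_case_fraction)))
    return GeneratedStudy(exposure=exposure, outcome=outcome, ld=ld, truth=truth)


def make_trait_catalog(dataset: SummaryDataset, confounder_fraction: float,
                       seed: int | None = None,
                       traits: list[str] | None = None) -> TraitCatalog:
    """Assign a confounder-trait association (p < 5e-8) to a fraction of SNPs.

    Exactly ``round(confounder_fraction * n)`` variants are flagged, so
    downstream exclusion can be verified against
    :attr:`TraitCatalog.flagged_rsids` exactly.
    """
    if not 0.0 <= confounder_fraction <= 1.0:
        raise ValueError("confounder_fraction must lie in [0,1]")
    traits = list(CONFOUNDER_TRAITS if traits is None else traits)
    rng = np.random.default_rng(seed)
    rsids = sorted(dataset.rsids)
    n_flag = round(confounder_fraction * len(rsids))
    flagged = rng.choice(rsids, size=n_flag, replace=False) if n_flag else []
    associations = {
        str(rsid): [(
            traits[int(rng.integers(len(traits)))],
            float(10.0 ** rng.uniform(-20.0, -8.5)),
        )]
        for rsid in flagged
    }
    return TraitCatalog(associations=associations, excluded_traits=traits)
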