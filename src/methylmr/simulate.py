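"""Synthetic cohorts with known causal structure.

A simulated region consists of a block of cis SNPs with autoregressive LD, a
single CpG whose methylation level is driven by a designated meQTL, and a
complex trait generated under one of five causal scenarios:

``mediation``
    variant → methylation → trait (Y = beta_my·M + e).
``linkage``
    the meQTL and a *distinct* trait-causal SNP sit in LD at a controlled
    dosage r² (Y = beta_gy·G2 + e, corr(G1, G2)² = linkage_r2).
``reverse``
    variant → trait → methylation: the trait is driven by unlinked
    instrument SNPs carried on a separate chromosome, and methylation gains
    a beta_yg_m·Y term.
``pleiotropy``
    one variant affects methylation and trait through independent paths
    (Y = beta_gy·G1 + e with G1 also the meQTL).
``null``
    the trait is independent of the region.

Genotypes are drawn from a Gaussian copula: latent standard normals with
first-order autoregressive correlation ``ld_decay`` are thresholded at
Phi^-1(MAF) per haplotype, and the two haplotypes summed to a {0,1,2}
dosage. Methylation sits on a continuous standardized scale with
unit-variance noise, which is what the estimators see after
rank-normalization of array data.

Trait summary statistics at GWAS scale are generated *analytically*: the
true marginal effect of every SNP is derived from the generative model and
the expected copula LD, and the observed effect is drawn around it with
standard error 1/sqrt(2·f·(1−f)·n_gwas) — the cost of simulating 10^5
individuals is never paid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import special

from ._stats import (
    InfeasibleLDError,
    dosage_correlation,
    latent_rho_for_dosage_corr,
    normal_p,
)
from .data import CohortData, GroundTruth, SummaryStats

SCENARIOS = ("mediation", "linkage", "reverse", "pleiotropy", "null")

# Non-palindromic allele pairs assigned cyclically to simulated SNPs.
_ALLELE_PAIRS = [("A", "G"), ("T", "C"), ("A", "C"), ("T", "G"), ("G", "A"), ("C", "T")]

CPG_CLASSES = ("island", "shore", "body")
_CPG_CLASS_PROBS = (0.3, 0.3, 0.4)

GWAS_SIGNIFICANCE = 5.0e-8


@dataclass
class ScenarioConfig:
    """Parameters of one simulated region.

    Effect sizes are per-allele on an SD-unit scale. ``n_cohort`` defaults
    to 1000, the scale of a typical array-methylation cohort; ``n_gwas``
    is the effective sample size behind the analytic trait summary
    statistics.
    """

    scenario: str
    n_cohort: int = 1000
    n_gwas: int = 100_000
    region_snps: int = 40
    ld_decay: float = 0.9
    maf_range: Tuple[float, float] = (0.1, 0.5)
    beta_gm: float = 0.5
    beta_my: float = 0.4
    beta_gy: float = 0.3
    beta_yg_m: float = 0.3
    linkage_r2: float = 0.25
    n_trait_snps: int = 5
    seed: int = 0
    region_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.linkage_r2 < 1:
            raise ValueError("linkage_r2 must lie in [0, 1)")
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must lie in [0, 1)")
        for name in ("n_cohort", "n_gwas", "region_snps", "n_trait_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.scenario == "linkage" and self.region_snps < 2:
            raise InfeasibleLDError(
                "linkage scenario requires two distinct causal SNPs in the region"
            )

    @property
    def label(self) -> str:
        return self.region_id if self.region_id is not None else f"s{self.seed}"


def _ar1_latent(rng: np.random.Generator, n_hap: int, n: int, m: int, rho: float):
    z = np.empty((n_hap, n, m))
    z[..., 0] = rng.standard_normal((n_hap, n))
    if m > 1:
        innov = rng.standard_normal((n_hap, n, m - 1))
        w = math.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[..., j] = rho * z[..., j - 1] + w * innov[..., j - 1]
    return z


def _sd_dosage(f: np.ndarray) -> np.ndarray:
    return np.sqrt(2.0 * f * (1.0 - f))


def simulate_region(
    config: ScenarioConfig,
) -> Tuple[CohortData, SummaryStats, GroundTruth]:
    """Simulate one cis region under ``config.scenario``.

    Returns the individual-level cohort (dosages, methylation, phenotype),
    GWAS-scale summary statistics for the trait, and the ground truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m, n = cfg.region_snps, cfg.n_cohort
    label = cfg.label

    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    meqtl_idx = m // 2
    trait_idx: Optional[int] = None
    latent_mix = None
    if cfg.scenario == "linkage":
        trait_idx = meqtl_idx + 1 if meqtl_idx + 1 < m else meqtl_idx - 1
        # Give both causal SNPs the same MAF so any target r2 in [0,1) is
        # attainable, then solve for the latent mixing weight.
        mafs[trait_idx] = mafs[meqtl_idx]
        target_corr = math.sqrt(cfg.linkage_r2)
        latent_mix = latent_rho_for_dosage_corr(
            mafs[meqtl_idx], mafs[trait_idx], target_corr
        )

    z = _ar1_latent(rng, 2, n, m, cfg.ld_decay)
    if trait_idx is not None:
        eps = rng.standard_normal((2, n))
        z[..., trait_idx] = latent_mix * z[..., meqtl_idx] + math.sqrt(
            1.0 - latent_mix**2
        ) * eps
    thresholds = special.ndtri(np.clip(mafs, 1e-12, 1 - 1e-12))
    dosages = (z < thresholds).sum(axis=0).T.astype(float)  # (m, n)

    snp_ids = [f"rs{label}_{j:03d}" for j in range(m)]
    positions = 1_000_000 + 5_000 * np.arange(m)
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    snps = pd.DataFrame(
        {
            "SNP": snp_ids,
            "CHR": "1",
            "POS": positions,
            "EA": [p[0] for p in pairs],
            "OA": [p[1] for p in pairs],
            "EAF": mafs,
        }
    )

    # Unlinked trait-instrument SNPs (reverse scenario only) live on chr 2.
    inst_dos = None
    if cfg.scenario == "reverse":
        k = cfg.n_trait_snps
        inst_mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=k)
        inst_dos = rng.binomial(2, inst_mafs[:, None], size=(k, n)).astype(float)
        inst_ids = [f"rs{label}_t{j:02d}" for j in range(k)]
        inst_pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(k)]
        inst_snps = pd.DataFrame(
            {
                "SNP": inst_ids,
                "CHR": "2",
                "POS": 1_000_000 * (1 + np.arange(k)),
                "EA": [p[0] for p in inst_pairs],
                "OA": [p[1] for p in inst_pairs],
                "EAF": inst_mafs,
            }
        )
        snps = pd.concat([snps, inst_snps], ignore_index=True)
        dosages = np.vstack([dosages, inst_dos])

    g1 = dosages[meqtl_idx]
    e_m = rng.standard_normal(n)
    e_y = rng.standard_normal(n)

    if cfg.scenario == "mediation":
        meth = cfg.beta_gm * g1 + e_m
        pheno = cfg.beta_my * meth + e_y
    elif cfg.scenario == "linkage":
        meth = cfg.beta_gm * g1 + e_m
        pheno = cfg.beta_gy * dosages[trait_idx] + e_y
    elif cfg.scenario == "pleiotropy":
        meth = cfg.beta_gm * g1 + e_m
        pheno = cfg.beta_gy * g1 + e_y
    elif cfg.scenario == "null":
        meth = cfg.beta_gm * g1 + e_m
        pheno = e_y
    else:  # reverse: variant(s) -> trait -> methylation
        pheno = cfg.beta_gy * inst_dos.sum(axis=0) + e_y
        meth = cfg.beta_gm * g1 + cfg.beta_yg_m * pheno + e_m

    cpg_id = f"cg{label}"
    cpg_class = rng.choice(CPG_CLASSES, p=_CPG_CLASS_PROBS)
    cpgs = pd.DataFrame(
        {
            "CPG": [cpg_id],
            "CHR": ["1"],
            "POS": [int(positions[meqtl_idx]) + 500],
            "CLASS": [cpg_class],
        }
    )
    cohort = CohortData(
        sample_ids=[f"id{j:05d}" for j in range(n)],
        snps=snps,
        dosages=dosages,
        cpgs=cpgs,
        methylation=meth[None, :],
        phenotype=pheno,
    )

    true_beta = _true_marginal_betas(cfg, mafs, meqtl_idx, trait_idx, latent_mix)
    all_f = snps["EAF"].to_numpy()
    if cfg.scenario == "reverse":
        true_beta = np.concatenate(
            [true_beta, np.full(cfg.n_trait_snps, cfg.beta_gy)]
        )
    se = 1.0 / np.sqrt(2.0 * all_f * (1.0 - all_f) * cfg.n_gwas)
    observed = true_beta + rng.standard_normal(true_beta.size) * se
    stats_df = snps.copy()
    stats_df["BETA"] = observed
    stats_df["SE"] = se
    stats_df["P"] = normal_p(observed / se)
    stats_df["N"] = cfg.n_gwas
    trait_name = f"trait_{label}"
    summary = SummaryStats(trait=trait_name, df=stats_df)

    achieved = None
    trait_snps: list = []
    if cfg.scenario == "linkage":
        achieved = float(
            dosage_correlation(mafs[meqtl_idx], mafs[trait_idx], latent_mix) ** 2
        )
        trait_snps = [snp_ids[trait_idx]]
    elif cfg.scenario == "pleiotropy":
        trait_snps = [snp_ids[meqtl_idx]]
    elif cfg.scenario == "mediation":
        trait_snps = [snp_ids[meqtl_idx]]
    elif cfg.scenario == "reverse":
        trait_snps = [s for s in snps["SNP"] if "_t" in s]

    truth = GroundTruth(
        scenario=cfg.scenario,
        cpg_id=cpg_id,
        meqtl_snp=snp_ids[meqtl_idx],
        trait_snps=trait_snps,
        effects={
            "beta_gm": cfg.beta_gm,
            "beta_my": cfg.beta_my,
            "beta_gy": cfg.beta_gy,
            "beta_yg_m": cfg.beta_yg_m,
        },
        true_trait_beta=pd.Series(true_beta, index=snps["SNP"].to_numpy()),
        achieved_linkage_r2=achieved,
    )
    return cohort, summary, truth


def _true_marginal_betas(cfg, mafs, meqtl_idx, trait_idx, latent_mix):
    """Expected per-allele marginal SNP→trait effects for the region SNPs."""
    m = cfg.region_snps
    sd = _sd_dosage(mafs)

    def corr_with(causal_idx, mix=None):
        lat = cfg.ld_decay ** np.abs(np.arange(m) - meqtl_idx).astype(float)
        if causal_idx == meqtl_idx and mix is None:
            out = dosage_correlation(mafs, mafs[meqtl_idx], lat)
        else:
            # causal SNP is the inserted trait SNP: latent corr to SNP j is
            # mix * ld_decay^|j - meqtl|, and exactly `mix` at the meQTL.
            lat = mix * lat
            out = dosage_correlation(mafs, mafs[causal_idx], lat)
            out[causal_idx] = 1.0
        out = np.asarray(out, dtype=float)
        out[causal_idx] = 1.0
        return out

    if cfg.scenario == "mediation":
        c = corr_with(meqtl_idx)
        return cfg.beta_my * cfg.beta_gm * c * sd[meqtl_idx] / sd
    if cfg.scenario == "pleiotropy":
        c = corr_with(meqtl_idx)
        return cfg.beta_gy * c * sd[meqtl_idx] / sd
    if cfg.scenario == "linkage":
        c = corr_with(trait_idx, mix=latent_mix)
        if trait_idx is not None and latent_mix is not None:
            # handle AR attenuation between the inserted SNP and its neighbours
            c[meqtl_idx] = dosage_correlation(
                mafs[meqtl_idx], mafs[trait_idx], latent_mix
            )
        return cfg.beta_gy * c * sd[trait_idx] / sd
    # null and reverse: region SNPs have no marginal trait effect.
    return np.zeros(m)


def simulate_trait_instruments(
    n_instruments: int,
    beta_range: Tuple[float, float] = (0.2, 0.5),
    n_gwas: int = 100_000,
    maf_range: Tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    max_tries: int = 1000,
    trait: str = "trait",
) -> SummaryStats:
    """Independent (unlinked) genome-wide-significant instruments for a
    complex trait; every emitted record satisfies p < 5.0e-8, resampling
    the observed effect up to ``max_tries`` times per instrument."""
    if n_instruments < 1:
        raise ValueError("n_instruments must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_instruments):
        f = rng.uniform(*maf_range)
        se = 1.0 / math.sqrt(2.0 * f * (1.0 - f) * n_gwas)
        true_b = rng.uniform(*beta_range) * rng.choice([-1.0, 1.0])
        for attempt in range(max_tries):
            obs = true_b + rng.standard_normal() * se
            p = float(normal_p(obs / se))
            if p < GWAS_SIGNIFICANCE:
                break
        else:
            raise RuntimeError(
                f"could not draw a genome-wide-significant instrument in "
                f"{max_tries} attempts (beta_range={beta_range}, n_gwas={n_gwas})"
            )
        ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        rows.append(
            {
                "SNP": f"rs_inst_{j:03d}",
                "CHR": str(3 + j),
                "POS": 1_000_000,
                "EA": ea,
                "OA": oa,
                "EAF": f,
                "BETA": obs,
                "SE": se,
                "P": p,
                "N": n_gwas,
            }
        )
    return SummaryStats(trait=trait, df=pd.DataFrame(rows))


def simulate_cpg_universe(
    n_cpgs: int = 5000,
    seed: int = 0,
    n_chroms: int = 5,
    class_probs=_CPG_CLASS_PROBS,
) -> pd.DataFrame:
    """A background universe of CpG sites with island/shore/body labels."""
    rng = np.random.default_rng(seed)
    chroms = rng.integers(1, n_chroms + 1, size=n_cpgs)
    pos = rng.integers(10_000, 50_000_000, size=n_cpgs)
    classes = rng.choice(CPG_CLASSES, size=n_cpgs, p=class_probs)
    df = pd.DataFrame(
        {
            "CPG": [f"cg_u{j:06d}" for j in range(n_cpgs)],
            "CHR": chroms.astype(str),
            "POS": pos,
            "CLASS": classes,
        }
    )
    return df.sort_values(["CHR", "POS"], kind="mergesort").reset_index(drop=True)


def simulate_annotation_tracks(
    cpgs: Union[CohortData, pd.DataFrame],
    planted_fold: float = 1.0,
    background_rate: float = 0.1,
    hit_fraction: float = 0.1,
    half_width: int = 50,
    seed: int = 0,
    hits=None,
    track_name: str = "track",
):
    """BED-like intervals in which a designated hit CpG set overlaps the
    track at ``planted_fold`` times the background rate.

    Returns ``(track_df, hit_ids)`` where ``track_df`` has 0-based
    half-open columns chrom/start/end/name.
    """
    if planted_fold < 1:
        raise ValueError("planted_fold must be >= 1")
    if planted_fold * background_rate > 1:
        raise ValueError("planted_fold * background_rate exceeds 1")
    table = cpgs.cpgs if isinstance(cpgs, CohortData) else cpgs
    rng = np.random.default_rng(seed)
    ids = table["CPG"].to_numpy()
    if hits is None:
        n_hits = max(1, int(round(hit_fraction * len(ids))))
        hits = list(rng.choice(ids, size=n_hits, replace=False))
    hit_set = set(hits)
    is_hit = np.array([c in hit_set for c in ids])
    p_cover = np.where(is_hit, planted_fold * background_rate, background_rate)
    covered = rng.random(len(ids)) < p_cover
    cov = table.loc[covered]
    track = pd.DataFrame(
        {
            "chrom": cov["CHR"].astype(str).to_numpy(),
            "start": np.maximum(cov["POS"].to_numpy() - 1 - half_width, 0),
            "end": cov["POS"].to_numpy() - 1 + half_width + 1,
            "name": track_name,
        }
    ).reset_index(drop=True)
    return track, list(hits)


def resimulate_outcome_stats(
    truth: GroundTruth, base: SummaryStats, n_gwas: int, seed: int, trait: str = None
) -> SummaryStats:
    """Fresh observed trait summary statistics around the same true marginal
    effects — an independent outcome sample for replication analyses."""
    rng = np.random.default_rng(seed)
    df = base.df.copy()
    f = df["EAF"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n_gwas)
    tb = truth.true_trait_beta.reindex(df["SNP"]).to_numpy()
    obs = tb + rng.standard_normal(len(df)) * se
    df["BETA"] = obs
    df["SE"] = se
    df["P"] = normal_p(obs / se)
    df["N"] = n_gwas
    return SummaryStats(trait=trait or f"{base.trait}_rep", df=df)


def simulate_expression_stats(
    cohort: CohortData,
    truth: GroundTruth,
    beta_me: float = 0.4,
    n_panel: int = 30_000,
    seed: int = 0,
) -> SummaryStats:
    """Summary statistics for a cis gene-expression trait downstream of the
    region's methylation (E = beta_me·M + noise), at eQTL-panel scale.

    Marginal SNP effects are beta_me·beta_gm·cov(G_j, G_meqtl)/var(G_j),
    estimated from the cohort's empirical dosage covariances.
    """
    rng = np.random.default_rng(seed)
    region = cohort.snps[cohort.snps["CHR"] == "1"]
    g1 = cohort.dosage(truth.meqtl_snp)
    bgm = truth.effects["beta_gm"]
    rows = []
    for _, row in region.iterrows():
        gj = cohort.dosage(row["SNP"])
        var_j = gj.var()
        cov = np.cov(gj, g1)[0, 1]
        tb = beta_me * bgm * cov / var_j if var_j > 0 else 0.0
        f = float(row["EAF"])
        se = 1.0 / math.sqrt(2.0 * f * (1.0 - f) * n_panel)
        obs = tb + rng.standard_normal() * se
        rows.append(
            {
                "SNP": row["SNP"],
                "CHR": row["CHR"],
                "POS": row["POS"],
                "EA": row["EA"],
                "OA": row["OA"],
                "EAF": f,
                "BETA": obs,
                "SE": se,
                "P": float(normal_p(obs / se)),
                "N": n_panel,
            }
        )
    return SummaryStats(trait=f"expr_{truth.cpg_id}", df=pd.DataFrame(rows))
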