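"""Permutation-based joint-likelihood colocalization.

An MR hit tells us a variant is associated with both methylation and a
complex trait; it does not tell us whether the *same* causal variant drives
both signals or whether two distinct causal variants merely sit in LD.
This module contrasts those explanations with a single-causal-variant
joint-likelihood statistic.

Under a single causal variant per trait, the log-likelihood gain of placing
trait t's causal variant at SNP i is l_t(i) = z_{t,i}^2 / 2. The statistic

    Lambda = max_i [l1(i) + l2(i)]
             - max_{(i,j): r2_ij < exclusion_r2} [l1(i) + l2(j)]

compares the best shared-variant configuration with the best configuration
placing the two causal variants on distinct, distinguishable SNPs.
Configurations whose two variants are in LD at r2 >= 0.8 are merged with
the shared hypothesis — at that LD level distinct variants are not
resolvable, the first stated limitation of joint likelihood mapping (the
second, weak QTL effects, is handled upstream by the instrument inclusion
rules). Lambda > 0 favours a shared causal variant.

Significance is calibrated by permutation using the trait with
individual-level data (methylation): the methylation vector is permuted
whole across samples — preserving LD among SNPs while destroying the
genotype–methylation association — methylation z-scores are recomputed
against the fixed genotypes, and Lambda is recomputed against the fixed
trait summary statistics. This is a reimplementation in spirit of joint
likelihood mapping, not a bit-compatible port.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .data import CohortData, SummaryStats
from .harmonize import AlleleRecord, harmonize
from .instruments import DEFAULT_CIS_WINDOW, scan_cis_meqtl

DEFAULT_EXCLUSION_R2 = 0.8


class UntestableRegionError(ValueError):
    """No SNP pair below the exclusion r2: the statistic is undefined."""


@dataclass
class RegionalAssoc:
    """Aligned per-SNP z-scores for two traits plus the signed LD matrix."""

    snps: list
    z1: np.ndarray  # methylation (individual-level trait)
    z2: np.ndarray  # complex trait (summary-level), sign-aligned to z1's alleles
    R: np.ndarray  # signed dosage correlation

    def __post_init__(self) -> None:
        m = len(self.snps)
        self.z1 = np.asarray(self.z1, dtype=float)
        self.z2 = np.asarray(self.z2, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.z1.shape != (m,) or self.z2.shape != (m,):
            raise ValueError("z vectors must match the SNP list")
        if self.R.shape != (m, m):
            raise ValueError("LD matrix must be square over the SNP list")
        if not np.all(np.abs(self.R) <= 1 + 1e-8):
            raise ValueError("LD entries must lie in [-1, 1]")
        if not np.allclose(np.diag(self.R), 1.0):
            raise ValueError("LD diagonal must be 1")
        if not (np.isfinite(self.z1).all() and np.isfinite(self.z2).all()):
            raise ValueError("z-scores must be finite")


@dataclass
class ColocResult:
    cpg_id: str
    trait: str
    lambda_obs: Optional[float]
    p_perm: Optional[float]
    n_perm: int
    exclusion_r2: float
    testable: bool = True

    def __post_init__(self) -> None:
        if self.testable and not (0 < self.p_perm <= 1):
            raise ValueError("permutation p must lie in (0, 1]")


def _distinct_bound(l2: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """b[i] = max over j with r2_ij < threshold of l2[j] (-inf if none)."""
    b = np.where(valid, l2[None, :], -np.inf).max(axis=1)
    return b


def coloc_statistic(
    assoc: RegionalAssoc, exclusion_r2: float = DEFAULT_EXCLUSION_R2
) -> float:
    """The shared-vs-distinct joint-likelihood contrast Lambda.

    Raises :class:`UntestableRegionError` when every SNP pair is in LD at
    r2 >= ``exclusion_r2`` (tiny or degenerate region).
    """
    if len(assoc.snps) < 2:
        raise UntestableRegionError("need >= 2 SNPs")
    l1 = assoc.z1**2 / 2.0
    l2 = assoc.z2**2 / 2.0
    valid = assoc.R**2 < exclusion_r2
    if not valid.any():
        raise UntestableRegionError(
            f"no SNP pair with r2 < {exclusion_r2}: distinct-variant "
            "configurations are not distinguishable here"
        )
    shared = float(np.max(l1 + l2))
    b = _distinct_bound(l2, valid)
    distinct = float(np.max(l1 + b))
    return shared - distinct


def build_regional_assoc(
    cohort: CohortData,
    cpg_id: str,
    trait_stats: SummaryStats,
    cis_window: int = DEFAULT_CIS_WINDOW,
) -> RegionalAssoc:
    """Assemble aligned z-vectors and LD for a CpG's cis region.

    Methylation z-scores come from the in-cohort scan; trait z-scores are
    taken from the summary statistics after harmonizing each SNP's effect
    allele to the cohort's coding. SNPs absent from either source (or
    dropped by harmonization) are excluded.
    """
    scan = scan_cis_meqtl(cohort, cpg_id, cis_window)
    snps, z1, z2 = [], [], []
    for _, row in scan.df.iterrows():
        out_row = trait_stats.lookup(row["SNP"])
        if out_row is None:
            continue
        pair = harmonize(
            AlleleRecord.from_row(row), AlleleRecord.from_row(out_row)
        )
        if not pair.ok:
            continue
        snps.append(row["SNP"])
        z1.append(row["T"])
        z2.append(pair.beta_out / pair.se_out)
    if len(snps) < 2:
        raise UntestableRegionError("fewer than 2 SNPs shared between datasets")
    G = np.vstack([cohort.dosage(s) for s in snps])
    R = np.corrcoef(G)
    return RegionalAssoc(snps=snps, z1=np.asarray(z1), z2=np.asarray(z2), R=R)


def coloc_permutation_test(
    cohort: CohortData,
    cpg_id: str,
    trait_stats: SummaryStats,
    n_perm: int,
    seed: int = 0,
    exclusion_r2: float = DEFAULT_EXCLUSION_R2,
    cis_window: int = DEFAULT_CIS_WINDOW,
) -> ColocResult:
    """Permutation p-value for the shared-causal-variant statistic.

    ``p = (1 + #{Lambda_perm >= Lambda_obs}) / (n_perm + 1)`` — the add-one
    estimator, so the smallest attainable p is 1/(n_perm+1). An untestable
    region propagates as an untestable result rather than an error.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    try:
        assoc = build_regional_assoc(cohort, cpg_id, trait_stats, cis_window)
        lambda_obs = coloc_statistic(assoc, exclusion_r2)
    except UntestableRegionError:
        return ColocResult(
            cpg_id=cpg_id,
            trait=trait_stats.trait,
            lambda_obs=None,
            p_perm=None,
            n_perm=n_perm,
            exclusion_r2=exclusion_r2,
            testable=False,
        )

    rng = np.random.default_rng(seed)
    n = cohort.n_samples
    G = np.vstack([cohort.dosage(s) for s in assoc.snps])
    Gs = G - G.mean(axis=1, keepdims=True)
    Gs /= np.sqrt((Gs**2).sum(axis=1, keepdims=True))
    y = cohort.meth(cpg_id)
    ys = (y - y.mean()) / np.sqrt(((y - y.mean()) ** 2).sum())
    # Permutations of the whole methylation vector, one column each.
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = ys[perm_idx].T  # (n, n_perm)
    r = Gs @ Yp  # (m, n_perm) correlations
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    z1p = r * np.sqrt((n - 2) / (1.0 - r**2))  # identical to the scan t-stat
    l1p = z1p**2 / 2.0
    l2 = assoc.z2**2 / 2.0
    valid = assoc.R**2 < exclusion_r2
    b = _distinct_bound(l2, valid)
    shared_p = (l1p + l2[:, None]).max(axis=0)
    distinct_p = (l1p + b[:, None]).max(axis=0)
    lambda_perm = shared_p - distinct_p
    n_ge = int(np.sum(lambda_perm >= lambda_obs))
    p_perm = (1.0 + n_ge) / (n_perm + 1.0)
    return ColocResult(
        cpg_id=cpg_id,
        trait=trait_stats.trait,
        lambda_obs=lambda_obs,
        p_perm=p_perm,
        n_perm=n_perm,
        exclusion_r2=exclusion_r2,
    )


def classify_associations(
    mr_hits,
    coloc_results: Dict,
    alpha_family: Optional[float] = None,
) -> Dict[str, list]:
    """Partition MR hits into shared-variant / linkage-confounded /
    untestable, at the family threshold 0.05 / (number of hits followed
    up) unless ``alpha_family`` is given."""
    hits = list(mr_hits)
    out = {"shared": [], "linkage": [], "untestable": []}
    if not hits:
        return out
    alpha = alpha_family if alpha_family is not None else 0.05 / len(hits)
    for hit in hits:
        res = coloc_results[hit]
        if not res.testable:
            out["untestable"].append(hit)
        elif res.p_perm < alpha:
            out["shared"].append(hit)
        else:
            out["linkage"].append(hit)
    return out


def coloc_table(results) -> pd.DataFrame:
    rows = []
    for res, cls in results:
        rows.append(
            {
                "CPG": res.cpg_id,
                "TRAIT": res.trait,
                "LAMBDA": res.lambda_obs if res.testable else "",
                "P_PERM": res.p_perm if res.testable else "",
                "N_PERM": res.n_perm,
                "CLASS": cls,
            }
        )
    return pd.DataFrame(
        rows, columns=["CPG", "TRAIT", "LAMBDA", "P_PERM", "N_PERM", "CLASS"]
    )
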