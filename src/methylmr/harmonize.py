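"""Allele harmonization between exposure and outcome summary records.

Two-sample MR combines effect estimates from different studies, which may
report the same SNP with swapped effect/other alleles or on opposite
strands. Harmonization re-expresses the outcome effect on the exposure's
effect allele: a swap negates the outcome beta, a strand flip complements
the alleles, and palindromic SNPs (A/T, G/C) — where the strand cannot be
inferred from alleles alone — are resolved by comparing effect-allele
frequencies, or dropped when both frequencies sit inside an ambiguity band
around 0.5.

When an instrument is absent from the outcome dataset, a proxy in strong LD
(r² >= 0.8 by default) can stand in for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Union

import numpy as np
import pandas as pd

from .data import CohortData, SummaryStats

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
DEFAULT_PROXY_R2 = 0.8
AMBIGUITY_BAND = (0.42, 0.58)


class AlleleRecord(NamedTuple):
    """One SNP association: effect allele, other allele, beta, SE, EAF."""

    snp: str
    ea: str
    oa: str
    beta: float
    se: float
    eaf: float

    @classmethod
    def from_row(cls, row: pd.Series, beta="BETA", se="SE") -> "AlleleRecord":
        return cls(
            snp=str(row["SNP"]),
            ea=str(row["EA"]),
            oa=str(row["OA"]),
            beta=float(row[beta]),
            se=float(row[se]),
            eaf=float(row["EAF"]),
        )


@dataclass
class HarmonizedPair:
    """Exposure and outcome effects aligned to a common effect allele."""

    snp: str
    ea: str
    oa: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float
    action: str  # ok | swap | flip | flip_swap | palindromic_kept |
    #              palindromic_flipped | dropped
    ok: bool
    reason: Optional[str] = None
    proxy_snp: Optional[str] = None
    proxy_r2: Optional[float] = None


def is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


def _valid_alleles(*alleles: str) -> bool:
    return all(a in COMPLEMENT for a in alleles)


def harmonize(
    exposure: AlleleRecord,
    outcome: AlleleRecord,
    ambiguity_band=AMBIGUITY_BAND,
) -> HarmonizedPair:
    """Align an outcome record to the exposure's effect allele.

    Returns a :class:`HarmonizedPair`; irreconcilable or ambiguous pairs
    come back with ``ok=False`` and a reason code rather than raising.
    """

    def rejected(reason: str) -> HarmonizedPair:
        return HarmonizedPair(
            snp=exposure.snp,
            ea=exposure.ea,
            oa=exposure.oa,
            beta_exp=exposure.beta,
            se_exp=exposure.se,
            beta_out=np.nan,
            se_out=outcome.se,
            eaf_exp=exposure.eaf,
            eaf_out=outcome.eaf,
            action="dropped",
            ok=False,
            reason=reason,
        )

    if not _valid_alleles(exposure.ea, exposure.oa, outcome.ea, outcome.oa):
        return rejected("non_acgt_allele")
    if exposure.ea == exposure.oa or outcome.ea == outcome.oa:
        return rejected("monomorphic_allele_pair")

    def accepted(beta_out, eaf_out, action) -> HarmonizedPair:
        return HarmonizedPair(
            snp=exposure.snp,
            ea=exposure.ea,
            oa=exposure.oa,
            beta_exp=exposure.beta,
            se_exp=exposure.se,
            beta_out=beta_out,
            se_out=outcome.se,
            eaf_exp=exposure.eaf,
            eaf_out=eaf_out,
            action=action,
            ok=True,
        )

    if is_palindromic(exposure.ea, exposure.oa):
        if {outcome.ea, outcome.oa} != {exposure.ea, exposure.oa}:
            return rejected("irreconcilable_alleles")
        # Orient nominally to the exposure effect allele, then decide the
        # strand by frequency. The four orientation hypotheses (as-is /
        # swapped x same-strand / flipped) collapse to two observable ones.
        if outcome.ea == exposure.ea:
            beta0, eaf0 = outcome.beta, outcome.eaf
        else:
            beta0, eaf0 = -outcome.beta, 1.0 - outcome.eaf
        lo, hi = ambiguity_band
        if lo <= exposure.eaf <= hi and lo <= eaf0 <= hi:
            return rejected("palindromic_ambiguous")
        if abs(exposure.eaf - eaf0) <= abs(exposure.eaf - (1.0 - eaf0)):
            return accepted(beta0, eaf0, "palindromic_kept")
        return accepted(-beta0, 1.0 - eaf0, "palindromic_flipped")

    if (outcome.ea, outcome.oa) == (exposure.ea, exposure.oa):
        return accepted(outcome.beta, outcome.eaf, "ok")
    if (outcome.ea, outcome.oa) == (exposure.oa, exposure.ea):
        return accepted(-outcome.beta, 1.0 - outcome.eaf, "swap")
    c_ea, c_oa = COMPLEMENT[outcome.ea], COMPLEMENT[outcome.oa]
    if (c_ea, c_oa) == (exposure.ea, exposure.oa):
        return accepted(outcome.beta, outcome.eaf, "flip")
    if (c_ea, c_oa) == (exposure.oa, exposure.ea):
        return accepted(-outcome.beta, 1.0 - outcome.eaf, "flip_swap")
    return rejected("irreconcilable_alleles")


def find_proxy(
    snp_id: str,
    outcome_stats: SummaryStats,
    genotypes: CohortData,
    min_r2: float = DEFAULT_PROXY_R2,
) -> Optional[str]:
    """The outcome-dataset SNP with maximal reference-panel r² (>= min_r2)
    to the query; the query itself when present; None when nothing
    qualifies. Absence is a valid result, not an error."""
    present = set(outcome_stats.df["SNP"])
    if snp_id in present:
        return snp_id
    if snp_id not in set(genotypes.snps["SNP"]):
        return None
    query = genotypes.dosage(snp_id)
    best, best_r2 = None, min_r2
    for cand in outcome_stats.df["SNP"]:
        if cand == snp_id or cand not in genotypes._snp_index:
            continue
        r = np.corrcoef(query, genotypes.dosage(cand))[0, 1]
        if r * r >= best_r2:
            best, best_r2 = cand, r * r
    return best


def proxy_alignment_sign(
    snp_id: str, proxy_id: str, genotypes: CohortData
) -> int:
    """Sign for mapping an exposure effect onto a proxy's effect allele,
    from the reference panel's dosage correlation sign."""
    r = np.corrcoef(genotypes.dosage(snp_id), genotypes.dosage(proxy_id))[0, 1]
    return 1 if r >= 0 else -1


def harmonization_report(pairs) -> pd.DataFrame:
    """One audit row per attempted pair (action code ok/swap/flip/...)."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "SNP": p.snp,
                "EA": p.ea,
                "OA": p.oa,
                "BETA_EXP": p.beta_exp,
                "SE_EXP": p.se_exp,
                "BETA_OUT": p.beta_out,
                "SE_OUT": p.se_out,
                "ACTION": p.action if p.proxy_snp is None else "proxy",
                "PROXY_SNP": p.proxy_snp if p.proxy_snp is not None else "",
                "PROXY_R2": p.proxy_r2 if p.proxy_r2 is not None else "",
                "REASON": p.reason or "",
            }
        )
    return pd.DataFrame(rows)
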