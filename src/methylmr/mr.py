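"""Two-sample MR estimators: Wald ratio and fixed-effect IVW.

With a single instrument Z the causal effect of exposure X on outcome Y is
the Wald ratio

    beta_hat = beta_Y|Z / beta_X|Z

with delta-method standard error

    se^2 = se_Y^2/beta_X^2 + beta_Y^2 se_X^2 / beta_X^4
           - 2 beta_Y cov(beta_X, beta_Y) / beta_X^3,

where the covariance term is zero in the two-sample setting (the exposure
and outcome effects come from non-overlapping samples) but is exposed as a
parameter. With k >= 2 instruments the inverse-variance-weighted estimate

    beta_hat = sum_k X_k Y_k s_k^-2 / sum_k X_k^2 s_k^-2,
    se_hat   = sqrt(1 / sum_k X_k^2 s_k^-2)

weights each per-instrument ratio by the precision of the outcome effect
(fixed-effect model; equivalent to weighted least squares through the
origin of outcome betas on exposure betas). p-values are two-sided from
the standard normal, the usual summary-data MR convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import math

import numpy as np
import pandas as pd

from ._stats import normal_p
from .data import CohortData, SummaryStats
from .harmonize import (
    AlleleRecord,
    HarmonizedPair,
    find_proxy,
    harmonization_report,
    harmonize,
    proxy_alignment_sign,
)
from .instruments import DEFAULT_CLUMP_R2, InstrumentSet

RESULT_COLUMNS = ["EXPOSURE", "OUTCOME", "DIRECTION", "METHOD", "NSNP", "BETA", "SE", "P"]


class NonInstrumentError(ValueError):
    """Raised when an exposure effect of exactly zero makes the ratio
    estimate undefined."""


@dataclass
class MrResult:
    exposure: str
    outcome: str
    method: str  # wald | ivw
    beta: float
    se: float
    p: float
    n_instruments: int
    direction: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("MR standard error must be positive")
        if not 0 < self.p <= 1:
            raise ValueError("MR p-value must lie in (0, 1]")
        if (self.method == "wald") != (self.n_instruments == 1):
            raise ValueError("wald method iff exactly one instrument")

    def to_row(self) -> dict:
        return {
            "EXPOSURE": self.exposure,
            "OUTCOME": self.outcome,
            "DIRECTION": self.direction,
            "METHOD": self.method,
            "NSNP": self.n_instruments,
            "BETA": self.beta,
            "SE": self.se,
            "P": self.p,
        }


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    cov: float = 0.0,
    exposure: str = "exposure",
    outcome: str = "outcome",
    direction: str = "forward",
) -> MrResult:
    """Single-instrument causal estimate beta_out / beta_exp."""
    if beta_exp == 0:
        raise NonInstrumentError("exposure effect is zero: ratio undefined")
    if se_exp <= 0 or se_out <= 0:
        raise ValueError("standard errors must be positive")
    beta = beta_out / beta_exp
    var = (
        se_out**2 / beta_exp**2
        + beta_out**2 * se_exp**2 / beta_exp**4
        - 2.0 * beta_out * cov / beta_exp**3
    )
    if var <= 0:
        raise ValueError("non-positive Wald variance (check the cov term)")
    se = math.sqrt(var)
    return MrResult(
        exposure=exposure,
        outcome=outcome,
        method="wald",
        beta=beta,
        se=se,
        p=float(normal_p(beta / se)),
        n_instruments=1,
        direction=direction,
    )


def ivw(
    beta_exp,
    beta_out,
    se_out,
    exposure: str = "exposure",
    outcome: str = "outcome",
    direction: str = "forward",
) -> MrResult:
    """Fixed-effect inverse-variance-weighted estimate over >=2 instruments."""
    X = np.asarray(beta_exp, dtype=float)
    Y = np.asarray(beta_out, dtype=float)
    S = np.asarray(se_out, dtype=float)
    if X.size < 2:
        raise ValueError("IVW requires >= 2 instruments (use wald_ratio for 1)")
    if (S <= 0).any():
        raise ValueError("outcome standard errors must be positive")
    if np.all(X == 0):
        raise NonInstrumentError("all exposure effects are zero")
    w = S**-2
    denom = float(np.sum(X * X * w))
    beta = float(np.sum(X * Y * w)) / denom
    se = math.sqrt(1.0 / denom)
    return MrResult(
        exposure=exposure,
        outcome=outcome,
        method="ivw",
        beta=beta,
        se=se,
        p=float(normal_p(beta / se)),
        n_instruments=int(X.size),
        direction=direction,
    )


def run_mr(
    exposure_instruments: InstrumentSet,
    outcome_stats: SummaryStats,
    direction: str = "forward",
    genotypes: Optional[CohortData] = None,
    min_proxy_r2: float = 0.8,
    clump_r2: float = DEFAULT_CLUMP_R2,
) -> Tuple[Optional[MrResult], pd.DataFrame]:
    """Harmonize every instrument into the outcome dataset and estimate.

    Dispatches to the Wald ratio for one harmonized instrument and to IVW
    for two or more. When an instrument is missing from the outcome
    dataset and ``genotypes`` are supplied, a proxy with reference r² >=
    ``min_proxy_r2`` is substituted (exposure effect sign-aligned through
    the panel); after substitution, mutual instrument independence is
    re-checked at ``clump_r2`` and offenders with the weaker exposure p
    are dropped.

    Returns ``(result, report)``; the result is None (reason in the
    report) when no instrument can be harmonized.
    """
    pairs: list[HarmonizedPair] = []
    kept_rows: list[pd.Series] = []
    for _, row in exposure_instruments.instruments.iterrows():
        exp_rec = AlleleRecord.from_row(row, beta="BETA_EXP", se="SE_EXP")
        target = row["SNP"]
        proxy_used = None
        proxy_r2 = None
        out_row = outcome_stats.lookup(target)
        if out_row is None and genotypes is not None:
            proxy = find_proxy(target, outcome_stats, genotypes, min_proxy_r2)
            if proxy is not None:
                sign = proxy_alignment_sign(target, proxy, genotypes)
                prow = genotypes.snp_row(proxy)
                exp_rec = AlleleRecord(
                    snp=proxy,
                    ea=str(prow["EA"]),
                    oa=str(prow["OA"]),
                    beta=sign * exp_rec.beta,
                    se=exp_rec.se,
                    eaf=float(prow["EAF"]),
                )
                proxy_used = proxy
                proxy_r2 = genotypes.r2(target, proxy)
                out_row = outcome_stats.lookup(proxy)
        if out_row is None:
            pair = HarmonizedPair(
                snp=str(target),
                ea=exp_rec.ea,
                oa=exp_rec.oa,
                beta_exp=exp_rec.beta,
                se_exp=exp_rec.se,
                beta_out=np.nan,
                se_out=np.nan,
                eaf_exp=exp_rec.eaf,
                eaf_out=np.nan,
                action="dropped",
                ok=False,
                reason="absent_from_outcome",
            )
        else:
            out_rec = AlleleRecord.from_row(out_row)
            pair = harmonize(exp_rec, out_rec)
            pair.proxy_snp = proxy_used
            pair.proxy_r2 = proxy_r2
        pairs.append(pair)
        if pair.ok:
            kept_rows.append((row, pair))

    # Re-check mutual independence after any proxy substitution.
    if genotypes is not None and any(p.proxy_snp for _, p in kept_rows):
        kept_rows.sort(key=lambda rp: (rp[0]["P_EXP"], str(rp[1].snp)))
        final = []
        for row, pair in kept_rows:
            snp = pair.proxy_snp or row["SNP"]
            if all(
                genotypes.r2(snp, p2.proxy_snp or r2_["SNP"]) < clump_r2
                for r2_, p2 in final
            ):
                final.append((row, pair))
            else:
                pair.ok = False
                pair.action = "dropped"
                pair.reason = "proxy_broke_independence"
        kept_rows = final

    report = harmonization_report(pairs)
    if not kept_rows:
        return None, report
    exposure_id = exposure_instruments.cpg_id
    if len(kept_rows) == 1:
        _, pair = kept_rows[0]
        result = wald_ratio(
            pair.beta_exp,
            pair.se_exp,
            pair.beta_out,
            pair.se_out,
            exposure=exposure_id,
            outcome=outcome_stats.trait,
            direction=direction,
        )
    else:
        result = ivw(
            [p.beta_exp for _, p in kept_rows],
            [p.beta_out for _, p in kept_rows],
            [p.se_out for _, p in kept_rows],
            exposure=exposure_id,
            outcome=outcome_stats.trait,
            direction=direction,
        )
    return result, report


def results_table(results) -> pd.DataFrame:
    """Long-format MR results (one row per CpG x trait test)."""
    rows = [r.to_row() for r in results if r is not None]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
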