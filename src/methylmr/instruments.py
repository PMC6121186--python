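"""cis-meQTL scan and LD clumping: independent instruments per CpG.

The scan regresses methylation on each in-window SNP dosage (simple linear
regression, two-sided p from t with n-2 df). Clumping then greedily keeps
the strongest association and discards everything correlated with a kept
SNP at dosage r² >= the clump threshold, so retained instruments are
mutually independent (r² < 0.01 by default) and strongly associated with
methylation (p < 1e-7 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from ._stats import simple_ols
from .data import CohortData

DEFAULT_CIS_WINDOW = 1_000_000
DEFAULT_CLUMP_R2 = 0.01
DEFAULT_INSTRUMENT_P = 1.0e-7

INSTRUMENT_COLUMNS = ["CPG", "SNP", "EA", "OA", "EAF", "BETA_EXP", "SE_EXP", "P_EXP"]


@dataclass
class MeqtlScan:
    """Per-SNP association of one CpG's methylation with cis dosages."""

    cpg_id: str
    df: pd.DataFrame  # SNP CHR POS EA OA EAF BETA SE T P DIST
    n_samples: int
    cis_window: int


@dataclass
class InstrumentSet:
    """Clumped cis-meQTL instruments for one CpG.

    May be empty — a CpG with no instrument is simply excluded downstream.
    """

    cpg_id: str
    instruments: pd.DataFrame  # INSTRUMENT_COLUMNS minus CPG
    clump_r2: float
    p_threshold: float

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def snp_ids(self) -> list:
        return list(self.instruments["SNP"])

    def to_tsv(self, path: str) -> None:
        out = self.instruments.copy()
        out.insert(0, "CPG", self.cpg_id)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(
        cls,
        path: str,
        clump_r2: float = DEFAULT_CLUMP_R2,
        p_threshold: float = DEFAULT_INSTRUMENT_P,
    ) -> "InstrumentSet":
        df = pd.read_csv(path, sep="\t")
        cpg = str(df["CPG"].iloc[0]) if len(df) else "NA"
        return cls(
            cpg_id=cpg,
            instruments=df.drop(columns=["CPG"]),
            clump_r2=clump_r2,
            p_threshold=p_threshold,
        )


def scan_cis_meqtl(
    cohort: CohortData, cpg_id: str, cis_window: Union[int, None] = DEFAULT_CIS_WINDOW
) -> MeqtlScan:
    """Associate one CpG with every SNP within ``cis_window`` bp.

    ``cis_window=None`` scans every SNP in the cohort regardless of
    position (the outcome scan of a reverse MR, whose trait instruments
    are genome-wide). Zero-variance dosages are skipped with a warning.
    Raises ValueError if no SNP lies within the window.
    """
    cpg = cohort.cpgs.loc[cohort.cpgs["CPG"] == cpg_id]
    if cpg.empty:
        raise KeyError(f"unknown CpG {cpg_id!r}")
    cpg = cpg.iloc[0]
    snps = cohort.snps
    same_chrom = snps["CHR"].astype(str).to_numpy() == str(cpg["CHR"])
    dist = np.where(
        same_chrom, np.abs(snps["POS"].to_numpy() - int(cpg["POS"])), -1
    )
    if cis_window is None:
        in_cis = np.ones(len(snps), dtype=bool)
    else:
        in_cis = same_chrom & (dist >= 0) & (dist <= cis_window)
    if not in_cis.any():
        raise ValueError(f"no SNP within {cis_window} bp of {cpg_id}")
    idx = np.flatnonzero(in_cis)
    G = cohort.dosages[idx]
    variance = G.var(axis=1)
    if (variance == 0).any():
        dropped = snps["SNP"].to_numpy()[idx[variance == 0]]
        warnings.warn(
            f"skipping zero-variance dosages in cis scan of {cpg_id}: "
            f"{', '.join(map(str, dropped))}",
            stacklevel=2,
        )
        idx = idx[variance > 0]
        G = cohort.dosages[idx]
    y = cohort.meth(cpg_id)
    beta, se, tstat, p = simple_ols(G, y)
    df = snps.iloc[idx].reset_index(drop=True).copy()
    df["BETA"] = beta
    df["SE"] = se
    df["T"] = tstat
    df["P"] = p
    df["DIST"] = dist[idx]
    return MeqtlScan(
        cpg_id=cpg_id, df=df, n_samples=cohort.n_samples, cis_window=cis_window
    )


def ld_clump(
    scan: MeqtlScan,
    genotypes: Union[CohortData, np.ndarray],
    clump_r2: float = DEFAULT_CLUMP_R2,
    p_threshold: float = DEFAULT_INSTRUMENT_P,
) -> InstrumentSet:
    """Greedy LD clumping of a cis scan.

    Eligible SNPs (p < ``p_threshold``) are visited in order of ascending p
    (ties broken by SNP id, making the result independent of input order);
    each kept SNP removes every remaining SNP whose dosage r² with it is
    >= ``clump_r2``. r² is the squared Pearson correlation of dosages in
    the same cohort the scan was run in.
    """
    if scan.df.empty:
        raise ValueError("cannot clump an empty scan")
    eligible = scan.df.loc[scan.df["P"] < p_threshold].copy()
    eligible = eligible.sort_values(["P", "SNP"], kind="mergesort").reset_index(
        drop=True
    )
    if eligible.empty:
        return InstrumentSet(
            cpg_id=scan.cpg_id,
            instruments=pd.DataFrame(columns=INSTRUMENT_COLUMNS[1:]),
            clump_r2=clump_r2,
            p_threshold=p_threshold,
        )
    if isinstance(genotypes, CohortData):
        G = np.vstack([genotypes.dosage(s) for s in eligible["SNP"]])
    else:
        G = np.asarray(genotypes, dtype=float)
        if G.shape[0] != len(eligible):
            raise ValueError(
                "genotype matrix rows must align with the eligible SNPs "
                "(pass a CohortData to avoid manual alignment)"
            )
    R = np.corrcoef(G) if len(eligible) > 1 else np.ones((1, 1))
    R2 = np.asarray(R) ** 2
    kept: list = []
    removed = np.zeros(len(eligible), dtype=bool)
    for i in range(len(eligible)):
        if removed[i]:
            continue
        kept.append(i)
        removed |= R2[i] >= clump_r2
    out = eligible.iloc[kept].reset_index(drop=True)
    instruments = pd.DataFrame(
        {
            "SNP": out["SNP"],
            "EA": out["EA"],
            "OA": out["OA"],
            "EAF": out["EAF"],
            "BETA_EXP": out["BETA"],
            "SE_EXP": out["SE"],
            "P_EXP": out["P"],
        }
    )
    return InstrumentSet(
        cpg_id=scan.cpg_id,
        instruments=instruments,
        clump_r2=clump_r2,
        p_threshold=p_threshold,
    )


def scan_to_summary(scan: MeqtlScan):
    """Express a cis scan as trait-style summary statistics (the outcome
    dataset of a reverse MR, where methylation is the outcome)."""
    from .data import SummaryStats

    df = scan.df[["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P"]].copy()
    df["N"] = scan.n_samples
    return SummaryStats(trait=f"meth_{scan.cpg_id}", df=df)
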