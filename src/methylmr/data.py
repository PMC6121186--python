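"""Core containers: individual-level cohort data, GWAS-style summary
statistics, and simulation ground truth.

All tabular IO is tab-separated text with fixed column sets so that a run is
byte-reproducible. Genomic positions are 1-based; cis distance between a SNP
and a CpG is ``abs(pos_snp - pos_cpg)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
SNP_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF"]
CPG_COLUMNS = ["CPG", "CHR", "POS", "CLASS"]

FLOAT_FORMAT = "%.10g"


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


@dataclass
class SummaryStats:
    """Per-SNP association records for one trait.

    ``df`` carries the columns SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N —
    the minimal set needed for harmonization and two-sample MR (reported
    beta, standard error and effect alleles).
    """

    trait: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMMARY_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        self.df = self.df.loc[:, SUMMARY_COLUMNS].reset_index(drop=True)
        if (self.df["SE"] <= 0).any():
            raise ValueError("summary statistics require SE > 0")

    def lookup(self, snp_id: str) -> Optional[pd.Series]:
        rows = self.df.loc[self.df["SNP"] == snp_id]
        if rows.empty:
            return None
        return rows.iloc[0]

    def to_tsv(self, path: str) -> None:
        _write_tsv(self.df, path)

    @classmethod
    def from_tsv(cls, path: str, trait: Optional[str] = None) -> "SummaryStats":
        name = trait or os.path.splitext(os.path.basename(path))[0]
        return cls(trait=name, df=pd.read_csv(path, sep="\t"))


@dataclass
class CohortData:
    """Individual-level genotype dosages and CpG methylation levels.

    ``dosages`` is (n_snps, n_samples) with entries in [0, 2];
    ``methylation`` is (n_cpgs, n_samples) on a continuous standardized
    scale (what rank-normalized array data looks like to the estimators).
    ``phenotype`` optionally carries an individual-level trait — the trait
    for which permutation-based colocalization needs raw data.
    """

    sample_ids: Sequence[str]
    snps: pd.DataFrame
    dosages: np.ndarray
    cpgs: pd.DataFrame
    methylation: np.ndarray
    phenotype: Optional[np.ndarray] = None
    _snp_index: dict = field(init=False, repr=False)
    _cpg_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.methylation = np.asarray(self.methylation, dtype=float)
        if self.dosages.shape != (len(self.snps), n):
            raise ValueError("dosage matrix shape does not match snps x samples")
        if self.methylation.shape != (len(self.cpgs), n):
            raise ValueError("methylation matrix shape does not match cpgs x samples")
        if np.isnan(self.dosages).any() or np.isnan(self.methylation).any():
            raise ValueError("cohort matrices must not contain missing values")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=float)
            if self.phenotype.shape != (n,):
                raise ValueError("phenotype length must equal sample count")
        self._snp_index = {s: i for i, s in enumerate(self.snps["SNP"])}
        self._cpg_index = {c: i for i, c in enumerate(self.cpgs["CPG"])}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.dosages[self._snp_index[snp_id]]

    def meth(self, cpg_id: str) -> np.ndarray:
        return self.methylation[self._cpg_index[cpg_id]]

    def snp_row(self, snp_id: str) -> pd.Series:
        return self.snps.iloc[self._snp_index[snp_id]]

    def r2(self, snp_a: str, snp_b: str) -> float:
        """Squared Pearson correlation between two dosage vectors."""
        r = np.corrcoef(self.dosage(snp_a), self.dosage(snp_b))[0, 1]
        return float(r * r)

    # ------------------------------------------------------------------ IO

    def write_dir(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        _write_tsv(self.snps, os.path.join(outdir, "snps.tsv"))
        _write_tsv(self.cpgs, os.path.join(outdir, "cpgs.tsv"))
        geno = pd.DataFrame(self.dosages, columns=list(self.sample_ids))
        geno.insert(0, "SNP", self.snps["SNP"].to_numpy())
        _write_tsv(geno, os.path.join(outdir, "genotypes.tsv"))
        meth = pd.DataFrame(self.methylation, columns=list(self.sample_ids))
        meth.insert(0, "CPG", self.cpgs["CPG"].to_numpy())
        _write_tsv(meth, os.path.join(outdir, "methylation.tsv"))
        if self.phenotype is not None:
            pheno = pd.DataFrame({"SAMPLE": list(self.sample_ids), "Y": self.phenotype})
            _write_tsv(pheno, os.path.join(outdir, "phenotype.tsv"))

    @classmethod
    def read_dir(cls, indir: str) -> "CohortData":
        snps = pd.read_csv(os.path.join(indir, "snps.tsv"), sep="\t")
        cpgs = pd.read_csv(os.path.join(indir, "cpgs.tsv"), sep="\t")
        geno = pd.read_csv(os.path.join(indir, "genotypes.tsv"), sep="\t")
        meth = pd.read_csv(os.path.join(indir, "methylation.tsv"), sep="\t")
        sample_ids = [c for c in geno.columns if c != "SNP"]
        pheno_path = os.path.join(indir, "phenotype.tsv")
        phenotype = None
        if os.path.exists(pheno_path):
            phenotype = pd.read_csv(pheno_path, sep="\t")["Y"].to_numpy()
        return cls(
            sample_ids=sample_ids,
            snps=snps,
            dosages=geno[sample_ids].to_numpy(dtype=float),
            cpgs=cpgs,
            methylation=meth[sample_ids].to_numpy(dtype=float),
            phenotype=phenotype,
        )

    def to_vcf(self, path: str) -> None:
        """Export genotypes as VCF with GT (best guess) and DS (dosage)."""
        import pysam

        header = pysam.VariantHeader()
        header.add_meta("source", "methylmr")
        for chrom in pd.unique(self.snps["CHR"].astype(str)):
            header.contigs.add(chrom, length=2_000_000_000)
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("DS", 1, "Float", "Dosage of the effect allele")
        for s in self.sample_ids:
            header.add_sample(str(s))
        with pysam.VariantFile(path, "w", header=header) as vcf:
            for i, row in self.snps.iterrows():
                rec = vcf.new_record(
                    contig=str(row["CHR"]),
                    start=int(row["POS"]) - 1,
                    stop=int(row["POS"]),
                    alleles=(str(row["OA"]), str(row["EA"])),
                    id=str(row["SNP"]),
                )
                for j, s in enumerate(self.sample_ids):
                    d = self.dosages[i, j]
                    g = int(round(d))
                    rec.samples[str(s)]["GT"] = [(0, 0), (0, 1), (1, 1)][g]
                    rec.samples[str(s)]["DS"] = float(d)
                vcf.write(rec)


@dataclass
class GroundTruth:
    """What the simulator actually planted in a region.

    Emitted alongside every simulated dataset for evaluation and never
    consumed by the estimation code.
    """

    scenario: str
    cpg_id: str
    meqtl_snp: str
    trait_snps: list
    effects: dict
    true_trait_beta: pd.Series
    achieved_linkage_r2: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "cpg_id": self.cpg_id,
            "meqtl_snp": self.meqtl_snp,
            "trait_snps": list(self.trait_snps),
            "effects": {k: float(v) for k, v in self.effects.items()},
            "achieved_linkage_r2": None
            if self.achieved_linkage_r2 is None
            else float(self.achieved_linkage_r2),
        }
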