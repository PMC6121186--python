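"""End-to-end orchestration: simulate → forward MR → colocalization →
reverse MR → replication → expression MR (→ enrichment), with a run
manifest tracking the test-count funnel at every stage.

Stage semantics mirror the discovery design: every instrumented CpG is
tested against every available trait; only forward-MR survivors enter
colocalization; the coloc shared-variant survivors are the unit for
reverse MR, replication (restricted to hits the alternative datasets
cover) and expression MR. All stage outputs are tab-separated files written
with fixed float formatting, so a run is byte-reproducible from its config
and seed. The ``threads`` setting is accepted for interface compatibility
and never changes results (the implementation is single-threaded numpy).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from .data import CohortData, GroundTruth, SummaryStats
from .enrichment import decorrelate_hits, enrich_test, enrichment_table
from .instruments import InstrumentSet, MeqtlScan, ld_clump, scan_cis_meqtl, scan_to_summary
from .mr import run_mr, results_table
from .multiplicity import ThresholdPlan, bonferroni_threshold
from .simulate import (
    SCENARIOS,
    ScenarioConfig,
    resimulate_outcome_stats,
    simulate_annotation_tracks,
    simulate_cpg_universe,
    simulate_expression_stats,
    simulate_region,
)

__version__ = "0.1.0"

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run; every discovery-design threshold
    is the out-of-box default (cis 1 Mb, clump r² 0.01, instrument p 1e-7,
    trait-instrument p 5e-8, alpha 0.05)."""

    seed: int = 0
    outdir: str = "methylmr_run"
    scenarios: Dict[str, int] = field(
        default_factory=lambda: {
            "mediation": 5,
            "linkage": 5,
            "reverse": 2,
            "pleiotropy": 3,
            "null": 5,
        }
    )
    scenario_params: Dict = field(default_factory=dict)
    extra_null_traits: int = 0
    cis_window: int = 1_000_000
    clump_r2: float = 0.01
    instrument_p: float = 1.0e-7
    trait_instrument_p: float = 5.0e-8
    alpha: float = 0.05
    exclusion_r2: float = 0.8
    perm_per_test: int = 20
    min_perm: int = 199
    max_perm: int = 20_000
    replication_n_gwas: int = 100_000
    expression_n_panel: int = 30_000
    run_forward: bool = True
    run_coloc: bool = True
    run_reverse: bool = True
    run_replication: bool = True
    run_expression: bool = True
    run_enrichment: bool = False
    enrichment_universe: int = 2_000
    enrichment_n_perm: int = 1_999
    enrichment_planted_fold: float = 4.0
    prune_bp: int = 1_000
    threads: int = 1

    def __post_init__(self) -> None:
        for name in (
            "cis_window",
            "clump_r2",
            "instrument_p",
            "trait_instrument_p",
            "alpha",
            "exclusion_r2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunManifest:
    """Per-stage test counts, survivor counts and thresholds."""

    seed: int
    version: str
    stages: List[dict] = field(default_factory=list)

    def add_stage(self, name: str, n_tests: int, n_survivors: int, threshold) -> None:
        if n_survivors > n_tests:
            raise ValueError("survivor count cannot exceed test count")
        self.stages.append(
            {
                "stage": name,
                "n_tests": int(n_tests),
                "n_survivors": int(n_survivors),
                "threshold": None if threshold is None else float(threshold),
            }
        )

    def stage(self, name: str) -> Optional[dict]:
        for s in self.stages:
            if s["stage"] == name:
                return s
        return None

    def validate_funnel(self) -> None:
        """Downstream stages consume only upstream survivors: coloc tests
        the forward survivors; reverse and expression MR test the coloc
        survivors; replication attempts at most the coloc survivors."""
        fwd, col = self.stage("forward_mr"), self.stage("coloc")
        if fwd and col and col["n_tests"] != fwd["n_survivors"]:
            raise ValueError("coloc must test exactly the forward-MR survivors")
        for name in ("reverse_mr", "expression_mr"):
            st = self.stage(name)
            if col and st and st["n_tests"] != col["n_survivors"]:
                raise ValueError(f"{name} must test exactly the coloc survivors")
        rep = self.stage("replication")
        if col and rep and rep["n_tests"] > col["n_survivors"]:
            raise ValueError("replication cannot attempt more than the coloc survivors")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"seed": self.seed, "version": self.version, "stages": self.stages},
                fh,
                indent=2,
            )
            fh.write("\n")


def forward_test_count(n_instrumented_cpgs: int, n_traits: int) -> int:
    """Total forward-MR tests: instrumented CpGs x traits."""
    return n_instrumented_cpgs * n_traits


@dataclass
class _Region:
    region_id: str
    config: ScenarioConfig
    cohort: CohortData
    traits: List[SummaryStats]
    truth: GroundTruth
    instruments: Optional[InstrumentSet] = None
    scan: Optional[MeqtlScan] = None


def _null_trait(stats: SummaryStats, truth: GroundTruth, n_gwas: int, seed: int, name: str):
    zero = GroundTruth(
        scenario="null",
        cpg_id=truth.cpg_id,
        meqtl_snp=truth.meqtl_snp,
        trait_snps=[],
        effects={},
        true_trait_beta=pd.Series(0.0, index=stats.df["SNP"].to_numpy()),
    )
    return resimulate_outcome_stats(zero, stats, n_gwas, seed, trait=name)


def _write(df: pd.DataFrame, outdir: str, name: str) -> None:
    df.to_csv(
        os.path.join(outdir, name), sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order and write all outputs to
    ``config.outdir``. Deterministic given config + seed."""
    os.makedirs(config.outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest = RunManifest(seed=config.seed, version=__version__)

    # ---------------------------------------------------------- simulate
    regions: List[_Region] = []
    idx = 0
    for scenario in SCENARIOS:
        for _ in range(int(config.scenarios.get(scenario, 0))):
            rid = f"r{idx:03d}"
            cfg = ScenarioConfig(
                scenario=scenario,
                seed=int(rng.integers(2**31)),
                region_id=rid,
                **config.scenario_params,
            )
            cohort, stats, truth = simulate_region(cfg)
            traits = [stats]
            for t in range(config.extra_null_traits):
                traits.append(
                    _null_trait(
                        stats,
                        truth,
                        cfg.n_gwas,
                        int(rng.integers(2**31)),
                        f"nulltrait{t}_{rid}",
                    )
                )
            regions.append(_Region(rid, cfg, cohort, traits, truth))
            idx += 1
    truth_rows = [
        dict(REGION=r.region_id, **r.truth.to_dict()) for r in regions
    ]
    for row in truth_rows:
        row["trait_snps"] = ",".join(row["trait_snps"])
        row["effects"] = json.dumps(row["effects"], sort_keys=True)
    _write(pd.DataFrame(truth_rows), config.outdir, "truth.tsv")

    # -------------------------------------------------------- forward MR
    mr_rows: List[dict] = []
    key_region: Dict[tuple, _Region] = {}
    n_tests = 0
    if config.run_forward:
        for reg in regions:
            scan = scan_cis_meqtl(reg.cohort, reg.truth.cpg_id, config.cis_window)
            inst = ld_clump(
                scan, reg.cohort, config.clump_r2, config.instrument_p
            )
            reg.scan, reg.instruments = scan, inst
            if len(inst) == 0:
                continue
            _assert_instrument_validity(inst, reg.cohort, config)
            n_tests += len(reg.traits)
            for stats in reg.traits:
                result, _ = run_mr(
                    inst, stats, direction="forward", genotypes=reg.cohort
                )
                if result is None:
                    continue
                row = result.to_row()
                row["REGION"] = reg.region_id
                mr_rows.append(row)
                key_region[(result.exposure, result.outcome)] = reg
    mr_df = pd.DataFrame(
        mr_rows,
        columns=["EXPOSURE", "OUTCOME", "DIRECTION", "METHOD", "NSNP", "BETA", "SE", "P", "REGION"],
    )
    plan_forward = (
        ThresholdPlan("forward_mr", max(n_tests, 1), alpha=config.alpha)
        if n_tests
        else None
    )
    threshold = plan_forward.threshold if plan_forward else None
    survivors = (
        mr_df.loc[mr_df["P"] < threshold] if threshold is not None else mr_df.iloc[:0]
    )
    manifest.add_stage("forward_mr", n_tests, len(survivors), threshold)
    _write(mr_df, config.outdir, "mr_results.tsv")

    # ------------------------------------------------------------- coloc
    hit_keys = [
        (row["EXPOSURE"], row["OUTCOME"]) for _, row in survivors.iterrows()
    ]
    coloc_results: Dict[tuple, coloc_mod.ColocResult] = {}
    classes: Dict[str, list] = {"shared": [], "linkage": [], "untestable": []}
    if config.run_coloc and hit_keys:
        n_perm = int(
            min(
                max(config.min_perm, config.perm_per_test * len(hit_keys)),
                config.max_perm,
            )
        )
        for key in hit_keys:
            reg = key_region[key]
            stats = next(s for s in reg.traits if s.trait == key[1])
            coloc_results[key] = coloc_mod.coloc_permutation_test(
                reg.cohort,
                key[0],
                stats,
                n_perm=n_perm,
                seed=int(rng.integers(2**31)),
                exclusion_r2=config.exclusion_r2,
                cis_window=config.cis_window,
            )
        classes = coloc_mod.classify_associations(hit_keys, coloc_results)
    coloc_alpha = bonferroni_threshold(len(hit_keys)) if hit_keys else None
    class_of = {k: c for c, keys in classes.items() for k in keys}
    coloc_df = coloc_mod.coloc_table(
        [(coloc_results[k], class_of[k]) for k in hit_keys]
        if coloc_results
        else []
    )
    manifest.add_stage("coloc", len(hit_keys), len(classes["shared"]), coloc_alpha)
    _write(coloc_df, config.outdir, "coloc_results.tsv")

    shared_keys = classes["shared"]

    # -------------------------------------------------------- reverse MR
    rev_rows: List[dict] = []
    n_rev_sig = 0
    if config.run_reverse and shared_keys:
        rev_alpha = bonferroni_threshold(len(shared_keys))
        for key in shared_keys:
            reg = key_region[key]
            stats = next(s for s in reg.traits if s.trait == key[1])
            inst = _clump_trait_instruments(
                stats, reg.cohort, config.clump_r2, config.trait_instrument_p
            )
            if len(inst) == 0:
                continue
            genome_scan = scan_cis_meqtl(reg.cohort, key[0], cis_window=None)
            outcome = scan_to_summary(genome_scan)
            result, _ = run_mr(
                inst, outcome, direction="reverse", genotypes=reg.cohort
            )
            if result is None:
                continue
            row = result.to_row()
            row["REGION"] = reg.region_id
            row["SINGLE_INSTRUMENT"] = result.n_instruments == 1
            rev_rows.append(row)
            if result.p < rev_alpha:
                n_rev_sig += 1
        manifest.add_stage("reverse_mr", len(shared_keys), n_rev_sig, rev_alpha)
    else:
        manifest.add_stage("reverse_mr", len(shared_keys), 0, None)
    _write(pd.DataFrame(rev_rows), config.outdir, "reverse_results.tsv")

    # ------------------------------------------------------- replication
    rep_df = pd.DataFrame()
    if config.run_replication and shared_keys:
        alt_exposure: Dict[str, InstrumentSet] = {}
        alt_outcome: Dict[str, SummaryStats] = {}
        discovery_rows = []
        for key in shared_keys:
            reg = key_region[key]
            alt_cfg = ScenarioConfig(
                **{
                    **{
                        f: getattr(reg.config, f)
                        for f in (
                            "scenario",
                            "n_cohort",
                            "n_gwas",
                            "region_snps",
                            "ld_decay",
                            "maf_range",
                            "beta_gm",
                            "beta_my",
                            "beta_gy",
                            "beta_yg_m",
                            "linkage_r2",
                            "n_trait_snps",
                        )
                    },
                    "seed": int(rng.integers(2**31)),
                    "region_id": reg.region_id,
                }
            )
            alt_cohort, _, _ = simulate_region(alt_cfg)
            alt_scan = scan_cis_meqtl(
                alt_cohort, reg.truth.cpg_id, config.cis_window
            )
            alt_inst = ld_clump(
                alt_scan, alt_cohort, config.clump_r2, config.instrument_p
            )
            alt_exposure[key[0]] = alt_inst
            stats = next(s for s in reg.traits if s.trait == key[1])
            alt_outcome[key[1]] = resimulate_outcome_stats(
                reg.truth,
                stats,
                config.replication_n_gwas,
                int(rng.integers(2**31)),
            )
            disc = survivors.loc[
                (survivors["EXPOSURE"] == key[0]) & (survivors["OUTCOME"] == key[1])
            ].iloc[0]
            discovery_rows.append(disc)
        rep_df = replicate_mr(
            pd.DataFrame(discovery_rows), alt_exposure, alt_outcome, config.alpha
        )
        manifest.add_stage(
            "replication",
            int((rep_df["ATTEMPTED"]).sum()) if len(rep_df) else 0,
            int(rep_df["REPLICATED"].sum()) if len(rep_df) else 0,
            bonferroni_threshold(max(int(rep_df["ATTEMPTED"].sum()), 1))
            if len(rep_df)
            else None,
        )
    else:
        manifest.add_stage("replication", 0, 0, None)
    _write(rep_df, config.outdir, "replication.tsv")

    # ----------------------------------------------------- expression MR
    expr_rows: List[dict] = []
    n_expr_sig = 0
    if config.run_expression and shared_keys:
        expr_alpha = bonferroni_threshold(len(shared_keys))
        for key in shared_keys:
            reg = key_region[key]
            expr_stats = simulate_expression_stats(
                reg.cohort,
                reg.truth,
                n_panel=config.expression_n_panel,
                seed=int(rng.integers(2**31)),
            )
            result, _ = run_mr(
                reg.instruments, expr_stats, direction="forward", genotypes=reg.cohort
            )
            if result is None:
                continue
            row = result.to_row()
            row["REGION"] = reg.region_id
            expr_rows.append(row)
            if result.p < expr_alpha:
                n_expr_sig += 1
        manifest.add_stage("expression_mr", len(shared_keys), n_expr_sig, expr_alpha)
    else:
        manifest.add_stage("expression_mr", len(shared_keys), 0, None)
    _write(pd.DataFrame(expr_rows), config.outdir, "expression_results.tsv")

    # -------------------------------------------------------- enrichment
    if config.run_enrichment:
        universe = simulate_cpg_universe(
            config.enrichment_universe, seed=int(rng.integers(2**31))
        )
        region_cpgs = pd.concat([r.cohort.cpgs for r in regions], ignore_index=True)
        universe = pd.concat([universe, region_cpgs], ignore_index=True)
        hit_ids = sorted({k[0] for k in shared_keys})
        hits = universe.loc[universe["CPG"].isin(hit_ids)]
        hits = decorrelate_hits(hits, config.prune_bp)
        results = []
        for fold, name in (
            (config.enrichment_planted_fold, "planted_track"),
            (1.0, "null_track"),
        ):
            track, _ = simulate_annotation_tracks(
                universe,
                planted_fold=fold,
                hits=list(hits["CPG"]),
                seed=int(rng.integers(2**31)),
                track_name=name,
            )
            results.append(
                enrich_test(
                    hits,
                    track,
                    universe,
                    n_perm=config.enrichment_n_perm,
                    seed=int(rng.integers(2**31)),
                    track_name=name,
                )
            )
        _write(enrichment_table(results), config.outdir, "enrichment_results.tsv")

    # --------------------------------------------------------- manhattan
    manhattan = _manhattan_table(mr_df, regions, class_of)
    _write(manhattan, config.outdir, "manhattan.tsv")

    manifest.validate_funnel()
    manifest.to_json(os.path.join(config.outdir, "manifest.json"))
    config.to_yaml(os.path.join(config.outdir, "config.yaml"))
    return manifest


def _assert_instrument_validity(
    inst: InstrumentSet, cohort: CohortData, config: RunConfig
) -> None:
    # Colocalization validity conditions: instruments independent and
    # strongly associated with methylation.
    assert (inst.instruments["P_EXP"] < config.instrument_p).all()
    snps = inst.snp_ids
    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            assert cohort.r2(snps[i], snps[j]) < config.clump_r2


def _clump_trait_instruments(
    stats: SummaryStats, cohort: CohortData, clump_r2: float, p_threshold: float
) -> InstrumentSet:
    """Genome-wide-significant, clumped instruments for a complex trait."""
    df = stats.df.copy()
    scan = MeqtlScan(
        cpg_id=stats.trait, df=df, n_samples=0, cis_window=0
    )
    return ld_clump(scan, cohort, clump_r2, p_threshold)


def replicate_mr(
    discovery_hits: pd.DataFrame,
    alt_exposure: Dict[str, InstrumentSet],
    alt_outcome: Dict[str, SummaryStats],
    alpha: float = 0.05,
    genotypes: Optional[CohortData] = None,
) -> pd.DataFrame:
    """Re-test discovery hits against alternative exposure and outcome
    datasets. A hit replicates iff its p-value beats 0.05 / (number
    attempted) and the effect direction agrees with discovery; hits the
    alternative data do not cover are reported but excluded from the
    multiplicity denominator."""
    rows = []
    for _, disc in discovery_hits.iterrows():
        cpg, trait = disc["EXPOSURE"], disc["OUTCOME"]
        inst = alt_exposure.get(cpg)
        stats = alt_outcome.get(trait)
        attempted = inst is not None and stats is not None and len(inst) > 0
        result = None
        if attempted:
            result, _ = run_mr(inst, stats, direction="forward", genotypes=genotypes)
            attempted = result is not None
        rows.append(
            {
                "EXPOSURE": cpg,
                "OUTCOME": trait,
                "DISCOVERY_BETA": disc["BETA"],
                "BETA": result.beta if result else np.nan,
                "SE": result.se if result else np.nan,
                "P": result.p if result else np.nan,
                "NSNP": result.n_instruments if result else 0,
                "ATTEMPTED": attempted,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["REPLICATED"] = []
        return out
    n_attempted = int(out["ATTEMPTED"].sum())
    thr = bonferroni_threshold(max(n_attempted, 1), alpha)
    out["THRESHOLD"] = thr
    out["REPLICATED"] = (
        out["ATTEMPTED"]
        & (out["P"] < thr)
        & (np.sign(out["BETA"]) == np.sign(out["DISCOVERY_BETA"]))
    )
    return out


def _manhattan_table(mr_df, regions, class_of) -> pd.DataFrame:
    pos = {}
    for reg in regions:
        row = reg.cohort.cpgs.iloc[0]
        pos[row["CPG"]] = (row["CHR"], row["POS"])
    rows = []
    for _, r in mr_df.iterrows():
        chrom, p = pos.get(r["EXPOSURE"], ("", np.nan))
        rows.append(
            {
                "TRAIT": r["OUTCOME"],
                "CPG": r["EXPOSURE"],
                "CHR": chrom,
                "POS": p,
                "NEGLOG10P": -np.log10(r["P"]),
                "COLOC_CLASS": class_of.get((r["EXPOSURE"], r["OUTCOME"]), ""),
            }
        )
    return pd.DataFrame(
        rows, columns=["TRAIT", "CPG", "CHR", "POS", "NEGLOG10P", "COLOC_CLASS"]
    )


def plot_manhattan(manhattan: pd.DataFrame, path: str) -> None:
    """Optional Manhattan-style rendering (shared-variant hits in red)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    shared = manhattan["COLOC_CLASS"] == "shared"
    ax.scatter(manhattan.loc[~shared, "POS"], manhattan.loc[~shared, "NEGLOG10P"], s=8, c="grey")
    ax.scatter(manhattan.loc[shared, "POS"], manhattan.loc[shared, "NEGLOG10P"], s=10, c="red")
    ax.set_xlabel("position")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
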