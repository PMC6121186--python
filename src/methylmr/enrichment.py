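"""Annotation enrichment of hit CpG sets against a matched background.

Hit CpGs (e.g. the CpGs behind shared-variant associations) are tested for
overlap with BED-like annotation tracks (histone mark peaks, DNase sites,
regulatory classes). Because CpG probes are not uniformly distributed over
genomic contexts, the null is calibrated against backgrounds *matched on
annotation class* (island/shore/body): the hypergeometric test uses a
class-matched universe, and the permutation p repeatedly redraws matched
backgrounds of the hit-set size.

Coordinates: CpGs are 1-based points, tracks are 0-based half-open
intervals; a CpG at position p overlaps [start, end) iff start <= p-1 < end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_PERM = 10_000
DEFAULT_PRUNE_BP = 1_000


class ClassShortageError(ValueError):
    """A matching class has too few universe CpGs to draw a background."""


def overlaps_track(cpgs: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Boolean overlap of each CpG (1-based point) with merged intervals."""
    out = np.zeros(len(cpgs), dtype=bool)
    if track.empty or cpgs.empty:
        return out
    pos0 = cpgs["POS"].to_numpy() - 1
    chroms = cpgs["CHR"].astype(str).to_numpy()
    for chrom, sub in track.groupby(track["chrom"].astype(str)):
        mask = chroms == chrom
        if not mask.any():
            continue
        iv = sub.sort_values("start")
        starts, ends = [], []
        for s, e in zip(iv["start"], iv["end"]):
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        p = pos0[mask]
        j = np.searchsorted(starts, p, side="right") - 1
        ok = (j >= 0) & (p < ends[np.clip(j, 0, len(ends) - 1)])
        out[mask] = ok
    return out


def matched_background(
    hits: pd.DataFrame,
    universe: pd.DataFrame,
    size: int,
    seed: int = 0,
    class_col: str = "CLASS",
) -> pd.DataFrame:
    """Sample ``size`` universe CpGs whose class composition matches the
    hit set's (largest-remainder allocation), excluding the hits
    themselves. Raises :class:`ClassShortageError` naming the first class
    with too few candidates."""
    if hits.empty:
        raise ValueError("empty hit set")
    rng = np.random.default_rng(seed)
    hit_ids = set(hits["CPG"])
    pool = universe.loc[~universe["CPG"].isin(hit_ids)]
    comp = hits[class_col].value_counts(normalize=True)
    exact = comp * size
    alloc = exact.astype(int)
    remainder = (exact - alloc).sort_values(ascending=False, kind="mergesort")
    short = size - int(alloc.sum())
    for cls in remainder.index[:short]:
        alloc[cls] += 1
    parts = []
    for cls in sorted(alloc.index):
        k = int(alloc[cls])
        if k == 0:
            continue
        cand = pool.loc[pool[class_col] == cls]
        if len(cand) < k:
            raise ClassShortageError(
                f"class {cls!r}: need {k} background CpGs, only {len(cand)} available"
            )
        take = rng.choice(len(cand), size=k, replace=False)
        parts.append(cand.iloc[np.sort(take)])
    return pd.concat(parts, ignore_index=True)


@dataclass
class EnrichmentResult:
    track: str
    n_hits: int
    k_overlap: int
    background_rate: float
    expected: float
    fold: float
    p_hypergeometric: float
    p_permutation: float
    n_perm: int
    testable: bool = True


def hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) drawing n from a population of N with K successes."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_test(
    hits: pd.DataFrame,
    track: pd.DataFrame,
    universe: pd.DataFrame,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    background_size: Optional[int] = None,
    class_col: str = "CLASS",
    track_name: Optional[str] = None,
) -> EnrichmentResult:
    """Hypergeometric + permutation enrichment of a hit CpG set in a track.

    The hypergeometric population is the matched universe (the hits plus a
    class-matched background, ``background_size`` defaulting to 10x the
    hit count); successes are its CpGs overlapping the track. Each
    permutation redraws a matched background of the hit-set size and
    counts its overlaps — per matching class that count is exactly
    hypergeometric, so it is drawn directly from that distribution.
    """
    name = track_name or (str(track["name"].iloc[0]) if len(track) else "track")
    if hits.empty or track.empty:
        return EnrichmentResult(
            track=name,
            n_hits=len(hits),
            k_overlap=0,
            background_rate=np.nan,
            expected=np.nan,
            fold=np.nan,
            p_hypergeometric=1.0,
            p_permutation=1.0,
            n_perm=n_perm,
            testable=False,
        )
    rng = np.random.default_rng(seed)
    n = len(hits)
    bg_size = background_size if background_size is not None else 10 * n
    bg = matched_background(
        hits, universe, bg_size, seed=int(rng.integers(2**31)), class_col=class_col
    )
    k = int(overlaps_track(hits, track).sum())
    bg_overlap = overlaps_track(bg, track)
    K_bg = int(bg_overlap.sum())
    N = n + len(bg)
    K = k + K_bg
    p_hyper = max(hypergeometric_enrichment(N, K, n, k), 5e-324)
    bg_rate = K_bg / len(bg)
    expected = n * bg_rate
    fold = k / expected if expected > 0 else np.nan

    # Permutation: freshly drawn matched backgrounds of size n. Within each
    # class the overlap count of a without-replacement draw is exactly
    # hypergeometric over that class's pool, so draw it directly.
    hit_ids = set(hits["CPG"])
    pool = universe.loc[~universe["CPG"].isin(hit_ids)]
    pool_overlap = overlaps_track(pool, track)
    comp = hits[class_col].value_counts()
    alloc = _largest_remainder(comp, n)
    k_perm = np.zeros(n_perm, dtype=int)
    for cls, need in alloc.items():
        if need == 0:
            continue
        cls_mask = (pool[class_col] == cls).to_numpy()
        m_cls = int(cls_mask.sum())
        good = int(pool_overlap[cls_mask].sum())
        if m_cls < need:
            raise ClassShortageError(
                f"class {cls!r}: need {need} background CpGs, only {m_cls} available"
            )
        k_perm += rng.hypergeometric(good, m_cls - good, need, size=n_perm)
    p_perm = (1.0 + np.sum(k_perm >= k)) / (n_perm + 1.0)
    return EnrichmentResult(
        track=name,
        n_hits=n,
        k_overlap=k,
        background_rate=bg_rate,
        expected=expected,
        fold=fold,
        p_hypergeometric=p_hyper,
        p_permutation=float(p_perm),
        n_perm=n_perm,
    )


def _largest_remainder(counts: pd.Series, total: int) -> Dict:
    frac = counts / counts.sum() * total
    alloc = frac.astype(int)
    rem = (frac - alloc).sort_values(ascending=False, kind="mergesort")
    short = total - int(alloc.sum())
    for cls in rem.index[:short]:
        alloc[cls] += 1
    return alloc.to_dict()


def decorrelate_hits(
    hits: pd.DataFrame, distance_bp: int = DEFAULT_PRUNE_BP
) -> pd.DataFrame:
    """Greedy pruning of proximal (possibly co-methylated) probes: sorted
    by position within chromosome, keep a hit only if it lies at least
    ``distance_bp`` from the last kept hit."""
    if hits.empty:
        return hits
    out_idx = []
    srt = hits.sort_values(["CHR", "POS"], kind="mergesort")
    last_chrom, last_pos = None, None
    for idx, row in srt.iterrows():
        if row["CHR"] != last_chrom or row["POS"] - last_pos >= distance_bp:
            out_idx.append(idx)
            last_chrom, last_pos = row["CHR"], row["POS"]
    return hits.loc[out_idx].sort_values(["CHR", "POS"], kind="mergesort").reset_index(
        drop=True
    )


def enrichment_table(results) -> pd.DataFrame:
    """Long-format enrichment output (one row per track), heat-map ready."""
    rows = []
    for r in results:
        rows.append(
            {
                "TRACK": r.track,
                "N_HITS": r.n_hits,
                "K_OVERLAP": r.k_overlap,
                "BG_RATE": r.background_rate,
                "FOLD": r.fold,
                "P_HYPER": r.p_hypergeometric,
                "P_PERM": r.p_permutation,
                "N_PERM": r.n_perm,
                "TESTABLE": r.testable,
            }
        )
    return pd.DataFrame(rows)
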