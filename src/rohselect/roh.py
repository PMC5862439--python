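"""Run-of-homozygosity detection and genome-wide autozygosity statistics.

The caller is a transparent, deterministic run-based detector: maximal runs
of consecutive homozygous genotype calls, with explicit allowances for
heterozygous and missing calls inside a run and a hard break wherever the
physical gap between consecutive SNPs exceeds ``max_gap``. Segment
coordinates are 1-based inclusive and span the first to the last homozygous
SNP of the run; length is ``end - start + 1``.

F_roh is the summed length of qualifying segments divided by the total
autosome length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, ChromSizes, GenotypeMatrix

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "n_snps", "length"]


@dataclass(frozen=True)
class ROHCallParams:
    min_snps: int = 20
    max_het_in_run: int = 0
    max_missing_in_run: int = 2
    max_gap: int = 500_000
    min_length: int = 0

    def __post_init__(self) -> None:
        for name in ("min_snps", "max_het_in_run", "max_missing_in_run", "max_gap", "min_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _empty_segments() -> pd.DataFrame:
    return pd.DataFrame(columns=SEGMENT_COLUMNS).astype(
        {"start": int, "end": int, "n_snps": int, "length": int, "chrom": str, "sample_id": str}
    )


def _runs_one_track(pos: np.ndarray, dos: np.ndarray, params: ROHCallParams):
    """Maximal qualifying runs on one (position, dosage) track.

    Returns (start, end, n_hom) tuples. Within each max-gap block, a
    two-pointer scan finds maximal index windows containing at most
    ``max_het_in_run`` heterozygous and ``max_missing_in_run`` missing
    calls; windows are trimmed to homozygous endpoints and overlapping
    trimmed segments are merged (only possible when allowances > 0).
    """
    is_het = dos == 1
    is_miss = dos == MISSING
    is_hom = ~is_het & ~is_miss
    blocks = []
    start = 0
    for k in range(1, len(pos)):
        if pos[k] - pos[k - 1] > params.max_gap:
            blocks.append((start, k))
            start = k
    blocks.append((start, len(pos)))

    raw = []
    for lo, hi in blocks:
        i = lo
        j = lo
        het = miss = 0
        best_j = -1
        while i < hi:
            while j < hi:
                d_het = 1 if is_het[j] else 0
                d_miss = 1 if is_miss[j] else 0
                if het + d_het > params.max_het_in_run or miss + d_miss > params.max_missing_in_run:
                    break
                het += d_het
                miss += d_miss
                j += 1
            if j > i and j > best_j:  # maximal window [i, j)
                raw.append((i, j))
                best_j = j
            if j == i:
                j += 1
                i = j
                het = miss = 0
            else:
                if is_het[i]:
                    het -= 1
                if is_miss[i]:
                    miss -= 1
                i += 1

    segs = []
    for a, b in raw:
        hom_idx = np.flatnonzero(is_hom[a:b]) + a
        if len(hom_idx) < max(params.min_snps, 1):
            continue
        segs.append((int(pos[hom_idx[0]]), int(pos[hom_idx[-1]]), int(len(hom_idx))))
    segs.sort()
    merged = []
    for s, e, n in segs:
        if merged and s <= merged[-1][1]:
            ms, me, mn = merged[-1]
            merged[-1] = (ms, max(me, e), max(mn, n))
        else:
            merged.append((s, e, n))
    return merged


def call_roh(genotypes: GenotypeMatrix, params: ROHCallParams = ROHCallParams()) -> pd.DataFrame:
    """Detect ROH per sample; returns a segments DataFrame.

    Columns: sample_id, chrom, start, end, n_snps (homozygous SNPs
    spanned), length. Runs with fewer than ``min_snps`` homozygous SNPs are
    discarded; ``min_length`` additionally drops short segments at call
    time (0 = keep all).
    """
    rows = []
    chroms = genotypes.variants["chrom"].to_numpy()
    pos_all = genotypes.variants["pos"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = pos_all[idx]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"unsorted variant positions on chromosome {chrom}")
        for s_i, sample in enumerate(genotypes.sample_ids):
            dos = genotypes.dosage[s_i, idx]
            for start, end, n_hom in _runs_one_track(pos, dos, params):
                length = end - start + 1
                if length >= params.min_length:
                    rows.append((sample, chrom, start, end, n_hom, length))
    if not rows:
        return _empty_segments()
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def filter_autozygous(segments: pd.DataFrame, min_length: int = 500_000) -> pd.DataFrame:
    """Keep segments of length >= min_length (shorter ones are discarded)."""
    if segments.empty:
        return segments
    return segments[segments["length"] >= min_length].reset_index(drop=True)


def threshold_profile(
    segments: pd.DataFrame,
    sample_ids: list[str],
    thresholds: list[int] | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per length threshold: mean segment count and total length per sample,
    and carrier frequency (fraction of samples with >= 1 qualifying segment).

    Default grid: 0-2000 kb in 100 kb steps.
    """
    if thresholds is None:
        thresholds = np.arange(0, 2_000_001, 100_000)
    thresholds = np.asarray(thresholds)
    if thresholds.size == 0:
        raise ValueError("threshold list is empty")
    n = len(sample_ids)
    rows = []
    lengths = segments["length"].to_numpy() if not segments.empty else np.array([], int)
    samples = segments["sample_id"].to_numpy() if not segments.empty else np.array([], str)
    for t in thresholds:
        keep = lengths >= t
        counts = pd.Series(samples[keep]).value_counts()
        total = pd.Series(lengths[keep]).groupby(samples[keep]).sum() if keep.any() else pd.Series(dtype=float)
        rows.append(
            (
                int(t),
                counts.reindex(sample_ids, fill_value=0).mean() if n else 0.0,
                total.reindex(sample_ids, fill_value=0).mean() if n else 0.0,
                (counts.reindex(sample_ids, fill_value=0) > 0).mean() if n else 0.0,
            )
        )
    return pd.DataFrame(rows, columns=["threshold", "mean_count", "mean_total_bp", "carrier_freq"])


def _merge_lengths(group: pd.DataFrame) -> int:
    total = 0
    for _, chrom_df in group.groupby("chrom"):
        last_end = 0
        for s, e in sorted(zip(chrom_df["start"], chrom_df["end"])):
            s = max(s, last_end + 1)
            if e >= s:
                total += e - s + 1
                last_end = max(last_end, e)
    return total


def compute_froh(
    segments: pd.DataFrame, chrom_sizes: ChromSizes, sample_ids: list[str]
) -> pd.DataFrame:
    """Per-sample F_roh = merged segment bp / total autosome length."""
    if not segments.empty:
        unknown = set(segments["chrom"]) - set(chrom_sizes)
        if unknown:
            raise ValueError(f"segments on chromosomes absent from sizes table: {sorted(unknown)}")
    total_len = chrom_sizes.total_length
    rows = []
    by_sample = dict(tuple(segments.groupby("sample_id"))) if not segments.empty else {}
    for sample in sample_ids:
        grp = by_sample.get(sample)
        if grp is None:
            rows.append((sample, 0, 0, 0.0))
        else:
            bp = _merge_lengths(grp)
            rows.append((sample, len(grp), bp, bp / total_len))
    return pd.DataFrame(rows, columns=["sample_id", "n_segments", "total_roh_bp", "f_roh"])


def froh_group_comparison(selected: pd.DataFrame, unselected: pd.DataFrame) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of group F_roh values."""
    a = np.asarray(selected["f_roh"] if "f_roh" in selected else selected, float)
    b = np.asarray(unselected["f_roh"] if "f_roh" in unselected else unselected, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return {
        "mean_selected": float(np.mean(a)),
        "mean_unselected": float(np.mean(b)),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
    }


def froh_resampling(
    selected: pd.DataFrame,
    unselected: pd.DataFrame,
    k: int = 10,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeatedly subsample k selected animals; record subgroup mean F_roh
    and the rank-sum p-value against the unselected group."""
    a = np.asarray(selected["f_roh"] if "f_roh" in selected else selected, float)
    b = np.asarray(unselected["f_roh"] if "f_roh" in unselected else unselected, float)
    if k > len(a):
        raise ValueError(f"k={k} exceeds selected group size {len(a)}")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(reps):
        sub = rng.choice(a, size=k, replace=False)
        res = stats.mannwhitneyu(sub, b, alternative="two-sided", method="auto")
        rows.append((r, float(np.mean(sub)), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["rep", "mean_froh", "p_value"])
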