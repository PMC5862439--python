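"""Shared-ROH (complete overlap) regions and regional inbreeding curves.

A "complete overlap" region is the maximal interval attaining the maximum
distinct-sample coverage depth: each sample counts once per position
regardless of how many of its segments cover it. Regional curves
characterize a candidate interval per sample group by windowed mean
pairwise LD (r^2) and a window inbreeding coefficient
F = 1 - observed het / expected het averaged over window SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix
from .popgen import pairwise_r2


def _merge_per_sample(segments: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (sample, chrom), grp in segments.groupby(["sample_id", "chrom"]):
        last = None
        for s, e in sorted(zip(grp["start"], grp["end"])):
            if last is not None and s <= last[1] + 1:
                last = (last[0], max(last[1], e))
                rows[-1] = (sample, chrom, *last)
            else:
                last = (s, e)
                rows.append((sample, chrom, s, e))
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end"])


def max_overlap_region(
    segments: pd.DataFrame, query: tuple[str, int, int] | None = None
) -> pd.DataFrame:
    """Maximal interval(s) of maximal distinct-sample segment coverage.

    ``query`` optionally restricts to (chrom, start, end); segments are
    clipped to it. Ties in depth return every maximal interval. Coverage
    uses an endpoint sweep over per-sample merged segments.
    """
    seg = segments
    if query is not None:
        chrom, qs, qe = query
        seg = seg[(seg["chrom"] == chrom) & (seg["end"] >= qs) & (seg["start"] <= qe)].copy()
        seg["start"] = seg["start"].clip(lower=qs)
        seg["end"] = seg["end"].clip(upper=qe)
    if seg.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "depth", "samples"])
    merged = _merge_per_sample(seg)
    out = []
    for chrom, grp in merged.groupby("chrom"):
        events: dict[int, int] = {}
        for s, e in zip(grp["start"], grp["end"]):
            events[s] = events.get(s, 0) + 1
            events[e + 1] = events.get(e + 1, 0) - 1
        pos = sorted(events)
        depth = 0
        best = 0
        intervals: list[tuple[int, int, int]] = []
        for i, x in enumerate(pos):
            depth += events[x]
            if i + 1 < len(pos):
                intervals.append((x, pos[i + 1] - 1, depth))
        best = max(d for _, _, d in intervals)
        run: list[tuple[int, int]] = []
        for s, e, d in intervals:
            if d == best:
                if run and s == run[-1][1] + 1:
                    run[-1] = (run[-1][0], e)
                else:
                    run.append((s, e))
        for s, e in run:
            covering = merged[(merged["chrom"] == chrom)
                              & (merged["start"] <= s) & (merged["end"] >= e)]
            out.append((chrom, s, e, best, sorted(covering["sample_id"].unique())))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "depth", "samples"])


def region_group_curves(
    genotypes: GenotypeMatrix,
    region: tuple[str, int, int],
    groups: dict[str, list[str]],
    window: int = 50_000,
) -> pd.DataFrame:
    """Windowed mean r^2 and inbreeding coefficient per sample group.

    Windows of ``window`` bp tile the region; per group and window,
    mean pairwise r^2 among window SNPs and
    F = 1 - mean(observed het) / mean(expected het) with group allele
    frequencies and the n/(n-1) correction. Windows without a polymorphic
    SNP in a group yield NaN entries.
    """
    chrom, rs, re_ = region
    sel = ((genotypes.variants["chrom"] == chrom)
           & (genotypes.variants["pos"] >= rs)
           & (genotypes.variants["pos"] <= re_)).to_numpy()
    idx = np.flatnonzero(sel)
    pos = genotypes.variants["pos"].to_numpy()[idx]
    rows = []
    for name, members in groups.items():
        if not members:
            raise ValueError(f"group {name!r} is empty")
        rows_idx = [genotypes.sample_ids.index(s) for s in members]
        dos = genotypes.dosage[rows_idx]
        start = rs
        while start <= re_:
            end = min(start + window - 1, re_)
            in_win = (pos >= start) & (pos <= end)
            snps = idx[in_win]
            mean_r2 = np.nan
            f_coef = np.nan
            if len(snps) >= 1:
                o_het_list, e_het_list = [], []
                for j in snps:
                    col = dos[:, j]
                    ok = col != MISSING
                    n = int(ok.sum())
                    if n < 2:
                        continue
                    p = col[ok].sum() / (2 * n)
                    if p in (0.0, 1.0):
                        continue
                    o_het_list.append(float((col[ok] == 1).mean()))
                    e_het_list.append(2 * p * (1 - p) * (2 * n) / (2 * n - 1))
                if e_het_list:
                    f_coef = 1.0 - float(np.mean(o_het_list)) / float(np.mean(e_het_list))
                if len(snps) >= 2:
                    vals = []
                    for a_i in range(len(snps)):
                        for b_i in range(a_i + 1, len(snps)):
                            r2 = pairwise_r2(dos[:, snps[a_i]], dos[:, snps[b_i]])
                            if np.isfinite(r2):
                                vals.append(r2)
                    if vals:
                        mean_r2 = float(np.mean(vals))
            rows.append((name, (start + end) // 2, start, end, len(snps), mean_r2, f_coef))
            start = end + 1
    return pd.DataFrame(
        rows, columns=["group", "midpoint", "start", "end", "n_snps", "mean_r2", "f_coef"]
    )


def confirm_overlap(
    segments_primary: pd.DataFrame,
    segments_validation: pd.DataFrame,
    region: tuple[str, int, int],
) -> dict:
    """Count samples per cohort carrying >= 1 segment overlapping the region."""
    chrom, rs, re_ = region

    def _count(seg: pd.DataFrame) -> tuple[int, pd.DataFrame]:
        if seg.empty:
            return 0, seg
        hit = seg[(seg["chrom"] == chrom) & (seg["end"] >= rs) & (seg["start"] <= re_)]
        return hit["sample_id"].nunique(), hit.reset_index(drop=True)

    n_primary, hits_p = _count(segments_primary)
    n_validation, hits_v = _count(segments_validation)
    table = pd.concat(
        [hits_p.assign(cohort="primary"), hits_v.assign(cohort="validation")],
        ignore_index=True,
    )
    return {
        "region": region,
        "n_primary": int(n_primary),
        "n_validation": int(n_validation),
        "segments": table,
    }
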