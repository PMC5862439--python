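"""Extended haplotype homozygosity (EHH) and the integrated haplotype score.

EHH at offset x from a core SNP is the probability that two randomly drawn
carrier haplotypes of the core allele are identical over the interval from
the core to x: sum over identity groups of C(n_g, 2) / C(n, 2). iHH per
allele class is the trapezoidal integral of EHH over physical distance,
extended in each direction until EHH drops below ``ehh_cutoff``; the
unstandardized score is ln(iHH_derived / iHH_ancestral). Scores are then
z-standardized within derived-allele-frequency bins (100 equal-width bins
by default), which removes the frequency dependence of haplotype ages.

Integration stops at the first point below the cutoff (that final trapezoid
is included). A core is left undefined when a physical gap larger than
``max_gap`` is crossed, or a chromosome edge is reached, before the cutoff
— truncated integrals would bias the score downwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HaplotypePanel


@dataclass(frozen=True)
class IHSParams:
    ehh_cutoff: float = 0.05
    max_gap: int = 200_000
    min_maf: float = 0.01


@dataclass
class EHHCurve:
    core: int
    allele: int
    offsets: np.ndarray  # bp, negative upstream / positive downstream, 0 at core
    ehh: np.ndarray


def _ehh_walk(haps: np.ndarray, positions: np.ndarray, core: int, allele: int,
              direction: int, stop_cutoff: float | None = None):
    """EHH values walking from the core in one direction (+1 right, -1 left).

    Yields (snp_index, ehh). Group identity is tracked incrementally: at
    each step every identity group is split by the allele at the new SNP.
    """
    carriers = np.flatnonzero(haps[:, core] == allele)
    n = len(carriers)
    if n < 2:
        return
    pairs_total = n * (n - 1) / 2
    ids = np.zeros(n, dtype=np.int64)
    j = core
    limit = haps.shape[1]
    while True:
        j += direction
        if j < 0 or j >= limit:
            return
        ids = ids * 2 + haps[carriers, j]
        _, ids, counts = np.unique(ids, return_inverse=True, return_counts=True)
        pairs = float(np.sum(counts * (counts - 1) / 2))
        e = pairs / pairs_total
        yield j, e
        if stop_cutoff is not None and e < stop_cutoff:
            return
        if e == 0.0:
            return
        # singletons can never rejoin a group; drop them to keep steps cheap
        keep = counts[ids] >= 2
        if not keep.all():
            carriers = carriers[keep]
            ids = ids[keep]
            _, ids = np.unique(ids, return_inverse=True)


def ehh(panel: HaplotypePanel, core: int, allele: int) -> EHHCurve:
    """Full EHH curve for one allele class at a core SNP.

    Requires >= 2 carriers; EHH is 1 at the core by definition and
    monotone non-increasing away from it.
    """
    haps = panel.haplotypes
    positions = panel.variants["pos"].to_numpy()
    carriers = int((haps[:, core] == allele).sum())
    if carriers < 2:
        raise ValueError(f"allele class {allele} at core {core} has < 2 carriers")
    left = [(positions[j] - positions[core], e)
            for j, e in _ehh_walk(haps, positions, core, allele, -1)]
    right = [(positions[j] - positions[core], e)
             for j, e in _ehh_walk(haps, positions, core, allele, +1)]
    offsets = [o for o, _ in reversed(left)] + [0] + [o for o, _ in right]
    values = [e for _, e in reversed(left)] + [1.0] + [e for _, e in right]
    return EHHCurve(core, allele, np.asarray(offsets), np.asarray(values))


def _ihh_one_side(haps, positions, core, allele, direction, params: IHSParams) -> float | None:
    """Trapezoidal iHH on one side; None if undefined (edge or gap hit)."""
    area = 0.0
    prev_pos = positions[core]
    prev_e = 1.0
    for j, e in _ehh_walk(haps, positions, core, allele, direction,
                          stop_cutoff=params.ehh_cutoff):
        gap = abs(int(positions[j]) - int(prev_pos))
        if gap > params.max_gap:
            return None
        area += 0.5 * (prev_e + e) * gap
        prev_pos = positions[j]
        prev_e = e
        if e < params.ehh_cutoff:
            return area
    # walk exhausted: chromosome edge reached before the cutoff
    if prev_e < params.ehh_cutoff:
        return area
    return None


def ihs_unstandardized(panel: HaplotypePanel, core: int,
                       params: IHSParams = IHSParams(),
                       ancestral_allele: int = 0) -> float:
    """Unstandardized iHS at one core SNP; NaN when undefined."""
    haps = panel.haplotypes
    positions = panel.variants["pos"].to_numpy()
    derived = 1 - ancestral_allele
    n = haps.shape[0]
    daf = float((haps[:, core] == derived).sum()) / n
    if min(daf, 1 - daf) < params.min_maf:
        return float("nan")
    if (haps[:, core] == derived).sum() < 2 or (haps[:, core] == ancestral_allele).sum() < 2:
        return float("nan")
    ihh = {}
    for allele in (derived, ancestral_allele):
        left = _ihh_one_side(haps, positions, core, allele, -1, params)
        right = _ihh_one_side(haps, positions, core, allele, +1, params)
        if left is None or right is None:
            return float("nan")
        ihh[allele] = left + right
    if ihh[ancestral_allele] <= 0.0 or ihh[derived] <= 0.0:
        return float("nan")
    return float(np.log(ihh[derived] / ihh[ancestral_allele]))


def ihs_scan(panel: HaplotypePanel, params: IHSParams = IHSParams(),
             ancestral_alleles: np.ndarray | None = None) -> pd.DataFrame:
    """Raw iHS track over all cores of a panel (per chromosome).

    ``ancestral_alleles`` optionally gives the ancestral allele (0/1) per
    SNP; by default the REF allele (0) is taken as ancestral.
    """
    chroms = panel.variants["chrom"].to_numpy()
    rows = []
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        sub = HaplotypePanel(
            panel.sample_ids,
            panel.variants.iloc[idx].reset_index(drop=True),
            panel.haplotypes[:, idx],
        )
        n = sub.haplotypes.shape[0]
        for local, glob in enumerate(idx):
            anc = int(ancestral_alleles[glob]) if ancestral_alleles is not None else 0
            der = 1 - anc
            daf = float((sub.haplotypes[:, local] == der).sum()) / n
            raw = ihs_unstandardized(sub, local, params, ancestral_allele=anc)
            rows.append((chrom, int(sub.variants["pos"].iloc[local]), daf, raw))
    return pd.DataFrame(rows, columns=["chrom", "pos", "daf", "raw_ihs"])


def standardize_ihs(track: pd.DataFrame, n_bins: int = 100) -> pd.DataFrame:
    """Z-standardize raw iHS within equal-width derived-allele-frequency bins.

    Bins with fewer than 2 defined scores or zero spread are flagged
    (``bin_flagged``) and their scores passed through unstandardized.
    """
    out = track.copy()
    defined = np.isfinite(out["raw_ihs"].to_numpy())
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = np.clip(np.digitize(out["daf"].to_numpy(), edges) - 1, 0, n_bins - 1)
    std = np.full(len(out), np.nan)
    flagged = np.zeros(len(out), dtype=bool)
    for b in np.unique(bins):
        sel = (bins == b) & defined
        vals = out.loc[sel, "raw_ihs"].to_numpy()
        if len(vals) < 2 or np.std(vals) == 0.0:
            std[sel] = vals
            flagged[sel] = True
        else:
            std[sel] = (vals - vals.mean()) / vals.std()
    out["std_ihs"] = std
    out["freq_bin"] = bins
    out["bin_flagged"] = flagged
    return out


def sweep_windows(track: pd.DataFrame, window: int = 100_000, min_snps: int = 10,
                  abs_cut: float = 2.0, top_frac: float = 0.01) -> pd.DataFrame:
    """Flag non-overlapping windows with the empirically highest proportion
    of |standardized iHS| > abs_cut.

    Windows with fewer than ``min_snps`` scored SNPs are dropped. A window
    is flagged when its proportion >= the empirical (1 - top_frac)
    quantile over retained windows (ties at the threshold included).
    """
    scored = track[np.isfinite(track["std_ihs"])].copy()
    if scored.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_snps", "proportion", "flagged"])
    scored["win"] = (scored["pos"] - 1) // window
    rows = []
    for (chrom, w), grp in scored.groupby(["chrom", "win"], sort=True):
        n = len(grp)
        if n < min_snps:
            continue
        prop = float((grp["std_ihs"].abs() > abs_cut).mean())
        rows.append((chrom, int(w * window + 1), int((w + 1) * window), n, prop))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_snps", "proportion", "flagged"])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "proportion"])
    thresh = float(np.quantile(df["proportion"], 1.0 - top_frac))
    df["flagged"] = df["proportion"] >= thresh
    return df


def top_snp_threshold(track: pd.DataFrame, top_frac: float = 0.01) -> float:
    """Genome-wide per-SNP |iHS| threshold at the empirical top fraction
    (second flagging mode: extreme individual scores rather than window
    proportions)."""
    vals = track.loc[np.isfinite(track["std_ihs"]), "std_ihs"].abs()
    if vals.empty:
        raise ValueError("no standardized scores available")
    return float(np.quantile(vals, 1.0 - top_frac))
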