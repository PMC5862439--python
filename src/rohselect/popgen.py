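"""SNP QC, LD pruning, SNP-based inbreeding, LD decay and the GRM.

F_snp is the method-of-moments excess-homozygosity estimator computed on
LD-pruned SNPs: per sample, (observed homozygotes - expected homozygotes) /
(non-missing SNPs - expected homozygotes), where the expectation uses
cohort allele frequencies with the small-sample correction n/(n-1) on
heterozygosity.

The genomic relationship matrix is VanRaden method 1:
G = Z Z' / (2 sum_k p_k (1 - p_k)) with Z the dosage matrix column-centered
by 2 p_k and missing dosages mean-imputed per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class PruneParams:
    window_snps: int = 50
    step_snps: int = 5
    r2_max: float = 0.5

    def __post_init__(self) -> None:
        if not (self.window_snps >= self.step_snps >= 1):
            raise ValueError("require window_snps >= step_snps >= 1")
        if not (0.0 < self.r2_max <= 1.0):
            raise ValueError("r2_max must lie in (0, 1]")


def snp_stats(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP missing rate, alt-allele frequency and MAF."""
    dos = genotypes.dosage
    miss = dos == MISSING
    n_obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore"):
        alt = np.where(n_obs > 0, np.where(miss, 0, dos).sum(axis=0) / (2 * n_obs), np.nan)
    maf = np.minimum(alt, 1 - alt)
    return pd.DataFrame(
        {"missing_rate": miss.mean(axis=0), "alt_freq": alt, "maf": maf, "n_obs": n_obs}
    )


def qc_filter_snps(
    genotypes: GenotypeMatrix, max_missing: float = 0.05, min_maf: float = 0.01
) -> GenotypeMatrix:
    """Drop SNPs with missing rate > max_missing or MAF < min_maf
    (strict inequalities: a SNP exactly at both boundaries is retained)."""
    st = snp_stats(genotypes)
    keep = ~((st["missing_rate"] > max_missing) | (st["maf"] < min_maf) | st["maf"].isna())
    idx = np.flatnonzero(keep.to_numpy())
    if idx.size == 0:
        raise ValueError("QC removed every SNP")
    return genotypes.subset_variants(idx)


def pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples; NaN if < 2 complete pairs or zero variance."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(genotypes: GenotypeMatrix, params: PruneParams = PruneParams()) -> np.ndarray:
    """Sliding-window LD pruning; returns retained global SNP indices.

    Windows of ``window_snps`` SNPs advance by ``step_snps`` per
    chromosome. Within a window, offending pairs (r^2 > r2_max among
    retained SNPs) are scanned left to right, lowest index first, and the
    later SNP of each offending pair is removed.
    """
    chroms = genotypes.variants["chrom"].to_numpy()
    keep = np.ones(genotypes.n_variants, dtype=bool)
    cache: dict[tuple[int, int], float] = {}

    def _r2(a: int, b: int) -> float:
        key = (a, b)
        if key not in cache:
            cache[key] = pairwise_r2(genotypes.dosage[:, a], genotypes.dosage[:, b])
        return cache[key]

    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        n = len(idx)
        s = 0
        while True:
            win = idx[s : s + params.window_snps]
            changed = True
            while changed:
                changed = False
                live = [g for g in win if keep[g]]
                for ai in range(len(live)):
                    if changed:
                        break
                    for bi in range(ai + 1, len(live)):
                        r2 = _r2(live[ai], live[bi])
                        if np.isfinite(r2) and r2 > params.r2_max:
                            keep[live[bi]] = False
                            changed = True
                            break
            if s + params.window_snps >= n:
                break
            s += params.step_snps
    return np.flatnonzero(keep)


def compute_fsnp(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Method-of-moments inbreeding coefficient per sample.

    expected_hom for a sample sums 1 - 2 p_i (1 - p_i) n_i/(n_i - 1) over
    SNPs non-missing in that sample (p_i = cohort alt-allele frequency,
    n_i = non-missing allele count); SNPs with n_i < 2 are excluded.
    """
    dos = genotypes.dosage
    miss = dos == MISSING
    n_alleles = 2 * (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(miss, 0, dos).sum(axis=0) / n_alleles
        corr = n_alleles / (n_alleles - 1)
    usable = n_alleles >= 2
    exp_snp = 1.0 - 2.0 * p * (1.0 - p) * corr
    rows = []
    for i, sample in enumerate(genotypes.sample_ids):
        ok = usable & ~miss[i]
        n_nm = int(ok.sum())
        e_hom = float(exp_snp[ok].sum())
        o_hom = int(((dos[i] == 0) | (dos[i] == 2))[ok].sum())
        denom = n_nm - e_hom
        f = (o_hom - e_hom) / denom if denom > 0 else float("nan")
        rows.append((sample, o_hom, e_hom, n_nm, f))
    return pd.DataFrame(
        rows, columns=["sample_id", "observed_hom", "expected_hom", "n_nonmissing", "f_snp"]
    )


def ld_decay_curve(
    genotypes: GenotypeMatrix, max_dist: int = 20_000, step: int = 5_000
) -> pd.DataFrame:
    """Mean pairwise r^2 in distance bins of width ``step`` up to ``max_dist``.

    All intra-chromosomal SNP pairs with separation <= max_dist are scored;
    pairs with undefined r^2 (zero variance) are excluded.
    """
    chroms = genotypes.variants["chrom"].to_numpy()
    pos = genotypes.variants["pos"].to_numpy()
    edges = np.arange(0, max_dist + step, step)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for ii in range(len(idx)):
            for jj in range(ii + 1, len(idx)):
                d = pos[idx[jj]] - pos[idx[ii]]
                if d > max_dist:
                    break
                r2 = pairwise_r2(genotypes.dosage[:, idx[ii]], genotypes.dosage[:, idx[jj]])
                if np.isfinite(r2):
                    b = min(int(d // step), len(sums) - 1) if d < max_dist else len(sums) - 1
                    sums[b] += r2
                    counts[b] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = (edges[:-1] + edges[1:]) / 2
    out = pd.DataFrame({"dist_mid": mids, "mean_r2": mean, "n_pairs": counts})
    return out[out["n_pairs"] > 0].reset_index(drop=True)


def compute_grm(genotypes: GenotypeMatrix) -> tuple[list[str], np.ndarray]:
    """VanRaden method-1 genomic relationship matrix.

    Missing dosages are mean-imputed per SNP; monomorphic SNPs are
    excluded. Returns (sample ids, symmetric N x N matrix).
    """
    dos = genotypes.dosage.astype(float)
    miss = genotypes.dosage == MISSING
    dos[miss] = np.nan
    p = np.nanmean(dos, axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; GRM undefined")
    dos = dos[:, poly]
    p = p[poly]
    col_mean = 2.0 * p
    inds = np.where(np.isnan(dos))
    dos[inds] = col_mean[inds[1]]
    z = dos - col_mean
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    g = z @ z.T / denom
    return list(genotypes.sample_ids), (g + g.T) / 2.0


def write_grm(sample_ids: list[str], grm: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(sample_ids) + "\n")
        for row in grm:
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
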