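"""Genotype, metadata and interval I/O.

All coordinate conversions are centralized here: VCF and internal segment
coordinates are 1-based inclusive, BED output is 0-based half-open.
Only autosomal biallelic SNPs are retained by the VCF reader; multiallelic
and non-SNP records are skipped and counted.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # dosage code for a missing genotype call

METADATA_COLUMNS = ["sample", "kpn", "selected", "facility", "weight12m"]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP matrix of alternate-allele dosages.

    ``dosage`` holds values in {0, 1, 2, MISSING}; ``variants`` is a
    DataFrame with columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``,
    sorted with strictly increasing positions within a chromosome.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        if len(self.sample_ids) < 1:
            raise ValueError("GenotypeMatrix requires at least one sample")
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        pos = self.variants["pos"].to_numpy()
        chrom = self.variants["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1] if len(pos) > 1 else np.array([], bool)
        if np.any(pos[1:][same] <= pos[:-1][same]):
            raise ValueError("variant positions must be strictly increasing per chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.sample_ids,
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosage[:, idx],
        )

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        pos = [self.sample_ids.index(s) for s in keep]
        return GenotypeMatrix(list(keep), self.variants, self.dosage[pos])


@dataclass
class HaplotypePanel:
    """Phased alleles: 2N haplotype rows x variants, values in {0, 1}.

    Rows ``2i`` and ``2i+1`` are the two haplotypes of sample ``i``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.haplotypes.shape != (2 * len(self.sample_ids), len(self.variants)):
            raise ValueError("haplotype panel must have 2N rows")

    def dosage(self) -> np.ndarray:
        return self.haplotypes[0::2] + self.haplotypes[1::2]


@dataclass(frozen=True)
class VariantFilterThresholds:
    """Hard-filter cutoffs applied to raw variant records.

    A record is removed iff QUAL < min_qual, or INFO/DP < min_depth, or
    INFO/MQ0 > max_mq0, or INFO/FS > max_fs (all strict inequalities, so a
    record exactly at every boundary is retained).
    """

    min_qual: float = 30.0
    min_depth: float = 5.0
    max_mq0: float = 4.0
    max_fs: float = 200.0

    def __post_init__(self) -> None:
        for name in ("min_qual", "min_depth", "max_mq0", "max_fs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ChromSizes:
    """Ordered chromosome name -> length (bp) map."""

    sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __getitem__(self, name: str) -> int:
        return self.sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sizes

    def __iter__(self):
        return iter(self.sizes)

    def items(self):
        return self.sizes.items()

    @property
    def total_length(self) -> int:
        return sum(self.sizes.values())


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_vcf(
    path: str | Path, region: tuple[str, int, int] | None = None
) -> tuple[GenotypeMatrix, HaplotypePanel | None]:
    """Read a VCF into a GenotypeMatrix (and a HaplotypePanel if fully phased).

    Multiallelic and non-SNP records are skipped with a logged count.
    ``region`` is an optional (chrom, start, end) 1-based inclusive filter.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} contains no samples")

    rows, dosages, haps = [], [], []
    n_skipped = 0
    all_phased = True
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        if region is not None:
            chrom, start, end = region
            if v.CHROM != chrom or not (start <= v.POS <= end):
                continue
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        gt = v.gt_types.copy()  # gts012: 0,1,2 dosage; 3 unknown
        gt[gt == 3] = MISSING
        dosages.append(gt.astype(np.int8))
        if all_phased:
            ph = np.asarray(v.genotypes, dtype=object)
            pair = np.empty(2 * len(samples), dtype=np.int8)
            for i, g in enumerate(v.genotypes):
                if len(g) < 3 or not g[2] or g[0] < 0 or g[1] < 0:
                    all_phased = False
                    break
                pair[2 * i] = g[0]
                pair[2 * i + 1] = g[1]
            else:
                haps.append(pair)
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"VCF {path} contains no usable biallelic SNP records")
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    gm = GenotypeMatrix(samples, variants, np.vstack(dosages).T.copy())
    panel = None
    if all_phased and len(haps) == len(rows):
        panel = HaplotypePanel(samples, variants, np.vstack(haps).T.copy())
    return gm, panel


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    panel: HaplotypePanel | None = None,
    chrom_sizes: ChromSizes | None = None,
) -> None:
    """Write a VCF v4.2; phased '|' genotypes if a panel is supplied."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if chrom_sizes is not None:
            for name, length in chrom_sizes.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in dict.fromkeys(gm.variants["chrom"]):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        unphased = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, row in enumerate(gm.variants.itertuples(index=False)):
            if panel is not None:
                gts = [
                    f"{panel.haplotypes[2 * i, j]}|{panel.haplotypes[2 * i + 1, j]}"
                    for i in range(gm.n_samples)
                ]
            else:
                gts = [unphased[int(d)] for d in gm.dosage[:, j]]
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def hard_filter_variants(
    records: Iterable,
    thresholds: VariantFilterThresholds = VariantFilterThresholds(),
    missing_info_passes: bool = True,
) -> tuple[list, dict[str, int]]:
    """Apply the hard filter to variant records.

    Records must expose ``QUAL`` and a mapping ``INFO`` with keys DP, MQ0
    and FS. A missing INFO key passes its criterion by default (logged).
    Returns (retained records, per-criterion rejection tally). A record
    failing several criteria is tallied once per criterion; ``removed``
    holds the count of distinct removed records.
    """
    tally = {"qual": 0, "depth": 0, "mq0": 0, "fs": 0, "removed": 0}
    kept = []
    n_missing_info = 0

    def _info(rec, key):
        nonlocal n_missing_info
        try:
            val = rec.INFO[key] if not hasattr(rec.INFO, "get") else rec.INFO.get(key)
        except KeyError:
            val = None
        if val is None:
            n_missing_info += 1
            if not missing_info_passes:
                raise KeyError(f"INFO key {key} absent and policy forbids passing")
        return val

    for rec in records:
        fails = []
        if rec.QUAL is not None and rec.QUAL < thresholds.min_qual:
            fails.append("qual")
        dp = _info(rec, "DP")
        if dp is not None and dp < thresholds.min_depth:
            fails.append("depth")
        mq0 = _info(rec, "MQ0")
        if mq0 is not None and mq0 > thresholds.max_mq0:
            fails.append("mq0")
        fs = _info(rec, "FS")
        if fs is not None and fs > thresholds.max_fs:
            fails.append("fs")
        if fails:
            tally["removed"] += 1
            for f in fails:
                tally[f] += 1
        else:
            kept.append(rec)
    if n_missing_info:
        logger.info("hard_filter_variants: %d absent INFO lookups passed", n_missing_info)
    return kept, tally


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample covariate table.

    TSV with header ``sample  kpn  selected  facility  weight12m``. KPN is
    empty for unselected animals; weight may be NA (such samples are later
    excluded from the body-weight mixed model only).
    """
    df = pd.read_csv(_open_text(path), sep="\t", dtype={"sample": str, "facility": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    df["kpn"] = pd.to_numeric(df["kpn"], errors="coerce").astype("Int64")
    df["selected"] = df["selected"].astype(int).astype(bool)
    df["weight12m"] = pd.to_numeric(df["weight12m"], errors="coerce")
    bad = df["selected"] & df["kpn"].isna()
    if bad.any():
        raise ValueError(
            f"selected animals without KPN: {df.loc[bad, 'sample'].tolist()}"
        )
    return df[METADATA_COLUMNS]


def write_sample_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def load_chrom_sizes(source: str | Path = "umd3.1_autosomes") -> ChromSizes:
    """Load chromosome sizes from the bundled assembly table or a TSV path.

    The bundled ``"umd3.1_autosomes"`` fixture holds the 29 B. taurus
    UMD3.1 autosome lengths.
    """
    if source == "umd3.1_autosomes":
        ref = resources.files("rohselect.data") / "umd3.1_autosomes.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    elif isinstance(source, (str, Path)) and Path(source).exists():
        df = pd.read_csv(_open_text(source), sep="\t", dtype={"chrom": str})
    else:
        raise ValueError(f"unknown chromosome-sizes source: {source!r}")
    if df["chrom"].duplicated().any():
        raise ValueError("duplicate chromosome names")
    return ChromSizes(dict(zip(df["chrom"], df["length"].astype(int))))


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\n")
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def segments_to_bed(segments: pd.DataFrame, path: str | Path, extra: list[str] | None = None) -> None:
    """Write 1-based inclusive segments as 0-based half-open BED."""
    cols = extra or [c for c in ("sample_id", "n_snps", "depth") if c in segments.columns]
    with open(path, "w") as fh:
        for row in segments.itertuples(index=False):
            fields = [str(row.chrom), str(row.start - 1), str(row.end)]
            fields += [str(getattr(row, c)) for c in cols]
            fh.write("\t".join(fields) + "\n")


def bed_to_segments(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    """Read a BED file into 1-based inclusive segment coordinates."""
    df = pd.read_csv(_open_text(path), sep="\t", header=None)
    cols = ["chrom", "start", "end"] + (names or [f"col{i}" for i in range(3, df.shape[1])])
    df.columns = cols[: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df
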