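"""Forward-time pedigree simulator of a sequential artificial-selection program.

The simulator emulates a bull-breeding scheme: each round a batch of
candidates is produced, the top males by phenotype are kept as sires of the
next round and receive sequential registration (KPN) numbers, so KPN tracks
selection time. An unselected control group is produced by random mating
from the founder pool. Every haplotype allele carries a founder-origin
label, so true autozygosity (founder-allele IBD) is known exactly per
individual, alongside tabular pedigree inbreeding coefficients.

Haplotypes are stored as breakpoint mosaics ``[(start, end, label), ...]``
in 1-based inclusive bp; meioses draw a Poisson number of crossovers at the
chromosome map length (Haldane, no interference) with uniform physical
positions (the genetic map is linear per chromosome). There is no mutation:
all variation is standing founder variation, which keeps IBD bookkeeping
exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    ChromSizes,
    GenotypeMatrix,
    HaplotypePanel,
    segments_to_bed,
    write_chrom_sizes,
    write_sample_metadata,
    write_vcf,
)

Hap = list[tuple[int, int, int]]  # (start, end, founder-haplotype label)

DEFAULT_GENOME = [("1", 50_000_000, 50.0), ("2", 50_000_000, 50.0), ("3", 50_000_000, 50.0)]


@dataclass
class SimConfig:
    """Parameters of the breeding-program simulation.

    ``genome`` is a list of (chromosome name, length bp, map length cM).
    ``h2`` is the narrow-sense heritability of 12-month body weight;
    facility effects (kg) add on top of the genetic + residual variance.
    """

    n_founders: int = 40
    n_generations: int = 21
    n_sires_selected: int = 6
    offspring_per_round: int = 60
    genome: list[tuple[str, int, float]] = field(default_factory=lambda: list(DEFAULT_GENOME))
    snp_density: float = 20.0  # SNPs per Mb
    founder_maf_law: tuple[str, float, float] = ("uniform", 0.05, 0.5)
    h2: float = 0.3
    selection_mode: str = "phenotype_truncation"
    n_facilities: int = 3
    facility_effect_sd: float = 5.0
    n_unselected: int = 10
    mean_weight: float = 340.0
    phenotype_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_generations", "n_sires_selected",
                     "offspring_per_round", "n_facilities", "n_unselected"):
            if getattr(self, name) < 0 or (name not in ("n_generations",) and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n_sires_selected > self.offspring_per_round:
            raise ValueError("n_sires_selected cannot exceed offspring_per_round")
        for name, length, cm in self.genome:
            if length <= 0 or cm <= 0:
                raise ValueError(f"chromosome {name}: length and map length must be positive")
            if round(self.snp_density * length / 1e6) < 1:
                raise ValueError(f"chromosome {name}: zero SNPs at density {self.snp_density}")
        if self.selection_mode != "phenotype_truncation":
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")

    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes({name: length for name, length, _ in self.genome})


@dataclass
class Individual:
    idx: int
    sire: int | None
    dam: int | None
    generation: int
    sex: str  # "M" | "F"
    haps: dict[str, tuple[Hap, Hap]]
    tbv: float = 0.0
    phenotype: float = 0.0
    facility: str = ""
    kpn: int | None = None
    sample_id: str | None = None


@dataclass
class SimTruth:
    """Ground truth emitted alongside the genotypes."""

    pedigree: pd.DataFrame  # id, sire, dam, generation (cohort + ancestors)
    true_ibd_segments: pd.DataFrame  # sample_id, chrom, start, end
    pedigree_F: pd.Series  # per cohort sample
    true_breeding_values: pd.Series  # kg, per cohort sample


@dataclass
class Cohort:
    genotypes: GenotypeMatrix
    panel: HaplotypePanel
    meta: pd.DataFrame
    truth: SimTruth
    config: SimConfig


def meiosis(hap_a: Hap, hap_b: Hap, length_bp: int, map_cm: float, rng: np.random.Generator) -> Hap:
    """One gamete from a parent's two haplotypes (Haldane crossovers)."""
    n_xo = rng.poisson(map_cm / 100.0)
    cuts = np.sort(rng.integers(1, length_bp, size=n_xo)) if n_xo else np.array([], dtype=int)
    cur = int(rng.integers(2))
    parents = (hap_a, hap_b)
    gamete: Hap = []
    start = 1
    for cut in list(cuts) + [length_bp]:
        cut = int(cut)
        if cut >= start:
            _extend(gamete, _slice(parents[cur], start, cut))
            start = cut + 1
        cur = 1 - cur
    return gamete


def _slice(hap: Hap, a: int, b: int) -> Hap:
    out = []
    for s, e, lab in hap:
        if e < a or s > b:
            continue
        out.append((max(s, a), min(e, b), lab))
    return out


def _extend(gamete: Hap, pieces: Hap) -> None:
    for s, e, lab in pieces:
        if gamete and gamete[-1][2] == lab and gamete[-1][1] + 1 == s:
            gamete[-1] = (gamete[-1][0], e, lab)
        else:
            gamete.append((s, e, lab))


def intersect_ibd(hap_a: Hap, hap_b: Hap) -> list[tuple[int, int]]:
    """Maximal intervals where both haplotypes carry the same founder label."""
    raw = []
    i = j = 0
    while i < len(hap_a) and j < len(hap_b):
        s = max(hap_a[i][0], hap_b[j][0])
        e = min(hap_a[i][1], hap_b[j][1])
        if s <= e and hap_a[i][2] == hap_b[j][2]:
            raw.append((s, e))
        if hap_a[i][1] < hap_b[j][1]:
            i += 1
        else:
            j += 1
    merged: list[tuple[int, int]] = []
    for s, e in raw:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class PedigreeSimulator:
    """Low-level pedigree machinery: founders, matings, truth extraction.

    Usable directly to build bespoke pedigrees (e.g. forced full-sib
    matings) with exact IBD and tabular pedigree-F bookkeeping.
    """

    def __init__(self, config: SimConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.individuals: list[Individual] = []
        self.parents: list[tuple[int | None, int | None]] = []
        self._kin: dict[tuple[int, int], float] = {}
        self._next_label = 0
        self._init_sites()

    def _init_sites(self) -> None:
        law, lo, hi = self.config.founder_maf_law
        if law != "uniform":
            raise ValueError(f"unknown founder_maf_law {law!r}")
        self.snp_positions: dict[str, np.ndarray] = {}
        self.snp_freqs: dict[str, np.ndarray] = {}
        for name, length, _cm in self.config.genome:
            n = int(round(self.config.snp_density * length / 1e6))
            pos = np.sort(self.rng.choice(np.arange(1, length + 1), size=n, replace=False))
            self.snp_positions[name] = pos
            self.snp_freqs[name] = self.rng.uniform(lo, hi, size=n)
        # founder haplotype alleles drawn lazily per founder in founder()
        self._founder_alleles: dict[str, list[np.ndarray]] = {
            name: [] for name, _, _ in self.config.genome
        }

    def founder(self, sex: str | None = None, generation: int = 0) -> Individual:
        if sex is None:
            sex = "M" if len(self.individuals) % 2 == 0 else "F"
        haps = {}
        for name, length, _cm in self.config.genome:
            lab_a, lab_b = self._next_label, self._next_label + 1
            haps[name] = ([(1, length, lab_a)], [(1, length, lab_b)])
            p = self.snp_freqs[name]
            for _ in range(2):
                self._founder_alleles[name].append(
                    (self.rng.random(len(p)) < p).astype(np.int8)
                )
        self._next_label += 2
        ind = Individual(len(self.individuals), None, None, generation, sex, haps)
        self.individuals.append(ind)
        self.parents.append((None, None))
        return ind

    def mate(self, sire: Individual, dam: Individual, generation: int | None = None,
             sex: str | None = None) -> Individual:
        if sex is None:
            sex = "M" if self.rng.random() < 0.5 else "F"
        if generation is None:
            generation = max(sire.generation, dam.generation) + 1
        haps = {}
        for name, length, cm in self.config.genome:
            pat = meiosis(*sire.haps[name], length, cm, self.rng)
            mat = meiosis(*dam.haps[name], length, cm, self.rng)
            haps[name] = (pat, mat)
        ind = Individual(len(self.individuals), sire.idx, dam.idx, generation, sex, haps)
        self.individuals.append(ind)
        self.parents.append((sire.idx, dam.idx))
        return ind

    # -- pedigree (tabular) kinship ------------------------------------
    def kinship(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in self._kin:
            return self._kin[key]
        if i == j:
            s, d = self.parents[i]
            f = self.kinship(s, d) if s is not None else 0.0
            val = 0.5 * (1.0 + f)
        else:
            s, d = self.parents[j]  # j is the younger individual
            if s is None:
                val = 0.0
            else:
                val = 0.5 * (self.kinship(i, s) + self.kinship(i, d))
        self._kin[key] = val
        return val

    def pedigree_f(self, ind: Individual) -> float:
        if ind.sire is None:
            return 0.0
        return self.kinship(ind.sire, ind.dam)

    # -- truth ---------------------------------------------------------
    def ibd_segments(self, ind: Individual) -> pd.DataFrame:
        rows = []
        for name, _, _ in self.config.genome:
            for s, e in intersect_ibd(*ind.haps[name]):
                rows.append((name, s, e))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def ibd_fraction(self, ind: Individual) -> float:
        total = sum(length for _, length, _ in self.config.genome)
        ibd = 0
        for name, _, _ in self.config.genome:
            ibd += sum(e - s + 1 for s, e in intersect_ibd(*ind.haps[name]))
        return ibd / total

    # -- genotypes -----------------------------------------------------
    def _hap_alleles(self, hap: Hap, chrom: str) -> np.ndarray:
        pos = self.snp_positions[chrom]
        alleles = np.empty(len(pos), dtype=np.int8)
        founder = self._founder_alleles[chrom]
        for s, e, lab in hap:
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, e, side="right")
            if hi > lo:
                alleles[lo:hi] = founder[lab][lo:hi]
        return alleles

    def haplotype_rows(self, individuals: Sequence[Individual]) -> np.ndarray:
        rows = []
        for ind in individuals:
            for which in (0, 1):
                parts = [
                    self._hap_alleles(ind.haps[name][which], name)
                    for name, _, _ in self.config.genome
                ]
                rows.append(np.concatenate(parts))
        return np.vstack(rows)

    def variants_table(self) -> pd.DataFrame:
        frames = []
        for name, _, _ in self.config.genome:
            pos = self.snp_positions[name]
            frames.append(pd.DataFrame({"chrom": name, "pos": pos, "ref": "A", "alt": "G"}))
        return pd.concat(frames, ignore_index=True)


def _assign_phenotypes(sim: PedigreeSimulator, inds: list[Individual],
                       facility_effects: np.ndarray, facility_of: np.ndarray) -> None:
    cfg = sim.config
    sigma_a = math.sqrt(cfg.h2) * cfg.phenotype_sd
    sigma_e = math.sqrt(1.0 - cfg.h2) * cfg.phenotype_sd
    for k, ind in enumerate(inds):
        if ind.sire is None:
            ind.tbv = sim.rng.normal(0.0, sigma_a)
        else:
            f_s = sim.pedigree_f(sim.individuals[ind.sire])
            f_d = sim.pedigree_f(sim.individuals[ind.dam])
            mend_sd = sigma_a * math.sqrt(max(0.5 * (1.0 - 0.5 * (f_s + f_d)), 0.0))
            ind.tbv = 0.5 * (sim.individuals[ind.sire].tbv + sim.individuals[ind.dam].tbv) \
                + sim.rng.normal(0.0, mend_sd)
        fac = int(facility_of[k])
        ind.facility = f"F{fac + 1}"
        ind.phenotype = (cfg.mean_weight + ind.tbv + facility_effects[fac]
                         + sim.rng.normal(0.0, sigma_e))


def simulate_cohort(config: SimConfig) -> Cohort:
    """Run the breeding program and emit the analysis-ready cohort.

    Output sample order is the unselected control group first, then the
    selected sires in KPN order (KPN = sequential integers over rounds,
    ties within a round broken by descending phenotype).
    """
    sim = PedigreeSimulator(config)
    rng = sim.rng
    facility_effects = rng.normal(0.0, config.facility_effect_sd, size=config.n_facilities)

    founders = [sim.founder() for _ in range(config.n_founders)]
    fac = rng.integers(0, config.n_facilities, size=len(founders))
    _assign_phenotypes(sim, founders, facility_effects, fac)
    founder_males = [f for f in founders if f.sex == "M"]
    founder_females = [f for f in founders if f.sex == "F"]
    if not founder_males or not founder_females:
        raise ValueError("founder pool must contain both sexes")

    selected: list[Individual] = []
    kpn = 0
    sires = sorted(founder_males, key=lambda i: -i.phenotype)[: config.n_sires_selected]
    dam_pool = list(founder_females)
    for gen in range(1, config.n_generations + 1):
        batch = []
        for _ in range(config.offspring_per_round):
            sire = sires[int(rng.integers(len(sires)))]
            dam = dam_pool[int(rng.integers(len(dam_pool)))]
            batch.append(sim.mate(sire, dam, generation=gen))
        fac = rng.integers(0, config.n_facilities, size=len(batch))
        _assign_phenotypes(sim, batch, facility_effects, fac)
        males = sorted((i for i in batch if i.sex == "M"), key=lambda i: -i.phenotype)
        n_take = min(config.n_sires_selected, len(males))
        round_sires = males[:n_take]
        for ind in round_sires:
            kpn += 1
            ind.kpn = kpn
        selected.extend(round_sires)
        sires = round_sires if round_sires else sires
        females = [i for i in batch if i.sex == "F"]
        if len(females) >= 2:
            dam_pool = females

    unselected = []
    for _ in range(config.n_unselected):
        sire = founder_males[int(rng.integers(len(founder_males)))]
        dam = founder_females[int(rng.integers(len(founder_females)))]
        unselected.append(sim.mate(sire, dam, generation=1))
    fac = rng.integers(0, config.n_facilities, size=len(unselected))
    _assign_phenotypes(sim, unselected, facility_effects, fac)

    cohort_inds = unselected + selected
    for k, ind in enumerate(unselected):
        ind.sample_id = f"U{k + 1:02d}"
    for k, ind in enumerate(selected):
        ind.sample_id = f"S{k + 1:03d}"

    variants = sim.variants_table()
    hap_rows = sim.haplotype_rows(cohort_inds)
    sample_ids = [i.sample_id for i in cohort_inds]
    panel = HaplotypePanel(sample_ids, variants, hap_rows)
    gm = GenotypeMatrix(sample_ids, variants, panel.dosage().astype(np.int8))

    meta = pd.DataFrame(
        {
            "sample": sample_ids,
            "kpn": pd.array([i.kpn for i in cohort_inds], dtype="Int64"),
            "selected": [i.kpn is not None for i in cohort_inds],
            "facility": [i.facility for i in cohort_inds],
            "weight12m": [round(i.phenotype, 3) for i in cohort_inds],
        }
    )

    ped = pd.DataFrame(
        [(i.idx, i.sire, i.dam, i.generation) for i in sim.individuals],
        columns=["id", "sire", "dam", "generation"],
    )
    ibd_rows = []
    for ind in cohort_inds:
        seg = sim.ibd_segments(ind)
        seg.insert(0, "sample_id", ind.sample_id)
        ibd_rows.append(seg)
    truth = SimTruth(
        pedigree=ped,
        true_ibd_segments=pd.concat(ibd_rows, ignore_index=True),
        pedigree_F=pd.Series({i.sample_id: sim.pedigree_f(i) for i in cohort_inds}),
        true_breeding_values=pd.Series({i.sample_id: i.tbv for i in cohort_inds}),
    )
    return Cohort(gm, panel, meta, truth, config)


def realized_ibd_fractions(truth: SimTruth, chrom_sizes: ChromSizes) -> pd.Series:
    """Per-sample fraction of the autosome covered by true IBD segments."""
    total = chrom_sizes.total_length
    seg = truth.true_ibd_segments
    lengths = (seg["end"] - seg["start"] + 1).groupby(seg["sample_id"]).sum()
    return lengths.reindex(truth.pedigree_F.index, fill_value=0) / total


def impose_sweep(panel: HaplotypePanel, chrom: str, start: int, end: int,
                 sweep_freq: float, rng: np.random.Generator) -> HaplotypePanel:
    """Drive one haplotype to ``sweep_freq`` inside a region by copy-replacement.

    Emulates a recent hard selective sweep: a random donor haplotype's
    alleles over [start, end] are copied into a random subset of haplotypes
    so the donor haplotype reaches the requested local frequency.
    """
    mask = ((panel.variants["chrom"] == chrom)
            & (panel.variants["pos"] >= start)
            & (panel.variants["pos"] <= end)).to_numpy()
    haps = panel.haplotypes.copy()
    n = haps.shape[0]
    donor = int(rng.integers(n))
    n_carriers = int(round(sweep_freq * n))
    carriers = rng.choice(n, size=n_carriers, replace=False)
    for c in carriers:
        haps[c, mask] = haps[donor, mask]
    return HaplotypePanel(panel.sample_ids, panel.variants, haps)


def ancestral_segment_lengths_cm(g: int, chrom_cm: float, n_reps: int,
                                 rng: np.random.Generator,
                                 chrom_bp: int = 100_000_000) -> np.ndarray:
    """Lengths (cM) of autozygous tracts tracing to an ancestor g generations back.

    Two independent lineages of ``g`` meioses each descend one ancestral
    haplotype; tracts where both descendant haplotypes retain the ancestral
    label are collected. Tract length is exponential with mean 100/(2g) cM
    away from chromosome ends (recombination shortens tracts each meiosis).
    """
    cfg = SimConfig(genome=[("1", chrom_bp, chrom_cm)], n_founders=1,
                    snp_density=max(1e6 / chrom_bp, 1e-6))
    lengths = []
    label_counter = [10]

    def descend(start_hap: Hap) -> Hap:
        hap = start_hap
        for _ in range(g):
            label_counter[0] += 1
            partner: Hap = [(1, chrom_bp, label_counter[0])]
            hap = meiosis(hap, partner, chrom_bp, chrom_cm, rng)
        return hap

    ancestor: Hap = [(1, chrom_bp, 0)]
    for _ in range(n_reps):
        h1 = descend(ancestor)
        h2 = descend(ancestor)
        for s, e in intersect_ibd(h1, h2):
            lengths.append((e - s + 1) / chrom_bp * chrom_cm)
    return np.asarray(lengths)


def export_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write VCF, phased VCF, metadata TSV, truth BED and chrom sizes TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sizes = cohort.config.chrom_sizes()
    paths = {
        "vcf": directory / "cohort.vcf",
        "phased_vcf": directory / "cohort.phased.vcf",
        "metadata": directory / "metadata.tsv",
        "truth_bed": directory / "truth_ibd.bed",
        "chrom_sizes": directory / "chrom_sizes.tsv",
    }
    write_vcf(cohort.genotypes, paths["vcf"], chrom_sizes=sizes)
    write_vcf(cohort.genotypes, paths["phased_vcf"], panel=cohort.panel, chrom_sizes=sizes)
    write_sample_metadata(cohort.meta, paths["metadata"])
    seg = cohort.truth.true_ibd_segments.copy()
    segments_to_bed(seg, paths["truth_bed"], extra=["sample_id"])
    write_chrom_sizes(sizes, paths["chrom_sizes"])
    return paths
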