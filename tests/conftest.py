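import numpy as np
import pandas as pd
import pytest

from rohselect.io import MISSING, GenotypeMatrix, HaplotypePanel


def make_genotypes(dosage, positions=None, chrom="1", sample_ids=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_snps = dosage.shape
    if positions is None:
        positions = np.arange(1, n_snps + 1) * 10_000
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions), "ref": "A", "alt": "G"}
    )
    ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(ids, variants, dosage)


def make_panel(haps, positions=None, chrom="1") -> HaplotypePanel:
    haps = np.asarray(haps, dtype=np.int8)
    n_h, n_snps = haps.shape
    assert n_h % 2 == 0
    if positions is None:
        positions = np.arange(1, n_snps + 1) * 10_000
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions), "ref": "A", "alt": "G"}
    )
    return HaplotypePanel([f"s{i}" for i in range(n_h // 2)], variants, haps)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def family_structured_grm(n_families=60, family_size=5, seed=77):
    """GRM over full-sib families from the pedigree simulator.

    Sib blocks give the eigenvalue spread needed to separate genetic from
    residual variance; a GRM over unrelated samples is near identity and
    leaves the variance ratio weakly identified.
    """
    from rohselect.popgen import compute_grm
    from rohselect.simulate import PedigreeSimulator, SimConfig

    cfg = SimConfig(n_founders=30, snp_density=10.0)
    sim = PedigreeSimulator(cfg, np.random.default_rng(seed))
    founders = [sim.founder() for _ in range(30)]
    males = [f for f in founders if f.sex == "M"]
    females = [f for f in founders if f.sex == "F"]
    rng = sim.rng
    inds = []
    for _ in range(n_families):
        s = males[int(rng.integers(len(males)))]
        d = females[int(rng.integers(len(females)))]
        inds.extend(sim.mate(s, d) for _ in range(family_size))
    haps = sim.haplotype_rows(inds)
    dos = (haps[0::2] + haps[1::2]).astype(np.int8)
    gm = GenotypeMatrix([f"i{k}" for k in range(len(inds))], sim.variants_table(), dos)
    return compute_grm(gm)


def random_track(rng, n_max=200, p_missing=0.05):
    """One random 1-sample genotype track for brute-force ROH comparisons."""
    n = int(rng.integers(5, n_max))
    pos = np.sort(rng.choice(np.arange(1, 3_000_000), size=n, replace=False))
    dos = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8),
        size=n,
        p=[0.35, 0.2, 0.35, 0.1],
    )
    return pos, dos


def brute_force_roh(pos, dos, params):
    """Independent maximal-run enumerator (O(n^2)); the oracle for call_roh.

    Enumerates every index window, keeps those satisfying the het/missing
    allowances and the gap rule, discards nested windows, trims to
    homozygous endpoints, applies min_snps and merges overlaps.
    """
    n = len(pos)
    is_het = dos == 1
    is_miss = dos == MISSING

    def qualifies(a, b):
        if is_het[a : b + 1].sum() > params.max_het_in_run:
            return False
        if is_miss[a : b + 1].sum() > params.max_missing_in_run:
            return False
        return all(pos[k] - pos[k - 1] <= params.max_gap for k in range(a + 1, b + 1))

    wins = [(a, b) for a in range(n) for b in range(a, n) if qualifies(a, b)]
    maximal = [
        (a, b)
        for a, b in wins
        if not any(c <= a and b <= d and (c, d) != (a, b) for c, d in wins)
    ]
    segs = []
    for a, b in maximal:
        hom = [k for k in range(a, b + 1) if dos[k] in (0, 2)]
        if len(hom) >= max(params.min_snps, 1):
            segs.append((int(pos[hom[0]]), int(pos[hom[-1]]), len(hom)))
    segs.sort()
    merged = []
    for s, e, c in segs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e), max(merged[-1][2], c))
        else:
            merged.append((s, e, c))
    return [(s, e, c) for s, e, c in merged if e - s + 1 >= params.min_length]
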