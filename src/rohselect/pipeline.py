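"""End-to-end pipeline: simulate or load a cohort, then run QC, ROH
calling, autozygosity statistics, associations, selection scans and
overlap-region detection, writing one TSV per stage plus a run manifest.

Every stage is a pure function of (inputs, config, seed); re-running with
identical inputs yields identical bytes. Randomness is drawn from named
substreams of a single seed so stage reproducibility is independent of
stage order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import association, ihs, overlap, popgen, roh
from .io import (
    ChromSizes,
    load_chrom_sizes,
    read_sample_metadata,
    read_vcf,
)
from .popgen import PruneParams, write_grm
from .roh import ROHCallParams
from .simulate import SimConfig, export_cohort, simulate_cohort

logger = logging.getLogger(__name__)


DEFAULT_CONFIG: dict[str, Any] = {
    "simulation": None,  # SimConfig fields; exactly one of simulation / inputs
    "inputs": None,      # {vcf, phased_vcf?, metadata, chrom_sizes}
    "roh": {},           # ROHCallParams fields
    "min_length": 500_000,
    "prune": {},         # PruneParams fields
    "qc": {"max_missing": 0.05, "min_maf": 0.01},
    "bin_width": 10_000_000,
    "kpn_cutoff": None,  # None -> median observed KPN; the study cohort used 486
    "ihs": {},           # IHSParams fields
    "sweep": {"window": 100_000, "min_snps": 10, "abs_cut": 2.0, "top_frac": 0.01},
    "resampling": {"k": 10, "reps": 1000},
    "alpha": 0.01,
    "seed": 0,
    "outdir": "run",
}


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    cfg = {**DEFAULT_CONFIG, **config}
    has_sim = cfg.get("simulation") is not None
    has_inputs = cfg.get("inputs") is not None
    if has_sim == has_inputs:
        raise ValueError("config must set exactly one of 'simulation' or 'inputs'")
    if not (0.0 < cfg["alpha"] < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return cfg


def _substream(seed: int, name: str) -> int:
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _param_hash(cfg: dict[str, Any]) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: dict[str, Any]) -> Path:
    """Run every stage; returns the report directory.

    Stage order: cohort acquisition, QC, ROH calling and length filter,
    threshold profile, F_roh / F_snp, group comparison and resampling,
    GRM, Analysis 1 (status ~ KPN), Analysis 2 (weight ~ length + facility
    + GRM), iHS track and sweep windows, overlap regions, correlations,
    manifest.
    """
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    stage = "cohort"
    try:
        if cfg["simulation"] is not None:
            sim_cfg = SimConfig(**{**cfg["simulation"], "seed": _substream(seed, "simulate")})
            cohort = simulate_cohort(sim_cfg)
            export_cohort(cohort, outdir / "cohort")
            gm, panel, meta = cohort.genotypes, cohort.panel, cohort.meta
            sizes = sim_cfg.chrom_sizes()
        else:
            paths = cfg["inputs"]
            gm, panel = read_vcf(paths["vcf"])
            if panel is None and paths.get("phased_vcf"):
                _, panel = read_vcf(paths["phased_vcf"])
            meta = read_sample_metadata(paths["metadata"])
            sizes = load_chrom_sizes(paths.get("chrom_sizes", "umd3.1_autosomes"))
        logger.info("stage=%s samples=%d variants=%d", stage, gm.n_samples, gm.n_variants)

        stage = "qc"
        gm_qc = popgen.qc_filter_snps(gm, **cfg["qc"])
        logger.info("stage=%s variants %d -> %d", stage, gm.n_variants, gm_qc.n_variants)

        stage = "roh"
        params = ROHCallParams(**cfg["roh"])
        segments = roh.call_roh(gm, params)
        auto = roh.filter_autozygous(segments, cfg["min_length"])
        _write(segments, outdir / "roh_segments.tsv")
        _write(auto, outdir / "roh_autozygous.tsv")
        logger.info("stage=%s segments %d -> %d (>= %d bp)", stage, len(segments),
                    len(auto), cfg["min_length"])

        stage = "threshold_profile"
        profile = roh.threshold_profile(segments, gm.sample_ids)
        _write(profile, outdir / "threshold_profile.tsv")

        stage = "froh"
        froh = roh.compute_froh(auto, sizes, gm.sample_ids)
        _write(froh, outdir / "froh.tsv")

        stage = "fsnp"
        pruned_idx = popgen.ld_prune(gm_qc, PruneParams(**cfg["prune"]))
        fsnp = popgen.compute_fsnp(gm_qc.subset_variants(pruned_idx))
        _write(fsnp, outdir / "fsnp.tsv")
        logger.info("stage=%s pruned %d -> %d SNPs", stage, gm_qc.n_variants, len(pruned_idx))

        stage = "group_comparison"
        meta_i = meta.set_index("sample")
        sel_ids = meta_i.index[meta_i["selected"]].tolist()
        unsel_ids = meta_i.index[~meta_i["selected"]].tolist()
        froh_i = froh.set_index("sample_id")
        comp = roh.froh_group_comparison(froh_i.loc[sel_ids], froh_i.loc[unsel_ids])
        pd.DataFrame([comp]).to_csv(outdir / "group_comparison.tsv", sep="\t", index=False)

        stage = "resampling"
        rs = cfg["resampling"]
        resamp = roh.froh_resampling(
            froh_i.loc[sel_ids], froh_i.loc[unsel_ids], k=rs["k"], reps=rs["reps"],
            seed=_substream(seed, "resampling"),
        )
        _write(resamp, outdir / "froh_resampling.tsv")

        stage = "grm"
        grm_ids, grm = popgen.compute_grm(gm_qc)
        write_grm(grm_ids, grm, outdir / "grm.tsv")

        stage = "bins"
        bins = association.make_bins(sizes, cfg["bin_width"])
        matrix = association.bin_roh_matrix(auto, bins, gm.sample_ids)
        informative = association.filter_uninformative_bins(matrix)
        logger.info("stage=%s bins %d -> %d informative", stage, matrix.shape[1],
                    informative.shape[1])

        stage = "analysis1"
        sel_matrix = informative.loc[sel_ids]
        sel_informative = sel_matrix.loc[:, sel_matrix.nunique(axis=0) > 1]
        a1 = association.analysis1_logistic(sel_informative, meta_i["kpn"].astype(float))
        a1["significant"] = a1["p_value"] < cfg["alpha"]
        _write(a1, outdir / "analysis1.tsv")

        stage = "analysis2"
        a2 = association.analysis2_lmm(
            sel_informative, meta_i["weight12m"], meta_i["facility"], grm_ids, grm
        )
        a2["significant"] = a2["p_value"] < cfg["alpha"]
        _write(a2, outdir / "analysis2.tsv")

        stage = "group_change"
        cutoff = cfg["kpn_cutoff"]
        if cutoff is None:
            cutoff = int(meta_i.loc[sel_ids, "kpn"].median())
        change = association.group_mean_length_change(
            sel_matrix, meta_i["kpn"].astype(float), cutoff
        )
        _write(change, outdir / "group_mean_length_change.tsv")

        stage = "ihs"
        if panel is not None:
            track = ihs.ihs_scan(panel, ihs.IHSParams(**cfg["ihs"]))
            track = ihs.standardize_ihs(track)
            _write(track, outdir / "ihs_track.tsv")
            windows = ihs.sweep_windows(track, **cfg["sweep"])
            _write(windows, outdir / "sweep_windows.tsv")
        else:
            logger.info("stage=%s skipped: no phased panel", stage)

        stage = "overlap"
        regions = overlap.max_overlap_region(auto)
        regions = regions.assign(samples=regions["samples"].map(lambda s: ",".join(s)))
        _write(regions, outdir / "overlap_regions.tsv")

        stage = "correlations"
        corr = association.cohort_correlations(
            froh_i.loc[sel_ids, "f_roh"],
            meta_i.loc[sel_ids, "kpn"].astype(float),
            meta_i.loc[sel_ids, "weight12m"],
        )
        _write(corr, outdir / "correlations.tsv")

        stage = "manifest"
        import rohselect

        manifest = {
            "package_version": rohselect.__version__,
            "seed": seed,
            "parameter_hash": _param_hash({k: v for k, v in cfg.items() if k != "outdir"}),
            "n_samples": gm.n_samples,
            "n_variants": gm.n_variants,
            "n_segments": int(len(segments)),
            "n_autozygous": int(len(auto)),
            "n_bins": int(matrix.shape[1]),
            "n_informative_bins": int(informative.shape[1]),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir
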