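"""End-to-end orchestration: QC -> rarity filter -> burden -> locus tests ->
breakpoint GWAS (both one-type models) -> CNVRs -> mirror scan -> power table.

A run is driven by a :class:`RunConfig` (YAML-serializable) that either
points at input files or embeds a simulation block; every threshold
defaults to the published value.  The config and a stage-by-stage count log
are written next to the result tables for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import breakpoints as bpmod
from . import burden as burden_mod
from . import loci as loci_mod
from .annotations import ConstraintTrack, read_genes, read_exons
from .calls import (CallSet, qc_filter, filter_rare, read_plink_cnv,
                    read_sample_table, read_probe_map)
from .power import power_grid
from .simulate import SimConfig, PlantedLocus, simulate


class PipelineError(RuntimeError):
    """A pipeline stage failed; message carries the stage name and cause."""


def _to_plain(obj):
    """Recursively convert tuples and numpy scalars for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class Thresholds:
    qc_min_length: int = 20_000
    qc_min_probes: int = 10
    rare_max_freq: float = 0.01
    ro_threshold: float = 0.5
    lead_alpha: float = 0.05
    r2_threshold: float = 0.5
    clump_window: int = 300_000
    cnvr_min_length: int = 20_000
    cnvr_min_probes: int = 10
    mirror_window: int = 300_000
    bonferroni_base_alpha: float = 0.05


@dataclass
class RunConfig:
    """Inputs (paths or a simulate block), thresholds, seed, output dir."""

    simulate: Optional[SimConfig] = None
    calls: Optional[str] = None
    samples: Optional[str] = None
    probes: Optional[str] = None
    genes: Optional[str] = None
    exons: Optional[str] = None
    phylop: Optional[str] = None
    phastcons: Optional[str] = None
    syndromic_loci: Optional[str] = None
    pleiotropic_loci: Optional[str] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    scan_regions: Optional[list] = None   # [(chrom, start, end), ...]
    seed: int = 0
    outdir: str = "rarecnv_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        sim = raw.pop("simulate", None)
        if sim is not None:
            planted = [PlantedLocus(**p) for p in sim.pop("planted_loci", [])]
            sim = SimConfig(planted_loci=planted, **sim)
        return cls(simulate=sim, thresholds=thr, **raw)

    def to_yaml(self, path) -> None:
        raw = _to_plain(dataclasses.asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class RunBundle:
    callset_raw: CallSet
    callset: CallSet                 # QC'd and rarity-filtered
    filter_log: list
    burden_profiles: pd.DataFrame
    burden_results: pd.DataFrame
    locus_results: pd.DataFrame
    scan_dup: pd.DataFrame
    scan_del: pd.DataFrame
    cnvrs: list
    mirror: pd.DataFrame
    power: pd.DataFrame


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        res = simulate(sim)
        ann = res.annotations
        return (res.callset, res.probe_map, ann.genes, ann.phylop,
                ann.phastcons, ann.syndromic, ann.pleiotropic)
    if config.calls is None or config.samples is None:
        raise PipelineError("inputs: need either a simulate block or calls+samples paths")
    samples = read_sample_table(config.samples)
    callset = read_plink_cnv(config.calls, samples=samples)
    probe_map = read_probe_map(config.probes) if config.probes else None
    genes = read_genes(config.genes) if config.genes else None
    phylop = ConstraintTrack.from_bed(config.phylop, "phylop") if config.phylop else None
    phastcons = (ConstraintTrack.from_bed(config.phastcons, "phastcons")
                 if config.phastcons else None)
    syn = loci_mod.read_locus_list(config.syndromic_loci) if config.syndromic_loci else []
    pleio = (loci_mod.read_locus_list(config.pleiotropic_loci)
             if config.pleiotropic_loci else [])
    return callset, probe_map, genes, phylop, phastcons, syn, pleio


def run_all(config: RunConfig, write: bool = True) -> RunBundle:
    """Execute every stage; write TSV/BED outputs, a count log and a summary."""
    stage = "load"
    try:
        (callset_raw, probe_map, genes, phylop, phastcons,
         syndromic, pleiotropic) = _load_inputs(config)
        thr = config.thresholds
        log = []

        stage = "qc"
        callset, rec = qc_filter(callset_raw, thr.qc_min_length, thr.qc_min_probes)
        log.append(rec)
        stage = "rare"
        callset, rec = filter_rare(callset, thr.rare_max_freq, thr.ro_threshold)
        log.append(rec)

        stage = "burden"
        profiles = burden_mod.burden_profiles(callset, genes, phylop, phastcons)
        burden_results = burden_mod.burden_table(profiles, callset.samples)

        stage = "locus"
        frames = []
        for loci in (syndromic, pleiotropic):
            if loci:
                frames.append(loci_mod.locus_scan(
                    callset, loci, alpha=thr.bonferroni_base_alpha))
        locus_results = (pd.concat(frames, ignore_index=True) if frames
                         else pd.DataFrame())

        stage = "breakpoint_gwas"
        bps = bpmod.enumerate_breakpoints(callset)
        scans = {}
        matrices = {}
        full_matrices = {}
        for model in bpmod.MODELS:
            full = bpmod.encode(callset, bps, model)
            full_matrices[model] = full
            mat, rec = bpmod.filter_rare_breakpoints(full, thr.rare_max_freq)
            log.append(rec)
            matrices[model] = mat
            if config.scan_regions:
                parts = [bpmod.scan(mat, region=tuple(r)) for r in config.scan_regions]
                scans[model] = pd.concat(parts, ignore_index=True)
            else:
                scans[model] = bpmod.scan(mat)

        stage = "cnvr"
        cnvrs = []
        if probe_map is not None:
            for model in bpmod.MODELS:
                cnvrs.extend(bpmod.clump_and_define_cnvrs(
                    scans[model], full_matrices[model], probe_map, genes=genes,
                    phylop=phylop, phastcons=phastcons,
                    lead_alpha=thr.lead_alpha, r2_threshold=thr.r2_threshold,
                    window=thr.clump_window, min_length=thr.cnvr_min_length,
                    min_probes=thr.cnvr_min_probes))

        stage = "mirror"
        mirror = bpmod.mirror_scan(scans["dup_only"], scans["del_only"],
                                   window=thr.mirror_window)

        stage = "power"
        n_cases = int((callset.samples["status"] == 1).sum())
        n_controls = int((callset.samples["status"] == 0).sum())
        power = pd.DataFrame(power_grid(n_cases, n_controls))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    bundle = RunBundle(callset_raw, callset, log, profiles, burden_results,
                       locus_results, scans["dup_only"], scans["del_only"],
                       cnvrs, mirror, power)
    if write:
        _write_bundle(config, bundle, matrices)
    return bundle


def _write_bundle(config: RunConfig, b: RunBundle, matrices) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    b.burden_profiles.reset_index().to_csv(out / "burden_profiles.tsv",
                                           sep="\t", index=False)
    b.burden_results.to_csv(out / "burden_results.tsv", sep="\t", index=False)
    b.locus_results.to_csv(out / "locus_results.tsv", sep="\t", index=False)
    for name, df in (("breakpoints_dup.tsv", b.scan_dup),
                     ("breakpoints_del.tsv", b.scan_del)):
        df.to_csv(out / name, sep="\t", index=False)
    cnvr_df = bpmod.cnvr_table(b.cnvrs)
    cnvr_df.to_csv(out / "cnvrs.tsv", sep="\t", index=False)
    if len(cnvr_df):
        cnvr_df[["chrom", "start", "end", "cnvr_id"]].to_csv(
            out / "cnvrs.bed", sep="\t", header=False, index=False)
        _write_cnvr_tracks(out, b, matrices)
    else:
        (out / "cnvrs.bed").write_text("")
    b.mirror.to_csv(out / "mirror_candidates.tsv", sep="\t", index=False)
    b.power.to_csv(out / "power.tsv", sep="\t", index=False)
    loglines = [f"{r.stage}\t{r.n_before}\t{r.n_after}\t{r.removed}"
                for r in b.filter_log]
    (out / "filter_log.tsv").write_text(
        "stage\tn_before\tn_after\tremoved\n" + "\n".join(loglines) + "\n")
    _write_summary(out, config, b)


def _write_cnvr_tracks(out: Path, b: RunBundle, matrices) -> None:
    """Per-CNVR plot data: the association track plus case/control call
    tracks overlapping the span by >= 1 bp."""
    tracks_dir = out / "cnvr_tracks"
    tracks_dir.mkdir(exist_ok=True)
    for r in b.cnvrs:
        scan_df = b.scan_dup if r.model == "dup_only" else b.scan_del
        pad = max(r.length, 40_000)
        sel = ((scan_df["chrom"].astype(str) == r.chrom)
               & (scan_df["pos"] >= r.start - pad)
               & (scan_df["pos"] <= r.end + pad))
        scan_df.loc[sel].to_csv(tracks_dir / f"{r.cnvr_id}_assoc.tsv",
                                sep="\t", index=False)
        cs = matrices[r.model].callset
        calls = cs.calls
        csel = ((calls["cnv_type"] == ("DUP" if r.model == "dup_only" else "DEL"))
                & (calls["chrom"].astype(str) == r.chrom)
                & (calls["start"] <= r.end) & (calls["end"] > r.start))
        sub = calls.loc[csel].copy()
        sub["status"] = cs.samples.loc[sub["sample_id"], "status"].to_numpy()
        sub["cohort"] = (cs.samples.loc[sub["sample_id"], "cohort"].to_numpy()
                         if "cohort" in cs.samples.columns else ".")
        sub.to_csv(tracks_dir / f"{r.cnvr_id}_calls.tsv", sep="\t", index=False)


def _write_summary(out: Path, config: RunConfig, b: RunBundle) -> None:
    n_sig_loci = int(b.locus_results["significant"].sum()) if len(b.locus_results) else 0
    lines = [
        "# rarecnv run summary", "",
        f"- samples: {b.callset.n_samples} "
        f"({int((b.callset.samples['status'] == 1).sum())} cases / "
        f"{int((b.callset.samples['status'] == 0).sum())} controls)",
        f"- calls before filtering: {len(b.callset_raw)}; after QC + rarity: {len(b.callset)}",
        f"- burden metrics tested: {len(b.burden_results)}",
        f"- loci tested: {len(b.locus_results)} (Bonferroni-significant: {n_sig_loci})",
        f"- rare breakpoints scanned: dup {len(b.scan_dup)}, del {len(b.scan_del)}",
        f"- CNVRs emitted: {len(b.cnvrs)}",
        f"- mirror candidates: {len(b.mirror)}",
        f"- seed: {config.seed}", "",
        "Filter stages (stage, before, after):",
    ]
    lines += [f"  {r.stage}: {r.n_before} -> {r.n_after}" for r in b.filter_log]
    (out / "summary.md").write_text("\n".join(lines) + "\n")
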