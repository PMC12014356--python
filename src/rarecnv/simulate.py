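"""Seeded generator of case-control CNV call sets with ANGI-like structure.

The generator emulates a post-calling, array-derived CNV call set for a
two-cohort case-control study: per-sample background CNV counts are Poisson
(0.9 duplications + 0.7 deletions per individual), lengths are log-normal
with median ~102.8 kb, call boundaries snap to a jittered ~2 kb probe grid,
and covariates (cohort, ancestry PC1, sex, lowest BMI, age) mirror the
study design (SWE 3664/3661, ANZUS 3750/1383 cases/controls at full scale).
Background CNVs are sampled independently of case status, so genome-wide
burden is null by construction unless ``burden_shift_sd`` is set.

Risk signal is planted per locus: carrier probability in controls is
``carrier_freq_controls`` and in cases the carrier odds are multiplied by
``odds_ratio`` (retrospective logistic tilt).  Recurrent loci use small
breakpoint jitter; non-recurrent loci (jitter sd large relative to the
locus) produce carrier calls "varying in size", which keeps both the calls
and their breakpoints below the 1% rarity threshold even when case and
control carriers together exceed it.

Everything is driven by one integer seed; identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotations import (ConstraintTrack, PHYLOP_THRESHOLD, PHASTCONS_THRESHOLD,
                          GENE_COLUMNS, EXON_COLUMNS, write_genes, write_exons)
from .calls import (CallSet, ProbeMap, DEL, DUP, write_plink_cnv,
                    write_sample_table, write_probe_map)
from .loci import LocusDefinition, write_locus_list


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class PlantedLocus:
    """A risk (or null) CNV locus planted into the simulated call set."""

    chrom: str
    start: int
    end: int
    cnv_type: str
    carrier_freq_controls: float
    odds_ratio: float = 1.0
    breakpoint_jitter_sd: float = 2_000.0
    bmi_effect: float = 0.0
    locus_id: str = ""

    def __post_init__(self):
        if self.odds_ratio <= 0:
            raise ConfigError("odds_ratio must be positive")
        if not 0 < self.carrier_freq_controls <= 0.01:
            raise ConfigError("carrier_freq_controls must be in (0, 0.01] for rare loci")
        if self.end <= self.start:
            raise ConfigError("locus end must exceed start")
        if not self.locus_id:
            self.locus_id = f"{self.cnv_type}_{self.chrom}_{self.start}"

    @property
    def carrier_freq_cases(self) -> float:
        odds = self.carrier_freq_controls / (1.0 - self.carrier_freq_controls)
        odds *= self.odds_ratio
        return odds / (1.0 + odds)


def mirror_pair(chrom: str, start: int, end: int, *, del_odds_ratio: float,
                del_freq_controls: float, dup_freq_controls: float,
                breakpoint_jitter_sd: float = 2_000.0) -> tuple:
    """A deletion-risk / duplication-protective pair with reciprocal odds ratios."""
    dele = PlantedLocus(chrom, start, end, DEL, del_freq_controls,
                        odds_ratio=del_odds_ratio,
                        breakpoint_jitter_sd=breakpoint_jitter_sd,
                        locus_id=f"mirror_{chrom}_{start}_DEL")
    dup = PlantedLocus(chrom, start, end, DUP, dup_freq_controls,
                       odds_ratio=1.0 / del_odds_ratio,
                       breakpoint_jitter_sd=breakpoint_jitter_sd,
                       locus_id=f"mirror_{chrom}_{start}_DUP")
    return dele, dup


_DEFAULT_CHROMS = {str(i): 100_000_000 for i in range(1, 7)}
# ANGI cohort composition: SWE 3664 cases / 3661 controls, ANZUS 3750 / 1383
_DEFAULT_COHORTS = {"SWE": (3664 / 7414, 3661 / 5044),
                    "ANZUS": (3750 / 7414, 1383 / 5044)}


@dataclass
class SimConfig:
    """All knobs of the generator; the seed fully determines the output."""

    n_cases: int = 7414
    n_controls: int = 5044
    dup_rate: float = 0.9
    del_rate: float = 0.7
    length_median_bp: float = 102_800.0
    length_sigma: float = 0.7            # log-scale sd of the log-normal length law
    probe_spacing: float = 2_000.0
    chrom_lengths: dict = field(default_factory=lambda: dict(_DEFAULT_CHROMS))
    planted_loci: list = field(default_factory=list)
    cohort_fractions: dict = field(default_factory=lambda: dict(_DEFAULT_COHORTS))
    pc1_effect_on_small_burden: float = 0.05   # log-rate per PC1 sd, CNVs < 100 kb
    small_cnv_cutoff: int = 100_000
    burden_shift_sd: float = 0.0         # case CNV-count shift in Poisson-sd units
    sex_female_frac_cases: float = 0.98
    sex_female_frac_controls: float = 0.94
    bmi_cases: tuple = (15.2, 2.1)
    bmi_controls: tuple = (20.9, 2.0)
    age_cases: tuple = (15.6, 4.4)
    age_controls: tuple = (21.1, 8.2)
    # annotation knobs
    frac_haploinsufficient: float = 0.165
    frac_triplosensitive: float = 0.069
    constrained_fraction: float = 0.0326
    gene_mean_span: float = 30_000.0
    gene_mean_gap: float = 70_000.0
    n_null_loci: int = 3                 # extra null entries per locus list
    seed: int = 0

    def __post_init__(self):
        if self.dup_rate < 0 or self.del_rate < 0:
            raise ConfigError("CNV rates must be non-negative")
        for a, b in itertools.combinations(self.planted_loci, 2):
            if (a.cnv_type == b.cnv_type and str(a.chrom) == str(b.chrom)
                    and a.start < b.end and b.start < a.end):
                raise ConfigError(
                    f"planted loci of the same type overlap: {a.locus_id}, {b.locus_id}")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def genome_size(self) -> int:
        return sum(int(v) for v in self.chrom_lengths.values())


@dataclass
class Annotations:
    genes: pd.DataFrame
    exons: pd.DataFrame
    phylop: ConstraintTrack
    phastcons: ConstraintTrack
    syndromic: list
    pleiotropic: list


@dataclass
class SimResult:
    callset: CallSet
    probe_map: ProbeMap
    annotations: Annotations
    config: SimConfig

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_plink_cnv(self.callset, out / "calls.cnv")
        write_sample_table(self.callset.samples, out / "samples.tsv")
        write_probe_map(self.probe_map, out / "probes.tsv")
        write_genes(self.annotations.genes, out / "genes.tsv")
        write_exons(self.annotations.exons, out / "exons.tsv")
        self.annotations.phylop.to_bed(out / "phylop.bed")
        self.annotations.phastcons.to_bed(out / "phastcons.bed")
        write_locus_list(self.annotations.syndromic, out / "syndromic_loci.tsv")
        write_locus_list(self.annotations.pleiotropic, out / "pleiotropic_loci.tsv")


# ---------------------------------------------------------------------------

def _make_samples(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_samples
    ids = np.array([f"S{i:06d}" for i in range(1, n + 1)], dtype=object)
    status = np.r_[np.ones(cfg.n_cases, dtype=np.int64),
                   np.zeros(cfg.n_controls, dtype=np.int64)]
    cohorts = list(cfg.cohort_fractions)
    p_case = np.array([cfg.cohort_fractions[c][0] for c in cohorts], dtype=float)
    p_ctrl = np.array([cfg.cohort_fractions[c][1] for c in cohorts], dtype=float)
    cohort = np.empty(n, dtype=object)
    cohort[status == 1] = rng.choice(cohorts, size=cfg.n_cases, p=p_case / p_case.sum())
    cohort[status == 0] = rng.choice(cohorts, size=cfg.n_controls, p=p_ctrl / p_ctrl.sum())
    pc1 = rng.normal(size=n)
    sex = np.where(
        rng.random(n) < np.where(status == 1, cfg.sex_female_frac_cases,
                                 cfg.sex_female_frac_controls), "F", "M")
    bmi = np.where(status == 1,
                   rng.normal(cfg.bmi_cases[0], cfg.bmi_cases[1], n),
                   rng.normal(cfg.bmi_controls[0], cfg.bmi_controls[1], n))
    age = np.where(status == 1,
                   rng.normal(cfg.age_cases[0], cfg.age_cases[1], n),
                   rng.normal(cfg.age_controls[0], cfg.age_controls[1], n))
    return pd.DataFrame(
        {"status": status, "sex": sex, "cohort": cohort, "pc1": pc1,
         "bmi_lowest": np.round(bmi, 2), "age": np.round(np.abs(age), 1)},
        index=pd.Index(ids, name="sample_id"))


def _make_probe_map(cfg: SimConfig, rng: np.random.Generator) -> ProbeMap:
    positions = {}
    for chrom, length in cfg.chrom_lengths.items():
        n_exp = int(length / cfg.probe_spacing * 1.2) + 10
        gaps = rng.exponential(cfg.probe_spacing, size=n_exp)
        pos = np.unique(np.cumsum(gaps).astype(np.int64))
        positions[str(chrom)] = pos[pos < int(length)]
    return ProbeMap(positions)


def _snap_to_probes(chroms, starts, ends, probe_map: ProbeMap):
    """Snap call boundaries to probe positions; returns starts, ends, n_probes.

    A call [p_i, p_j) spans probes i..j-1, so n_probes = j - i, matching the
    convention that a ~20 kb call on a ~2 kb grid carries ~10 probes.
    """
    out_s = np.empty(len(starts), dtype=np.int64)
    out_e = np.empty(len(starts), dtype=np.int64)
    out_np = np.empty(len(starts), dtype=np.int64)
    chroms = np.asarray(chroms, dtype=object)
    for chrom in pd.unique(chroms):
        pos = probe_map.positions[str(chrom)]
        m = chroms == chrom
        i = np.clip(np.searchsorted(pos, starts[m], "left"), 0, len(pos) - 2)
        j = np.clip(np.searchsorted(pos, ends[m], "left"), i + 1, len(pos) - 1)
        out_s[m] = pos[i]
        out_e[m] = pos[j]
        out_np[m] = j - i
    return out_s, out_e, out_np


def _truncated_lognormal(rng, n, mu, sigma, lower=None, upper=None):
    """Log-normal lengths restricted to an interval, by inverse-CDF sampling."""
    lo = 0.0 if lower is None else norm.cdf((np.log(lower) - mu) / sigma)
    hi = 1.0 if upper is None else norm.cdf((np.log(upper) - mu) / sigma)
    u = rng.uniform(lo, hi, size=n)
    return np.exp(mu + sigma * norm.ppf(u))


def _background_calls(cfg: SimConfig, samples: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    mu = np.log(cfg.length_median_bp)
    p_small = norm.cdf((np.log(cfg.small_cnv_cutoff) - mu) / cfg.length_sigma)
    chroms = list(cfg.chrom_lengths)
    chrom_len = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    p_chrom = chrom_len / chrom_len.sum()
    status = samples["status"].to_numpy()
    pc1 = samples["pc1"].to_numpy()
    shift = np.where(status == 1, 1.0 + cfg.burden_shift_sd / np.sqrt(
        max(cfg.dup_rate + cfg.del_rate, 1e-9)), 1.0)
    frames = []
    for cnv_type, rate in ((DUP, cfg.dup_rate), (DEL, cfg.del_rate)):
        for small in (True, False):
            base = rate * (p_small if small else 1.0 - p_small)
            lam = base * shift
            if small:
                lam = lam * np.exp(cfg.pc1_effect_on_small_burden * pc1)
            counts = rng.poisson(lam)
            total = int(counts.sum())
            if total == 0:
                continue
            sample_idx = np.repeat(np.arange(len(samples)), counts)
            lengths = _truncated_lognormal(
                rng, total, mu, cfg.length_sigma,
                upper=cfg.small_cnv_cutoff if small else None,
                lower=None if small else cfg.small_cnv_cutoff)
            ci = rng.choice(len(chroms), size=total, p=p_chrom)
            max_start = np.maximum(chrom_len[ci] - lengths, 1.0)
            starts = (rng.random(total) * max_start).astype(np.int64)
            frames.append(pd.DataFrame({
                "sample_id": samples.index.to_numpy()[sample_idx],
                "chrom": np.array(chroms, dtype=object)[ci],
                "start": starts,
                "end": starts + lengths.astype(np.int64),
                "cnv_type": cnv_type,
            }))
    if not frames:
        return pd.DataFrame(columns=["sample_id", "chrom", "start", "end", "cnv_type"])
    return pd.concat(frames, ignore_index=True)


def _planted_calls(cfg: SimConfig, samples: pd.DataFrame,
                   rng: np.random.Generator) -> pd.DataFrame:
    status = samples["status"].to_numpy()
    frames = []
    for locus in cfg.planted_loci:
        freq = np.where(status == 1, locus.carrier_freq_cases,
                        locus.carrier_freq_controls)
        carriers = np.flatnonzero(rng.random(len(samples)) < freq)
        if len(carriers) == 0:
            continue
        sd = locus.breakpoint_jitter_sd
        starts = np.empty(len(carriers), dtype=np.int64)
        ends = np.empty(len(carriers), dtype=np.int64)
        todo = np.arange(len(carriers))
        chrom_len = int(cfg.chrom_lengths[str(locus.chrom)])
        while len(todo):
            s = rng.normal(locus.start, sd, size=len(todo)).round().astype(np.int64)
            e = rng.normal(locus.end, sd, size=len(todo)).round().astype(np.int64)
            ok = (s < e) & (s < locus.end) & (e > locus.start)  # >=1 bp locus overlap
            ok &= (s >= 0) & (e <= chrom_len)
            starts[todo[ok]] = s[ok]
            ends[todo[ok]] = e[ok]
            todo = todo[~ok]
        frames.append(pd.DataFrame({
            "sample_id": samples.index.to_numpy()[carriers],
            "chrom": str(locus.chrom),
            "start": starts,
            "end": ends,
            "cnv_type": locus.cnv_type,
        }))
        if locus.bmi_effect and "bmi_lowest" in samples.columns:
            samples.loc[samples.index[carriers], "bmi_lowest"] += locus.bmi_effect
    if not frames:
        return pd.DataFrame(columns=["sample_id", "chrom", "start", "end", "cnv_type"])
    return pd.concat(frames, ignore_index=True)


def simulate(cfg: SimConfig) -> SimResult:
    """Generate a full synthetic study: calls, samples, probes, annotations."""
    root = np.random.SeedSequence(cfg.seed)
    rng_samples, rng_probes, rng_bg, rng_planted, rng_annot = (
        np.random.default_rng(s) for s in root.spawn(5))
    samples = _make_samples(cfg, rng_samples)
    probe_map = _make_probe_map(cfg, rng_probes)

    bg = _background_calls(cfg, samples, rng_bg)
    planted = _planted_calls(cfg, samples, rng_planted)
    calls = pd.concat([bg, planted], ignore_index=True)
    if len(calls):
        s, e, n_probes = _snap_to_probes(
            calls["chrom"].to_numpy(object), calls["start"].to_numpy(np.int64),
            calls["end"].to_numpy(np.int64), probe_map)
        calls["start"], calls["end"], calls["n_probes"] = s, e, n_probes
    else:
        calls["n_probes"] = pd.Series(dtype=np.int64)
    calls["score"] = np.nan
    calls = calls.sort_values(
        ["chrom", "start", "end", "sample_id", "cnv_type"]).reset_index(drop=True)
    callset = CallSet(calls, samples, genome_build="synthetic")
    annotations = make_annotations(cfg, rng=rng_annot)
    return SimResult(callset, probe_map, annotations, cfg)


# ---------------------------------------------------------------------------
# annotations

def make_annotations(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> Annotations:
    """Genes with pHaplo/pTriplo and exons, constraint tracks, locus lists.

    Standalone calls derive the stream from ``cfg.seed``; :func:`simulate`
    passes its own spawned stream so one seed drives everything.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[4])
    genes, exons = _make_genes(cfg, rng)
    phylop = _make_track(cfg, rng, "phylop", PHYLOP_THRESHOLD, 9.28)
    phastcons = _make_track(cfg, rng, "phastcons", PHASTCONS_THRESHOLD, 1.0)
    syndromic, pleiotropic = _make_locus_lists(cfg, rng)
    return Annotations(genes, exons, phylop, phastcons, syndromic, pleiotropic)


def _make_genes(cfg: SimConfig, rng: np.random.Generator):
    rows, exon_rows = [], []
    gid = 0
    for chrom, length in cfg.chrom_lengths.items():
        pos = 0
        while True:
            pos += int(rng.exponential(cfg.gene_mean_gap)) + 1_000
            span = int(rng.exponential(cfg.gene_mean_span)) + 2_000
            if pos + span >= length:
                break
            gid += 1
            name = f"G{gid:05d}"
            phaplo = (rng.uniform(0.86, 1.0) if rng.random() < cfg.frac_haploinsufficient
                      else rng.uniform(0.0, 0.86))
            ptriplo = (rng.uniform(0.94, 1.0) if rng.random() < cfg.frac_triplosensitive
                       else rng.uniform(0.0, 0.94))
            rows.append((str(chrom), pos, pos + span, name,
                         round(phaplo, 4), round(ptriplo, 4)))
            n_ex = 1 + rng.poisson(4)
            ex_starts = np.sort(rng.integers(pos, pos + span, size=n_ex))
            for es in ex_starts:
                ee = min(es + int(rng.uniform(100, 2_000)), pos + span)
                if ee > es:
                    exon_rows.append((str(chrom), int(es), int(ee), name))
            pos += span
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    exons = pd.DataFrame(exon_rows, columns=EXON_COLUMNS)
    return genes, exons


def _make_track(cfg: SimConfig, rng: np.random.Generator, name: str,
                threshold: float, score_max: float) -> ConstraintTrack:
    mean_len = 500.0
    rows = []
    for chrom, length in cfg.chrom_lengths.items():
        n_iv = int(cfg.constrained_fraction * length / mean_len)
        if n_iv == 0:
            continue
        starts = np.sort(rng.integers(0, int(length), size=n_iv))
        lens = (rng.exponential(mean_len - 50.0, size=n_iv) + 50.0).astype(np.int64)
        ends = np.minimum(starts + lens, int(length))
        scores = np.round(rng.uniform(threshold, score_max, size=n_iv), 3)
        rows.append(pd.DataFrame({"chrom": str(chrom), "start": starts,
                                  "end": ends, "score": scores}))
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["chrom", "start", "end", "score"])
    return ConstraintTrack(df, name=name)


def _make_locus_lists(cfg: SimConfig, rng: np.random.Generator):
    """Syndromic (two-sided, 50%-overlap rule) and pleiotropic (one-sided
    segment rule) locus lists: one entry per planted locus plus null entries."""
    syndromic, pleiotropic = [], []
    chroms = list(cfg.chrom_lengths)
    for locus in cfg.planted_loci:
        syndromic.append(LocusDefinition(
            locus_id=f"syn_{locus.locus_id}", chrom=str(locus.chrom),
            start=locus.start, end=locus.end, cnv_type=locus.cnv_type,
            rule="syndromic_50", sided="two"))
        seg_len = max(locus.end - locus.start, 200_000)
        mid = (locus.start + locus.end) // 2
        pleiotropic.append(LocusDefinition(
            locus_id=f"pleio_{locus.locus_id}", chrom=str(locus.chrom),
            start=max(0, mid - seg_len // 2), end=mid + seg_len // 2,
            cnv_type=locus.cnv_type, rule="pleiotropic_seg", sided="one"))
    for i in range(cfg.n_null_loci):
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = int(rng.uniform(500_000, 2_000_000))
        start = int(rng.integers(0, int(cfg.chrom_lengths[chrom]) - size))
        cnv_type = DEL if rng.random() < 0.5 else DUP
        syndromic.append(LocusDefinition(
            locus_id=f"syn_null_{i}", chrom=chrom, start=start, end=start + size,
            cnv_type=cnv_type, rule="syndromic_50", sided="two"))
        seg = max(size, 200_000)
        pleiotropic.append(LocusDefinition(
            locus_id=f"pleio_null_{i}", chrom=chrom, start=start, end=start + seg,
            cnv_type=cnv_type, rule="pleiotropic_seg", sided="one"))
    return syndromic, pleiotropic
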