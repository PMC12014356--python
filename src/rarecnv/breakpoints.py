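"""CNV-type-specific rare-breakpoint GWAS and CNV-region (CNVR) definition.

Breakpoints are the unique start/end positions of called CNVs.  Under the
duplication-only model a sample is ALT at a position covered by one of its
duplications, MISSING if only a deletion covers it, REF otherwise; the
deletion-only model uses the reciprocal encoding.  Extra copies beyond one
event do not change the entry, and a call covers both of its own endpoints
(closed right end), so every call is an observation at its own breakpoints.

Rare (frequency < 1% among non-missing samples) breakpoints are tested with
Firth regression (status ~ ALT-carrier + cohort + pc1; missing samples
excluded per test).  CNVRs are then defined by greedy PLINK-style clumping:
the best remaining nominally significant (p <= 0.05) breakpoint becomes a
lead, breakpoints within +-300 kb with r^2 >= 0.5 to the lead join it, and
the resulting span is kept if it is >= 20 kb, spans >= 10 probes and the
lead effect is in the risk direction (OR > 1).  Opposite-direction nominal
signals of the two models at nearby positions are flagged as mirror-effect
candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import ConstraintTrack, PHYLOP_THRESHOLD, PHASTCONS_THRESHOLD
from .calls import CallSet, DEL, DUP, FilterRecord, ProbeMap
from .firth import firth_fit, firth_scan_columns, build_design

MODELS = ("dup_only", "del_only")
_MODEL_TYPE = {"dup_only": DUP, "del_only": DEL}


def enumerate_breakpoints(callset: CallSet) -> pd.DataFrame:
    """Deduplicated union of all call start/end positions, per chromosome.

    ``origin`` records whether the position is a start, an end, or both.
    """
    calls = callset.calls
    if len(calls) == 0:
        return pd.DataFrame(columns=["chrom", "pos", "origin"])
    starts = calls[["chrom", "start"]].rename(columns={"start": "pos"}).drop_duplicates()
    ends = calls[["chrom", "end"]].rename(columns={"end": "pos"}).drop_duplicates()
    starts["origin"] = "start"
    ends["origin"] = "end"
    both = pd.concat([starts, ends], ignore_index=True)
    agg = both.groupby(["chrom", "pos"], sort=True)["origin"].agg(
        lambda s: "both" if s.nunique() > 1 else s.iloc[0])
    out = agg.reset_index()
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


@dataclass
class BreakpointMatrix:
    """Sparse samples x breakpoints matrix under a one-CNV-type model.

    Per breakpoint, ``alt_sets[i]`` holds indices of samples with a
    model-type call covering the position and ``miss_sets[i]`` those covered
    only by an opposite-type call (missing genotype).  Everyone else is REF.
    """

    model: str
    breakpoints: pd.DataFrame            # chrom, pos, origin
    alt_sets: list
    miss_sets: list
    callset: CallSet

    @property
    def n_samples(self) -> int:
        return self.callset.n_samples

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints)

    def subset(self, keep: np.ndarray) -> "BreakpointMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            breakpoints=self.breakpoints.iloc[keep].reset_index(drop=True),
            alt_sets=[self.alt_sets[i] for i in keep],
            miss_sets=[self.miss_sets[i] for i in keep])

    def entry(self, sample_idx: int, bp_idx: int) -> str:
        if sample_idx in self.alt_sets[bp_idx]:
            return "ALT"
        if sample_idx in self.miss_sets[bp_idx]:
            return "MISSING"
        return "REF"


def _expand_ranges(lo: np.ndarray, hi: np.ndarray):
    """Concatenated arange(lo_i, hi_i) plus the repeated row index."""
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return (np.empty(0, dtype=np.int64),) * 2
    rep_lo = np.repeat(lo, counts)
    base = np.repeat(np.cumsum(counts) - counts, counts)
    inner = rep_lo + (np.arange(total) - base)
    rows = np.repeat(np.arange(len(lo)), counts)
    return inner, rows


def encode(callset: CallSet, breakpoints: pd.DataFrame, model: str) -> BreakpointMatrix:
    """Build the one-type pseudo-genotype matrix.

    A position ``p`` is covered by call ``[s, e)`` iff ``s <= p <= e`` — the
    end coordinate counts, so a call registers at both of its breakpoints.
    A sample carrying both types over ``p`` is ALT (model type wins).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    model_type = _MODEL_TYPE[model]
    sample_codes = callset.samples.index.get_indexer(callset.calls["sample_id"])
    nbp = len(breakpoints)
    alt_pairs_bp, alt_pairs_s = [], []
    opp_pairs_bp, opp_pairs_s = [], []
    bp_index = breakpoints.reset_index(drop=True)
    for chrom, bsub in bp_index.groupby("chrom", sort=False):
        pos = bsub["pos"].to_numpy(np.int64)
        global_idx = bsub.index.to_numpy()
        csub = callset.calls[callset.calls["chrom"] == chrom]
        if len(csub) == 0:
            continue
        s = csub["start"].to_numpy(np.int64)
        e = csub["end"].to_numpy(np.int64)
        lo = np.searchsorted(pos, s, "left")
        hi = np.searchsorted(pos, e, "right")      # inclusive end
        inner, rows = _expand_ranges(lo, hi)
        codes = sample_codes[csub.index.to_numpy()][rows]
        is_model = (csub["cnv_type"].to_numpy() == model_type)[rows]
        alt_pairs_bp.append(global_idx[inner[is_model]])
        alt_pairs_s.append(codes[is_model])
        opp_pairs_bp.append(global_idx[inner[~is_model]])
        opp_pairs_s.append(codes[~is_model])

    def collect(bp_list, s_list):
        if not bp_list:
            return [np.empty(0, dtype=np.int64)] * nbp
        bp = np.concatenate(bp_list)
        sc = np.concatenate(s_list)
        if len(bp) == 0:
            return [np.empty(0, dtype=np.int64)] * nbp
        order = np.lexsort((sc, bp))
        bp, sc = bp[order], sc[order]
        dedup = np.r_[True, (bp[1:] != bp[:-1]) | (sc[1:] != sc[:-1])]
        bp, sc = bp[dedup], sc[dedup]
        sets = [np.empty(0, dtype=np.int64)] * nbp
        bounds = np.flatnonzero(np.r_[True, bp[1:] != bp[:-1]])
        for i, start_i in enumerate(bounds):
            end_i = bounds[i + 1] if i + 1 < len(bounds) else len(bp)
            sets[bp[start_i]] = sc[start_i:end_i].astype(np.int64)
        return sets

    alt_sets = collect(alt_pairs_bp, alt_pairs_s)
    opp_sets = collect(opp_pairs_bp, opp_pairs_s)
    miss_sets = [np.setdiff1d(o, a, assume_unique=True)
                 for a, o in zip(alt_sets, opp_sets)]
    return BreakpointMatrix(model, bp_index, alt_sets, miss_sets, callset)


def breakpoint_frequency(matrix: BreakpointMatrix) -> pd.DataFrame:
    """ALT count and frequency per breakpoint (denominator: non-missing samples)."""
    n = matrix.n_samples
    alt = np.array([len(a) for a in matrix.alt_sets], dtype=np.int64)
    miss = np.array([len(m) for m in matrix.miss_sets], dtype=np.int64)
    denom = n - miss
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, alt / denom, np.nan)
    out = matrix.breakpoints.copy()
    out["alt_count"] = alt
    out["n_nonmissing"] = denom
    out["freq"] = freq
    return out


def filter_rare_breakpoints(matrix: BreakpointMatrix, max_freq: float = 0.01
                            ) -> tuple[BreakpointMatrix, FilterRecord]:
    """Keep testable rare breakpoints: 0 < ALT frequency < ``max_freq``.

    All-missing columns are excluded with a warning; 0-ALT columns are
    untestable and dropped.
    """
    freq = breakpoint_frequency(matrix)
    all_missing = freq["n_nonmissing"] == 0
    if all_missing.any():
        warnings.warn(f"{int(all_missing.sum())} all-missing breakpoint(s) excluded")
    keep = ((freq["alt_count"] > 0) & ~all_missing
            & (freq["freq"] < max_freq)).to_numpy()
    out = matrix.subset(keep)
    return out, FilterRecord(f"rare_breakpoints[{matrix.model}]",
                             matrix.n_breakpoints, out.n_breakpoints)


def scan(matrix: BreakpointMatrix, covariates=("cohort", "pc1"),
         region: Optional[tuple] = None, chunk: int = 256) -> pd.DataFrame:
    """Firth association scan over (optionally region-restricted) breakpoints.

    ``region`` is (chrom, start, end) limiting the scanned columns.
    Identical (ALT set, MISSING set) columns — e.g. the two breakpoints of a
    singleton call — are fitted once.  The result carries the Bonferroni
    threshold 0.05 / n_tested in ``df.attrs["bonferroni_alpha"]``.
    """
    m = matrix
    if region is not None:
        chrom, start, end = region
        bp = m.breakpoints
        m = m.subset(((bp["chrom"].astype(str) == str(chrom))
                      & (bp["pos"] >= start) & (bp["pos"] <= end)).to_numpy())
    samples = m.callset.samples
    y = samples["status"].to_numpy(float)
    Z, _ = build_design(samples, covariates)

    keys = {}
    uniq_alt, uniq_miss, col_of = [], [], np.zeros(m.n_breakpoints, dtype=np.int64)
    for i, (a, mi) in enumerate(zip(m.alt_sets, m.miss_sets)):
        key = (a.tobytes(), mi.tobytes())
        if key not in keys:
            keys[key] = len(uniq_alt)
            uniq_alt.append(a)
            uniq_miss.append(mi)
        col_of[i] = keys[key]

    res = firth_scan_columns(Z, y, uniq_alt, uniq_miss, chunk=chunk)
    out = m.breakpoints.copy()
    out["model"] = m.model
    for name, key in (("alt_case", "alt_case"), ("alt_control", "alt_control"),
                      ("n_eff", "n_eff"), ("beta", "beta"), ("se", "se"),
                      ("OR", "or_"), ("p_two_sided", "p_two"),
                      ("p_one_sided", "p_one")):
        out[name] = res[key][col_of]
    out["converged"] = res["converged"][col_of]
    out.attrs["bonferroni_alpha"] = 0.05 / max(len(out), 1)
    out.attrs["model"] = m.model
    return out


def ld_r2(matrix: BreakpointMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of ALT indicators over pairwise-complete
    samples; 0.0 when either column is constant on the shared support."""
    n = matrix.n_samples
    x = np.zeros(n)
    yv = np.zeros(n)
    x[matrix.alt_sets[i]] = 1.0
    yv[matrix.alt_sets[j]] = 1.0
    keep = np.ones(n, dtype=bool)
    keep[matrix.miss_sets[i]] = False
    keep[matrix.miss_sets[j]] = False
    x, yv = x[keep], yv[keep]
    if len(x) < 2 or x.std() == 0 or yv.std() == 0:
        return 0.0
    r = np.corrcoef(x, yv)[0, 1]
    return float(r * r)


@dataclass
class CnvRegion:
    """An associated CNV region around a lead breakpoint."""

    cnvr_id: str
    chrom: str
    start: int
    end: int
    model: str
    lead_pos: int
    n_breakpoints: int
    length: int
    n_probes: int
    n_case_carriers: int
    n_control_carriers: int
    or_: float
    ci_low: float
    ci_high: float
    p: float
    genes: list = field(default_factory=list)
    max_phylop: float = float("nan")
    max_phastcons: float = float("nan")
    constrained_prop: float = float("nan")


def _span_carriers(callset: CallSet, model: str, chrom: str,
                   start: int, end: int) -> tuple[int, int]:
    """Case/control counts of samples with a model-type call overlapping the
    span by >= 1 bp (direct recount from the calls, not from the matrix)."""
    df = callset.calls
    sel = ((df["cnv_type"] == _MODEL_TYPE[model])
           & (df["chrom"].astype(str) == str(chrom))
           & (df["start"] <= end) & (df["end"] > start))
    ids = pd.unique(df.loc[sel, "sample_id"])
    status = callset.samples.loc[ids, "status"]
    return int((status == 1).sum()), int((status == 0).sum())


def clump_and_define_cnvrs(scan_df: pd.DataFrame, matrix: BreakpointMatrix,
                           probe_map: ProbeMap,
                           genes: Optional[pd.DataFrame] = None,
                           phylop: Optional[ConstraintTrack] = None,
                           phastcons: Optional[ConstraintTrack] = None,
                           lead_alpha: float = 0.05, r2_threshold: float = 0.5,
                           window: int = 300_000, min_length: int = 20_000,
                           min_probes: int = 10, ci: bool = True,
                           covariates=("cohort", "pc1")) -> list:
    """Greedy p-ascending clumping of nominally significant rare breakpoints.

    The best remaining breakpoint with p <= ``lead_alpha`` (ties broken by
    genomic position) becomes a lead; matrix breakpoints within ``window``
    bp and r^2 >= ``r2_threshold`` to the lead are assigned to it and leave
    candidacy.  Leads must be *rare* breakpoints (they come from the scan),
    but ``matrix`` should be the full encoded matrix: the span-defining
    partners are any correlated breakpoints, including ones whose carrier
    frequency sits above the rarity bound — a region's interior positions
    are covered by every carrier and would otherwise be excluded from the
    very CNVR they define.  The CNVR span is [min, max] over the lead and its assigned
    breakpoints, and is kept only if >= ``min_length`` bp, >= ``min_probes``
    probes and the lead OR exceeds 1 (risk direction).  The reported OR/CI/p
    are the lead's, the CI refitted with profile penalized likelihood.
    """
    bp = matrix.breakpoints
    pos_index = {}
    for k, (c, p_) in enumerate(zip(bp["chrom"].astype(str), bp["pos"])):
        pos_index[(c, int(p_))] = k

    cand = scan_df[scan_df["p_two_sided"] <= lead_alpha].copy()
    cand = cand.sort_values(["p_two_sided", "chrom", "pos"],
                            kind="stable").reset_index(drop=True)
    assigned = set()
    regions = []
    samples = matrix.callset.samples
    y = samples["status"].to_numpy(float)
    Z, _ = build_design(samples, covariates)

    for row in cand.itertuples(index=False):
        key = (str(row.chrom), int(row.pos))
        if key in pos_index and pos_index[key] in assigned:
            continue
        lead_idx = pos_index.get(key)
        if lead_idx is None:
            continue
        same = bp.index[(bp["chrom"].astype(str) == str(row.chrom))
                        & (bp["pos"] >= row.pos - window)
                        & (bp["pos"] <= row.pos + window)].to_numpy()
        members = [lead_idx]
        for k in same:
            if k == lead_idx or k in assigned:
                continue
            if ld_r2(matrix, lead_idx, k) >= r2_threshold:
                members.append(int(k))
        assigned.update(members)
        span_pos = bp["pos"].to_numpy()[members]
        start, end = int(span_pos.min()), int(span_pos.max())
        length = end - start
        nprobes = probe_map.count(str(row.chrom), start, end + 1)
        if length < min_length or nprobes < min_probes or row.OR <= 1.0:
            continue
        ci_lo, ci_hi = np.nan, np.nan
        if ci:
            mask = np.ones(matrix.n_samples, dtype=bool)
            mask[matrix.miss_sets[lead_idx]] = False
            mask[matrix.alt_sets[lead_idx]] = True
            carrier = np.zeros(matrix.n_samples)
            carrier[matrix.alt_sets[lead_idx]] = 1.0
            X = np.column_stack([Z[:, :1], carrier, Z[:, 1:]])
            fit = firth_fit(X, y, test_idx=[1], ci=True,
                            weights=mask.astype(float))
            ci_lo, ci_hi = np.exp(fit.ci_low[1]), np.exp(fit.ci_high[1])
        n_case, n_ctrl = _span_carriers(matrix.callset, matrix.model,
                                        str(row.chrom), start, end)
        gene_ids = []
        if genes is not None:
            gsub = genes[(genes["chrom"].astype(str) == str(row.chrom))
                         & (genes["start"] < end) & (genes["end"] > start)]
            gene_ids = list(gsub["gene_id"])
        maxp = phylop.max_score(str(row.chrom), start, end) if phylop else float("nan")
        maxc = phastcons.max_score(str(row.chrom), start, end) if phastcons else float("nan")
        cprop = (phastcons.coverage(str(row.chrom), start, end, PHASTCONS_THRESHOLD)
                 / length if phastcons else float("nan"))
        regions.append(CnvRegion(
            cnvr_id=f"{matrix.model}_{row.chrom}_{start}",
            chrom=str(row.chrom), start=start, end=end, model=matrix.model,
            lead_pos=int(row.pos), n_breakpoints=len(members), length=length,
            n_probes=nprobes, n_case_carriers=n_case, n_control_carriers=n_ctrl,
            or_=float(row.OR), ci_low=float(ci_lo), ci_high=float(ci_hi),
            p=float(row.p_two_sided), genes=gene_ids,
            max_phylop=float(maxp), max_phastcons=float(maxc),
            constrained_prop=float(cprop)))
    return regions


def cnvr_table(regions: Sequence[CnvRegion]) -> pd.DataFrame:
    """Result table mirroring the published CNVR columns."""
    rows = [{
        "cnvr_id": r.cnvr_id, "chrom": r.chrom, "start": r.start, "end": r.end,
        "model": r.model, "genotype": "Duplication" if r.model == "dup_only" else "Deletion",
        "lead_pos": r.lead_pos, "length_kb": r.length / 1_000.0,
        "n_probes": r.n_probes, "n_case_carriers": r.n_case_carriers,
        "n_control_carriers": r.n_control_carriers, "OR": r.or_,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
        "genes": ";".join(r.genes) if r.genes else ".",
        "max_phylop": r.max_phylop, "max_phastcons": r.max_phastcons,
        "constrained_prop": r.constrained_prop,
    } for r in regions]
    columns = ["cnvr_id", "chrom", "start", "end", "model", "genotype",
               "lead_pos", "length_kb", "n_probes", "n_case_carriers",
               "n_control_carriers", "OR", "ci_low", "ci_high", "p", "genes",
               "max_phylop", "max_phastcons", "constrained_prop"]
    return pd.DataFrame(rows, columns=columns)


def mirror_scan(results_dup: pd.DataFrame, results_del: pd.DataFrame,
                window: int = 300_000, alpha: float = 0.05) -> pd.DataFrame:
    """Nearby breakpoint pairs nominally significant in both one-type models
    with opposite effect directions (deletion-risk / duplication-protection
    or the reverse) — candidate mirror-effect loci."""
    dsig = results_dup[(results_dup["p_two_sided"] < alpha)
                       & np.isfinite(results_dup["beta"])]
    lsig = results_del[(results_del["p_two_sided"] < alpha)
                       & np.isfinite(results_del["beta"])]
    rows = []
    for drow in dsig.itertuples(index=False):
        near = lsig[(lsig["chrom"].astype(str) == str(drow.chrom))
                    & (np.abs(lsig["pos"] - drow.pos) <= window)]
        for lrow in near.itertuples(index=False):
            if drow.beta * lrow.beta < 0:
                rows.append({
                    "chrom": str(drow.chrom), "pos_dup": int(drow.pos),
                    "pos_del": int(lrow.pos),
                    "distance": int(abs(drow.pos - lrow.pos)),
                    "or_dup": drow.OR, "p_dup": drow.p_two_sided,
                    "or_del": lrow.OR, "p_del": lrow.p_two_sided,
                    "direction": ("del_risk_dup_protective" if lrow.beta > 0
                                  else "dup_risk_del_protective")})
    return pd.DataFrame(rows, columns=["chrom", "pos_dup", "pos_del", "distance",
                                       "or_dup", "p_dup", "or_del", "p_del",
                                       "direction"])
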