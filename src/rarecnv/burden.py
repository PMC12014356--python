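"""Genome-wide per-sample rCNV burden metrics and covariate-adjusted tests.

Five burden metrics per sample: total CNV distance (kb), CNV count,
deletions' distinct haploinsufficient genes hit (pHaplo >= 0.86, >= 1 bp),
duplications' distinct triplosensitive genes hit (pTriplo >= 0.94, >= 1 bp),
and the average per-CNV proportion of highly constrained bases (mammalian
PhyloP >= 2.27; primate PhastCons >= 0.96).  Burden tests are ordinary
maximum-likelihood logistic regressions of status on the scaled metric plus
cohort and PC1 — events are not rare at the sample level — falling back to
the Firth engine only if the fit separates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .annotations import (ConstraintTrack, overlap_join,
                          PHAPLO_THRESHOLD, PTRIPLO_THRESHOLD,
                          PHYLOP_THRESHOLD, PHASTCONS_THRESHOLD)
from .calls import CallSet, CnvCall, DEL, DUP, call_frequencies
from .firth import firth_fit, build_design, RankError

METRICS = ("total_kb", "n_cnv", "n_haplo_del_genes", "n_triplo_dup_genes",
           "mean_constrained_prop_mam", "mean_constrained_prop_pri")

#: default length strata (kb), left-closed right-open
LENGTH_BINS_KB = (20, 100, 200, 500, float("inf"))


def constrained_proportion(call: CnvCall, track: ConstraintTrack,
                           threshold: Optional[float] = None) -> float:
    """Fraction of the call's bases inside highly constrained intervals."""
    if threshold is None:
        threshold = PHYLOP_THRESHOLD if track.name == "phylop" else PHASTCONS_THRESHOLD
    cov = track.coverage(call.chrom, call.start, call.end, threshold)
    return cov / call.length


def _gene_hits_per_sample(calls: pd.DataFrame, genes: pd.DataFrame,
                          cnv_type: str, score_col: str,
                          threshold: float) -> pd.Series:
    """Distinct dosage-sensitive genes intersected >= 1 bp, per sample."""
    sub = calls[calls["cnv_type"] == cnv_type]
    gsub = genes[genes[score_col] >= threshold]
    if len(sub) == 0 or len(gsub) == 0:
        return pd.Series(dtype=np.int64)
    pairs = overlap_join(sub.reset_index(drop=True), gsub.reset_index(drop=True))
    if len(pairs) == 0:
        return pd.Series(dtype=np.int64)
    hit = pd.DataFrame({
        "sample_id": sub.reset_index(drop=True)["sample_id"].to_numpy()[pairs["q_idx"]],
        "gene": gsub.reset_index(drop=True)["gene_id"].to_numpy()[pairs["s_idx"]],
    }).drop_duplicates()
    return hit.groupby("sample_id").size()


def _mean_constrained(calls: pd.DataFrame, track: ConstraintTrack,
                      threshold: float) -> pd.Series:
    props = np.zeros(len(calls))
    for chrom, sub in calls.groupby("chrom", sort=False):
        s = sub["start"].to_numpy(np.int64)
        e = sub["end"].to_numpy(np.int64)
        cov = track.coverage_many(chrom, s, e, threshold)
        props[sub.index.to_numpy()] = cov / (e - s)
    return pd.Series(props, index=calls["sample_id"]).groupby(level=0).mean()


def burden_profiles(callset: CallSet, genes: Optional[pd.DataFrame] = None,
                    phylop: Optional[ConstraintTrack] = None,
                    phastcons: Optional[ConstraintTrack] = None) -> pd.DataFrame:
    """Per-sample burden metric table, aligned to the sample table.

    Samples with zero CNVs get zero counts and zero constrained proportions
    (they stay in the regressions; dropping them would condition on
    carriership).  Metrics whose annotation input is missing are omitted
    with a warning rather than zero-filled.
    """
    calls = callset.calls.reset_index(drop=True)
    idx = callset.samples.index
    out = pd.DataFrame(index=idx)
    lengths = (calls["end"] - calls["start"]) / 1_000.0
    out["total_kb"] = lengths.groupby(calls["sample_id"]).sum().reindex(idx, fill_value=0.0)
    out["n_cnv"] = calls.groupby("sample_id").size().reindex(idx, fill_value=0)
    if genes is not None:
        out["n_haplo_del_genes"] = _gene_hits_per_sample(
            calls, genes, DEL, "phaplo", PHAPLO_THRESHOLD).reindex(idx, fill_value=0)
        out["n_triplo_dup_genes"] = _gene_hits_per_sample(
            calls, genes, DUP, "ptriplo", PTRIPLO_THRESHOLD).reindex(idx, fill_value=0)
    else:
        warnings.warn("no gene table: dosage-sensitive gene metrics omitted")
    for name, track, thr in (("mean_constrained_prop_mam", phylop, PHYLOP_THRESHOLD),
                             ("mean_constrained_prop_pri", phastcons, PHASTCONS_THRESHOLD)):
        if track is not None:
            out[name] = _mean_constrained(calls, track, thr).reindex(idx, fill_value=0.0)
        else:
            warnings.warn(f"no constraint track for {name}: metric omitted")
    return out


@dataclass
class BurdenResult:
    metric: str
    scale: float
    or_: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    p_one_sided: float
    beta: float
    se: float
    n_cases: int
    n_controls: int
    engine: str = "logistic"     # logistic | firth
    status: str = "tested"       # tested | degenerate

    @property
    def scaling_note(self) -> str:
        return f"OR per {self.scale:g} {('kb' if 'kb' in self.metric else 'units')}"


def burden_test(profiles: pd.DataFrame, samples: pd.DataFrame, metric: str,
                scale: float = 1.0, covariates=("cohort", "pc1")) -> BurdenResult:
    """Logistic regression of status on metric/scale + covariates.

    ``scale`` expresses the OR per ``scale`` units of the metric (e.g.
    scale=100 with total_kb reports the OR per 100 kb).  A metric constant
    across samples is degenerate and flagged; separation falls back to the
    Firth engine.
    """
    x = profiles[metric].to_numpy(float) / scale
    y = samples.loc[profiles.index, "status"].to_numpy(float)
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if np.ptp(x) == 0:
        return BurdenResult(metric, scale, np.nan, np.nan, np.nan, np.nan, np.nan,
                            np.nan, np.nan, n_cases, n_controls, status="degenerate")
    Z, _ = build_design(samples.loc[profiles.index], covariates)
    X = np.column_stack([Z[:, :1], x, Z[:, 1:]])
    engine = "logistic"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta, se = fit.params[1], fit.bse[1]
        if not np.isfinite(se) or abs(beta) > 30:
            raise PerfectSeparationError("separated")
        z = beta / se
        p_two = 2 * norm.sf(abs(z))
        ci_lo, ci_hi = beta - 1.959964 * se, beta + 1.959964 * se
    except (PerfectSeparationError, np.linalg.LinAlgError, RankError):
        engine = "firth"
        ffit = firth_fit(X, y, test_idx=[1])
        beta, se = ffit.coef[1], ffit.se[1]
        p_two = ffit.p_two_sided[1]
        ci_lo, ci_hi = ffit.ci_low[1], ffit.ci_high[1]
    p_one = p_two / 2 if beta > 0 else 1 - p_two / 2
    return BurdenResult(metric, scale, float(np.exp(beta)), float(np.exp(ci_lo)),
                        float(np.exp(ci_hi)), float(p_two), float(p_one),
                        float(beta), float(se), n_cases, n_controls, engine=engine)


# ---------------------------------------------------------------------------
# partitioned burden

def _length_stratum_labels(lengths_kb: np.ndarray, bins_kb) -> np.ndarray:
    edges = list(bins_kb)
    labels = np.empty(len(lengths_kb), dtype=object)
    labels[:] = f"<{edges[0]:g}kb"          # underflow stratum, if any
    for lo, hi in zip(edges[:-1], edges[1:]):
        name = f">{lo:g}kb" if np.isinf(hi) else f"{lo:g}-{hi:g}kb"
        labels[(lengths_kb >= lo) & (lengths_kb < hi)] = name
    return labels


def _frequency_stratum_labels(counts: np.ndarray, n_samples: int) -> np.ndarray:
    """Carrier-count strata from singletons up to the 1% count."""
    max_rare = max(int(0.01 * n_samples), 1)
    edges = [(1, 1), (2, 5), (6, 25), (26, max_rare)]
    labels = np.empty(len(counts), dtype=object)
    labels[:] = f">{max_rare}"
    for lo, hi in edges:
        if lo > max_rare:
            continue
        hi = min(hi, max_rare)
        name = "singleton" if (lo, hi) == (1, 1) else f"{lo}-{hi}"
        labels[(counts >= lo) & (counts <= hi)] = name
    return labels


def partition_burden(callset: CallSet, by: str = "length",
                     length_bins_kb=LENGTH_BINS_KB, metric: str = "n_cnv",
                     covariates=("cohort", "pc1"), scale: float = 1.0,
                     split_type: bool = True) -> pd.DataFrame:
    """Stratified burden tests by CNV type, length bin or frequency bin.

    ``by`` is "type", "length" or "frequency"; length and frequency strata
    are additionally crossed with CNV type when ``split_type``.  Returns one
    row per stratum with the test result (empty strata are ``unobserved``).
    """
    calls = callset.calls
    lengths_kb = callset.lengths() / 1_000.0
    if by == "type":
        strata = calls["cnv_type"].to_numpy(object)
        split_type = False
    elif by == "length":
        strata = _length_stratum_labels(lengths_kb, length_bins_kb)
    elif by == "frequency":
        counts, _ = call_frequencies(callset)
        strata = _frequency_stratum_labels(counts, callset.n_samples)
    else:
        raise ValueError("by must be 'type', 'length' or 'frequency'")
    if split_type:
        strata = np.char.add(np.char.add(
            calls["cnv_type"].to_numpy(str), ":"), strata.astype(str))
    idx = callset.samples.index
    rows = []
    for stratum in sorted(pd.unique(strata)):
        sub = calls.loc[strata == stratum]
        prof = pd.DataFrame(index=idx)
        prof["n_cnv"] = sub.groupby("sample_id").size().reindex(idx, fill_value=0)
        prof["total_kb"] = ((sub["end"] - sub["start"]) / 1_000.0).groupby(
            sub["sample_id"]).sum().reindex(idx, fill_value=0.0)
        if len(sub) == 0:
            rows.append({"stratum": stratum, "n_calls": 0, "status": "unobserved"})
            continue
        res = burden_test(prof, callset.samples, metric, scale=scale,
                          covariates=covariates)
        rows.append({"stratum": stratum, "n_calls": int(len(sub)),
                     "metric": metric, "OR": res.or_, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "p_two_sided": res.p_two_sided,
                     "p_one_sided": res.p_one_sided, "engine": res.engine,
                     "status": res.status})
    return pd.DataFrame(rows)


def stratified_counts(callset: CallSet, by: str = "length",
                      length_bins_kb=LENGTH_BINS_KB) -> pd.DataFrame:
    """Per-sample CNV counts per stratum (columns sum to the total n_cnv)."""
    calls = callset.calls
    lengths_kb = callset.lengths() / 1_000.0
    if by == "length":
        strata = _length_stratum_labels(lengths_kb, length_bins_kb)
    elif by == "frequency":
        counts, _ = call_frequencies(callset)
        strata = _frequency_stratum_labels(counts, callset.n_samples)
    elif by == "type":
        strata = calls["cnv_type"].to_numpy(object)
    else:
        raise ValueError("by must be 'type', 'length' or 'frequency'")
    tab = pd.crosstab(calls["sample_id"], pd.Series(strata, name="stratum"))
    return tab.reindex(callset.samples.index, fill_value=0)


def burden_table(profiles: pd.DataFrame, samples: pd.DataFrame,
                 covariates=("cohort", "pc1")) -> pd.DataFrame:
    """The five-metric summary table (total distance per 100 kb, count, gene
    hits, constrained proportions), one test per available metric."""
    scales = {"total_kb": 100.0}
    rows = []
    for metric in METRICS:
        if metric not in profiles.columns:
            continue
        res = burden_test(profiles, samples, metric,
                          scale=scales.get(metric, 1.0), covariates=covariates)
        rows.append({"metric": metric, "scale": res.scale, "OR": res.or_,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "p_two_sided": res.p_two_sided, "p_one_sided": res.p_one_sided,
                     "engine": res.engine, "status": res.status})
    return pd.DataFrame(rows)
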