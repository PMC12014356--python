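"""Syndromic / pleiotropic locus annotation and per-locus association.

Three annotation rules decide whether a called CNV counts as an event at a
curated locus (the call's type must match the locus type first):

* ``syndromic_50`` — the call covers >= 50% of the locus, or >= 50% of the
  call lies inside the locus (either denominator suffices);
* ``pleiotropic_seg`` — the call is >= 100 kb long and >= 50% of it overlaps
  the segment, or the call covers >= 25% of the segment;
* ``exon_1bp`` — the call overlaps any listed exon by >= 1 bp (the rule used
  for NRXN1-style exonic-deletion loci; purely intronic calls do not count).

Each observed locus is tested with Firth regression (status ~ carrier +
cohort + pc1), two-sided for syndromic lists and one-sided (risk direction)
for disease-risk segment lists; significance is Bonferroni at 0.05/n with n
the full list length, unobserved loci included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .calls import CallSet, CnvCall, overlap_bp
from .firth import firth_test

RULES = ("syndromic_50", "exon_1bp", "pleiotropic_seg")


@dataclass
class LocusDefinition:
    locus_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    rule: str = "syndromic_50"
    sided: str = "two"
    exon_intervals: Optional[list] = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"locus {self.locus_id}: end must exceed start")
        if self.rule not in RULES:
            raise ValueError(f"locus {self.locus_id}: unknown rule {self.rule!r}")
        if (self.rule == "exon_1bp") != (self.exon_intervals is not None):
            raise ValueError(
                f"locus {self.locus_id}: exon_intervals required iff rule is exon_1bp")

    @property
    def length(self) -> int:
        return self.end - self.start


def annotate_locus(call: CnvCall, locus: LocusDefinition) -> bool:
    """Does this call count as an event at this locus under the locus rule?"""
    if call.cnv_type != locus.cnv_type or str(call.chrom) != str(locus.chrom):
        return False
    ov = overlap_bp(call.start, call.end, locus.start, locus.end)
    if locus.rule == "syndromic_50":
        return ov / locus.length >= 0.5 or ov / call.length >= 0.5
    if locus.rule == "pleiotropic_seg":
        return ((call.length >= 100_000 and ov >= 0.5 * call.length)
                or ov >= 0.25 * locus.length)
    # exon_1bp
    return any(overlap_bp(call.start, call.end, es, ee) >= 1
               for es, ee in locus.exon_intervals)


def carrier_vector(callset: CallSet, locus: LocusDefinition) -> np.ndarray:
    """Per-sample 0/1 indicator: carries >= 1 call annotated to the locus."""
    df = callset.calls
    sel = (df["cnv_type"] == locus.cnv_type) & (df["chrom"].astype(str) == str(locus.chrom))
    sub = df.loc[sel]
    carrier = np.zeros(callset.n_samples, dtype=np.int64)
    if len(sub) == 0:
        return carrier
    s = sub["start"].to_numpy(np.int64)
    e = sub["end"].to_numpy(np.int64)
    ln = e - s
    ov = np.minimum(e, locus.end) - np.maximum(s, locus.start)
    ov = np.maximum(ov, 0)
    if locus.rule == "syndromic_50":
        hit = (ov / locus.length >= 0.5) | (ov / ln >= 0.5)
    elif locus.rule == "pleiotropic_seg":
        hit = ((ln >= 100_000) & (ov >= 0.5 * ln)) | (ov >= 0.25 * locus.length)
    else:
        hit = np.zeros(len(sub), dtype=bool)
        for es, ee in locus.exon_intervals:
            hit |= (np.minimum(e, ee) - np.maximum(s, es)) >= 1
    samples_hit = pd.unique(sub.loc[hit, "sample_id"])
    idx = callset.samples.index.get_indexer(samples_hit)
    carrier[idx] = 1
    return carrier


def locus_scan(callset: CallSet, loci: Sequence[LocusDefinition],
               covariates=("cohort", "pc1"), alpha: float = 0.05,
               n_bonferroni: Optional[int] = None,
               ci: bool = True) -> pd.DataFrame:
    """Firth association per locus with Bonferroni over the *full* list.

    Loci with zero carriers are reported as ``unobserved`` and not tested,
    but still count toward the Bonferroni denominator.
    """
    n_bf = n_bonferroni if n_bonferroni is not None else len(loci)
    bf_alpha = alpha / max(n_bf, 1)
    rows = []
    for locus in loci:
        carrier = carrier_vector(callset, locus)
        res = firth_test(carrier, callset.samples, covariates=covariates,
                         sided=locus.sided, ci=ci)
        p_sided = res.p_sided
        rows.append({
            "locus_id": locus.locus_id, "chrom": locus.chrom,
            "start": locus.start, "end": locus.end,
            "cnv_type": locus.cnv_type, "rule": locus.rule, "sided": locus.sided,
            "n_carriers": res.n_carriers,
            "n_case_carriers": res.n_case_carriers,
            "n_control_carriers": res.n_control_carriers,
            "OR": res.or_, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p_two_sided": res.p_two_sided, "p_one_sided": res.p_one_sided,
            "p_sided": p_sided, "bonferroni_alpha": bf_alpha,
            "significant": bool(p_sided < bf_alpha) if res.status == "tested" else False,
            "status": res.status, "converged": res.converged,
        })
    return pd.DataFrame(rows)


def bmi_linear(callset: CallSet, loci: Sequence[LocusDefinition],
               stratum: str, covariates=("cohort", "pc1")) -> pd.DataFrame:
    """OLS of lowest BMI on locus carriership within cases or controls.

    ``stratum`` is "cases" or "controls".  Loci with zero carriers in the
    stratum are ``unobserved``; 1 carrier is reported but flagged
    ``low_information``.
    """
    if stratum not in ("cases", "controls"):
        raise ValueError("stratum must be 'cases' or 'controls'")
    samples = callset.samples
    if "bmi_lowest" not in samples.columns:
        raise ValueError("sample table has no bmi_lowest column")
    want = 1 if stratum == "cases" else 0
    in_stratum = (samples["status"] == want).to_numpy()
    rows = []
    for locus in loci:
        carrier = carrier_vector(callset, locus)[in_stratum]
        sub = samples.loc[in_stratum]
        keep = sub["bmi_lowest"].notna().to_numpy()
        sub, carrier = sub.loc[keep], carrier[keep]
        n_car = int(carrier.sum())
        row = {"locus_id": locus.locus_id, "stratum": stratum, "n_carriers": n_car}
        if n_car == 0:
            row.update(slope=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
                       p=np.nan, status="unobserved")
        else:
            X = [np.ones(len(sub)), carrier.astype(float)]
            for cov in covariates:
                if cov not in sub.columns:
                    continue
                col = sub[cov]
                if col.dtype == object or str(col.dtype) == "category":
                    for lev in sorted(col.astype(str).unique())[1:]:
                        X.append((col.astype(str) == lev).to_numpy(float))
                else:
                    X.append(col.to_numpy(float))
            fit = sm.OLS(sub["bmi_lowest"].to_numpy(float), np.column_stack(X)).fit()
            lo, hi = fit.conf_int()[1]
            row.update(slope=fit.params[1], se=fit.bse[1], ci_low=lo, ci_high=hi,
                       p=fit.pvalues[1],
                       status="low_information" if n_car < 2 else "tested")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# locus-list TSV I/O (BED-like, editable)

def _fmt_exons(exons) -> str:
    if not exons:
        return "."
    return ";".join(f"{int(s)}-{int(e)}" for s, e in exons)


def _parse_exons(text):
    if text in (".", "", None) or (isinstance(text, float) and np.isnan(text)):
        return None
    out = []
    for part in str(text).split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out


def write_locus_list(loci: Sequence[LocusDefinition], path) -> None:
    rows = [{"locus_id": l.locus_id, "chrom": l.chrom, "start": l.start,
             "end": l.end, "cnv_type": l.cnv_type, "rule": l.rule,
             "sided": l.sided, "exons": _fmt_exons(l.exon_intervals)}
            for l in loci]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_locus_list(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    loci = []
    for row in df.itertuples(index=False):
        loci.append(LocusDefinition(
            locus_id=row.locus_id, chrom=str(row.chrom), start=int(row.start),
            end=int(row.end), cnv_type=row.cnv_type, rule=row.rule,
            sided=row.sided, exon_intervals=_parse_exons(row.exons)))
    return loci
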