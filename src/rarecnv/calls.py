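"""CNV call-set data model, PLINK-CNV/TSV I/O, interval arithmetic and filtering.

Coordinates are 0-based half-open internally. PLINK CNV text files use
1-based inclusive coordinates; conversion happens only at the I/O boundary.
A call ``[start, end)`` has ``length = end - start``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

DEL = "DEL"
DUP = "DUP"
CNV_TYPES = (DEL, DUP)

#: PLINK CNV TYPE column encodes the called copy number.
_CN_TO_TYPE = {0: DEL, 1: DEL, 3: DUP}
_TYPE_TO_CN = {DEL: 1, DUP: 3}

CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "cnv_type", "n_probes", "score"]


class CnvParseError(ValueError):
    """Malformed or invalid CNV input, with the offending line number."""


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


@dataclass(frozen=True)
class CnvCall:
    """One called deletion or duplication for one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    n_probes: int
    score: Optional[float] = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"zero/negative-length call [{self.start}, {self.end}) for {self.sample_id}"
            )
        if self.cnv_type not in CNV_TYPES:
            raise ValidationError(f"cnv_type must be DEL or DUP, got {self.cnv_type!r}")
        if self.n_probes < 1:
            raise ValidationError(f"n_probes must be positive, got {self.n_probes}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ProbeMap:
    """Array probe positions per chromosome, sorted and unique."""

    positions: dict  # chrom -> int64 array (sorted)
    probe_ids: dict = field(default_factory=dict)  # chrom -> object array

    def __post_init__(self):
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(f"probe positions on {chrom} not sorted/unique")
            self.positions[chrom] = pos

    def count(self, chrom: str, start: int, end: int) -> int:
        """Number of probes with position in [start, end)."""
        pos = self.positions.get(str(chrom))
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))

    @property
    def n_probes(self) -> int:
        return sum(len(p) for p in self.positions.values())


@dataclass
class FilterRecord:
    """Log entry for one filtering stage."""

    stage: str
    n_before: int
    n_after: int

    @property
    def removed(self) -> int:
        return self.n_before - self.n_after


@dataclass
class CallSet:
    """A table of CNV calls plus the sample table they refer to.

    ``calls`` columns: sample_id, chrom, start, end, cnv_type, n_probes, score.
    ``samples`` is indexed by sample_id with at least a ``status`` column
    (case=1/control=0) and typically sex, cohort, pc1, bmi_lowest, age.
    """

    calls: pd.DataFrame
    samples: pd.DataFrame
    genome_build: str = "synthetic"

    def __post_init__(self):
        calls = self.calls.reset_index(drop=True)
        missing = [c for c in CALL_COLUMNS if c not in calls.columns]
        if missing:
            raise ValidationError(f"calls table missing columns {missing}")
        if len(calls) and (calls["end"] <= calls["start"]).any():
            bad = calls.index[(calls["end"] <= calls["start"])][0]
            raise ValidationError(f"zero-length call at row {bad}")
        if len(calls) and not calls["cnv_type"].isin(CNV_TYPES).all():
            raise ValidationError("cnv_type entries must be DEL or DUP")
        unknown = set(calls["sample_id"]) - set(self.samples.index)
        if unknown:
            raise ValidationError(f"calls reference unknown samples, e.g. {sorted(unknown)[:3]}")
        self.calls = calls

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def lengths(self) -> np.ndarray:
        return (self.calls["end"] - self.calls["start"]).to_numpy()

    def iter_calls(self) -> Iterable[CnvCall]:
        for row in self.calls.itertuples(index=False):
            yield CnvCall(row.sample_id, row.chrom, int(row.start), int(row.end),
                          row.cnv_type, int(row.n_probes),
                          None if pd.isna(row.score) else float(row.score))

    def subset(self, mask) -> "CallSet":
        return replace(self, calls=self.calls.loc[mask].reset_index(drop=True))


# ---------------------------------------------------------------------------
# interval arithmetic

def overlap_bp(a_start, a_end, b_start, b_end):
    """Overlap length of two half-open intervals (0 when disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _interval(x) -> tuple:
    """(chrom|None, start, end) from a CnvCall-like object or (start, end) pair."""
    if hasattr(x, "start") and hasattr(x, "end"):
        return getattr(x, "chrom", None), int(x.start), int(x.end)
    start, end = x
    return None, int(start), int(end)


def reciprocal_overlap(a, b) -> float:
    """min(ov/len(a), ov/len(b)) for half-open intervals; 0 across chromosomes.

    Accepts ``CnvCall``-like objects or plain ``(start, end)`` pairs. Touching
    half-open intervals are disjoint (overlap 0); identical intervals give 1.
    """
    ca, sa, ea = _interval(a)
    cb, sb, eb = _interval(b)
    if ca is not None and cb is not None and str(ca) != str(cb):
        return 0.0
    ov = overlap_bp(sa, ea, sb, eb)
    if ov <= 0:
        return 0.0
    return min(ov / (ea - sa), ov / (eb - sb))


# ---------------------------------------------------------------------------
# frequency by 50% reciprocal overlap

def _sample_codes(callset: CallSet) -> np.ndarray:
    idx = pd.Index(callset.samples.index)
    codes = idx.get_indexer(callset.calls["sample_id"])
    return codes.astype(np.int64)


def call_frequencies(callset: CallSet, ro_threshold: float = 0.5,
                     block: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Carrier count and sample frequency for every call, vectorized.

    The count for call *i* is the number of distinct samples carrying a
    same-type call on the same chromosome with reciprocal overlap
    ``>= ro_threshold`` against *i* (the carrier itself included).  The
    frequency denominator is the total number of samples in the sample table.
    """
    df = callset.calls
    n = len(df)
    counts = np.zeros(n, dtype=np.int64)
    if n == 0:
        return counts, counts.astype(float)
    codes = _sample_codes(callset)
    starts = df["start"].to_numpy(np.int64)
    ends = df["end"].to_numpy(np.int64)
    lens = ends - starts
    grp = df.groupby(["chrom", "cnv_type"], sort=False).indices
    for _, idx in grp.items():
        idx = np.asarray(idx)
        # order group columns by sample so distinct-sample reduction is a reduceat
        order = np.argsort(codes[idx], kind="stable")
        idx = idx[order]
        s, e, ln, sc = starts[idx], ends[idx], lens[idx], codes[idx]
        bounds = np.flatnonzero(np.r_[True, sc[1:] != sc[:-1]])
        m = len(idx)
        for lo in range(0, m, block):
            hi = min(lo + block, m)
            ov = (np.minimum(e[lo:hi, None], e[None, :])
                  - np.maximum(s[lo:hi, None], s[None, :]))
            need = ro_threshold * np.maximum(ln[lo:hi, None], ln[None, :])
            match = ov >= np.maximum(need, 1)  # >=1 bp and reciprocal threshold
            per_sample = np.maximum.reduceat(match, bounds, axis=1)
            counts[idx[lo:hi]] = per_sample.sum(axis=1)
    return counts, counts / callset.n_samples


def cnv_frequency(call: CnvCall, callset: CallSet,
                  ro_threshold: float = 0.5) -> tuple[int, float]:
    """Carrier count and frequency of one call against a call set."""
    if callset.n_samples == 0:
        raise ValidationError("empty sample table")
    df = callset.calls
    sel = (df["chrom"].astype(str) == str(call.chrom)) & (df["cnv_type"] == call.cnv_type)
    sub = df.loc[sel]
    if len(sub) == 0:
        return 0, 0.0
    s = sub["start"].to_numpy(np.int64)
    e = sub["end"].to_numpy(np.int64)
    ln = e - s
    ov = np.minimum(e, call.end) - np.maximum(s, call.start)
    need = ro_threshold * np.maximum(ln, call.length)
    match = ov >= np.maximum(need, 1)
    count = sub.loc[match, "sample_id"].nunique()
    return int(count), count / callset.n_samples


# ---------------------------------------------------------------------------
# filters

def qc_filter(callset: CallSet, min_length: int = 20_000,
              min_probes: int = 10) -> tuple[CallSet, FilterRecord]:
    """Retain calls with length strictly > ``min_length`` and >= ``min_probes`` probes."""
    lens = callset.lengths()
    keep = (lens > min_length) & (callset.calls["n_probes"].to_numpy() >= min_probes)
    out = callset.subset(keep)
    return out, FilterRecord("qc", len(callset), len(out))


def filter_rare(callset: CallSet, max_freq: float = 0.01,
                ro_threshold: float = 0.5) -> tuple[CallSet, FilterRecord]:
    """Retain calls whose 50%-reciprocal-overlap sample frequency is < ``max_freq``."""
    if len(callset) == 0:
        return callset.subset(slice(None)), FilterRecord("rare", 0, 0)
    _, freq = call_frequencies(callset, ro_threshold=ro_threshold)
    out = callset.subset(freq < max_freq)
    return out, FilterRecord("rare", len(callset), len(out))


# ---------------------------------------------------------------------------
# PLINK CNV text I/O (header: FID IID CHR BP1 BP2 TYPE SCORE SITES)

_PLINK_HEADER = ["FID", "IID", "CHR", "BP1", "BP2", "TYPE", "SCORE", "SITES"]


def read_plink_cnv(path: Union[str, Path, io.TextIOBase],
                   samples: Optional[pd.DataFrame] = None,
                   genome_build: str = "unknown") -> CallSet:
    """Read a PLINK CNV text file into a :class:`CallSet`.

    BP1/BP2 are 1-based inclusive and converted to 0-based half-open
    ``[BP1-1, BP2)``.  TYPE is the called copy number: 0/1 → DEL, 3 or more →
    DUP; TYPE 2 (copy-neutral) is rejected.  If no ``samples`` table is
    given, a minimal one (status unknown, coded -1) is built from the IIDs.
    """
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path)
        close = True
    else:
        fh = path
    rows = []
    try:
        header = fh.readline().split()
        if header != _PLINK_HEADER:
            raise CnvParseError(f"line 1: expected header {' '.join(_PLINK_HEADER)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 8:
                raise CnvParseError(f"line {lineno}: expected 8 fields, got {len(parts)}")
            _fid, iid, chrom, bp1, bp2, cn, score, sites = parts
            try:
                bp1, bp2, cn, sites = int(bp1), int(bp2), int(cn), int(sites)
                score = float(score) if score.lower() not in ("na", "nan", ".") else np.nan
            except ValueError as exc:
                raise CnvParseError(f"line {lineno}: {exc}") from None
            if cn == 2:
                raise ValidationError(f"line {lineno}: TYPE=2 is copy-neutral, not a CNV")
            if cn not in _CN_TO_TYPE and cn < 3:
                raise ValidationError(f"line {lineno}: bad copy number {cn}")
            if bp2 <= bp1:
                raise ValidationError(f"line {lineno}: BP2 must exceed BP1 (zero-length call)")
            if sites < 1:
                raise ValidationError(f"line {lineno}: SITES must be positive")
            cnv_type = _CN_TO_TYPE.get(cn, DUP)
            rows.append((iid, str(chrom), bp1 - 1, bp2, cnv_type, sites, score))
    finally:
        if close:
            fh.close()
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    calls["start"] = calls["start"].astype(np.int64)
    calls["end"] = calls["end"].astype(np.int64)
    calls["n_probes"] = calls["n_probes"].astype(np.int64)
    if samples is None:
        ids = pd.unique(calls["sample_id"])
        samples = pd.DataFrame({"status": -1}, index=pd.Index(ids, name="sample_id"))
    return CallSet(calls, samples, genome_build=genome_build)


def write_plink_cnv(callset: CallSet, path: Union[str, Path, io.TextIOBase]) -> None:
    """Write calls back to PLINK CNV text (the read/write round-trip is exact)."""
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path, "w")
        close = True
    else:
        fh = path
    try:
        fh.write(" ".join(_PLINK_HEADER) + "\n")
        for row in callset.calls.itertuples(index=False):
            score = "NA" if pd.isna(row.score) else f"{row.score:g}"
            fh.write(f"{row.sample_id} {row.sample_id} {row.chrom} "
                     f"{row.start + 1} {row.end} {_TYPE_TO_CN[row.cnv_type]} "
                     f"{score} {row.n_probes}\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# sample table / probe map / BED I/O

def read_sample_table(path) -> pd.DataFrame:
    """TSV with columns sample_id, status, and optional sex/cohort/pc1/bmi_lowest/age."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "status" not in df.columns:
        raise CnvParseError("sample table needs 'sample_id' and 'status' columns")
    if not df["status"].isin([0, 1]).all():
        raise ValidationError("status must be binary (case=1, control=0)")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample table")
    return df.set_index("sample_id")


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        path, sep="\t", index=False)


def read_probe_map(path) -> ProbeMap:
    """TSV with columns chrom, position, probe_id, sorted by (chrom, position)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    positions, ids = {}, {}
    for chrom, sub in df.groupby("chrom", sort=False):
        positions[chrom] = sub["position"].to_numpy(np.int64)
        ids[chrom] = sub["probe_id"].to_numpy(object)
    return ProbeMap(positions, ids)


def write_probe_map(pm: ProbeMap, path) -> None:
    frames = []
    for chrom, pos in pm.positions.items():
        ids = pm.probe_ids.get(chrom)
        if ids is None:
            ids = np.array([f"{chrom}:{p}" for p in pos], dtype=object)
        frames.append(pd.DataFrame({"chrom": chrom, "position": pos, "probe_id": ids}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_bed(path, names=("chrom", "start", "end"), extra=()) -> pd.DataFrame:
    """BED-like TSV (0-based half-open), with optional named extra columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=list(names) + list(extra), dtype={0: str})
    df["chrom"] = df["chrom"].astype(str)
    return df
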