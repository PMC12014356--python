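"""Gene and constraint-track annotations.

Genes carry dosage-sensitivity probabilities: pHaplo (probability of
haploinsufficiency, deletions relevant at >= 0.86) and pTriplo
(triplosensitivity, duplications relevant at >= 0.94).  Constraint tracks
are scored intervals (mammalian PhyloP, primate PhastCons); bases are
"highly constrained" at PhyloP >= 2.27 or PhastCons >= 0.96, a level
covering about 3.26% of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHAPLO_THRESHOLD = 0.86
PTRIPLO_THRESHOLD = 0.94
PHYLOP_THRESHOLD = 2.27
PHASTCONS_THRESHOLD = 0.96

GENE_COLUMNS = ["chrom", "start", "end", "gene_id", "phaplo", "ptriplo"]
EXON_COLUMNS = ["chrom", "start", "end", "gene_id"]


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Merge overlapping/touching half-open intervals (inputs sorted by start)."""
    if len(starts) == 0:
        return starts, ends
    ms, me = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms, dtype=np.int64), np.asarray(me, dtype=np.int64)


@dataclass
class ConstraintTrack:
    """Scored genomic intervals with fast coverage and max-score queries."""

    intervals: pd.DataFrame  # chrom, start, end, score
    name: str = "constraint"
    _merged: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        df = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        df["chrom"] = df["chrom"].astype(str)
        self.intervals = df

    def _merged_for(self, min_score: float):
        key = float(min_score)
        if key not in self._merged:
            per_chrom = {}
            df = self.intervals[self.intervals["score"] >= key]
            for chrom, sub in df.groupby("chrom", sort=False):
                s, e = _merge_intervals(sub["start"].to_numpy(np.int64),
                                        sub["end"].to_numpy(np.int64))
                # prefix sums of merged interval lengths for O(log) coverage
                cum = np.concatenate([[0], np.cumsum(e - s)])
                per_chrom[chrom] = (s, e, cum)
            self._merged[key] = per_chrom
        return self._merged[key]

    def coverage(self, chrom: str, start: int, end: int, min_score: float) -> int:
        """Bases in [start, end) lying in intervals scoring >= min_score."""
        per = self._merged_for(min_score).get(str(chrom))
        if per is None or end <= start:
            return 0
        s, e, cum = per
        if len(s) == 0:
            return 0
        i = np.searchsorted(e, start, "right")   # first interval ending after start
        j = np.searchsorted(s, end, "left")      # first interval starting at/after end
        if i >= j:
            return 0
        total = cum[j] - cum[i]
        total -= max(0, start - s[i])            # clip the first interval
        total -= max(0, e[j - 1] - end)          # clip the last interval
        return int(total)

    def coverage_many(self, chrom: str, starts, ends, min_score: float) -> np.ndarray:
        """Vectorized :meth:`coverage` for arrays of intervals on one chromosome."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        per = self._merged_for(min_score).get(str(chrom))
        out = np.zeros(len(starts), dtype=np.int64)
        if per is None:
            return out
        s, e, cum = per
        if len(s) == 0:
            return out
        i = np.searchsorted(e, starts, "right")
        j = np.searchsorted(s, ends, "left")
        ok = i < j
        ii, jj = i[ok], j[ok]
        total = cum[jj] - cum[ii]
        total -= np.maximum(0, starts[ok] - s[ii])
        total -= np.maximum(0, e[jj - 1] - ends[ok])
        out[ok] = total
        return out

    def max_score(self, chrom: str, start: int, end: int) -> float:
        """Maximum interval score overlapping [start, end); NaN if none."""
        sub = self.intervals[self.intervals["chrom"] == str(chrom)]
        if len(sub) == 0:
            return float("nan")
        s = sub["start"].to_numpy(np.int64)
        e = sub["end"].to_numpy(np.int64)
        hit = (s < end) & (e > start)
        if not hit.any():
            return float("nan")
        return float(sub["score"].to_numpy()[hit].max())

    def genome_fraction(self, chrom_lengths: dict, min_score: float) -> float:
        covered = sum(self.coverage(c, 0, int(L), min_score)
                      for c, L in chrom_lengths.items())
        return covered / sum(int(L) for L in chrom_lengths.values())

    @classmethod
    def from_bed(cls, path, name="constraint") -> "ConstraintTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "score"],
                         dtype={"chrom": str})
        return cls(df, name=name)

    def to_bed(self, path) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)


def read_genes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing columns {missing}")
    return df


def write_genes(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_exons(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_exons(exons: pd.DataFrame, path) -> None:
    exons.to_csv(path, sep="\t", index=False)


def overlap_join(query: pd.DataFrame, subject: pd.DataFrame) -> pd.DataFrame:
    """Pairs (query row, subject row) with >= 1 bp interval overlap per chromosome.

    Both frames need chrom/start/end columns.  Returns a frame with
    ``q_idx``/``s_idx`` integer row indices.  Intended for modest sizes
    (thousands of calls against thousands of genes).
    """
    pairs_q, pairs_s = [], []
    sub_by_chrom = {c: g for c, g in subject.groupby("chrom", sort=False)}
    for chrom, qsub in query.groupby("chrom", sort=False):
        ssub = sub_by_chrom.get(chrom)
        if ssub is None:
            continue
        s_start = ssub["start"].to_numpy(np.int64)
        s_end = ssub["end"].to_numpy(np.int64)
        order = np.argsort(s_start, kind="stable")
        s_start_sorted = s_start[order]
        # running max of ends lets us bound the candidate window from the left
        run_max_end = np.maximum.accumulate(s_end[order])
        for q_idx, qs, qe in zip(qsub.index.to_numpy(),
                                 qsub["start"].to_numpy(np.int64),
                                 qsub["end"].to_numpy(np.int64)):
            hi = np.searchsorted(s_start_sorted, qe, "left")
            lo = np.searchsorted(run_max_end[:hi], qs, "right")
            cand = order[lo:hi]
            hit = cand[s_end[cand] > qs]
            pairs_q.extend([q_idx] * len(hit))
            pairs_s.extend(ssub.index.to_numpy()[hit])
    return pd.DataFrame({"q_idx": pairs_q, "s_idx": pairs_s})
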