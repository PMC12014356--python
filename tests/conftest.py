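import numpy as np
import pandas as pd
import pytest

from rarecnv.calls import CallSet
from rarecnv.simulate import SimConfig, PlantedLocus, simulate


def make_callset(rows, sample_ids=None, statuses=None):
    """Build a CallSet from (sample_id, chrom, start, end, cnv_type[, n_probes]) rows."""
    recs = []
    for row in rows:
        sid, chrom, start, end, cnv_type = row[:5]
        n_probes = row[5] if len(row) > 5 else max((end - start) // 2_000, 1)
        recs.append((sid, str(chrom), start, end, cnv_type, n_probes, np.nan))
    calls = pd.DataFrame(recs, columns=["sample_id", "chrom", "start", "end",
                                        "cnv_type", "n_probes", "score"])
    if sample_ids is None:
        sample_ids = sorted({r[0] for r in rows})
    if statuses is None:
        statuses = [i % 2 for i in range(len(sample_ids))]
    rng = np.random.default_rng(1)
    samples = pd.DataFrame(
        {"status": statuses,
         "sex": "F",
         "cohort": ["SWE" if i % 2 else "ANZUS" for i in range(len(sample_ids))],
         "pc1": rng.normal(size=len(sample_ids))},
        index=pd.Index(sample_ids, name="sample_id"))
    return CallSet(calls, samples)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated study with one planted recurrent deletion locus."""
    cfg = SimConfig(
        n_cases=1800, n_controls=1200, seed=5,
        chrom_lengths={"1": 60_000_000, "2": 60_000_000},
        planted_loci=[PlantedLocus("1", 20_000_000, 20_100_000, "DEL",
                                   carrier_freq_controls=0.003, odds_ratio=4.0)],
    )
    return simulate(cfg)
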