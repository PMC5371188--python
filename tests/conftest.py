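import numpy as np
import pytest

from rdcnv import (build_truth, call_sample, make_genome, plant_noisy_regions,
                   simulate_cohort)
from rdcnv.caller import CnvCall


def mk_call(chrom="chr1", start=0, end=10_000, type="deletion",
            sample="high1", rd=0.5, cn=1, p=1e-6, q0=0.05) -> CnvCall:
    return CnvCall(sample_id=sample, chrom=chrom, start=start, end=end,
                   type=type, normalized_rd=rd, estimated_cn=cn,
                   p_value=p, q0=q0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 2 x 2 Mb cohort with 4 events per label, simulated at ~10x."""
    genome = make_genome(n_chroms=2, chrom_length=2_000_000)
    truth = build_truth(
        genome, n_per_group=4,
        n_events_per_label={"shared": 4, "high_specific": 4,
                            "low_specific": 4, "private": 4},
        seed=7)
    genome.noisy_regions = plant_noisy_regions(
        genome, n=4, seed=7, avoid=list(truth.events))
    tracks = simulate_cohort(truth, lambda_per_bin=20.0, gc_bias_amplitude=0.3)
    return truth, tracks


@pytest.fixture(scope="session")
def small_cohort_calls(small_cohort):
    truth, tracks = small_cohort
    genome = truth.genome
    calls = {
        s: call_sample(tracks[s], genome.baseline_cn_by_chrom, genome.gaps)
        for s in truth.sample_ids
    }
    return truth, calls


def random_calls(rng: np.random.Generator, n: int, samples, chroms=("chr1",),
                 max_pos=100_000, min_len=500, max_len=10_000):
    """Random well-formed calls for oracle-equivalence fixtures."""
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(min_len, max_len))
        ctype = "deletion" if rng.random() < 0.5 else "duplication"
        out.append(mk_call(
            chrom=str(rng.choice(list(chroms))), start=start, end=start + length,
            type=ctype, sample=str(rng.choice(list(samples))),
            rd=0.5 if ctype == "deletion" else 1.6,
            cn=1 if ctype == "deletion" else 3))
    return out
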