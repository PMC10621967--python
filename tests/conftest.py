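import numpy as np
import pandas as pd
import pytest

from haplocn import PatientData, SampleData, run_pipeline, simulate_patient


def make_sample(sample_id, segments, snps=None, purity=0.8, ploidy=2.0, group=None):
    """Build a SampleData from terse segment/SNP tuples.

    segments: list of (chrom, start, end, cn_major, cn_minor)
    snps: list of (chrom, pos, baf, logr) -- all flagged heterozygous
    """
    seg = pd.DataFrame(
        segments, columns=["chrom", "start", "end", "cn_major", "cn_minor"]
    )
    if snps is None:
        snps = []
    snp = pd.DataFrame(snps, columns=["chrom", "pos", "baf", "logr"])
    snp["is_het"] = True
    return SampleData(
        sample_id=sample_id, purity=purity, ploidy=ploidy,
        snps=snp, segments=seg, group_label=group,
    )


@pytest.fixture
def two_sample_patient():
    """Two samples, one chromosome, one shared segment with clear imbalance.

    S1 carries a 2/1 gain (purity 1 -> expected BAF 1/3 or 2/3); S2 is
    balanced 1/1 at the same locus.
    """
    pos = list(range(1000, 11000, 1000))
    hap = [i % 2 == 0 for i in range(10)]  # alternate haplotypes
    s1_snps = [("chr1", p, 2 / 3 if b else 1 / 3, np.log2(1.5)) for p, b in zip(pos, hap)]
    s2_snps = [("chr1", p, 0.5, 0.0) for p in pos]
    s1 = make_sample("S1", [("chr1", 1, 20000, 2, 1)], s1_snps, purity=1.0)
    s2 = make_sample("S2", [("chr1", 1, 20000, 1, 1)], s2_snps, purity=1.0)
    return PatientData(patient_id="P1", samples=[s1, s2])


@pytest.fixture(scope="session")
def sim_patient():
    truth, patient = simulate_patient(3, seed=11)
    return truth, patient


@pytest.fixture(scope="session")
def sim_result(sim_patient):
    _, patient = sim_patient
    return run_pipeline(patient)
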