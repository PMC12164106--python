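import numpy as np
import pytest

from introsel.io import AlleleFrequencyTable, GenotypeDataset
from introsel.simulate import ScenarioParams, simulate

POPS4 = ["P1", "P2", "P3", "O"]


def make_dataset(gt, populations, chrom=None, pos=None, sequence_length=None):
    """GenotypeDataset from a (sites x samples) dosage array and pop spec."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    samples = [f"s{i}" for i in range(n_samples)]
    chrom = np.array(["1"] * n_sites, dtype=object) if chrom is None else chrom
    pos = np.arange(n_sites) if pos is None else pos
    return GenotypeDataset(samples, chrom, pos,
                           ["A"] * n_sites, ["T"] * n_sites, gt,
                           populations, sequence_length)


def make_freqs(rows, pops=POPS4, pos=None, n_called=10):
    """AlleleFrequencyTable from explicit derived-frequency rows."""
    return AlleleFrequencyTable.from_frequencies(rows, pops=tuple(pops),
                                                 pos=pos, n_called=n_called)


@pytest.fixture(scope="session")
def pulse_dataset():
    """One simulated dataset with a known f=0.3 pulse from W2 into C1."""
    params = ScenarioParams(sequence_length=4_000_000, pulse_fraction=0.3,
                            candidates=("C1", "C2"), pulse_recipients=("C1",),
                            seed=20)
    ds, tracts = simulate(params)
    return params, ds, tracts


@pytest.fixture(scope="session")
def neutral_dataset():
    """One simulated dataset with no pulse and no sweep."""
    params = ScenarioParams(sequence_length=4_000_000, pulse_fraction=0.0,
                            candidates=("C1",), seed=21)
    ds, _ = simulate(params)
    return params, ds


def write_toy_vcf(path, records, samples):
    """records: (chrom, pos1, ref, alt_field, [gt strings])."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1,length=1000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
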