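import numpy as np
import pytest

from breedpanel import GenotypeTable, Locus, Sample, SimulationConfig, simulate


def make_table(dosages, populations=None, locus_alleles=None):
    """Build a small GenotypeTable from a dosage matrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    populations = populations or ["P1"] * n
    samples = [Sample(f"s{i}", populations[i]) for i in range(n)]
    loci = []
    for j in range(L):
        ref, alt = (locus_alleles[j] if locus_alleles else ("A", "C"))
        loci.append(Locus(f"l{j}", chromosome="1", position=(j + 1) * 100,
                          allele_ref=ref, allele_alt=alt))
    return GenotypeTable(samples=samples, loci=loci, dosages=dosages)


def counts_table(pop_counts):
    """Table from per-population (n_AA, n_AB, n_BB) counts at one locus."""
    dosages, pops = [], []
    for k, (aa, ab, bb) in enumerate(pop_counts):
        dosages += [0] * aa + [1] * ab + [2] * bb
        pops += [f"P{k + 1}"] * (aa + ab + bb)
    return make_table(np.asarray(dosages)[:, None], populations=pops)


@pytest.fixture(scope="session")
def default_sim():
    """The emulated study design: 3 breeds x 100 animals x 300 SNPs."""
    return simulate(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def default_table(default_sim):
    return default_sim[0]
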