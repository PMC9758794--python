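import numpy as np
import pytest

from raddemog.datasets import GenotypeDataset
from raddemog.demography import build_ns
from raddemog.simulate import SimConfig, sim_genotypes


@pytest.fixture(scope="session")
def panmictic_genotypes() -> GenotypeDataset:
    """12 diploids from one constant-size population, ~1000 SNPs."""
    model = build_ns(10_000, 10_000, 0)
    cfg = SimConfig(samples={"deme0": 12}, n_loci=4000, seed=20260924)
    return sim_genotypes(model, cfg)


def make_dataset(geno_rows, pos_in_locus=None, locus_id=None, depth=None, labels=None):
    """Small literal dataset: geno_rows is sites x individuals."""
    geno = np.asarray(geno_rows, dtype=np.int8).T
    n_ind, n_sites = geno.shape
    samples = [f"s{i}" for i in range(n_ind)]
    return GenotypeDataset(
        samples=samples,
        site_labels=labels or list(samples),
        genotypes=geno,
        locus_id=np.array(locus_id if locus_id is not None else [f"L{j}" for j in range(n_sites)]),
        pos_in_locus=np.array(pos_in_locus if pos_in_locus is not None else [10] * n_sites),
        depth=None if depth is None else np.asarray(depth).T,
    )
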