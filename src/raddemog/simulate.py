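"""Coalescent simulation of RAD-like data under a DemographyModel.

Loci are simulated as independent non-recombining 125-bp fragments
(free recombination between loci, none within, matching RAD-seq locus
structure), with infinite-sites binary mutations.  Output can be a
genotype dataset, a folded 1D-SFS, or a joint 2D-SFS; everything is
reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import msprime
import numpy as np

from .datasets import GenotypeDataset
from .demography import DemographyModel
from .sfs import GEN_TIME_YEARS, MU_RAD, FoldedSFS, Joint2DSFS


@dataclass
class SimConfig:
    """Simulation settings shared by all output modes.

    ``samples`` maps population label to a diploid sample count.
    """

    samples: dict[str, int]
    n_loci: int = 1000
    locus_len_bp: int = 125
    mu: float = MU_RAD
    gen_time_years: float = GEN_TIME_YEARS
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.locus_len_bp < 1:
            raise ValueError("locus_len_bp must be >= 1")
        if any(n < 1 for n in self.samples.values()):
            raise ValueError("sample counts must be >= 1")


def _check_samples(model: DemographyModel, cfg: SimConfig) -> None:
    sizes = dict(model.populations)
    for pop, n in cfg.samples.items():
        if pop not in sizes:
            raise ValueError(f"population {pop!r} not in model")
        if 2 * n > 2 * sizes[pop]:
            raise ValueError(
                f"requested {2 * n} haploid samples from population {pop!r} "
                f"of diploid size {sizes[pop]}"
            )


def _seeds(seed: int | None, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 2) + 1


def sim_tree_replicates(
    model: DemographyModel, cfg: SimConfig, n_reps: int | None = None
) -> Iterator:
    """Independent single-locus tree sequences (no mutations)."""
    _check_samples(model, cfg)
    seed = _seeds(cfg.seed, 1)[0]
    return msprime.sim_ancestry(
        samples=cfg.samples,
        demography=model.to_msprime(),
        sequence_length=cfg.locus_len_bp,
        discrete_genome=False,
        num_replicates=n_reps if n_reps is not None else cfg.n_loci,
        random_seed=seed,
    )


def _mutated(ts, mu: float, seed: int):
    return msprime.sim_mutations(
        ts,
        rate=mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=seed,
    )


def sim_genotypes(model: DemographyModel, cfg: SimConfig) -> GenotypeDataset:
    """Simulate diploid genotypes at polymorphic sites of ``cfg.n_loci`` loci."""
    _check_samples(model, cfg)
    anc_seed, mut_seed = _seeds(cfg.seed, 2)
    pops = list(cfg.samples)
    sample_ids, labels = [], []
    for pop in pops:
        for i in range(cfg.samples[pop]):
            sample_ids.append(f"{pop}_{i}")
            labels.append(pop)
    n_ind = len(sample_ids)

    geno_cols, locus_ids, positions = [], [], []
    width = max(6, len(str(cfg.n_loci)))
    reps = msprime.sim_ancestry(
        samples=cfg.samples,
        demography=model.to_msprime(),
        sequence_length=cfg.locus_len_bp,
        discrete_genome=False,
        num_replicates=cfg.n_loci,
        random_seed=anc_seed,
    )
    mut_rng = np.random.default_rng(mut_seed)
    for k, ts in enumerate(reps):
        mts = _mutated(ts, cfg.mu, int(mut_rng.integers(1, 2**31 - 1)))
        if mts.num_sites == 0:
            continue
        hap = mts.genotype_matrix()  # (sites, haploids)
        dip = hap[:, 0::2] + hap[:, 1::2]
        geno_cols.append(dip)
        lid = f"L{k:0{width}d}"
        for site in mts.sites():
            locus_ids.append(lid)
            positions.append(int(site.position) + 1)
    if geno_cols:
        geno = np.concatenate(geno_cols, axis=0).T.astype(np.int8)
    else:
        geno = np.zeros((n_ind, 0), dtype=np.int8)
    return GenotypeDataset(
        samples=sample_ids,
        site_labels=labels,
        genotypes=geno,
        locus_id=np.array(locus_ids),
        pos_in_locus=np.array(positions, dtype=np.int64),
        locus_len=cfg.locus_len_bp,
    )


def sim_folded_sfs(model: DemographyModel, cfg: SimConfig, population: str) -> FoldedSFS:
    """Folded 1D-SFS of one population's sample, mutation-sampled."""
    if population not in cfg.samples:
        raise ValueError(f"no samples requested from {population!r}")
    sub = SimConfig(
        samples={population: cfg.samples[population]},
        n_loci=cfg.n_loci,
        locus_len_bp=cfg.locus_len_bp,
        mu=cfg.mu,
        gen_time_years=cfg.gen_time_years,
        seed=cfg.seed,
    )
    _check_samples(model, sub)
    anc_seed, mut_seed = _seeds(cfg.seed, 2)
    n_hap = 2 * sub.samples[population]
    eta = np.zeros(n_hap // 2)
    n_sites = 0
    reps = msprime.sim_ancestry(
        samples=sub.samples,
        demography=model.to_msprime(),
        sequence_length=cfg.locus_len_bp,
        discrete_genome=False,
        num_replicates=cfg.n_loci,
        random_seed=anc_seed,
    )
    mut_rng = np.random.default_rng(mut_seed)
    for ts in reps:
        mts = _mutated(ts, cfg.mu, int(mut_rng.integers(1, 2**31 - 1)))
        afs = mts.allele_frequency_spectrum(mode="site", polarised=True, span_normalise=False)
        n_sites += int(afs.sum())
        folded = np.zeros(n_hap // 2 + 1)
        for c in range(n_hap + 1):
            folded[min(c, n_hap - c)] += afs[c]
        eta += folded[1:]
    n_mono = cfg.n_loci * cfg.locus_len_bp - int(eta.sum())
    return FoldedSFS(n_hap=n_hap, eta=eta, n_monomorphic=n_mono)


def sim_joint_sfs(
    model: DemographyModel,
    cfg: SimConfig,
    pops: tuple[str, str],
    fold: bool = True,
) -> Joint2DSFS:
    """Joint 2D-SFS between two sampled populations, mutation-sampled."""
    _check_samples(model, cfg)
    p1, p2 = pops
    anc_seed, mut_seed = _seeds(cfg.seed, 2)
    n1, n2 = 2 * cfg.samples[p1], 2 * cfg.samples[p2]
    counts = np.zeros((n1 + 1, n2 + 1))
    dem = model.to_msprime()
    pop_ids = {p.name: p.id for p in dem.populations}
    reps = msprime.sim_ancestry(
        samples=cfg.samples,
        demography=dem,
        sequence_length=cfg.locus_len_bp,
        discrete_genome=False,
        num_replicates=cfg.n_loci,
        random_seed=anc_seed,
    )
    mut_rng = np.random.default_rng(mut_seed)
    sets = None
    for ts in reps:
        if sets is None:
            sets = [ts.samples(population=pop_ids[p1]), ts.samples(population=pop_ids[p2])]
        mts = _mutated(ts, cfg.mu, int(mut_rng.integers(1, 2**31 - 1)))
        if mts.num_sites == 0:
            continue
        afs = mts.allele_frequency_spectrum(
            sample_sets=sets, mode="site", polarised=True, span_normalise=False
        )
        counts += afs
    # mutation-free sites are monomorphic at (0, 0)
    counts[0, 0] += cfg.n_loci * cfg.locus_len_bp - counts.sum()
    sfs = Joint2DSFS(n1, n2, counts, folded=False)
    return sfs.fold() if fold else sfs
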