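"""Population differentiation and isolation by distance.

Pairwise FST between sampling sites with permutation significance, FST
linearization (FST/(1-FST)) and a Mantel test of genetic against
geographic distance.

The FST estimator is an unbiased two-population coancestry moment
estimator in the Reynolds (1983) tradition: per SNP a numerator
``alpha`` (unbiased estimate of the squared population allele-frequency
difference) and a denominator ``alpha + beta`` (adds the unbiased mean
expected heterozygosity), combined across SNPs as a ratio of sums so
the multi-SNP value is E[alpha]/E[alpha+beta] = theta.  It works on
called genotypes, an openly stated approximation to the
genotype-likelihood route used on low-coverage data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import MISSING, GenotypeDataset


@dataclass
class FstResult:
    fst: float
    n_snps_used: int
    p_value: float | None = None
    n_permutations: int = 0


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    degenerate: bool = False  # constant distance matrix: r undefined


# ---------------------------------------------------------------------------
# Reynolds-type FST


def _counts_for_groups(
    data: GenotypeDataset, samples1: list[str], samples2: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complete-case alternate-allele counts per group and the site index."""
    if set(samples1) & set(samples2):
        raise ValueError("sample lists overlap")
    idx1 = data.sample_indices(samples1)
    idx2 = data.sample_indices(samples2)
    geno = data.genotypes[np.concatenate([idx1, idx2])]
    keep = ~(geno == MISSING).any(axis=0)
    g1 = data.genotypes[np.ix_(idx1, np.flatnonzero(keep))].astype(np.int64)
    g2 = data.genotypes[np.ix_(idx2, np.flatnonzero(keep))].astype(np.int64)
    return g1, g2, np.flatnonzero(keep)

def _reynolds_components(
    ac1: np.ndarray, ac2: np.ndarray, c1: int, c2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP numerator and denominator from alternate-allele counts.

    ``c1``, ``c2`` are haploid sample sizes.  h_i is the unbiased
    estimate of the expected heterozygosity 2 P_i (1 - P_i).
    """
    p1, p2 = ac1 / c1, ac2 / c2
    h1 = 2.0 * p1 * (1 - p1) * c1 / (c1 - 1)
    h2 = 2.0 * p2 * (1 - p2) * c2 / (c2 - 1)
    alpha = (p1 - p2) ** 2 - h1 / (2 * c1) - h2 / (2 * c2)
    denom = alpha + (h1 + h2) / 2.0
    return alpha, denom


def reynolds_fst(
    data: GenotypeDataset,
    samples1: list[str],
    samples2: list[str],
    min_maf: float = 0.05,
) -> FstResult:
    """Weighted multi-SNP Reynolds-type FST between two sample groups.

    SNPs are filtered on pooled minor allele frequency >= ``min_maf``
    before estimation; the multi-SNP estimate is the ratio of summed
    numerators to summed denominators.
    """
    g1, g2, _ = _counts_for_groups(data, samples1, samples2)
    c1, c2 = 2 * g1.shape[0], 2 * g2.shape[0]
    ac1, ac2 = g1.sum(axis=0), g2.sum(axis=0)
    pooled = (ac1 + ac2) / (c1 + c2)
    maf = np.minimum(pooled, 1 - pooled)
    use = maf >= min_maf if min_maf > 0 else maf > 0
    if not use.any():
        raise ValueError("no SNP passes the MAF filter")
    alpha, denom = _reynolds_components(ac1[use], ac2[use], c1, c2)
    return FstResult(fst=float(alpha.sum() / denom.sum()), n_snps_used=int(use.sum()))


def fst_permutation(
    data: GenotypeDataset,
    samples1: list[str],
    samples2: list[str],
    n_perm: int = 1000,
    seed: int | None = None,
    min_maf: float = 0.05,
) -> FstResult:
    """Permutation p-value for FST by re-allocating individuals.

    Individuals are randomly re-assigned to two groups of the original
    sizes; p = (1 + #{perm FST >= observed}) / (n_perm + 1).
    """
    if len(samples1) + len(samples2) < 4:
        raise ValueError("need at least 4 individuals in total")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value", stacklevel=2)
    obs = reynolds_fst(data, samples1, samples2, min_maf=min_maf)
    g1, g2, _ = _counts_for_groups(data, samples1, samples2)
    geno = np.concatenate([g1, g2], axis=0)  # complete cases, group order
    n1 = g1.shape[0]
    n = geno.shape[0]
    c1, c2 = 2 * n1, 2 * (n - n1)
    ac = geno.sum(axis=0)
    pooled = ac / (c1 + c2)
    maf = np.minimum(pooled, 1 - pooled)
    use = maf >= min_maf if min_maf > 0 else maf > 0
    geno = geno[:, use]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        order = rng.permutation(n)
        ac1 = geno[order[:n1]].sum(axis=0)
        ac2 = geno[order[n1:]].sum(axis=0)
        alpha, denom = _reynolds_components(ac1, ac2, c1, c2)
        if alpha.sum() / denom.sum() >= obs.fst:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return FstResult(
        fst=obs.fst, n_snps_used=obs.n_snps_used, p_value=float(p), n_permutations=n_perm
    )


def pairwise_fst_matrix(
    data: GenotypeDataset,
    site_order: list[str] | None = None,
    min_maf: float = 0.05,
    n_perm: int = 0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    """FST (and optional permutation p) between all sampling-site pairs."""
    sites = site_order or list(dict.fromkeys(data.site_labels))
    k = len(sites)
    fst = np.zeros((k, k))
    pvals = np.full((k, k), np.nan) if n_perm else None
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            s1 = data.samples_at_site(sites[i])
            s2 = data.samples_at_site(sites[j])
            if n_perm:
                res = fst_permutation(
                    data, s1, s2, n_perm=n_perm,
                    seed=int(rng.integers(2**31 - 1)), min_maf=min_maf,
                )
                pvals[i, j] = pvals[j, i] = res.p_value
            else:
                res = reynolds_fst(data, s1, s2, min_maf=min_maf)
            fst[i, j] = fst[j, i] = res.fst
    return fst, pvals, sites


# ---------------------------------------------------------------------------
# isolation by distance


def linearized_fst(fst: np.ndarray) -> np.ndarray:
    """Genetic distance FST / (1 - FST)."""
    return np.asarray(fst) / (1.0 - np.asarray(fst))


def great_circle_km(coords: np.ndarray) -> np.ndarray:
    """Haversine distance matrix (km) from (lon, lat) decimal degrees."""
    coords = np.radians(np.asarray(coords, dtype=float))
    lon, lat = coords[:, 0], coords[:, 1]
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def mantel_ibd(
    fst_matrix: np.ndarray,
    coords: np.ndarray | dict | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    distance: str | np.ndarray = "great-circle",
) -> MantelResult:
    """Mantel test between linearized FST and geographic distance.

    ``coords`` are per-site (lon, lat); alternatively pass a
    user-supplied geographic distance matrix via ``distance``.  The
    statistic is the Pearson correlation of the upper triangles; the
    null permutes the site labels of the genetic matrix.
    """
    fst_matrix = np.asarray(fst_matrix, dtype=float)
    k = fst_matrix.shape[0]
    if k < 4:
        raise ValueError("Mantel test needs at least 4 sites")
    if not np.allclose(fst_matrix, fst_matrix.T):
        raise ValueError("FST matrix must be symmetric")
    if isinstance(distance, str):
        if distance != "great-circle":
            raise ValueError("distance must be 'great-circle' or a matrix")
        if coords is None:
            raise ValueError("coords required for great-circle distances")
        if isinstance(coords, dict):
            coords = np.array(list(coords.values()), dtype=float)
        geo = great_circle_km(coords)
    else:
        geo = np.asarray(distance, dtype=float)
    if geo.shape != fst_matrix.shape:
        raise ValueError("distance matrix shape mismatch")

    gen = linearized_fst(fst_matrix)
    iu = np.triu_indices(k, 1)
    x, y = gen[iu], geo[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        return MantelResult(r=np.nan, p_value=np.nan, n_permutations=0, degenerate=True)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        xp = gen[np.ix_(perm, perm)][iu]
        if np.std(xp) == 0:
            continue
        if abs(np.corrcoef(xp, y)[0, 1]) >= abs(r_obs):
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p_value=float(p), n_permutations=n_perm)
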