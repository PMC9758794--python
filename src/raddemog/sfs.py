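"""Folded site frequency spectra and SFS-based diversity statistics.

Builds folded 1D and joint 2D site frequency spectra from genotype
matrices, computes the classical SFS summaries (nucleotide diversity
:math:`\\theta_\\pi`, Watterson's :math:`\\theta_w`, Tajima's *D*) and
tests Tajima's *D* against a constant-size coalescent null.

Spectra are exchanged in a fastsimcoal-style whitespace text format
(header line ``1 observations``) and in a JSON mirror.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import kingman
from .datasets import MISSING, GenotypeDataset

MU_RAD = 1.93e-8  #: RAD-seq mutation rate per site per generation (tiger shark calibration)
GEN_TIME_YEARS = 10.0  #: generation time used to convert generations to years


# ---------------------------------------------------------------------------
# containers


@dataclass
class FoldedSFS:
    """Folded 1D site frequency spectrum.

    ``eta[i-1]`` counts sites with minor-allele count ``i`` for
    ``i = 1 .. n_hap // 2``; monomorphic sites are tallied separately so
    that ``L = n_monomorphic + sum(eta)`` is the total number of sites
    (needed for per-site diversity estimates).
    """

    n_hap: int
    eta: np.ndarray
    n_monomorphic: int
    n_dropped: int = 0  # sites excluded for missing genotypes

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        if len(self.eta) != self.n_hap // 2:
            raise ValueError(f"eta must have {self.n_hap // 2} entries for n_hap={self.n_hap}")
        if np.any(self.eta < 0) or self.n_monomorphic < 0:
            raise ValueError("SFS entries must be non-negative")

    @property
    def S(self) -> float:
        return float(self.eta.sum())

    @property
    def L(self) -> float:
        return float(self.n_monomorphic + self.eta.sum())

    def proportions(self) -> np.ndarray:
        """Polymorphic entries normalized to proportions."""
        s = self.eta.sum()
        if s == 0:
            raise ValueError("no polymorphic sites")
        return self.eta / s

    # fastsimcoal-style "_MAFpop0.obs" dialect
    def to_fsc(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("1 observations\n")
            fh.write("\t".join(f"d0_{i}" for i in range(self.n_hap // 2 + 1)) + "\n")
            vals = [self.n_monomorphic, *self.eta.tolist()]
            fh.write("\t".join(_fmt(v) for v in vals) + "\n")

    @classmethod
    def from_fsc(cls, path: str) -> "FoldedSFS":
        with open(path) as fh:
            lines = [ln for ln in fh.read().splitlines() if ln.strip()]
        if "observations" not in lines[0]:
            raise ValueError("not a fastsimcoal-style SFS file")
        vals = [float(x) for x in lines[2].split()]
        n_hap = 2 * (len(vals) - 1)
        return cls(n_hap=n_hap, eta=np.array(vals[1:]), n_monomorphic=int(vals[0]))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_hap": self.n_hap,
                    "eta": self.eta.tolist(),
                    "n_monomorphic": self.n_monomorphic,
                    "n_dropped": self.n_dropped,
                },
                fh,
                indent=2,
            )


@dataclass
class Joint2DSFS:
    """Joint 2-population site frequency spectrum.

    ``counts[i, j]`` tallies sites with alternate (or, when folded,
    global-minor) allele count ``i`` in population 1 and ``j`` in
    population 2.
    """

    n1_hap: int
    n2_hap: int
    counts: np.ndarray
    folded: bool = True
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n1_hap + 1, self.n2_hap + 1):
            raise ValueError("counts matrix shape must be (n1_hap+1, n2_hap+1)")
        if np.any(self.counts < 0):
            raise ValueError("SFS entries must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def fold(self) -> "Joint2DSFS":
        """Fold onto the global minor allele.

        Entry ``(i, j)`` with ``i + j > (n1 + n2) / 2`` is added to its
        mirror ``(n1 - i, n2 - j)``; exact ties (total count equal to
        half the pooled sample) are kept where they fall.
        """
        if self.folded:
            return self
        n1, n2 = self.n1_hap, self.n2_hap
        half = (n1 + n2) / 2.0
        out = np.zeros_like(self.counts)
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                if i + j > half:
                    out[n1 - i, n2 - j] += self.counts[i, j]
                else:
                    out[i, j] += self.counts[i, j]
        return Joint2DSFS(n1, n2, out, folded=True, n_dropped=self.n_dropped)

    # fastsimcoal-style "_jointMAFpop1_0.obs" dialect: rows = population 2
    def to_fsc(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("1 observations\n")
            fh.write("\t" + "\t".join(f"d0_{i}" for i in range(self.n1_hap + 1)) + "\n")
            for j in range(self.n2_hap + 1):
                row = "\t".join(_fmt(self.counts[i, j]) for i in range(self.n1_hap + 1))
                fh.write(f"d1_{j}\t{row}\n")

    @classmethod
    def from_fsc(cls, path: str, folded: bool = True) -> "Joint2DSFS":
        with open(path) as fh:
            lines = [ln for ln in fh.read().splitlines() if ln.strip()]
        if "observations" not in lines[0]:
            raise ValueError("not a fastsimcoal-style SFS file")
        n1 = len(lines[1].split())
        rows = [[float(x) for x in ln.split()[1:]] for ln in lines[2:]]
        counts = np.array(rows).T  # back to (pop1, pop2) indexing
        return cls(n1_hap=n1 - 1, n2_hap=len(rows) - 1, counts=counts, folded=folded)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n1_hap": self.n1_hap,
                    "n2_hap": self.n2_hap,
                    "counts": self.counts.tolist(),
                    "folded": self.folded,
                    "n_dropped": self.n_dropped,
                },
                fh,
                indent=2,
            )


@dataclass
class DiversityStats:
    """Per-site diversity summaries of a folded SFS.

    ``tajimas_d`` is ``None`` (never silently NaN) when undefined
    because no site is segregating.
    """

    theta_pi: float
    theta_w: float
    tajimas_d: float | None
    td_pvalue: float | None = None


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:.6f}"


# ---------------------------------------------------------------------------
# spectra from genotypes


def _complete_case(
    data: GenotypeDataset, idx: np.ndarray
) -> tuple[np.ndarray, int]:
    """Mask of sites with no missing genotype among ``idx``; drop count."""
    geno = data.genotypes[idx]
    keep = ~(geno == MISSING).any(axis=0)
    return keep, int((~keep).sum())


def fold_sfs_from_genotypes(
    data: GenotypeDataset, samples: list[str], total_sites: int | None = None
) -> FoldedSFS:
    """Folded SFS over the listed samples, complete cases only.

    Sites with any missing genotype among the selected samples are
    excluded; the exclusion count is reported on ``n_dropped``.  A
    genotype matrix usually holds polymorphic sites only; pass
    ``total_sites`` (loci x locus length) to count the invariant sites
    that per-site diversity estimates need.
    """
    if not samples:
        raise ValueError("empty sample list")
    idx = data.sample_indices(samples)
    keep, n_dropped = _complete_case(data, idx)
    if not keep.any():
        raise ValueError("all sites have missing genotypes in the selected samples")
    geno = data.genotypes[np.ix_(idx, np.flatnonzero(keep))]
    n_hap = 2 * len(idx)
    alt = geno.sum(axis=0, dtype=np.int64)
    folded = np.minimum(alt, n_hap - alt)
    tally = np.bincount(folded, minlength=n_hap // 2 + 1)
    eta = tally[1:].astype(float)
    n_mono = int(tally[0])
    if total_sites is not None:
        extra = total_sites - int(tally.sum()) - n_dropped
        if extra < 0:
            raise ValueError("total_sites smaller than the number of genotyped sites")
        n_mono += extra
    return FoldedSFS(n_hap=n_hap, eta=eta, n_monomorphic=n_mono, n_dropped=n_dropped)


def joint_sfs_from_genotypes(
    data: GenotypeDataset,
    samples1: list[str],
    samples2: list[str],
    fold: bool = True,
) -> Joint2DSFS:
    """Joint 2D-SFS between two sample groups, complete cases only."""
    if set(samples1) & set(samples2):
        raise ValueError("sample lists overlap")
    idx1 = data.sample_indices(samples1)
    idx2 = data.sample_indices(samples2)
    keep, n_dropped = _complete_case(data, np.concatenate([idx1, idx2]))
    sites = np.flatnonzero(keep)
    n1, n2 = 2 * len(idx1), 2 * len(idx2)
    c1 = data.genotypes[np.ix_(idx1, sites)].sum(axis=0, dtype=np.int64)
    c2 = data.genotypes[np.ix_(idx2, sites)].sum(axis=0, dtype=np.int64)
    counts = np.zeros((n1 + 1, n2 + 1))
    np.add.at(counts, (c1, c2), 1.0)
    sfs = Joint2DSFS(n1, n2, counts, folded=False, n_dropped=n_dropped)
    return sfs.fold() if fold else sfs


# ---------------------------------------------------------------------------
# diversity statistics


def tajima_constants(n: int) -> dict[str, float]:
    """The Tajima (1989) normalization constants for sample size ``n``."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _pi_total(eta: np.ndarray, n: int) -> np.ndarray:
    """Mean pairwise differences (total, not per site) from folded eta."""
    i = np.arange(1, eta.shape[-1] + 1)
    return (eta * i * (n - i)).sum(axis=-1) / math.comb(n, 2)


def diversity_stats(sfs: FoldedSFS) -> DiversityStats:
    """:math:`\\theta_\\pi`, :math:`\\theta_w` (both per site) and Tajima's D."""
    n = sfs.n_hap
    if n < 4:
        raise ValueError("need n_hap >= 4")
    L = sfs.L
    if L == 0:
        raise ValueError("SFS has no sites")
    c = tajima_constants(n)
    S = sfs.S
    if S == 0:
        return DiversityStats(theta_pi=0.0, theta_w=0.0, tajimas_d=None)
    pi = float(_pi_total(sfs.eta, n))
    theta_w = S / (c["a1"] * L)
    theta_pi = pi / L
    d = (pi - S / c["a1"]) / math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    return DiversityStats(theta_pi=theta_pi, theta_w=theta_w, tajimas_d=d)


def _td_from_eta(eta: np.ndarray, n: int) -> np.ndarray:
    """Vectorized Tajima's D over rows of folded eta (NaN where S=0)."""
    c = tajima_constants(n)
    S = eta.sum(axis=-1)
    pi = _pi_total(eta, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = c["e1"] * S + c["e2"] * S * (S - 1)
        return np.where(S > 0, (pi - S / c["a1"]) / np.sqrt(np.maximum(var, 1e-300)), np.nan)


def td_significance(
    sfs: FoldedSFS,
    n_sims: int = 1000,
    seed: int | None = None,
    mu: float = MU_RAD,
    locus_len: int = 125,
    condition: str = "theta_w",
) -> float:
    """Two-sided simulation p-value for Tajima's D.

    The null is a constant-size coalescent matched to the data: ``L``
    sites arranged as independent ``locus_len``-bp loci, population size
    set so that the expected Watterson theta equals the observed one.
    With ``condition="theta_w"`` the simulated number of SNPs is random
    (Poisson around the theta_w expectation); with ``condition="S"``
    each replicate is conditioned on the observed number of segregating
    sites.

    Returns the fraction of replicates with ``|D|`` at least as extreme
    as observed.
    """
    if condition not in ("theta_w", "S"):
        raise ValueError("condition must be 'theta_w' or 'S'")
    if n_sims < 100:
        warnings.warn("n_sims < 100 gives a coarse p-value", stacklevel=2)
    stats = diversity_stats(sfs)
    if stats.tajimas_d is None:
        raise ValueError("Tajima's D undefined (no segregating sites)")
    n = sfs.n_hap
    n_loci = max(1, int(round(sfs.L / locus_len)))
    N0 = stats.theta_w / (4.0 * mu)
    mu_locus = mu * locus_len
    rng = np.random.default_rng(seed)
    half = n // 2

    td_sims = np.empty(0)
    # chunk replicates to bound memory at ~2e6 genealogies per block
    chunk = max(1, int(2e6 / n_loci))
    done = 0
    while done < n_sims:
        r = min(chunk, n_sims - done)
        branch = kingman.branch_afs(n, r * n_loci, [(0.0, N0)], rng)
        per_rep = branch.reshape(r, n_loci, n - 1).sum(axis=1)
        if condition == "theta_w":
            eta = kingman.sample_folded_eta(per_rep, mu_locus, rng)
        else:
            S_obs = int(sfs.S)
            p = per_rep / per_rep.sum(axis=1, keepdims=True)
            xi = np.stack([rng.multinomial(S_obs, row) for row in p])
            eta = kingman.fold_xi(xi)
        td_sims = np.concatenate([td_sims, _td_from_eta(eta, n)])
        done += r
    td_sims = td_sims[~np.isnan(td_sims)]
    if td_sims.size == 0:
        raise RuntimeError("all null replicates were monomorphic; theta too small")
    return float(np.mean(np.abs(td_sims) >= abs(stats.tajimas_d)))
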