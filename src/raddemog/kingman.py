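"""Vectorized single-population coalescent branch-length sampler.

Simulates the branch-length site frequency spectrum of independent
Kingman genealogies under a piecewise-constant diploid population size,
vectorized across replicates with numpy.  This is the workhorse for
operations that need very large numbers of unstructured genealogies
(the Tajima's D null distribution, reference tables for the
no-structure model); all structured demographies go through msprime.

Times are in generations, sizes are diploid effective sizes: a pair of
lineages coalesces at rate 1/(2N) per generation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["branch_afs", "sample_folded_eta"]


def _waiting_times(
    t: np.ndarray, k: int, starts: np.ndarray, sizes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Waiting time to the next coalescence for ``k`` lineages.

    Piecewise-exponential sampling: a unit-rate exponential budget is
    consumed through successive epochs at the epoch-specific rate
    ``k(k-1)/2 / (2N_e)``.
    """
    u = rng.exponential(size=t.shape)
    w = np.zeros_like(t)
    rem = u
    cur = t.astype(float).copy()
    pair_rate = k * (k - 1) / 2.0
    for e in range(len(starts)):
        t_end = starts[e + 1] if e + 1 < len(starts) else np.inf
        lam = pair_rate / (2.0 * sizes[e])
        act = (cur >= starts[e]) & (cur < t_end) & (rem > 0)
        if not act.any():
            continue
        needed = rem[act] / lam
        take = np.minimum(needed, t_end - cur[act])
        w[act] += take
        rem[act] -= take * lam
        cur[act] += take
    return w


def branch_afs(
    n_hap: int,
    n_reps: int,
    epochs: list[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unfolded branch-length AFS of independent genealogies.

    Parameters
    ----------
    n_hap
        Haploid sample size.
    n_reps
        Number of independent genealogies.
    epochs
        ``[(t_start_generations, N_diploid), ...]`` backwards in time;
        the first start must be 0, starts strictly increasing.
    rng
        numpy random generator.

    Returns
    -------
    ndarray of shape ``(n_reps, n_hap - 1)`` with total branch length
    (generations) subtending ``i = 1 .. n_hap-1`` of the samples.
    """
    if n_hap < 2:
        raise ValueError("need at least two haploid samples")
    starts = np.array([e[0] for e in epochs], dtype=float)
    sizes = np.array([e[1] for e in epochs], dtype=float)
    if starts[0] != 0 or np.any(np.diff(starts) <= 0):
        raise ValueError("epoch starts must begin at 0 and increase")
    if np.any(sizes <= 0):
        raise ValueError("population sizes must be positive")

    n, R = n_hap, n_reps
    counts = np.ones((R, n), dtype=np.int32)
    t = np.zeros(R)
    afs_flat = np.zeros(R * (n - 1))
    row_off = np.arange(R) * (n - 1)
    for k in range(n, 1, -1):
        w = _waiting_times(t, k, starts, sizes, rng)
        idx = (row_off[:, None] + counts[:, :k] - 1).ravel()
        afs_flat += np.bincount(idx, weights=np.repeat(w, k), minlength=R * (n - 1))
        t += w
        i = rng.integers(0, k, size=R)
        j = rng.integers(0, k - 1, size=R)
        j = j + (j >= i)
        rows = np.arange(R)
        counts[rows, i] += counts[rows, j]
        counts[rows, j] = counts[rows, k - 1]
    return afs_flat.reshape(R, n - 1)


def sample_folded_eta(
    branch: np.ndarray, mu_per_locus: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson-sample mutations on branch AFS rows and fold.

    ``branch`` has shape ``(R, n-1)`` (one row per replicate, columns =
    unfolded frequency classes); returns folded counts of shape
    ``(R, n//2)``.
    """
    xi = rng.poisson(branch * mu_per_locus)
    return fold_xi(xi)


def fold_xi(xi: np.ndarray) -> np.ndarray:
    """Fold unfolded class counts ``xi_1..xi_{n-1}`` (last axis)."""
    xi = np.atleast_2d(xi)
    n = xi.shape[-1] + 1
    half = n // 2
    eta = xi[..., :half].astype(float).copy()
    for i in range(1, half + 1):
        if n - i != i and n - i <= n - 1:
            eta[..., i - 1] += xi[..., n - i - 1]
    return eta
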