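"""Piecewise-constant Ne(t) estimation from a folded SFS.

A simplified stairway-style estimator: the expected folded SFS under a
piecewise-constant diploid population size is computed exactly from the
expected branch lengths of the coalescent (death-process matrix
exponentials for the lineage-count distribution, combined with the
classical probability that a branch with ``k`` coexisting lineages
subtends ``i`` of ``n`` samples), and per-epoch sizes are fitted by
maximizing a Poisson composite likelihood of the folded SFS classes.
Epoch boundaries sit on coalescent-time quantiles of the Watterson
estimate; the number of epochs is chosen by AIC among {2, 4, 7, 9};
confidence bands come from a nonparametric bootstrap over sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .sfs import GEN_TIME_YEARS, MU_RAD, FoldedSFS, diversity_stats


@dataclass
class SkylineEstimate:
    """Piecewise-constant Ne(t) with bootstrap band.

    ``boundaries_years`` has one entry per epoch start (years BP,
    first entry 0); ``ne`` / ``lower`` / ``upper`` are per-epoch diploid
    sizes, the band at the configured level.
    """

    boundaries_years: np.ndarray
    ne: np.ndarray
    lower: np.ndarray | None
    upper: np.ndarray | None
    level: float
    n_bootstraps: int
    n_epochs: int
    lnl: float
    converged: bool

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "time_years_bp": self.boundaries_years,
                "ne": self.ne,
                "lower": np.full(len(self.ne), np.nan) if self.lower is None else self.lower,
                "upper": np.full(len(self.ne), np.nan) if self.upper is None else self.upper,
            }
        ).to_csv(path, sep="\t", index=False)

    def plot(self, path: str) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        t = np.append(self.boundaries_years, self.boundaries_years[-1] * 3 + 1)
        ax.stairs(self.ne, t, baseline=None, label="Ne")
        if self.lower is not None:
            ax.stairs(self.lower, t, baseline=None, color="grey", alpha=0.6)
            ax.stairs(self.upper, t, baseline=None, color="grey", alpha=0.6)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("years BP")
        ax.set_ylabel("diploid Ne")
        fig.savefig(path, dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# expected folded SFS under piecewise-constant Ne


def _expected_level_times(
    n_hap: int, epochs: list[tuple[float, float]]
) -> np.ndarray:
    """E[time with k lineages], k = 2..n, generations.

    The lineage count is a pure death process with rate C(k,2)/(2N(t));
    within each constant epoch the occupation times follow from matrix
    exponentials of the (rescaled) generator, and the final open-ended
    epoch from the fundamental matrix of the absorbing chain.
    """
    n = n_hap
    ks = np.arange(n, 1, -1)  # states n..2 (transient); absorbing state 1
    m = len(ks)
    rates = ks * (ks - 1) / 2.0  # per 2N generations
    v = np.zeros(m)
    v[0] = 1.0
    occupancy = np.zeros(m)
    starts = [e[0] for e in epochs]
    sizes = [e[1] for e in epochs]
    for e in range(len(epochs)):
        Q = np.zeros((m, m))
        lam = rates / (2.0 * sizes[e])
        for a in range(m):
            Q[a, a] = -lam[a]
            if a + 1 < m:
                Q[a, a + 1] = lam[a]
            # flow into the absorbing state (k=1) leaves the system
        if e + 1 < len(epochs):
            tau = starts[e + 1] - starts[e]
            # block trick: expm([[Q, I], [0, 0]]) = [[e^{Qt}, int e^{Qs} ds], [0, I]]
            M = np.zeros((2 * m, 2 * m))
            M[:m, :m] = Q * tau
            M[:m, m:] = np.eye(m) * tau
            E = expm(M)
            occupancy += v @ E[:m, m:]
            v = v @ E[:m, :m]
        else:
            occupancy += v @ np.linalg.inv(-Q)
    # occupancy is ordered by state n..2; return for k=2..n
    return occupancy[::-1]


def _subtend_prob(n: int) -> np.ndarray:
    """P[a branch present with k lineages subtends i of n samples].

    Returns ``(n-1, n-1)`` matrix indexed by ``(k-2, i-1)``.
    """
    P = np.zeros((n - 1, n - 1))
    for k in range(2, n + 1):
        for i in range(1, n - k + 2):
            P[k - 2, i - 1] = math.comb(n - i - 1, k - 2) / math.comb(n - 1, k - 1)
    return P


def expected_branch_lengths(n_hap: int, epochs: list[tuple[float, float]]) -> np.ndarray:
    """E[total branch length subtending i = 1..n-1 samples], generations."""
    tk = _expected_level_times(n_hap, epochs)  # k = 2..n
    ks = np.arange(2, n_hap + 1)
    return (ks * tk) @ _subtend_prob(n_hap)


def _fold_lengths(ell: np.ndarray) -> np.ndarray:
    n = len(ell) + 1
    half = n // 2
    out = ell[:half].copy()
    for i in range(1, half + 1):
        if n - i != i:
            out[i - 1] += ell[n - i - 1]
    return out


def expected_folded_sfs_piecewise(
    Ne_epochs: list[tuple[float, float]],
    n_hap: int,
    mu: float = MU_RAD,
    L: float = 1.0,
) -> np.ndarray:
    """Expected folded SFS counts (classes 1..n//2) for ``L`` sites.

    ``Ne_epochs`` is ``[(t_start_generations, N_diploid), ...]``.
    Normalize the result to obtain expected proportions.
    """
    if not Ne_epochs:
        raise ValueError("need at least one epoch")
    ell = expected_branch_lengths(n_hap, Ne_epochs)
    return _fold_lengths(ell) * mu * L


# ---------------------------------------------------------------------------
# fitting


def _epoch_boundaries(n_hap: int, N_ref: float, n_epochs: int) -> np.ndarray:
    """Epoch start times on coalescent-time quantiles of a constant-size
    reference: geometric levels of remaining lineages map to cumulative
    expected coalescent times."""
    levels = np.geomspace(n_hap, 2, n_epochs + 1)[1:-1]
    times = 4.0 * N_ref * (1.0 / levels - 1.0 / n_hap)
    return np.concatenate([[0.0], np.sort(times)])


def _fit_fixed_epochs(
    eta: np.ndarray,
    n_hap: int,
    boundaries: np.ndarray,
    mu: float,
    L: float,
    N0: float,
    include_singletons: bool,
) -> tuple[np.ndarray, float, bool]:
    """Maximize the Poisson composite likelihood over per-epoch log-Ne."""
    half = n_hap // 2
    classes = np.arange(half) if include_singletons else np.arange(1, half)
    obs = eta[classes]

    def nll(logs: np.ndarray) -> float:
        epochs = [(t, 10.0**s) for t, s in zip(boundaries, logs)]
        lam = expected_folded_sfs_piecewise(epochs, n_hap, mu, L)[classes]
        lam = np.maximum(lam, 1e-12)
        return float(-(obs * np.log(lam) - lam).sum())

    x0 = np.full(len(boundaries), np.log10(N0))
    res = minimize(
        nll, x0, method="L-BFGS-B", bounds=[(1.0, 7.5)] * len(x0),
        options={"maxiter": 200},
    )
    return 10.0**res.x, -res.fun, bool(res.success)


def fit_skyline(
    sfs: FoldedSFS,
    mu: float = MU_RAD,
    gen_time_years: float = GEN_TIME_YEARS,
    n_epochs: int | str = "auto",
    n_boot: int = 199,
    seed: int | None = None,
    include_singletons: bool = True,
    level: float = 0.75,
) -> SkylineEstimate:
    """Fit a piecewise-constant Ne history to a folded SFS.

    ``n_epochs="auto"`` compares {2, 4, 7, 9} epochs by AIC.  Bands at
    ``level`` (default 75%) come from ``n_boot`` nonparametric
    bootstraps over sites (multinomial resampling of the SFS classes,
    monomorphic class included).  Singletons are used by default; they
    carry most of the signal about very recent sizes.
    """
    if sfs.L == 0:
        raise ValueError("SFS has no sites")
    if sfs.S < sfs.n_hap:
        raise ValueError("too few segregating sites for a skyline fit")
    n = sfs.n_hap
    stats = diversity_stats(sfs)
    N_ref = stats.theta_w / (4.0 * mu)
    L = sfs.L

    grid = [2, 4, 7, 9] if n_epochs == "auto" else [int(n_epochs)]
    grid = [e for e in grid if e <= max(1, n // 2 - (0 if include_singletons else 1))]
    best = None
    for e in grid:
        bounds_gen = _epoch_boundaries(n, N_ref, e)
        ne, lnl, ok = _fit_fixed_epochs(
            sfs.eta, n, bounds_gen, mu, L, N_ref, include_singletons
        )
        aic = 2 * e - 2 * lnl
        if best is None or aic < best["aic"]:
            best = {"e": e, "bounds": bounds_gen, "ne": ne, "lnl": lnl, "ok": ok, "aic": aic}

    lower = upper = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        probs = np.concatenate([[sfs.n_monomorphic], sfs.eta]) / L
        boot_ne = np.empty((n_boot, best["e"]))
        for b in range(n_boot):
            draw = rng.multinomial(int(L), probs)
            ne_b, _, _ = _fit_fixed_epochs(
                draw[1:].astype(float), n, best["bounds"], mu, draw.sum(), N_ref,
                include_singletons,
            )
            boot_ne[b] = ne_b
        alpha = (1.0 - level) / 2.0
        lower = np.quantile(boot_ne, alpha, axis=0)
        upper = np.quantile(boot_ne, 1 - alpha, axis=0)

    return SkylineEstimate(
        boundaries_years=best["bounds"] * gen_time_years,
        ne=best["ne"],
        lower=lower,
        upper=upper,
        level=level,
        n_bootstraps=n_boot,
        n_epochs=best["e"],
        lnl=best["lnl"],
        converged=best["ok"],
    )
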