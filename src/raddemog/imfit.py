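"""Isolation/migration model fitting on a folded joint 2D-SFS.

Five nested two-population models describe the divergence of an
Indo-Pacific (IP) and an Atlantic (AO) population from a common
ancestor at ``T_div``, each modern population changing exponentially
from its modern size back to an ancestral size, with asymmetric
migration that is either time-structured (two epochs split at
``T_mig``), constant, or absent:

========  ====================================================  ======
variant   migration                                             k
========  ====================================================  ======
full      recent (0..T_mig) and ancestral (T_mig..T_div) rates    13
anc       ancestral epoch only                                    11
rec       recent epoch only                                       11
bsc       one constant rate per direction on 0..T_div             10
div       none                                                     8
========  ====================================================  ======

The expected folded 2D-SFS under a parameter vector is approximated by
Monte-Carlo (mean branch-length AFS over independent coalescent
genealogies), and parameters are estimated by maximizing the
multinomial composite likelihood of the observed spectrum, best of
``n_runs`` bounded derivative-free searches from random starts.  Model
choice uses AIC on the best run per model; a distinguishability check
re-estimates the likelihood distribution of each fitted model, and
confidence intervals come from a parametric bootstrap.

Migration is reported as the forward number of migrants per generation
(``Nm``); internally rates are backwards fractions converted with the
receiving population's modern diploid size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import msprime
import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .demography import DemographyModel
from .sfs import GEN_TIME_YEARS, MU_RAD, Joint2DSFS
from .simulate import SimConfig, sim_joint_sfs

VARIANTS = ("full", "anc", "rec", "bsc", "div")

_SIZES = ["N_anc", "N_mod_IP", "N_mod_AO", "N_anc_IP", "N_anc_AO"]
_TIMES_COMMON = ["T_s_IP", "T_s_AO", "T_div"]

_PARAMS = {
    "full": _SIZES + _TIMES_COMMON + ["T_mig", "Nm1_IP_AO", "Nm1_AO_IP", "Nm2_IP_AO", "Nm2_AO_IP"],
    "anc": _SIZES + _TIMES_COMMON + ["T_mig", "Nm2_IP_AO", "Nm2_AO_IP"],
    "rec": _SIZES + _TIMES_COMMON + ["T_mig", "Nm1_IP_AO", "Nm1_AO_IP"],
    "bsc": _SIZES + _TIMES_COMMON + ["Nm_IP_AO", "Nm_AO_IP"],
    "div": _SIZES + _TIMES_COMMON,
}

DEFAULT_BOUNDS = {
    **{p: (100.0, 100_000.0) for p in _SIZES},
    **{p: (100.0, 1_000_000.0) for p in _TIMES_COMMON + ["T_mig"]},
    **{p: (0.0, 50.0) for p in ("Nm_IP_AO", "Nm_AO_IP", "Nm1_IP_AO", "Nm1_AO_IP",
                                "Nm2_IP_AO", "Nm2_AO_IP")},
}

#: effective lower bound for migration parameters in log-space searches
NM_FLOOR = 1e-3


@dataclass
class IMModelSpec:
    """One of the five nested isolation/migration model variants."""

    variant: str
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    mu: float = MU_RAD
    gen_time_years: float = GEN_TIME_YEARS

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.bounds = {**{p: DEFAULT_BOUNDS[p] for p in self.param_names}, **self.bounds}

    @property
    def param_names(self) -> list[str]:
        return list(_PARAMS[self.variant])

    @property
    def k(self) -> int:
        return len(self.param_names)

    def validate(self, params: dict[str, float]) -> None:
        missing = set(self.param_names) - set(params)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        if self.variant == "div":
            extra = [p for p in params if p.startswith("Nm") and params[p] != 0]
            if extra:
                raise ValueError(f"div variant admits no migration, got {extra}")
        if "T_mig" in params and params["T_mig"] > params["T_div"]:
            raise ValueError("T_mig must not exceed T_div")


@dataclass
class FitResult:
    spec: IMModelSpec
    ml_params: dict[str, float]
    lnl_composite: float
    lnl_saturated: float
    aic: float
    n_runs: int
    run_lnls: list[float]
    seed: int | None
    min_entry: int
    n_free: int
    improved: bool  # at least one run improved over its starting point

    @property
    def lnl_log10(self) -> float:
        """Composite log-likelihood in base 10 (fastsimcoal convention)."""
        return self.lnl_composite / np.log(10.0)


@dataclass
class BootstrapCI:
    ml: dict[str, float]
    q05: dict[str, float]
    q95: dict[str, float]
    n_boot: int
    nonconvergence_rate: float
    flagged: bool


# ---------------------------------------------------------------------------
# demography construction


def build_im_demography(spec: IMModelSpec, params: dict[str, float]) -> DemographyModel:
    """Translate an IM parameter vector to a two-population demography.

    Times are given in years and converted with ``spec.gen_time_years``;
    sizes are diploid.  The exponential size change of each modern
    population runs from the present back to ``T_s``; if a drawn
    ``T_s`` exceeds ``T_div`` it is truncated at the divergence time.
    """
    spec.validate(params)
    gen = spec.gen_time_years
    T_div = params["T_div"] / gen
    N_mod_IP, N_mod_AO = params["N_mod_IP"], params["N_mod_AO"]

    size_changes = []
    for pop, ts_name, anc_name in (
        ("IP", "T_s_IP", "N_anc_IP"),
        ("AO", "T_s_AO", "N_anc_AO"),
    ):
        t = min(params[ts_name] / gen, T_div)
        size_changes.append((pop, t, params[anc_name], "exponential-to"))

    def fmat(nm_ip_ao: float, nm_ao_ip: float) -> np.ndarray:
        # forward m[i][j]: fraction of pop j replaced by migrants from i
        m = np.zeros((2, 2))
        m[0, 1] = nm_ip_ao / N_mod_AO  # IP -> AO
        m[1, 0] = nm_ao_ip / N_mod_IP  # AO -> IP
        return m

    epochs = []
    v = spec.variant
    if v == "bsc":
        if params["Nm_IP_AO"] > 0 or params["Nm_AO_IP"] > 0:
            epochs.append((0.0, T_div, fmat(params["Nm_IP_AO"], params["Nm_AO_IP"])))
    elif v in ("full", "rec"):
        T_mig = min(params["T_mig"] / gen, T_div)
        if T_mig > 0 and (params["Nm1_IP_AO"] > 0 or params["Nm1_AO_IP"] > 0):
            epochs.append((0.0, T_mig, fmat(params["Nm1_IP_AO"], params["Nm1_AO_IP"])))
        if v == "full" and T_mig < T_div and (
            params["Nm2_IP_AO"] > 0 or params["Nm2_AO_IP"] > 0
        ):
            epochs.append((T_mig, T_div, fmat(params["Nm2_IP_AO"], params["Nm2_AO_IP"])))
    if v == "anc":
        T_mig = min(params["T_mig"] / gen, T_div)
        if T_mig < T_div and (params["Nm2_IP_AO"] > 0 or params["Nm2_AO_IP"] > 0):
            epochs.append((T_mig, T_div, fmat(params["Nm2_IP_AO"], params["Nm2_AO_IP"])))

    return DemographyModel(
        populations=[("IP", N_mod_IP), ("AO", N_mod_AO)],
        size_changes=size_changes,
        migration_epochs=epochs,
        merges=[(T_div, ["IP", "AO"], "ANC", params["N_anc"])],
    )


# ---------------------------------------------------------------------------
# expected SFS and composite likelihood


def _excluded_mask(n1: int, n2: int) -> np.ndarray:
    """Cells excluded from the likelihood: the two fixed/tie cells of
    the folded spectrum (their folding is convention-dependent)."""
    mask = np.zeros((n1 + 1, n2 + 1), dtype=bool)
    mask[n1, 0] = True
    mask[0, n2] = True
    return mask


def expected_2dsfs(
    spec: IMModelSpec,
    params: dict[str, float],
    n_sims: int = 300_000,
    seed: int | None = None,
    samples: tuple[int, int] = (6, 6),
) -> np.ndarray:
    """Monte-Carlo expected folded 2D-SFS entry probabilities per site.

    Averages the branch-length joint AFS over ``n_sims`` independent
    genealogies (same expectation as mutation sampling, lower
    variance), folds on the global minor allele, and converts branch
    lengths to per-site probabilities with the mutation rate.  The
    monomorphic cell is included (``p(0,0) = 1 - mu * E[total length]``):
    it carries the information that pins the absolute size/time scale —
    without it the likelihood is invariant under joint rescaling of all
    sizes and times.  The two fixed/tie cells are excluded, empty
    polymorphic cells are floored at 1/(10 n_sims) of the polymorphic
    mass, and the retained cells are renormalized.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be at least 1000")
    model = build_im_demography(spec, params)
    n1, n2 = 2 * samples[0], 2 * samples[1]
    reps = msprime.sim_ancestry(
        samples={"IP": samples[0], "AO": samples[1]},
        demography=model.to_msprime(),
        sequence_length=1,
        discrete_genome=False,
        num_replicates=n_sims,
        random_seed=(seed or 1) % (2**31 - 2) + 1,
    )
    sets = [np.arange(n1, dtype=np.int32), np.arange(n1, n1 + n2, dtype=np.int32)]
    total = np.zeros((n1 + 1, n2 + 1))
    for ts in reps:
        total += ts.allele_frequency_spectrum(
            sample_sets=sets, mode="branch", polarised=True, span_normalise=False
        )
    folded = Joint2DSFS(n1, n2, total, folded=False).fold().counts / n_sims
    folded *= spec.mu  # expected mutations per site per cell
    mask = _excluded_mask(n1, n2)
    ij = np.add.outer(np.arange(n1 + 1), np.arange(n2 + 1))
    keep_poly = ~mask & (ij <= (n1 + n2) / 2)
    keep_poly[0, 0] = False
    p = np.zeros_like(folded)
    poly_mass = folded[keep_poly].sum()
    floor = poly_mass / (10.0 * n_sims)
    p[keep_poly] = np.maximum(folded[keep_poly], floor)
    p[0, 0] = max(1.0 - poly_mass - folded[mask].sum(), floor)
    retained = keep_poly.copy()
    retained[0, 0] = True
    p[retained] /= p[retained].sum()
    return p


def composite_loglik(
    obs: Joint2DSFS | np.ndarray,
    expected: np.ndarray,
    min_entry: int = 10,
) -> float:
    """Multinomial composite log-likelihood with small-entry pooling.

    Cells (or 1D classes) with observed count below ``min_entry`` are
    pooled into a single class (counts and probabilities summed); the
    log-likelihood is ``sum_c m_c ln p_c`` over retained classes with
    probabilities renormalized on them.
    """
    counts = obs.counts if isinstance(obs, Joint2DSFS) else np.asarray(obs, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if counts.shape != expected.shape:
        raise ValueError("observed and expected shapes differ")
    keep = expected > 0
    m = counts[keep]
    p = expected[keep]
    p = p / p.sum()
    small = m < min_entry
    if small.all():
        raise ValueError("all entries pooled; likelihood uninformative")
    classes_m = list(m[~small])
    classes_p = list(p[~small])
    if small.any():
        classes_m.append(m[small].sum())
        classes_p.append(p[small].sum())
    mv = np.array(classes_m)
    pv = np.array(classes_p)
    pv = pv / pv.sum()
    nz = mv > 0
    return float((mv[nz] * np.log(pv[nz])).sum())


def saturated_loglik(obs: Joint2DSFS | np.ndarray, expected: np.ndarray, min_entry: int = 10) -> float:
    """Upper bound of the composite likelihood: observed proportions."""
    counts = obs.counts if isinstance(obs, Joint2DSFS) else np.asarray(obs, dtype=float)
    keep = np.asarray(expected) > 0
    m = counts[keep]
    small = m < min_entry
    if small.all():
        raise ValueError("all entries pooled; likelihood uninformative")
    mv = list(m[~small])
    if small.any():
        mv.append(m[small].sum())
    mv = np.array(mv)
    tot = mv.sum()
    nz = mv > 0
    return float((mv[nz] * np.log(mv[nz] / tot)).sum())


# ---------------------------------------------------------------------------
# maximization


def _structured_starts(
    spec: IMModelSpec,
    obs: Joint2DSFS,
    free: list[str],
    fixed: dict[str, float],
) -> list[tuple[str, dict[str, float]]]:
    """Data-driven starting points on a coarse regime grid.

    The size scale comes from Watterson moments of the observed
    marginal spectra (N = theta_w / 4mu); candidate divergence times
    are multiples of the coalescent time scale and migration covers the
    qualitative regimes (symmetric, strongly asymmetric either way,
    near-isolation).  Purely a search aid: no quantity outside the
    observed spectrum enters.
    """
    C = obs.counts
    n1, n2 = obs.n1_hap, obs.n2_hap
    L = max(C.sum(), 1.0)
    a1_1 = sum(1.0 / i for i in range(1, n1))
    a1_2 = sum(1.0 / i for i in range(1, n2))
    S1 = C[1:n1, :].sum()
    S2 = C[:, 1:n2].sum()
    N1 = max((S1 / (a1_1 * L)) / (4 * spec.mu), 100.0)
    N2 = max((S2 / (a1_2 * L)) / (4 * spec.mu), 100.0)
    N_bar = (N1 + N2) / 2.0
    gen = spec.gen_time_years

    nm_patterns = {
        "sym": (1.0, 1.0), "ip_to_ao": (5.0, 0.1),
        "ao_to_ip": (0.1, 5.0), "isolated": (0.1, 0.1),
    }
    starts = []
    for f_T in (0.25, 0.5, 1.0, 2.0):
        T_div = f_T * 4.0 * N_bar * gen  # years
        base = {
            "N_anc": N_bar, "N_mod_IP": N1, "N_mod_AO": N2,
            "N_anc_IP": N1, "N_anc_AO": N2,
            "T_s_IP": T_div / 3, "T_s_AO": T_div / 3, "T_div": T_div,
        }
        if spec.variant == "div":
            starts.append((f"t{f_T}", {**base, **fixed}))
            continue
        for label, (nm_ip_ao, nm_ao_ip) in nm_patterns.items():
            p = dict(base)
            if spec.variant == "bsc":
                p.update(Nm_IP_AO=nm_ip_ao, Nm_AO_IP=nm_ao_ip)
            else:
                p["T_mig"] = T_div / 2
                if spec.variant in ("full", "rec"):
                    p.update(Nm1_IP_AO=nm_ip_ao, Nm1_AO_IP=nm_ao_ip)
                if spec.variant in ("full", "anc"):
                    p.update(Nm2_IP_AO=nm_ip_ao, Nm2_AO_IP=nm_ao_ip)
            starts.append((label, {**p, **fixed}))
    return starts


def _transforms(spec: IMModelSpec, free: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Log10 search bounds for the free parameters."""
    lo, hi = [], []
    for p in free:
        b = spec.bounds[p]
        if p.startswith("Nm"):
            lo.append(np.log10(max(b[0], NM_FLOOR)))
            hi.append(np.log10(max(b[1], NM_FLOOR * 10)))
        else:
            lo.append(np.log10(b[0]))
            hi.append(np.log10(b[1]))
    return np.array(lo), np.array(hi)


def fit_model(
    spec: IMModelSpec,
    obs: Joint2DSFS,
    n_runs: int = 100,
    n_sims: int = 5000,
    seed: int | None = None,
    min_entry: int = 10,
    maxiter: int = 40,
    fixed_params: dict[str, float] | None = None,
    n_screen: int = 0,
    polish_maxiter: int = 0,
    n_deepen: int = 0,
    deepen_maxfev: int = 400,
    structured_starts: bool = True,
    refine_n_sims: int | None = None,
    refine_maxfev: int = 0,
    refine_restarts: int = 1,
    profile_migration: bool = False,
    profile_reopt: int = 10,
    profile_passes: int = 2,
) -> FitResult:
    """Best-of-``n_runs`` composite-likelihood maximization.

    Each of the ``n_runs`` random restarts (Latin-hypercube starts in
    log10 parameter space) is searched with bounded Nelder-Mead for at
    most ``maxiter`` outer cycles (``maxiter=0`` turns a restart into a
    single evaluation); within a run the expected-SFS seed is held
    fixed (common random numbers) so the objective is deterministic.
    ``structured_starts`` appends data-driven candidates (Watterson-
    moment size scale on a coarse divergence-time/migration-regime
    grid) to the random starts.  All endpoints are scored with one
    shared seed, and ``n_deepen`` of them — the best of each migration
    regime first, so one symmetric endpoint cannot crowd out the
    asymmetric candidates, then the remainder by score — are deepened
    with a wide-simplex adaptive Nelder-Mead run of ``deepen_maxfev``
    evaluations, which is what actually traverses the correlated
    valleys of this surface.  ``polish_maxiter`` adds a final
    continuation of the overall best point.  ``fixed_params`` pins a
    subset of parameters (they do not count as free in the AIC);
    ``n_screen`` extra starting points are screened by a single
    evaluation before the restarts.
    """
    fixed = dict(fixed_params or {})
    free = [p for p in spec.param_names if p not in fixed]
    if not free:
        raise ValueError("no free parameters")
    lo, hi = _transforms(spec, free)
    rng = np.random.default_rng(seed)
    n1h, n2h = obs.n1_hap // 2, obs.n2_hap // 2

    def to_params(x: np.ndarray) -> dict[str, float]:
        params = dict(fixed)
        for name, xv in zip(free, x):
            params[name] = 10.0**xv
        return params

    def objective(x: np.ndarray, sim_seed: int, ns: int | None = None) -> float:
        params = to_params(np.clip(x, lo, hi))
        if "T_mig" in params and params["T_mig"] > params["T_div"]:
            return 1e12
        try:
            p = expected_2dsfs(spec, params, n_sims=ns or n_sims, seed=sim_seed,
                               samples=(n1h, n2h))
            return -composite_loglik(obs, p, min_entry=min_entry)
        except Exception:
            # degenerate corners (e.g. vanishing sizes) can break the
            # coalescent machinery; treat them as -inf likelihood
            return 1e12

    n_start = max(n_runs + n_screen, n_runs)
    sampler = qmc.LatinHypercube(d=len(free), seed=rng.integers(2**31 - 1))
    starts = lo + sampler.random(n_start) * (hi - lo)
    run_seeds = rng.integers(1, 2**31 - 2, size=n_start)
    if n_screen > 0:
        screen = np.array(
            [objective(starts[i], int(run_seeds[i])) for i in range(n_start)]
        )
        order = np.argsort(screen)[:n_runs]
        starts, run_seeds = starts[order], run_seeds[order]
    classes = ["lhs"] * len(starts)
    if structured_starts:
        extra, extra_classes = [], []
        for label, p in _structured_starts(spec, obs, free, fixed):
            x = np.array([np.log10(max(p[name], NM_FLOOR)) for name in free])
            extra.append(np.clip(x, lo, hi))
            extra_classes.append(label)
        if extra:
            starts = np.vstack([starts, extra])
            classes = classes + extra_classes
            run_seeds = np.concatenate(
                [run_seeds, rng.integers(1, 2**31 - 2, size=len(extra))]
            )

    def nm(x0: np.ndarray, budget: int, sim_seed: int):
        return minimize(
            lambda x: objective(x, sim_seed),
            x0,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxiter": budget, "maxfev": 2 * budget + len(free) + 1,
                     "xatol": 1e-3, "fatol": 0.05},
        )

    def deep_nm(x0: np.ndarray, maxfev: int, sim_seed: int):
        """Wide-simplex adaptive Nelder-Mead: the initial simplex spans
        0.35 log-units per coordinate so the search can take the
        coordinated steps the correlated valleys of this surface need."""
        simplex = [x0]
        for i in range(len(free)):
            xt = x0.copy()
            xt[i] = xt[i] + 0.35 if xt[i] + 0.35 <= hi[i] else xt[i] - 0.35
            simplex.append(np.clip(xt, lo, hi))
        return minimize(
            lambda x: objective(x, sim_seed),
            x0,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={
                "maxfev": maxfev, "maxiter": maxfev, "xatol": 1e-4, "fatol": 0.01,
                "initial_simplex": np.array(simplex), "adaptive": True,
            },
        )

    common_seed = int(rng.integers(1, 2**31 - 2))
    run_lnls, run_xs, improved = [], [], False
    for r in range(len(starts)):
        sim_seed = int(run_seeds[r]) if maxiter > 0 else common_seed
        f0 = objective(starts[r], sim_seed)
        if maxiter > 0:
            res = nm(starts[r], maxiter, sim_seed)
            xr, fr = res.x, res.fun
        else:
            xr, fr = starts[r], f0
        run_lnls.append(-fr)
        run_xs.append(xr)
        if fr < f0 - 1e-9:
            improved = True
    if not improved and maxiter > 0:
        warnings.warn("no run improved over its starting point", stacklevel=2)

    if maxiter > 0:
        # re-score endpoints with one shared seed so ranking is comparable
        common_vals = np.array([objective(x, common_seed) for x in run_xs])
    else:
        common_vals = -np.asarray(run_lnls)
    order = np.argsort(common_vals)
    best_x = run_xs[order[0]]
    best_val = common_vals[order[0]]

    if n_deepen > 0:
        # regime-diverse selection: best endpoint of each structured
        # class first (by score), then everything else by score
        chosen: list[int] = []
        seen_classes: set[str] = set()
        for r in order:
            c = classes[r]
            if c != "lhs" and c not in seen_classes:
                chosen.append(r)
                seen_classes.add(c)
        for r in order:
            if r not in chosen:
                chosen.append(r)
        for r in chosen[:n_deepen]:
            res = deep_nm(run_xs[r], deepen_maxfev, common_seed)
            improved = improved or res.fun < common_vals[r] - 1e-9
            if res.fun < best_val:
                best_val, best_x = res.fun, res.x

    if polish_maxiter > 0:
        res = nm(best_x, polish_maxiter, common_seed)
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x

    mig_pairs = [
        (a, b)
        for a, b in (("Nm_IP_AO", "Nm_AO_IP"), ("Nm1_IP_AO", "Nm1_AO_IP"),
                     ("Nm2_IP_AO", "Nm2_AO_IP"))
        if a in free and b in free
    ]
    if profile_migration and mig_pairs:
        # profile-likelihood refinement of the migration pair: the two
        # rates trade off against the size/time nuisances along a curved
        # valley, so each candidate pair gets a brief nuisance
        # re-optimization before comparison (common random numbers
        # throughout keeps the comparisons paired)
        for mults in ((0.12, 0.5, 2.0, 8.0), (0.45, 1.0, 2.2))[: max(profile_passes, 1)]:
            for a, b in mig_pairs:
                ia, ib = free.index(a), free.index(b)
                others = [i for i in range(len(free)) if i not in (ia, ib)]
                base = best_x.copy()
                for ma in mults:
                    for mb in mults:
                        xs = base.copy()
                        xs[ia] = np.clip(base[ia] + np.log10(ma), lo[ia], hi[ia])
                        xs[ib] = np.clip(base[ib] + np.log10(mb), lo[ib], hi[ib])

                        def sub(y, xs=xs):
                            xt = xs.copy()
                            xt[others] = y
                            return objective(xt, common_seed)

                        res = minimize(
                            sub, xs[others], method="Nelder-Mead",
                            bounds=[(lo[i], hi[i]) for i in others],
                            options={"maxfev": profile_reopt,
                                     "maxiter": profile_reopt, "adaptive": True},
                        )
                        if res.fun < best_val:
                            xt = xs.copy()
                            xt[others] = res.x
                            best_val, best_x = res.fun, xt

    if refine_maxfev > 0 and refine_n_sims:
        # low-noise continuations: the Monte-Carlo error of the expected
        # SFS limits how finely weakly-constrained parameters (small
        # migration rates) can be resolved, so finish at a larger n_sims;
        # each restart draws a fresh seed and re-widens the simplex,
        # which frees the search from the noise features of the previous
        # common-random-numbers surface
        for _ in range(max(refine_restarts, 1)):
            ref_seed = int(rng.integers(1, 2**31 - 2))
            f_ref = objective(best_x, ref_seed, ns=refine_n_sims)
            simplex = [best_x]
            for i in range(len(free)):
                xt = best_x.copy()
                xt[i] = xt[i] + 0.12 if xt[i] + 0.12 <= hi[i] else xt[i] - 0.12
                simplex.append(np.clip(xt, lo, hi))
            res = minimize(
                lambda x: objective(x, ref_seed, ns=refine_n_sims),
                best_x,
                method="Nelder-Mead",
                bounds=list(zip(lo, hi)),
                options={"maxfev": refine_maxfev, "maxiter": refine_maxfev,
                         "xatol": 1e-4, "fatol": 0.01, "adaptive": True,
                         "initial_simplex": np.array(simplex)},
            )
            if res.fun < f_ref:
                best_x = res.x

    ml = to_params(np.clip(best_x, lo, hi))
    final_seed = int(rng.integers(1, 2**31 - 2))
    p_final = expected_2dsfs(
        spec, ml, n_sims=refine_n_sims or n_sims, seed=final_seed, samples=(n1h, n2h)
    )
    lnl = composite_loglik(obs, p_final, min_entry=min_entry)
    lnl_sat = saturated_loglik(obs, p_final, min_entry=min_entry)
    n_free = len(free)
    return FitResult(
        spec=spec,
        ml_params=ml,
        lnl_composite=lnl,
        lnl_saturated=lnl_sat,
        aic=2 * n_free - 2 * lnl,
        n_runs=n_runs,
        run_lnls=run_lnls,
        seed=seed,
        min_entry=min_entry,
        n_free=n_free,
        improved=improved,
    )


def select_model(fits: list[FitResult]) -> list[dict]:
    """Rank fitted models by AIC (ascending); reports delta-AIC."""
    if len({f.min_entry for f in fits}) > 1:
        raise ValueError("fits use different pooling thresholds")
    ranked = sorted(fits, key=lambda f: f.aic)
    best_aic = ranked[0].aic
    return [
        {
            "variant": f.spec.variant,
            "aic": f.aic,
            "delta_aic": f.aic - best_aic,
            "lnl": f.lnl_composite,
            "k": f.n_free,
        }
        for f in ranked
    ]


def distinguishability_check(
    fits: list[FitResult],
    obs: Joint2DSFS,
    n_rep: int = 100,
    n_sims: int = 100_000,
    seed: int | None = None,
) -> dict:
    """Likelihood-distribution overlap between fitted models.

    For each fit, the expected SFS at its ML parameters is re-estimated
    ``n_rep`` times (independent Monte-Carlo draws) and scored against
    the observed spectrum; two models are called distinguishable when
    their central 95% likelihood ranges are disjoint.  The verdict is
    symmetric in the model order.
    """
    if n_rep < 10:
        warnings.warn("n_rep < 10 gives an unstable verdict", stacklevel=2)
    rng = np.random.default_rng(seed)
    n1h, n2h = obs.n1_hap // 2, obs.n2_hap // 2
    dists = {}
    for f in fits:
        vals = []
        for _ in range(n_rep):
            p = expected_2dsfs(
                f.spec, f.ml_params, n_sims=n_sims,
                seed=int(rng.integers(1, 2**31 - 2)), samples=(n1h, n2h),
            )
            vals.append(composite_loglik(obs, p, min_entry=f.min_entry))
        dists[f.spec.variant] = np.array(vals)
    verdicts = {}
    names = sorted(dists)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            qa = np.quantile(dists[a], [0.025, 0.975])
            qb = np.quantile(dists[b], [0.025, 0.975])
            disjoint = qa[1] < qb[0] or qb[1] < qa[0]
            verdicts[f"{a}|{b}"] = "distinguishable" if disjoint else "not distinguishable"
    return {"distributions": dists, "verdicts": verdicts}


def parametric_bootstrap(
    spec: IMModelSpec,
    ml_params: dict[str, float],
    obs_cfg: SimConfig,
    n_boot: int = 100,
    seed: int | None = None,
    fit_kwargs: dict | None = None,
    boot_mode: str = "coalescent",
) -> BootstrapCI:
    """Parametric-bootstrap 90% confidence intervals.

    Simulates ``n_boot`` observed-size 2D-SFS at the ML parameters,
    refits each and takes the 5th/95th percentiles of the refitted
    estimates.  ``boot_mode="coalescent"`` resimulates genealogies and
    mutations per locus (full parametric variance);
    ``boot_mode="multinomial"`` draws site counts from the fitted
    expected spectrum — with short RAD loci carrying mostly 0-1 SNPs
    the two are nearly equivalent, and the multinomial route is much
    cheaper.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    if boot_mode not in ("coalescent", "multinomial"):
        raise ValueError("boot_mode must be 'coalescent' or 'multinomial'")
    fit_kwargs = dict(fit_kwargs or {})
    rng = np.random.default_rng(seed)
    model = build_im_demography(spec, ml_params)
    names = [p for p in spec.param_names if p not in fit_kwargs.get("fixed_params", {})]
    est = {p: [] for p in names}
    n_bad = 0
    n1h = obs_cfg.samples.get("IP", 0)
    n2h = obs_cfg.samples.get("AO", 0)
    p_fit = None
    if boot_mode == "multinomial":
        p_fit = expected_2dsfs(
            spec, ml_params, n_sims=max(fit_kwargs.get("n_sims", 5000), 5000),
            seed=int(rng.integers(1, 2**31 - 2)), samples=(n1h, n2h),
        )
    L_total = obs_cfg.n_loci * obs_cfg.locus_len_bp
    for _ in range(n_boot):
        if boot_mode == "multinomial":
            draw = rng.multinomial(L_total, p_fit.ravel() / p_fit.sum())
            boot = Joint2DSFS(2 * n1h, 2 * n2h, draw.reshape(p_fit.shape).astype(float),
                              folded=True)
        else:
            cfg = SimConfig(
                samples=dict(obs_cfg.samples), n_loci=obs_cfg.n_loci,
                locus_len_bp=obs_cfg.locus_len_bp, mu=obs_cfg.mu,
                gen_time_years=obs_cfg.gen_time_years,
                seed=int(rng.integers(1, 2**31 - 2)),
            )
            boot = sim_joint_sfs(model, cfg, pops=("IP", "AO"), fold=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_model(spec, boot, seed=int(rng.integers(1, 2**31 - 2)), **fit_kwargs)
            if not fit.improved:
                n_bad += 1
            for p in names:
                est[p].append(fit.ml_params[p])
        except ValueError:
            n_bad += 1
    rate = n_bad / n_boot
    q05 = {p: float(np.quantile(v, 0.05)) for p, v in est.items() if v}
    q95 = {p: float(np.quantile(v, 0.95)) for p, v in est.items() if v}
    return BootstrapCI(
        ml={p: ml_params[p] for p in names},
        q05=q05,
        q95=q95,
        n_boot=n_boot,
        nonconvergence_rate=rate,
        flagged=rate > 0.20,
    )
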