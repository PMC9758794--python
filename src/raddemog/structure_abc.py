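"""ABC model choice among spatial-structure scenarios for one sampling site.

A single sampling location cannot reveal structure through FST, but its
gene genealogy retains signatures of the metapopulation it sits in:
sampling one deme of a structured population mimics a bottleneck-like
site frequency spectrum.  Three scenarios are compared — no structure
(NS: one population with an instantaneous size change), finite island
(FIM: 100 demes, uniform migration) and two-dimensional stepping-stone
(SS: 100 demes, nearest-neighbour migration) — by simulating summary
statistics under parameter draws from priors and classifying the
observed summaries with a random forest, optionally augmented with
linear discriminant axes.  The forest's vote shares select the model
and a regression forest on out-of-bag misclassification supplies the
posterior probability of the selected model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from . import kingman
from .demography import build_fim, build_ss
from .sfs import FoldedSFS, diversity_stats
from .simulate import SimConfig, sim_tree_replicates

MODELS = ("NS", "FIM", "SS")


@dataclass
class ParamPrior:
    name: str
    dist: str  # "uniform" | "log-uniform"
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.low) and np.isfinite(self.high) and self.low < self.high):
            raise ValueError("prior bounds must be finite with low < high")
        if self.dist not in ("uniform", "log-uniform"):
            raise ValueError("dist must be 'uniform' or 'log-uniform'")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.dist == "uniform":
            return rng.uniform(self.low, self.high, size)
        return np.exp(rng.uniform(np.log(self.low), np.log(self.high), size))


def default_priors() -> dict[str, list[ParamPrior]]:
    """Wide priors bracketing the search bounds used for model fitting.

    Sizes are diploid, times in years (converted with the generation
    time at simulation), Nm in migrants per generation.
    """
    N = lambda name: ParamPrior(name, "log-uniform", 100, 100_000)
    T = lambda name: ParamPrior(name, "log-uniform", 100, 1_000_000)
    Nm = ParamPrior("Nm", "log-uniform", 0.05, 50)
    return {
        "NS": [N("N_mod"), N("N_anc"), T("T_s")],
        "FIM": [N("N_deme"), Nm, T("T_col"), N("N_anc")],
        "SS": [N("N_deme"), Nm, T("T_col"), N("N_anc")],
    }


@dataclass
class ReferenceTable:
    """Simulated summary statistics with model labels.

    ``frame`` holds one row per simulation: summary columns, then a
    ``model`` label column; LDA axis columns (``LD1``, ``LD2``) appear
    after :func:`add_lda_axes`.
    """

    frame: pd.DataFrame
    lda: LinearDiscriminantAnalysis | None = None

    def __post_init__(self) -> None:
        if "model" not in self.frame.columns:
            raise ValueError("reference table needs a 'model' column")
        if self.frame.isna().any().any():
            raise ValueError("reference table must not contain missing values")
        if self.frame["model"].nunique() < 2:
            raise ValueError("need at least two models in the reference table")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != "model"]

    def to_tsv(self, path: str, sidecar: dict | None = None) -> None:
        self.frame.to_csv(path, sep="\t", index=False)
        if sidecar is not None:
            with open(path + ".json", "w") as fh:
                json.dump(sidecar, fh, indent=2, default=str)

    @classmethod
    def from_tsv(cls, path: str) -> "ReferenceTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class ClassifierReport:
    votes: dict[str, float]
    selected: str
    posterior: float
    oob_error_curve: list[tuple[int, float]]
    n_trees_used: int


# ---------------------------------------------------------------------------
# summaries


def summaries_from_eta(eta: np.ndarray, n_hap: int, L: float) -> dict[str, float]:
    """Summary-statistic row from a folded SFS (proportions, theta_pi,
    theta_w, Tajima's D); degenerate S=0 rows get uniform proportions
    and D = 0 so the table stays complete."""
    eta = np.asarray(eta, dtype=float)
    S = eta.sum()
    half = n_hap // 2
    if S == 0:
        props = np.full(half, 1.0 / half)
        pi_s = tw = td = 0.0
    else:
        sfs = FoldedSFS(n_hap=n_hap, eta=eta, n_monomorphic=int(max(L - S, 0)))
        st = diversity_stats(sfs)
        props = eta / S
        pi_s, tw, td = st.theta_pi, st.theta_w, st.tajimas_d
    row = {f"sfs_{i + 1}": float(props[i]) for i in range(half)}
    row.update(theta_pi=float(pi_s), theta_w=float(tw), tajimas_d=float(td))
    return row


def observed_summaries(sfs: FoldedSFS) -> dict[str, float]:
    """Summaries of an observed folded SFS, matching the reference table."""
    return summaries_from_eta(sfs.eta, sfs.n_hap, sfs.L)


def _structured_eta(
    model_name: str, params: dict[str, float], cfg: SimConfig, n_hap: int, seed: int
) -> np.ndarray:
    """Folded SFS counts for one draw of a structured (100-deme) model.

    One deme is sampled (deme 0 for FIM, a central deme for SS) and
    mutations are Poisson-sampled on the summed branch-length AFS."""
    gen = cfg.gen_time_years
    if model_name == "FIM":
        dem = build_fim(params["N_deme"], params["Nm"], params["T_col"] / gen, params["N_anc"])
        deme = "deme0"
    else:
        dem = build_ss(params["N_deme"], params["Nm"], params["T_col"] / gen, params["N_anc"])
        deme = "deme55"  # central deme of the 10x10 grid
    sub = SimConfig(
        samples={deme: n_hap // 2}, n_loci=cfg.n_loci, locus_len_bp=cfg.locus_len_bp,
        mu=cfg.mu, gen_time_years=gen, seed=seed,
    )
    branch = np.zeros(n_hap - 1)
    for ts in sim_tree_replicates(dem, sub):
        branch += ts.allele_frequency_spectrum(mode="branch", polarised=True, span_normalise=False)[1:n_hap]
    rng = np.random.default_rng(seed + 1)
    return kingman.sample_folded_eta(branch[None, :], cfg.mu * cfg.locus_len_bp, rng)[0]


def simulate_reference(
    priors: dict[str, list[ParamPrior]],
    n_per_model: int,
    samples: int,
    cfg: SimConfig,
    seed: int | None = None,
) -> ReferenceTable:
    """Simulate the ABC reference table.

    ``samples`` is the diploid sample size of the (single) sampling
    site; each simulation draws parameters from the model's priors,
    simulates ``cfg.n_loci`` independent loci and records the summary
    statistics.  Rows are shuffled.
    """
    if n_per_model < 100:
        warnings.warn("n_per_model < 100 is test-mode only", stacklevel=2)
    rng = np.random.default_rng(seed)
    n_hap = 2 * samples
    gen = cfg.gen_time_years
    mu_locus = cfg.mu * cfg.locus_len_bp
    L = cfg.n_loci * cfg.locus_len_bp
    rows = []
    for model_name, model_priors in priors.items():
        draws = {p.name: p.draw(rng, n_per_model) for p in model_priors}
        if model_name == "NS":
            for r in range(n_per_model):
                epochs = [(0.0, draws["N_mod"][r])]
                ts_gen = draws["T_s"][r] / gen
                if ts_gen > 0:
                    epochs.append((ts_gen, draws["N_anc"][r]))
                branch = kingman.branch_afs(n_hap, cfg.n_loci, epochs, rng).sum(axis=0)
                eta = kingman.sample_folded_eta(branch[None, :], mu_locus, rng)[0]
                rows.append({**summaries_from_eta(eta, n_hap, L), "model": model_name})
        elif model_name in ("FIM", "SS"):
            for r in range(n_per_model):
                params = {k: v[r] for k, v in draws.items()}
                sub_seed = int(rng.integers(1, 2**31 - 2))
                eta = _structured_eta(model_name, params, cfg, n_hap, sub_seed)
                rows.append({**summaries_from_eta(eta, n_hap, L), "model": model_name})
        else:
            raise ValueError(f"unknown model {model_name!r}")
    frame = pd.DataFrame(rows).sample(frac=1.0, random_state=rng.integers(2**31 - 1))
    return ReferenceTable(frame.reset_index(drop=True))


# ---------------------------------------------------------------------------
# LDA augmentation and random-forest classification


def add_lda_axes(table: ReferenceTable) -> ReferenceTable:
    """Append the first two linear-discriminant projections as columns.

    With only two classes a single axis exists and a warning is issued.
    Collinear or duplicated summary columns are tolerated (the svd
    solver effectively regularizes them).
    """
    X = table.frame[table.feature_columns].to_numpy()
    y = table.frame["model"].to_numpy()
    n_axes = min(2, len(np.unique(y)) - 1)
    if n_axes < 2:
        warnings.warn("fewer than 3 classes: only one LDA axis appended", stacklevel=2)
    lda = LinearDiscriminantAnalysis(solver="svd", n_components=n_axes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinearity warnings from svd
        proj = lda.fit_transform(X, y)
    frame = table.frame.copy()
    for a in range(n_axes):
        frame[f"LD{a + 1}"] = proj[:, a]
    cols = [c for c in frame.columns if c != "model"] + ["model"]
    return ReferenceTable(frame[cols], lda=lda)


def classify(
    table: ReferenceTable,
    observed_stats: dict[str, float],
    n_trees: int = 500,
    seed: int | None = None,
    abcrf_posterior: bool = True,
    oob_step: int = 50,
    **rf_kwargs,
) -> ClassifierReport:
    """Random-forest model choice for one observed summary vector.

    Vote shares come from the forest's per-tree votes; the posterior
    probability of the selected model uses the two-step scheme of
    regressing the out-of-bag misclassification indicator on the
    summaries (``abcrf_posterior=False`` falls back to the vote share).
    The out-of-bag error is recorded every ``oob_step`` trees.
    """
    base_cols = [c for c in table.feature_columns if not c.startswith("LD")]
    obs = dict(observed_stats)
    if table.lda is not None:
        missing_ld = [c for c in table.feature_columns if c.startswith("LD") and c not in obs]
        if missing_ld:
            x = np.array([[obs[c] for c in base_cols]])
            proj = table.lda.transform(x)
            for a, c in enumerate(sorted(missing_ld)):
                obs[c] = float(proj[0, a])
    cols = table.feature_columns
    X = table.frame[cols].to_numpy()
    y = table.frame["model"].to_numpy()
    x_obs = np.array([[obs[c] for c in cols]])

    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.any(x_obs[0] < lo) or np.any(x_obs[0] > hi):
        warnings.warn(
            "observed summaries outside the range of the reference table "
            "(possible prior misfit)",
            stacklevel=2,
        )

    rf = RandomForestClassifier(
        n_estimators=0, warm_start=True, oob_score=True, random_state=seed, n_jobs=1,
        bootstrap=True, **rf_kwargs,
    )
    curve = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # few-tree OOB coverage warnings
        for t in range(oob_step, n_trees + 1, oob_step):
            rf.set_params(n_estimators=t)
            rf.fit(X, y)
            curve.append((t, float(1.0 - rf.oob_score_)))
        if rf.n_estimators < n_trees:
            rf.set_params(n_estimators=n_trees)
            rf.fit(X, y)
            curve.append((n_trees, float(1.0 - rf.oob_score_)))

    votes_arr = rf.predict_proba(x_obs)[0]
    votes = {cls: float(v) for cls, v in zip(rf.classes_, votes_arr)}
    selected = max(votes, key=votes.get)

    if abcrf_posterior:
        oob_pred = rf.classes_[np.argmax(rf.oob_decision_function_, axis=1)]
        misclass = (oob_pred != y).astype(float)
        reg = RandomForestRegressor(
            n_estimators=min(n_trees, 200), random_state=seed, n_jobs=1
        )
        reg.fit(X, misclass)
        posterior = float(np.clip(1.0 - reg.predict(x_obs)[0], 0.0, 1.0))
    else:
        posterior = votes[selected]

    return ClassifierReport(
        votes=votes,
        selected=selected,
        posterior=posterior,
        oob_error_curve=curve,
        n_trees_used=rf.n_estimators,
    )
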