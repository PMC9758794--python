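"""Parameterized demographic models and their coalescent translation.

:class:`DemographyModel` is a small declarative language — populations
with diploid sizes, instantaneous or exponential size changes,
migration epochs with forward-in-time rate matrices, and merges into
ancestral populations — that translates to an :class:`msprime.Demography`.
Times are generations, sizes are diploid effective sizes.

Builders cover the spatial-structure model family used for the
single-site structure test (no-structure, finite-island, 2D
stepping-stone); the two-population isolation/migration family lives in
:mod:`raddemog.imfit`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import msprime
import numpy as np

#: forward migration matrix entry m[i][j]: fraction of population j made of
#: new migrants from population i, each generation.
MigrationMatrix = np.ndarray


@dataclass
class DemographyModel:
    """Declarative demography: populations, size changes, migration, merges."""

    populations: list[tuple[str, float]]
    size_changes: list[tuple[str, float, float, str]] = field(default_factory=list)
    #: (t_start, t_end, forward matrix) — rates active on [t_start, t_end)
    migration_epochs: list[tuple[float, float, MigrationMatrix]] = field(default_factory=list)
    #: (time, derived labels, ancestral label, ancestral size)
    merges: list[tuple[float, list[str], str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(size <= 0 for _, size in self.populations):
            raise ValueError("population sizes must be positive")
        for pop, t, size, mode in self.size_changes:
            if t < 0 or size <= 0:
                raise ValueError("size-change times must be >= 0 and sizes > 0")
            if mode not in ("instantaneous", "exponential-to"):
                raise ValueError(f"unknown size-change mode {mode!r}")
        for t0, t1, m in self.migration_epochs:
            if not (0 <= t0 < t1):
                raise ValueError("migration epochs need 0 <= t_start < t_end")
            if np.any(np.asarray(m) < 0):
                raise ValueError("migration rates must be non-negative")
        for t, _, _, size in self.merges:
            if t < 0 or size <= 0:
                raise ValueError("merge times must be >= 0 and ancestral sizes > 0")

    @property
    def labels(self) -> list[str]:
        return [name for name, _ in self.populations]

    def initial_size(self, label: str) -> float:
        return dict(self.populations)[label]

    # -- msprime translation -------------------------------------------

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        labels = self.labels
        for name, size in self.populations:
            dem.add_population(name=name, initial_size=size)
        for t, derived, anc, anc_size in self.merges:
            if anc not in [p.name for p in dem.populations]:
                dem.add_population(name=anc, initial_size=anc_size)

        # size changes, per population in time order; exponential-to spans
        # from the previous event (or the present) to its own time
        by_pop: dict[str, list[tuple[float, float, str]]] = {}
        for pop, t, size, mode in self.size_changes:
            by_pop.setdefault(pop, []).append((t, size, mode))
        for pop, events in by_pop.items():
            events.sort()
            if [t for t, _, _ in events] != sorted({t for t, _, _ in events}):
                raise ValueError(f"duplicate size-change times for population {pop}")
            t_prev, size_prev = 0.0, self.initial_size(pop)
            for t, size, mode in events:
                if mode == "instantaneous":
                    dem.add_population_parameters_change(
                        time=t, population=pop, initial_size=size, growth_rate=0
                    )
                else:  # exponential-to: reach `size` at time t (backwards)
                    if t <= t_prev:
                        raise ValueError("exponential-to change needs a positive time span")
                    g = np.log(size_prev / size) / (t - t_prev)
                    if t_prev == 0:
                        dem[pop].growth_rate = g
                    else:
                        dem.add_population_parameters_change(
                            time=t_prev, population=pop, initial_size=size_prev, growth_rate=g
                        )
                    dem.add_population_parameters_change(
                        time=t, population=pop, initial_size=size, growth_rate=0
                    )
                t_prev, size_prev = t, size

        # migration epochs: msprime's matrix is backwards in time,
        # M[j][i] = forward rate i -> j
        idx = {name: i for i, name in enumerate(labels)}
        boundaries = sorted({t for t0, t1, _ in self.migration_epochs for t in (t0, t1)})
        for t0, t1, m in self.migration_epochs:
            m = np.asarray(m, dtype=float)
            if t0 == 0:
                k = len(labels)
                dem.migration_matrix[:k, :k] = m.T  # backward M[j][i] = forward m[i][j]
            else:
                for i, j in itertools.product(range(len(labels)), repeat=2):
                    if i != j:
                        dem.add_migration_rate_change(
                            time=t0, source=labels[j], dest=labels[i], rate=m[i, j]
                        )
        # zero all rates at epoch ends not covered by a following epoch
        covered = {t0 for t0, _, _ in self.migration_epochs}
        for t in boundaries:
            if t > 0 and t not in covered and np.isfinite(t):
                dem.add_migration_rate_change(time=t, rate=0)

        for t, derived, anc, anc_size in self.merges:
            # msprime caps the populations per split event; chunk large merges
            derived = list(derived)
            for i in range(0, len(derived), 90):
                dem.add_population_split(time=t, derived=derived[i : i + 90], ancestral=anc)
        dem.sort_events()
        return dem

    # -- structured text round trip ------------------------------------

    def to_dict(self) -> dict:
        return {
            "populations": [[n, s] for n, s in self.populations],
            "size_changes": [[p, t, s, m] for p, t, s, m in self.size_changes],
            "migration_epochs": [
                [t0, t1, np.asarray(m).tolist()] for t0, t1, m in self.migration_epochs
            ],
            "merges": [[t, list(d), a, s] for t, d, a, s in self.merges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographyModel":
        return cls(
            populations=[(n, float(s)) for n, s in d["populations"]],
            size_changes=[(p, float(t), float(s), m) for p, t, s, m in d["size_changes"]],
            migration_epochs=[
                (float(t0), float(t1), np.asarray(m, dtype=float))
                for t0, t1, m in d["migration_epochs"]
            ],
            merges=[(float(t), list(dd), a, float(s)) for t, dd, a, s in d["merges"]],
        )


# ---------------------------------------------------------------------------
# spatial-structure model builders (single sampling site test)


def build_ns(N_mod: float, N_anc: float, T_s_gen: float) -> DemographyModel:
    """No-structure model: one population whose size changes instantly
    from ``N_mod`` (present) to ``N_anc`` at ``T_s_gen`` generations."""
    changes = []
    if T_s_gen > 0 and N_mod != N_anc:
        changes.append(("deme0", float(T_s_gen), float(N_anc), "instantaneous"))
    size0 = N_anc if T_s_gen == 0 else N_mod
    return DemographyModel(populations=[("deme0", float(size0))], size_changes=changes)


def build_fim(
    N_deme: float,
    Nm: float,
    T_col_gen: float,
    N_anc: float,
    n_demes: int = 100,
) -> DemographyModel:
    """Finite-island metapopulation: ``n_demes`` demes of size ``N_deme``
    exchanging ``Nm`` migrants per generation with all other demes, all
    colonized instantaneously from an ancestor of size ``N_anc``."""
    if n_demes < 2:
        raise ValueError("need at least 2 demes")
    if Nm < 0:
        raise ValueError("Nm must be non-negative")
    labels = [f"deme{i}" for i in range(n_demes)]
    m = np.full((n_demes, n_demes), Nm / (N_deme * (n_demes - 1)))
    np.fill_diagonal(m, 0.0)
    return DemographyModel(
        populations=[(lab, float(N_deme)) for lab in labels],
        migration_epochs=[(0.0, float(T_col_gen), m)] if Nm > 0 else [],
        merges=[(float(T_col_gen), labels, "anc", float(N_anc))],
    )


def build_ss(
    N_deme: float,
    Nm: float,
    T_col_gen: float,
    N_anc: float,
    grid: tuple[int, int] = (10, 10),
) -> DemographyModel:
    """2D stepping-stone: demes on a non-periodic grid, migration only
    between the four nearest neighbours (edge demes have 2-3)."""
    rows, cols = grid
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    if Nm < 0:
        raise ValueError("Nm must be non-negative")
    n = rows * cols
    labels = [f"deme{i}" for i in range(n)]
    rate = Nm / (N_deme * 4.0)  # per-neighbour rate; interior demes receive Nm total
    m = np.zeros((n, n))
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    m[i, rr * cols + cc] = rate
    return DemographyModel(
        populations=[(lab, float(N_deme)) for lab in labels],
        migration_epochs=[(0.0, float(T_col_gen), m)] if Nm > 0 else [],
        merges=[(float(T_col_gen), labels, "anc", float(N_anc))],
    )
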