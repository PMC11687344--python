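"""Plant-pollinator interaction networks and Blüthgen's standardised specialisation d'.

The interaction network is a pollinator-by-plant-genus count matrix built from an
edge list of observed visits.  For each pollinator species we compute

* ``degree`` — the number of plant genera the species was recorded visiting;
* ``d`` — the Kullback-Leibler divergence between the species' interaction
  frequencies and partner "availability" (the column marginals of the network),
  d_i = sum_g p'_ig * ln(p'_ig / q_g) over genera the species uses;
* ``d'`` — d rescaled to [0, 1] by its achievable extremes given the species'
  total interaction count and the availability vector.

The upper extreme is exclusive use of a genus whose interactions all come from
the focal species, d_max = ln(m / A_i).  The lower extreme is the smallest d
achievable by an *integer* allocation of the species' A_i interactions across
genera; we find it by largest-remainder proportional rounding followed by local
one-unit swaps, and pin that heuristic against brute-force enumeration in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InteractionNetwork",
    "SpecializationScore",
    "availability",
    "kullback_leibler_d",
    "d_extremes",
    "d_min_bruteforce",
    "d_prime",
    "read_interactions",
]


@dataclass(frozen=True)
class InteractionNetwork:
    """Pollinator × plant-genus count matrix with its marginals.

    Rows with zero interactions are disallowed: a species never observed on a
    flower carries no information about specialisation.
    """

    counts: np.ndarray          # (n_pollinators, n_genera) non-negative ints
    pollinators: list[str]
    genera: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if c.size == 0 or c.sum() == 0:
            raise ValueError("empty interaction network")
        if (c < 0).any():
            raise ValueError("interaction counts must be non-negative")
        if (c.sum(axis=1) == 0).any():
            bad = [self.pollinators[i] for i in np.flatnonzero(c.sum(axis=1) == 0)]
            raise ValueError(f"species with zero interactions must be excluded: {bad}")

    @property
    def row_totals(self) -> np.ndarray:
        return np.asarray(self.counts).sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return np.asarray(self.counts).sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(np.asarray(self.counts).sum())

    @classmethod
    def from_edge_list(cls, edges: pd.DataFrame) -> "InteractionNetwork":
        """Build the network from an edge list with columns
        ``pollinator_species, plant_genus, count`` (a ``source`` column, if
        present, is provenance only and ignored here).

        Species whose total count is zero are dropped.
        """
        required = {"pollinator_species", "plant_genus", "count"}
        missing = required - set(edges.columns)
        if missing:
            raise ValueError(f"edge list missing columns: {sorted(missing)}")
        if (edges["count"] < 0).any():
            raise ValueError("interaction counts must be non-negative")
        mat = edges.pivot_table(
            index="pollinator_species", columns="plant_genus",
            values="count", aggfunc="sum", fill_value=0,
        )
        mat = mat.loc[mat.sum(axis=1) > 0]
        if mat.empty:
            raise ValueError("empty interaction network")
        return cls(
            counts=mat.to_numpy(dtype=np.int64),
            pollinators=list(mat.index.astype(str)),
            genera=list(mat.columns.astype(str)),
        )


@dataclass(frozen=True)
class SpecializationScore:
    species_id: str
    d: float
    d_min: float
    d_max: float
    d_prime: float
    degree: int


def availability(network: InteractionNetwork) -> np.ndarray:
    """Partner availability q_g: the share of all interactions received by each
    plant genus (the network's column marginal, normalised to sum to one)."""
    m = network.grand_total
    if m == 0:
        raise ValueError("empty interaction network")
    return network.column_totals / m


def kullback_leibler_d(row: np.ndarray, q: np.ndarray) -> float:
    """KL divergence d_i between a species' interaction frequencies and
    availability, summed only over genera the species actually uses."""
    row = np.asarray(row, dtype=float)
    a_i = row.sum()
    if a_i <= 0:
        raise ValueError("species has no interactions (A_i = 0)")
    used = row > 0
    if (np.asarray(q)[used] <= 0).any():
        raise ValueError("availability must be positive on genera the species uses")
    p = row[used] / a_i
    return float(np.sum(p * np.log(p / np.asarray(q)[used])))


def _alloc_d(alloc: np.ndarray, q: np.ndarray) -> float:
    used = alloc > 0
    p = alloc[used] / alloc.sum()
    return float(np.sum(p * np.log(p / q[used])))


def d_min_bruteforce(a_i: int, q: np.ndarray) -> float:
    """Minimum d over all integer allocations of a_i interactions to the genera
    with availability q.  Exponential in the number of genera; used as the test
    oracle for the greedy heuristic on small problems."""
    q = np.asarray(q)
    usable = np.flatnonzero(q > 0)
    q = q[usable]
    n_g = len(q)
    best = np.inf
    for cuts in itertools.combinations_with_replacement(range(n_g), a_i):
        alloc = np.bincount(np.array(cuts), minlength=n_g)
        best = min(best, _alloc_d(alloc, q))
    return best


def _d_min_greedy(a_i: int, q: np.ndarray) -> float:
    """Largest-remainder proportional allocation followed by local one-unit
    swaps until no swap lowers d.  Remainder ties break toward the lower genus
    index (deterministic)."""
    # genera no pollinator uses have zero availability and can never lower d
    usable = np.flatnonzero(q > 0)
    if usable.size < len(q):
        inner = _d_min_greedy(a_i, q[usable])
        return inner
    n_g = len(q)
    ideal = a_i * q
    alloc = np.floor(ideal).astype(np.int64)
    short = a_i - alloc.sum()
    if short > 0:
        remainders = ideal - alloc
        # stable sort descending on remainder -> ties to lower index
        order = np.argsort(-remainders, kind="stable")
        alloc[order[:short]] += 1
    best = _alloc_d(alloc, q)
    improved = True
    while improved:
        improved = False
        donors = np.flatnonzero(alloc > 0)
        for src in donors:
            for dst in range(n_g):
                if dst == src:
                    continue
                alloc[src] -= 1
                alloc[dst] += 1
                val = _alloc_d(alloc, q)
                if val < best - 1e-15:
                    best = val
                    improved = True
                else:
                    alloc[src] += 1
                    alloc[dst] -= 1
    return best


def d_extremes(row: np.ndarray, network: InteractionNetwork) -> tuple[float, float]:
    """Achievable (d_min, d_max) for a species with this interaction row.

    d_max = ln(m / A_i): the species uses a single genus exclusively and is that
    genus's only visitor.  d_min comes from the greedy integer allocation.
    """
    row = np.asarray(row)
    a_i = int(row.sum())
    if a_i < 1:
        raise ValueError("species has no interactions (A_i = 0)")
    m = network.grand_total
    q = availability(network)
    d_max = float(np.log(m / a_i))
    d_min = _d_min_greedy(a_i, q)
    return d_min, d_max


def d_prime(network: InteractionNetwork) -> list[SpecializationScore]:
    """Standardised specialisation d' = (d - d_min)/(d_max - d_min) and degree
    for every pollinator species in the network.

    Degenerate networks where d_max = d_min (a species that is the whole
    network) get d' = 0: with no alternative partners there is no
    specialisation signal.
    """
    q = availability(network)
    counts = np.asarray(network.counts)
    scores = []
    for i, sp in enumerate(network.pollinators):
        row = counts[i]
        d = kullback_leibler_d(row, q)
        d_min, d_max = d_extremes(row, network)
        if d_max - d_min > 1e-12:
            dp = (d - d_min) / (d_max - d_min)
        else:
            dp = 0.0
        dp = float(np.clip(dp, 0.0, 1.0))
        scores.append(SpecializationScore(
            species_id=sp, d=d, d_min=d_min, d_max=d_max, d_prime=dp,
            degree=int((row > 0).sum()),
        ))
    return scores


def read_interactions(path) -> InteractionNetwork:
    """Read an interaction edge list CSV (pollinator_species, plant_genus,
    count[, source]) and build the network."""
    return InteractionNetwork.from_edge_list(pd.read_csv(path))


def scores_frame(scores: list[SpecializationScore]) -> pd.DataFrame:
    """Tabulate specialisation scores (one row per pollinator species)."""
    return pd.DataFrame(
        [(s.species_id, s.degree, s.d, s.d_min, s.d_max, s.d_prime) for s in scores],
        columns=["species_id", "degree", "d", "d_min", "d_max", "d_prime"],
    )
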