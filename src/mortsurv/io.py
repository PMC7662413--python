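"""Input/output for mortality tables, region-adjacency graphs, and result tables.

The mortality input is a long-format CSV with one row per
(area, age group, year, sex) cell and columns
``area, age_group, year, sex, deaths, population, decile``.
Age groups are serialized as ``"0-0"``, ``"1-4"``, ``"5-9"``, ..., ``"90+"``:
a label ``"a-b"`` denotes the half-open interval ``[a, b+1)`` in years and a
trailing ``+`` marks the open-ended last group.

The region graph uses the plain-text convention common in disease mapping:
the first line is the number of areas N, and each subsequent line reads
``node-index degree neighbor-indices...`` with 1-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MortalityDataset",
    "AdjacencyGraph",
    "read_mortality_table",
    "read_region_graph",
    "write_region_graph",
    "write_table",
    "parse_age_label",
    "format_age_group",
]

VALID_SEXES = ("female", "male")


def parse_age_label(label: str) -> tuple[int, int | None]:
    """Parse an age-group label into a half-open interval ``(lower, upper)``.

    ``"0-0"`` -> ``(0, 1)``; ``"1-4"`` -> ``(1, 5)``; ``"90+"`` -> ``(90, None)``.
    """
    label = str(label).strip()
    if label.endswith("+"):
        return int(label[:-1]), None
    if "-" not in label:
        raise ValueError(f"malformed age-group label {label!r}")
    lo, hi = label.split("-", 1)
    lower, upper = int(lo), int(hi) + 1
    if upper <= lower:
        raise ValueError(f"empty age interval in label {label!r}")
    return lower, upper


def format_age_group(interval: tuple[int, int | None]) -> str:
    lower, upper = interval
    if upper is None:
        return f"{lower}+"
    return f"{lower}-{upper - 1}"


@dataclass
class AdjacencyGraph:
    """Symmetric areal adjacency, 0-based internally.

    ``neighbors[i]`` lists the nodes adjacent to node ``i``; the relation is
    symmetric and irreflexive. Node order matches the dataset's area order.
    """

    n_nodes: int
    neighbors: list[list[int]]

    def __post_init__(self) -> None:
        if len(self.neighbors) != self.n_nodes:
            raise ValueError("neighbor list length does not match node count")
        seen = [set(nbrs) for nbrs in self.neighbors]
        for i, nbrs in enumerate(self.neighbors):
            if len(seen[i]) != len(nbrs):
                raise ValueError(f"duplicate neighbor entries at node {i + 1}")
            for j in nbrs:
                if not 0 <= j < self.n_nodes:
                    raise ValueError(f"neighbor index {j + 1} out of range at node {i + 1}")
                if j == i:
                    raise ValueError(f"self-loop at node {i + 1}")
                if i not in seen[j]:
                    raise ValueError(
                        f"asymmetric adjacency: node {i + 1} lists {j + 1} but not vice versa"
                    )

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(n) for n in self.neighbors], dtype=int)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edge list with i < j."""
        return [(i, j) for i, nbrs in enumerate(self.neighbors) for j in nbrs if i < j]

    @property
    def n_edges(self) -> int:
        return len(self.edges())

    def n_components(self) -> int:
        import networkx as nx

        return nx.number_connected_components(self.to_networkx())

    def is_connected(self) -> bool:
        return self.n_components() == 1

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges())
        return g


@dataclass
class MortalityDataset:
    """Dense death/population tensors for one sex.

    ``deaths`` and ``population`` are indexed ``(area i, age group j, year t)``.
    ``decile`` maps each area id to its deprivation decile, 1 = most deprived.
    """

    area_ids: list[str]
    age_groups: list[tuple[int, int | None]]
    years: list[int]
    sex: str
    deaths: np.ndarray
    population: np.ndarray
    decile: dict[str, int] = field(repr=False)

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths)
        self.population = np.asarray(self.population, dtype=float)
        shape = (len(self.area_ids), len(self.age_groups), len(self.years))
        if self.deaths.shape != shape or self.population.shape != shape:
            raise ValueError(f"tensor shape mismatch, expected {shape}")
        if self.sex not in VALID_SEXES:
            raise ValueError(f"sex must be one of {VALID_SEXES}, got {self.sex!r}")
        if len(set(self.area_ids)) != len(self.area_ids):
            raise ValueError("area ids are not unique")
        if np.any(self.deaths < 0) or not np.issubdtype(self.deaths.dtype, np.integer):
            raise ValueError("deaths must be non-negative integers")
        if np.any(self.population < 0):
            raise ValueError("population must be non-negative")
        bad = (self.population == 0) & (self.deaths > 0)
        if np.any(bad):
            i, j, t = (int(x[0]) for x in np.nonzero(bad))
            raise ValueError(
                "deaths > 0 with zero population at "
                f"(area {self.area_ids[i]}, age {format_age_group(self.age_groups[j])}, "
                f"year {self.years[t]})"
            )
        yrs = list(self.years)
        if yrs != list(range(yrs[0], yrs[0] + len(yrs))):
            raise ValueError("years must be consecutive calendar years")
        self._check_age_grid()
        missing = set(self.area_ids) - set(self.decile)
        if missing:
            raise ValueError(f"areas without a decile: {sorted(missing)}")
        for a in self.area_ids:
            d = self.decile[a]
            if not (isinstance(d, (int, np.integer)) and 1 <= d <= 10):
                raise ValueError(f"decile for area {a} outside 1..10: {d}")

    def _check_age_grid(self) -> None:
        groups = self.age_groups
        if groups[0][0] != 0 or groups[0][1] != 1:
            raise ValueError("first age group must be [0, 1)")
        if groups[-1][1] is not None:
            raise ValueError("last age group must be open-ended")
        for k in range(len(groups) - 1):
            lo, hi = groups[k]
            if hi is None or hi <= lo:
                raise ValueError(f"malformed closed age interval {groups[k]}")
            if hi != groups[k + 1][0]:
                raise ValueError(
                    f"age groups not contiguous between {format_age_group(groups[k])} "
                    f"and {format_age_group(groups[k + 1])}"
                )

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_ages(self) -> int:
        return len(self.age_groups)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_deciles(self) -> int:
        return max(self.decile.values())

    @property
    def decile_index(self) -> np.ndarray:
        """0-based decile index per area, aligned with ``area_ids``."""
        return np.array([self.decile[a] - 1 for a in self.area_ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table matching the CSV layout of :func:`read_mortality_table`."""
        rows = []
        for i, a in enumerate(self.area_ids):
            for j, g in enumerate(self.age_groups):
                for t, y in enumerate(self.years):
                    rows.append(
                        (a, format_age_group(g), y, self.sex,
                         int(self.deaths[i, j, t]), float(self.population[i, j, t]),
                         self.decile[a])
                    )
        return pd.DataFrame(
            rows,
            columns=["area", "age_group", "year", "sex", "deaths", "population", "decile"],
        )


REQUIRED_COLUMNS = ["area", "age_group", "year", "sex", "deaths", "population", "decile"]


def read_mortality_table(path, sex: str) -> MortalityDataset:
    """Read and validate a long-format mortality CSV for one sex.

    Every (area, age group, year) combination must be present exactly once;
    missing cells are an error, never silently zero-filled.
    """
    if sex not in VALID_SEXES:
        raise ValueError(f"sex must be one of {VALID_SEXES}, got {sex!r}")
    df = pd.read_csv(path)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"mortality table missing columns: {missing_cols}")
    df = df[df["sex"] == sex]
    if df.empty:
        raise ValueError(f"no rows for sex={sex!r}")

    dup = df.duplicated(["area", "age_group", "year"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(
            f"duplicate row for (area {r['area']}, age {r['age_group']}, year {r['year']})"
        )

    areas = sorted(df["area"].astype(str).unique())
    labels = sorted(df["age_group"].astype(str).unique(), key=lambda s: parse_age_label(s)[0])
    age_groups = [parse_age_label(s) for s in labels]
    years = sorted(int(y) for y in df["year"].unique())

    # decile must be constant per area
    dmap: dict[str, int] = {}
    for a, grp in df.groupby(df["area"].astype(str))["decile"]:
        vals = set(int(v) for v in grp.unique())
        if len(vals) != 1:
            raise ValueError(f"area {a} has conflicting deciles {sorted(vals)}")
        dmap[a] = vals.pop()

    ai = {a: k for k, a in enumerate(areas)}
    ji = {g: k for k, g in enumerate(labels)}
    ti = {y: k for k, y in enumerate(years)}
    shape = (len(areas), len(labels), len(years))
    deaths = np.full(shape, -1, dtype=np.int64)
    pop = np.zeros(shape, dtype=float)
    for row in df.itertuples(index=False):
        i, j, t = ai[str(row.area)], ji[str(row.age_group)], ti[int(row.year)]
        deaths[i, j, t] = int(row.deaths)
        pop[i, j, t] = float(row.population)
    if np.any(deaths < 0):
        i, j, t = (int(x[0]) for x in np.nonzero(deaths < 0))
        raise ValueError(
            f"missing cell for (area {areas[i]}, age {labels[j]}, year {years[t]})"
        )
    return MortalityDataset(
        area_ids=areas, age_groups=age_groups, years=years, sex=sex,
        deaths=deaths, population=pop, decile=dmap,
    )


def read_region_graph(path) -> AdjacencyGraph:
    """Read a plain-text region graph (``N`` then ``node degree neighbors...``)."""
    with open(path) as fh:
        tokens = [line.split() for line in fh if line.strip()]
    if not tokens:
        raise ValueError("empty graph file")
    n = int(tokens[0][0])
    if len(tokens) - 1 != n:
        raise ValueError(f"expected {n} node lines, found {len(tokens) - 1}")
    neighbors: list[list[int]] = [[] for _ in range(n)]
    seen_nodes = set()
    for parts in tokens[1:]:
        node = int(parts[0])
        if not 1 <= node <= n:
            raise ValueError(f"node index {node} out of range 1..{n}")
        if node in seen_nodes:
            raise ValueError(f"duplicate line for node {node}")
        seen_nodes.add(node)
        degree = int(parts[1])
        nbrs = [int(x) for x in parts[2:]]
        if len(nbrs) != degree:
            raise ValueError(
                f"node {node} declares degree {degree} but lists {len(nbrs)} neighbors"
            )
        for m in nbrs:
            if not 1 <= m <= n:
                raise ValueError(f"neighbor index {m} out of range at node {node}")
        neighbors[node - 1] = [m - 1 for m in nbrs]
    return AdjacencyGraph(n_nodes=n, neighbors=neighbors)


def write_region_graph(graph: AdjacencyGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{graph.n_nodes}\n")
        for i, nbrs in enumerate(graph.neighbors):
            parts = [str(i + 1), str(len(nbrs))] + [str(j + 1) for j in sorted(nbrs)]
            fh.write(" ".join(parts) + "\n")


def write_table(records, path) -> None:
    """Write a result table (DataFrame or list of dicts) as a headed CSV.

    Values round-trip at full ``repr`` precision, so re-reading reproduces them.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, index=False)
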