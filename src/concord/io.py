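"""Reading and writing networks and overlapping community covers.

Networks are plain undirected simple graphs stored as whitespace-separated
edge lists (one ``u v`` pair per line, ``#`` comments allowed).  Covers use
the SNAP ``cmty`` dialect: one community per line, whitespace-separated
integer node ids.  Node ids may be arbitrary integers; they are kept as-is
and only remapped to dense indices inside numerical routines.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "CommunityCover",
    "read_edge_list",
    "write_edge_list",
    "read_community_file",
    "write_community_file",
    "filter_ground_truth",
    "internal_density",
]


class CommunityCover:
    """An overlapping community assignment: an ordered list of node-id sets.

    A node may appear in any number of communities (including several),
    which is what distinguishes a *cover* from a partition.  Every
    community is non-empty; order is preserved because file round-trips
    are expected to be loss-less up to line order.
    """

    def __init__(self, communities: Iterable[Iterable[int]]):
        comms = [set(map(int, c)) for c in communities]
        if any(len(c) == 0 for c in comms):
            raise ValueError("communities must be non-empty")
        self.communities: list[set[int]] = comms

    def __len__(self) -> int:
        return len(self.communities)

    def __iter__(self) -> Iterator[set[int]]:
        return iter(self.communities)

    def __getitem__(self, i: int) -> set[int]:
        return self.communities[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityCover):
            return NotImplemented
        return self.communities == other.communities

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"CommunityCover({len(self)} communities, {len(self.nodes())} nodes)"

    def nodes(self) -> set[int]:
        """Union of all communities."""
        out: set[int] = set()
        for c in self.communities:
            out |= c
        return out

    def memberships(self, node: int) -> list[int]:
        """Indices of the communities containing ``node``."""
        return [i for i, c in enumerate(self.communities) if node in c]

    def membership_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for c in self.communities:
            for v in c:
                counts[v] = counts.get(v, 0) + 1
        return counts

    def overlapping_nodes(self) -> set[int]:
        """Nodes belonging to more than one community (O_n numerator)."""
        return {v for v, k in self.membership_counts().items() if k > 1}


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected simple graph from a whitespace edge list.

    Duplicate lines and reversed duplicates collapse to a single edge.
    Self-loops are rejected.  Lines starting with ``#`` and blank lines
    are skipped.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two integer tokens, got {line!r}"
                )
            try:
                u, v = int(tokens[0]), int(tokens[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer token in {line!r}"
                ) from exc
            if u == v:
                raise ValueError(f"{path}: line {lineno}: self-loop {u}-{v} rejected")
            g.add_edge(u, v)
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in g.edges():
            fh.write(f"{u} {v}\n")


def read_community_file(path: str | Path) -> CommunityCover:
    """Read a cover in the SNAP ``cmty`` dialect (one community per line)."""
    comms: list[set[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                members = {int(tok) for tok in line.split()}
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer token"
                ) from exc
            comms.append(members)
    return CommunityCover(comms)


def write_community_file(cover: CommunityCover, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in cover:
            fh.write(" ".join(str(v) for v in sorted(c)) + "\n")


def internal_density(community: set[int], g: nx.Graph) -> float:
    """Fraction of realised internal edges, 2 m_C / (n_C (n_C - 1)).

    Singleton communities have no possible internal edge and get density 0.
    """
    n = len(community)
    if n < 2:
        return 0.0
    m = g.subgraph(community).number_of_edges()
    return 2.0 * m / (n * (n - 1))


def filter_ground_truth(
    cover: CommunityCover,
    g: nx.Graph,
    top_k: int = 5000,
    min_size: int = 5,
    density_quartile: bool = True,
) -> CommunityCover:
    """Apply the ground-truth filtering pipeline used for annotated covers.

    Steps, in order: keep the ``top_k`` largest communities; rank survivors
    by internal density and discard the bottom quartile (``floor(0.25 n)``
    lowest, smaller community discarded first on ties); drop exact duplicate
    node sets; drop communities smaller than ``min_size``.

    The quartile cut is applied before de-duplication; that ordering is an
    assumption of this implementation (see docs/methods.md).
    """
    if len(cover) == 0:
        raise ValueError("cover is empty")
    if top_k < 1 or min_size < 1:
        raise ValueError("top_k and min_size must be >= 1")
    for c in cover:
        missing = c - set(g.nodes())
        if missing:
            raise ValueError(f"community contains nodes absent from network: {sorted(missing)[:5]}")

    # 1. top_k largest (stable on ties: earlier community first)
    order = sorted(range(len(cover)), key=lambda i: (-len(cover[i]), i))
    kept = [cover[i] for i in order[:top_k]]

    # 2. bottom density quartile discarded
    if density_quartile and kept:
        n_drop = int(0.25 * len(kept))
        if n_drop > 0:
            dens = [(internal_density(c, g), len(c), i) for i, c in enumerate(kept)]
            # lowest density first; ties: smaller community discarded first
            drop = {i for _, _, i in sorted(dens, key=lambda t: (t[0], t[1], t[2]))[:n_drop]}
            kept = [c for i, c in enumerate(kept) if i not in drop]

    # 3. exact-duplicate removal (first occurrence survives)
    seen: set[frozenset[int]] = set()
    deduped = []
    for c in kept:
        key = frozenset(c)
        if key not in seen:
            seen.add(key)
            deduped.append(c)

    # 4. minimum size
    final = [c for c in deduped if len(c) >= min_size]
    return CommunityCover(final)
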