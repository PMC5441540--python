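"""Word-trajectory graphs and their connectedness attributes.

Each unique word of a report is a node; every consecutive token pair
contributes one directed edge (a multigraph: repeated transitions are
repeated edges, so E = token count - 1 and directly tracks verbosity).
Three attributes summarize connectedness:

* ``E``   - number of edges (word-to-word transitions);
* ``LCC`` - node count of the largest component linked by some path when
  edge direction is ignored (weak connectivity);
* ``LSC`` - node count of the largest component whose members are all
  mutually reachable along directed paths, i.e. the largest strongly
  connected component. LSC captures recurrent "loop" structure in speech.

Normalized attributes divide by word rate (tokens produced in the
time-limited report). For protocols without a time limit, verbosity is
instead controlled by averaging attributes over sliding 30-word windows
(:func:`windowed_attributes`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ConnectednessAttributes",
    "build_graph",
    "connectedness",
    "sequence_attributes",
    "windowed_attributes",
    "write_edgelist_tsv",
]


@dataclass(frozen=True)
class ConnectednessAttributes:
    """Connectedness profile of one report.

    Invariant: 1 <= LSC <= LCC <= number of nodes <= word_rate, and
    E = word_rate - 1 for a single contiguous report.
    """

    E: int
    LCC: int
    LSC: int
    word_rate: int

    def __post_init__(self) -> None:
        if self.word_rate <= 0:
            raise ValueError("word_rate must be positive")
        if not (1 <= self.LSC <= self.LCC):
            raise ValueError(f"require 1 <= LSC ({self.LSC}) <= LCC ({self.LCC})")
        if self.E < 0:
            raise ValueError("E must be nonnegative")

    @property
    def E_norm(self) -> float:
        return self.E / self.word_rate

    @property
    def LCC_norm(self) -> float:
        return self.LCC / self.word_rate

    @property
    def LSC_norm(self) -> float:
        return self.LSC / self.word_rate

    def as_dict(self) -> dict[str, float]:
        return {
            "E": self.E, "LCC": self.LCC, "LSC": self.LSC,
            "word_rate": self.word_rate,
            "E_norm": self.E_norm, "LCC_norm": self.LCC_norm,
            "LSC_norm": self.LSC_norm,
        }


def build_graph(tokens: Sequence[str], *, keep_self_loops: bool = True) -> nx.MultiDiGraph:
    """Build the directed word-trajectory multigraph of a token sequence.

    Nodes are distinct tokens; edges are ``(tokens[i], tokens[i+1])`` for
    every i, with order and repeats retained. A consecutively repeated word
    yields a self-loop edge unless ``keep_self_loops=False`` (the node is
    kept either way).
    """
    if len(tokens) == 0:
        raise ValueError("cannot build a graph from an empty token sequence")
    g = nx.MultiDiGraph()
    g.add_nodes_from(tokens)
    for i, (u, v) in enumerate(zip(tokens[:-1], tokens[1:])):
        if u == v and not keep_self_loops:
            continue
        g.add_edge(u, v, occurrence_index=i)
    return g


def connectedness(graph: nx.MultiDiGraph, word_rate: int) -> ConnectednessAttributes:
    """Compute E, LCC, LSC (and normalized forms) of a word-trajectory graph."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    if word_rate <= 0:
        raise ValueError("word_rate must be positive")
    E = graph.number_of_edges()
    lcc = max(len(c) for c in nx.weakly_connected_components(graph))
    lsc = max(len(c) for c in nx.strongly_connected_components(graph))
    return ConnectednessAttributes(E=E, LCC=lcc, LSC=lsc, word_rate=word_rate)


def sequence_attributes(
    tokens: Sequence[str], *, keep_self_loops: bool = True
) -> ConnectednessAttributes:
    """Connectedness attributes of one contiguous report (word rate = token count)."""
    return connectedness(build_graph(tokens, keep_self_loops=keep_self_loops), len(tokens))


def windowed_attributes(
    tokens: Sequence[str],
    window: int = 30,
    step: int = 1,
    *,
    keep_self_loops: bool = True,
) -> dict[str, float]:
    """Average connectedness attributes over sliding windows of tokens.

    Builds a graph on each window of ``window`` consecutive tokens advanced
    by ``step`` (default 1, maximal overlap), computes per-window
    attributes, and returns their arithmetic means. Used to control
    verbosity differences in protocols without a time limit.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    n = len(tokens)
    if n < window:
        raise ValueError(
            f"report has {n} tokens, fewer than window={window}; "
            "use whole-report attributes instead"
        )
    rows = []
    for start in range(0, n - window + 1, step):
        chunk = tokens[start:start + window]
        rows.append(sequence_attributes(chunk, keep_self_loops=keep_self_loops).as_dict())
    keys = rows[0].keys()
    return {k: float(np.mean([r[k] for r in rows])) for k in keys}


def write_edgelist_tsv(graph: nx.MultiDiGraph, path) -> None:
    """Export the trajectory as a directed edge list (TSV: source, target,
    occurrence_index), loadable by standard graph tools."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\toccurrence_index\n")
        edges = sorted(
            graph.edges(data="occurrence_index"), key=lambda e: (e[2] is None, e[2])
        )
        for u, v, occ in edges:
            fh.write(f"{u}\t{v}\t{'' if occ is None else occ}\n")


# ---------------------------------------------------------------------------
# Fast path on integer-coded sequences.
#
# The surrogate engine evaluates the largest strongly connected component of
# hundreds of thousands of small shuffled trajectories; going through a
# networkx MultiDiGraph for each costs ~5x more than this compact iterative
# Tarjan on the integer-coded token sequence. Equivalence with networkx is
# asserted by tests (and against a brute-force reachability oracle).
# ---------------------------------------------------------------------------

def encode_tokens(tokens: Sequence[str]) -> np.ndarray:
    """Map tokens to dense integer codes (first-occurrence order is irrelevant)."""
    _, codes = np.unique(np.asarray(tokens, dtype=object), return_inverse=True)
    return codes.astype(np.int64)


def max_scc_size_codes(codes: Sequence[int]) -> int:
    """Largest strongly connected component size of a coded trajectory.

    ``codes`` must use dense nonnegative integers. Iterative Tarjan; a
    single node counts as a (trivial) strong component of size 1, with or
    without a self-loop.
    """
    codes = list(codes)
    if not codes:
        raise ValueError("empty sequence")
    n = max(codes) + 1
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in zip(codes[:-1], codes[1:]):
        adj[a].append(b)
    index = [-1] * n
    low = [0] * n
    on_stack = [False] * n
    stack: list[int] = []
    best = 1
    counter = 0
    for root in range(n):
        if index[root] != -1:
            continue
        work: list[tuple[int, int]] = [(root, 0)]
        while work:
            v, pi = work[-1]
            if pi == 0:
                index[v] = low[v] = counter
                counter += 1
                stack.append(v)
                on_stack[v] = True
            descend = False
            neighbors = adj[v]
            for i in range(pi, len(neighbors)):
                w = neighbors[i]
                if index[w] == -1:
                    work[-1] = (v, i + 1)
                    work.append((w, 0))
                    descend = True
                    break
                elif on_stack[w] and index[w] < low[v]:
                    low[v] = index[w]
            if descend:
                continue
            work.pop()
            if low[v] == index[v]:
                size = 0
                while True:
                    w = stack.pop()
                    on_stack[w] = False
                    size += 1
                    if w == v:
                        break
                if size > best:
                    best = size
            if work:
                u = work[-1][0]
                if low[v] < low[u]:
                    low[u] = low[v]
    return best
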