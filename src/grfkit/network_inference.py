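"""Combinatorial inference of strongly connected regulatory networks.

Each candidate node carries a menu of pre-fitted regulations (best form per
allowed input set, sizes 1 or 2).  A network picks one regulation per node;
its score is the arithmetic mean of the chosen node scores, so networks can
be ranked exactly without refitting.  Only strongly connected networks are
admitted: in a closed oscillator module every gene must be reachable from
every other along regulation edges.  Declared external drivers (e.g. a
cyclin input) are excluded from the connectivity requirement.
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dataio import GeneTimeSeries, InteractionMatrix
from .fitting import FitResult

__all__ = ["NodeCandidateSet", "NetworkModel", "periodicity_score",
           "select_candidate_tfs", "is_strongly_connected",
           "enumerate_networks", "rank_report"]


@dataclass
class NodeCandidateSet:
    """Pre-fitted regulation menu for one gene (best form per input set)."""

    gene: str
    candidates: list[FitResult]

    def __post_init__(self):
        seen = set()
        for c in self.candidates:
            if c.gene != self.gene:
                raise ValueError(f"candidate for {c.gene!r} in set of {self.gene!r}")
            key = frozenset(c.inputs)
            if key in seen:
                raise ValueError(f"{self.gene}: duplicate input set {set(key)}")
            if len(key) not in (1, 2):
                raise ValueError(f"{self.gene}: input sets must have size 1 or 2")
            seen.add(key)


@dataclass
class NetworkModel:
    """A closed ODE-ready network: one regulation per node plus rate maps."""

    nodes: dict[str, FitResult]
    lam: dict[str, float] = field(default_factory=dict)
    delta: dict[str, float] = field(default_factory=dict)
    externals: tuple[str, ...] = ()

    def __post_init__(self):
        self.externals = tuple(self.externals)
        known = set(self.nodes) | set(self.externals)
        for gene, fit in self.nodes.items():
            for inp in fit.inputs:
                if inp not in known:
                    raise ValueError(
                        f"input {inp!r} of node {gene!r} is neither a node "
                        f"nor a declared external")

    @property
    def score(self) -> float:
        """Network score: mean of node scores."""
        return float(np.mean([f.score for f in self.nodes.values()]))

    def graph(self, include_externals: bool = False) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for gene, fit in self.nodes.items():
            for inp in fit.inputs:
                if inp in self.nodes or include_externals:
                    g.add_edge(inp, gene)
        return g

    def topology(self) -> dict[str, frozenset[str]]:
        return {g: frozenset(f.inputs) for g, f in self.nodes.items()}

    def to_dict(self) -> dict:
        return {"nodes": {g: f.to_dict() for g, f in self.nodes.items()},
                "lam": dict(self.lam), "delta": dict(self.delta),
                "externals": list(self.externals), "score": self.score}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        return cls(nodes={g: FitResult.from_dict(f) for g, f in d["nodes"].items()},
                   lam=dict(d.get("lam", {})), delta=dict(d.get("delta", {})),
                   externals=tuple(d.get("externals", ())))


def periodicity_score(series: GeneTimeSeries, period: float = 60.0,
                      bandwidth: int = 1) -> float:
    """Fraction of (mean-removed) spectral power near the given period.

    Stand-in periodicity statistic: the original ranking method for DTA
    data is an external procedure; this simple power-fraction score is NOT
    that method and exists so periodicity flags can be computed
    self-containedly.  Power is summed over ``bandwidth`` Fourier bins
    around the bin closest to 1/period.
    """
    v = series.values - series.values.mean()
    power = np.abs(np.fft.rfft(v)) ** 2
    power[0] = 0.0
    total = power.sum()
    if total == 0:
        return 0.0
    dt = float(np.diff(series.grid.times).mean())
    freqs = np.fft.rfftfreq(v.size, d=dt)
    k = int(np.argmin(np.abs(freqs - 1.0 / period)))
    lo, hi = max(k - bandwidth, 1), min(k + bandwidth, power.size - 1)
    return float(power[lo:hi + 1].sum() / total)


def select_candidate_tfs(periodic_flags: dict[str, bool],
                         interactions: InteractionMatrix,
                         merge: dict[str, str] | None = None) -> list[str]:
    """Iterated pruning to the maximal periodic subset in which every gene
    has at least one regulator and one target inside the subset.

    ``merge`` maps absorbed genes onto their surviving homolog (e.g. a
    second redundant activator folded into the first); the merged node
    inherits the union of edges before pruning.
    """
    merge = merge or {}
    edges = set()
    for (r, t) in interactions.allowed:
        r, t = merge.get(r, r), merge.get(t, t)
        if r != t:
            edges.add((r, t))
    alive = {merge.get(g, g) for g, flag in periodic_flags.items() if flag}
    changed = True
    while changed:
        changed = False
        for g in sorted(alive):
            has_reg = any((r, g) in edges and r in alive for r in alive)
            has_tgt = any((g, t) in edges and t in alive for t in alive)
            if not (has_reg and has_tgt):
                alive.discard(g)
                changed = True
    if not alive:
        warnings.warn("candidate-TF selection pruned every gene", stacklevel=2)
    return sorted(alive)


def is_strongly_connected(network: NetworkModel | nx.DiGraph) -> bool:
    """Every node reaches every other along regulation edges; externals are
    not part of the connectivity graph."""
    g = network.graph() if isinstance(network, NetworkModel) else network
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_nodes() == 1:
        return True
    return nx.is_strongly_connected(g)


def enumerate_networks(candidates: dict[str, NodeCandidateSet],
                       lam: dict[str, float] | None = None,
                       delta: dict[str, float] | None = None,
                       externals: tuple[str, ...] = (),
                       require_strongly_connected: bool = True):
    """Lazily yield candidate networks in ascending network-score order.

    One candidate regulation is chosen per node; because node scores are
    independent of the combination, the mean score ranks combinations
    exactly and a best-first heap enumerates them without materializing
    the full product space.  Networks failing the strong-connectivity
    requirement are skipped.
    """
    genes = sorted(candidates)
    if not genes:
        raise ValueError("no candidate nodes")
    menus = []
    for g in genes:
        menu = sorted(candidates[g].candidates, key=lambda f: f.score)
        if not menu:
            raise ValueError(f"gene {g!r} has no candidate regulations")
        menus.append(menu)

    def build(index: tuple[int, ...]) -> NetworkModel:
        return NetworkModel(
            nodes={g: menus[i][index[i]] for i, g in enumerate(genes)},
            lam=dict(lam or {}), delta=dict(delta or {}), externals=externals)

    start = (0,) * len(genes)
    total0 = sum(m[0].score for m in menus)
    heap = [(total0, start)]
    seen = {start}
    yielded = 0
    while heap:
        total, index = heapq.heappop(heap)
        net = build(index)
        ok = True
        if require_strongly_connected:
            try:
                ok = is_strongly_connected(net)
            except ValueError:
                ok = False
        if ok:
            yielded += 1
            yield net
        for i in range(len(genes)):
            if index[i] + 1 < len(menus[i]):
                nxt = index[:i] + (index[i] + 1,) + index[i + 1:]
                if nxt not in seen:
                    seen.add(nxt)
                    delta_s = menus[i][index[i] + 1].score - menus[i][index[i]].score
                    heapq.heappush(heap, (total + delta_s, nxt))
    if yielded == 0:
        warnings.warn("no strongly connected network among the combinations",
                      stacklevel=2)


def rank_report(stream, top_k: int = 5) -> list[dict]:
    """Take the top-k networks from an (already score-ordered) enumeration
    and report per-node input sets, forms and scores, with differences to
    the rank-1 network highlighted."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    top = list(itertools.islice(stream, top_k))
    report = []
    best_topology = top[0].topology() if top else {}
    for rank, net in enumerate(top, start=1):
        diffs = [g for g, inp in net.topology().items()
                 if inp != best_topology.get(g)]
        report.append({
            "rank": rank,
            "score": net.score,
            "nodes": {g: {"inputs": sorted(f.inputs),
                          "form": f.spec.form.value,
                          "score": f.score}
                      for g, f in sorted(net.nodes.items())},
            "differs_from_rank1_at": sorted(diffs),
        })
    return report
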