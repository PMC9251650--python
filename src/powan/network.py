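"""mtDNA haplotypes and median-joining networks.

`collapse_haplotypes` merges identical aligned sequences (sites containing a
gap or IUPAC ambiguity in any sequence are excluded alignment-wide before
comparison, the convention of the usual network software; configurable).
`median_joining` builds the Bandelt-Forster-Röhl network: iterate between an
epsilon-relaxed minimum spanning network over Hamming distances and the
addition of median (Steiner) vectors — per-site majority consensus of
connected node triples — whenever the median shortens the triple's
connection cost, pruning median vectors of degree < 3 at each round, until a
fixpoint.  With epsilon = 0 the result contains a minimum spanning tree of
the observed haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from Bio import SeqIO

_UNAMBIGUOUS = set("ACGT")


@dataclass
class HaplotypeSet:
    sequences: list              # distinct haplotypes (strings over kept sites)
    labels: list                 # canonical label per haplotype (H1, H2, ...)
    frequency: np.ndarray        # sample count per haplotype
    pop_counts: dict             # label -> {population: count}
    kept_sites: np.ndarray       # alignment columns retained
    members: dict                # label -> list of input sequence names

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)


def read_alignment(path) -> list:
    """Aligned FASTA -> [(name, sequence)]; unequal lengths are an error."""
    recs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not recs:
        raise ValueError(f"{path}: empty alignment")
    lens = {len(s) for _, s in recs}
    if len(lens) != 1:
        raise ValueError(f"{path}: sequences have unequal lengths {sorted(lens)}")
    return recs


def collapse_haplotypes(alignment, pop_of: dict | None = None,
                        exclude_ambiguous: bool = True) -> HaplotypeSet:
    """Merge identical sequences into haplotypes with frequencies.

    `alignment` is a FASTA path or a list of (name, sequence).  With
    exclude_ambiguous, any column holding a non-ACGT character in any
    sequence is removed before comparison, so sequences differing only at
    such columns merge.  Haplotypes are labelled H1, H2, ... in order of
    decreasing frequency (ties: first appearance).
    """
    recs = read_alignment(alignment) if not isinstance(alignment, list) else alignment
    if not recs:
        raise ValueError("empty alignment")
    lens = {len(s) for _, s in recs}
    if len(lens) != 1:
        raise ValueError(f"sequences have unequal lengths {sorted(lens)}")
    length = lens.pop()
    if exclude_ambiguous:
        keep = np.array([all(s[i] in _UNAMBIGUOUS for _, s in recs)
                         for i in range(length)])
    else:
        keep = np.ones(length, dtype=bool)
    kept = np.flatnonzero(keep)
    groups: dict = {}
    order = []
    for name, seq in recs:
        h = "".join(seq[i] for i in kept)
        if h not in groups:
            groups[h] = []
            order.append(h)
        groups[h].append(name)
    ranked = sorted(order, key=lambda h: (-len(groups[h]), order.index(h)))
    labels = [f"H{i + 1}" for i in range(len(ranked))]
    freq = np.array([len(groups[h]) for h in ranked])
    pop_counts = {}
    for lab, h in zip(labels, ranked):
        cnt: dict = {}
        for name in groups[h]:
            pop = (pop_of or {}).get(name, "all")
            cnt[pop] = cnt.get(pop, 0) + 1
        pop_counts[lab] = cnt
    return HaplotypeSet(ranked, labels, freq, pop_counts, kept,
                        {lab: groups[h] for lab, h in zip(labels, ranked)})


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _median(a: str, b: str, c: str) -> str | None:
    """Per-site majority consensus of three sequences; None when any site is
    a three-way tie (no new ambiguity is invented)."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            return None
    return "".join(out)


@dataclass
class MJNetwork:
    graph: nx.Graph              # nodes: labels; edge attr 'weight' = steps
    sequences: dict              # label -> sequence (observed + medians)
    observed: list               # labels of observed haplotypes
    medians: list                # labels of retained median vectors

    def total_weight(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node1\tnode2\tsteps\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']}\n")


def median_joining(h: HaplotypeSet, epsilon: int = 0,
                   max_rounds: int = 50) -> MJNetwork:
    """Bandelt-Forster-Röhl median-joining network (see module docstring).

    Raises RuntimeError with the current node set if the median-addition
    loop has not converged after max_rounds rounds.
    """
    if h.n_haplotypes < 2:
        raise ValueError("median-joining needs at least two haplotypes")
    seqs = dict(zip(h.labels, h.sequences))
    observed = list(h.labels)
    n_median = 0
    for _ in range(max_rounds):
        net = _build_msn(seqs, epsilon)
        # prune median vectors of degree < 3 (they lie on, or off, a path an
        # observed-to-observed edge of equal cost replaces)
        pruned = True
        while pruned:
            pruned = False
            for v in list(net.nodes):
                if v not in observed and net.degree(v) < 3:
                    del seqs[v]
                    net = _build_msn(seqs, epsilon)
                    pruned = True
        added = False
        nodes = sorted(net.nodes)
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                if not net.has_edge(u, v):
                    continue
                for w in nodes:
                    if w in (u, v) or not (net.has_edge(u, w) or net.has_edge(v, w)):
                        continue
                    m = _median(seqs[u], seqs[v], seqs[w])
                    if m is None or m in seqs.values():
                        continue
                    cost_with = (_hamming(seqs[u], m) + _hamming(seqs[v], m)
                                 + _hamming(seqs[w], m))
                    cost_now = (_hamming(seqs[u], seqs[v])
                                + min(_hamming(seqs[u], seqs[w]),
                                      _hamming(seqs[v], seqs[w])))
                    if cost_with < cost_now:
                        n_median += 1
                        seqs[f"mv{n_median}"] = m
                        added = True
        if not added:
            graph = _build_msn(seqs, epsilon)
            medians = [n for n in graph.nodes if n not in observed]
            return MJNetwork(graph, seqs, observed, medians)
    raise RuntimeError(
        f"median_joining did not converge in {max_rounds} rounds; "
        f"nodes: {sorted(seqs)}")


def _build_msn(seqs: dict, epsilon: int) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network.

    Process candidate edges in increasing weight; an edge (u, v) of weight w
    is kept when its endpoints were in different connected components before
    edges of weight w - epsilon were processed (epsilon = 0: the union of
    all minimum spanning trees).  Deterministic by (weight, label) ordering.
    """
    nodes = sorted(seqs)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    edges = sorted(((_hamming(seqs[u], seqs[v]), u, v)
                    for i, u in enumerate(nodes) for v in nodes[i + 1:]),
                   key=lambda e: (e[0], e[1], e[2]))
    parent = {u: u for u in nodes}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    levels = sorted({w for w, _, _ in edges})
    for lvl in levels:
        # components as they stood before edges of weight lvl - epsilon
        cutoff = lvl - epsilon
        pre = {u: u for u in nodes}

        def pfind(u):
            while pre[u] != u:
                pre[u] = pre[pre[u]]
                u = pre[u]
            return u

        for w, u, v in edges:
            if w >= cutoff:
                break
            ru, rv = pfind(u), pfind(v)
            if ru != rv:
                pre[ru] = rv
        for w, u, v in edges:
            if w == lvl and pfind(u) != pfind(v):
                g.add_edge(u, v, weight=w)
    # connectivity guaranteed: every MST edge satisfies the criterion
    return g
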