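"""Backward-time coalescent simulation for multi-deme demographies.

The demography is a set of named demes with diploid effective sizes and a
time-ordered (backward, in generations) event list of population splits,
admixture pulses and size changes.  Splits move all lineages of a derived
deme into its ancestor; a pulse at time t moves each lineage currently in the
admixed deme into the donor deme with probability alpha — the backward-time
dual of an instantaneous admixture event contributing a fraction alpha of the
deme's ancestry.  Between events each deme follows the standard neutral
coalescent (pair rate 1/(2N_e) per generation).

Mutations follow the infinite-sites model: Poisson(mu * L * branch length)
per branch, each mutation defining one biallelic site carried by the sampled
genes descending from that branch.  Loci are unlinked and non-recombining, as
appropriate for short ddRAD loci thinned to independence.

Two implementation layers share one algorithm: a readable pure-Python
genealogy builder (`simulate_genealogy`) for tree-level work, and a compiled
batch walker (`powan._engine`) behind `simulate_msfs`, `branch_length_spectrum`
and `simulate_genotypes`, which is what inference and the data generator use.
Batch simulations are reproducible bit-for-bit given (model, samples, seed),
with per-locus counter-derived substreams so enlarging n_loci never changes
earlier loci.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import _engine
from .msfs import MSFS, strides_for

# dense configuration-space ceiling for SFS accumulation; larger sample
# layouts must be down-sampled or projected first
MAX_DENSE_CONFIGS = 1 << 26


@dataclass(frozen=True)
class Deme:
    name: str
    size: float  # diploid effective size N_e

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError(f"deme {self.name}: N_e must be > 0, got {self.size}")


@dataclass(frozen=True)
class Split:
    """At `time` (backward) the `derived` deme merges into `ancestral`."""
    time: float
    derived: str
    ancestral: str


@dataclass(frozen=True)
class Pulse:
    """At `time`, a fraction `proportion` of `dest`'s ancestry comes from `source`.

    Backward in time, each lineage in `dest` moves to `source` with
    probability `proportion`.
    """
    time: float
    dest: str
    source: str
    proportion: float


@dataclass(frozen=True)
class SizeChange:
    """Backward of `time`, `deme` has diploid effective size `size`."""
    time: float
    deme: str
    size: float


class ModelError(ValueError):
    pass


@dataclass
class DemographicModel:
    demes: list
    events: list = field(default_factory=list)
    mutation_rate: float = 1e-8     # per bp per generation
    generation_time: float = 3.5    # years
    locus_length: int = 142         # bp per unlinked locus

    # -- validation ---------------------------------------------------------
    def validate(self) -> "DemographicModel":
        """Normalize (time-sort) the event list and check consistency.

        Raises ModelError on: non-positive or non-finite event times, pulse
        proportions outside [0, 1], events naming unknown demes, events
        scheduled on a deme after it has merged into its ancestor, repeated
        splits of one deme, or a forest that does not leave exactly one
        ancestral deme.
        """
        names = [d.name for d in self.demes]
        if len(set(names)) != len(names):
            raise ModelError(f"duplicate deme names in {names}")
        known = set(names)
        events = sorted(self.events, key=lambda e: e.time)
        merged_at = {}  # deme -> time it merges into its parent
        for ev in events:
            if not np.isfinite(ev.time) or ev.time <= 0:
                raise ModelError(f"event time must be positive and finite: {ev}")
            involved = (
                (ev.derived, ev.ancestral) if isinstance(ev, Split)
                else (ev.dest, ev.source) if isinstance(ev, Pulse)
                else (ev.deme,)
            )
            for nm in involved:
                if nm not in known:
                    raise ModelError(f"event {ev} names unknown deme {nm!r}")
                if nm in merged_at and ev.time >= merged_at[nm]:
                    raise ModelError(
                        f"event {ev} involves deme {nm!r} after it merged at "
                        f"t={merged_at[nm]}")
            if isinstance(ev, Split):
                merged_at[ev.derived] = ev.time
            elif isinstance(ev, Pulse):
                if not 0.0 <= ev.proportion <= 1.0:
                    raise ModelError(f"pulse proportion outside [0, 1]: {ev}")
            elif not isinstance(ev, SizeChange):
                raise ModelError(f"unknown event type: {ev!r}")
        roots = known - set(merged_at)
        if len(roots) != 1:
            raise ModelError(
                f"model must leave exactly one ancestral deme; found {sorted(roots)}")
        return replace(self, events=events)

    # -- engine encoding ----------------------------------------------------
    def _encode(self, samples_genes: dict):
        """Flatten to the arrays the compiled walker consumes."""
        m = self.validate()
        names = [d.name for d in m.demes]
        idx = {nm: i for i, nm in enumerate(names)}
        for nm, g in samples_genes.items():
            if nm not in idx:
                raise ModelError(f"samples reference unknown deme {nm!r}")
            if g < 0:
                raise ModelError(f"negative sample size for deme {nm!r}")
        D = len(names)
        sizes0 = np.array([2.0 * d.size for d in m.demes])  # gene-copy units
        init = np.zeros(D, dtype=np.int64)
        for nm, g in samples_genes.items():
            init[idx[nm]] = g
        if init.sum() < 2:
            raise ModelError("need at least two sampled gene copies overall")
        samp_dim = np.flatnonzero(init > 0).astype(np.int64)
        sample_sizes = init[samp_dim]
        stride = strides_for(sample_sizes)
        E = len(m.events)
        ev_time = np.empty(E)
        ev_type = np.empty(E, dtype=np.int64)
        ev_a = np.empty(E, dtype=np.int64)
        ev_b = np.empty(E, dtype=np.int64)
        ev_x = np.empty(E)
        for i, ev in enumerate(m.events):
            ev_time[i] = ev.time
            if isinstance(ev, Split):
                ev_type[i], ev_a[i], ev_b[i], ev_x[i] = 0, idx[ev.derived], idx[ev.ancestral], 0.0
            elif isinstance(ev, Pulse):
                ev_type[i], ev_a[i], ev_b[i], ev_x[i] = 1, idx[ev.dest], idx[ev.source], ev.proportion
            else:
                ev_type[i], ev_a[i], ev_b[i], ev_x[i] = 2, idx[ev.deme], -1, 2.0 * ev.size
        deme_names = tuple(names[d] for d in samp_dim)
        return dict(sizes0=sizes0, init=init, samp_dim=samp_dim, stride=stride,
                    ev_time=ev_time, ev_type=ev_type, ev_a=ev_a, ev_b=ev_b,
                    ev_x=ev_x, sample_sizes=sample_sizes, deme_names=deme_names)

    # -- config round-trip --------------------------------------------------
    def to_dict(self) -> dict:
        evs = []
        for ev in self.events:
            if isinstance(ev, Split):
                evs.append({"type": "split", "time": ev.time,
                            "derived": ev.derived, "ancestral": ev.ancestral})
            elif isinstance(ev, Pulse):
                evs.append({"type": "pulse", "time": ev.time, "dest": ev.dest,
                            "source": ev.source, "proportion": ev.proportion})
            else:
                evs.append({"type": "size", "time": ev.time,
                            "deme": ev.deme, "size": ev.size})
        return {"demes": [{"name": d.name, "size": d.size} for d in self.demes],
                "events": evs, "mutation_rate": self.mutation_rate,
                "generation_time": self.generation_time,
                "locus_length": self.locus_length}

    @classmethod
    def from_dict(cls, cfg: dict) -> "DemographicModel":
        demes = [Deme(d["name"], float(d["size"])) for d in cfg["demes"]]
        events = []
        for ev in cfg.get("events", []):
            t = ev["type"]
            if t == "split":
                events.append(Split(float(ev["time"]), ev["derived"], ev["ancestral"]))
            elif t == "pulse":
                events.append(Pulse(float(ev["time"]), ev["dest"], ev["source"],
                                    float(ev["proportion"])))
            elif t == "size":
                events.append(SizeChange(float(ev["time"]), ev["deme"], float(ev["size"])))
            else:
                raise ModelError(f"unknown event type {t!r}")
        return cls(demes, events,
                   mutation_rate=float(cfg.get("mutation_rate", 1e-8)),
                   generation_time=float(cfg.get("generation_time", 3.5)),
                   locus_length=int(cfg.get("locus_length", 142))).validate()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DemographicModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def validate(model: DemographicModel) -> DemographicModel:
    return model.validate()


def _genes(samples: dict, ploidy: int) -> dict:
    return {nm: int(n) * ploidy for nm, n in samples.items() if n > 0}


# ---------------------------------------------------------------------------
# pure-Python genealogy layer
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """Binary coalescent tree: leaves 0..n-1, internal nodes appended in
    coalescence order, root last; times in generations before present."""

    parent: np.ndarray       # int, -1 for the root
    time: np.ndarray         # node ages
    leaf_deme: tuple         # deme name per leaf

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_deme)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def tmrca(self) -> float:
        return float(self.time[-1])

    def total_branch_length(self) -> float:
        keep = self.parent >= 0
        return float(np.sum(self.time[self.parent[keep]] - self.time[keep]))

    def branch_lengths(self) -> np.ndarray:
        out = np.zeros(self.n_nodes)
        keep = self.parent >= 0
        out[keep] = self.time[self.parent[keep]] - self.time[keep]
        return out

    def leaves_below(self) -> np.ndarray:
        """Boolean (n_nodes, n_leaves) descendant-leaf indicator."""
        below = np.zeros((self.n_nodes, self.n_leaves), dtype=bool)
        below[np.arange(self.n_leaves), np.arange(self.n_leaves)] = True
        for v in range(self.n_nodes - 1):  # children precede parents
            below[self.parent[v]] |= below[v]
        return below


def simulate_genealogy(model: DemographicModel, samples: dict, seed: int,
                       ploidy: int = 2) -> Genealogy:
    """Simulate one genealogy of the sampled gene copies (see module docs)."""
    enc = model._encode(_genes(samples, ploidy))
    rng = np.random.default_rng(seed)
    sizes = enc["sizes0"].copy()
    D = len(sizes)
    # leaf order follows sampled-deme order, matching the batch engine
    leaf_deme = []
    lin = {d: [] for d in range(D)}
    node = 0
    for s, d in enumerate(enc["samp_dim"]):
        for _ in range(enc["init"][d]):
            lin[d].append(node)
            leaf_deme.append(enc["deme_names"][s])
            node += 1
    n = node
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    t, ep = 0.0, 0
    ev = enc["ev_time"], enc["ev_type"], enc["ev_a"], enc["ev_b"], enc["ev_x"]
    nl = n
    while nl > 1:
        rates = np.array([len(lin[d]) * (len(lin[d]) - 1) * 0.5 / sizes[d]
                          for d in range(D)])
        rate = rates.sum()
        tnext = t + rng.exponential(1.0 / rate) if rate > 0 else np.inf
        if ep < len(ev[0]) and ev[0][ep] <= tnext:
            t = ev[0][ep]
            typ, a, b, x = ev[1][ep], ev[2][ep], ev[3][ep], ev[4][ep]
            if typ == 0:
                lin[b].extend(lin[a])
                lin[a] = []
            elif typ == 1:
                stay, move = [], []
                for l in lin[a]:
                    (move if rng.random() <= x else stay).append(l)
                lin[a] = stay
                lin[b].extend(move)
            else:
                sizes[a] = x
            ep += 1
            continue
        t = tnext
        d = rng.choice(D, p=rates / rate)
        i, j = rng.choice(len(lin[d]), size=2, replace=False)
        li, lj = lin[d][i], lin[d][j]
        parent[li] = parent[lj] = node
        time[node] = t
        lin[d] = [l for l in lin[d] if l not in (li, lj)]
        lin[d].append(node)
        node += 1
        nl -= 1
    return Genealogy(parent, time, tuple(leaf_deme))


def simulate_locus(tree: Genealogy, mu: float, length: int, seed: int) -> np.ndarray:
    """Drop infinite-sites mutations on a genealogy.

    Returns a boolean (n_sites, n_leaves) carrier matrix: entry [s, l] is
    True when leaf l inherits the derived allele at segregating site s.
    """
    rng = np.random.default_rng(seed)
    bl = tree.branch_lengths()
    hits = rng.poisson(mu * length * bl)
    below = tree.leaves_below()
    rows = [below[v] for v in range(tree.n_nodes) for _ in range(hits[v]) if tree.parent[v] >= 0]
    if not rows:
        return np.zeros((0, tree.n_leaves), dtype=bool)
    return np.array(rows)


# ---------------------------------------------------------------------------
# batch layer (compiled walker)
# ---------------------------------------------------------------------------

_DUMMY_F8 = np.zeros(1)
_DUMMY_I8 = np.zeros(1, dtype=np.int64)
_DUMMY_U64 = np.zeros((1, 1), dtype=np.uint64)


def _check_dense(sample_sizes):
    ncfg = int(np.prod(sample_sizes + 1))
    if ncfg > MAX_DENSE_CONFIGS:
        raise ModelError(
            f"configuration space of size {ncfg} is too large for dense SFS "
            "accumulation; down-sample or project to fewer gene copies")
    return ncfg


def branch_length_spectrum(model: DemographicModel, samples: dict, n_sims: int,
                           seed: int, ploidy: int = 2):
    """Mean branch length subtending each configuration, over n_sims genealogies.

    Returns (flat mixed-radix array in generations, sample_sizes, deme_names).
    mu * lengths is the per-bp expected density of segregating sites per
    configuration — the expected-SFS estimator behind the composite likelihood.
    """
    enc = model._encode(_genes(samples, ploidy))
    ncfg = _check_dense(enc["sample_sizes"])
    out_len = np.zeros(ncfg)
    tmrca = np.empty(n_sims)
    totlen = np.empty(n_sims)
    _engine.walk(seed, 0, n_sims, 0, enc["sizes0"], enc["init"], enc["samp_dim"],
                 enc["stride"], enc["ev_time"], enc["ev_type"], enc["ev_a"],
                 enc["ev_b"], enc["ev_x"], 0.0, out_len, _DUMMY_I8, _DUMMY_U64,
                 _DUMMY_I8, tmrca, totlen)
    return out_len / n_sims, enc["sample_sizes"], enc["deme_names"]


def simulate_tree_stats(model: DemographicModel, samples: dict, n_reps: int,
                        seed: int, ploidy: int = 2):
    """Per-replicate (TMRCA, total branch length) in generations."""
    enc = model._encode(_genes(samples, ploidy))
    ncfg = _check_dense(enc["sample_sizes"])
    out_len = np.zeros(ncfg)
    tmrca = np.empty(n_reps)
    totlen = np.empty(n_reps)
    _engine.walk(seed, 0, n_reps, 0, enc["sizes0"], enc["init"], enc["samp_dim"],
                 enc["stride"], enc["ev_time"], enc["ev_type"], enc["ev_a"],
                 enc["ev_b"], enc["ev_x"], 0.0, out_len, _DUMMY_I8, _DUMMY_U64,
                 _DUMMY_I8, tmrca, totlen)
    return tmrca, totlen


def simulate_msfs(model: DemographicModel, samples: dict, n_loci: int, seed: int,
                  ploidy: int = 2, folded: bool = True) -> MSFS:
    """Aggregate infinite-sites mutations over n_loci unlinked loci into an
    MSFS; the monomorphic entry is n_loci * locus_length minus the
    segregating sites (mutations fixed in the whole sample count as
    monomorphic)."""
    enc = model._encode(_genes(samples, ploidy))
    ncfg = _check_dense(enc["sample_sizes"])
    out_cnt = np.zeros(ncfg, dtype=np.int64)
    tmrca = np.empty(n_loci)
    totlen = np.empty(n_loci)
    mu_l = model.mutation_rate * model.locus_length
    _engine.walk(seed, 0, n_loci, 1, enc["sizes0"], enc["init"], enc["samp_dim"],
                 enc["stride"], enc["ev_time"], enc["ev_type"], enc["ev_a"],
                 enc["ev_b"], enc["ev_x"], mu_l, _DUMMY_F8, out_cnt, _DUMMY_U64,
                 _DUMMY_I8, tmrca, totlen)
    total_sites = n_loci * model.locus_length
    sfs = MSFS.from_dense(out_cnt, enc["sample_sizes"], enc["deme_names"],
                          folded=folded)
    return sfs.correct_monomorphic(total_sites)


def simulate_sites(model: DemographicModel, samples: dict, n_loci: int, seed: int,
                   ploidy: int = 2, chunk: int = 2000):
    """Simulate carrier matrices for all segregating sites of n_loci loci.

    Returns (carriers bool (n_sites, n_genes), locus index per site,
    deme name per gene).  Gene order: sampled demes in model order, genes
    consecutive within a deme (a diploid's genes are adjacent pairs).
    """
    enc = model._encode(_genes(samples, ploidy))
    n_genes = int(enc["init"].sum())
    nwords = (n_genes + 63) // 64
    mu_l = model.mutation_rate * model.locus_length
    gene_deme = []
    for s, d in enumerate(enc["samp_dim"]):
        gene_deme += [enc["deme_names"][s]] * int(enc["init"][d])
    all_words, all_rep = [], []
    guess = 8
    done = 0
    while done < n_loci:
        m = min(chunk, n_loci - done)
        while True:
            cap = max(64, guess * m)
            words = np.zeros((cap, nwords), dtype=np.uint64)
            rep = np.zeros(cap, dtype=np.int64)
            tmrca = np.empty(m)
            totlen = np.empty(m)
            ns = _engine.walk(seed, done, m, 2, enc["sizes0"], enc["init"],
                              enc["samp_dim"], enc["stride"], enc["ev_time"],
                              enc["ev_type"], enc["ev_a"], enc["ev_b"],
                              enc["ev_x"], mu_l, _DUMMY_F8, _DUMMY_I8,
                              words, rep, tmrca, totlen)
            if ns >= 0:
                break
            guess *= 2  # counter-based substreams make the retry identical
        all_words.append(words[:ns])
        all_rep.append(rep[:ns])
        guess = max(guess, 2 * (ns // m + 1))
        done += m
    words = np.concatenate(all_words) if all_words else np.zeros((0, nwords), np.uint64)
    rep = np.concatenate(all_rep) if all_rep else np.zeros(0, np.int64)
    bits = np.unpackbits(words.view(np.uint8), axis=1, bitorder="little")
    return bits[:, :n_genes].astype(bool), rep, gene_deme


def simulate_genotypes(model: DemographicModel, samples: dict, n_loci: int,
                       seed: int):
    """Diploid genotype matrix (alt-allele dosage) for all segregating sites.

    Returns (genotypes int8 (n_diploids, n_sites), locus index per site,
    deme name per diploid).
    """
    carriers, locus_of, gene_deme = simulate_sites(model, samples, n_loci, seed)
    geno = (carriers[:, 0::2].astype(np.int8) + carriers[:, 1::2]).T
    return geno, locus_of, tuple(gene_deme[::2])
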