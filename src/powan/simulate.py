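"""Synthetic study-like datasets.

The default `StudyTemplate` encodes a six-population European-whitefish
demography — Norwegian (NOR), Baltic (BAL), Alpine (ALP), Scottish (LOM),
Welsh (LTE) and English (RTA) demes — with divergence times 26,247 / 23,205
/ 18,674 / 5,965 / 3,887 generations, admixture pulses into the Baltic deme
(0.46 from NOR down to 0.15 from LOM, between 6,663 and 4,433 generations
ago) and a 0.15 pulse from the Scottish into the Welsh deme at 3,473
generations, with mu = 1e-8 per bp per generation and a 3.5-year generation
time.  Effective sizes are template defaults chosen so the model reproduces
the observed per-bp diversity of each population and the Scotland-England
differentiation (see docs/methods.md); they are free configuration, not
estimates.

`generate_vcf` emits a ddRAD-style dataset: unlinked 142-bp loci spread over
40 pseudo-chromosomes, negative-binomial read depths, per-population
missingness, a popmap, and a truth record holding every generating
parameter so estimates can be compared against the generating model.
`generate_mtdna` emits short haplotype alignments with a planted genealogy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coalescent import (Deme, DemographicModel, Genealogy, Pulse, Split,
                         simulate_genealogy, simulate_genotypes)
from .genotypes import GenotypeMatrix, write_popmap, write_vcf

POPS = ("NOR", "BAL", "ALP", "LOM", "LTE", "RTA")

#: generating parameters of the six-deme demography (times in generations,
#: sizes in diploids, pulse proportions as ancestry fractions)
DEFAULT_PARAMS = {
    "t_root": 26247.0,       # NOR vs all others
    "t_bal": 23205.0,        # BAL vs (ALP, LOM, LTE, RTA)
    "t_sct": 18674.0,        # LOM vs (ALP, LTE, RTA)
    "t_alp": 5965.0,         # ALP vs (LTE, RTA)
    "t_we": 3887.0,          # LTE vs RTA
    "a_nor_bal": 0.46, "t_nor_bal": 6663.0,
    "a_alp_bal": 0.20, "t_alp_bal": 5600.0,
    "a_we_bal": 0.18, "t_we_bal": 5000.0,    # from the Wales/England ancestor
    "a_lom_bal": 0.15, "t_lom_bal": 4433.0,
    "a_lom_lte": 0.15, "t_lom_lte": 3473.0,
    "n_nor": 12000.0, "n_bal": 12000.0, "n_alp": 3200.0,
    "n_lom": 8300.0, "n_lte": 3000.0, "n_rta": 3000.0,
    "n_anc": 110000.0,
}

#: pop-gen-dataset diploid sample sizes per deme
DEFAULT_SAMPLES = {"NOR": 10, "BAL": 8, "ALP": 9, "LOM": 10, "LTE": 7, "RTA": 10}


def whitefish_model(params: dict | None = None, mutation_rate: float = 1e-8,
                    generation_time: float = 3.5,
                    locus_length: int = 142) -> DemographicModel:
    """Build the six-deme model from a (possibly partial) parameter dict."""
    p = {**DEFAULT_PARAMS, **(params or {})}
    demes = [Deme("NOR", p["n_nor"]), Deme("BAL", p["n_bal"]),
             Deme("ALP", p["n_alp"]), Deme("LOM", p["n_lom"]),
             Deme("LTE", p["n_lte"]), Deme("RTA", p["n_rta"]),
             Deme("ANC_WE", p["n_anc"]), Deme("ANC_SW", p["n_anc"]),
             Deme("ANC_LS", p["n_anc"]), Deme("ANC_LB", p["n_anc"]),
             Deme("ROOT", p["n_anc"])]
    events = [
        Pulse(p["t_lom_lte"], "LTE", "LOM", p["a_lom_lte"]),
        Pulse(p["t_lom_bal"], "BAL", "LOM", p["a_lom_bal"]),
        Split(p["t_we"], "LTE", "ANC_WE"),
        Split(p["t_we"], "RTA", "ANC_WE"),
        Pulse(p["t_we_bal"], "BAL", "ANC_WE", p["a_we_bal"]),
        Pulse(p["t_alp_bal"], "BAL", "ALP", p["a_alp_bal"]),
        Split(p["t_alp"], "ALP", "ANC_SW"),
        Split(p["t_alp"], "ANC_WE", "ANC_SW"),
        Pulse(p["t_nor_bal"], "BAL", "NOR", p["a_nor_bal"]),
        Split(p["t_sct"], "LOM", "ANC_LS"),
        Split(p["t_sct"], "ANC_SW", "ANC_LS"),
        Split(p["t_bal"], "BAL", "ANC_LB"),
        Split(p["t_bal"], "ANC_LS", "ANC_LB"),
        Split(p["t_root"], "NOR", "ROOT"),
        Split(p["t_root"], "ANC_LB", "ROOT"),
    ]
    return DemographicModel(demes, events, mutation_rate=mutation_rate,
                            generation_time=generation_time,
                            locus_length=locus_length).validate()


@dataclass
class StudyTemplate:
    """Generating conditions for a study-like synthetic dataset."""

    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    samples: dict = field(default_factory=lambda: dict(DEFAULT_SAMPLES))
    n_loci: int = 20000
    locus_length: int = 142
    mutation_rate: float = 1e-8
    generation_time: float = 3.5
    n_chromosomes: int = 40
    chrom_length: int = 50_000_000
    missingness: dict | float = 0.05       # per-genotype Bernoulli, per population
    depth_mean: float = 20.0               # negative-binomial read depth
    depth_size: float = 5.0                # NB dispersion ('size'); None: uniform depth
    mtdna_length: int = 975
    mtdna_mutation_rate: float = 5e-8      # per bp per generation, ND1-like scale
    mtdna_samples: dict = field(default_factory=lambda: {
        "NOR": 10, "BAL": 5, "ALP": 6, "LOM": 17, "LTE": 5})

    def __post_init__(self):
        miss = self.missingness
        if not isinstance(miss, dict):
            miss = {p: float(miss) for p in self.samples}
        for p, m in miss.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"missingness[{p!r}]={m} outside [0, 1]")
        self.missingness = miss

    def model(self) -> DemographicModel:
        return whitefish_model(self.params, self.mutation_rate,
                               self.generation_time, self.locus_length)

    def mtdna_model(self) -> DemographicModel:
        """The same demography with N_e/4, the haploid maternal scaling."""
        m = self.model()
        return DemographicModel(
            [Deme(d.name, d.size / 4.0) for d in m.demes], m.events,
            mutation_rate=self.mtdna_mutation_rate,
            generation_time=self.generation_time,
            locus_length=self.mtdna_length).validate()

    def truth(self, seed: int) -> dict:
        return {"seed": seed, "params": dict(self.params),
                "samples": dict(self.samples), "n_loci": self.n_loci,
                "locus_length": self.locus_length,
                "mutation_rate": self.mutation_rate,
                "generation_time": self.generation_time,
                "missingness": dict(self.missingness),
                "depth_mean": self.depth_mean, "depth_size": self.depth_size,
                "model": self.model().to_dict()}


_BASES = np.array(list("ACGT"))


def generate_vcf(template: StudyTemplate, seed: int,
                 out_dir: str | Path | None = None):
    """Simulate a study-like SNP dataset.

    Returns (GenotypeMatrix, truth dict); with out_dir set, also writes
    data.vcf, popmap.txt and truth.json.  Byte-identical output for a fixed
    template and seed.
    """
    tpl = template
    model = tpl.model()
    geno, locus_of, deme_of = simulate_genotypes(model, tpl.samples, tpl.n_loci,
                                                 seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    sample_ids, pops = [], []
    tally: dict = {}
    for pop in deme_of:
        tally[pop] = tally.get(pop, 0) + 1
        sample_ids.append(f"{pop}_{tally[pop]:02d}")
        pops.append(pop)

    # place loci on pseudo-chromosomes with evenly spaced starts; site
    # offsets within a locus walk a coprime stride so they never collide
    lpc = -(-tpl.n_loci // tpl.n_chromosomes)   # loci per chromosome
    gap = max(tpl.chrom_length // (lpc + 1), tpl.locus_length + 1)
    import pandas as pd
    per_locus: dict = {}
    rows = []
    for j, loc in enumerate(locus_of):
        loc = int(loc)
        k = per_locus.get(loc, 0)
        if k >= tpl.locus_length:
            continue  # infinite-sites overflow of a short locus; drop site
        per_locus[loc] = k + 1
        c, slot = divmod(loc, lpc)
        off = (k * 53) % tpl.locus_length
        rows.append((f"chr{c + 1:02d}", gap * (slot + 1) + off, f"L{loc + 1}", j))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "locus", "col"])
    sites = sites.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    geno = geno[:, sites["col"].to_numpy()]
    n_sites = geno.shape[1]

    ref_i = rng.integers(0, 4, n_sites)
    alt_i = (ref_i + rng.integers(1, 4, n_sites)) % 4
    ref = _BASES[ref_i]
    alt = _BASES[alt_i]

    # read depths and per-population missingness
    if tpl.depth_size is None:
        depth = np.full(geno.shape, int(round(tpl.depth_mean)), dtype=np.int32)
    else:
        pnb = tpl.depth_size / (tpl.depth_size + tpl.depth_mean)
        depth = rng.negative_binomial(tpl.depth_size, pnb,
                                      size=geno.shape).astype(np.int32)
    miss = np.zeros(geno.shape, dtype=bool)
    for pop, frac in tpl.missingness.items():
        if frac > 0:
            rows = [i for i, p in enumerate(pops) if p == pop]
            miss[rows] = rng.random((len(rows), n_sites)) < frac
    geno = geno.copy()
    geno[miss] = -1
    depth[miss] = 0

    sites_df = sites[["chrom", "pos", "locus"]].reset_index(drop=True)
    sites_df["ref"] = ref
    sites_df["alt"] = alt
    g = GenotypeMatrix(sample_ids, pops, sites_df, geno, depth)
    truth = tpl.truth(seed)
    truth["n_snps"] = int(g.n_sites)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(g, out / "data.vcf")
        write_popmap(g.pop_of, out / "popmap.txt")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return g, truth


# ---------------------------------------------------------------------------
# mtDNA
# ---------------------------------------------------------------------------

def generate_mtdna(genealogy: Genealogy, length: int = 975, seed: int = 0,
                   mu: float | None = 5e-8,
                   mutations_per_branch: dict | None = None):
    """Evolve sequences of `length` bp down a genealogy (infinite sites).

    Mutation counts per branch are Poisson(mu * length * branch length)
    unless `mutations_per_branch` plants explicit counts (node -> count).
    Returns (records [(name, sequence)], info) where info holds the mutated
    sites and the per-branch counts actually used.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3D7A]))
    bl = genealogy.branch_lengths()
    if mutations_per_branch is None:
        if mu is None:
            raise ValueError("need either mu or mutations_per_branch")
        counts = rng.poisson(mu * length * bl)
    else:
        counts = np.zeros(genealogy.n_nodes, dtype=np.int64)
        for node, c in mutations_per_branch.items():
            counts[node] = c
    counts[-1] = 0  # the root has no branch
    total = int(counts.sum())
    if total > length:
        raise ValueError(f"{total} mutations exceed sequence length {length}")
    anc = _BASES[rng.integers(0, 4, length)]
    sites = rng.choice(length, size=total, replace=False)
    below = genealogy.leaves_below()
    seqs = np.tile(anc, (genealogy.n_leaves, 1))
    si = 0
    branch_sites = {}
    for v in range(genealogy.n_nodes - 1):
        for _ in range(int(counts[v])):
            s = int(sites[si]); si += 1
            old = anc[s]
            new = _BASES[(int(np.searchsorted(_BASES, old)) + int(rng.integers(1, 4))) % 4]
            if new == old:
                new = _BASES[(int(np.searchsorted(_BASES, old)) + 1) % 4]
            seqs[below[v], s] = new
            branch_sites.setdefault(v, []).append(s)
    tally = {}
    names = []
    for i, deme in enumerate(genealogy.leaf_deme):
        tally[deme] = tally.get(deme, 0) + 1
        names.append(f"{deme}_{tally[deme]:02d}")
    records = [(nm, "".join(row)) for nm, row in zip(names, seqs)]
    info = {"n_mutations": total, "branch_sites": branch_sites,
            "counts": counts.tolist()}
    return records, info


def generate_study_mtdna(template: StudyTemplate, seed: int,
                         out_path: str | Path | None = None):
    """Simulate the mtDNA alignment of the study template (haploid sampling
    under the N_e/4-scaled demography)."""
    model = template.mtdna_model()
    tree = simulate_genealogy(model, template.mtdna_samples, seed, ploidy=1)
    records, info = generate_mtdna(tree, template.mtdna_length, seed + 1,
                                   mu=template.mtdna_mutation_rate)
    if out_path is not None:
        write_fasta(records, out_path)
    return records, info


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
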