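"""Independent brute-force oracles, written directly from first principles.

These deliberately avoid the package's vectorised code paths: scalar loops,
explicit pair enumeration, exact combinatorics.  They are slow and only run
on tiny instances.
"""

import itertools
import math

import numpy as np


def genes_of(genotypes):
    """Unphased diploid codes -> flat list of gene-copy alleles (0/1),
    missing (-1) skipped."""
    out = []
    for g in genotypes:
        if g < 0:
            continue
        out.extend([1] * int(g) + [0] * (2 - int(g)))
    return out


def wc_theta_oracle(gA, gB):
    """Weir & Cockerham (1984) theta for two populations, transcribed
    per-site from the a/b/c component formulas (r = 2, diploids).

    gA, gB: integer arrays (samples x sites), -1 missing.
    """
    num = den = 0.0
    for j in range(gA.shape[1]):
        colA = [x for x in gA[:, j] if x >= 0]
        colB = [x for x in gB[:, j] if x >= 0]
        nA, nB = len(colA), len(colB)
        if nA < 1 or nB < 1 or nA + nB < 3:
            continue
        r = 2
        nbar = (nA + nB) / r
        nc = (r * nbar - (nA * nA + nB * nB) / (r * nbar)) / (r - 1)
        pA = sum(colA) / (2 * nA)
        pB = sum(colB) / (2 * nB)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1) * nbar)
        hA = sum(1 for x in colA if x == 1) / nA
        hB = sum(1 for x in colB if x == 1) / nB
        hbar = (nA * hA + nB * hB) / (r * nbar)
        a = (nbar / nc) * (s2 - (1.0 / (nbar - 1))
                           * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2
                                   - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


def dxy_oracle(gA, gB, total_length):
    """Mean mismatch over every cross-population gene-copy pair, per site,
    enumerated explicitly."""
    acc = 0.0
    for j in range(gA.shape[1]):
        genesA = genes_of(gA[:, j])
        genesB = genes_of(gB[:, j])
        if not genesA or not genesB:
            continue
        acc += sum(x != y for x in genesA for y in genesB) / (len(genesA) * len(genesB))
    return acc / total_length


def he_oracle(genotypes):
    """Unbiased gene diversity per site: mean mismatch over distinct
    gene-copy pairs, averaged over sites with >= 2 gene copies."""
    vals = []
    for j in range(genotypes.shape[1]):
        genes = genes_of(genotypes[:, j])
        if len(genes) < 2:
            continue
        pairs = list(itertools.combinations(range(len(genes)), 2))
        vals.append(sum(genes[i] != genes[k] for i, k in pairs) / len(pairs))
    return float(np.mean(vals)) if vals else float("nan")


def ar_oracle(genes, k_genes):
    """Rarefied allele count at one site: mean number of distinct alleles
    over every size-k_genes subsample, by exhaustive enumeration."""
    subs = list(itertools.combinations(genes, k_genes))
    return sum(len(set(s)) for s in subs) / len(subs)


def projection_oracle(entries, sample_sizes, k):
    """Project a sparse multidimensional SFS entry dict by exact
    per-deme hypergeometric sums with integer combinatorics."""
    out = {}
    for cfg, m in entries.items():
        axes = []
        for d, n_d in enumerate(sample_sizes):
            dist = []
            for j in range(k + 1):
                w = (math.comb(cfg[d], j) * math.comb(n_d - cfg[d], k - j)
                     / math.comb(n_d, k))
                dist.append(w)
            axes.append(dist)
        for combo in itertools.product(*[range(k + 1)] * len(sample_sizes)):
            w = m
            for d, j in enumerate(combo):
                w *= axes[d][j]
            if w:
                out[combo] = out.get(combo, 0.0) + w
    return out


def hwe_pvalue_oracle(n_het, n_hom_1, n_hom_2):
    """Exact HWE p-value by direct enumeration of all genotype splits with
    the observed allele counts, probabilities from counting arguments."""
    n = n_het + n_hom_1 + n_hom_2
    rare = 2 * min(n_hom_1, n_hom_2) + n_het
    common = 2 * n - rare

    def prob(h):
        if (rare - h) % 2 or h > rare or h > common:
            return 0.0
        hr = (rare - h) // 2
        hc = (common - h) // 2
        return (math.comb(n, hr) * math.comb(n - hr, hc) * 2**h
                / math.comb(2 * n, rare))

    probs = [prob(h) for h in range(0, min(rare, common) + 1)]
    total = sum(probs)
    obs = prob(n_het)
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-12)) / total)
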