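"""Diversity, differentiation and genome-scan statistics.

Estimators:

* observed / expected heterozygosity, with the small-sample 2n/(2n-1)
  correction on H_E, and per-site nucleotide diversity over a
  variant-plus-invariant length;
* rarefied allelic richness A_R (expected allele count in a fixed-size gene
  subsample, exact hypergeometric form);
* multi-locus Weir & Cockerham (1984) theta via the ratio of summed a / (a+b+c)
  variance components, with a label-permutation significance test;
* absolute divergence Dxy;
* a 1-Mb windowed F_ST scan with a mean + 3 SD outlier rule;
* PCA on the frequency-standardised genotype matrix with per-SNP
  eigenvector correlations, for localising the signal of each component.

Missing genotypes are handled by pairwise deletion per site; H_O denominators
count genotyped samples only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeMatrix


def _pop_site_summaries(g: GenotypeMatrix, pop):
    """(n diploids genotyped, alt-allele count, het count) per site.

    `pop` may be a population label or an explicit sample-index array.
    """
    idx = g.pop_indices()[pop] if isinstance(pop, str) else np.asarray(pop)
    sub = g.genotypes[idx]
    called = sub >= 0
    n = called.sum(axis=0).astype(np.int64)
    alt = np.where(called, sub, 0).sum(axis=0).astype(np.int64)
    het = (sub == 1).sum(axis=0).astype(np.int64)
    return n, alt, het


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def diversity(g: GenotypeMatrix, invariant_sites_per_locus: int = 142,
              populations=None) -> pd.DataFrame:
    """Per-population H_O, H_E and pi.

    H_O is the mean genotyped-sample heterozygote fraction over variant
    sites; H_E the mean unbiased gene diversity (2n/(2n-1)) (1 - sum p^2);
    pi the summed per-site mean pairwise difference divided by the
    variant+invariant sequence length, taken as
    n_loci * invariant_sites_per_locus + n_variant_sites.
    Populations with no genotyped data get NaN entries.
    """
    populations = populations or g.pop_labels()
    n_loci = g.sites["locus"].nunique()
    length = n_loci * invariant_sites_per_locus + g.n_sites
    rows = []
    for pop in populations:
        n, alt, het = _pop_site_summaries(g, pop)
        has = n > 0
        if not has.any():
            rows.append((pop, len(g.pop_indices()[pop]), np.nan, np.nan, np.nan))
            continue
        genes = 2 * n[has]
        p = alt[has] / genes
        he = genes / (genes - 1) * 2 * p * (1 - p)  # unbiased, needs genes >= 2
        he[genes < 2] = np.nan
        ho = het[has] / n[has]
        rows.append((pop, len(g.pop_indices()[pop]),
                     float(np.nanmean(he)), float(np.mean(ho)),
                     float(np.nansum(he)) / length))
    return pd.DataFrame(rows, columns=["pop", "n", "He", "Ho", "pi"])


def _log_comb(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def rarefied_allelic_richness(g: GenotypeMatrix, min_diploids: int = 3,
                              populations=None) -> pd.Series:
    """Expected allele count in subsamples of 2*min_diploids gene copies.

    Per site, A_R = sum_alleles [1 - C(N - N_a, g) / C(N, g)] with N the
    genes genotyped in the population and g = 2*min_diploids; averaged over
    the sites where the population has at least min_diploids genotyped
    individuals (others are skipped for that population).
    """
    populations = populations or g.pop_labels()
    gsub = 2 * min_diploids
    out = {}
    for pop in populations:
        n, alt, _ = _pop_site_summaries(g, pop)
        has = n >= min_diploids
        if not has.any():
            out[pop] = np.nan
            continue
        genes = 2 * n[has]
        a1 = alt[has]
        a0 = genes - a1
        ar = np.zeros(has.sum())
        for counts in (a0, a1):
            with np.errstate(invalid="ignore"):
                miss = np.exp(_log_comb(genes - counts, gsub) - _log_comb(genes, gsub))
            miss = np.where(genes - counts >= gsub, miss, 0.0)
            ar += 1.0 - miss
        out[pop] = float(ar.mean())
    return pd.Series(out, name="A_R")


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(g: GenotypeMatrix, popA, popB):
    """Per-site (a, b, c) variance components for two populations
    (labels or explicit sample-index arrays)."""
    nA, altA, hetA = _pop_site_summaries(g, popA)
    nB, altB, hetB = _pop_site_summaries(g, popB)
    use = (nA >= 1) & (nB >= 1) & (nA + nB >= 3)
    nA, altA, hetA = nA[use], altA[use], hetA[use]
    nB, altB, hetB = nB[use], altB[use], hetB[use]
    r = 2.0
    nbar = (nA + nB) / r
    nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1)
    pA = altA / (2 * nA)
    pB = altB / (2 * nB)
    pbar = (nA * pA + nB * pB) / (r * nbar)
    s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (hetA + hetB) / (r * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                     / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c, use


@dataclass
class FstResult:
    theta: float
    p_value: float | None
    n_sites: int
    n_perm: int = 0


def wc_fst(g: GenotypeMatrix, popA: str, popB: str, n_perm: int = 0,
           seed: int = 0) -> FstResult:
    """Multi-locus Weir & Cockerham theta between two populations.

    theta = sum(a) / sum(a + b + c) over usable sites; significance (when
    n_perm > 0) is the fraction of permutations — individuals shuffled
    between the two populations, sizes preserved — with theta at least the
    observed value.  With no usable polymorphic site the estimate is NaN and
    p = 1.
    """
    a, b, c, use = _wc_components(g, popA, popB)
    denom = (a + b + c).sum()
    if use.sum() == 0 or denom == 0:
        return FstResult(np.nan, 1.0 if n_perm else None, int(use.sum()), n_perm)
    theta = float(a.sum() / denom)
    if n_perm <= 0:
        return FstResult(theta, None, int(use.sum()), 0)
    idx = g.pop_indices()
    pool = np.concatenate([idx[popA], idx[popB]])
    nA = len(idx[popA])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        ap, bp, cp, _ = _wc_components(g, perm[:nA], perm[nA:])
        dp = (ap + bp + cp).sum()
        tp = ap.sum() / dp if dp != 0 else np.nan
        if not np.isnan(tp) and tp >= theta:
            hits += 1
    return FstResult(theta, hits / n_perm, int(use.sum()), n_perm)


def pairwise_matrices(g: GenotypeMatrix, n_perm: int = 0, seed: int = 0,
                      populations=None):
    """Symmetric population x population F_ST (and p-value) DataFrames."""
    populations = populations or g.pop_labels()
    k = len(populations)
    fst = pd.DataFrame(np.nan, index=populations, columns=populations)
    pval = pd.DataFrame(np.nan, index=populations, columns=populations)
    for i in range(k):
        for j in range(i + 1, k):
            r = wc_fst(g, populations[i], populations[j], n_perm=n_perm,
                       seed=seed + 1000003 * (i * k + j))
            fst.iloc[i, j] = fst.iloc[j, i] = r.theta
            if r.p_value is not None:
                pval.iloc[i, j] = pval.iloc[j, i] = r.p_value
    return fst, pval


# ---------------------------------------------------------------------------
# Dxy
# ---------------------------------------------------------------------------

def dxy(g: GenotypeMatrix, popA: str, popB: str,
        total_length: float | None = None,
        invariant_sites_per_locus: int = 142) -> float:
    """Absolute divergence: mean pairwise difference per site between the
    populations, over variant+invariant length.

    For popA == popB the distinct-pair (unbiased) within-population form is
    used, so dxy of a population with itself equals its pi under the same
    length denominator.
    """
    nA, altA, _ = _pop_site_summaries(g, popA)
    if total_length is None:
        n_loci = g.sites["locus"].nunique()
        total_length = n_loci * invariant_sites_per_locus + g.n_sites
    if popA == popB:
        use = nA >= 1
        genes = 2 * nA[use]
        p = altA[use] / genes
        per_site = np.where(genes >= 2, genes / np.maximum(genes - 1, 1)
                            * 2 * p * (1 - p), np.nan)
        return float(np.nansum(per_site)) / total_length
    nB, altB, _ = _pop_site_summaries(g, popB)
    use = (nA >= 1) & (nB >= 1)
    pA = altA[use] / (2 * nA[use])
    pB = altB[use] / (2 * nB[use])
    return float(np.sum(pA * (1 - pB) + pB * (1 - pA))) / total_length


# ---------------------------------------------------------------------------
# windowed scan
# ---------------------------------------------------------------------------

@dataclass
class WindowScan:
    windows: pd.DataFrame     # chrom, start, end, n_snps, fst, outlier
    mean: float
    sd: float
    window_bp: int
    min_snps: int

    def to_tsv(self, path):
        self.windows.to_csv(path, sep="\t", index=False)


def window_fst_scan(g: GenotypeMatrix, popA: str, popB: str,
                    window_bp: int = 1_000_000, min_snps: int = 5,
                    sd_threshold: float = 3.0) -> WindowScan:
    """Weighted F_ST in non-overlapping windows with an outlier rule.

    Windows are 0-based half-open [k*W, (k+1)*W) tiled per chromosome;
    windows with fewer than min_snps SNPs are excluded; the remaining
    windows are flagged as outliers when fst >= mean + sd_threshold * SD.
    Negative window values are reported as-is.
    """
    a, b, c, use = _wc_components(g, popA, popB)
    sites = g.sites.loc[use].reset_index(drop=True)
    win = (sites["pos"].to_numpy() - 1) // window_bp  # VCF pos is 1-based
    df = pd.DataFrame({"chrom": sites["chrom"], "win": win,
                       "a": a, "d": a + b + c})
    rows = []
    for (chrom, w), grp in df.groupby(["chrom", "win"], sort=True):
        n = len(grp)
        denom = grp["d"].sum()
        fst = grp["a"].sum() / denom if denom != 0 else np.nan
        rows.append((chrom, int(w) * window_bp, (int(w) + 1) * window_bp, n, fst))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "fst"])
    out = out[(out["n_snps"] >= min_snps) & out["fst"].notna()].reset_index(drop=True)
    mean = float(out["fst"].mean()) if len(out) else np.nan
    sd = float(out["fst"].std(ddof=1)) if len(out) > 1 else 0.0
    out["outlier"] = (sd > 0) & (out["fst"] >= mean + sd_threshold * sd)
    return WindowScan(out, mean, sd, window_bp, min_snps)


# ---------------------------------------------------------------------------
# PCA + SNP-eigenvector correlation
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray          # samples x components
    explained: np.ndarray       # variance fraction per component
    snp_corr: np.ndarray        # |r|, kept SNPs x components
    kept_sites: np.ndarray      # site indices that entered the decomposition


def pca_with_snp_correlation(g: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of the allele-frequency centred and scaled genotype matrix.

    Missing genotypes are mean-imputed per SNP; zero-variance SNPs are
    dropped; each SNP column is centred by 2p and scaled by sqrt(2p(1-p)).
    Returns sample scores, explained-variance fractions, and the absolute
    Pearson correlation of every kept SNP with each component's scores.
    """
    if g.n_samples < 2 or g.n_sites < 2:
        raise ValueError("PCA needs at least 2 samples and 2 SNPs")
    x = g.genotypes.astype(float)
    x[x < 0] = np.nan
    mean = np.nanmean(x, axis=0)
    filled = np.where(np.isnan(x), mean, x)
    var = filled.var(axis=0)
    keep = np.flatnonzero(var > 0)
    filled = filled[:, keep]
    p = filled.mean(axis=0) / 2
    z = (filled - 2 * p) / np.sqrt(2 * p * (1 - p))
    z -= z.mean(axis=0)
    n_components = min(n_components, min(z.shape) - 1) or 1
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    explained = (s**2 / (s**2).sum())[:n_components]
    zc = z - z.mean(axis=0)
    sc = scores - scores.mean(axis=0)
    num = zc.T @ sc
    den = np.sqrt((zc**2).sum(axis=0))[:, None] * np.sqrt((sc**2).sum(axis=0))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(num / den)
    return PCAResult(scores, explained, corr, keep)
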