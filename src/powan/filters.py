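"""ddRAD SNP filter cascade.

Re-expresses the standard Stacks -> vcftools -> per-population HWE filtering
pipeline as one explicit, ordered rule cascade over a GenotypeMatrix:

  presence -> per-population completeness -> observed heterozygosity ->
  depth -> missingness -> minor allele frequency -> HWE -> one SNP per locus

Each site is charged to the first rule that removes it, so the per-rule
removal counts sum to the total number of sites dropped.  The depth rule has
two parts, mirroring vcftools: per-genotype depth bounds recode individual
genotypes to missing, then sites with an out-of-range mean depth are removed;
the recoded genotypes feed the downstream missingness/MAF/HWE rules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

RULE_ORDER = ("presence", "per_pop_completeness", "obs_het", "depth",
              "missingness", "maf", "hwe", "one_snp_per_locus")


@dataclass
class FilterConfig:
    """Thresholds of the site-filter cascade (defaults: the ddRAD pipeline
    values this package is built around; set a threshold to None to disable
    the rule)."""

    min_pops: int | None = 9                 # -p: populations a locus must appear in
    min_prop_per_pop: float | None = 0.8     # -r: genotyped fraction within a population
    max_obs_het: float | None = 0.6
    min_maf: float | None = 0.05
    min_gt_depth: int | None = 5             # per-genotype; below -> recoded missing
    max_gt_depth: int | None = 30
    min_mean_depth: float | None = 10.0      # per-site mean across individuals
    max_mean_depth: float | None = 30.0
    max_missing_frac: float | None = 0.15
    hwe_alpha: float | None = 0.001
    hwe_pop_frac: float = 0.5
    one_snp_per_locus: bool = True

    def __post_init__(self):
        for name in ("min_prop_per_pop", "max_obs_het", "min_maf",
                     "max_missing_frac", "hwe_pop_frac"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("min_gt_depth", "max_gt_depth"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if (self.min_gt_depth is not None and self.max_gt_depth is not None
                and self.min_gt_depth > self.max_gt_depth):
            raise ValueError("min_gt_depth exceeds max_gt_depth")
        if (self.min_mean_depth is not None and self.max_mean_depth is not None
                and self.min_mean_depth > self.max_mean_depth):
            raise ValueError("min_mean_depth exceeds max_mean_depth")


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_het: int, n_hom_1: int, n_hom_2: int) -> float:
    """Exact HWE test p-value from genotype counts (Wigginton-Cutler-Abecasis).

    Sums the probabilities of all heterozygote counts (conditional on the
    allele counts) no more likely than the observed one.  Monomorphic
    samples return 1.0.
    """
    n = n_het + n_hom_1 + n_hom_2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_1, n_hom_2) + n_het
    if rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare-allele count
    h_max = rare if rare <= 2 * n - rare else 2 * n - rare
    probs = np.zeros(h_max + 1)
    h_mid = rare * (2 * n - rare) // (2 * n)
    if (h_mid % 2) != (rare % 2):
        h_mid += 1
    probs[h_mid] = 1.0
    h = h_mid
    while h >= 2:
        probs[h - 2] = probs[h] * h * (h - 1) / (
            (rare - h + 2) * (2 * n - rare - h + 2))
        h -= 2
    h = h_mid
    while h + 2 <= h_max:
        n_rare_hom = (rare - h) // 2
        n_comm_hom = (2 * n - rare - h) // 2
        probs[h + 2] = probs[h] * 4.0 * n_rare_hom * n_comm_hom / ((h + 2) * (h + 1))
        h += 2
    probs /= probs.sum()
    return float(np.minimum(probs[probs <= probs[n_het] * (1 + 1e-12)].sum(), 1.0))


def hwe_filter(g: GenotypeMatrix, alpha: float = 0.001,
               pop_frac: float = 0.5) -> np.ndarray:
    """Boolean mask of sites out of HWE within populations.

    A site is flagged when the exact test gives p < alpha in more than
    pop_frac of the populations with genotyped data at that site.
    Monomorphic-within-population sites contribute p = 1.
    """
    flags = np.zeros(g.n_sites, dtype=bool)
    pop_idx = g.pop_indices()
    for j in range(g.n_sites):
        n_tested = n_fail = 0
        for idx in pop_idx.values():
            col = g.genotypes[idx, j]
            col = col[col >= 0]
            if col.size == 0:
                continue
            n_tested += 1
            p = hwe_exact_pvalue(int((col == 1).sum()), int((col == 0).sum()),
                                 int((col == 2).sum()))
            if p < alpha:
                n_fail += 1
        if n_tested and n_fail / n_tested > pop_frac:
            flags[j] = True
    return flags


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def apply_filters(g: GenotypeMatrix, cfg: FilterConfig):
    """Run the full cascade; returns (filtered matrix, per-rule report).

    The report is a DataFrame (rule, n_removed) in cascade order; counts are
    first-hit, so they sum to input sites minus output sites.
    """
    geno = g.genotypes.copy()
    depth = g.depth
    alive = np.ones(g.n_sites, dtype=bool)
    removed = {r: 0 for r in RULE_ORDER}
    pop_idx = g.pop_indices()

    # genotype-level depth recoding happens before any site rule so that the
    # cascade is idempotent: every rule sees the genotypes the output carries
    wants_depth = any(x is not None for x in (cfg.min_gt_depth, cfg.max_gt_depth,
                                              cfg.min_mean_depth, cfg.max_mean_depth))
    if wants_depth and depth is None:
        log.warning("apply_filters: no DP in input; depth rules skipped")
    elif wants_depth:
        known = depth >= 0
        bad_cell = np.zeros_like(known)
        if cfg.min_gt_depth is not None:
            bad_cell |= known & (depth < cfg.min_gt_depth)
        if cfg.max_gt_depth is not None:
            bad_cell |= known & (depth > cfg.max_gt_depth)
        geno[bad_cell & (geno >= 0)] = MISSING

    def drop(rule, bad_mask):
        bad = alive & bad_mask
        removed[rule] = int(bad.sum())
        alive[bad] = False

    # presence: site genotyped in at least min_pops populations
    if cfg.min_pops is not None:
        with_data = np.zeros(g.n_sites, dtype=np.int64)
        for idx in pop_idx.values():
            with_data += (geno[idx] >= 0).any(axis=0)
        drop("presence", with_data < cfg.min_pops)

    # per-population completeness: >= min_prop genotyped, in >= min_pops pops
    if cfg.min_prop_per_pop is not None:
        need = cfg.min_pops if cfg.min_pops is not None else len(pop_idx)
        complete = np.zeros(g.n_sites, dtype=np.int64)
        for idx in pop_idx.values():
            frac = (geno[idx] >= 0).mean(axis=0)
            complete += frac >= cfg.min_prop_per_pop
        drop("per_pop_completeness", complete < need)

    # observed heterozygosity
    if cfg.max_obs_het is not None:
        called = (geno >= 0).sum(axis=0)
        het = (geno == 1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            oh = np.where(called > 0, het / called, 0.0)
        drop("obs_het", oh > cfg.max_obs_het)

    # depth as a site rule: mean read depth across genotyped individuals
    if wants_depth and depth is not None:
        called = geno >= 0
        with np.errstate(invalid="ignore"):
            mean_dp = np.where(called.sum(axis=0) > 0,
                               np.where(called, depth, 0).sum(axis=0)
                               / np.maximum(called.sum(axis=0), 1), np.nan)
        bad = np.zeros(g.n_sites, dtype=bool)
        if cfg.min_mean_depth is not None:
            bad |= ~(mean_dp >= cfg.min_mean_depth)
        if cfg.max_mean_depth is not None:
            bad |= ~(mean_dp <= cfg.max_mean_depth)
        drop("depth", bad)

    # missingness
    if cfg.max_missing_frac is not None:
        drop("missingness", (geno == MISSING).mean(axis=0) > cfg.max_missing_frac)

    # minor allele frequency (single global pass)
    if cfg.min_maf is not None:
        called = geno >= 0
        genes = 2 * called.sum(axis=0)
        alt = np.where(called, geno, 0).sum(axis=0)
        p = alt / np.maximum(genes, 1)
        maf = np.where(genes > 0, np.minimum(p, 1 - p), 0.0)
        drop("maf", maf < cfg.min_maf)

    # HWE within populations
    if cfg.hwe_alpha is not None:
        sub = GenotypeMatrix(list(g.sample_ids), list(g.populations),
                             g.sites.iloc[alive].reset_index(drop=True),
                             geno[:, alive],
                             None if depth is None else depth[:, alive])
        flags = hwe_filter(sub, cfg.hwe_alpha, cfg.hwe_pop_frac)
        bad = np.zeros(g.n_sites, dtype=bool)
        bad[np.flatnonzero(alive)[flags]] = True
        drop("hwe", bad)

    # one SNP per locus: keep the first by position within each locus id
    if cfg.one_snp_per_locus:
        seen = set()
        bad = np.zeros(g.n_sites, dtype=bool)
        for j in np.flatnonzero(alive):
            loc = g.sites["locus"].iat[j]
            if loc in seen:
                bad[j] = True
            seen.add(loc)
        drop("one_snp_per_locus", bad)

    report = pd.DataFrame({"rule": list(RULE_ORDER),
                           "n_removed": [removed[r] for r in RULE_ORDER]})
    out = GenotypeMatrix(list(g.sample_ids), list(g.populations),
                         g.sites.iloc[alive].reset_index(drop=True),
                         geno[:, alive],
                         None if depth is None else depth[:, alive])
    if out.n_sites == 0:
        warnings.warn("apply_filters: no sites survived the cascade")
    return out, report


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
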