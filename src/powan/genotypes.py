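"""Diploid SNP genotype matrices and VCF / population-map I/O.

The central container is `GenotypeMatrix`: samples x sites alt-allele
dosages (0/1/2, -1 for missing) with per-site coordinates, ddRAD locus ids,
optional per-cell read depths, and a sample -> population map.  Reading uses
cyvcf2; writing emits plain VCF 4.2 text so filtered datasets round-trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

MISSING = -1

# cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_GT_DECODE = np.array([0, 1, MISSING, 2], dtype=np.int8)


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes with population structure.

    genotypes[i, j] counts alt alleles of sample i at site j; -1 is missing.
    `sites` columns: chrom, pos (1-based, as in VCF), locus, ref, alt.
    """

    sample_ids: list
    populations: list                      # population label per sample
    sites: pd.DataFrame
    genotypes: np.ndarray                  # int8 (n_samples, n_sites)
    depth: np.ndarray | None = None        # int32, -1 where unknown
    _pop_cache: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError("genotype matrix shape does not match samples x sites")
        if len(self.populations) != len(self.sample_ids):
            raise ValueError("every sample needs a population label")
        bad = ~np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype codes outside {{0,1,2,missing}}")
        pos = self.sites["pos"].to_numpy()
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        self.sites = self.sites.reset_index(drop=True)

    # -- shape / lookup -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def pop_of(self) -> dict:
        return dict(zip(self.sample_ids, self.populations))

    def pop_labels(self) -> list:
        seen = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen

    def pop_indices(self) -> dict:
        if self._pop_cache is None:
            pops = np.asarray(self.populations)
            self._pop_cache = {p: np.flatnonzero(pops == p) for p in self.pop_labels()}
        return self._pop_cache

    # -- subsetting ---------------------------------------------------------
    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            list(self.sample_ids), list(self.populations),
            self.sites.iloc[index].reset_index(drop=True),
            self.genotypes[:, index],
            None if self.depth is None else self.depth[:, index])

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in index],
            [self.populations[i] for i in index],
            self.sites.copy(), self.genotypes[index],
            None if self.depth is None else self.depth[index])

    # -- per-site summaries -------------------------------------------------
    def allele_counts(self, sample_index=None):
        """(alt gene copies, called gene copies) per site."""
        g = self.genotypes if sample_index is None else self.genotypes[sample_index]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=0).astype(np.int64)
        return alt, 2 * called.sum(axis=0).astype(np.int64)

    def minor_allele_frequency(self) -> np.ndarray:
        alt, genes = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / genes
        return np.where(np.isnan(p), np.nan, np.minimum(p, 1 - p))

    def missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def obs_het_fraction(self) -> np.ndarray:
        called = (self.genotypes >= 0).sum(axis=0)
        het = (self.genotypes == 1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(called > 0, het / called, np.nan)


# ---------------------------------------------------------------------------
# population maps
# ---------------------------------------------------------------------------

def read_popmap(path) -> dict:
    """Two whitespace-separated columns: sample, population."""
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'sample population'")
            out[parts[0]] = parts[1]
    return out


def write_popmap(pop_of: dict, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in pop_of.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _locus_from_id(vid, chrom, pos) -> str:
    if vid in (None, "", "."):
        return f"{chrom}_{pos}"
    return str(vid).split(":")[0]


def read_vcf(path, popmap) -> GenotypeMatrix:
    """Read a VCF (GT, optional per-genotype DP) plus a population map.

    Non-biallelic sites are skipped (count logged); a VCF sample missing
    from the popmap is an error naming the sample.
    """
    pop_of = read_popmap(popmap) if not isinstance(popmap, dict) else dict(popmap)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    for s in samples:
        if s not in pop_of:
            raise KeyError(f"sample {s!r} present in VCF but absent from the popmap")
    has_dp = False
    for h in vcf.header_iter():
        info = h.info()
        if info.get("HeaderType") == "FORMAT" and info.get("ID") == "DP":
            has_dp = True
    rows, gts, dps = [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        rows.append((v.CHROM, v.POS, _locus_from_id(v.ID, v.CHROM, v.POS),
                     v.REF, v.ALT[0]))
        gts.append(_GT_DECODE[v.gt_types])
        if has_dp:
            dp = v.format("DP")
            if dp is None:
                dp = np.full(len(samples), -1, dtype=np.int32)
            else:
                dp = dp.ravel().astype(np.int64)
                dp[dp < 0] = -1  # '.' decodes as a large negative sentinel
            dps.append(dp)
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic site(s)", n_skipped)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "locus", "ref", "alt"])
    geno = (np.array(gts, dtype=np.int8).T if gts
            else np.zeros((len(samples), 0), dtype=np.int8))
    depth = None
    if has_dp:
        depth = (np.array(dps, dtype=np.int32).T if dps
                 else np.zeros((len(samples), 0), dtype=np.int32))
    return GenotypeMatrix(samples, [pop_of[s] for s in samples], sites, geno, depth)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Emit plain VCF 4.2; site IDs are '<locus>:<pos>' so locus assignment
    round-trips through read_vcf."""
    chroms = list(dict.fromkeys(g.sites["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=powan\n")
        for c in chroms:
            ln = int(g.sites.loc[g.sites["chrom"] == c, "pos"].max()) + 1000
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if g.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        fmt = "GT:DP" if g.depth is not None else "GT"
        for j in range(g.n_sites):
            chrom, pos, locus, ref, alt = g.sites.iloc[j][
                ["chrom", "pos", "locus", "ref", "alt"]]
            cells = []
            for i in range(g.n_samples):
                gt = _GT_STR[int(g.genotypes[i, j])]
                if g.depth is not None:
                    dp = int(g.depth[i, j])
                    gt += ":" + (str(dp) if dp >= 0 else ".")
                cells.append(gt)
            fh.write(f"{chrom}\t{pos}\t{locus}:{pos}\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t"
                     + "\t".join(cells) + "\n")
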