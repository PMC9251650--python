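"""Multidimensional site frequency spectra (MSFS).

The MSFS is the joint spectrum of allele counts across demes: entry
(c_1, ..., c_D) counts SNPs whose allele occurs c_d times among the n_d
sampled gene copies of deme d.  Folded spectra index the globally minor
allele; a separate monomorphic entry carries the invariant-site mass that
makes absolute (rather than relative) demographic parameters identifiable
under a known mutation rate.

Entries are stored sparsely (dict of count-vector tuples); dense flat-array
views use mixed radix with the first deme most significant so numeric order
on the flat index equals lexicographic order on the count vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln


def strides_for(sample_sizes) -> np.ndarray:
    """Mixed-radix strides (first deme most significant)."""
    n = np.asarray(sample_sizes, dtype=np.int64)
    s = np.ones(len(n), dtype=np.int64)
    for i in range(len(n) - 2, -1, -1):
        s[i] = s[i + 1] * (n[i + 1] + 1)
    return s


def _log_comb(n, k):
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def projection_matrix(n: int, k: int) -> np.ndarray:
    """Hypergeometric projection weights W[d, j] = P(j of k | d of n)."""
    if k > n:
        raise ValueError(f"cannot project {n} gene copies up to {k}")
    d = np.arange(n + 1)[:, None]
    j = np.arange(k + 1)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        lw = _log_comb(d, j) + _log_comb(n - d, k - j) - _log_comb(n, k)
    w = np.exp(lw)
    w[(j > d) | (k - j > n - d)] = 0.0
    return w


@dataclass
class MSFS:
    """Sparse multidimensional SFS with a monomorphic-count entry."""

    deme_names: tuple
    sample_sizes: np.ndarray          # gene copies per deme
    entries: dict = field(default_factory=dict)   # tuple -> count
    monomorphic: float = 0.0
    folded: bool = True

    def __post_init__(self):
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=np.int64)
        self.deme_names = tuple(self.deme_names)
        for cfg in self.entries:
            c = np.asarray(cfg)
            if np.any(c < 0) or np.any(c > self.sample_sizes):
                raise ValueError(f"entry {cfg} outside [0, n] for n={self.sample_sizes}")

    # -- basic accounting ---------------------------------------------------
    @property
    def n_demes(self) -> int:
        return len(self.sample_sizes)

    @property
    def total_genes(self) -> int:
        return int(self.sample_sizes.sum())

    @property
    def n_polymorphic(self) -> float:
        return float(sum(self.entries.values()))

    @property
    def total(self) -> float:
        return self.n_polymorphic + self.monomorphic

    # -- construction -------------------------------------------------------
    @classmethod
    def from_dense(cls, flat, sample_sizes, deme_names=None, folded=False,
                   monomorphic=0.0):
        """Build from a flat mixed-radix array of per-configuration counts.

        The all-zero and all-fixed configurations are moved into the
        monomorphic entry (they are invisible as polymorphisms).
        """
        sample_sizes = np.asarray(sample_sizes, dtype=np.int64)
        if deme_names is None:
            deme_names = tuple(f"deme{i}" for i in range(len(sample_sizes)))
        st = strides_for(sample_sizes)
        flat = np.asarray(flat)
        idx = np.flatnonzero(flat)
        full = int(np.dot(sample_sizes, st))
        mono = float(monomorphic)
        entries = {}
        for i in idx:
            cfg = tuple(int(x) for x in (i // st) % (sample_sizes + 1))
            if i == 0 or i == full:
                mono += float(flat[i])
            else:
                entries[cfg] = entries.get(cfg, 0.0) + float(flat[i])
        out = cls(tuple(deme_names), sample_sizes, entries, mono, folded=False)
        return out.fold() if folded else out

    def to_dense(self) -> np.ndarray:
        st = strides_for(self.sample_sizes)
        flat = np.zeros(int(np.prod(self.sample_sizes + 1)), dtype=np.float64)
        for cfg, m in self.entries.items():
            flat[int(np.dot(cfg, st))] += m
        return flat

    # -- folding ------------------------------------------------------------
    def fold(self) -> "MSFS":
        """Fold to the globally minor allele.

        Ties (count exactly half the sampled genes) keep the configuration
        with the lexicographically smaller count vector.
        """
        ntot = self.total_genes
        n = self.sample_sizes
        out = {}
        for cfg, m in self.entries.items():
            tot = int(sum(cfg))
            comp = tuple(int(n[i] - cfg[i]) for i in range(len(cfg)))
            if 2 * tot > ntot or (2 * tot == ntot and comp < cfg):
                cfg = comp
            out[cfg] = out.get(cfg, 0.0) + m
        return MSFS(self.deme_names, n.copy(), out, self.monomorphic, folded=True)

    # -- projection ---------------------------------------------------------
    def project(self, k) -> "MSFS":
        """Exact hypergeometric projection down to k gene copies per deme.

        k may be a scalar or one value per deme.  Mass projecting onto the
        all-zero / all-fixed configuration joins the monomorphic entry; a
        folded input is re-folded at the new sample sizes (projection
        commutes with minor-allele folding, so this is exact).
        """
        k = np.broadcast_to(np.asarray(k, dtype=np.int64), (self.n_demes,)).copy()
        if np.any(k > self.sample_sizes):
            raise ValueError(f"projection sizes {k} exceed sample sizes {self.sample_sizes}")
        mats = [projection_matrix(int(n), int(kk)) for n, kk in zip(self.sample_sizes, k)]
        dense = self.to_dense().reshape(tuple(self.sample_sizes + 1))
        for ax in range(self.n_demes):
            dense = np.moveaxis(np.tensordot(dense, mats[ax], axes=([ax], [0])), -1, ax)
        out = MSFS.from_dense(dense.reshape(-1), k, self.deme_names,
                              folded=False, monomorphic=self.monomorphic)
        return out.fold() if self.folded else out

    # -- monomorphic correction --------------------------------------------
    def correct_monomorphic(self, total_sites: float) -> "MSFS":
        """Set the invariant entry so polymorphic + monomorphic = total_sites."""
        poly = self.n_polymorphic
        if total_sites < poly:
            raise ValueError(
                f"total_sites={total_sites} is below the polymorphic count {poly}")
        return MSFS(self.deme_names, self.sample_sizes.copy(), dict(self.entries),
                    float(total_sites) - poly, self.folded)

    # -- plain-text serialisation ------------------------------------------
    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#demes\t" + "\t".join(self.deme_names) + "\n")
            fh.write("#samples\t" + "\t".join(str(int(x)) for x in self.sample_sizes) + "\n")
            fh.write(f"#folded\t{int(self.folded)}\n")
            fh.write(f"#monomorphic\t{self.monomorphic:.10g}\n")
            for cfg in sorted(self.entries):
                fh.write("\t".join(str(int(c)) for c in cfg)
                         + f"\t{self.entries[cfg]:.10g}\n")

    @classmethod
    def from_text(cls, path) -> "MSFS":
        names = sizes = None
        folded = True
        mono = 0.0
        entries = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "#demes":
                    names = tuple(parts[1:])
                elif parts[0] == "#samples":
                    sizes = np.array([int(x) for x in parts[1:]], dtype=np.int64)
                elif parts[0] == "#folded":
                    folded = bool(int(parts[1]))
                elif parts[0] == "#monomorphic":
                    mono = float(parts[1])
                elif parts[0].startswith("#") or not parts[0]:
                    continue
                else:
                    cfg = tuple(int(x) for x in parts[:-1])
                    entries[cfg] = entries.get(cfg, 0.0) + float(parts[-1])
        if names is None or sizes is None:
            raise ValueError(f"{path}: missing #demes / #samples header")
        return cls(names, sizes, entries, mono, folded)

    @classmethod
    def from_flat_text(cls, path, folded=False, deme_names=None) -> "MSFS":
        """Import a dadi/fastsimcoal-style flat SFS (1-D or 2-D).

        First non-comment line: the shape (n_d + 1 per deme) and optionally
        the token 'folded'/'unfolded'; next line(s): the flattened counts,
        row-major, entry 0 being the monomorphic/zero cell.
        """
        with open(path) as fh:
            tokens = []
            dims = None
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "//")):
                    continue
                if dims is None:
                    head = line.split()
                    dims = []
                    for tok in head:
                        if tok.lower().startswith("fold"):
                            folded = True
                        elif tok.lower().startswith("unfold"):
                            folded = False
                        elif tok.lstrip("-").isdigit():
                            dims.append(int(tok))
                    if len(dims) not in (1, 2):
                        raise ValueError("flat SFS import supports 1-D and 2-D spectra")
                else:
                    tokens.extend(line.split())
        if dims is None:
            raise ValueError(f"{path}: empty SFS file")
        flat = np.array([float(t) for t in tokens])
        if flat.size != int(np.prod(dims)):
            raise ValueError(f"{path}: expected {np.prod(dims)} entries, found {flat.size}")
        sizes = np.array(dims, dtype=np.int64) - 1
        return cls.from_dense(flat, sizes, deme_names, folded=folded)
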