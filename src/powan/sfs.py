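"""Composite-likelihood demographic inference from the MSFS.

Pipeline: build a folded MSFS from fully-genotyped genotypes (down-sampling
each deme first to equalise sample sizes), project it hypergeometrically to
a smaller number of gene copies to thin near-empty cells, restore the
monomorphic entry from the known total sequence length, then fit demographic
models by maximising the composite likelihood

    CL = sum_entries m_c * log p_c  +  M * log p_mono,

where the per-site entry probabilities p_c = mu * E[l_c] come from the mean
branch length E[l_c] subtending configuration c over n_sims simulated
genealogies (the Rao-Blackwellised expected SFS), and
p_mono = 1 - sum_c p_c.  All evaluations inside one fit share a common
random-number stream, so the objective is a deterministic function of the
parameters and standard 1-D search is applicable.

The optimiser draws n_starts log-uniform starting points and refines each by
n_cycles of cyclic per-parameter golden-section search on a shrinking
bracket.  Model selection is by maximum CL (AIC reported alongside);
confidence intervals come from a parametric bootstrap: simulate datasets of
the observed size under the point estimates and re-optimise each from
jittered starts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import DemographicModel, ModelError, branch_length_spectrum, simulate_msfs
from .genotypes import GenotypeMatrix
from .msfs import MSFS, strides_for

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# observed-MSFS construction
# ---------------------------------------------------------------------------

def msfs_from_genotypes(g: GenotypeMatrix, demes) -> MSFS:
    """Fold the SNPs of the listed populations into an MSFS.

    Requires complete genotypes in every listed deme (down-sample first);
    a missing genotype is an error naming the site.  Sites monomorphic
    across the listed demes are skipped; the monomorphic entry starts at 0
    pending `correct_monomorphic`.
    """
    demes = list(demes)
    pop_idx = g.pop_indices()
    for d in demes:
        if d not in pop_idx:
            raise KeyError(f"population {d!r} not in the genotype matrix")
    idx = [pop_idx[d] for d in demes]
    sizes = np.array([2 * len(i) for i in idx], dtype=np.int64)
    entries = {}
    for j in range(g.n_sites):
        cfg = []
        for i in idx:
            col = g.genotypes[i, j]
            if (col < 0).any():
                site = g.sites.iloc[j]
                raise ValueError(
                    f"missing genotype at {site['chrom']}:{site['pos']} — "
                    "down-sample to fully genotyped individuals first")
            cfg.append(int(col.sum()))
        tot = sum(cfg)
        if tot == 0 or tot == sizes.sum():
            continue
        cfg = tuple(cfg)
        entries[cfg] = entries.get(cfg, 0.0) + 1.0
    out = MSFS(tuple(demes), sizes, entries, 0.0, folded=False)
    return out.fold()


def downsample_genotypes(g: GenotypeMatrix, k_per_pop: int, seed: int = 0,
                         populations=None) -> GenotypeMatrix:
    """Keep k individuals per population, greedily maximising jointly
    complete sites, then drop any site with residual missingness.

    The greedy step starts from the most complete individual of each
    population and repeatedly adds the candidate that keeps the most sites
    complete (ties broken by a seeded shuffle).  A population smaller than k
    is an error.
    """
    populations = populations or g.pop_labels()
    rng = np.random.default_rng(seed)
    chosen = []
    for pop in populations:
        idx = g.pop_indices()[pop]
        if len(idx) < k_per_pop:
            raise ValueError(f"population {pop!r} has {len(idx)} < {k_per_pop} samples")
        order = rng.permutation(len(idx))  # tie-break order
        idx = idx[order]
        called = g.genotypes[idx] >= 0
        picked = [int(np.argmax(called.sum(axis=1)))]
        complete = called[picked[0]].copy()
        while len(picked) < k_per_pop:
            best, best_n = -1, -1
            for c in range(len(idx)):
                if c in picked:
                    continue
                n = int((complete & called[c]).sum())
                if n > best_n:
                    best, best_n = c, n
            picked.append(best)
            complete &= called[best]
        chosen.extend(int(idx[c]) for c in picked)
    sub = g.take_samples(np.array(sorted(chosen)))
    full = (sub.genotypes >= 0).all(axis=0)
    return sub.take_sites(full)


def project_msfs(sfs: MSFS, k) -> MSFS:
    """Hypergeometric projection to k gene copies per deme (see MSFS.project)."""
    return sfs.project(k)


def correct_monomorphic(sfs: MSFS, total_sites: float) -> MSFS:
    """Restore the invariant-site entry from the total sequence length."""
    return sfs.correct_monomorphic(total_sites)


# ---------------------------------------------------------------------------
# composite likelihood
# ---------------------------------------------------------------------------

def cl_from_expected(observed: MSFS, lengths: np.ndarray, mu: float,
                     p_floor: float) -> float:
    """CL of an observed MSFS given mean subtending branch lengths.

    Per-site entry probabilities are p_c = mu * lengths[c] (folded entries
    pool a configuration with its complement); the monomorphic probability
    is 1 minus the total segregating probability.  Expected probabilities
    below p_floor are floored to keep the sum finite.
    """
    st = strides_for(observed.sample_sizes)
    full = int(np.dot(observed.sample_sizes, st))
    p_seg = mu * (lengths.sum() - lengths[0] - lengths[full])
    p_mono = max(1.0 - p_seg, p_floor)
    cl = observed.monomorphic * np.log(p_mono)
    for cfg, m in observed.entries.items():
        i = int(np.dot(cfg, st))
        val = lengths[i]
        if observed.folded:
            j = full - i
            if j != i:
                val = val + lengths[j]
        cl += m * np.log(max(mu * val, p_floor))
    return float(cl)


def composite_log_likelihood(observed: MSFS, model: DemographicModel,
                             n_sims: int, seed: int,
                             p_floor: float | None = None) -> float:
    """CL of the observed MSFS under the model (see module docstring).

    p_floor (default 1 / (10 * n_sims * locus_length)) replaces expected
    probabilities of zero for configurations present in the data but never
    seen in the simulations, keeping CL finite.
    """
    samples = {nm: int(n) for nm, n in zip(observed.deme_names, observed.sample_sizes)}
    lengths, sizes, names = branch_length_spectrum(model, samples, n_sims, seed,
                                                   ploidy=1)
    if tuple(names) != tuple(observed.deme_names) or np.any(sizes != observed.sample_sizes):
        raise ModelError(
            f"sample-size mismatch: observed {observed.deme_names} "
            f"{observed.sample_sizes}, model gives {names} {sizes}")
    if p_floor is None:
        p_floor = 1.0 / (10.0 * n_sims * model.locus_length)
    return cl_from_expected(observed, lengths, model.mutation_rate, p_floor)


# ---------------------------------------------------------------------------
# model templates and fitting
# ---------------------------------------------------------------------------

@dataclass
class ParamSpec:
    lo: float
    hi: float
    scale: str = "log"   # "log" or "linear"

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"empty parameter range [{self.lo}, {self.hi}]")
        if self.scale == "log" and self.lo <= 0:
            raise ValueError("log-scaled parameter ranges must be positive")

    def transform(self, x):
        return np.log(x) if self.scale == "log" else x

    def inverse(self, u):
        return float(np.exp(u)) if self.scale == "log" else float(u)


@dataclass
class ModelTemplate:
    """A demographic model with free parameters.

    `builder` maps a complete parameter dict to a DemographicModel; `free`
    maps parameter names to ParamSpec ranges; `fixed` holds the rest.
    """
    builder: object
    free: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    name: str = "model"

    def build(self, params: dict) -> DemographicModel:
        return self.builder({**self.fixed, **params}).validate()

    @property
    def n_free(self) -> int:
        return len(self.free)


@dataclass
class FitResult:
    template: ModelTemplate
    observed: MSFS
    params: dict
    loglik: float
    per_start: list            # [(params, loglik)] best point of each start
    n_starts: int
    n_cycles: int
    n_sims: int
    seed: int

    def to_dict(self) -> dict:
        return {"model": self.template.name, "params": self.params,
                "loglik": self.loglik, "n_starts": self.n_starts,
                "n_cycles": self.n_cycles, "n_sims": self.n_sims,
                "seed": self.seed,
                "per_start": [{"params": p, "loglik": l} for p, l in self.per_start]}


_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_refine(f, lo, hi, n_evals=8):
    """Golden-section maximisation of f on [lo, hi]; returns (x, f(x))."""
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(n_evals - 2):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return (c, fc) if fc >= fd else (d, fd)


def fit(template: ModelTemplate, observed: MSFS, n_starts: int = 100,
        n_cycles: int = 40, n_sims: int = 100_000, seed: int = 0,
        starts: list | None = None, p_floor: float | None = None) -> FitResult:
    """Maximise the composite likelihood of a model template.

    Each of n_starts independent runs draws a start log-uniformly (linear
    parameters uniformly) within its range, then performs n_cycles of cyclic
    per-parameter golden-section refinement on a bracket that halves each
    cycle.  All CL evaluations share one simulation stream (common random
    numbers), making the objective deterministic.  Explicit `starts`
    (list of param dicts) override the random draws.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF17]))
    eval_seed = int(np.random.SeedSequence([seed, 0xC1]).generate_state(1)[0] % (2**31))
    cache: dict = {}

    def objective(params: dict) -> float:
        key = tuple(round(float(params[k]), 10) for k in template.free)
        if key not in cache:
            try:
                model = template.build(params)
                cache[key] = composite_log_likelihood(observed, model, n_sims,
                                                      eval_seed, p_floor)
            except ModelError:
                cache[key] = -np.inf
        return cache[key]

    if not template.free:
        ll = objective({})
        return FitResult(template, observed, dict(template.fixed), ll,
                         [({}, ll)], 0, 0, n_sims, seed)

    names = list(template.free)
    if starts is None:
        starts = []
        for _ in range(n_starts):
            p = {}
            for nm in names:
                spec = template.free[nm]
                u = rng.uniform(spec.transform(spec.lo), spec.transform(spec.hi))
                p[nm] = spec.inverse(u)
            starts.append(p)
    per_start = []
    for s_i, start in enumerate(starts):
        cur = dict(start)
        cur_ll = objective(cur)
        for cycle in range(n_cycles):
            shrink = 0.5 ** cycle
            for nm in names:
                spec = template.free[nm]
                lo_t, hi_t = spec.transform(spec.lo), spec.transform(spec.hi)
                half = 0.5 * (hi_t - lo_t) * shrink
                center = spec.transform(cur[nm])
                a = max(lo_t, center - half)
                b = min(hi_t, center + half)

                def f1(u, nm=nm, spec=spec):
                    trial = dict(cur)
                    trial[nm] = spec.inverse(u)
                    return objective(trial)

                x, fx = _golden_refine(f1, a, b)
                if fx > cur_ll:
                    cur[nm] = spec.inverse(x)
                    cur_ll = fx
        per_start.append((cur, cur_ll))
    lls = [l for _, l in per_start]
    if not np.isfinite(lls).any():
        raise RuntimeError(
            f"composite likelihood non-finite at every start of {template.name}; "
            f"starts tried: {starts}")
    best = int(np.argmax(lls))
    params, ll = per_start[best]
    return FitResult(template, observed, {**template.fixed, **params}, float(ll),
                     per_start, len(starts), n_cycles, n_sims, seed)


def profile_scan(observed: MSFS, template: ModelTemplate, param: str, grid,
                 n_sims: int, seed: int) -> pd.DataFrame:
    """Composite-likelihood profile of one parameter over an explicit grid,
    all other parameters held at their `fixed` values.

    Grid values yielding an inconsistent event ordering (an infeasible
    model) get CL = NaN and are ignored by the argmax.  Evaluations share a
    common random-number stream.
    """
    eval_seed = int(np.random.SeedSequence([seed, 0x9F0F]).generate_state(1)[0] % (2**31))
    rows = []
    for x in grid:
        try:
            model = template.build({param: float(x)})
            cl = composite_log_likelihood(observed, model, n_sims, eval_seed)
        except ModelError:
            cl = np.nan
        rows.append((float(x), cl))
    df = pd.DataFrame(rows, columns=[param, "loglik"])
    df["is_max"] = False
    if df["loglik"].notna().any():
        df.loc[df["loglik"].idxmax(), "is_max"] = True
    return df


# ---------------------------------------------------------------------------
# model comparison / hierarchical building
# ---------------------------------------------------------------------------

def compare_models(fits: list) -> pd.DataFrame:
    """Rank fits of the same observed MSFS by maximum CL; AIC alongside."""
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0].observed
    for f in fits[1:]:
        same = (f.observed is ref
                or (tuple(f.observed.deme_names) == tuple(ref.deme_names)
                    and np.array_equal(f.observed.sample_sizes, ref.sample_sizes)
                    and f.observed.entries == ref.entries
                    and f.observed.monomorphic == ref.monomorphic))
        if not same:
            raise ValueError("fits compare different observed spectra")
    rows = [(f.template.name, f.template.n_free, f.loglik,
             2 * f.template.n_free - 2 * f.loglik) for f in fits]
    df = pd.DataFrame(rows, columns=["model", "k", "loglik", "AIC"])
    df["rank"] = df["loglik"].rank(ascending=False, method="first").astype(int)
    df["best"] = df["rank"] == 1
    return df.sort_values("rank", kind="stable").reset_index(drop=True)


def hierarchical_build(levels: list, n_starts: int = 100, n_cycles: int = 40,
                       n_sims: int = 100_000, seed: int = 0) -> list:
    """Sequential model building: at each level fit every candidate model
    (all parameters free, including the previously established backbone) on
    that level's observed MSFS and carry the best forward.

    `levels` is a list of dicts: {"name", "observed": MSFS, "candidates":
    list of ModelTemplate OR callable(best FitResult | None) -> list}.
    Returns [(name, best FitResult, ranking DataFrame), ...].
    """
    out = []
    best = None
    for li, level in enumerate(levels):
        cands = level["candidates"]
        if callable(cands):
            cands = cands(best)
        if not cands:
            raise ValueError(f"level {level.get('name', li)!r}: empty candidate set")
        fits = [fit(tpl, level["observed"], n_starts=n_starts, n_cycles=n_cycles,
                    n_sims=n_sims, seed=seed + 101 * li + 7 * ci)
                for ci, tpl in enumerate(cands)]
        table = compare_models(fits)
        best = fits[int(np.argmax([f.loglik for f in fits]))]
        out.append((level.get("name", f"level{li}"), best, table))
    return out


# ---------------------------------------------------------------------------
# parametric bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapCI:
    table: pd.DataFrame        # param, point, lower, upper
    n_boot: int
    n_failed: int
    replicates: pd.DataFrame   # per-replicate best parameters

    def interval(self, param: str):
        row = self.table.set_index("param").loc[param]
        return float(row["lower"]), float(row["upper"])


def parametric_bootstrap(best: FitResult, n_boot: int = 50, n_opt: int = 15,
                         seed: int = 0, n_cycles: int | None = None,
                         n_sims: int | None = None, jitter: float = 0.25,
                         ci: float = 0.95) -> BootstrapCI:
    """Percentile bootstrap CIs by re-fitting simulated datasets.

    Each replicate simulates an MSFS of the observed size (total sites /
    locus length loci) under the point estimates, then runs n_opt
    optimisations started from the point estimates jittered by
    *exp(U(-jitter, jitter)) (linear parameters shifted by a matching
    fraction of their range), keeping the best.  Replicates whose fits all
    fail are excluded (warning above 10% failures).  The interval is the
    (1-ci)/2 .. 1-(1-ci)/2 percentile range per parameter; a point estimate
    outside its own CI is flagged.
    """
    tpl = best.template
    n_cycles = n_cycles if n_cycles is not None else best.n_cycles
    n_sims = n_sims if n_sims is not None else best.n_sims
    model = tpl.build({k: v for k, v in best.params.items() if k in tpl.free})
    samples = {nm: int(n) for nm, n in zip(best.observed.deme_names,
                                           best.observed.sample_sizes)}
    n_loci = max(1, int(round(best.observed.total / model.locus_length)))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    names = list(tpl.free)
    rows, n_failed = [], 0
    for b in range(n_boot):
        sim = simulate_msfs(model, samples, n_loci,
                            int(rng.integers(2**31)), ploidy=1,
                            folded=best.observed.folded)
        starts = []
        for _ in range(n_opt):
            p = {}
            for nm in names:
                spec = tpl.free[nm]
                x = best.params[nm]
                if spec.scale == "log":
                    x = x * float(np.exp(rng.uniform(-jitter, jitter)))
                else:
                    x = x + float(rng.uniform(-jitter, jitter)) * (spec.hi - spec.lo)
                p[nm] = float(np.clip(x, spec.lo, spec.hi))
            starts.append(p)
        try:
            f = fit(tpl, sim, n_cycles=n_cycles, n_sims=n_sims,
                    seed=int(rng.integers(2**31)), starts=starts)
            rows.append({nm: f.params[nm] for nm in names} | {"loglik": f.loglik})
        except RuntimeError as err:
            n_failed += 1
            log.warning("bootstrap replicate %d failed: %s", b, err)
    if n_failed > 0.1 * n_boot:
        warnings.warn(f"parametric_bootstrap: {n_failed}/{n_boot} replicates failed")
    reps = pd.DataFrame(rows)
    q = (1.0 - ci) / 2.0
    recs = []
    for nm in names:
        lo, hi = np.quantile(reps[nm], [q, 1 - q]) if len(reps) else (np.nan, np.nan)
        point = best.params[nm]
        if not lo <= point <= hi:
            log.warning("bootstrap CI for %s excludes the point estimate", nm)
        recs.append((nm, point, float(lo), float(hi)))
    table = pd.DataFrame(recs, columns=["param", "point", "lower", "upper"])
    return BootstrapCI(table, n_boot, n_failed, reps)


# ---------------------------------------------------------------------------
# time conversion
# ---------------------------------------------------------------------------

def generations_to_years(t, generation_time: float = 3.5):
    """Generations before present -> years before present."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("generation counts must be non-negative")
    out = t * generation_time
    return float(out) if out.ndim == 0 else out


def to_ky(years) -> int:
    """Round years to the nearest thousand years, for reporting."""
    return int(round(float(years) / 1000.0))
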