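"""Forward Wright-Fisher simulator of a de-domestication scenario.

A cultivated source population at ancestral size drifts to mutation-drift
equilibrium; a feral (weedy) population splits through a bottleneck of
``N_b`` founders lasting ``T_b`` generations, recovers to ``N_w`` and evolves
for ``T`` further generations with optional symmetric migration to and from
the cultivated population. Sites are unlinked (free recombination) and
mutate under a recurrent biallelic model: a mutated gamete flips its allele,
so new mutations can arise at sites monomorphic in the source.

Per generation and population the order of events is mutation, viability
selection, migration (post-bottleneck only), then binomial resampling of
2N gametes. Selection weights for alt-allele dosage (0, 1, 2):
directional (1, 1+s, 1+2s); overdominant (1, 1+s, 1).

Desk-scale rescaling convention: to emulate a large population of size N,
simulate N' = N / lambda with mu' = lambda * mu so that 4 N mu (and the SFS
shape) is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import GenotypeMatrix, PopulationMap

REGIMES = ("directional", "overdominant")
TARGETS = ("weedy", "cultivated")


# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------


@dataclass
class DemographyParams:
    """Concrete (unscaled) demographic parameters of the split scenario."""

    N_a: int  # ancestral cultivated diploid size
    N_b: int  # bottleneck founder size
    N_w: int  # recovered weedy size
    T_b: int  # bottleneck duration, generations
    T: int  # generations from recovery to present
    m: float  # symmetric post-bottleneck migration fraction per generation

    def __post_init__(self):
        for name in ("N_a", "N_b", "N_w"):
            if getattr(self, name) < 2:
                raise ParameterError(f"{name} must be >= 2")
        if self.T_b < 0 or self.T < 0:
            raise ParameterError("durations must be >= 0")
        if not (0 <= self.m < 0.5):
            raise ParameterError("migration fraction must be in [0, 0.5)")


@dataclass
class SelectionLocus:
    chrom: str
    pos: int  # 0-based
    regime: str
    s: float
    target_pop: str = "weedy"
    init_freq: float = None  # optional standing frequency seeded at the split

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ParameterError(f"unknown regime {self.regime!r}")
        if self.target_pop not in TARGETS:
            raise ParameterError(f"unknown target population {self.target_pop!r}")
        if self.s <= 0:
            raise ParameterError("selection coefficient must be > 0")
        if self.init_freq is not None and not (0 < self.init_freq < 1):
            raise ParameterError("init_freq must be in (0, 1)")


@dataclass
class GenomeSpec:
    chrom_lengths: dict  # chrom -> bp
    n_sites: dict  # chrom -> number of mutation target sites
    mu: float  # per-site per-generation mutation rate

    def __post_init__(self):
        if self.mu < 0:
            raise ParameterError("mutation rate must be >= 0")
        for c, L in self.chrom_lengths.items():
            if L <= 0:
                raise ParameterError(f"chromosome {c} has non-positive length")
            if self.n_sites.get(c, 0) > L:
                raise ParameterError(f"more target sites than bp on {c}")


# ---------------------------------------------------------------------------
# Engine primitives (shared with the demographic-inference module)
# ---------------------------------------------------------------------------


def mutate_freqs(p, mu):
    """Recurrent biallelic mutation: expected post-mutation frequency."""
    if mu == 0:
        return p
    return p * (1.0 - mu) + (1.0 - p) * mu


def selection_shift(p, regime, s):
    """Post-viability gamete frequency under the given regime (vectorized)."""
    q = 1.0 - p
    if regime == "directional":
        w0, w1, w2 = 1.0, 1.0 + s, 1.0 + 2.0 * s
    elif regime == "overdominant":
        w0, w1, w2 = 1.0, 1.0 + s, 1.0
    else:
        raise ParameterError(f"unknown regime {regime!r}")
    wbar = w0 * q**2 + w1 * 2 * p * q + w2 * p**2
    out = np.where(wbar > 0, (w2 * p**2 + w1 * p * q) / np.where(wbar > 0, wbar, 1.0), p)
    return out


def drift(p, n_diploid, rng):
    """Binomial resampling of 2N gametes; returns next-generation frequency."""
    n2 = 2 * int(n_diploid)
    return rng.binomial(n2, p) / n2


class _SelectionConfig:
    """Selection loci of one population, resolved to site indices."""

    def __init__(self, loci, site_index):
        by_regime = {}
        for loc in loci:
            key = loc.chrom, loc.pos
            if key not in site_index:
                raise ParameterError(f"selection locus {key} is not a simulated site")
            by_regime.setdefault((loc.regime, loc.s), []).append(site_index[key])
        self.groups = [
            (regime, s, np.array(idx, dtype=np.intp))
            for (regime, s), idx in by_regime.items()
        ]

    def apply(self, p):
        for regime, s, idx in self.groups:
            p[idx] = selection_shift(p[idx], regime, s)
        return p


def evolve_population(p0, n_diploid, generations, mu=0.0, seed=None, rng=None,
                      regime=None, s=0.0):
    """Evolve a vector of unlinked site frequencies in one population.

    With ``regime`` set, the same selection regime applies to every site
    (useful for replicate-locus experiments). Returns the final frequencies.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p = np.array(p0, dtype=float)
    n2 = 2 * int(n_diploid)
    for _ in range(int(generations)):
        p = mutate_freqs(p, mu)
        if regime is not None:
            p = selection_shift(p, regime, s)
        p = rng.binomial(n2, p) / n2
    return p


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------


def _sample_genotypes(p, sel: _SelectionConfig, n_ind, rng):
    """Draw diploid genotypes; selected sites use post-viability genotype
    frequencies, neutral sites are Hardy-Weinberg."""
    geno = rng.binomial(2, p, size=(n_ind, p.size)).astype(np.int8)
    for regime, s, idx in sel.groups:
        if regime == "directional":
            w = np.array([1.0, 1.0 + s, 1.0 + 2.0 * s])
        else:
            w = np.array([1.0, 1.0 + s, 1.0])
        for j in idx:
            pj = p[j]
            g = np.array([(1 - pj) ** 2, 2 * pj * (1 - pj), pj**2]) * w
            g /= g.sum()
            geno[:, j] = rng.choice(3, size=n_ind, p=g)
    return geno


# ---------------------------------------------------------------------------
# Scenario simulation
# ---------------------------------------------------------------------------


def _draw_positions(spec: GenomeSpec, loci, rng):
    """Random site positions per chromosome, unioned with selection loci."""
    chrom_arr, pos_arr = [], []
    loci_by_chrom = {}
    for loc in loci:
        if loc.chrom not in spec.chrom_lengths:
            raise ParameterError(f"locus chromosome {loc.chrom!r} not in genome spec")
        if not (0 <= loc.pos < spec.chrom_lengths[loc.chrom]):
            raise ParameterError(f"locus position {loc.pos} outside {loc.chrom}")
        loci_by_chrom.setdefault(loc.chrom, set()).add(loc.pos)
    for chrom, length in spec.chrom_lengths.items():
        n = spec.n_sites.get(chrom, 0)
        fixed = loci_by_chrom.get(chrom, set())
        pos = set(map(int, rng.choice(length, size=min(n, length), replace=False)))
        pos |= fixed
        pos = np.array(sorted(pos), dtype=np.int64)
        chrom_arr.extend([chrom] * pos.size)
        pos_arr.append(pos)
    return (
        np.array(chrom_arr, dtype=object),
        np.concatenate(pos_arr) if pos_arr else np.zeros(0, dtype=np.int64),
    )


def simulate_dedomestication(
    spec: GenomeSpec,
    demo: DemographyParams,
    loci,
    n_sample_weedy,
    n_sample_cult,
    burn_in=None,
    seed=0,
):
    """Simulate the split scenario and sample genotypes from both populations.

    Returns ``(GenotypeMatrix, PopulationMap, TruthTable)``. The truth table
    (a DataFrame) records, for every site segregating in the union sample,
    whether its alternative allele arose before the split (``standing``) or
    after (``new``), plus the selection regime and coefficient (neutral
    sites have regime ``neutral`` and s = 0).
    """
    if n_sample_weedy > demo.N_w:
        raise ParameterError("weedy sample size exceeds N_w")
    if n_sample_cult > demo.N_a:
        raise ParameterError("cultivated sample size exceeds N_a")
    if burn_in is None:
        burn_in = 8 * demo.N_a
    if burn_in < 0:
        raise ParameterError("burn_in must be >= 0")
    rng = np.random.default_rng(seed)
    chrom_arr, pos_arr = _draw_positions(spec, loci, rng)
    site_index = {(c, int(p)): i for i, (c, p) in enumerate(zip(chrom_arr, pos_arr))}
    sel_c = _SelectionConfig([l for l in loci if l.target_pop == "cultivated"], site_index)
    sel_w = _SelectionConfig([l for l in loci if l.target_pop == "weedy"], site_index)
    mu = spec.mu
    n_sites = pos_arr.size

    # ancestral equilibrium
    p = np.zeros(n_sites)
    n2a = 2 * demo.N_a
    for _ in range(int(burn_in)):
        p = mutate_freqs(p, mu)
        p = sel_c.apply(p)
        p = rng.binomial(n2a, p) / n2a

    # seed standing frequencies for loci that request them
    for loc in loci:
        if loc.init_freq is not None:
            p[site_index[(loc.chrom, loc.pos)]] = loc.init_freq

    p_c = p
    p_split = p_c.copy()
    p_w = rng.binomial(2 * demo.N_b, p_c) / (2 * demo.N_b)

    # bottleneck: no migration
    n2b = 2 * demo.N_b
    for _ in range(demo.T_b):
        p_c = rng.binomial(n2a, sel_c.apply(mutate_freqs(p_c, mu))) / n2a
        p_w = rng.binomial(n2b, sel_w.apply(mutate_freqs(p_w, mu))) / n2b

    # recovery: symmetric migration active
    n2w = 2 * demo.N_w
    m = demo.m
    for _ in range(demo.T):
        pc1 = sel_c.apply(mutate_freqs(p_c, mu))
        pw1 = sel_w.apply(mutate_freqs(p_w, mu))
        pc2 = (1.0 - m) * pc1 + m * pw1
        pw2 = (1.0 - m) * pw1 + m * pc1
        p_c = rng.binomial(n2a, pc2) / n2a
        p_w = rng.binomial(n2w, pw2) / n2w

    geno_w = _sample_genotypes(p_w, sel_w, n_sample_weedy, rng)
    geno_c = _sample_genotypes(p_c, sel_c, n_sample_cult, rng)
    geno = np.concatenate([geno_w, geno_c], axis=0)

    alt_total = geno.sum(axis=0)
    segregating = (alt_total > 0) & (alt_total < 2 * geno.shape[0])
    keep = np.nonzero(segregating)[0]

    samples = [f"W{i + 1:03d}" for i in range(n_sample_weedy)] + [
        f"C{i + 1:03d}" for i in range(n_sample_cult)
    ]
    matrix = GenotypeMatrix(
        samples=samples,
        chrom=chrom_arr[keep],
        pos=pos_arr[keep],
        ref=np.full(keep.size, "A", dtype=object),
        alt=np.full(keep.size, "T", dtype=object),
        geno=geno[:, keep],
    )
    popmap = PopulationMap(
        {s: ("weedy", "weedy") for s in samples[:n_sample_weedy]}
        | {s: ("cultivated", "cultivated") for s in samples[n_sample_weedy:]}
    )

    locus_info = {(l.chrom, l.pos): (l.regime, l.s) for l in loci}
    rows = []
    for i in keep:
        c, pp = chrom_arr[i], int(pos_arr[i])
        regime, s = locus_info.get((c, pp), ("neutral", 0.0))
        origin = "standing" if p_split[i] > 0 else "new"
        # cult_present: alternative allele exists in the cultivated
        # population at sampling time (standing alleles can be lost to
        # drift; the operational shared/unique classifier is judged against
        # the contemporary pool, not the split-time origin)
        rows.append((c, pp, origin, regime, s, bool(p_c[i] > 0)))
    truth = pd.DataFrame(
        rows, columns=["chrom", "pos", "origin", "regime", "s", "cult_present"]
    )
    return matrix, popmap, truth


def simulate_equilibrium(n_sites, N, mu, group_sizes, burn_in=None, seed=0,
                         chrom="chr1", length=None):
    """Sample several groups from one panmictic equilibrium population.

    ``group_sizes`` maps group name -> diploid sample count; all groups are
    drawn from the same population (role ``cultivated``). Useful for neutral
    calibration: between-group FST is pure sampling noise.
    """
    if burn_in is None:
        burn_in = 8 * N
    if length is None:
        length = max(1000 * n_sites, 1)
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(length, size=n_sites, replace=False)).astype(np.int64)
    p = evolve_population(np.zeros(n_sites), N, burn_in, mu=mu, rng=rng)
    genos, samples, assignments = [], [], {}
    for group, count in group_sizes.items():
        if count > N:
            raise ParameterError(f"sample size for {group!r} exceeds N")
        genos.append(rng.binomial(2, p, size=(count, n_sites)).astype(np.int8))
        names = [f"{group}_{i + 1:03d}" for i in range(count)]
        samples.extend(names)
        assignments.update({s: (group, "cultivated") for s in names})
    geno = np.concatenate(genos, axis=0)
    alt_total = geno.sum(axis=0)
    keep = np.nonzero((alt_total > 0) & (alt_total < 2 * geno.shape[0]))[0]
    matrix = GenotypeMatrix(
        samples=samples,
        chrom=np.full(keep.size, chrom, dtype=object),
        pos=pos[keep],
        ref=np.full(keep.size, "A", dtype=object),
        alt=np.full(keep.size, "T", dtype=object),
        geno=geno[:, keep],
    )
    return matrix, PopulationMap(assignments)


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

#: span of the overdominant block in the de-domestication preset (chrom2);
#: must stay below ~5% of genome windows or the top-quantile Tajima's D
#: threshold lands inside the block plateau and fragments the region
BALANCING_BLOCK = ("chr2", 2_000_000, 2_600_000)

#: focal centers of the directional sweep clusters (chrom1)
DIRECTIONAL_CENTERS = [1_000_000, 2_000_000, 3_000_000, 4_000_000, 5_000_000]

#: half-width of each directional cluster, bp
DIRECTIONAL_HALF_WIDTH = 20_000

#: preset sweep-cluster coefficients and standing start frequency
PRESET_SWEEP_S = 0.3
PRESET_OVERDOM_S = 0.3
PRESET_INIT_FREQ = 0.1


def dedomestication_preset(with_selection=True):
    """Bottleneck + selection scenario used by the scan/AFD recovery tests.

    Two 8 Mb chromosomes; five directional sweep clusters on chr1 and one
    0.6 Mb overdominant block on chr2, all seeded as standing variation at
    frequency 0.1 under a tight founder bottleneck. The mutation rate is
    kept low (theta = 0.008/site) so the standing/new dichotomy stays crisp:
    at higher rates recurrent mutation keeps re-introducing alleles into the
    cultivated pool and the origin classes blur. ``with_selection=False``
    gives the matched neutral control.
    """
    spec = GenomeSpec(
        chrom_lengths={"chr1": 8_000_000, "chr2": 8_000_000},
        n_sites={"chr1": 24_000, "chr2": 24_000},
        mu=8e-6,
    )
    demo = DemographyParams(N_a=250, N_b=15, N_w=250, T_b=10, T=60, m=0.0)
    loci = []
    if with_selection:
        for center in DIRECTIONAL_CENTERS:
            for pos in range(
                center - DIRECTIONAL_HALF_WIDTH,
                center + DIRECTIONAL_HALF_WIDTH + 1,
                2000,
            ):
                loci.append(
                    SelectionLocus(
                        "chr1", pos, "directional", PRESET_SWEEP_S, "weedy",
                        PRESET_INIT_FREQ,
                    )
                )
        chrom, start, end = BALANCING_BLOCK
        for pos in range(start, end, 1000):
            loci.append(
                SelectionLocus(
                    chrom, pos, "overdominant", PRESET_OVERDOM_S, "weedy",
                    PRESET_INIT_FREQ,
                )
            )
    return spec, demo, loci


# ---------------------------------------------------------------------------
# Truth table IO
# ---------------------------------------------------------------------------

_TRUTH_COLS = ["chrom", "pos", "origin", "regime", "s"]


def write_truth(truth: pd.DataFrame, path):
    """Write the truth table as TSV (positions 0-based, exact round-trip)."""
    truth[_TRUTH_COLS].to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "pos": np.int64, "origin": str, "regime": str, "s": float},
    )
    if list(df.columns) != _TRUTH_COLS:
        raise ParameterError(f"{path}: not a truth table")
    return df


def truth_to_string(truth: pd.DataFrame) -> str:
    buf = StringIO()
    write_truth(truth, buf)
    return buf.getvalue()
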