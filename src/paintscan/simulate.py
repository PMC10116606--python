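"""Forward-in-time Wright-Fisher simulation of a single-pulse admixed population.

The admixed population is founded in a single generation by mixing two
source populations: each founding haplotype carries ancestry 1 (the source
carrying the beneficial allele, by convention) with probability ``m`` and
ancestry 0 otherwise.  The population then evolves by discrete,
non-overlapping Wright-Fisher generations with recombination.  Local
ancestry is tracked directly as an ordered tiling of ancestry tracts per
haplotype; there is no mutation, so the only genetic state is the ancestry
mosaic plus the allele at each configured selected site.

Selection is fecundity selection: each offspring draws its two parents
independently with probability proportional to diploid fitness.  Per-site
fitness is ``1 + s`` for carrier homozygotes, ``1 + h*s`` for heterozygotes
and 1 otherwise, multiplicative across sites.

All randomness flows through a single :class:`numpy.random.Generator`, so a
run is reproducible from ``(configs, seed)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from ._kernels import compact_kernel, gamete_kernel

__all__ = [
    "RecombinationMap",
    "SizeEvent",
    "DemographicModel",
    "SelectedSite",
    "SelectionModel",
    "HaplotypeTractSet",
    "Population",
    "SampleSet",
    "SimulationResult",
    "init_founders",
    "draw_crossovers",
    "meiosis",
    "diploid_fitness",
    "next_generation",
    "run_simulation",
    "sample_haplotypes",
    "ancestry_proportion_profile",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecombinationMap:
    """Crossover model for one chromosome.

    Either a uniform per-basepair crossover probability (``rate``) or a
    monotone table of ``(physical position bp, cumulative genetic position
    cM)`` pairs.  The expected number of crossovers per meiosis equals the
    total map length in Morgans.
    """

    length: float
    rate: float | None = None
    table: np.ndarray | None = None  # (K, 2): position bp, cumulative cM

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("chromosome length must be positive")
        if (self.rate is None) == (self.table is None):
            raise ValueError("exactly one of rate / table must be given")
        if self.rate is not None and self.rate < 0:
            raise ValueError("uniform rate must be >= 0")
        if self.table is not None:
            tab = np.asarray(self.table, dtype=float)
            if tab.ndim != 2 or tab.shape[1] != 2 or tab.shape[0] < 2:
                raise ValueError("table must be (K>=2, 2)")
            if tab[0, 1] != 0:
                raise ValueError("cumulative map must start at 0 cM")
            if np.any(np.diff(tab[:, 0]) <= 0) or np.any(np.diff(tab[:, 1]) <= 0):
                raise ValueError("table must be strictly increasing in both columns")
            object.__setattr__(self, "table", tab)

    @property
    def mode(self) -> str:
        return "uniform" if self.rate is not None else "table"

    @property
    def total_morgans(self) -> float:
        if self.rate is not None:
            return self.rate * self.length
        return float(self.table[-1, 1]) / 100.0

    def cumulative_cm(self, position):
        """Genetic position (cM) of physical position(s) in bp."""
        position = np.asarray(position, dtype=float)
        if self.rate is not None:
            return position * self.rate * 100.0
        return np.interp(position, self.table[:, 0], self.table[:, 1])

    def cm_to_bp(self, cm):
        """Inverse of :meth:`cumulative_cm` (monotone interpolation)."""
        cm = np.asarray(cm, dtype=float)
        if self.rate is not None:
            if self.rate == 0:
                raise ValueError("zero-rate uniform map is not invertible")
            return cm / (self.rate * 100.0)
        return np.interp(cm, self.table[:, 1], self.table[:, 0])


@dataclass(frozen=True)
class SizeEvent:
    """Instantaneous population-size change at a given generation.

    ``set_size`` and ``bottleneck_start`` set the diploid size to ``size``;
    ``bottleneck_end`` restores the founding size N0 (``size`` ignored).
    """

    generation: int
    kind: str = "set_size"
    size: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"set_size", "bottleneck_start", "bottleneck_end"}:
            raise ValueError(f"unknown size event kind {self.kind!r}")
        if self.kind != "bottleneck_end" and (self.size is None or self.size <= 0):
            raise ValueError("size event requires a positive size")


@dataclass(frozen=True)
class DemographicModel:
    """Single-pulse admixture demography.

    m
        Admixture fraction contributed by source 1, the source that carries
        the beneficial allele in the baseline scenario.
    N0
        Founding diploid population size.
    generations
        Number of Wright-Fisher generations simulated after founding.
    """

    m: float
    N0: int
    generations: int
    chromosomes: tuple[RecombinationMap, ...]
    size_events: tuple[SizeEvent, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.m <= 1:
            raise ValueError("m must be in [0, 1]")
        if self.N0 <= 0:
            raise ValueError("N0 must be positive")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        for ev in self.size_events:
            if not 0 <= ev.generation <= self.generations:
                raise ValueError("size event generation outside [0, generations]")
        object.__setattr__(
            self, "size_events", tuple(sorted(self.size_events, key=lambda e: e.generation))
        )

    def size_trajectory(self) -> np.ndarray:
        """Diploid size at each generation 0..generations (inclusive)."""
        sizes = np.empty(self.generations + 1, dtype=np.int64)
        cur = self.N0
        events = {ev.generation: ev for ev in self.size_events}
        for t in range(self.generations + 1):
            ev = events.get(t)
            if ev is not None:
                cur = self.N0 if ev.kind == "bottleneck_end" else ev.size
            sizes[t] = cur
        return sizes


@dataclass(frozen=True)
class SelectedSite:
    """One site under post-admixture selection.

    ``p_source1`` / ``p_source2`` are the founder allele frequencies in the
    two source populations; the baseline scenario fixes the allele in source
    1 (p=1) and removes it from source 2 (p=0).
    """

    chromosome: int
    position: float
    s: float
    h: float = 0.5
    p_source1: float = 1.0
    p_source2: float = 0.0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if not 0 <= self.h <= 1:
            raise ValueError("h must be in [0, 1]")
        for p in (self.p_source1, self.p_source2):
            if not 0 <= p <= 1:
                raise ValueError("founder allele frequencies must be in [0, 1]")


@dataclass(frozen=True)
class SelectionModel:
    sites: tuple[SelectedSite, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))

    @property
    def neutral(self) -> bool:
        return len(self.sites) == 0

    def validate_positions(self, model: DemographicModel) -> None:
        for site in self.sites:
            if not 0 <= site.chromosome < len(model.chromosomes):
                raise ValueError("selected site on unknown chromosome")
            if not 0 <= site.position < model.chromosomes[site.chromosome].length:
                raise ValueError("selected site outside chromosome bounds")


def config_hash(model: DemographicModel, selection: SelectionModel) -> str:
    """Stable short hash of the simulation configuration."""

    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (tuple, list)):
            return [encode(v) for v in obj]
        return obj

    payload = json.dumps(
        {"model": encode(model), "selection": encode(selection)}, sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# population state
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeTracts:
    """Flat tract storage for all haplotypes of one chromosome."""

    ends: np.ndarray  # float64, concatenated tract end positions
    anc: np.ndarray  # int8, tract ancestries
    offsets: np.ndarray  # int64, (n_haplotypes + 1,)

    @property
    def n_haplotypes(self) -> int:
        return len(self.offsets) - 1

    def haplotype(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        a, b = self.offsets[i], self.offsets[i + 1]
        return self.ends[a:b].copy(), self.anc[a:b].copy()


@dataclass
class Population:
    generation: int
    chromosomes: list[ChromosomeTracts]
    alleles: np.ndarray  # int8 (2N, n_sites)
    site_ancestry: np.ndarray  # int8 (2N, n_sites)

    @property
    def n_diploid(self) -> int:
        return self.chromosomes[0].n_haplotypes // 2


@dataclass
class HaplotypeTractSet:
    """One haplotype: per-chromosome ancestry tract tiling plus allele states.

    ``tracts[c]`` is a pair ``(ends, ancestry)`` of equal-length arrays; the
    tracts tile ``[0, L_c)`` as half-open intervals whose starts are implicit
    (0 then the previous end).  Adjacent tracts differ in ancestry after
    normalization.
    """

    tracts: list[tuple[np.ndarray, np.ndarray]]
    alleles: np.ndarray | None = None

    def validate(self, lengths) -> None:
        for (ends, anc), L in zip(self.tracts, lengths):
            if len(ends) != len(anc) or len(ends) == 0:
                raise ValueError("tract arrays malformed")
            if ends[-1] != L:
                raise ValueError("tracts do not tile the chromosome")
            if np.any(np.diff(ends) <= 0) or ends[0] <= 0:
                raise ValueError("tract ends must be strictly increasing and positive")
            if np.any(anc[1:] == anc[:-1]):
                raise ValueError("adjacent tracts share ancestry (not normalized)")

    def ancestry_at(self, chromosome: int, positions) -> np.ndarray:
        ends, anc = self.tracts[chromosome]
        idx = np.searchsorted(ends, np.asarray(positions, dtype=float), side="right")
        return anc[np.minimum(idx, len(anc) - 1)]


@dataclass
class SampleSet:
    """Haplotypes sampled as whole diploids from the final generation."""

    haplotypes: list[HaplotypeTractSet]
    chrom_lengths: tuple[float, ...]
    individuals: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.haplotypes)


@dataclass
class SimulationResult:
    population: Population
    allele_frequency: np.ndarray  # (generations + 1, n_sites)
    ancestry_proportion: np.ndarray  # (generations + 1, n_sites)
    model: DemographicModel
    selection: SelectionModel
    seed: int | None = None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def init_founders(
    model: DemographicModel, selection: SelectionModel, rng: np.random.Generator
) -> Population:
    """Generation-0 population: each founding haplotype is one full-length
    tract with ancestry Bernoulli(m); selected-site alleles are drawn from
    the founder frequency of the source the haplotype came from."""
    selection.validate_positions(model)
    n_hap = 2 * model.N0
    hap_anc = (rng.random(n_hap) < model.m).astype(np.int8)
    chroms = []
    for rmap in model.chromosomes:
        chroms.append(
            ChromosomeTracts(
                ends=np.full(n_hap, rmap.length, dtype=np.float64),
                anc=hap_anc.copy(),
                offsets=np.arange(n_hap + 1, dtype=np.int64),
            )
        )
    n_sites = len(selection.sites)
    alleles = np.zeros((n_hap, n_sites), dtype=np.int8)
    site_anc = np.zeros((n_hap, n_sites), dtype=np.int8)
    for k, site in enumerate(selection.sites):
        p = np.where(hap_anc == 1, site.p_source1, site.p_source2)
        alleles[:, k] = rng.random(n_hap) < p
        site_anc[:, k] = hap_anc
    return Population(0, chroms, alleles, site_anc)


def draw_crossovers(rmap: RecombinationMap, rng: np.random.Generator) -> np.ndarray:
    """Crossover breakpoints (bp) for one meiosis: Poisson count with mean
    equal to the map length in Morgans; positions uniform in genetic
    distance (which is uniform in bp for a uniform-rate map)."""
    k = rng.poisson(rmap.total_morgans)
    if k == 0:
        return np.empty(0, dtype=np.float64)
    if rmap.rate is not None:
        pos = rng.uniform(0.0, rmap.length, k)
    else:
        cm = rng.uniform(0.0, float(rmap.table[-1, 1]), k)
        pos = rmap.cm_to_bp(cm)
    return np.unique(pos)


def _draw_crossovers_batch(rmap, n_gam, rng):
    """Flat, per-gamete-sorted crossover positions for `n_gam` meioses."""
    counts = rng.poisson(rmap.total_morgans, n_gam)
    offsets = np.zeros(n_gam + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    total = int(offsets[-1])
    if total == 0:
        return np.empty(0, dtype=np.float64), offsets
    if rmap.rate is not None:
        pos = rng.uniform(0.0, rmap.length, total)
    else:
        cm = rng.uniform(0.0, float(rmap.table[-1, 1]), total)
        pos = rmap.cm_to_bp(cm)
    # positions are sorted per gamete inside the kernel
    return pos, offsets


def diploid_fitness(alleles0, alleles1, selection: SelectionModel) -> float:
    """Multiplicative fitness of one diploid from its two haplotype allele
    vectors: per site 1+s (two copies), 1+h*s (one copy), 1 (none)."""
    if selection.neutral:
        return 1.0
    g = np.asarray(alleles0, dtype=int) + np.asarray(alleles1, dtype=int)
    s = np.array([site.s for site in selection.sites])
    h = np.array([site.h for site in selection.sites])
    w = 1.0 + np.where(g == 2, s, 0.0) + np.where(g == 1, h * s, 0.0)
    return float(np.prod(w))


def _population_fitness(alleles: np.ndarray, selection: SelectionModel) -> np.ndarray:
    g = alleles[0::2].astype(np.float64) + alleles[1::2]
    s = np.array([site.s for site in selection.sites])
    h = np.array([site.h for site in selection.sites])
    w = 1.0 + (g == 2) * s + (g == 1) * (h * s)
    return w.prod(axis=1)


def _sites_by_chromosome(selection: SelectionModel):
    by_chrom: dict[int, list[int]] = {}
    for k, site in enumerate(selection.sites):
        by_chrom.setdefault(site.chromosome, []).append(k)
    return by_chrom


def _make_gametes(chrom: ChromosomeTracts, rmap, parent, start, alleles_cols, rng):
    """Run the meiosis kernel for one chromosome over a batch of gametes.

    Returns (new ChromosomeTracts, child alleles, child site ancestry) where
    the allele arrays have one column per selected site on this chromosome.
    """
    n_gam = len(parent)
    site_pos, p_alleles = alleles_cols
    xo, xo_off = _draw_crossovers_batch(rmap, n_gam, rng)
    n_tracts = np.diff(chrom.offsets)
    per_parent = n_tracts[2 * parent] + n_tracts[2 * parent + 1]
    bounds = per_parent + np.diff(xo_off) + 1
    bound_off = np.zeros(n_gam + 1, dtype=np.int64)
    np.cumsum(bounds, out=bound_off[1:])
    out_ends = np.empty(int(bound_off[-1]), dtype=np.float64)
    out_anc = np.empty(int(bound_off[-1]), dtype=np.int8)
    out_n = np.empty(n_gam, dtype=np.int64)
    n_sites = len(site_pos)
    out_alleles = np.zeros((n_gam, n_sites), dtype=np.int8)
    out_site_anc = np.zeros((n_gam, n_sites), dtype=np.int8)
    gamete_kernel(
        chrom.ends,
        chrom.anc,
        chrom.offsets,
        p_alleles,
        parent,
        start,
        xo,
        xo_off,
        site_pos,
        float(rmap.length),
        out_ends,
        out_anc,
        bound_off,
        out_n,
        out_alleles,
        out_site_anc,
    )
    new_off = np.zeros(n_gam + 1, dtype=np.int64)
    np.cumsum(out_n, out=new_off[1:])
    new_ends = np.empty(int(new_off[-1]), dtype=np.float64)
    new_anc = np.empty(int(new_off[-1]), dtype=np.int8)
    compact_kernel(out_ends, out_anc, bound_off[:-1], out_n, new_off[:-1], new_ends, new_anc)
    return ChromosomeTracts(new_ends, new_anc, new_off), out_alleles, out_site_anc


def meiosis(
    parent_haplotypes: tuple[HaplotypeTractSet, HaplotypeTractSet],
    rmap: RecombinationMap,
    rng: np.random.Generator,
    chromosome: int = 0,
    breakpoints: np.ndarray | None = None,
    start: int | None = None,
    site_positions=None,
) -> HaplotypeTractSet:
    """One recombinant gamete for a single chromosome of one diploid parent.

    The gamete starts on a fair-coin choice of parental haplotype and
    switches at each crossover breakpoint; adjacent same-ancestry tracts are
    merged.  When the parents carry allele states and ``site_positions`` are
    given, each child allele is copied from whichever parental haplotype
    donates the segment containing that site.  ``breakpoints`` / ``start``
    may be supplied explicitly (e.g. for hand-traced checks); otherwise they
    are drawn from ``rng``.
    """
    hap_a, hap_b = parent_haplotypes
    for hap in (hap_a, hap_b):
        hap.validate([rmap.length] * len(hap.tracts))
    if breakpoints is None:
        breakpoints = draw_crossovers(rmap, rng)
    if start is None:
        start = int(rng.integers(0, 2))
    ends_a, anc_a = hap_a.tracts[chromosome]
    ends_b, anc_b = hap_b.tracts[chromosome]
    flat_ends = np.concatenate([ends_a, ends_b])
    flat_anc = np.concatenate([anc_a, anc_b]).astype(np.int8)
    offsets = np.array([0, len(ends_a), len(ends_a) + len(ends_b)], dtype=np.int64)
    chrom = ChromosomeTracts(flat_ends, flat_anc, offsets)
    if site_positions is None:
        site_pos = np.empty(0, dtype=np.float64)
        p_alleles = np.zeros((2, 0), dtype=np.int8)
    else:
        site_pos = np.asarray(site_positions, dtype=np.float64)
        if hap_a.alleles is None or hap_b.alleles is None:
            raise ValueError("site_positions given but parents carry no allele states")
        p_alleles = np.vstack([hap_a.alleles, hap_b.alleles]).astype(np.int8)
    n_sites = len(site_pos)
    n_bounds = len(ends_a) + len(ends_b) + len(breakpoints) + 1
    xo = np.array(breakpoints, dtype=np.float64)  # copy: the kernel sorts in place
    xo_off = np.array([0, len(xo)], dtype=np.int64)
    out_ends = np.empty(n_bounds, dtype=np.float64)
    out_anc = np.empty(n_bounds, dtype=np.int8)
    out_n = np.empty(1, dtype=np.int64)
    out_alleles = np.zeros((1, n_sites), dtype=np.int8)
    gamete_kernel(
        chrom.ends,
        chrom.anc,
        chrom.offsets,
        p_alleles,
        np.zeros(1, dtype=np.int64),
        np.array([start], dtype=np.int8),
        xo,
        xo_off,
        site_pos,
        float(rmap.length),
        out_ends,
        out_anc,
        np.array([0, n_bounds], dtype=np.int64),
        out_n,
        out_alleles,
        np.zeros((1, n_sites), dtype=np.int8),
    )
    m = int(out_n[0])
    return HaplotypeTractSet(
        [(out_ends[:m].copy(), out_anc[:m].copy())],
        out_alleles[0].copy() if n_sites else None,
    )


def next_generation(
    pop: Population,
    model: DemographicModel,
    selection: SelectionModel,
    rng: np.random.Generator,
) -> Population:
    """One Wright-Fisher generation: fitness-weighted parent sampling
    (selfing allowed) and per-chromosome meiosis with free recombination
    between chromosomes."""
    sizes = model.size_trajectory()
    if pop.generation + 1 > model.generations:
        raise ValueError("population already at final generation")
    n_next = int(sizes[pop.generation + 1])
    n_cur = pop.n_diploid
    if selection.neutral:
        parents = rng.integers(0, n_cur, size=(n_next, 2))
    else:
        w = _population_fitness(pop.alleles, selection)
        total = w.sum()
        if total <= 0:
            raise RuntimeError("all-zero fitness in population")
        cdf = np.cumsum(w)
        parents = np.searchsorted(cdf, rng.random((n_next, 2)) * cdf[-1], side="right")
        np.minimum(parents, n_cur - 1, out=parents)
    par_gam = parents.ravel().astype(np.int64)  # gamete 2i from parents[i,0], 2i+1 from [i,1]
    by_chrom = _sites_by_chromosome(selection)
    n_sites = len(selection.sites)
    new_alleles = np.zeros((2 * n_next, n_sites), dtype=np.int8)
    new_site_anc = np.zeros((2 * n_next, n_sites), dtype=np.int8)
    new_chroms = []
    for c, rmap in enumerate(model.chromosomes):
        start = rng.integers(0, 2, size=2 * n_next).astype(np.int8)
        cols = by_chrom.get(c, [])
        site_pos = np.array([selection.sites[k].position for k in cols], dtype=np.float64)
        p_alleles = np.ascontiguousarray(pop.alleles[:, cols]) if cols else np.zeros(
            (2 * n_cur, 0), dtype=np.int8
        )
        chrom, child_alleles, child_site_anc = _make_gametes(
            pop.chromosomes[c], rmap, par_gam, start, (site_pos, p_alleles), rng
        )
        new_chroms.append(chrom)
        if cols:
            new_alleles[:, cols] = child_alleles
            new_site_anc[:, cols] = child_site_anc
    return Population(pop.generation + 1, new_chroms, new_alleles, new_site_anc)


def run_simulation(
    model: DemographicModel,
    selection: SelectionModel,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Run the full simulation; deterministic given (configs, seed).

    Per-generation allele-frequency and ancestry-proportion trajectories are
    recorded for every selected site.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pop = init_founders(model, selection, rng)
    n_sites = len(selection.sites)
    g = model.generations
    freq = np.zeros((g + 1, n_sites))
    anc = np.zeros((g + 1, n_sites))
    if n_sites:
        freq[0] = pop.alleles.mean(axis=0)
        anc[0] = pop.site_ancestry.mean(axis=0)
    for t in range(g):
        pop = next_generation(pop, model, selection, rng)
        if n_sites:
            freq[t + 1] = pop.alleles.mean(axis=0)
            anc[t + 1] = pop.site_ancestry.mean(axis=0)
    return SimulationResult(pop, freq, anc, model, selection, seed)


def sample_haplotypes(
    result: SimulationResult | Population,
    n: int = 200,
    rng: np.random.Generator | None = None,
    model: DemographicModel | None = None,
    seed: int | None = None,
) -> SampleSet:
    """Sample ``n`` haplotypes as ``n/2`` whole diploids without replacement.

    Both haplotypes of each sampled individual are kept adjacent and the
    individual order is stable (sorted index).
    """
    if isinstance(result, SimulationResult):
        pop = result.population
        model = result.model
    else:
        pop = result
        if model is None:
            raise ValueError("model required when sampling from a bare Population")
    if n % 2 != 0:
        raise ValueError("n must be even (haplotypes are sampled as diploids)")
    if n // 2 > pop.n_diploid:
        raise ValueError("cannot sample more diploids than the population holds")
    if rng is None:
        rng = np.random.default_rng(seed)
    inds = np.sort(rng.choice(pop.n_diploid, size=n // 2, replace=False))
    hap_idx = np.empty(n, dtype=np.int64)
    hap_idx[0::2] = 2 * inds
    hap_idx[1::2] = 2 * inds + 1
    haplotypes = []
    for i in hap_idx:
        tracts = [chrom.haplotype(int(i)) for chrom in pop.chromosomes]
        alleles = pop.alleles[i].copy() if pop.alleles.shape[1] else None
        haplotypes.append(HaplotypeTractSet(tracts, alleles))
    lengths = tuple(r.length for r in model.chromosomes)
    return SampleSet(haplotypes, lengths, inds, {"n": n, "generation": pop.generation})


def ancestry_proportion_profile(samples: SampleSet, positions, chromosome: int = 0) -> np.ndarray:
    """Fraction of sampled haplotypes carrying ancestry 1 at each position."""
    positions = np.asarray(positions, dtype=float)
    if np.any(positions < 0) or np.any(positions >= samples.chrom_lengths[chromosome]):
        raise ValueError("positions outside chromosome bounds")
    acc = np.zeros(len(positions))
    for hap in samples.haplotypes:
        acc += hap.ancestry_at(chromosome, positions)
    return acc / samples.n


def check_tiling(pop: Population, model: DemographicModel) -> None:
    """Assert every haplotype's tracts exactly tile [0, L) (debug helper)."""
    for chrom, rmap in zip(pop.chromosomes, model.chromosomes):
        off = chrom.offsets
        for i in range(chrom.n_haplotypes):
            ends = chrom.ends[off[i] : off[i + 1]]
            anc = chrom.anc[off[i] : off[i + 1]]
            assert len(ends) >= 1
            assert ends[-1] == rmap.length, "tracts do not reach chromosome end"
            assert ends[0] > 0 and np.all(np.diff(ends) > 0), "non-increasing tract ends"
            assert not np.any(anc[1:] == anc[:-1]), "unmerged adjacent tracts"
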