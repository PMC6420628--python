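"""Forward simulators for yeast-like strain panels.

Implements every synthetic input the pipeline consumes:

* random point mutations on a 16-chromosome genome with a configurable
  transition:transversion ratio;
* admixed populations (founder lineages, one-crossover-per-chromosome
  in-silico meiosis, private mutations) with a complete ground-truth event
  log, so the true extent of homoplasy is known exactly;
* balanced ancestral polymorphism overlaid on such a population, each strain
  drawn independently at the balancing minor-allele frequency;
* neutral placement of variants on a fixed tree, branch-length-proportional;
* an inbred haploid cross with planted causal nucleotides and replicated,
  plate-structured colony-size phenotypes.

All randomness flows through an injected :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, VariantLocus
from .trees import PhyloTree

__all__ = [
    "GenomeModel",
    "MutationModel",
    "AdmixtureParams",
    "BalancingParams",
    "CrossSimParams",
    "MutationEvent",
    "SimulatedPopulation",
    "generate_random_mutations",
    "simulate_meiosis",
    "build_admixed_population",
    "overlay_balanced_polymorphisms",
    "place_neutral_variants_on_tree",
    "simulate_f6_cross",
]

#: S288C reference karyotype (R64), chromosome lengths in bp.
YEAST_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("chrI", 230218),
    ("chrII", 813184),
    ("chrIII", 316620),
    ("chrIV", 1531933),
    ("chrV", 576874),
    ("chrVI", 270161),
    ("chrVII", 1090940),
    ("chrVIII", 562643),
    ("chrIX", 439888),
    ("chrX", 745751),
    ("chrXI", 666816),
    ("chrXII", 1078177),
    ("chrXIII", 924431),
    ("chrXIV", 784333),
    ("chrXV", 1091291),
    ("chrXVI", 948066),
)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names and lengths; uniform base composition."""

    names: tuple[str, ...] = tuple(n for n, _ in YEAST_CHROMOSOMES)
    lengths: tuple[int, ...] = tuple(l for _, l in YEAST_CHROMOSOMES)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths) or not self.names:
            raise ValueError("names and lengths must be non-empty and parallel")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def yeast(cls, scale: float = 1.0) -> "GenomeModel":
        """The 16-chromosome S. cerevisiae karyotype, optionally scaled
        down by a single factor for fast tests."""
        if scale <= 0:
            raise ValueError("scale must be positive")
        return cls(
            names=tuple(n for n, _ in YEAST_CHROMOSOMES),
            lengths=tuple(max(1, int(round(l * scale))) for _, l in YEAST_CHROMOSOMES),
        )

    @property
    def n_chromosomes(self) -> int:
        return len(self.names)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    @property
    def offsets(self) -> np.ndarray:
        """Cumulative start offset of each chromosome in the concatenated
        genome, plus the total length (length ``n_chromosomes + 1``)."""
        return np.concatenate([[0], np.cumsum(self.lengths)]).astype(np.int64)

    def locate(self, global_sites: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map 0-based concatenated-genome offsets to (chrom index, 1-based
        position)."""
        global_sites = np.asarray(global_sites, dtype=np.int64)
        off = self.offsets
        cidx = np.searchsorted(off, global_sites, side="right") - 1
        pos = global_sites - off[cidx] + 1
        return cidx.astype(np.int64), pos


@dataclass(frozen=True)
class MutationModel:
    """Point-mutation parameters.

    ``tstv_ratio`` is the expected transition:transversion ratio;
    ``per_bp_rate`` the per-base per-division mutation probability;
    ``effective_population`` the effective population size (used only by the
    exploration-timescale arithmetic).
    """

    tstv_ratio: float = 3.0
    per_bp_rate: float = 5e-10
    effective_population: float = 1e6

    def __post_init__(self) -> None:
        if self.tstv_ratio <= 0:
            raise ValueError("tstv_ratio must be > 0")
        if not 0 < self.per_bp_rate < 1:
            raise ValueError("per_bp_rate must be in (0, 1)")


@dataclass(frozen=True)
class AdmixtureParams:
    n_founders: int = 5
    muts_per_founder: int = 30_000
    n_mosaics: int = 10
    muts_per_strain_post: int = 10_000
    crossovers_per_chromosome: int = 1

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.n_mosaics > 0 and self.n_founders < 2:
            raise ValueError("need at least two founders to generate mosaics")
        if self.crossovers_per_chromosome != 1:
            raise NotImplementedError("only one crossover per chromosome is modeled")


@dataclass(frozen=True)
class BalancingParams:
    """Fraction of loci under balancing selection and its equilibrium
    minor-allele frequency."""

    f_ancestral: float = 0.1
    maf_balanced: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_ancestral <= 1.0:
            raise ValueError("f_ancestral must be in [0, 1]")
        if not 0.0 < self.maf_balanced <= 0.5:
            raise ValueError("maf_balanced must be in (0, 0.5]")


@dataclass(frozen=True)
class MutationEvent:
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    is_transition: bool
    lineage: str | None = None


@dataclass
class SimulatedPopulation:
    """A genotype matrix plus the ground truth that produced it.

    ``events`` holds one row per independent de novo origination event
    (columns: site, chrom, pos, lineage, stage, carriers); ``balanced``
    flags loci created by the balancing-selection overlay, which have no
    origination event.  The true emergence count of a locus is its number
    of event rows.
    """

    matrix: GenotypeMatrix
    events: pd.DataFrame
    balanced: np.ndarray
    breakpoints: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def true_emergence_counts(self) -> np.ndarray:
        """Number of independent origination events per locus (0 for
        balanced loci)."""
        counts = np.zeros(self.matrix.n_loci, dtype=np.int64)
        if len(self.events):
            sites = self._locus_sites()
            ev = self.events["site"].to_numpy()
            idx = np.searchsorted(sites, ev)
            np.add.at(counts, idx, 1)
        return counts

    def true_homoplasy_count(self) -> int:
        """Number of loci at which the same site mutated independently in
        two or more lineages."""
        return int((self.true_emergence_counts() >= 2).sum())

    def _locus_sites(self) -> np.ndarray:
        v = self.matrix.variants
        g: GenomeModel = self.meta["genome"]
        off = g.offsets
        return off[v["chrom"].cat.codes.to_numpy()] + v["pos"].to_numpy() - 1


# -- random mutations ---------------------------------------------------------


def _draw_sites(
    rng: np.random.Generator,
    genome_length: int,
    n: int,
    forbidden: np.ndarray | None = None,
) -> np.ndarray:
    """Draw ``n`` distinct uniform sites, excluding ``forbidden`` (sorted).

    A redraw loop implements the no-reversion rule: a site already mutated
    in the same lineage is simply drawn again.
    """
    n_forbidden = 0 if forbidden is None else len(forbidden)
    if n > genome_length - n_forbidden:
        raise ValueError(
            f"cannot place {n} distinct mutations on {genome_length} free bp"
        )
    out: list[np.ndarray] = []
    have = 0
    taken = set() if forbidden is None else set(forbidden.tolist())
    while have < n:
        batch = rng.integers(0, genome_length, size=(n - have) + 16)
        fresh = []
        for s in batch.tolist():
            if s not in taken:
                taken.add(s)
                fresh.append(s)
                if have + len(fresh) == n:
                    break
        if fresh:
            arr = np.array(fresh, dtype=np.int64)
            out.append(arr)
            have += len(arr)
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def _draw_alleles(
    rng: np.random.Generator, n: int, tstv: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform reference base, then transition with probability
    tstv/(1+tstv), else one of the two transversions."""
    ref = rng.integers(0, 4, size=n)
    is_ts = rng.random(n) < tstv / (1.0 + tstv)
    tv_pick = rng.integers(0, 2, size=n)
    alt = np.where(is_ts, (ref + 2) % 4, (ref + 1 + 2 * tv_pick) % 4)
    return ref, alt, is_ts


def generate_random_mutations(
    n: int,
    genome: GenomeModel | None = None,
    mutation_model: MutationModel | None = None,
    rng: np.random.Generator | None = None,
    *,
    occupied: np.ndarray | None = None,
    lineage: str | None = None,
) -> list[MutationEvent]:
    """Generate ``n`` random point mutations.

    Positions are uniform over the genome; within one lineage a site is hit
    at most once (occupied sites are redrawn).  The transition fraction is
    tstv/(1+tstv) in expectation.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    genome = genome or GenomeModel.yeast()
    mutation_model = mutation_model or MutationModel()
    rng = rng if rng is not None else np.random.default_rng()
    if n == 0:
        return []
    sites = _draw_sites(rng, genome.total_length, n, forbidden=occupied)
    ref, alt, is_ts = _draw_alleles(rng, n, mutation_model.tstv_ratio)
    cidx, pos = genome.locate(sites)
    return [
        MutationEvent(
            chromosome=genome.names[c],
            position=int(p),
            ref_allele=_BASES[r],
            alt_allele=_BASES[a],
            is_transition=bool(t),
            lineage=lineage,
        )
        for c, p, r, a, t in zip(cidx, pos, ref, alt, is_ts)
    ]


# -- meiosis ------------------------------------------------------------------


def _recombine(
    ga: np.ndarray,
    gb: np.ndarray,
    locus_chrom: np.ndarray,
    locus_pos: np.ndarray,
    genome: GenomeModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One haploid meiotic product with one crossover per chromosome.

    The breakpoint is uniform in physical bp (1 .. length-1, so both bp
    segments are non-empty); which parent contributes the left segment is a
    fair coin per chromosome.  Returns (child, breakpoints, left_is_a).
    """
    lengths = np.asarray(genome.lengths, dtype=np.int64)
    bp = np.array(
        [rng.integers(1, max(2, l)) for l in lengths], dtype=np.int64
    )
    left_is_a = rng.random(genome.n_chromosomes) < 0.5
    take_a = (locus_pos <= bp[locus_chrom]) == left_is_a[locus_chrom]
    child = np.where(take_a, ga, gb).astype(ga.dtype)
    return child, bp, left_is_a


def simulate_meiosis(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    variants: pd.DataFrame,
    genome: GenomeModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """In-silico meiosis of two haploid genotype vectors.

    ``variants`` must carry ``chrom`` (categorical, genome order) and
    ``pos`` columns describing the shared loci.  Every output call equals
    one parent's call at that locus.
    """
    genome = genome or GenomeModel.yeast()
    rng = rng if rng is not None else np.random.default_rng()
    parent_a = np.asarray(parent_a)
    parent_b = np.asarray(parent_b)
    if parent_a.shape != parent_b.shape or len(parent_a) != len(variants):
        raise ValueError("parents must be defined over the same loci")
    cidx = variants["chrom"].cat.codes.to_numpy().astype(np.int64)
    pos = variants["pos"].to_numpy()
    child, bp, left_is_a = _recombine(parent_a, parent_b, cidx, pos, genome, rng)
    breakpoints = pd.DataFrame(
        {
            "chrom": list(genome.names),
            "breakpoint": bp,
            "left_parent": np.where(left_is_a, "a", "b"),
        }
    )
    return child, breakpoints


# -- admixed populations ------------------------------------------------------


def _strain_names(n_founders: int, n_mosaics: int) -> tuple[list[str], list[str]]:
    wf = max(2, len(str(n_founders)))
    wm = max(2, len(str(n_mosaics)))
    founders = [f"F{i + 1:0{wf}d}" for i in range(n_founders)]
    mosaics = [f"M{i + 1:0{wm}d}" for i in range(n_mosaics)]
    return founders, mosaics


def build_admixed_population(
    params: AdmixtureParams | None = None,
    genome: GenomeModel | None = None,
    mutation_model: MutationModel | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedPopulation:
    """Simulate an admixed panel: founder lineages with private mutations,
    mosaics from random founder matings, then further private mutations in
    every strain.

    Every de novo mutation is logged as it occurs, so the true extent of
    homoplasy (the same site mutated independently in two or more lineages)
    can be recounted from the truth log.  Allelic identity is resolved per
    site: the first event at a site fixes its ref/alt pair and a recurrent
    hit at the same site in another lineage re-creates the same substitution.
    """
    params = params or AdmixtureParams()
    genome = genome or GenomeModel.yeast()
    mutation_model = mutation_model or MutationModel()
    rng = rng if rng is not None else np.random.default_rng()

    founders, mosaics = _strain_names(params.n_founders, params.n_mosaics)
    strains = founders + mosaics
    n_strains = len(strains)
    G = genome.total_length

    site_ref: dict[int, int] = {}
    site_alt: dict[int, int] = {}

    def _register_alleles(sites: np.ndarray) -> None:
        new = [s for s in sites.tolist() if s not in site_ref]
        if new:
            ref, alt, _ = _draw_alleles(rng, len(new), mutation_model.tstv_ratio)
            for s, r, a in zip(new, ref.tolist(), alt.tolist()):
                site_ref[s] = r
                site_alt[s] = a

    ev_site: list[np.ndarray] = []
    ev_lineage: list[str] = []
    ev_stage: list[str] = []

    # 1. founder lineages
    founder_sites: list[np.ndarray] = []
    for f in founders:
        s = _draw_sites(rng, G, params.muts_per_founder)
        _register_alleles(s)
        founder_sites.append(s)
        ev_site.append(s)
        ev_lineage.extend([f] * len(s))
        ev_stage.extend(["founder"] * len(s))

    fcols = np.unique(np.concatenate(founder_sites)) if founder_sites else np.empty(
        0, np.int64
    )
    n_fcols = len(fcols)
    fcalls = np.zeros((n_strains, n_fcols), dtype=np.int8)
    for i, s in enumerate(founder_sites):
        fcalls[i, np.searchsorted(fcols, s)] = 1
    fchrom, fpos = genome.locate(fcols)

    # 2. mosaics by random mating of two distinct founders + one crossover
    #    per chromosome; the event an inherited allele traces back to is the
    #    contributing parent's own mutation at that site
    carrier_bonus: dict[tuple[str, int], int] = {}
    bp_rows = []
    for m_i, m in enumerate(mosaics):
        pa, pb = sorted(rng.choice(params.n_founders, size=2, replace=False).tolist())
        child, bp, left_is_a = _recombine(
            fcalls[pa], fcalls[pb], fchrom, fpos, genome, rng
        )
        fcalls[params.n_founders + m_i] = child
        from_a = (fpos <= bp[fchrom]) == left_is_a[fchrom]
        ones = child == 1
        src = np.where(from_a, pa, pb)[ones]
        for s, p in zip(fcols[ones].tolist(), src.tolist()):
            key = (founders[p], s)
            carrier_bonus[key] = carrier_bonus.get(key, 0) + 1
        for c, b, l in zip(genome.names, bp, left_is_a):
            bp_rows.append(
                {
                    "mosaic": m,
                    "chrom": c,
                    "breakpoint": int(b),
                    "left_parent": founders[pa] if l else founders[pb],
                    "right_parent": founders[pb] if l else founders[pa],
                }
            )

    # 3. post-admixture private mutations in every strain
    post_site: list[np.ndarray] = []
    post_strain: list[int] = []
    for i, name in enumerate(strains):
        occupied = fcols[fcalls[i] == 1]
        s = _draw_sites(rng, G, params.muts_per_strain_post, forbidden=occupied)
        _register_alleles(s)
        post_site.append(s)
        post_strain.extend([i] * len(s))
        ev_site.append(s)
        ev_lineage.extend([name] * len(s))
        ev_stage.extend(["post"] * len(s))

    # 4. assemble the full matrix
    all_post = (
        np.concatenate(post_site) if post_site else np.empty(0, np.int64)
    )
    sites = np.unique(np.concatenate([fcols, all_post]))
    L = len(sites)
    calls = np.zeros((n_strains, L), dtype=np.int8)
    calls[:, np.searchsorted(sites, fcols)] = fcalls
    if len(all_post):
        cols = np.searchsorted(sites, all_post)
        calls[np.array(post_strain), cols] = 1

    cidx, pos = genome.locate(sites)
    chrom_names = [genome.names[c] for c in cidx]
    variants = pd.DataFrame(
        {
            "chrom": pd.Categorical(
                chrom_names, categories=list(genome.names), ordered=True
            ),
            "pos": pos,
            "ref": _BASES[[site_ref[s] for s in sites.tolist()]],
            "alt": _BASES[[site_alt[s] for s in sites.tolist()]],
            "functional_class": "unknown",
        }
    )
    matrix = GenotypeMatrix(strains, variants, calls)

    ev_sites_arr = (
        np.concatenate(ev_site) if ev_site else np.empty(0, np.int64)
    )
    ec, ep = genome.locate(ev_sites_arr)
    carriers = np.ones(len(ev_sites_arr), dtype=np.int64)
    for k, (lin, s) in enumerate(zip(ev_lineage, ev_sites_arr.tolist())):
        carriers[k] += carrier_bonus.get((lin, s), 0)
    events = pd.DataFrame(
        {
            "site": ev_sites_arr,
            "chrom": [genome.names[c] for c in ec],
            "pos": ep,
            "lineage": ev_lineage,
            "stage": ev_stage,
            "carriers": carriers,
        }
    )

    return SimulatedPopulation(
        matrix=matrix,
        events=events,
        balanced=np.zeros(L, dtype=bool),
        breakpoints=pd.DataFrame(bp_rows) if bp_rows else None,
        meta={
            "genome": genome,
            "mutation_model": mutation_model,
            "admixture_params": params,
        },
    )


def overlay_balanced_polymorphisms(
    pop: SimulatedPopulation,
    params: BalancingParams,
    genome: GenomeModel | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedPopulation:
    """Add balanced ancestral polymorphism to a simulated population.

    ``round(f_ancestral * N_total)`` new loci are created at fresh random
    positions, where ``N_total`` is the number of de novo mutation events in
    the population; at each, every strain carries the alternate allele
    independently with probability ``maf_balanced`` (a random colony draw
    from a balanced mixed population).  Balanced loci are flagged in the
    truth log and carry no origination event.
    """
    genome = genome or pop.meta.get("genome") or GenomeModel.yeast()
    mutation_model = pop.meta.get("mutation_model") or MutationModel()
    rng = rng if rng is not None else np.random.default_rng()

    n_total = len(pop.events)
    n_bal = int(round(params.f_ancestral * n_total))
    if n_bal == 0:
        return pop

    existing = pop._locus_sites()
    sites = np.sort(
        _draw_sites(rng, genome.total_length, n_bal, forbidden=np.sort(existing))
    )
    S = pop.matrix.n_strains
    bal_calls = (rng.random((S, n_bal)) < params.maf_balanced).astype(np.int8)
    ref, alt, _ = _draw_alleles(rng, n_bal, mutation_model.tstv_ratio)

    cidx, bpos = genome.locate(sites)
    bal_variants = pd.DataFrame(
        {
            "chrom": pd.Categorical(
                [genome.names[c] for c in cidx],
                categories=list(genome.names),
                ordered=True,
            ),
            "pos": bpos,
            "ref": _BASES[ref],
            "alt": _BASES[alt],
            "functional_class": "unknown",
        }
    )

    # merge, keeping global site order
    all_sites = np.concatenate([existing, sites])
    order = np.argsort(all_sites, kind="stable")
    variants = pd.concat(
        [pop.matrix.variants, bal_variants], ignore_index=True
    ).iloc[order]
    calls = np.concatenate([pop.matrix.calls, bal_calls], axis=1)[:, order]
    balanced = np.concatenate(
        [pop.balanced, np.ones(n_bal, dtype=bool)]
    )[order]

    matrix = GenotypeMatrix(pop.matrix.strains, variants, calls)
    meta = dict(pop.meta)
    meta["balancing_params"] = params
    return SimulatedPopulation(
        matrix=matrix,
        events=pop.events,
        balanced=balanced,
        breakpoints=pop.breakpoints,
        meta=meta,
    )


# -- neutral placement on a fixed tree ---------------------------------------


def place_neutral_variants_on_tree(
    tree: PhyloTree,
    n: int,
    genome: GenomeModel | None = None,
    rng: np.random.Generator | None = None,
    mutation_model: MutationModel | None = None,
) -> SimulatedPopulation:
    """Distribute ``n`` variants on a tree, neutrally.

    Each variant lands on a branch with probability proportional to branch
    length and is propagated to every leaf descended from that branch;
    reversions are neglected, so every variant is a single emergence by
    construction.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    genome = genome or GenomeModel.yeast()
    mutation_model = mutation_model or MutationModel()
    rng = rng if rng is not None else np.random.default_rng()

    strains = sorted(tree.leaf_names)
    lengths, desc = tree.edge_descendants(strain_order=strains)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("tree must have positive total branch length")

    counts = rng.multinomial(n, lengths / total)
    sites = np.sort(_draw_sites(rng, genome.total_length, n))
    # assign branches to site slots in a random order
    branch_of = np.repeat(np.arange(len(lengths)), counts)
    rng.shuffle(branch_of)

    S = len(strains)
    calls = np.zeros((S, n), dtype=np.int8)
    for j, b in enumerate(branch_of):
        calls[desc[b], j] = 1

    ref, alt, _ = _draw_alleles(rng, n, mutation_model.tstv_ratio)
    cidx, pos = genome.locate(sites)
    variants = pd.DataFrame(
        {
            "chrom": pd.Categorical(
                [genome.names[c] for c in cidx],
                categories=list(genome.names),
                ordered=True,
            ),
            "pos": pos,
            "ref": _BASES[ref],
            "alt": _BASES[alt],
            "functional_class": "unknown",
        }
    )
    matrix = GenotypeMatrix(strains, variants, calls)
    events = pd.DataFrame(
        {
            "site": sites,
            "chrom": variants["chrom"].astype(str),
            "pos": variants["pos"],
            "lineage": [f"branch{b}" for b in branch_of],
            "stage": "neutral",
            "carriers": [len(desc[b]) for b in branch_of],
        }
    )
    return SimulatedPopulation(
        matrix=matrix,
        events=events,
        balanced=np.zeros(n, dtype=bool),
        meta={"genome": genome, "mutation_model": mutation_model, "tree": tree},
    )


# -- inbred cross with planted causal nucleotides -----------------------------


@dataclass(frozen=True)
class CrossSimParams:
    """Parameters of the simulated inbred haploid cross.

    ``qtns`` maps marker index to effect size in phenotype standard
    deviations; ``None`` plants three additive effects of 0.4/0.3/0.2 SD at
    the 10/45/80% quantiles of the marker list.  Replicate colony sizes get
    independent noise (``noise_sd``) plus a shared per-plate offset
    (``plate_effect_sd``); plates hold ``plate_shape`` colonies.
    """

    n_progeny: int = 1125
    n_markers: int = 12_054
    n_generations_inbreeding: int = 6
    qtns: tuple[tuple[int, float], ...] | None = None
    n_replicates: int = 2
    noise_sd: float = 1.0
    plate_effect_sd: float = 0.25
    plate_shape: tuple[int, int] = (16, 24)

    def resolved_qtns(self) -> tuple[tuple[int, float], ...]:
        if self.qtns is not None:
            idx = [q[0] for q in self.qtns]
            if len(set(idx)) != len(idx):
                raise ValueError("planted QTN markers must be distinct")
            if any(not 0 <= i < self.n_markers for i in idx):
                raise ValueError("planted QTN marker index out of range")
            if any(not np.isfinite(e) for _, e in self.qtns):
                raise ValueError("planted effects must be finite")
            return self.qtns
        return tuple(
            (int(q * self.n_markers), e)
            for q, e in ((0.10, 0.4), (0.45, 0.3), (0.80, 0.2))
        )


def simulate_f6_cross(
    params: CrossSimParams | None = None,
    genome: GenomeModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Simulate a highly inbred haploid cross with planted causal variants.

    Two parental haplotypes (all-reference vs all-alternate across the
    markers) are intercrossed for ``n_generations_inbreeding`` rounds of
    in-silico meiosis (one crossover per chromosome per round, random pairs
    from the previous generation), shrinking linkage blocks.  Phenotype is
    the sum of planted effects times genotype, plus a per-plate offset and
    replicate noise; replicates of a progeny share its genotype.

    Returns (progeny genotype matrix, replicate phenotype table, truth
    record of the planted nucleotides).
    """
    params = params or CrossSimParams()
    genome = genome or GenomeModel.yeast()
    rng = rng if rng is not None else np.random.default_rng()

    sites = np.sort(_draw_sites(rng, genome.total_length, params.n_markers))
    cidx, pos = genome.locate(sites)
    ref, alt, _ = _draw_alleles(rng, params.n_markers, MutationModel().tstv_ratio)

    n = params.n_progeny
    pool = np.zeros((2, params.n_markers), dtype=np.int8)
    pool[1] = 1
    for gen in range(params.n_generations_inbreeding):
        nxt = np.empty((n, params.n_markers), dtype=np.int8)
        for i in range(n):
            if pool.shape[0] == 2:
                pa, pb = 0, 1
            else:
                pa, pb = rng.choice(pool.shape[0], size=2, replace=False)
            nxt[i], _, _ = _recombine(pool[pa], pool[pb], cidx, pos, genome, rng)
        pool = nxt
    progeny = pool

    qtns = params.resolved_qtns()
    g_value = np.zeros(n)
    for idx, eff in qtns:
        g_value += eff * progeny[:, idx]

    n_rep = params.n_replicates
    per_plate = params.plate_shape[0] * params.plate_shape[1]
    total = n * n_rep
    slot = np.arange(total)
    plate = slot // per_plate
    row = (slot % per_plate) // params.plate_shape[1]
    col = slot % params.plate_shape[1]
    plate_eff = rng.normal(0.0, params.plate_effect_sd, size=plate.max() + 1)
    prog_idx = np.repeat(np.arange(n), n_rep)
    size = (
        g_value[prog_idx]
        + plate_eff[plate]
        + rng.normal(0.0, params.noise_sd, size=total)
    )

    width = len(str(n))
    names = [f"S{i + 1:0{width}d}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": pd.Categorical(
                [genome.names[c] for c in cidx],
                categories=list(genome.names),
                ordered=True,
            ),
            "pos": pos,
            "ref": _BASES[ref],
            "alt": _BASES[alt],
            "functional_class": "unknown",
        }
    )
    matrix = GenotypeMatrix(names, variants, progeny)
    phenotypes = pd.DataFrame(
        {
            "progeny": np.array(names)[prog_idx],
            "replicate": np.tile(np.arange(n_rep), n),
            "plate": plate,
            "row": row,
            "col": col,
            "colony_size": size,
        }
    )
    truth = {
        "qtns": [
            {
                "marker": int(idx),
                "chrom": str(variants["chrom"].iloc[idx]),
                "pos": int(variants["pos"].iloc[idx]),
                "effect_sd": float(eff),
            }
            for idx, eff in qtns
        ],
        "noise_sd": params.noise_sd,
        "plate_effect_sd": params.plate_effect_sd,
    }
    return matrix, phenotypes, truth
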