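"""Synthetic data generation for hybrid-parentage inference.

Everything the downstream census stages consume can be simulated here with
seeded determinism: a set of candidate parent genomes diverged from a common
ancestor under Jukes-Cantor (JC69) substitution, a diploid F1 or first-
generation backcross (BC1) hybrid with maternally inherited mitochondria,
short sequencing reads with uniform per-base error, and forests of gene
trees whose focal-tip sister is drawn from a controllable species mixture.

Sequences are held as ``numpy`` ``uint8`` arrays over the code {0:A, 1:C,
2:G, 3:T}; :func:`decode_seq` / :func:`encode_seq` convert to strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase


def encode_seq(s: str) -> np.ndarray:
    """String -> uint8 codes (A,C,G,T -> 0..3; anything else -> 4)."""
    return _ENCODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def decode_seq(a: np.ndarray) -> str:
    out = np.where(a < 4, BASES[np.minimum(a, 3)], np.uint8(ord("N")))
    return out.astype(np.uint8).tobytes().decode("ascii")


def revcomp(a: np.ndarray) -> np.ndarray:
    """Reverse complement in code space (0<->3, 1<->2; 4 stays 4)."""
    out = a[::-1].copy()
    valid = out < 4
    out[valid] = 3 - out[valid]
    return out


def jc69_expected_p(d: float) -> float:
    """Expected observed per-site difference for JC69 branch length *d*."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


@dataclass
class GeneTreeForestSpec:
    """Specification of a simulated gene-tree forest.

    The focal tip's sister is a single leaf drawn from ``sister_mixture``
    (species -> probability), or, with probability ``non_singleton_fraction``,
    a two-leaf cherry of other taxa.  The probabilities must sum to 1.
    ``quota_counts`` switches from Bernoulli sampling to exact quota
    construction: a mapping of species name (or the key ``"__multi__"``) to
    the exact number of trees in that category; counts must sum to
    ``n_trees``.
    """

    n_trees: int
    taxa: list[str]
    focal: str
    outgroup: str
    sister_mixture: dict[str, float]
    non_singleton_fraction: float = 0.0
    quota_counts: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees <= 0:
            raise ValueError("n_trees must be positive")
        if self.focal not in self.taxa or self.outgroup not in self.taxa:
            raise ValueError("focal and outgroup must be listed in taxa")
        for sp in self.sister_mixture:
            if sp not in self.taxa or sp in (self.focal, self.outgroup):
                raise ValueError(f"invalid sister-mixture species {sp!r}")
        total = sum(self.sister_mixture.values()) + self.non_singleton_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"sister_mixture plus non_singleton_fraction must sum to 1 (got {total})"
            )
        if self.quota_counts is not None:
            if sum(self.quota_counts.values()) != self.n_trees:
                raise ValueError("quota_counts must sum to n_trees")
            for sp in self.quota_counts:
                if sp != "__multi__" and (
                    sp not in self.taxa or sp in (self.focal, self.outgroup)
                ):
                    raise ValueError(f"invalid quota species {sp!r}")


#: default candidate set: two close parents and two more distant relatives.
#: Divergences are JC69 branch lengths from the common ancestor, so the two
#: parents sit at ~10% observed pairwise divergence.
DEFAULT_SPECIES: list[tuple[str, float]] = [
    ("numida", 0.05),
    ("gallus", 0.05),
    ("phasianus", 0.20),
    ("meleagris", 0.30),
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study system.

    ``species`` lists (name, JC69 branch length from the shared ancestor).
    ``dam``/``sire`` name the hybrid's parents; the dam contributes the
    mitochondrion.  ``hybrid_cross`` is ``"F1"`` or ``"BC1"``; a BC1 is an
    F1 backcrossed to ``backcross_parent`` and carries an expected 75% of
    its genome from that parent.  The nuclear genome is split into
    ``n_chromosomes`` equal chromosomes, each receiving
    ``n_crossovers_per_chromosome`` crossovers in the recombinant gamete.
    ``balanced_crossovers`` places a single midpoint crossover per
    chromosome so the recombinant haplotype carries exactly half of each
    F1 haplotype (the deterministic analogue of quota sampling for trees).
    """

    seed: int = 0
    genome_length: int = 50_000
    n_chromosomes: int = 20
    mito_length: int = 16_000
    species: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_SPECIES)
    )
    dam: str = "numida"
    sire: str = "gallus"
    hybrid_cross: str = "F1"
    backcross_parent: str | None = None
    n_crossovers_per_chromosome: int = 1
    balanced_crossovers: bool = False
    read_length: int = 100
    n_reads: int = 20_000
    error_rate: float = 0.005
    mito_read_fraction: float = 0.05
    tree_forest_spec: GeneTreeForestSpec | None = None

    def __post_init__(self) -> None:
        names = [n for n, _ in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        if any(d < 0 for _, d in self.species):
            raise ValueError("divergences must be >= 0")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.mito_length <= 0:
            raise ValueError("mito_length must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length > self.genome_length // self.n_chromosomes:
            raise ValueError("read_length exceeds chromosome length")
        if not 0 <= self.mito_read_fraction <= 1:
            raise ValueError("mito_read_fraction must be in [0, 1]")
        for p in (self.dam, self.sire):
            if p not in names:
                raise ValueError(f"hybrid parent {p!r} not among species")
        if self.hybrid_cross not in ("F1", "BC1"):
            raise ValueError("hybrid_cross must be 'F1' or 'BC1'")
        if self.hybrid_cross == "BC1":
            if self.backcross_parent is None:
                raise ValueError("BC1 cross requires backcross_parent")
            if self.backcross_parent not in (self.dam, self.sire):
                raise ValueError("backcross_parent must be one of the two parents")
        if self.n_crossovers_per_chromosome < 0:
            raise ValueError("n_crossovers_per_chromosome must be >= 0")

    @property
    def chromosome_length(self) -> int:
        return self.genome_length // self.n_chromosomes


@dataclass
class SpeciesGenome:
    name: str
    chromosomes: list[np.ndarray]
    mito: np.ndarray
    divergence: float

    @property
    def contigs(self) -> dict[str, np.ndarray]:
        return {f"chr{i}": c for i, c in enumerate(self.chromosomes)}


@dataclass
class GenomeSet:
    """Named species -> nuclear chromosomes + one mitochondrial sequence."""

    genomes: dict[str, SpeciesGenome]
    ancestor: list[np.ndarray]
    mito_ancestor: np.ndarray
    seed: int

    def __getitem__(self, name: str) -> SpeciesGenome:
        return self.genomes[name]

    def __iter__(self):
        return iter(self.genomes.values())

    @property
    def species(self) -> list[str]:
        return list(self.genomes)


@dataclass
class HybridGenome:
    """Diploid mosaic genome with a per-base true-origin track.

    ``haplotypes[h][c]`` is chromosome *c* of haplotype *h*; ``origins``
    mirrors it with values indexing ``parent_names``.  ``mito`` is copied
    verbatim from the dam.
    """

    parent_names: tuple[str, str]  # (dam, sire)
    haplotypes: tuple[list[np.ndarray], list[np.ndarray]]
    origins: tuple[list[np.ndarray], list[np.ndarray]]
    mito: np.ndarray
    dam: str
    cross: str

    def ancestry_fraction(self, parent: str) -> float:
        """Realized genome-wide fraction of positions inherited from *parent*."""
        idx = self.parent_names.index(parent)
        total = 0
        hits = 0
        for hap in self.origins:
            for track in hap:
                total += track.size
                hits += int(np.count_nonzero(track == idx))
        return hits / total


@dataclass
class Read:
    id: str
    seq: str
    qual: str
    origin: str = ""


@dataclass
class ReadSet:
    reads: list[Read]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def origins(self) -> list[str]:
        return [r.origin for r in self.reads]


def _mutate(rng: np.random.Generator, seq: np.ndarray, d: float) -> np.ndarray:
    """Apply JC69 substitutions for branch length *d* (expected substitutions/site)."""
    p = jc69_expected_p(d)
    out = seq.copy()
    mask = rng.random(seq.size) < p
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
    return out


def simulate_parent_genomes(config: SimulationConfig) -> GenomeSet:
    """Draw a uniform ancestor and derive each candidate species under JC69.

    Each species' observed per-site difference from the ancestor has
    expectation ``(3/4)(1 - exp(-4d/3))`` for its branch length ``d``; two
    species with branches ``d1`` and ``d2`` behave as a single branch of
    ``d1 + d2`` (the star phylogeny has no shared internal branches).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x67E0]))
    clen = config.chromosome_length
    ancestor = [
        rng.integers(0, 4, clen, dtype=np.uint8) for _ in range(config.n_chromosomes)
    ]
    mito_anc = rng.integers(0, 4, config.mito_length, dtype=np.uint8)
    genomes: dict[str, SpeciesGenome] = {}
    for name, d in config.species:
        chroms = [_mutate(rng, c, d) for c in ancestor]
        mito = _mutate(rng, mito_anc, d)
        genomes[name] = SpeciesGenome(name, chroms, mito, d)
    return GenomeSet(genomes, ancestor, mito_anc, config.seed)


def _recombine(
    rng: np.random.Generator,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    n_crossovers: int,
    balanced: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """One recombinant gamete chromosome from an F1's two haplotypes.

    Returns (sequence, origin) where origin is 0 for hap_a and 1 for hap_b.
    Balanced mode forces a single midpoint crossover so each haplotype
    contributes exactly half the chromosome.
    """
    length = hap_a.size
    if balanced:
        cuts = [length // 2]
    else:
        cuts = sorted(rng.integers(1, length, n_crossovers).tolist())
    start = int(rng.integers(0, 2))
    seq = np.empty(length, dtype=np.uint8)
    origin = np.empty(length, dtype=np.uint8)
    bounds = [0] + cuts + [length]
    src = (hap_a, hap_b)
    for i in range(len(bounds) - 1):
        which = (start + i) % 2
        lo, hi = bounds[i], bounds[i + 1]
        seq[lo:hi] = src[which][lo:hi]
        origin[lo:hi] = which
    return seq, origin


def make_hybrid(genomes: GenomeSet, config: SimulationConfig) -> HybridGenome:
    """Construct an F1 or BC1 hybrid with maternal mitochondrial inheritance.

    F1: one complete haplotype from each parent.  BC1: one complete
    haplotype from the backcrossed parent (its gamete) plus one recombinant
    gamete from the F1, giving an expected 75% ancestry from the
    backcrossed parent.  The per-base origin track indexes
    ``(dam, sire)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB41D]))
    dam_g = genomes[config.dam]
    sire_g = genomes[config.sire]
    parent_names = (config.dam, config.sire)
    n_chr = len(dam_g.chromosomes)

    if config.hybrid_cross == "F1":
        hap0 = [c.copy() for c in dam_g.chromosomes]
        hap1 = [c.copy() for c in sire_g.chromosomes]
        org0 = [np.zeros(c.size, dtype=np.uint8) for c in hap0]
        org1 = [np.ones(c.size, dtype=np.uint8) for c in hap1]
    else:
        bc = config.backcross_parent
        if bc is None:
            raise ValueError("BC1 cross requires backcross_parent")
        bc_idx = parent_names.index(bc)
        bc_g = genomes[bc]
        # gamete straight from the backcrossed parent
        hap0 = [c.copy() for c in bc_g.chromosomes]
        org0 = [np.full(c.size, bc_idx, dtype=np.uint8) for c in hap0]
        # recombinant gamete from the F1 (dam haplotype = 0, sire haplotype = 1)
        hap1, org1 = [], []
        for i in range(n_chr):
            seq, origin = _recombine(
                rng,
                dam_g.chromosomes[i],
                sire_g.chromosomes[i],
                config.n_crossovers_per_chromosome,
                config.balanced_crossovers,
            )
            hap1.append(seq)
            org1.append(origin)
    return HybridGenome(
        parent_names=parent_names,
        haplotypes=(hap0, hap1),
        origins=(org0, org1),
        mito=dam_g.mito.copy(),
        dam=config.dam,
        cross=config.hybrid_cross,
    )


def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, round(-10.0 * math.log10(error_rate)))
    return chr(33 + q)


def simulate_reads(
    source: HybridGenome | SpeciesGenome,
    config: SimulationConfig,
) -> ReadSet:
    """Simulate single-end reads with uniform start positions and errors.

    Each read draws a haplotype/chromosome (probability proportional to
    length), a uniform start, a random strand, and independent per-base
    substitution errors at ``config.error_rate``.  With probability
    ``config.mito_read_fraction`` the read comes from the mitochondrion
    instead.  The true origin (majority parent over the read span, or
    ``mito``) is recorded in the read header.
    """
    if config.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EAD]))
    rl = config.read_length

    if isinstance(source, SpeciesGenome):
        pools = [(c, None, source.name, f"hap0/chr{i}") for i, c in enumerate(source.chromosomes)]
        mito_seq = source.mito
        mito_label = f"mito:{source.name}"
    else:
        pools = []
        for h, (haps, orgs) in enumerate(zip(source.haplotypes, source.origins)):
            for c, (seq, org) in enumerate(zip(haps, orgs)):
                pools.append((seq, org, None, f"hap{h}/chr{c}"))
        mito_seq = source.mito
        mito_label = f"mito:{source.dam}"
        parent_names = source.parent_names
    for seq, *_ in pools:
        if seq.size < rl:
            raise ValueError("read_length exceeds source sequence length")
    if mito_seq.size < rl:
        raise ValueError("read_length exceeds mitochondrial length")

    weights = np.array([p[0].size for p in pools], dtype=float)
    weights /= weights.sum()
    qual = _phred_char(config.error_rate) * rl

    is_mito = rng.random(config.n_reads) < config.mito_read_fraction
    pool_pick = rng.choice(len(pools), size=config.n_reads, p=weights)
    strands = rng.random(config.n_reads) < 0.5

    reads: list[Read] = []
    for i in range(config.n_reads):
        if is_mito[i]:
            src_seq, src_org, label, loc = mito_seq, None, mito_label, "mito"
        else:
            src_seq, src_org, label, loc = pools[pool_pick[i]]
        start = int(rng.integers(0, src_seq.size - rl + 1))
        frag = src_seq[start : start + rl].copy()
        if label is None:  # hybrid nuclear read: majority origin over the span
            track = src_org[start : start + rl]
            label = parent_names[int(np.mean(track) >= 0.5)]
        if config.error_rate > 0:
            mask = rng.random(rl) < config.error_rate
            n = int(mask.sum())
            if n:
                frag[mask] = (frag[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
        strand = "-" if strands[i] else "+"
        if strand == "-":
            frag = revcomp(frag)
        rid = f"read{i}|origin={label}|loc={loc}|start={start}|strand={strand}"
        reads.append(Read(rid, decode_seq(frag), qual, label))
    return ReadSet(reads, seed=config.seed)


def _ladder(taxa: list[str]) -> str:
    """Nested (a,(b,(c,...))) newick fragment with unit branch lengths."""
    if len(taxa) == 1:
        return f"{taxa[0]}:1.0"
    return f"({taxa[0]}:1.0,{_ladder(taxa[1:])}):1.0"


def simulate_gene_trees(spec: GeneTreeForestSpec) -> list[str]:
    """Generate Newick gene trees with a controlled focal-sister mixture.

    Each tree contains every taxon in ``spec.taxa``; the focal tip's sister
    is a single leaf drawn from ``sister_mixture`` or, in the non-singleton
    case, a two-leaf cherry.  The outgroup subtends the root.  With
    ``quota_counts`` the per-category tree counts are exact; otherwise
    categories are drawn independently (Bernoulli sampling).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7EEE]))
    others = [t for t in spec.taxa if t not in (spec.focal, spec.outgroup)]

    if spec.quota_counts is not None:
        categories: list[str] = []
        for sp, n in spec.quota_counts.items():
            categories.extend([sp] * n)
        categories = list(np.array(categories)[rng.permutation(len(categories))])
    else:
        names = list(spec.sister_mixture) + ["__multi__"]
        probs = [spec.sister_mixture[s] for s in spec.sister_mixture] + [
            spec.non_singleton_fraction
        ]
        picks = rng.choice(len(names), size=spec.n_trees, p=probs)
        categories = [names[i] for i in picks]

    trees: list[str] = []
    for cat in categories:
        rest = list(np.array(others)[rng.permutation(len(others))])
        if cat == "__multi__":
            if len(rest) < 3:
                raise ValueError("non-singleton trees need at least 3 non-focal taxa")
            cherry = f"({rest[0]}:1.0,{rest[1]}:1.0):1.0"
            core = f"({spec.focal}:1.0,{cherry}):1.0"
            rest = rest[2:]
        else:
            rest.remove(cat)
            core = f"({spec.focal}:1.0,{cat}:1.0):1.0"
        if rest:
            ingroup = f"({core},{_ladder(rest)}):1.0"
        else:
            ingroup = core
        trees.append(f"({ingroup},{spec.outgroup}:1.0);")
    return trees
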