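"""Balanced, species-tagged fragment reference database.

To compare hit counts across candidate parent species whose assemblies
differ in size and contiguity, each species' genome is partitioned into
fixed-length fragments (default 100 bp) and an equal number of fragments is
sampled per species.  The resulting database, together with an exact k-mer
index, is what reads are aligned against.

Fragment ids are ``species|contig|start`` with 0-based, half-open
coordinates.  Tiling is non-overlapping from position 0; a terminal
remainder shorter than the fragment length is discarded.  Only the forward
strand is stored — the aligner searches both strands of the query.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .simdata import GenomeSet, SpeciesGenome, decode_seq, encode_seq

DEFAULT_FRAGMENT_LENGTH = 100
DEFAULT_KMER_SIZE = 11  # classic blastn word size


@dataclass
class Fragment:
    species: str
    frag_id: str
    seq: np.ndarray  # uint8 codes, length == fragment_length


@dataclass
class KmerIndex:
    """Exact k-mer index over the fragment matrix.

    Postings are stored as three parallel arrays sorted by k-mer code
    (base-4 integer): ``codes``, ``frag`` (fragment ordinal) and ``off``
    (offset within the fragment).  Lookup is a binary search.
    """

    k: int
    codes: np.ndarray  # uint64, sorted
    frag: np.ndarray  # int32
    off: np.ndarray  # int32

    def lookup(self, code: int) -> tuple[np.ndarray, np.ndarray]:
        lo = int(np.searchsorted(self.codes, code, side="left"))
        hi = int(np.searchsorted(self.codes, code, side="right"))
        return self.frag[lo:hi], self.off[lo:hi]


@dataclass
class FragmentDatabase:
    """Species-tagged fragments plus (optionally) a k-mer index."""

    fragments: list[Fragment]
    fragment_length: int
    n_sampled: int | None = None
    seed: int | None = None
    index: KmerIndex | None = None
    # dense views used by the aligner, built lazily
    _matrix: np.ndarray | None = field(default=None, repr=False)
    _species_idx: np.ndarray | None = field(default=None, repr=False)
    _species_names: list[str] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def total_length(self) -> int:
        """Total database length in bases (the n of the E-value m*n)."""
        return len(self.fragments) * self.fragment_length

    @property
    def species_names(self) -> list[str]:
        if self._species_names is None:
            self._build_dense()
        return self._species_names

    @property
    def species_index(self) -> np.ndarray:
        """Per-fragment species ordinal into :attr:`species_names`."""
        if self._species_idx is None:
            self._build_dense()
        return self._species_idx

    @property
    def matrix(self) -> np.ndarray:
        """(n_fragments, fragment_length) uint8 sequence matrix."""
        if self._matrix is None:
            self._build_dense()
        return self._matrix

    def _build_dense(self) -> None:
        names = sorted({f.species for f in self.fragments})
        lut = {n: i for i, n in enumerate(names)}
        self._species_names = names
        self._species_idx = np.array(
            [lut[f.species] for f in self.fragments], dtype=np.int32
        )
        mat = np.empty((len(self.fragments), self.fragment_length), dtype=np.uint8)
        for i, f in enumerate(self.fragments):
            mat[i] = f.seq
        self._matrix = mat

    def write_fasta(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for f in self.fragments:
                fh.write(f">{f.frag_id}\n{decode_seq(f.seq)}\n")
        meta = {
            "fragment_length": self.fragment_length,
            "n_sampled": self.n_sampled,
            "seed": self.seed,
            "n_fragments": len(self.fragments),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2)
        )

    @classmethod
    def read_fasta(cls, path: str | Path, fragment_length: int | None = None):
        from Bio import SeqIO

        path = Path(path)
        frags = []
        for rec in SeqIO.parse(str(path), "fasta"):
            species = rec.id.split("|", 1)[0]
            frags.append(Fragment(species, rec.id, encode_seq(str(rec.seq))))
        if not frags:
            raise ValueError(f"no fragments in {path}")
        length = fragment_length or frags[0].seq.size
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        seed = n_sampled = None
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            length = meta.get("fragment_length", length)
            seed = meta.get("seed")
            n_sampled = meta.get("n_sampled")
        return cls(frags, length, n_sampled=n_sampled, seed=seed)


def tile_fragments(
    genome: SpeciesGenome | dict[str, np.ndarray],
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    species: str | None = None,
) -> list[Fragment]:
    """Partition contigs into non-overlapping fixed-length fragments.

    Tiling starts at position 0 of each contig; the terminal remainder
    shorter than ``fragment_length`` is discarded.
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    if isinstance(genome, SpeciesGenome):
        contigs = genome.contigs
        species = species or genome.name
    else:
        contigs = genome
        if species is None:
            raise ValueError("species name required for raw contig mapping")
    if not contigs or all(c.size == 0 for c in contigs.values()):
        raise ValueError("empty genome")
    frags: list[Fragment] = []
    for cname, seq in contigs.items():
        n = seq.size // fragment_length
        for i in range(n):
            start = i * fragment_length
            frags.append(
                Fragment(
                    species,
                    f"{species}|{cname}|{start}",
                    seq[start : start + fragment_length],
                )
            )
    return frags


def sample_fragments(
    fragments: list[Fragment], n: int, seed: int = 0
) -> list[Fragment]:
    """Uniform sample of *n* fragments without replacement, seeded.

    If *n* exceeds the number available, all fragments are used and a
    warning is emitted (small synthetic genomes must still work).
    """
    if n >= len(fragments):
        if n > len(fragments):
            warnings.warn(
                f"requested {n} fragments but only {len(fragments)} available; "
                "using all",
                stacklevel=2,
            )
        return list(fragments)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF8A6]))
    picks = rng.choice(len(fragments), size=n, replace=False)
    return [fragments[i] for i in sorted(picks)]


def build_index(db: FragmentDatabase, k: int = DEFAULT_KMER_SIZE) -> FragmentDatabase:
    """Attach an exact k-mer index to the database (in place; returns it).

    Every k-mer occurrence in every fragment becomes a posting; k-mers
    containing non-ACGT codes are skipped.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > db.fragment_length:
        raise ValueError("k exceeds fragment_length")
    mat = db.matrix
    n_frags, flen = mat.shape
    n_kmers = flen - k + 1
    # rolling base-4 encoding across all fragments at once
    codes = np.zeros((n_frags, n_kmers), dtype=np.uint64)
    valid = np.ones((n_frags, n_kmers), dtype=bool)
    for j in range(k):
        col = mat[:, j : j + n_kmers]
        codes = codes * np.uint64(4) + col.astype(np.uint64)
        valid &= col < 4
    frag_idx, off_idx = np.nonzero(valid)
    flat = codes[frag_idx, off_idx]
    order = np.argsort(flat, kind="stable")
    db.index = KmerIndex(
        k=k,
        codes=flat[order],
        frag=frag_idx[order].astype(np.int32),
        off=off_idx[order].astype(np.int32),
    )
    return db


def build_database(
    genomes: GenomeSet | dict[str, SpeciesGenome],
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    n_sample: int | None = None,
    seed: int = 0,
    k: int = DEFAULT_KMER_SIZE,
    mito: bool = False,
) -> FragmentDatabase:
    """Tile, per-species sample, and index a multi-species database.

    With ``mito=True`` the species' mitochondrial sequences are tiled
    instead of the nuclear chromosomes (whole mitogenome, no subsampling
    unless requested).
    """
    entries = genomes.genomes.values() if isinstance(genomes, GenomeSet) else genomes.values()
    all_frags: list[Fragment] = []
    for g in entries:
        if mito:
            frags = tile_fragments({"mito": g.mito}, fragment_length, species=g.name)
        else:
            frags = tile_fragments(g, fragment_length)
        if n_sample is not None:
            frags = sample_fragments(frags, n_sample, seed=seed)
        all_frags.extend(frags)
    if not all_frags:
        raise ValueError("empty database")
    db = FragmentDatabase(
        all_frags, fragment_length, n_sampled=n_sample, seed=seed
    )
    return build_index(db, k=k)
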