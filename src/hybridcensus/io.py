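"""FASTA/FASTQ/manifest input-output (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simdata import GenomeSet, Read, ReadSet, SpeciesGenome, decode_seq, encode_seq


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path: str | Path) -> ReadSet:
    """Parse a Phred+33 FASTQ file; origins are recovered from headers
    written by the simulator (``origin=<label>``) when present."""
    reads: list[Read] = []
    path = Path(path)
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            origin = ""
            for part in rec.description.split("|"):
                if part.startswith("origin="):
                    origin = part[len("origin=") :]
            reads.append(Read(rec.description, str(rec.seq), qual, origin))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc
    return ReadSet(reads)


def write_genomes(genomes: GenomeSet, outdir: str | Path) -> None:
    """One nuclear FASTA and one mito FASTA per species."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        recs = [
            SeqRecord(Seq(decode_seq(c)), id=f"{g.name}|chr{i}", description="")
            for i, c in enumerate(g.chromosomes)
        ]
        SeqIO.write(recs, str(outdir / f"{g.name}.fasta"), "fasta")
        SeqIO.write(
            [SeqRecord(Seq(decode_seq(g.mito)), id=f"{g.name}|mito", description="")],
            str(outdir / f"{g.name}.mito.fasta"),
            "fasta",
        )


def read_genomes(indir: str | Path) -> dict[str, SpeciesGenome]:
    """Load per-species FASTA pairs written by :func:`write_genomes`."""
    indir = Path(indir)
    genomes: dict[str, SpeciesGenome] = {}
    for f in sorted(indir.glob("*.fasta")):
        if f.name.endswith(".mito.fasta"):
            continue
        name = f.stem
        chroms = [encode_seq(str(rec.seq)) for rec in SeqIO.parse(str(f), "fasta")]
        mito_path = indir / f"{name}.mito.fasta"
        if mito_path.exists():
            mito = encode_seq(str(next(SeqIO.parse(str(mito_path), "fasta")).seq))
        else:
            mito = np.empty(0, dtype=np.uint8)
        genomes[name] = SpeciesGenome(name, chroms, mito, divergence=float("nan"))
    if not genomes:
        raise FileNotFoundError(f"no FASTA genomes found in {indir}")
    return genomes


def write_origin_manifest(reads: ReadSet, path: str | Path) -> None:
    """Tab-separated true-origin manifest (read id, origin label)."""
    with open(path, "w") as fh:
        fh.write("read_id\torigin\n")
        for r in reads:
            fh.write(f"{r.id}\t{r.origin}\n")


def write_newick_forest(trees: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.rstrip("\n") + "\n")
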