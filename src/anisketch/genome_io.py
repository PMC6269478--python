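"""Genome assembly input, assembly statistics, and query fragmentation.

A :class:`Genome` is an ordered list of contigs.  Draft assemblies arrive
as multi-record FASTA; every record becomes one contig and fragmentation
never crosses a contig join (a fragment spanning two unrelated contig
ends would be chimeric).  Coordinates are 0-based, half-open everywhere
in this package; only human-facing exports convert to 1-based inclusive.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

_VALID = set("ACGTN")
_CLEAN = str.maketrans(
    {c: "N" for c in map(chr, range(65, 91)) if c not in "ACGT"}
)


class EmptyGenomeError(ValueError):
    """Raised when a FASTA file contains no non-empty records."""


def _normalize(seq: str) -> str:
    """Uppercase and map any character outside {A,C,G,T,N} to N."""
    s = seq.upper()
    if set(s) <= _VALID:
        return s
    # translate handles A-Z; anything still outside the alphabet (digits,
    # punctuation, gap characters) is mapped in a second pass
    s = s.translate(_CLEAN)
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


@dataclass
class Genome:
    """An assembly: ordered contigs with ids plus a genome-level id."""

    id: str
    contigs: list[tuple[str, str]]
    total_length: int = field(init=False)

    def __post_init__(self) -> None:
        self.contigs = [
            (cid, _normalize(seq)) for cid, seq in self.contigs if len(seq) > 0
        ]
        ids = [cid for cid, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate contig ids in genome {self.id!r}")
        self.total_length = sum(len(seq) for _, seq in self.contigs)

    def contig_lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.contigs]


@dataclass(frozen=True)
class Fragment:
    """A fixed-length non-overlapping piece of a query genome."""

    fragment_id: int
    source_contig: str
    start: int  # 0-based offset within source_contig
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def _open_maybe_gzip(path: str | Path) -> TextIO:
    """Open plain or gzipped text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fasta(path: str | Path, genome_id: str | None = None) -> Genome:
    """Read a (possibly gzipped) FASTA assembly into a :class:`Genome`.

    Records keep file order; empty records are dropped; sequences are
    uppercased with non-ACGTN characters mapped to N.

    Raises
    ------
    EmptyGenomeError
        If the file holds no non-empty sequence record.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    with _open_maybe_gzip(path) as handle:
        contigs = [
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")
        ]
    genome = Genome(id=genome_id or str(path), contigs=contigs)
    if genome.total_length == 0 or not genome.contigs:
        raise EmptyGenomeError(f"no non-empty FASTA records in {path}")
    return genome


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    """Write a genome as uncompressed FASTA."""
    with open(path, "wt") as fh:
        for cid, seq in genome.contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def n50(genome: Genome) -> int:
    """N50 contig length.

    The smallest contig length L such that contigs of length >= L sum to
    at least half the assembly length.
    """
    lengths = sorted(genome.contig_lengths(), reverse=True)
    if not lengths:
        raise EmptyGenomeError(f"genome {genome.id!r} has no contigs")
    half = genome.total_length / 2
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    return lengths[-1]  # unreachable: acc reaches total


def passes_assembly_filter(genome: Genome, min_n50: int = 10_000) -> bool:
    """Assembly-contiguity pre-filter: keep genomes with N50 >= ``min_n50``.

    Low-contiguity assemblies (N50 below 10 Kbp by default) give
    unreliable identity estimates and are skipped; the boundary value
    passes.
    """
    return n50(genome) >= min_n50


def fragment_genome(genome: Genome, l: int = 3000) -> list[Fragment]:
    """Cut the genome into non-overlapping fragments of exactly ``l`` bp.

    Each contig yields floor(len/l) fragments at offsets 0, l, 2l, ...;
    the trailing remainder shorter than l is discarded and fragments never
    span a contig join.  Fragment ids are consecutive from 0 over the
    whole genome in contig order.
    """
    if l <= 0:
        raise ValueError(f"fragment length must be positive, got {l}")
    fragments: list[Fragment] = []
    fid = 0
    for cid, seq in genome.contigs:
        for start in range(0, len(seq) - l + 1, l):
            fragments.append(Fragment(fid, cid, start, seq[start : start + l]))
            fid += 1
    return fragments


def write_fragments_bed(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Debug export of fragment coordinates as BED-like TSV (0-based, half-open)."""
    with open(path, "wt") as fh:
        for frag in fragments:
            fh.write(
                f"{frag.source_contig}\t{frag.start}\t"
                f"{frag.start + len(frag)}\t{frag.fragment_id}\n"
            )


def read_path_list(path: str | Path) -> list[str]:
    """Read a list file of FASTA paths, one per line; ``#`` starts a comment."""
    paths: list[str] = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            entry = line.split("#", 1)[0].strip()
            if not entry:
                continue
            if not Path(entry).is_file():
                raise FileNotFoundError(
                    f"{path}:{lineno}: no such file: {entry!r}"
                )
            paths.append(entry)
    return paths
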