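"""Synthetic genome pairs with known divergence, and alignment oracles.

Every stage of the pipeline is testable without downloads: genomes are
i.i.d. uniform A/C/G/T sequences; a mutated copy at per-base
substitution rate ``d`` has expected ANI of exactly ``100 * (1 - d)``
under the no-indel model, so the realized substitution fraction is an
analytic ground truth.  Draft-assembly artifacts (contig fragmentation,
incompleteness, foreign contamination) are applied on top.  The
alignment oracle computes true global-alignment identity by dynamic
programming, independent of the sketching engine.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np

from ._kmers import decode, encode
from .genome_io import Genome, write_fasta

__all__ = [
    "MutationModel",
    "DraftModel",
    "random_genome",
    "mutate_genome",
    "make_draft",
    "alignment_identity_oracle",
    "write_fixture_pair",
]


@dataclass(frozen=True)
class MutationModel:
    """Point-mutation process: substitution rate ``d``, optional short indels.

    ``indel_rate`` is the per-base probability of opening an indel of
    1-10 bp (insertion or deletion with equal probability).  Identical
    (input, model) pairs always produce identical output.
    """

    d: float
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.d < 1.0:
            raise ValueError(f"substitution rate must be in [0, 1), got {self.d}")
        if not 0.0 <= self.indel_rate <= 0.01:
            raise ValueError(
                f"indel rate must be in [0, 0.01], got {self.indel_rate}"
            )


@dataclass(frozen=True)
class DraftModel:
    """Draft-assembly artifacts: fragmentation, incompleteness, contamination."""

    n_contigs: int = 1
    completeness: float = 1.0
    contamination_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError(
                f"completeness must be in (0, 1], got {self.completeness}"
            )
        if self.contamination_fraction < 0.0:
            raise ValueError("contamination_fraction must be >= 0")


def random_genome(length: int, seed: int, genome_id: str | None = None) -> Genome:
    """A single-contig genome of i.i.d. uniform A/C/G/T bases."""
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, length, dtype=np.int64).astype(np.uint8)
    gid = genome_id or f"random_{length}_{seed}"
    return Genome(id=gid, contigs=[("c1", decode(codes))])


def mutate_genome(genome: Genome, model: MutationModel) -> tuple[Genome, float]:
    """Mutated copy of a genome plus its realized substitution fraction.

    Substitution sites are Bernoulli(``d``) per base, each replaced
    uniformly by one of the three alternative bases, so every flagged
    site truly differs.  Indels (if enabled) do not count toward the
    realized divergence, which is the substituted fraction of the
    original length — the analytic ground truth for expected ANI,
    ``100 * (1 - realized)``.
    """
    rng = np.random.default_rng(model.seed)
    contigs: list[tuple[str, str]] = []
    substituted = 0
    total = 0
    for cid, seq in genome.contigs:
        codes = encode(seq)
        n = codes.shape[0]
        total += n
        out = codes.copy()
        sites = rng.random(n) < model.d
        valid = sites & (codes < 4)  # never substitute into/out of N
        k = int(valid.sum())
        substituted += k
        out[valid] = (out[valid] + rng.integers(1, 4, k).astype(np.uint8)) % 4
        if model.indel_rate > 0.0:
            out = _apply_indels(out, model.indel_rate, rng)
        contigs.append((cid, decode(out)))
    mutated = Genome(id=f"{genome.id}_mut", contigs=contigs)
    realized = substituted / total if total else 0.0
    return mutated, realized


def _apply_indels(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    sites = np.flatnonzero(rng.random(codes.shape[0]) < rate)
    if sites.size == 0:
        return codes
    pieces: list[np.ndarray] = []
    prev = 0
    for pos in sites.tolist():
        if pos < prev:
            continue  # swallowed by a previous deletion
        length = int(rng.integers(1, 11))
        if rng.random() < 0.5:  # deletion
            pieces.append(codes[prev:pos])
            prev = pos + length
        else:  # insertion of random bases
            pieces.append(codes[prev:pos])
            pieces.append(rng.integers(0, 4, length, dtype=np.int64).astype(np.uint8))
            prev = pos
    pieces.append(codes[prev:])
    return np.concatenate(pieces)


def make_draft(
    genome: Genome, model: DraftModel, min_useful_contig: int = 3000
) -> Genome:
    """Degrade a genome into a draft-like assembly.

    The concatenated sequence is split at random positions into
    ``n_contigs`` pieces; a random subset of pieces totalling
    approximately ``completeness`` of the genome is retained (original
    order); contamination contigs drawn from an independent random
    genome are appended.  Warns when no retained contig reaches
    ``min_useful_contig`` bp, since such a draft cannot produce any
    mappable fragment.
    """
    rng = np.random.default_rng(model.seed)
    seq = "".join(s for _, s in genome.contigs)
    total = len(seq)
    if model.n_contigs > 1:
        cuts = np.sort(
            rng.choice(np.arange(1, total), size=model.n_contigs - 1, replace=False)
        )
        bounds = [0, *cuts.tolist(), total]
    else:
        bounds = [0, total]
    pieces = [
        (bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
    ]
    target = model.completeness * total
    order = rng.permutation(len(pieces))
    kept_idx: list[int] = []
    acc = 0
    for idx in order.tolist():
        if acc >= target:
            break
        size = pieces[idx][1] - pieces[idx][0]
        # take the piece only if it moves the total closer to the target
        if abs(acc + size - target) <= abs(acc - target) or not kept_idx:
            kept_idx.append(idx)
            acc += size
    kept_idx.sort()
    contigs = [
        (f"contig_{i}", seq[pieces[i][0] : pieces[i][1]]) for i in kept_idx
    ]
    if model.contamination_fraction > 0.0:
        foreign_len = max(1, int(round(model.contamination_fraction * total)))
        foreign = random_genome(
            foreign_len, seed=int(rng.integers(0, 2**31)), genome_id="foreign"
        )
        contigs.append(("contamination_0", foreign.contigs[0][1]))
    if not any(len(s) >= min_useful_contig for _, s in contigs):
        warnings.warn(
            f"draft of {genome.id!r}: no retained contig reaches "
            f"{min_useful_contig} bp; no fragment will be mappable",
            stacklevel=2,
        )
    return Genome(id=f"{genome.id}_draft", contigs=contigs)


def alignment_identity_oracle(seq_a: str, seq_b: str) -> float:
    """True global-alignment identity (percent) of two sequences.

    Needleman-Wunsch with unit mismatch and gap costs (edit-distance
    optimal); identity is matches over alignment columns.  Quadratic —
    intended for fragment-scale validation, capped at 10 kbp.
    """
    if len(seq_a) > 10_000 or len(seq_b) > 10_000:
        raise ValueError("oracle is quadratic; sequences must be <= 10 kbp")
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(seq_a.upper(), seq_b.upper(), mode="NW", task="path")
    matches = 0
    columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return 100.0 * matches / columns


def write_fixture_pair(
    outdir: str | Path,
    name: str,
    genome_a: Genome,
    genome_b: Genome,
    metadata: dict,
) -> tuple[Path, Path, Path]:
    """Write a FASTA genome pair plus a JSON sidecar of its provenance.

    The sidecar records whatever the caller knows (seeds, substitution
    rate, realized divergence, completeness) so a test corpus can be
    regenerated and audited.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path_a = outdir / f"{name}_A.fasta"
    path_b = outdir / f"{name}_B.fasta"
    path_meta = outdir / f"{name}.json"
    write_fasta(genome_a, path_a)
    write_fasta(genome_b, path_b)
    with open(path_meta, "wt") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path_a, path_b, path_meta
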