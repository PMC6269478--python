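"""Alignment-free fragment mapping via winnowed minimizers and MinHash.

The engine follows the two-stage mapping scheme of minimizer-based
mappers: the reference is indexed by its winnowed minimizers once; for a
query fragment, stage 1 sweeps the reference positions that share
minimizers with the fragment and keeps windows sharing at least ``m``
of them, where ``m`` is the count expected at the identity cutoff; stage
2 estimates the k-mer Jaccard similarity of the fragment against each
candidate window with a bottom-s MinHash sketch and converts it to a
nucleotide identity through the Poisson mutation model

    I/100 = 1 + (1/k) * ln( 2J / (1+J) )

which relates alignment identity ``I`` to Jaccard similarity ``J`` for
k-mer size ``k``.  Mappings on either strand are found because k-mers
are canonicalized before hashing.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from ._kmers import (
    DEFAULT_HASH_SEED,
    canonical_hashes,
    encode,
    minimizer_arrays,
    valid_hash_set,
)
from .genome_io import Fragment, Genome

__all__ = [
    "SketchParams",
    "MinimizerIndex",
    "FragmentMapping",
    "jaccard_to_identity",
    "identity_to_jaccard",
    "minimizers",
    "build_index",
    "map_fragment",
    "minhash_jaccard",
    "exact_jaccard",
]


def jaccard_to_identity(jaccard: float, k: int) -> float:
    """Convert a Jaccard similarity to percent nucleotide identity.

    Inverts the Poisson-model relation between per-base substitution
    rate and k-mer survival; strictly increasing in ``jaccard``.
    ``jaccard`` must be in (0, 1]; 0 would map to minus infinity.
    """
    if not 0.0 < jaccard <= 1.0:
        raise ValueError(f"Jaccard must be in (0, 1], got {jaccard}")
    return 100.0 * (1.0 + math.log(2.0 * jaccard / (1.0 + jaccard)) / k)


def identity_to_jaccard(identity: float, k: int) -> float:
    """Expected Jaccard similarity at a given percent identity.

    Algebraic inverse of :func:`jaccard_to_identity`:
    ``J = d / (2 - d)`` with ``d = exp(k * (I/100 - 1))``.
    """
    if not 0.0 < identity <= 100.0:
        raise ValueError(f"identity must be in (0, 100], got {identity}")
    d = math.exp(k * (identity / 100.0 - 1.0))
    return d / (2.0 - d)


@dataclass(frozen=True)
class SketchParams:
    """Sketching and mapping parameters.

    Parameters
    ----------
    k : int
        K-mer size.  16 keeps random collisions negligible for
        megabase-scale genomes while remaining sensitive at 80%
        identity.
    w : int
        Winnowing window in k-mer positions; minimizer density on
        random sequence is 2/(w+1), so 24 samples roughly 8% of k-mers.
    min_identity : float
        Identity cutoff I0 in percent; mappings estimated below it are
        dropped.  The stage-1 shared-minimizer threshold derives from
        the equivalent Jaccard cutoff.
    hash_seed : int
        Fixed seed of the 64-bit k-mer hash; results are reproducible
        across runs and platforms.
    """

    k: int = 16
    w: int = 24
    min_identity: float = 80.0
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 31:
            raise ValueError(f"k must be in [1, 31], got {self.k}")
        if self.w < 1:
            raise ValueError(f"w must be >= 1, got {self.w}")
        if not 0.0 < self.min_identity <= 100.0:
            raise ValueError(
                f"min_identity must be in (0, 100], got {self.min_identity}"
            )

    @property
    def min_jaccard(self) -> float:
        """Jaccard cutoff equivalent to ``min_identity`` (J0)."""
        return identity_to_jaccard(self.min_identity, self.k)

    def sketch_size(self, l: int) -> int:
        """Expected minimizer count of an ``l`` bp window: 2(l-k+1)/(w+1)."""
        return max(1, round(2.0 * (l - self.k + 1) / (self.w + 1)))


def minimizers(sequence: str, params: SketchParams) -> list[tuple[int, int]]:
    """Winnowed minimizers of a sequence as ``(hash, position)`` pairs.

    Positions are 0-based k-mer starts; k-mers containing N are skipped;
    a sequence shorter than ``k + w - 1`` yields an empty list.
    """
    hashes, positions = minimizer_arrays(
        encode(sequence.upper()), params.k, params.w, params.hash_seed
    )
    return list(zip(hashes.tolist(), positions.tolist()))


@dataclass(frozen=True)
class FragmentMapping:
    """One mapping of a query fragment: the triplet (fragment, identity, position)."""

    fragment_id: int
    identity: float  # percent, >= params.min_identity
    ref_contig: str
    position: int  # 0-based window start on the reference contig
    jaccard: float  # diagnostic: the estimated Jaccard behind `identity`


class MinimizerIndex:
    """Winnowed-minimizer index of a reference genome.

    Built once per reference and reused across any number of query
    fragments.  Stores, per minimizer hash, the sorted list of
    (contig, position) occurrences, plus the encoded contig sequences
    needed to sketch candidate windows during mapping.
    """

    def __init__(self, reference: Genome, params: SketchParams) -> None:
        self.genome_id = reference.id
        self.params = params
        self.contig_ids = [cid for cid, _ in reference.contigs]
        self._codes = [encode(seq) for _, seq in reference.contigs]
        self.contig_lengths = [c.shape[0] for c in self._codes]

        hash_parts, ci_parts, pos_parts = [], [], []
        for ci, codes in enumerate(self._codes):
            h, p = minimizer_arrays(codes, params.k, params.w, params.hash_seed)
            hash_parts.append(h)
            ci_parts.append(np.full(h.shape[0], ci, dtype=np.int32))
            pos_parts.append(p)
        hashes = np.concatenate(hash_parts) if hash_parts else np.empty(0, np.uint64)
        cis = np.concatenate(ci_parts) if ci_parts else np.empty(0, np.int32)
        positions = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        # sort by (hash, contig, position) so occurrence lists are runs
        order = np.lexsort((positions, cis, hashes))
        self._hashes = hashes[order]
        self._cis = cis[order]
        self._positions = positions[order]

    def __len__(self) -> int:
        return self._hashes.shape[0]

    def occurrences(self, hash_value: int) -> list[tuple[int, int]]:
        """Sorted (contig index, position) occurrences of one minimizer hash."""
        lo = bisect_left(self._hashes, np.uint64(hash_value))
        hi = bisect_right(self._hashes, np.uint64(hash_value), lo=lo)
        return list(zip(self._cis[lo:hi].tolist(), self._positions[lo:hi].tolist()))

    def _lookup_many(
        self, hashes: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Occurrences of several hashes: (contig idx, position, hash) arrays."""
        lo = np.searchsorted(self._hashes, hashes, side="left")
        hi = np.searchsorted(self._hashes, hashes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            e = np.empty(0, np.int64)
            return e, e, e.astype(np.uint64)
        idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
        return (
            self._cis[idx].astype(np.int64),
            self._positions[idx],
            self._hashes[idx],
        )

    def window_codes(self, contig_index: int, start: int, length: int) -> np.ndarray:
        codes = self._codes[contig_index]
        return codes[start : start + length]


def build_index(reference: Genome, params: SketchParams) -> MinimizerIndex:
    """Index all reference minimizers; see :class:`MinimizerIndex`."""
    return MinimizerIndex(reference, params)


def _bottom_s_jaccard(set_a: np.ndarray, set_b: np.ndarray, s: int) -> float:
    """Bottom-s MinHash estimate of J(A, B) from sorted unique hash arrays.

    The s smallest hashes of the union form the sample; the estimate is
    the fraction of the sample present in both sets.  Unbiased for
    uniformly hashed sets.
    """
    if set_a.size == 0 or set_b.size == 0:
        return 0.0
    union = np.union1d(set_a, set_b)
    sample = union[: min(s, union.size)]
    shared = np.isin(sample, set_a, assume_unique=True) & np.isin(
        sample, set_b, assume_unique=True
    )
    return float(shared.sum()) / sample.size


def minhash_jaccard(
    seq_a: str, seq_b: str, params: SketchParams, s: int | None = None
) -> float:
    """Bottom-s MinHash Jaccard estimate between two sequences.

    This is the stage-2 estimator used by :func:`map_fragment`, exposed
    for validation against :func:`exact_jaccard`.  ``s`` defaults to the
    sketch size for the longer sequence.
    """
    if s is None:
        s = params.sketch_size(max(len(seq_a), len(seq_b)))
    ua = valid_hash_set(encode(seq_a.upper()), params.k, params.hash_seed)
    ub = valid_hash_set(encode(seq_b.upper()), params.k, params.hash_seed)
    return _bottom_s_jaccard(ua, ub, s)


def exact_jaccard(seq_a: str, seq_b: str, k: int) -> float:
    """Exact Jaccard similarity of the canonical k-mer sets of two sequences.

    Brute-force set construction; the validation oracle for the MinHash
    estimator.  K-mers containing N are excluded.
    """
    sa = valid_hash_set(encode(seq_a.upper()), k)
    sb = valid_hash_set(encode(seq_b.upper()), k)
    if sa.size == 0 and sb.size == 0:
        return 0.0
    inter = np.intersect1d(sa, sb, assume_unique=True).size
    union = sa.size + sb.size - inter
    return inter / union if union else 0.0


def map_fragment(
    fragment: Fragment, index: MinimizerIndex, params: SketchParams
) -> list[FragmentMapping]:
    """All mappings of a query fragment above the identity cutoff.

    Stage 1 collects the reference occurrences of the fragment's
    minimizers, clusters them along each contig (gap > fragment length
    starts a new cluster) and keeps clusters whose best l-sized window
    shares at least ``m = ceil(s * J0)`` distinct minimizers.  Stage 2
    anchors candidate window starts from the first shared minimizer of
    the best window (both strands considered), sketches each candidate
    reference window, and emits one mapping per cluster at the
    highest-Jaccard window if its identity reaches the cutoff.
    Deterministic: ties resolve to the smallest (contig, position).
    """
    l = len(fragment)
    frag_codes = encode(fragment.sequence)
    fh, fp = minimizer_arrays(frag_codes, params.k, params.w, params.hash_seed)
    if fh.size == 0:
        return []
    frag_set = valid_hash_set(frag_codes, params.k, params.hash_seed)
    s = params.sketch_size(l)
    m = max(1, math.ceil(s * params.min_jaccard - 1e-12))

    uniq = np.unique(fh)
    hit_ci, hit_pos, hit_hash = index._lookup_many(uniq)
    if hit_ci.size == 0:
        return []
    order = np.lexsort((hit_pos, hit_ci))
    hit_ci, hit_pos, hit_hash = hit_ci[order], hit_pos[order], hit_hash[order]

    mappings: list[FragmentMapping] = []
    n = hit_ci.size
    start = 0
    while start < n:
        ci = hit_ci[start]
        end = start
        while end < n and hit_ci[end] == ci:
            end += 1
        pos = hit_pos[start:end]
        hsh = hit_hash[start:end]
        # split the contig's hits into clusters separated by gaps > l
        breaks = np.flatnonzero(np.diff(pos) > l) + 1
        for c_lo, c_hi in zip(
            np.concatenate(([0], breaks)), np.concatenate((breaks, [pos.size]))
        ):
            mapping = _map_cluster(
                fragment, frag_set, fh, fp, pos[c_lo:c_hi], hsh[c_lo:c_hi],
                index, int(ci), l, s, m, params,
            )
            if mapping is not None:
                mappings.append(mapping)
        start = end
    return mappings


def _map_cluster(
    fragment: Fragment,
    frag_set: np.ndarray,
    frag_min_hashes: np.ndarray,
    frag_min_pos: np.ndarray,
    pos: np.ndarray,
    hsh: np.ndarray,
    index: MinimizerIndex,
    ci: int,
    l: int,
    s: int,
    m: int,
    params: SketchParams,
) -> FragmentMapping | None:
    """Stage 1+2 for one cluster of minimizer hits on one contig."""
    # stage 1: leftmost l-window maximizing the distinct shared-minimizer count
    counts: dict[int, int] = {}
    distinct = 0
    best_count = -1
    best_i = 0
    j = 0
    for i in range(pos.size):
        while j < pos.size and pos[j] < pos[i] + l:
            h = int(hsh[j])
            counts[h] = counts.get(h, 0) + 1
            if counts[h] == 1:
                distinct += 1
            j += 1
        if distinct > best_count:
            best_count = distinct
            best_i = i
        h = int(hsh[i])
        counts[h] -= 1
        if counts[h] == 0:
            distinct -= 1
    if best_count < m:
        return None

    # stage 2: candidate window starts anchored on the first hit of the
    # best window, projected through every fragment occurrence of its
    # hash on both strands
    clen = index.contig_lengths[ci]
    anchor_hash = hsh[best_i]
    r0 = int(pos[best_i])
    frag_offsets = frag_min_pos[frag_min_hashes == anchor_hash]
    hi_start = max(0, clen - l)
    candidates = set()
    for off in frag_offsets.tolist():
        for delta in (off, l - params.k - off):
            candidates.add(min(max(r0 - delta, 0), hi_start))

    best: tuple[float, int] | None = None  # (jaccard, start)
    for cand in sorted(candidates):
        win = index.window_codes(ci, cand, l)
        win_set = valid_hash_set(win, params.k, params.hash_seed)
        jac = _bottom_s_jaccard(frag_set, win_set, s)
        if best is None or jac > best[0]:
            best = (jac, cand)
    assert best is not None
    jac, p = best
    if jac <= 0.0:
        return None
    identity = jaccard_to_identity(jac, params.k)
    if identity < params.min_identity:
        return None
    return FragmentMapping(
        fragment_id=fragment.fragment_id,
        identity=identity,
        ref_contig=index.contig_ids[ci],
        position=p,
        jaccard=jac,
    )


def write_mappings_tsv(mappings: list[FragmentMapping], path) -> None:
    """Debug dump: fragment_id, contig, position, jaccard, identity."""
    with open(path, "wt") as fh:
        for mp in mappings:
            fh.write(
                f"{mp.fragment_id}\t{mp.ref_contig}\t{mp.position}\t"
                f"{mp.jaccard:.6f}\t{mp.identity:.4f}\n"
            )
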