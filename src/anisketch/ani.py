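"""ANI computation from fragment mappings.

Whole-genome Average Nucleotide Identity (ANI) is the mean identity of
the orthologous regions shared by two genomes.  The query genome is cut
into fixed-size fragments; every fragment is mapped against the
reference; the best mapping per fragment (``M_forward``) is then reduced
to the best mapping per reference bin (``M_reciprocal``), which discards
extra hits of duplicated (paralogous) regions, emulating a reciprocal
best-hit search without a reverse pass.  ANI is the unweighted mean of
the reciprocal mapping identities, reported only when at least ``tau``
fragments survive — with the defaults (l = 3000 bp, tau = 50) this
demands 150 kbp of shared sequence before a value is trusted.
"""

from __future__ import annotations

import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_io import Fragment, Genome, fragment_genome
from .sketch import (
    FragmentMapping,
    MinimizerIndex,
    SketchParams,
    build_index,
    map_fragment,
)

__all__ = [
    "ANIParams",
    "ANIResult",
    "OrthologousMapping",
    "OrthologousMappingTable",
    "forward_best",
    "bin_of",
    "reciprocal_filter",
    "compute_ani",
    "ani_many_to_many",
    "demarcation_metrics",
    "write_results_tsv",
    "write_phylip_matrix",
]


@dataclass(frozen=True)
class ANIParams:
    """Fragment length l, reliability threshold tau, sketching parameters."""

    l: int = 3000
    tau: int = 50
    sketch: SketchParams = field(default_factory=SketchParams)

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError(f"fragment length must be positive, got {self.l}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.l < self.sketch.k:
            raise ValueError("fragment length must be >= k-mer size")

    @property
    def min_homology(self) -> int:
        """Minimum shared sequence implied by the reliability gate: l * tau bp."""
        return self.l * self.tau


@dataclass(frozen=True)
class ANIResult:
    """One ordered query-reference comparison."""

    query_id: str
    reference_id: str
    ani: float | None  # percent; None when not reported
    n_reciprocal: int
    n_fragments: int
    reported: bool


@dataclass(frozen=True)
class OrthologousMapping:
    """One reciprocal mapping with both-side coordinates (0-based half-open)."""

    fragment_id: int
    query_contig: str
    query_start: int
    query_end: int
    ref_contig: str
    ref_start: int
    ref_end: int
    identity: float


@dataclass
class OrthologousMappingTable:
    """The reciprocal mapping set of one comparison, for visualization."""

    query_id: str
    reference_id: str
    rows: list[OrthologousMapping]

    def write_tsv(self, path) -> None:
        """Export with 1-based inclusive coordinates (plotting convention)."""
        with open(path, "wt") as fh:
            fh.write(
                "fragment_id\tquery_contig\tquery_start\tquery_end\t"
                "ref_contig\tref_start\tref_end\tidentity\n"
            )
            for r in self.rows:
                fh.write(
                    f"{r.fragment_id}\t{r.query_contig}\t{r.query_start + 1}\t"
                    f"{r.query_end}\t{r.ref_contig}\t{r.ref_start + 1}\t"
                    f"{r.ref_end}\t{r.identity:.4f}\n"
                )


def forward_best(mappings: Iterable[FragmentMapping]) -> list[FragmentMapping]:
    """Best mapping per query fragment (``M_forward``).

    Keeps, for every fragment id present, the maximum-identity mapping;
    ties resolve to the smallest (contig, position).  Output sorted by
    fragment id.
    """
    best: dict[int, FragmentMapping] = {}
    for m in mappings:
        cur = best.get(m.fragment_id)
        if (
            cur is None
            or m.identity > cur.identity
            or (
                m.identity == cur.identity
                and (m.ref_contig, m.position) < (cur.ref_contig, cur.position)
            )
        ):
            best[m.fragment_id] = m
    return [best[f] for f in sorted(best)]


def bin_of(mapping: FragmentMapping, l: int) -> tuple[str, int]:
    """Reference bin of a mapping: (contig, floor(position / l)).

    Fragments mapped to the same or nearby reference positions share a
    bin; adjacent positions straddling a multiple of l may split, which
    is accepted.
    """
    if l <= 0:
        raise ValueError(f"fragment length must be positive, got {l}")
    return (mapping.ref_contig, mapping.position // l)


def reciprocal_filter(
    forward: Iterable[FragmentMapping], l: int
) -> list[FragmentMapping]:
    """Best mapping per reference bin (``M_reciprocal``).

    Input must hold one mapping per fragment (the output of
    :func:`forward_best`).  Per occupied bin the maximum-identity
    mapping survives; ties resolve to the smallest fragment id.  This
    discards the surplus hits that duplicated reference regions attract,
    restricting the mean to orthologous pairs.  Output sorted by
    fragment id.
    """
    best: dict[tuple[str, int], FragmentMapping] = {}
    for m in forward:
        key = bin_of(m, l)
        cur = best.get(key)
        if (
            cur is None
            or m.identity > cur.identity
            or (m.identity == cur.identity and m.fragment_id < cur.fragment_id)
        ):
            best[key] = m
    return sorted(best.values(), key=lambda m: m.fragment_id)


def compute_ani(
    query: Genome,
    reference: Genome,
    params: ANIParams | None = None,
    index: MinimizerIndex | None = None,
) -> tuple[ANIResult, OrthologousMappingTable]:
    """ANI of an ordered (query, reference) genome pair.

    Fragments the query, maps every fragment against the reference
    minimizer index (built here unless a prebuilt one is passed),
    applies the forward and reciprocal filters, and averages the
    surviving identities.  The result is flagged unreported when fewer
    than ``tau`` reciprocal mappings exist; the ANI value is then None
    but counts are still returned.
    """
    params = params or ANIParams()
    fragments = fragment_genome(query, params.l)
    table = OrthologousMappingTable(query.id, reference.id, [])
    if not fragments:
        return (
            ANIResult(query.id, reference.id, None, 0, 0, False),
            table,
        )
    if index is None:
        index = build_index(reference, params.sketch)
    all_mappings: list[FragmentMapping] = []
    for frag in fragments:
        all_mappings.extend(map_fragment(frag, index, params.sketch))
    reciprocal = reciprocal_filter(forward_best(all_mappings), params.l)

    reported = len(reciprocal) >= params.tau
    ani = (
        sum(m.identity for m in reciprocal) / len(reciprocal)
        if reported
        else None
    )
    by_id = {f.fragment_id: f for f in fragments}
    ref_len = dict(zip(index.contig_ids, index.contig_lengths))
    for m in reciprocal:
        frag = by_id[m.fragment_id]
        table.rows.append(
            OrthologousMapping(
                fragment_id=m.fragment_id,
                query_contig=frag.source_contig,
                query_start=frag.start,
                query_end=frag.start + len(frag),
                ref_contig=m.ref_contig,
                ref_start=m.position,
                ref_end=min(m.position + params.l, ref_len[m.ref_contig]),
                identity=m.identity,
            )
        )
    result = ANIResult(
        query_id=query.id,
        reference_id=reference.id,
        ani=ani,
        n_reciprocal=len(reciprocal),
        n_fragments=len(fragments),
        reported=reported,
    )
    return result, table


def _many_to_many_serial(
    queries: Sequence[Genome], references: Sequence[Genome], params: ANIParams
) -> list[list[ANIResult]]:
    """Result grid indexed [query][reference]; each reference indexed once."""
    grid: list[list[ANIResult | None]] = [
        [None] * len(references) for _ in queries
    ]
    for ri, ref in enumerate(references):
        index = build_index(ref, params.sketch)
        for qi, query in enumerate(queries):
            grid[qi][ri], _ = compute_ani(query, ref, params, index=index)
    return [list(row) for row in grid]  # type: ignore[arg-type]


def _worker(args) -> list[list[ANIResult]]:
    queries, ref_chunk, params = args
    return _many_to_many_serial(queries, ref_chunk, params)


def ani_many_to_many(
    queries: Sequence[Genome],
    references: Sequence[Genome],
    params: ANIParams | None = None,
    processes: int = 1,
) -> list[ANIResult]:
    """All ordered (query, reference) comparisons.

    Returns one result per pair in query-major order (query order x
    reference order).  Each reference is indexed once and reused for
    every query.  With ``processes > 1`` the references are partitioned
    across worker processes; the merged output is identical to the
    serial one.
    """
    if not queries or not references:
        raise ValueError("query and reference lists must be non-empty")
    params = params or ANIParams()
    if processes <= 1 or len(references) == 1:
        grid = _many_to_many_serial(queries, references, params)
    else:
        nproc = min(processes, len(references))
        chunks = [list(references[i::nproc]) for i in range(nproc)]
        with ProcessPoolExecutor(max_workers=nproc) as pool:
            parts = list(
                pool.map(_worker, [(list(queries), c, params) for c in chunks])
            )
        # stitch strided chunks back into reference order
        grid = [[None] * len(references) for _ in queries]  # type: ignore[misc]
        for ci, part in enumerate(parts):
            for qi in range(len(queries)):
                for rj, res in enumerate(part[qi]):
                    grid[qi][ci + rj * nproc] = res
    return [res for row in grid for res in row]


def demarcation_metrics(
    labeled_results: Sequence[tuple[ANIResult, bool]],
    threshold: float = 95.0,
) -> tuple[float, float]:
    """Precision and recall of the ANI species threshold on labeled pairs.

    A reported ANI at or above ``threshold`` predicts "same species";
    the labels give the truth.  Unreported results are ignored.  The
    conventional prokaryotic species boundary is 95% ANI.

    Returns ``(precision, recall)`` = (TP/(TP+FP), TP/(TP+FN)); a
    denominator of zero yields NaN for that metric.
    """
    considered = [(r, lab) for r, lab in labeled_results if r.reported]
    if not considered:
        raise ValueError("no reported labeled results: metrics undefined")
    tp = fp = fn = 0
    for result, same_species in considered:
        predicted = result.ani is not None and result.ani >= threshold
        if predicted and same_species:
            tp += 1
        elif predicted and not same_species:
            fp += 1
        elif not predicted and same_species:
            fn += 1
    precision = tp / (tp + fp) if (tp + fp) else math.nan
    recall = tp / (tp + fn) if (tp + fn) else math.nan
    return precision, recall


def format_ani(ani: float | None) -> str:
    return f"{ani:.4f}" if ani is not None else "NA"


def write_results_tsv(results: Iterable[ANIResult], path) -> None:
    """Tab-separated report: query, reference, ANI, reciprocal count, fragments.

    Unreported pairs appear with ANI = NA so every requested comparison
    is accounted for.
    """
    with open(path, "wt") as fh:
        for r in results:
            fh.write(
                f"{r.query_id}\t{r.reference_id}\t{format_ani(r.ani)}\t"
                f"{r.n_reciprocal}\t{r.n_fragments}\n"
            )


def write_phylip_matrix(
    results: Sequence[ANIResult], path, labels: Sequence[str] | None = None
) -> None:
    """Lower-triangular PHYLIP-style ANI matrix.

    Requires results of a square all-vs-all run (same genomes as queries
    and references).  Cell (i, j), i > j, holds ANI(genome_i as query,
    genome_j as reference); unreported cells print NA.
    """
    lookup = {(r.query_id, r.reference_id): r.ani for r in results}
    if labels is None:
        labels = list(dict.fromkeys(r.query_id for r in results))
    for a in labels:
        for b in labels:
            if (a, b) not in lookup:
                raise ValueError(
                    "matrix output needs every ordered pair; "
                    f"missing ({a!r}, {b!r})"
                )
    with open(path, "wt") as fh:
        fh.write(f"{len(labels)}\n")
        for i, a in enumerate(labels):
            cells = [format_ani(lookup[(a, labels[j])]) for j in range(i)]
            fh.write("\t".join([a] + cells).rstrip() + "\n")
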