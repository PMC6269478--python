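# Methods

## Model

`anisketch` estimates average nucleotide identity without alignment by
relating the k-mer Jaccard similarity *J* of two sequences to their
alignment identity *I* under a Poisson model of independent per-base
substitutions:

    I/100 = 1 + (1/k) · ln( 2J / (1+J) )

and its algebraic inverse J = c/(2−c) with c = exp(k·(I/100 − 1)). The
two functions are exact inverses (the test suite checks 1e-9 over a
(J, k) grid). The model assumes substitutions are independent and
uniform; under that assumption a fragment pair at per-base divergence d
has expected identity 100·(1−d), which is what the synthetic benchmarks
recover. For k = 16 the model's small-d error is the gap between
(1−d)^k and e^(−kd); at d = 0.10 this biases identity by about −0.5
points, which dominates the residual error of the pipeline at high
divergence and stays inside the ±1 point recovery target.

## Mapping engine

The reference genome is indexed once by winnowed minimizers: every
k-mer is canonicalized (lexicographic minimum of the k-mer and its
reverse complement, so mapping is strand-independent), packed into 2
bits per base, and scrambled with a splitmix64 finalizer under a fixed
seed (42); from each window of w consecutive k-mers the leftmost
minimum-hash k-mer is kept. K-mers overlapping an N are never sampled.
Expected sampling density on random sequence is 2/(w+1).

Mapping a query fragment is two-staged:

- **Stage 1 (candidates).** The reference occurrences of the fragment's
  minimizers are collected and clustered along each contig (a gap larger
  than the fragment length l starts a new cluster). Within a cluster, a
  sweep finds the leftmost l-sized window sharing the most distinct
  minimizers with the fragment; clusters sharing fewer than
  m = ⌈s·J₀⌉ minimizers are discarded, where s = 2(l−k+1)/(w+1) is the
  expected minimizer count of an l-window and J₀ is the Jaccard
  equivalent of the identity cutoff I₀.
- **Stage 2 (scoring).** Candidate window starts are anchored on the
  first shared minimizer of the best window, projected through every
  fragment occurrence of its hash on both strands and clamped to the
  contig. Each candidate window is scored by a bottom-s MinHash
  estimate of the k-mer Jaccard: the s smallest distinct hashes of the
  union of the two windows' full canonical k-mer hash sets form the
  sample, and J is the sampled fraction present in both sets. The
  best-scoring window (ties to the smallest start) becomes the
  mapping; mappings converting to identity below I₀ are dropped.

Scoring windows with *full* k-mer hash sets rather than with the two
minimizer sets is a deliberate design choice. Minimizer *selection*
decorrelates under mutation — a shared k-mer can be a minimizer in one
sequence but not the other once a nearby substitution introduces a
smaller hash — so Jaccard estimates over minimizer sets are
systematically low (measured −0.02 to −0.04 at 1–5% divergence, many
standard errors from zero). The bottom-s estimator over full k-mer sets
is the classical MinHash estimator and is unbiased within measurement
noise (|bias|/SE < 1 over 500 fragment pairs, MAE ≈ 0.018); winnowed
minimizers are retained where sparsity matters, in the reference index
and stage-1 candidate search. Because a candidate window is re-sketched
from the reference sequence itself, a fragment excised verbatim from
the reference scores J = 1 at its source window and self-ANI is exactly
100.0.

## ANI aggregation

Per ordered (query, reference) pair: the best mapping per fragment
(M_forward, ties to the smallest (contig, position)) is reduced to the
best mapping per reference bin (contig, ⌊p/l⌋) (M_reciprocal, ties to
the smallest fragment id). The bin key includes the contig so draft
references bin correctly. ANI is the unweighted arithmetic mean of the
reciprocal identities, reported only when |M_reciprocal| ≥ τ. Results
below the gate are still emitted as rows with ANI = NA so that
many-to-many matrices stay complete and auditable. Adjacent mappings
that straddle a multiple of l may fall into different bins; this is
accepted (binning is a proxy for reciprocal best hits, not an exact
partition) and only makes the paralog filter marginally more permissive.

Both directions of a pair are computed and reported separately; they are
not averaged. On clean substitution-only pairs the directions agree
essentially exactly, because fragment coordinates align and both
directions average identities of the same window pairs; indels and
rearrangements break that exact agreement, which is why the symmetry
check allows half a point.

## Parameters

| name | default | unit | rationale |
|------|---------|------|-----------|
| l | 3000 | bp | fragment length; long enough for a stable sketch, short enough that a fragment rarely spans a recombination breakpoint |
| τ | 50 | fragments | reliability gate; with l = 3000 requires 150 kbp of shared sequence |
| I₀ | 80 | % | identity cutoff; the Jaccard-identity model is calibrated for the 80–100% range |
| k | 16 | bases | random 16-mer collisions are negligible at megabase scale while 80%-identity windows still share k-mers |
| w | 24 | k-mer positions | ≈ 8% sampling density; balances index size against mapping sensitivity |
| hash seed | 42 | — | fixed so outputs are reproducible across platforms |
| min N50 | 10 000 | bp | assemblies below this contiguity give unreliable estimates and are skipped (boundary passes); the filter can be disabled |

## Synthetic data

The generator emulates exactly the features the method is sensitive to:
i.i.d. uniform-composition genomes, Bernoulli per-base substitutions
(uniform over the three alternatives, so the *realized* substitution
fraction — returned alongside the mutated genome — is an analytic ground
truth with expected ANI 100·(1−realized)), optional short indels
(1–10 bp), draft fragmentation into a target contig count, random
incompleteness, and contamination drawn from an independent random
genome (which cannot spuriously map: random 16-mer collisions are
negligible). It does not emulate GC skew, repeat families, horizontal
transfer, rearrangements or codon structure; passing tests therefore
demonstrate correctness of the estimator under its own model, not
robustness to every artifact of real assemblies. The alignment oracle
(global alignment with unit costs via dynamic programming, identity =
matches/columns) is independent of the sketching engine and bounds
inputs at 10 kbp because it is quadratic.

Contamination tolerances are exploratory: the reciprocal filter ignores
foreign contigs that attract no mappings, but no quantitative
contamination guarantee is claimed.

## Numerical and edge-case choices

- Coordinates are 0-based half-open internally; exports for plotting are
  1-based inclusive.
- All tie-breaks are total orders ((contig, position), then fragment
  id), so outputs are byte-identical across runs and across the
  serial/multiprocess paths (references are partitioned over workers and
  results re-merged in query-major order).
- A query shorter than l yields zero fragments and an unreported result;
  a reference contig shorter than l is scored over its truncated window.
- Genomes are uppercased on ingest and characters outside {A,C,G,T,N}
  become N; N-containing k-mers are excluded from sketching and from the
  exact-Jaccard oracle.
- ANI is printed with four decimals on the 0–100 scale.

## Problem sizes

Accuracy tests and the acceptance script use 1 Mbp genomes — large
enough that fragment sampling noise is well below the tolerances (333
fragments per genome), small enough for a laptop-class run: the full
test suite takes a few minutes and the acceptance script about a
minute on one CPU. Divergence recovery uses d ∈ {0.02, 0.05, 0.10}
(ten seeds per rate in the tests, five in the acceptance script), the
draft sweep uses 20 contigs at completeness 0.2–1.0, and estimator
calibration uses 200 fragment pairs at 0–15% divergence.

## Known limitations

- Identity estimates inherit the Poisson-model bias at high divergence
  (≈ −0.5 points at 90% identity); below ~80% identity mappings are cut
  off by design.
- Mapping positions are anchored on shared minimizers and can be off by
  a few tens of bases under heavy mutation; bins absorb this slack, but
  the exported coordinates are approximate, not alignments.
- Indel-rich or highly rearranged genomes reduce the number of
  reciprocal fragments rather than degrading individual identities; the
  τ gate turns severe cases into "not reported" rather than a wrong
  number.
- No repeat masking: a fragment consisting almost entirely of an exact
  repeat maps to every copy, and only the binning step arbitrates.
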