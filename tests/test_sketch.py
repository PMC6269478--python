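"""Jaccard-identity model, winnowed minimizers, and fragment mapping."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anisketch import (
    SketchParams,
    build_index,
    exact_jaccard,
    identity_to_jaccard,
    jaccard_to_identity,
    map_fragment,
    minhash_jaccard,
    minimizers,
    random_genome,
)
from anisketch.genome_io import Fragment, Genome

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq):
    return seq.translate(_COMP)[::-1]


def _random_seq(n, seed):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutate(seq, d, seed):
    rng = random.Random(seed)
    out = []
    for c in seq:
        if rng.random() < d:
            out.append(rng.choice([b for b in "ACGT" if b != c]))
        else:
            out.append(c)
    return "".join(out)


class TestIdentityModel:
    def test_full_jaccard_is_full_identity(self):
        for k in (11, 16, 21, 31):
            assert jaccard_to_identity(1.0, k) == 100.0
            assert identity_to_jaccard(100.0, k) == 1.0

    def test_printed_formula_value(self):
        # 100 * (1 + ln(2*0.0475/1.0475)/16) evaluated directly
        assert jaccard_to_identity(0.0475, 16) == pytest.approx(85.0, abs=0.05)

    @given(
        st.floats(0.01, 0.99),
        st.integers(4, 31),
    )
    @settings(max_examples=300, deadline=None)
    def test_mutual_inverses(self, j, k):
        assert identity_to_jaccard(jaccard_to_identity(j, k), k) == pytest.approx(
            j, abs=1e-9
        )

    def test_inverse_roundtrip_from_identity(self):
        j = identity_to_jaccard(80.0, 16)
        assert 0 < j < 1
        assert jaccard_to_identity(j, 16) == pytest.approx(80.0, abs=1e-9)

    def test_strictly_increasing_in_jaccard_and_k(self):
        grid = np.linspace(0.01, 1.0, 50)
        vals = [jaccard_to_identity(j, 16) for j in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert identity_to_jaccard(85.0, 16) > identity_to_jaccard(80.0, 16)
        # for fixed J < 1 the implied identity rises with k
        assert jaccard_to_identity(0.2, 21) > jaccard_to_identity(0.2, 16)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            jaccard_to_identity(0.0, 16)
        with pytest.raises(ValueError):
            jaccard_to_identity(1.5, 16)
        with pytest.raises(ValueError):
            identity_to_jaccard(0.0, 16)
        with pytest.raises(ValueError):
            identity_to_jaccard(101.0, 16)


class TestSketchParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            SketchParams(k=0)
        with pytest.raises(ValueError):
            SketchParams(k=32)
        with pytest.raises(ValueError):
            SketchParams(w=0)
        with pytest.raises(ValueError):
            SketchParams(min_identity=0.0)

    def test_derived_jaccard_cutoff(self):
        p = SketchParams()
        assert 0 < p.min_jaccard < 1
        # d = exp(k (I/100 - 1)); J0 = d / (2 - d)
        d = math.exp(16 * (0.8 - 1.0))
        assert p.min_jaccard == pytest.approx(d / (2 - d))

    def test_sketch_size_follows_winnow_density(self):
        p = SketchParams(k=16, w=24)
        assert p.sketch_size(3000) == round(2 * (3000 - 16 + 1) / 25)


class TestMinimizers:
    def test_window_of_one_keeps_every_kmer(self):
        seq = _random_seq(200, 0)
        p = SketchParams(k=16, w=1)
        mins = minimizers(seq, p)
        assert [pos for _, pos in mins] == list(range(len(seq) - 16 + 1))

    def test_density_close_to_two_over_w_plus_one(self):
        seq = _random_seq(100_000, 1)
        p = SketchParams()
        mins = minimizers(seq, p)
        n_kmers = len(seq) - p.k + 1
        expected = 2 / (p.w + 1)
        se = math.sqrt(expected * (1 - expected) / n_kmers)
        assert abs(len(mins) / n_kmers - expected) < 3 * se

    def test_reverse_complement_same_hash_multiset(self):
        seq = _random_seq(5000, 2)
        p = SketchParams()
        fwd = sorted(h for h, _ in minimizers(seq, p))
        rev = sorted(h for h, _ in minimizers(revcomp(seq), p))
        assert fwd == rev

    def test_ambiguous_kmers_skipped(self):
        seq = _random_seq(500, 3) + "N" + _random_seq(500, 4)
        p = SketchParams()
        for _, pos in minimizers(seq, p):
            assert "N" not in seq[pos : pos + p.k]

    def test_short_sequence_empty(self):
        assert minimizers("ACGT", SketchParams()) == []

    def test_deterministic(self):
        seq = _random_seq(3000, 5)
        p = SketchParams()
        assert minimizers(seq, p) == minimizers(seq, p)


def _py_exact_jaccard(a, b, k):
    """Independent oracle: canonical k-mer sets via plain string handling."""

    def canon_set(s):
        out = set()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if set(km) <= set("ACGT"):
                out.add(min(km, revcomp(km)))
        return out

    sa, sb = canon_set(a), canon_set(b)
    if not sa and not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


class TestExactJaccard:
    def test_identical(self):
        seq = _random_seq(300, 0)
        assert exact_jaccard(seq, seq, 16) == 1.0

    def test_disjoint(self):
        assert exact_jaccard("A" * 50, "C" * 50, 16) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_set_construction_oracle(self, seed):
        a = _random_seq(400, seed)
        b = _mutate(a, 0.08, seed + 100)
        assert exact_jaccard(a, b, 16) == pytest.approx(
            _py_exact_jaccard(a, b, 16), abs=1e-12
        )

    def test_strand_independent(self):
        a = _random_seq(300, 1)
        b = _mutate(a, 0.05, 2)
        assert exact_jaccard(a, revcomp(b), 16) == exact_jaccard(a, b, 16)


class TestIndex:
    def test_positions_within_bounds(self):
        g = random_genome(10_000, seed=3)
        p = SketchParams()
        idx = build_index(g, p)
        assert len(idx) > 0
        assert all(0 <= pos <= 10_000 - p.k for pos in idx._positions)

    def test_deterministic_rebuild(self):
        g = random_genome(20_000, seed=4)
        p = SketchParams()
        a, b = build_index(g, p), build_index(g, p)
        assert np.array_equal(a._hashes, b._hashes)
        assert np.array_equal(a._positions, b._positions)

    def test_occurrences_lookup(self):
        g = random_genome(20_000, seed=5)
        p = SketchParams()
        idx = build_index(g, p)
        h = int(idx._hashes[0])
        occ = idx.occurrences(h)
        assert occ and all(ci == 0 for ci, _ in occ)


@pytest.fixture(scope="module")
def ref_and_index():
    g = random_genome(200_000, seed=10, genome_id="ref")
    return g, build_index(g, SketchParams())


class TestMapFragment:
    def _excise(self, genome, start, l=3000):
        seq = genome.contigs[0][1][start : start + l]
        return Fragment(0, "c1", start, seq)

    def test_exact_copy_maps_at_source_with_full_identity(self, ref_and_index):
        g, idx = ref_and_index
        frag = self._excise(g, 51_000)
        maps = map_fragment(frag, idx, SketchParams())
        best = max(maps, key=lambda m: m.identity)
        assert best.identity == 100.0
        assert best.jaccard == 1.0
        assert best.position == 51_000

    def test_unrelated_fragment_finds_nothing(self, ref_and_index):
        _, idx = ref_and_index
        frag = Fragment(0, "x", 0, _random_seq(3000, 999))
        assert map_fragment(frag, idx, SketchParams()) == []

    def test_ten_percent_divergence_maps_near_ninety(self, ref_and_index):
        g, idx = ref_and_index
        p = SketchParams()
        start = 90_000
        original = g.contigs[0][1][start : start + 3000]
        mutated = _mutate(original, 0.10, seed=42)
        frag = Fragment(0, "q", 0, mutated)
        maps = map_fragment(frag, idx, p)
        assert maps
        best = max(maps, key=lambda m: m.identity)
        assert abs(best.position - start) <= 100
        assert best.identity == pytest.approx(90.0, abs=2.0)
        # the estimate must agree with the exact-Jaccard identity oracle
        oracle = jaccard_to_identity(exact_jaccard(mutated, original, p.k), p.k)
        assert best.identity == pytest.approx(oracle, abs=2.0)

    def test_strand_symmetry(self, ref_and_index):
        g, idx = ref_and_index
        p = SketchParams()
        frag = self._excise(g, 120_000)
        frag_rc = Fragment(0, "c1", 0, revcomp(frag.sequence))
        fwd = map_fragment(frag, idx, p)
        rev = map_fragment(frag_rc, idx, p)
        best_f = max(fwd, key=lambda m: m.identity)
        best_r = max(rev, key=lambda m: m.identity)
        assert (best_f.position, best_f.identity) == (
            best_r.position, best_r.identity,
        )

    def test_never_below_cutoff_and_in_bounds(self, ref_and_index):
        g, idx = ref_and_index
        p = SketchParams()
        clen = g.total_length
        for seed in range(8):
            start = 3000 * (seed + 1)
            mutated = _mutate(
                g.contigs[0][1][start : start + 3000], 0.12, seed
            )
            for m in map_fragment(Fragment(0, "q", 0, mutated), idx, p):
                assert m.identity >= p.min_identity
                assert 0 <= m.position <= clen
                assert 0.0 <= m.jaccard <= 1.0

    def test_byte_identical_determinism(self, ref_and_index):
        g, idx = ref_and_index
        p = SketchParams()
        frag = self._excise(g, 33_000)
        assert map_fragment(frag, idx, p) == map_fragment(frag, idx, p)


class TestMinHashEstimator:
    def test_tracks_exact_jaccard(self):
        p = SketchParams()
        rng = random.Random(0)
        errors = []
        for i in range(40):
            d = rng.uniform(0.0, 0.15)
            a = _random_seq(3000, 2 * i)
            b = _mutate(a, d, 2 * i + 1)
            errors.append(minhash_jaccard(a, b, p) - exact_jaccard(a, b, p.k))
        errors = np.array(errors)
        assert np.abs(errors).mean() <= 0.05

    def test_identical_sequences_estimate_one(self):
        seq = _random_seq(3000, 9)
        assert minhash_jaccard(seq, seq, SketchParams()) == 1.0
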