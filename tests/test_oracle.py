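import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from concord.io import CommunityCover
from concord.oracle import (
    CL,
    ML,
    Constraint,
    ConstraintSet,
    annotate_pairs,
    inject_noise,
    true_label,
)


class TestTrueLabel:
    def test_shared_community_is_must_link(self):
        cover = CommunityCover([{1, 2}, {2, 3}])
        assert true_label(1, 2, cover) == ML

    def test_overlap_breaks_transitivity(self):
        # (a,b) and (b,c) are ML through the overlapping node b, yet (a,c)
        # is CL: must-link is not transitive over overlapping communities
        cover = CommunityCover([{1, 2}, {2, 3}])
        assert true_label(1, 2, cover) == ML
        assert true_label(2, 3, cover) == ML
        assert true_label(1, 3, cover) == CL

    def test_triple_in_one_community(self):
        cover = CommunityCover([{1, 2, 3}])
        assert true_label(1, 3, cover) == ML

    def test_symmetric(self):
        cover = CommunityCover([{1, 2}, {3, 4}])
        for u, v in [(1, 2), (1, 3), (2, 4)]:
            assert true_label(u, v, cover) == true_label(v, u, cover)

    def test_missing_node_rejected(self):
        cover = CommunityCover([{1, 2}])
        with pytest.raises(ValueError, match="absent"):
            true_label(1, 99, cover)

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            true_label(1, 1, CommunityCover([{1, 2}]))

    def test_disjoint_cover_ml_is_transitive(self):
        # sanity bound: with pairwise-disjoint communities the ML relation
        # restricted to the cover is an equivalence relation
        cover = CommunityCover([{0, 1, 2}, {3, 4, 5}, {6, 7}])
        nodes = sorted(cover.nodes())
        for a in nodes:
            for b in nodes:
                for c in nodes:
                    if len({a, b, c}) < 3:
                        continue
                    if true_label(a, b, cover) == ML and true_label(b, c, cover) == ML:
                        assert true_label(a, c, cover) == ML


class TestAnnotate:
    def test_triangle_cover_all_ml(self):
        cs = annotate_pairs([(1, 2), (2, 3), (1, 3)], CommunityCover([{1, 2, 3}]))
        assert len(cs.view_ml) == 3 and len(cs.view_cl) == 0

    def test_empty_pairs(self):
        assert len(annotate_pairs([], CommunityCover([{1, 2}]))) == 0

    def test_mixed_labels(self):
        cs = annotate_pairs([(1, 2), (1, 3)], CommunityCover([{1, 2}, {3, 4}]))
        assert len(cs.view_ml) == 1 and len(cs.view_cl) == 1
        assert cs.noisy_count() == 0

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            annotate_pairs([(1, 2), (2, 1)], CommunityCover([{1, 2}]))


def _make_set(n_ml: int, n_cl: int) -> ConstraintSet:
    cs = ConstraintSet()
    k = 0
    for _ in range(n_ml):
        cs.add(Constraint(k, k + 1, ML, ML))
        k += 2
    for _ in range(n_cl):
        cs.add(Constraint(k, k + 1, CL, CL))
        k += 2
    return cs


class TestInjectNoise:
    def test_flip_count_is_tenth_of_smaller_set(self):
        cs = _make_set(200, 100)
        out = inject_noise(cs, rate=0.1, rng=0)
        assert out.noisy_count() == 10

    def test_zero_rate_warns_and_returns_unchanged(self):
        cs = _make_set(5, 5)
        with pytest.warns(UserWarning):
            out = inject_noise(cs, rate=0.0, rng=0)
        assert out.noisy_count() == 0
        assert out.pairs == cs.pairs

    def test_full_rate_deterministic(self):
        cs = _make_set(5, 5)
        a = inject_noise(cs, rate=1.0, rng=123)
        b = inject_noise(cs, rate=1.0, rng=123)
        assert a.noisy_count() == 5
        assert [c.pair for c in a if c.is_noisy] == [c.pair for c in b if c.is_noisy]

    def test_flipped_constraints_change_view(self):
        cs = _make_set(10, 10)
        out = inject_noise(cs, rate=1.0, rng=1)
        for c in out:
            if c.is_noisy:
                assert c.observed_label != c.true_label

    def test_minimum_one_flip(self):
        cs = _make_set(3, 3)
        out = inject_noise(cs, rate=0.01, rng=0)
        assert out.noisy_count() == 1

    @given(n_ml=st.integers(1, 60), n_cl=st.integers(1, 60),
           rate=st.floats(0.05, 1.0), seed=st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None)
    def test_flip_count_exact(self, n_ml, n_cl, rate, seed):
        cs = _make_set(n_ml, n_cl)
        k = max(1, int(np.floor(rate * min(n_ml, n_cl) + 0.5)))
        out = inject_noise(cs, rate=rate, rng=seed)
        assert out.noisy_count() == k


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path):
        cs = inject_noise(_make_set(6, 4), rate=0.5, rng=5)
        p = tmp_path / "c.tsv"
        cs.to_tsv(p)
        back = ConstraintSet.from_tsv(p)
        assert back.pairs == cs.pairs
        assert back.noisy_count() == cs.noisy_count()
        assert [c.observed_label for c in back] == [c.observed_label for c in cs]

    def test_views_partition(self):
        cs = inject_noise(_make_set(8, 8), rate=0.5, rng=2)
        assert len(cs.view_ml) + len(cs.view_cl) == len(cs)

    def test_canonical_pair_order(self):
        c = Constraint(5, 2, ML, ML)
        assert c.pair == (2, 5)
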