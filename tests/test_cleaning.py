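import networkx as nx
import numpy as np
import pytest

from concord.benchmark import BenchmarkParams, generate_benchmark
from concord.cleaning import (
    CleaningConfig,
    ConstraintCleaner,
    ViewModel,
    clean_constraint_set,
    default_config,
    network_scale,
    recheck_discarded,
)
from concord.features import PairFeaturizer
from concord.io import CommunityCover
from concord.oracle import CL, ML, Constraint, ConstraintSet, annotate_pairs, inject_noise
from concord.outliers import OutlierModelSpec


class TestDefaultConfig:
    def test_hybrid_small_uses_encoder_plus_forest_for_cannot_link(self):
        cfg = default_config("small", "hybrid")
        assert cfg.ml_model.kind == "ae" and cfg.ml_model.ae_name == "AE1_L1"
        assert cfg.cl_model.kind == "encoder+detector"
        assert cfg.cl_model.ae_name == "AE3"
        assert cfg.cl_model.detector.family == "isolation_forest"

    def test_autoencoder_large_uses_deeper_sparse_model(self):
        cfg = default_config("large", "autoencoder")
        assert cfg.ml_model.ae_name == "AE2_L1"
        assert cfg.cl_model.ae_name == "AE3_L1"

    def test_traditional_pairs_svm_with_forest(self):
        cfg = default_config("small", "traditional")
        assert cfg.ml_model.detector.family == "ocsvm"
        assert cfg.cl_model.detector.family == "isolation_forest"

    def test_deep_embedding_varies_with_scale(self):
        small = default_config("small", "deep_embedding")
        large = default_config("large", "deep_embedding")
        assert small.ml_model.ae_name == "AE3"
        assert large.ml_model.ae_name == "AE2"

    def test_unknown_inputs_rejected(self):
        with pytest.raises(ValueError):
            default_config("tiny", "hybrid")
        with pytest.raises(ValueError):
            default_config("small", "nonsense")

    def test_scale_switch_at_midpoint(self):
        assert network_scale(nx.empty_graph(1000)) == "small"
        assert network_scale(nx.empty_graph(3000)) == "large"


@pytest.fixture(scope="module")
def bench():
    g, truth = generate_benchmark(
        BenchmarkParams(N=300, C_min=10, C_max=50, mu=0.1, On=0.1, Om=2, seed=21)
    )
    fz = PairFeaturizer(g, simrank_max_iter=10, n_walks=3, walk_length=20,
                        window=3, seed=0)
    return g, truth, fz


def sample_constraints(g, truth, n_pairs, seed, noise=0.1):
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes())
    pairs = set()
    while len(pairs) < n_pairs:
        u, v = (int(x) for x in rng.choice(nodes, 2, replace=False))
        pairs.add((min(u, v), max(u, v)))
    cs = annotate_pairs(sorted(pairs), truth)
    if noise:
        cs = inject_noise(cs, rate=noise, rng=seed)
    return cs


class TestCleanConstraintSet:
    def test_conservation_of_constraints(self, bench):
        g, truth, fz = bench
        cs = sample_constraints(g, truth, 400, seed=1)
        kept, discarded = clean_constraint_set(cs, g, featurizer=fz, seed=0)
        assert kept.pairs | discarded.pairs == cs.pairs
        assert kept.pairs & discarded.pairs == set()

    def test_deterministic_partition(self, bench):
        g, truth, fz = bench
        cs = sample_constraints(g, truth, 300, seed=2)
        k1, d1 = clean_constraint_set(cs, g, featurizer=fz, seed=5)
        k2, d2 = clean_constraint_set(cs, g, featurizer=fz, seed=5)
        assert k1.pairs == k2.pairs and d1.pairs == d2.pairs

    def test_traditional_flags_near_contamination_floor(self, bench):
        # clean constraints, one round: flagged fraction tracks the 10%
        # contamination and never exceeds twice it
        g, truth, fz = bench
        cs = sample_constraints(g, truth, 400, seed=3, noise=0)
        cfg = default_config("small", "traditional")
        cfg.sub_iterations = 1
        cfg.ml_model = ViewModel("detector", detector=OutlierModelSpec("isolation_forest"))
        kept, discarded = clean_constraint_set(cs, g, config=cfg, featurizer=fz, seed=0)
        frac = len(discarded) / len(cs)
        assert frac <= 0.2

    def test_empty_cl_view_passes_through(self, bench):
        g, truth, fz = bench
        comms = [c for c in truth.communities if len(c) >= 8][:2]
        members = sorted(comms[0])
        pairs = [(members[i], members[j]) for i in range(6) for j in range(i + 1, 7)]
        cs = annotate_pairs(pairs, truth)
        ml_only = ConstraintSet([c for c in cs if c.observed_label == ML])
        assert len(ml_only.view_cl) == 0
        kept, discarded = clean_constraint_set(ml_only, g, featurizer=fz, seed=0)
        assert kept.pairs | discarded.pairs == ml_only.pairs

    def test_planted_profile_noise_mostly_discarded(self, bench):
        # 90 well-connected true-ML rows + 10 flipped rows whose endpoints
        # are distant and dissimilar: the hybrid ML model should discard
        # most of the planted noise
        g, truth, fz = bench
        rng = np.random.default_rng(8)
        ml_pairs = []
        for c in truth.communities:
            members = sorted(c)
            sub = g.subgraph(members)
            for u, v in sub.edges():
                ml_pairs.append((min(u, v), max(u, v)))
        ml_pairs = list(dict.fromkeys(ml_pairs))[:90]
        nodes = sorted(g.nodes())
        planted = []
        while len(planted) < 10:
            u, v = (int(x) for x in rng.choice(nodes, 2, replace=False))
            p = (min(u, v), max(u, v))
            if p in planted or p in ml_pairs:
                continue
            if not any({u, v} <= c for c in truth.communities) and not g.has_edge(u, v):
                planted.append(p)
        cs = ConstraintSet(
            [Constraint(u, v, ML, ML) for u, v in ml_pairs]
            + [Constraint(u, v, ML, CL) for u, v in planted]
        )
        kept, discarded = clean_constraint_set(cs, g, featurizer=fz, seed=0)
        n_planted_discarded = sum(1 for c in discarded if c.is_noisy)
        assert n_planted_discarded >= 8

    def test_empty_set_rejected(self, bench):
        g, _, fz = bench
        with pytest.raises(ValueError):
            clean_constraint_set(ConstraintSet(), g, featurizer=fz)


class TestRecheck:
    def test_empty_discarded_gives_empty_recovery(self, bench):
        g, _, fz = bench
        assert len(recheck_discarded(ConstraintSet(), g, featurizer=fz)) == 0

    def test_recovered_subset_of_discarded(self, bench):
        g, truth, fz = bench
        cs = sample_constraints(g, truth, 400, seed=4)
        _, discarded = clean_constraint_set(cs, g, featurizer=fz, seed=1)
        if len(discarded) >= 10:
            recovered = recheck_discarded(discarded, g, featurizer=fz, seed=1)
            assert recovered.pairs <= discarded.pairs

    def test_tight_clean_cluster_mostly_recovered(self, bench):
        # a discarded pool consisting entirely of correctly-labelled,
        # well-connected must-link rows: the recheck keeps the majority
        g, truth, fz = bench
        ml_pairs = []
        for c in truth.communities:
            sub = g.subgraph(sorted(c))
            for u, v in sub.edges():
                ml_pairs.append((min(u, v), max(u, v)))
        ml_pairs = list(dict.fromkeys(ml_pairs))[:60]
        pool = ConstraintSet([Constraint(u, v, ML, ML) for u, v in ml_pairs])
        recovered = recheck_discarded(pool, g, featurizer=fz, seed=2)
        assert len(recovered) >= 0.5 * len(pool)


class TestProvenance:
    def test_log_records_rounds(self, bench):
        g, truth, fz = bench
        cs = sample_constraints(g, truth, 300, seed=6)
        cleaner = ConstraintCleaner(default_config("small", "traditional"), fz, random_state=0)
        cleaner.clean(cs)
        assert cleaner.log_
        assert {"view", "round", "removed", "surviving"} <= set(cleaner.log_[0])
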