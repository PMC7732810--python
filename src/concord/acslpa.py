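"""Active semi-supervised community finding (AC-SLPA) with noise handling.

The loop alternates three stages.  Stage 1, repeated for a fixed number
of iterations: select informative node pairs, have the (noisy) oracle
label them, pool the new constraints with the accumulated kept set,
clean the pool (detectors retrained each iteration), and run constrained
propagation with the survivors.  Stage 2, once after the loop: re-clean
the accumulated discarded pool and recover constraints that were
over-zealously removed.  Stage 3: a final constrained propagation run on
everything kept.

Pair selection ranks nodes by the entropy of their label memories
(membership uncertainty) and pairs each uncertain node with (i) its most
strongly attached neighbour and (ii) a sampled non-neighbour from a
different current community, falling back to uniform sampling of
unqueried pairs when no uncertainty signal exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .cleaning import CleaningConfig, ConstraintCleaner, default_config, network_scale
from .features import PairFeaturizer
from .io import CommunityCover
from .oracle import ConstraintSet, annotate_pairs, inject_noise
from .slpa import PCSLPA, SLPA

logger = logging.getLogger(__name__)

__all__ = ["ActiveConfig", "select_informative_pairs", "ACSLPA", "run_acslpa"]


@dataclass
class ActiveConfig:
    """Budgets and sub-configurations of one active run.

    The default total budget is 2% of all node pairs capped at 5000,
    split evenly over 10 iterations.
    """

    iterations: int = 10
    total_budget: int | None = None
    budget_per_iteration: int | None = None
    noise_rate: float = 0.1
    cleaning: CleaningConfig | None = None
    cleaning_enabled: bool = True
    recheck: bool = True
    rounds: int = 100
    threshold: float = 0.1
    track_nmi: bool = False  # record per-iteration NMI vs the oracle cover
    seed: int = 0

    def resolve_budgets(self, n_nodes: int) -> tuple[int, int]:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        total = self.total_budget
        if total is None:
            total = min(5000, int(0.02 * n_nodes * (n_nodes - 1) / 2))
        per_iter = self.budget_per_iteration
        if per_iter is None:
            per_iter = max(1, total // self.iterations)
        if total < 1 or per_iter < 1:
            raise ValueError("budgets must be positive")
        return total, per_iter


def _memory_entropy(mem: np.ndarray) -> np.ndarray:
    """Shannon entropy of each node's label-memory distribution."""
    n = mem.shape[0]
    out = np.empty(n)
    for i in range(n):
        _, counts = np.unique(mem[i], return_counts=True)
        p = counts / counts.sum()
        out[i] = float(-(p * np.log(p)).sum())
    return out


def select_informative_pairs(
    g: nx.Graph,
    cover: CommunityCover | None,
    memories: np.ndarray | None,
    mem_nodes: np.ndarray | None,
    already_queried: set[tuple[int, int]],
    budget: int,
    seed: int | None = 0,
) -> list[tuple[int, int]]:
    """Select up to ``budget`` unqueried pairs around uncertain nodes.

    Uncertainty is label-memory entropy; every selected node contributes
    one within-neighbourhood pair (its most attached neighbour, by common
    neighbour count) and one cross-community pair (a sampled non-neighbour
    currently placed in a different community).  With no entropy signal
    (or no memories at all) selection is uniform over unqueried pairs.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes())
    n = len(nodes)
    queried = {tuple(sorted(p)) for p in already_queried}

    def norm(u: int, v: int) -> tuple[int, int]:
        return (u, v) if u < v else (v, u)

    chosen: list[tuple[int, int]] = []
    chosen_set: set[tuple[int, int]] = set()

    def try_add(u: int, v: int) -> bool:
        if u == v:
            return False
        p = norm(u, v)
        if p in queried or p in chosen_set:
            return False
        chosen.append(p)
        chosen_set.add(p)
        return True

    if memories is not None and mem_nodes is not None:
        ent = _memory_entropy(memories)
        if ent.max() > 0:
            order = np.argsort(-ent, kind="stable")
            node_of = {i: int(mem_nodes[i]) for i in range(len(mem_nodes))}
            memb: dict[int, set[int]] = {}
            if cover is not None:
                for ci, c in enumerate(cover):
                    for v in c:
                        memb.setdefault(v, set()).add(ci)
            adj = {v: set(g.neighbors(v)) for v in nodes}
            for i in order:
                if len(chosen) >= budget:
                    break
                u = node_of[int(i)]
                nbrs = sorted(
                    adj[u], key=lambda w: (-len(adj[u] & adj[w]), w)
                )
                # most attached neighbour not yet queried
                for w in nbrs:
                    if try_add(u, int(w)):
                        break
                if len(chosen) >= budget:
                    break
                # boundary pair: a two-hop non-neighbour currently placed in
                # a different community (ambiguous pairs are the informative
                # ones); fall back to any different-community node
                mine = memb.get(u, set())
                two_hop = [
                    w
                    for w in set().union(*(adj[x] for x in nbrs)) - adj[u] - {u}
                    if not (memb.get(w, set()) & mine)
                ] if nbrs else []
                added = False
                if two_hop:
                    for w in rng.permutation(len(two_hop))[:10]:
                        if try_add(u, int(two_hop[int(w)])):
                            added = True
                            break
                if not added:
                    for _ in range(10):
                        w = int(nodes[rng.integers(n)])
                        if w != u and w not in adj[u] and not (memb.get(w, set()) & mine):
                            try_add(u, w)
                            break

    # fallback / top-up: uniform sampling of unqueried pairs
    attempts = 0
    max_attempts = 50 * budget + 100
    while len(chosen) < budget and attempts < max_attempts:
        attempts += 1
        u, v = rng.integers(n, size=2)
        if u == v:
            continue
        try_add(int(nodes[u]), int(nodes[v]))
    return chosen[:budget]


class ACSLPA:
    """The full active loop; an estimator over (network, oracle cover).

    ``fit(g, truth)`` emulates the noisy oracle from the ground-truth
    cover ``truth`` and runs stages 1-3.  Attributes afterwards:

    cover_ : the final community cover.
    kept_, discarded_ : accumulated constraint partition (after recheck).
    provenance_ : per-iteration counts and, when a reference cover is
        given, the NMI trace.
    """

    def __init__(self, config: ActiveConfig | None = None):
        self.config = config or ActiveConfig()

    def fit(self, g: nx.Graph, truth: CommunityCover, featurizer: PairFeaturizer | None = None) -> "ACSLPA":
        cfg = self.config
        n = g.number_of_nodes()
        if n == 0:
            raise ValueError("empty network")
        total_budget, per_iter = cfg.resolve_budgets(n)
        rng = np.random.default_rng(cfg.seed)
        scale = network_scale(g)
        cleaning = cfg.cleaning or default_config(scale, "hybrid")
        if featurizer is None and cfg.cleaning_enabled:
            featurizer = PairFeaturizer(g, seed=cfg.seed)
        cleaner = (
            ConstraintCleaner(cleaning, featurizer, random_state=cfg.seed)
            if cfg.cleaning_enabled
            else None
        )

        queried: set[tuple[int, int]] = set()
        kept = ConstraintSet()
        discarded = ConstraintSet()
        memories = None
        mem_nodes = None
        cover: CommunityCover | None = None
        self.provenance_ = []

        for it in range(cfg.iterations):
            remaining = total_budget - len(queried)
            if remaining <= 0:
                break
            budget = min(per_iter, remaining)
            pairs = select_informative_pairs(
                g, cover, memories, mem_nodes, queried, budget,
                seed=int(rng.integers(2**31 - 1)),
            )
            if not pairs:
                break
            queried |= set(pairs)
            new_cs = annotate_pairs(pairs, truth)
            new_cs = inject_noise(new_cs, cfg.noise_rate, rng=rng)
            pool = kept.merge(new_cs)

            if cleaner is not None and len(pool) >= 10:
                kept, newly_discarded = cleaner.clean(pool)
                discarded = discarded.merge(newly_discarded)
            else:
                kept = pool
                newly_discarded = ConstraintSet()

            model = self._propagate(g, kept, seed=cfg.seed + it)
            memories, mem_nodes, cover = model.memories_, model.nodes_, model.cover_
            record = {
                "iteration": it,
                "queried": len(pairs),
                "pool": len(pool),
                "kept": len(kept),
                "discarded_total": len(discarded),
            }
            if cfg.track_nmi:
                from .metrics import overlapping_nmi

                record["nmi"] = overlapping_nmi(cover, truth)
            self.provenance_.append(record)

        # Stage 2: recheck the accumulated discarded pool once
        recovered = ConstraintSet()
        if cfg.recheck and cleaner is not None and len(discarded) >= 10:
            recovered, _ = cleaner.clean(discarded)
            kept = kept.merge(recovered)

        # Stage 3: final constrained run on everything kept
        model = self._propagate(g, kept, seed=cfg.seed + cfg.iterations)
        self.cover_ = model.cover_
        self.kept_ = kept
        self.discarded_ = discarded
        self.recovered_ = recovered
        self.provenance_.append(
            {"stage": "final", "kept": len(kept), "recovered": len(recovered),
             "queried_total": len(queried)}
        )
        return self

    def _propagate(self, g: nx.Graph, constraints: ConstraintSet, seed: int):
        cfg = self.config
        if len(constraints) == 0:
            logger.warning("no constraints kept; falling back to unsupervised propagation")
            return SLPA(rounds=cfg.rounds, threshold=cfg.threshold, random_state=seed).fit(g)
        return PCSLPA(
            constraints=constraints,
            rounds=cfg.rounds,
            threshold=cfg.threshold,
            random_state=seed,
        ).fit(g)

    def fit_predict(self, g: nx.Graph, truth: CommunityCover, **kw) -> CommunityCover:
        return self.fit(g, truth, **kw).cover_


def run_acslpa(
    g: nx.Graph, truth: CommunityCover, config: ActiveConfig | None = None,
    featurizer: PairFeaturizer | None = None,
) -> tuple[CommunityCover, list[dict]]:
    """Functional wrapper over :class:`ACSLPA`; returns (cover, provenance)."""
    model = ACSLPA(config).fit(g, truth, featurizer=featurizer)
    return model.cover_, model.provenance_
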