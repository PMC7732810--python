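"""Speaker-listener label propagation for overlapping communities.

Every node keeps a memory of labels.  In each round every listener
receives one label from each neighbour (the speaker emits a label drawn
from its memory proportionally to frequency, which is exactly a uniform
draw over memory entries) and stores the most frequent received label,
ties broken uniformly at random.  After ``T`` rounds a node belongs to
the communities of every label that occupies at least a fraction ``r``
of its memory; overlap arises whenever several labels survive.

Listeners are processed in shuffled blocks each round; speakers in later
blocks emit from memories already updated earlier in the same round, a
block-wise approximation of the asynchronous sweep of the original
algorithm that keeps every block fully vectorised (``n_blocks`` controls
the granularity; one block per node recovers the classic asynchronous
schedule at python speed).  The constrained variant (PC-SLPA) adds
must-link / cannot-link guidance during and after propagation; see
:class:`PCSLPA` for the exact rules.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from sklearn.base import BaseEstimator

from .io import CommunityCover
from .oracle import ML, CL, ConstraintSet

__all__ = ["SLPA", "PCSLPA", "run_slpa", "run_pcslpa"]


def _ranges(counts: np.ndarray) -> np.ndarray:
    """Concatenated ``arange(c)`` for every positive c in counts."""
    c = counts[counts > 0]
    if len(c) == 0:
        return np.empty(0, dtype=np.int64)
    out = np.ones(int(c.sum()), dtype=np.int64)
    out[0] = 0
    starts = np.cumsum(c)[:-1]
    out[starts] = 1 - c[:-1]
    return np.cumsum(out)


def _segment_argmax_mode(listeners: np.ndarray, labels: np.ndarray, weights: np.ndarray,
                         n_nodes: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-listener weighted mode of received labels, random tie-break.

    Returns (chosen label per node, has_any per node).  ``listeners`` need
    not be sorted; labels are node indices in [0, n_nodes).
    """
    if len(listeners) == 0:
        return np.zeros(n_nodes, dtype=np.int64), np.zeros(n_nodes, dtype=bool)
    # group (listener, label) pairs and sum weights per group
    key = listeners.astype(np.int64) * n_nodes + labels
    order = np.argsort(key, kind="stable")
    key_s = key[order]
    w_s = weights[order]
    boundaries = np.flatnonzero(np.r_[True, key_s[1:] != key_s[:-1]])
    counts = np.add.reduceat(w_s, boundaries)
    grp_key = key_s[boundaries]
    grp_listener = grp_key // n_nodes
    grp_label = grp_key % n_nodes
    # random tie-break: jitter < 1 never flips a strict weight ordering
    priority = counts + rng.random(len(counts)) * 0.5
    seg_start = np.flatnonzero(np.r_[True, grp_listener[1:] != grp_listener[:-1]])
    seg_max = np.maximum.reduceat(priority, seg_start)
    max_per_group = np.repeat(seg_max, np.diff(np.r_[seg_start, len(priority)]))
    winner = priority == max_per_group
    chosen = np.zeros(n_nodes, dtype=np.int64)
    has = np.zeros(n_nodes, dtype=bool)
    chosen[grp_listener[winner]] = grp_label[winner]
    has[grp_listener[winner]] = True
    return chosen, has


class SLPA(BaseEstimator):
    """Unsupervised speaker-listener label propagation.

    Parameters
    ----------
    rounds : number of propagation rounds T.
    threshold : post-processing frequency threshold r in (0, 0.5]; labels
        seen in less than ``r`` of a node's memory are dropped.
    random_state : seed controlling speaker draws and tie-breaks.

    Attributes
    ----------
    cover_ : CommunityCover over the input graph's node ids.
    memories_ : (n_nodes, rounds + 1) array of stored label indices.
    nodes_ : node ids aligned with the memory rows.
    """

    def __init__(
        self,
        rounds: int = 100,
        threshold: float = 0.1,
        n_blocks: int = 32,
        random_state: int | None = 0,
    ):
        self.rounds = rounds
        self.threshold = threshold
        self.n_blocks = n_blocks
        self.random_state = random_state

    def _check_params(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not (0.0 < self.threshold <= 0.5):
            raise ValueError("threshold must lie in (0, 0.5]")

    # -- propagation core --------------------------------------------------

    def _propagate(
        self,
        g: nx.Graph,
        rng: np.random.Generator,
        ml_pairs: np.ndarray | None = None,
        cl_pairs: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        nodes = np.array(sorted(g.nodes()))
        idx = {int(v): i for i, v in enumerate(nodes)}
        n = len(nodes)
        li, sp = [], []
        for u, v in g.edges():
            li += [idx[u], idx[v]]
            sp += [idx[v], idx[u]]
        weights = [1.0] * len(li)
        if ml_pairs is not None and len(ml_pairs):
            # must-link partners also speak to each other, double weight
            for u, v in ml_pairs:
                li += [idx[u], idx[v]]
                sp += [idx[v], idx[u]]
                weights += [2.0, 2.0]
        listeners = np.asarray(li, dtype=np.int64)
        speakers = np.asarray(sp, dtype=np.int64)
        weights_arr = np.asarray(weights)
        cl_idx = (
            np.array([[idx[u], idx[v]] for u, v in cl_pairs], dtype=np.int64)
            if cl_pairs is not None and len(cl_pairs)
            else None
        )

        # sort incoming arcs by listener so each listener block is a set of
        # contiguous slices; listeners are processed in shuffled blocks,
        # later blocks seeing memories already updated this round (the
        # block-wise approximation of the asynchronous sweep)
        arc_order = np.argsort(listeners, kind="stable")
        listeners = listeners[arc_order]
        speakers = speakers[arc_order]
        weights_arr = weights_arr[arc_order]
        indptr = np.searchsorted(listeners, np.arange(n + 1))

        T = self.rounds
        n_blocks = max(1, min(self.n_blocks, n))
        mem = np.empty((n, T + 1), dtype=np.int64)
        mem[:, 0] = np.arange(n)
        filled = np.ones(n, dtype=np.int64)  # entries written per node
        # incremental per-node label counts and running mode keep the
        # cannot-link separation rule from rescanning memories each round;
        # only needed when cannot-link pairs are present
        track = cl_idx is not None
        if track:
            cnt: list[dict[int, int]] = [{i: 1} for i in range(n)]
            top = np.arange(n, dtype=np.int64)
            top_n = np.ones(n, dtype=np.int64)
        for t in range(1, T + 1):
            perm = rng.permutation(n)
            for blk in np.array_split(perm, n_blocks):
                counts = indptr[blk + 1] - indptr[blk]
                if counts.sum() == 0:
                    mem[blk, t] = mem[blk, t - 1]
                    filled[blk] += 1
                    continue
                # gather the arc slices of this block's listeners
                arc_idx = np.repeat(indptr[blk], counts) + _ranges(counts)
                lb = listeners[arc_idx]
                sb = speakers[arc_idx]
                wb = weights_arr[arc_idx]
                draw = np.floor(rng.random(len(sb)) * filled[sb]).astype(np.int64)
                emitted = mem[sb, draw]
                chosen, has = _segment_argmax_mode(lb, emitted, wb, n, rng)
                mem[blk, t] = np.where(has[blk], chosen[blk], mem[blk, t - 1])
                filled[blk] += 1
            if track:
                new = mem[:, t]
                for i in range(n):
                    lab = int(new[i])
                    c = cnt[i].get(lab, 0) + 1
                    cnt[i][lab] = c
                    if c > top_n[i]:
                        top[i], top_n[i] = lab, c
                self._separate_cl_round(mem, t, cl_idx, cnt, top, top_n, rng)
        return mem, nodes

    @staticmethod
    def _second_label(c: dict[int, int], top_lab: int) -> int | None:
        best, best_c = None, -1
        for lab, k in c.items():
            if lab != top_lab and k > best_c:
                best, best_c = lab, k
        return best

    def _separate_cl_round(
        self,
        mem: np.ndarray,
        t: int,
        cl_idx: np.ndarray,
        cnt: list[dict[int, int]],
        top: np.ndarray,
        top_n: np.ndarray,
        rng: np.random.Generator,
    ) -> None:
        """After a round, pull apart cannot-link pairs that agree on their
        current top label: the more weakly attached node swaps this round's
        memory entry for its second most frequent label."""
        conflict = top[cl_idx[:, 0]] == top[cl_idx[:, 1]]
        for a, b in cl_idx[conflict]:
            if top[a] != top[b]:  # may have changed within this sweep
                continue
            fa, fb = int(top_n[a]), int(top_n[b])
            if fa == fb:
                weak = int(a) if rng.random() < 0.5 else int(b)
            else:
                weak = int(a) if fa < fb else int(b)
            sec = self._second_label(cnt[weak], int(top[weak]))
            if sec is None:
                continue
            old = int(mem[weak, t])
            mem[weak, t] = sec
            cnt[weak][old] -= 1
            if cnt[weak][old] == 0:
                del cnt[weak][old]
            cnt[weak][sec] = cnt[weak].get(sec, 0) + 1
            # running mode may have shifted either way; recompute locally
            best, best_c = None, -1
            for lab, k in cnt[weak].items():
                if k > best_c:
                    best, best_c = lab, k
            top[weak], top_n[weak] = best, best_c

    # -- post-processing ---------------------------------------------------

    def _memories_to_cover(
        self,
        mem: np.ndarray,
        nodes: np.ndarray,
        ml_pairs: np.ndarray | None = None,
        cl_pairs: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> CommunityCover:
        n, width = mem.shape
        node_labels: list[dict[int, int]] = []  # surviving label -> frequency
        top_label = np.empty(n, dtype=np.int64)
        top_freq = np.empty(n, dtype=np.int64)
        min_count = self.threshold * width
        for i in range(n):
            vals, counts = np.unique(mem[i], return_counts=True)
            order = np.argsort(-counts, kind="stable")
            top_label[i] = vals[order[0]]
            top_freq[i] = counts[order[0]]
            surv = {int(v): int(c) for v, c in zip(vals, counts) if c >= min_count}
            if not surv:
                surv = {int(vals[order[0]]): int(counts[order[0]])}
            node_labels.append(surv)

        idx = {int(v): i for i, v in enumerate(nodes)}
        if ml_pairs is not None:
            # must-link repair: pairs sharing no surviving label inherit the
            # stronger node's top label into the weaker node's set
            for u, v in ml_pairs:
                a, b = idx[u], idx[v]
                if set(node_labels[a]) & set(node_labels[b]):
                    continue
                strong, weak = (a, b) if top_freq[a] >= top_freq[b] else (b, a)
                node_labels[weak][int(top_label[strong])] = 1
        if cl_pairs is not None:
            # cannot-link enforcement: remove the weaker member from every
            # shared label; a node never loses its last label silently —
            # it moves to a fresh singleton community instead
            for u, v in cl_pairs:
                a, b = idx[u], idx[v]
                shared = set(node_labels[a]) & set(node_labels[b])
                for lab in shared:
                    weak = a if node_labels[a][lab] <= node_labels[b][lab] else b
                    del node_labels[weak][lab]
                    if not node_labels[weak]:
                        node_labels[weak][-(weak + 1)] = 1  # unique fresh label

        groups: dict[int, set[int]] = {}
        for i, labs in enumerate(node_labels):
            for lab in labs:
                groups.setdefault(lab, set()).add(int(nodes[i]))
        # merge exact duplicates, then drop communities that are strict
        # subsets of another (fragment labels that survived thresholding);
        # co-membership is preserved because every member of a subset
        # community is also a member of its superset
        seen: set[frozenset[int]] = set()
        comms: list[frozenset[int]] = []
        for lab in sorted(groups):
            key = frozenset(groups[lab])
            if key not in seen:
                seen.add(key)
                comms.append(key)
        keep = [c for c in comms if not any(c < d for d in comms)]
        return CommunityCover(set(c) for c in keep)

    # -- estimator surface -------------------------------------------------

    def fit(self, g: nx.Graph, y=None) -> "SLPA":
        self._check_params()
        if g.number_of_nodes() == 0:
            raise ValueError("empty network")
        rng = np.random.default_rng(self.random_state)
        mem, nodes = self._propagate(g, rng)
        self.memories_ = mem
        self.nodes_ = nodes
        self.cover_ = self._memories_to_cover(mem, nodes)
        return self

    def fit_predict(self, g: nx.Graph, y=None) -> CommunityCover:
        return self.fit(g).cover_


class PCSLPA(SLPA):
    """Pairwise-constrained SLPA.

    Constraint guidance, on top of the unconstrained propagation:

    (a) must-link partners of a listener speak to it with doubled weight
        (in addition to any network edge between them);
    (b) after each round, a cannot-link pair whose nodes agree on their
        current most-frequent label is pulled apart — the weaker node
        replaces this round's memory entry with its second label;
    (c) in post-processing, must-link pairs sharing no surviving label
        have the stronger node's top label granted to the weaker node,
        and cannot-link pairs sharing a community lose the weaker member
        from it (a node losing its last community gets a fresh singleton).

    Rule (c) runs must-link repair first, so cannot-link constraints are
    satisfied unconditionally in the output; must-link is best-effort
    (the relation is not transitive for overlapping communities).
    """

    def __init__(
        self,
        constraints: ConstraintSet | None = None,
        rounds: int = 100,
        threshold: float = 0.1,
        n_blocks: int = 32,
        random_state: int | None = 0,
    ):
        super().__init__(
            rounds=rounds, threshold=threshold, n_blocks=n_blocks, random_state=random_state
        )
        self.constraints = constraints

    def fit(self, g: nx.Graph, y=None) -> "PCSLPA":
        self._check_params()
        cs = self.constraints if self.constraints is not None else ConstraintSet()
        nodes = set(g.nodes())
        for c in cs:
            if c.u not in nodes or c.v not in nodes:
                raise ValueError(f"constraint pair {c.pair} references unknown node")
        ml = np.array([c.pair for c in cs if c.observed_label == ML], dtype=np.int64).reshape(-1, 2)
        cl = np.array([c.pair for c in cs if c.observed_label == CL], dtype=np.int64).reshape(-1, 2)
        rng = np.random.default_rng(self.random_state)
        mem, node_arr = self._propagate(g, rng, ml_pairs=ml, cl_pairs=cl)
        self.memories_ = mem
        self.nodes_ = node_arr
        self.cover_ = self._memories_to_cover(mem, node_arr, ml_pairs=ml, cl_pairs=cl, rng=rng)
        return self


def run_slpa(g: nx.Graph, rounds: int = 100, threshold: float = 0.1,
             seed: int | None = 0) -> CommunityCover:
    """Functional wrapper over :class:`SLPA`."""
    return SLPA(rounds=rounds, threshold=threshold, random_state=seed).fit_predict(g)


def run_pcslpa(g: nx.Graph, constraints: ConstraintSet, rounds: int = 100,
               threshold: float = 0.1, seed: int | None = 0) -> CommunityCover:
    """Functional wrapper over :class:`PCSLPA`."""
    return PCSLPA(constraints=constraints, rounds=rounds, threshold=threshold,
                  random_state=seed).fit_predict(g)
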