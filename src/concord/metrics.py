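"""Evaluation metrics: noise-detection AUC, overlapping NMI, community-size
KS comparison, and average ranks.

The overlapping NMI is the normalised-conditional-entropy form defined on
per-community binary membership vectors (the "LFK" variant): each
community of one cover is matched to its best counterpart in the other,
conditional entropies are normalised by the community's own entropy, and
the final score is ``1 - (H_norm(A|B) + H_norm(B|A)) / 2``.  A matching
term is only admissible when ``h(a) + h(d) >= h(b) + h(c)``, which guards
against accidental complement matches; communities with zero entropy (the
full node set) contribute their unnormalised entropy ratio of 1.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .io import CommunityCover

__all__ = ["roc_auc", "overlapping_nmi", "ks_two_sample", "average_ranks"]


def roc_auc(scores: np.ndarray, noise_flags: np.ndarray) -> float:
    """Probability that a random noisy constraint outscores a random clean
    one, ties counted half (the rank-statistic AUC)."""
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(noise_flags).astype(int)
    if len(scores) != len(flags):
        raise ValueError("scores and flags must align")
    if len(np.unique(flags)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(flags, scores))


def _h(p):
    """Entropy contribution -p log2 p with the 0 log 0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = -p[pos] * np.log2(p[pos])
    return out if out.ndim else float(out)


def _cover_matrix(cover: CommunityCover, universe: list[int]) -> np.ndarray:
    pos = {v: i for i, v in enumerate(universe)}
    M = np.zeros((len(cover), len(universe)), dtype=bool)
    for k, comm in enumerate(cover):
        for v in comm:
            M[k, pos[v]] = True
    return M


def _norm_cond_entropy(A: np.ndarray, B: np.ndarray) -> float:
    """Mean over communities of A of the normalised conditional entropy
    H(A_k | B) / H(A_k), with the admissibility guard."""
    n = A.shape[1]
    scores = []
    sizes_b = B.sum(axis=1).astype(float)
    Bf = B.astype(np.float32)
    for k in range(A.shape[0]):
        x = A[k]
        px = x.sum() / n
        hx = float(_h(px)) + float(_h(1 - px))
        if hx == 0.0:
            # a community covering everything (or nothing) carries no
            # information; its normalised entropy is defined as maximal
            scores.append(1.0)
            continue
        # joint counts against every community of B, vectorised
        a = Bf @ x.astype(np.float32)      # in both
        b_ = sizes_b - a                   # in B only
        c = float(x.sum()) - a             # in A_k only
        d = n - a - b_ - c                 # in neither
        ha, hb, hc, hd = _h(a / n), _h(b_ / n), _h(c / n), _h(d / n)
        admissible = ha + hd >= hb + hc    # complement-match guard
        hy = _h((a + b_) / n) + _h((c + d) / n)
        cond = ha + hb + hc + hd - hy
        if admissible.any():
            scores.append(float(np.clip(cond[admissible].min() / hx, 0.0, 1.0)))
        else:
            scores.append(1.0)
    return float(np.mean(scores)) if scores else 0.0


def overlapping_nmi(cover_a: CommunityCover, cover_b: CommunityCover) -> float:
    """Overlapping NMI between two covers of the same node universe.

    1 for identical covers; values near 0 mean the covers agree no better
    than chance.  Symmetric in its arguments.
    """
    nodes_a, nodes_b = cover_a.nodes(), cover_b.nodes()
    universe = sorted(nodes_a | nodes_b)
    if not universe:
        raise ValueError("both covers are empty")
    if not (nodes_a & nodes_b):
        raise ValueError("covers share no nodes; NMI undefined")
    A = _cover_matrix(cover_a, universe)
    B = _cover_matrix(cover_b, universe)
    hab = _norm_cond_entropy(A, B)
    hba = _norm_cond_entropy(B, A)
    return 1.0 - 0.5 * (hab + hba)


def ks_two_sample(sizes_a: list[int], sizes_b: list[int]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value for
    comparing community-size distributions."""
    if len(sizes_a) == 0 or len(sizes_b) == 0:
        raise ValueError("KS test requires non-empty samples")
    res = stats.ks_2samp(sizes_a, sizes_b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def average_ranks(score_table: np.ndarray, higher_is_better: bool = True) -> np.ndarray:
    """Mean rank per algorithm over networks.

    ``score_table`` has one row per algorithm and one column per network;
    rank 1 is best on each network, ties share the mean of the tied ranks.
    """
    scores = np.asarray(score_table, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("score table contains missing values")
    direction = -scores if higher_is_better else scores
    ranks = np.apply_along_axis(stats.rankdata, 0, direction)
    return ranks.mean(axis=1)
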