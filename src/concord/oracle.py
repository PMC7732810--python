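"""The (noisy) constraint oracle.

Pairwise supervision for community finding comes as *must-link* (ML) pairs
that share at least one ground-truth community and *cannot-link* (CL)
pairs that share none.  Because communities overlap, the ML relation is
not transitive: an overlapping node can be must-linked with members of
all of its communities while those members are cannot-linked with each
other.  The oracle is made imperfect by flipping the observed label of a
randomly-chosen subset of pairs; the flip count is tied to the size of
the smaller of the two constraint sets (10% of it by convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io import CommunityCover

ML = "ML"
CL = "CL"

__all__ = ["ML", "CL", "Constraint", "ConstraintSet", "true_label", "annotate_pairs", "inject_noise"]


@dataclass(frozen=True)
class Constraint:
    """A labelled node pair.

    ``observed_label`` is what the oracle reported; ``true_label`` is the
    ground truth it was derived from.  The two differ exactly when the
    constraint is noisy.
    """

    u: int
    v: int
    observed_label: str
    true_label: str

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError("self-pair constraint")
        if self.u > self.v:  # canonical order for unordered pairs
            u, v = self.u, self.v
            object.__setattr__(self, "u", v)
            object.__setattr__(self, "v", u)

    @property
    def pair(self) -> tuple[int, int]:
        return (self.u, self.v)

    @property
    def is_noisy(self) -> bool:
        return self.observed_label != self.true_label


def _canonical(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


def make_constraint(u: int, v: int, observed: str, true: str) -> Constraint:
    cu, cv = _canonical(int(u), int(v))
    return Constraint(cu, cv, observed, true)


class ConstraintSet:
    """An ordered collection of pairwise constraints without duplicate pairs.

    The observed-ML and observed-CL views partition the set; they are the
    two inputs cleaned by separate processes.
    """

    def __init__(self, constraints: Iterable[Constraint] = ()):
        self.constraints: list[Constraint] = []
        self._pairs: set[tuple[int, int]] = set()
        for c in constraints:
            self.add(c)

    def add(self, c: Constraint) -> None:
        if c.pair in self._pairs:
            raise ValueError(f"duplicate constraint pair {c.pair}")
        self._pairs.add(c.pair)
        self.constraints.append(c)

    def __len__(self) -> int:
        return len(self.constraints)

    def __iter__(self) -> Iterator[Constraint]:
        return iter(self.constraints)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return _canonical(*pair) in self._pairs

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return set(self._pairs)

    @property
    def view_ml(self) -> list[Constraint]:
        return [c for c in self.constraints if c.observed_label == ML]

    @property
    def view_cl(self) -> list[Constraint]:
        return [c for c in self.constraints if c.observed_label == CL]

    def noisy_count(self) -> int:
        return sum(1 for c in self.constraints if c.is_noisy)

    def merge(self, other: "ConstraintSet") -> "ConstraintSet":
        """Union of two sets; on pair collision the receiver's labels win."""
        out = ConstraintSet(self.constraints)
        for c in other:
            if c.pair not in out._pairs:
                out.add(c)
        return out

    def subset(self, pairs: Iterable[tuple[int, int]]) -> "ConstraintSet":
        wanted = {_canonical(*p) for p in pairs}
        return ConstraintSet(c for c in self.constraints if c.pair in wanted)

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("u\tv\tobserved\ttrue\tnoisy\n")
            for c in self.constraints:
                fh.write(f"{c.u}\t{c.v}\t{c.observed_label}\t{c.true_label}\t{int(c.is_noisy)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConstraintSet":
        out = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("u\t"):
                raise ValueError(f"{path}: missing constraint TSV header")
            for line in fh:
                u, v, obs, true, _ = line.rstrip("\n").split("\t")
                out.add(make_constraint(int(u), int(v), obs, true))
        return out


def true_label(u: int, v: int, cover: CommunityCover) -> str:
    """Ground-truth label of a pair: ML iff the nodes share >= 1 community.

    Overlap-aware and deliberately non-transitive: with cover
    ``[{a,b},{b,c}]`` both (a,b) and (b,c) are ML while (a,c) is CL.
    """
    if u == v:
        raise ValueError("self-pair has no constraint label")
    found_u = found_v = False
    for c in cover:
        in_u, in_v = u in c, v in c
        if in_u and in_v:
            return ML
        found_u |= in_u
        found_v |= in_v
    if not (found_u and found_v):
        missing = [x for x, f in ((u, found_u), (v, found_v)) if not f]
        raise ValueError(f"nodes absent from cover: {missing}")
    return CL


def annotate_pairs(pairs: Sequence[tuple[int, int]], cover: CommunityCover) -> ConstraintSet:
    """Label pairs with the noiseless oracle (observed = true)."""
    cs = ConstraintSet()
    for u, v in pairs:
        lab = true_label(u, v, cover)
        cs.add(make_constraint(u, v, lab, lab))
    return cs


def inject_noise(
    cs: ConstraintSet, rate: float = 0.1, rng: np.random.Generator | int | None = None
) -> ConstraintSet:
    """Flip observed labels of ``k = round(rate * min(|ML|, |CL|))`` pairs.

    The flipped pairs are drawn uniformly without replacement from the
    union of both views, so noise may concentrate entirely in the smaller
    set.  At least one pair is flipped whenever ``rate > 0`` and the
    smaller view is non-empty.  Rounding is half-up.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    n_ml, n_cl = len(cs.view_ml), len(cs.view_cl)
    k = int(np.floor(rate * min(n_ml, n_cl) + 0.5))
    if rate > 0 and min(n_ml, n_cl) > 0:
        k = max(k, 1)
    if k == 0:
        warnings.warn("noise injection requested but flip count is 0; returning input unchanged")
        return ConstraintSet(cs.constraints)
    idx = rng.choice(len(cs), size=k, replace=False)
    flip = set(int(i) for i in idx)
    out = ConstraintSet()
    for i, c in enumerate(cs.constraints):
        if i in flip:
            out.add(replace(c, observed_label=CL if c.observed_label == ML else ML))
        else:
            out.add(c)
    return out
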