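"""Constraint cleaning: two parallel outlier-detection processes split
the incoming noisy constraint pool (PC-) into a kept set (PC+) and a
discarded set.

The must-link and cannot-link views are cleaned separately because their
feature distributions differ markedly (cannot-link pairs cluster near
zero similarity, must-link pairs spread over the similar range, and
noise sits on the wrong side in each case).  Four cleaning categories are
supported, each configurable per view:

* ``traditional`` — a stand-alone detector (Isolation Forest, one-class
  SVM or LOF) flags outliers directly on the 7-dim features;
* ``autoencoder`` — an autoencoder is trained on the view and the rows
  with the highest reconstruction error are discarded;
* ``deep_embedding`` — the encoder half of an autoencoder compresses the
  features and a traditional detector is fitted on the latent codes;
* ``hybrid`` — an autoencoder cleans the must-link view while
  encoder+Isolation-Forest cleans the cannot-link view (the best
  performing combination of the above).

Each view runs ``sub_iterations`` rounds of fit → flag → remove → refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np

from .features import PairFeaturizer, minmax_scale_columns
from .oracle import ConstraintSet
from .outliers import (
    OutlierModelSpec,
    fit_and_flag,
    make_autoencoder,
    select_clean_by_error,
)

__all__ = ["ViewModel", "CleaningConfig", "default_config", "ConstraintCleaner",
           "clean_constraint_set", "recheck_discarded", "network_scale"]

Category = Literal["traditional", "deep_embedding", "autoencoder", "hybrid"]


@dataclass
class ViewModel:
    """The model cleaning one constraint view.

    kind='detector'   : ``detector`` flags rows directly.
    kind='ae'         : ``ae_name`` autoencoder, reconstruction-error cut.
    kind='encoder+detector' : ``ae_name`` encoder feeds ``detector``.
    """

    kind: Literal["detector", "ae", "encoder+detector"]
    ae_name: str | None = None
    detector: OutlierModelSpec | None = None

    def __post_init__(self) -> None:
        if self.kind in ("ae", "encoder+detector") and self.ae_name is None:
            raise ValueError("autoencoder-based view model needs ae_name")
        if self.kind in ("detector", "encoder+detector") and self.detector is None:
            raise ValueError(f"view model kind {self.kind!r} needs a detector spec")


@dataclass
class CleaningConfig:
    """Which model serves each constraint view, and how many rounds."""

    category: Category = "hybrid"
    ml_model: ViewModel = field(
        default_factory=lambda: ViewModel("ae", ae_name="AE1_L1")
    )
    cl_model: ViewModel = field(
        default_factory=lambda: ViewModel(
            "encoder+detector", ae_name="AE3", detector=OutlierModelSpec("isolation_forest")
        )
    )
    regime: str = "small"  # autoencoder training regime
    sub_iterations: int = 2
    keep_fraction: float = 0.9


def network_scale(g: nx.Graph, cutover: int = 2500) -> str:
    """'small' or 'large' training regime by node count (midpoint of the
    1000/5000 benchmark regimes)."""
    return "small" if g.number_of_nodes() < cutover else "large"


def default_config(scale: str, category: Category = "hybrid") -> CleaningConfig:
    """The per-category model selections that performed best for each
    constraint view, keyed by network-size regime."""
    if scale not in ("small", "large"):
        raise ValueError("scale must be 'small' or 'large'")
    svm = OutlierModelSpec("ocsvm")
    iforest = OutlierModelSpec("isolation_forest")
    ml_ae = "AE1_L1" if scale == "small" else "AE2_L1"
    if category == "hybrid":
        ml = ViewModel("ae", ae_name=ml_ae)
        cl = ViewModel("encoder+detector", ae_name="AE3", detector=iforest)
    elif category == "autoencoder":
        ml = ViewModel("ae", ae_name=ml_ae)
        cl = ViewModel("ae", ae_name="AE3_L1")
    elif category == "deep_embedding":
        ml = ViewModel(
            "encoder+detector",
            ae_name="AE3" if scale == "small" else "AE2",
            detector=svm,
        )
        cl = ViewModel("encoder+detector", ae_name="AE3", detector=iforest)
    elif category == "traditional":
        ml = ViewModel("detector", detector=svm)
        cl = ViewModel("detector", detector=iforest)
    else:
        raise ValueError(f"unknown cleaning category {category!r}")
    return CleaningConfig(category=category, ml_model=ml, cl_model=cl, regime=scale)


class ConstraintCleaner:
    """Fits the configured view models and partitions a constraint set.

    Parameters
    ----------
    config : CleaningConfig selecting the models per view.
    featurizer : PairFeaturizer for the underlying network (reused across
        calls so SimRank / embeddings are computed once).
    random_state : seed for model fitting.

    Attributes (after clean())
    --------------------------
    kept_, discarded_ : the PC+ / candidate-noise partition.
    scores_ml_, scores_cl_ : last-round outlier scores per surviving row
        (larger = more anomalous), aligned with ``score_pairs_ml_`` /
        ``score_pairs_cl_``.
    log_ : per-view, per-round removal counts.
    """

    def __init__(
        self,
        config: CleaningConfig,
        featurizer: PairFeaturizer,
        random_state: int | None = 0,
    ):
        self.config = config
        self.featurizer = featurizer
        self.random_state = random_state

    # -- single view -------------------------------------------------------

    def _score_view(
        self, model: ViewModel, X: np.ndarray, seed: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Fit the view model on X; return (outlier flags, scores)."""
        cfg = self.config
        if model.kind == "detector":
            _, flags, scores = fit_and_flag(model.detector, X, seed=seed)
            return flags, scores
        ae = make_autoencoder(model.ae_name, cfg.regime, random_state=seed)
        ae.fit(X)
        if model.kind == "ae":
            errors = ae.reconstruction_errors(X)
            keep = select_clean_by_error(errors, cfg.keep_fraction)
            return ~keep, errors
        latent = ae.transform(X)
        latent, _, _ = minmax_scale_columns(latent)
        _, flags, scores = fit_and_flag(model.detector, latent, seed=seed)
        return flags, scores

    def _clean_view(
        self, constraints: list, model: ViewModel, label: str, seed: int
    ) -> tuple[list, list, np.ndarray]:
        """Iteratively clean one view; returns (kept, discarded, last scores)."""
        cfg = self.config
        surviving = list(constraints)
        removed: list = []
        scores = np.empty(0)
        for rnd in range(cfg.sub_iterations):
            if len(surviving) < 10:
                if rnd == 0 and surviving:
                    warnings.warn(
                        f"{label} view too small to clean ({len(surviving)} rows); "
                        "passing through unchanged"
                    )
                break
            X = self.featurizer([c.pair for c in surviving])
            X, _, _ = minmax_scale_columns(X)
            try:
                flags, scores = self._score_view(model, X, seed + rnd)
            except ValueError as exc:
                warnings.warn(f"{label} view not cleaned: {exc}")
                break
            removed += [c for c, f in zip(surviving, flags) if f]
            surviving = [c for c, f in zip(surviving, flags) if not f]
            self.log_.append(
                {"view": label, "round": rnd, "removed": int(flags.sum()),
                 "surviving": len(surviving)}
            )
        return surviving, removed, scores

    # -- public surface ----------------------------------------------------

    def clean(self, cs: ConstraintSet) -> tuple[ConstraintSet, ConstraintSet]:
        """Partition ``cs`` into (kept PC+, discarded candidate noise)."""
        if len(cs) == 0:
            raise ValueError("empty constraint set")
        seed = 0 if self.random_state is None else int(self.random_state)
        self.log_: list[dict] = []
        ml_kept, ml_disc, self.scores_ml_ = self._clean_view(
            cs.view_ml, self.config.ml_model, "ML", seed
        )
        cl_kept, cl_disc, self.scores_cl_ = self._clean_view(
            cs.view_cl, self.config.cl_model, "CL", seed + 1000
        )
        self.score_pairs_ml_ = [c.pair for c in ml_kept] if len(self.scores_ml_) else []
        self.score_pairs_cl_ = [c.pair for c in cl_kept] if len(self.scores_cl_) else []
        self.kept_ = ConstraintSet(ml_kept + cl_kept)
        self.discarded_ = ConstraintSet(ml_disc + cl_disc)
        return self.kept_, self.discarded_


def clean_constraint_set(
    cs: ConstraintSet,
    g: nx.Graph,
    config: CleaningConfig | None = None,
    featurizer: PairFeaturizer | None = None,
    seed: int | None = 0,
) -> tuple[ConstraintSet, ConstraintSet]:
    """Functional wrapper: clean ``cs`` against network ``g``.

    Builds a default hybrid config for the network's size regime and a
    fresh featurizer unless either is supplied.
    """
    if config is None:
        config = default_config(network_scale(g), "hybrid")
    if featurizer is None:
        featurizer = PairFeaturizer(g, seed=0 if seed is None else seed)
    cleaner = ConstraintCleaner(config, featurizer, random_state=seed)
    return cleaner.clean(cs)


def recheck_discarded(
    discarded: ConstraintSet,
    g: nx.Graph,
    config: CleaningConfig | None = None,
    featurizer: PairFeaturizer | None = None,
    seed: int | None = 0,
) -> ConstraintSet:
    """Second-stage recheck: re-clean the discarded pool and return the
    rows that survive every round (recovered constraints)."""
    if len(discarded) == 0:
        return ConstraintSet()
    recovered, _ = clean_constraint_set(
        discarded, g, config=config, featurizer=featurizer, seed=seed
    )
    return recovered
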