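"""Site-reactivity classification and site-yield regression.

Both estimators follow the scikit-learn contract (``fit`` / ``predict``,
``get_params`` / ``set_params``, trailing-underscore fitted attributes)
so they compose with pipelines and model selection. Input ``X`` is a
sequence of site-reaction SMILES (``substrate>>site_product``); the DRFP
featurization runs inside the estimator so a fitted model is fully
self-contained and can score a bare substrate via
:func:`predict_molecule`.

The forest hyperparameters are pinned numerically in
:data:`FOREST_DEFAULTS` rather than left to library defaults, so the
model cannot drift silently across scikit-learn versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from .chem_core import Molecule
from .drfp import DEFAULT_N_BITS, DEFAULT_RADIUS, DrfpFeaturizer
from .metrics import DEFAULT_SUCCESS_THRESHOLD
from .site_enum import SiteDataset, SiteInstance, enumerate_sites

#: Pinned random-forest hyperparameters (the classical defaults, written out).
FOREST_DEFAULTS = {
    "n_estimators": 100,
    "classifier_criterion": "gini",
    "regressor_criterion": "squared_error",
    "classifier_max_features": "sqrt",
    "regressor_max_features": 1.0,
    "min_samples_split": 2,
    "min_samples_leaf": 1,
}


class _SiteEstimatorBase(BaseEstimator):
    def __init__(
        self,
        n_bits: int = DEFAULT_N_BITS,
        radius: int = DEFAULT_RADIUS,
        n_estimators: int = FOREST_DEFAULTS["n_estimators"],
        random_state: int = 0,
    ):
        self.n_bits = n_bits
        self.radius = radius
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _featurize(self, X) -> np.ndarray:
        X = list(X)
        if X and isinstance(X[0], str):
            feats = DrfpFeaturizer(self.n_bits, self.radius).fit(X).transform(X)
        else:
            feats = np.asarray(X)
        if feats.ndim != 2 or (feats.size and feats.shape[1] != self.n_bits):
            raise ValueError(
                f"expected fingerprints of length {self.n_bits}, "
                f"got shape {feats.shape}"
            )
        return feats


class SiteReactivityClassifier(ClassifierMixin, _SiteEstimatorBase):
    """Random-forest classifier over DRFPs: reactive (1) vs unreactive (0).

    Parameters
    ----------
    n_bits, radius : int
        DRFP parameters; must match any externally supplied features.
    n_estimators : int
        Trees in the forest.
    random_state : int
        Seed; fitting twice with the same data and seed gives identical
        predictions.
    """

    def fit(self, X, y):
        feats = self._featurize(X)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError(
                f"training labels contain a single class {classes.tolist()}; "
                "both reactive and unreactive sites are required"
            )
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            criterion=FOREST_DEFAULTS["classifier_criterion"],
            max_features=FOREST_DEFAULTS["classifier_max_features"],
            min_samples_split=FOREST_DEFAULTS["min_samples_split"],
            min_samples_leaf=FOREST_DEFAULTS["min_samples_leaf"],
            random_state=self.random_state,
        ).fit(feats, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = self.n_bits
        self.metadata_ = {
            "kind": "classifier",
            "n_bits": self.n_bits,
            "radius": self.radius,
            "seed": self.random_state,
            "n_trees": self.n_estimators,
            "n_train": len(y),
        }
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict(self._featurize(X))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(self._featurize(X))


class SiteYieldRegressor(RegressorMixin, _SiteEstimatorBase):
    """Random-forest regressor over DRFPs predicting percent yield.

    Unreactive sites train at 0 percent yield; predicted yields at or
    above the success threshold (default 5 percent) are read as
    "reaction happens here".
    """

    def fit(self, X, y):
        feats = self._featurize(X)
        y = np.asarray(y, dtype=float)
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            criterion=FOREST_DEFAULTS["regressor_criterion"],
            max_features=FOREST_DEFAULTS["regressor_max_features"],
            min_samples_split=FOREST_DEFAULTS["min_samples_split"],
            min_samples_leaf=FOREST_DEFAULTS["min_samples_leaf"],
            random_state=self.random_state,
        ).fit(feats, y)
        self.n_features_in_ = self.n_bits
        self.metadata_ = {
            "kind": "regressor",
            "n_bits": self.n_bits,
            "radius": self.radius,
            "seed": self.random_state,
            "n_trees": self.n_estimators,
            "n_train": len(y),
        }
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict(self._featurize(X))


def train(
    dataset: SiteDataset,
    kind: str = "classifier",
    features: np.ndarray | None = None,
    n_bits: int = DEFAULT_N_BITS,
    radius: int = DEFAULT_RADIUS,
    n_estimators: int = FOREST_DEFAULTS["n_estimators"],
    seed: int = 0,
):
    """Fit a site model on a labeled SiteDataset.

    The classifier trains on every labeled site. The regressor trains
    label-0 sites at 0 percent yield; label-1 sites missing a reported
    yield are excluded rather than imputed, since absent yields reflect
    reporting bias, not failure.
    """
    instances = [i for i in dataset.instances if i.label is not None]
    if not instances:
        raise ValueError("dataset has no labeled instances")
    if features is not None and len(features) != len(dataset.instances):
        raise ValueError("features are not row-aligned with the dataset")

    def _rows(selected: list[int]):
        if features is not None:
            return features[selected]
        return [dataset.instances[i].site_reaction for i in selected]

    idx_all = [i for i, inst in enumerate(dataset.instances) if inst.label is not None]
    if kind == "classifier":
        model = SiteReactivityClassifier(n_bits, radius, n_estimators, seed)
        y = [dataset.instances[i].label for i in idx_all]
        return model.fit(_rows(idx_all), y)
    if kind == "regressor":
        idx = [
            i
            for i in idx_all
            if dataset.instances[i].label == 0
            or dataset.instances[i].yield_label is not None
        ]
        y = [
            0.0
            if dataset.instances[i].label == 0
            else float(dataset.instances[i].yield_label)
            for i in idx
        ]
        model = SiteYieldRegressor(n_bits, radius, n_estimators, seed)
        return model.fit(_rows(idx), y)
    raise ValueError(f"kind must be 'classifier' or 'regressor', got {kind!r}")


@dataclass
class MoleculePrediction:
    """Per-site scores aggregated to a molecule-level call."""

    substrate: Molecule
    sites: list[SiteInstance] = field(default_factory=list)
    scores: dict[int, float] = field(default_factory=dict)
    reactive_set: set[int] = field(default_factory=set)
    major_site: int | None = None

    @property
    def no_reaction_flag(self) -> bool:
        return len(self.reactive_set) == 0


def predict_molecule(
    model,
    substrate: Molecule | str,
    mode: str = "aromatic_CH",
    success_threshold: float = DEFAULT_SUCCESS_THRESHOLD,
) -> MoleculePrediction:
    """Enumerate, featurize and score every candidate site of a substrate.

    Classifier models call a site reactive when the forest votes class 1
    (probability > 0.5); regressor models when the predicted yield
    reaches the success threshold. If every site is unreactive - or the
    substrate has no enumerable site at all - the molecule-level call is
    "no reaction". The major site is the argmax score, ties broken by
    lowest canonical atom id.
    """
    if isinstance(substrate, str):
        substrate = Molecule.from_smiles(substrate)
    sites = enumerate_sites(substrate, mode)
    pred = MoleculePrediction(substrate=substrate, sites=sites)
    if not sites:
        return pred
    reactions = [s.site_reaction for s in sites]
    if isinstance(model, SiteReactivityClassifier):
        proba = model.predict_proba(reactions)
        pos = list(model.classes_).index(1)
        scores = proba[:, pos]
        reactive = scores > 0.5
    elif isinstance(model, SiteYieldRegressor):
        scores = model.predict(reactions)
        reactive = scores >= success_threshold
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    pred.scores = {s.site_atom: float(v) for s, v in zip(sites, scores)}
    pred.reactive_set = {s.site_atom for s, r in zip(sites, reactive) if r}
    best = max(zip(sites, scores), key=lambda t: (t[1], -t[0].site_atom))
    pred.major_site = best[0].site_atom
    return pred


def substructure_postfilter(
    substrate: Molecule, candidates: list[Molecule]
) -> list[Molecule]:
    """Keep candidate products that contain the substrate as a substructure.

    In C-H activation the starting material survives intact inside the
    product, so any candidate in which the substrate's molecular graph
    cannot be embedded (aromaticity-aware matching) is spurious and is
    dropped. Order is preserved.
    """
    query = substrate.mol
    return [c for c in candidates if c.mol.HasSubstructMatch(query)]
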