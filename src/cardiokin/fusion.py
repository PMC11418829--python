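"""Late fusion of per-kinematic embeddings and random-forest classification.

Each kinematic channel gets its own trained network; the embedding
vectors extracted from those networks for the same slice are concatenated
in a canonical order (a_N, div, vor, then the rest alphabetically) into a
single cardiac descriptor.  A seeded random forest (100 trees, maximum
depth 60) classifies descriptors, either between a pair of diagnostic
classes or pathology-versus-normal triage; each tree votes and the
fraction of votes is the class score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .kinematics import CANONICAL_ORDER
from .model import EmbeddingVector

__all__ = ["FusedDescriptor", "ForestConfig", "fuse_embeddings",
           "to_triage_label", "fit_forest", "forest_predict"]

PATHOLOGY_LABELS = ("DCM", "HCM", "MINF", "RV")


@dataclass
class FusedDescriptor:
    """Concatenated per-kinematic embedding (length = sum of parts)."""

    values: np.ndarray
    kinematic_order: tuple[str, ...]
    patient_id: str
    slice_index: int
    label: str


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters: 100 trees, depth cap 60 (reference
    recipe); remaining settings are scikit-learn defaults, frozen here."""

    n_trees: int = 100
    max_depth: int = 60
    seed: int = 0
    task: str = "pairwise"         # pairwise | triage

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValueError("n_trees and max_depth must be >= 1")


def _canonical_sort_key(channels: tuple[str, ...]) -> tuple[int, str]:
    key = "|".join(channels)
    try:
        return (CANONICAL_ORDER.index(channels[0]), key)
    except (ValueError, IndexError):
        return (len(CANONICAL_ORDER), key)


def fuse_embeddings(per_kinematic: list[EmbeddingVector]) -> FusedDescriptor:
    """Concatenate one slice's per-kinematic embeddings into a descriptor.

    All embeddings must come from the same (patient, slice) and carry
    distinct kinematic channels; concatenation order is canonical
    regardless of the input order, and is recorded on the descriptor.
    """
    if not per_kinematic:
        raise ValueError("need at least one embedding")
    sources = {(e.patient_id, e.slice_index) for e in per_kinematic}
    if len(sources) > 1:
        raise ValueError(f"embeddings mix sources: {sorted(sources)}")
    chans = [e.kinematic_channels for e in per_kinematic]
    if len(set(chans)) != len(chans):
        raise ValueError("duplicate kinematic channel among embeddings")
    ordered = sorted(per_kinematic,
                     key=lambda e: _canonical_sort_key(e.kinematic_channels))
    first = per_kinematic[0]
    return FusedDescriptor(
        values=np.concatenate([e.values for e in ordered]),
        kinematic_order=tuple(c for e in ordered for c in e.kinematic_channels),
        patient_id=first.patient_id,
        slice_index=first.slice_index,
        label=first.label,
    )


def to_triage_label(label: str) -> str:
    """Map the four disease classes to 'pathology'; N stays N."""
    return "pathology" if label in PATHOLOGY_LABELS else label


def _as_matrix(descriptors) -> np.ndarray:
    rows = [d.values if isinstance(d, FusedDescriptor) else np.asarray(d)
            for d in descriptors]
    return np.vstack(rows)


def fit_forest(descriptors, labels: list[str] | None = None,
               config: ForestConfig | None = None) -> RandomForestClassifier:
    """Fit the seeded random forest on fused descriptors.

    For the triage task, disease labels are first merged into a single
    'pathology' class.  Deterministic given ``config.seed``.
    """
    config = config or ForestConfig()
    if labels is None:
        labels = [d.label for d in descriptors]
    if config.task == "triage":
        labels = [to_triage_label(l) for l in labels]
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 classes to fit the forest")
    forest = RandomForestClassifier(n_estimators=config.n_trees,
                                    max_depth=config.max_depth,
                                    random_state=config.seed)
    forest.fit(_as_matrix(descriptors), labels)
    forest.cardiokin_config = config
    return forest


def forest_predict(forest: RandomForestClassifier,
                   descriptors) -> tuple[list[str], np.ndarray]:
    """Majority-vote labels and per-class vote fractions.

    Ties break toward the lexicographically first class (scikit-learn
    orders ``classes_`` lexicographically and ``argmax`` takes the first
    maximum).
    """
    x = _as_matrix(descriptors)
    expected = forest.n_features_in_
    if x.shape[1] != expected:
        raise ValueError(
            f"descriptor length {x.shape[1]} != trained length {expected}"
        )
    scores = forest.predict_proba(x)
    labels = [str(forest.classes_[i]) for i in np.argmax(scores, axis=1)]
    return labels, scores
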