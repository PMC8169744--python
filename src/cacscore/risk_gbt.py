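"""Non-gated post-processing: slice summary vectors -> bucket classifier.

On routine (non-gated) chest CT the per-slice segmentation is noisier, so
instead of trusting the summed Agatston score directly, each exam is reduced
to a fixed-length feature vector and a gradient-boosted decision tree
classifier maps it to a CVD risk bucket I–V, trained against bucket labels
derived from paired gated reference scores.

Each axial slice is summarized by four components computed from its
predicted lesions: total calcified area (mm^2), peak HU within the predicted
calcified region, the sum over lesions of area x peak HU, and the lesion
count.  The summaries of the 5 slices with the highest predicted area
(descending; ties by slice index) are concatenated into a 20-component
vector, zero-padded when the exam has fewer than 5 lesion-bearing slices.

Binary calls at the clinical cutoffs are derived from the predicted bucket
via the bucket boundaries: cutoff 1 <-> bucket >= II, 10 <-> >= III,
100 <-> >= IV, 400 <-> V.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier

from .network import ProbabilityVolume
from .scoring import (BUCKETS, CUTOFFS, Lesion, ScoringConfig,
                      bucket_index, score_volume)

__all__ = [
    "SliceSummary",
    "FEATURE_NAMES",
    "summarize_slice",
    "exam_features",
    "features_from_lesions",
    "BucketClassifier",
    "fit_bucket_classifier",
    "predict_bucket",
    "bucket_positive_at_cutoff",
    "save_classifier",
    "load_classifier",
]

N_TOP_SLICES = 5
FEATURE_NAMES = tuple(
    f"slice{r + 1}_{name}" for r in range(N_TOP_SLICES)
    for name in ("area_mm2", "max_hu", "weighted_area", "n_lesions"))

_FEATURE_LAYOUT_VERSION = 1


@dataclass(frozen=True)
class SliceSummary:
    """Four-component summary of one slice's predicted lesions."""

    predicted_area_mm2: float
    max_intensity_hu: float
    weighted_area: float
    n_lesions: int

    def as_array(self) -> np.ndarray:
        return np.array([self.predicted_area_mm2, self.max_intensity_hu,
                         self.weighted_area, float(self.n_lesions)])


def summarize_slice(lesions: list[Lesion]) -> SliceSummary:
    """Summary of the lesions on one slice; all-zero for an empty slice
    (the peak intensity of an empty region is defined as 0)."""
    if not lesions:
        return SliceSummary(0.0, 0.0, 0.0, 0)
    return SliceSummary(
        predicted_area_mm2=float(sum(l.area_mm2 for l in lesions)),
        max_intensity_hu=float(max(l.max_hu for l in lesions)),
        weighted_area=float(sum(l.area_mm2 * l.max_hu for l in lesions)),
        n_lesions=len(lesions),
    )


def features_from_lesions(lesions: list[Lesion], n_slices: int) -> np.ndarray:
    """20-component exam feature vector; a pure function of the lesion list.

    Slices are ranked by predicted area (descending, ties broken by the
    smaller slice index); the top 5 summaries are concatenated and the
    vector is zero-padded when fewer than 5 slices bear lesions.
    """
    by_slice: dict[int, list[Lesion]] = {}
    for l in lesions:
        by_slice.setdefault(l.slice_index, []).append(l)
    summaries = {si: summarize_slice(ls) for si, ls in by_slice.items()}
    ranked = sorted(summaries,
                    key=lambda si: (-summaries[si].predicted_area_mm2, si))
    parts = [summaries[si].as_array() for si in ranked[:N_TOP_SLICES]]
    while len(parts) < N_TOP_SLICES:
        parts.append(np.zeros(4))
    return np.concatenate(parts)


def exam_features(prob_volume: ProbabilityVolume, hu_volume: np.ndarray,
                  pixel_area_mm2: float,
                  cfg: ScoringConfig = ScoringConfig()) -> np.ndarray:
    """Run the scoring stage and summarize the exam (see module docstring)."""
    _, lesions = score_volume(prob_volume, hu_volume, pixel_area_mm2, cfg)
    return features_from_lesions(lesions, prob_volume.n_slices)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

class BucketClassifier:
    """Multiclass gradient-boosted decision trees over buckets I–V."""

    def __init__(self, n_estimators: int = 200, max_depth: int = 3,
                 learning_rate: float = 0.1, seed: int = 0):
        self._gbt = GradientBoostingClassifier(
            n_estimators=n_estimators, max_depth=max_depth,
            learning_rate=learning_rate, random_state=seed)
        self.feature_layout_version = _FEATURE_LAYOUT_VERSION

    def fit(self, features: np.ndarray, buckets) -> "BucketClassifier":
        features = np.asarray(features, dtype=np.float64)
        y = np.asarray([bucket_index(b) for b in buckets])
        if features.ndim != 2 or features.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"features must be (n, {len(FEATURE_NAMES)})")
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single bucket; "
                             "at least two classes are required")
        self._gbt.fit(features, y)
        return self

    def predict(self, features: np.ndarray) -> list[str]:
        features = np.asarray(features, dtype=np.float64)
        if features.ndim == 1:
            features = features[None]
        return [BUCKETS[i - 1] for i in self._gbt.predict(features)]


def fit_bucket_classifier(features: np.ndarray, buckets,
                          cv_splits: int | None = None, *,
                          n_estimators: int = 200, max_depth: int = 3,
                          learning_rate: float = 0.1, seed: int = 0):
    """Fit the bucket classifier on exam features and gated-reference bucket
    labels.

    With ``cv_splits`` set, also returns stratified-ish K-fold
    cross-validated predictions (same splits reusable for the CNN), as
    ``(classifier, cv_predicted_buckets)``; otherwise returns the
    classifier alone.
    """
    clf = BucketClassifier(n_estimators, max_depth, learning_rate, seed)
    clf.fit(features, buckets)
    if cv_splits is None:
        return clf
    from sklearn.model_selection import StratifiedKFold
    features = np.asarray(features, dtype=np.float64)
    y = np.asarray([bucket_index(b) for b in buckets])
    preds = np.empty(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=cv_splits, shuffle=True, random_state=seed)
    for tr, te in skf.split(features, y):
        fold = BucketClassifier(n_estimators, max_depth, learning_rate, seed)
        fold.fit(features[tr], [BUCKETS[i - 1] for i in y[tr]])
        preds[te] = [bucket_index(b) for b in fold.predict(features[te])]
    return clf, [BUCKETS[i - 1] for i in preds]


def predict_bucket(classifier: BucketClassifier,
                   feature: np.ndarray) -> str:
    """Bucket I–V for one 20-component exam feature vector."""
    return classifier.predict(np.asarray(feature)[None] if
                              np.asarray(feature).ndim == 1
                              else np.asarray(feature))[0]


def bucket_positive_at_cutoff(bucket: str, cutoff: int) -> bool:
    """Binary call at a clinical cutoff derived from the predicted bucket:
    1 -> bucket >= II, 10 -> >= III, 100 -> >= IV, 400 -> V."""
    if cutoff not in CUTOFFS:
        raise ValueError(f"cutoff must be one of {CUTOFFS}")
    min_bucket = {1: 2, 10: 3, 100: 4, 400: 5}[cutoff]
    return bucket_index(bucket) >= min_bucket


def save_classifier(classifier: BucketClassifier, path) -> None:
    Path(path).write_bytes(pickle.dumps(classifier))


def load_classifier(path) -> BucketClassifier:
    clf = pickle.loads(Path(path).read_bytes())
    if clf.feature_layout_version != _FEATURE_LAYOUT_VERSION:
        raise ValueError("classifier was trained with a different feature "
                         "layout version")
    return clf
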