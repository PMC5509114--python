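"""Tribe classification from EFA amplitude features.

Specimens are classified with random forests under leave-one-out
cross-validation (LOOCV): each specimen is predicted by a forest
trained on all the others, and the forest's vote fractions are its
class probabilities.  Performance is scored three ways:

* log-loss, ``-(1/N) sum ln p_hat(actual class)`` (natural log, so
  uniform guessing over C classes scores ``ln C``);
* the confusion matrix (rows actual, columns predicted);
* the classification rate, ``trace(confusion) / N``.

:func:`run_conditions` reproduces the four evaluation conditions of
the crowdsourcing experiment: expert outlines alone, repeated random
single-worker samples (a sampling distribution of log-loss), the
filtered worker consensus, and the consensus averaged together with
the expert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .efa import LandmarkSet, canonicalize, efa_forward, features, normalize
from .shapes import ConsensusConfig, TracingBundle, filter_tracings, mean_shape

log = logging.getLogger(__name__)

__all__ = [
    "ForestConfig",
    "ClassProbabilities",
    "ConfusionMatrix",
    "EvalReport",
    "landmark_features",
    "loocv_predict",
    "log_loss",
    "evaluate",
    "confusion_share",
    "run_conditions",
]


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest settings; the experiment makes no claims about
    these, they are knobs with conventional defaults."""

    n_trees: int = 500
    max_features: str | int | float = "sqrt"


@dataclass(frozen=True)
class ClassProbabilities:
    specimen_id: str
    probs: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.probs.values()))
        if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be nonnegative and sum to 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    classes: tuple[str, ...]
    counts: np.ndarray  # rows actual, columns predicted

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        n = len(self.classes)
        if counts.shape != (n, n) or (counts < 0).any():
            raise ValueError("counts must be a nonnegative square grid")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def classification_rate(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclass(frozen=True)
class EvalReport:
    condition_label: str
    log_loss: float
    classification_rate: float
    confusion: ConfusionMatrix
    n_dropped: int = 0


def landmark_features(landmarks: LandmarkSet, H: int = 10,
                      drop_normalized_entries: bool = False,
                      label: str | None = None,
                      specimen_id: str | None = None):
    """EFA amplitude feature vector of a landmark outline."""
    decomp = normalize(efa_forward(landmarks.points, H=H))
    return features(decomp, drop_normalized_entries=drop_normalized_entries,
                    label=label, specimen_id=specimen_id)


def _design(feature_vectors) -> tuple[np.ndarray, np.ndarray, list[str]]:
    X = np.stack([np.asarray(f.values, dtype=float) for f in feature_vectors])
    y = np.array([f.label for f in feature_vectors])
    ids = [f.specimen_id or str(i) for i, f in enumerate(feature_vectors)]
    return X, y, ids


def loocv_predict(feature_vectors, config: ForestConfig = ForestConfig(),
                  seed: int = 0) -> list[ClassProbabilities]:
    """Leave-one-out class probabilities from a random forest.

    A fresh forest is trained per fold with a seed derived from
    ``seed`` and the fold index, so reruns are bit-identical.
    """
    X, y, ids = _design(feature_vectors)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"every class needs >= 2 specimens; too few in {small}")
    preds = []
    n = len(y)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        forest = RandomForestClassifier(
            n_estimators=config.n_trees, max_features=config.max_features,
            random_state=(seed + i) % (2**31), n_jobs=1)
        forest.fit(X[train], y[train])
        p = forest.predict_proba(X[i:i + 1])[0]
        probs = dict.fromkeys(classes, 0.0)
        for cls, pv in zip(forest.classes_, p):
            probs[cls] = float(pv)
        preds.append(ClassProbabilities(specimen_id=ids[i], probs=probs))
    return preds


def log_loss(preds: list[ClassProbabilities], actual: dict[str, str] | list[str],
             clip: float = 1e-15) -> float:
    """Mean negative log probability of the true class (natural log).

    Probabilities are clipped below at ``clip`` so a zero-vote true
    class yields a large finite penalty rather than infinity.
    """
    if not isinstance(actual, dict):
        actual = {p.specimen_id: a for p, a in zip(preds, actual)}
    total = 0.0
    for p in preds:
        if p.specimen_id not in actual:
            raise ValueError(f"no label for specimen {p.specimen_id}")
        truth = actual[p.specimen_id]
        total += -np.log(max(clip, p.probs.get(truth, 0.0)))
    return float(total / len(preds))


def evaluate(preds: list[ClassProbabilities],
             actual: dict[str, str] | list[str],
             condition_label: str = "", clip: float = 1e-15,
             n_dropped: int = 0) -> EvalReport:
    """Score predictions: log-loss, confusion matrix, classification rate.

    Predicted class is the argmax probability; ties resolve to the
    lexicographically first label (and are logged).
    """
    if not isinstance(actual, dict):
        actual = {p.specimen_id: a for p, a in zip(preds, actual)}
    classes = sorted(set(actual.values()) |
                     {c for p in preds for c in p.probs})
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for p in preds:
        best = max(p.probs.values())
        winners = sorted(c for c, v in p.probs.items() if v == best)
        if len(winners) > 1:
            log.info("argmax tie for %s between %s; taking %s",
                     p.specimen_id, winners, winners[0])
        counts[index[actual[p.specimen_id]], index[winners[0]]] += 1
    confusion = ConfusionMatrix(classes=tuple(classes), counts=counts)
    return EvalReport(condition_label=condition_label,
                      log_loss=log_loss(preds, actual, clip=clip),
                      classification_rate=confusion.classification_rate(),
                      confusion=confusion, n_dropped=n_dropped)


def confusion_share(confusion: ConfusionMatrix, pair: tuple[str, str]) -> float:
    """Fraction of all misclassified specimens confused between the two
    named classes (in either direction)."""
    a, b = pair
    ia, ib = confusion.classes.index(a), confusion.classes.index(b)
    off_diagonal = confusion.total - int(np.trace(confusion.counts))
    if off_diagonal == 0:
        raise ValueError("no misclassifications: share undefined")
    return (int(confusion.counts[ia, ib]) + int(confusion.counts[ib, ia])) \
        / off_diagonal


# ---------------------------------------------------------------------------
# the four evaluation conditions

@dataclass(frozen=True)
class ConditionResults:
    reports: dict[str, EvalReport]
    single_worker_log_losses: np.ndarray  # sampling distribution, length R


def _fit_features(dataset, H, drop_normalized_entries, outlines):
    out = []
    for spec in dataset.specimens:
        if spec.specimen_id not in outlines:
            continue
        out.append(landmark_features(
            outlines[spec.specimen_id], H=H,
            drop_normalized_entries=drop_normalized_entries,
            label=spec.class_label, specimen_id=spec.specimen_id))
    return out


def run_conditions(dataset, consensus: ConsensusConfig = ConsensusConfig(),
                   forest: ForestConfig = ForestConfig(), H: int = 10,
                   R: int = 50, seed: int = 0,
                   drop_normalized_entries: bool = False,
                   sample_kept_only: bool = False) -> ConditionResults:
    """Run the expert / single-worker / consensus / consensus+expert
    comparison on a synthetic dataset with tracings.

    Returns per-condition :class:`EvalReport` objects plus the length-R
    sampling distribution of single-worker log-loss (each draw picks
    one random tracing per specimen, re-fits features, and runs LOOCV;
    the ``single_worker_sample`` report describes the final draw, the
    distribution is the primary output for that condition).
    Specimens with no usable tracings are dropped from the worker
    conditions and counted in ``n_dropped``.  ``sample_kept_only``
    restricts the single-worker draws to tracings that survive the
    quality filter (both readings of the resampling protocol are
    supported).
    """
    labels = {s.specimen_id: s.class_label for s in dataset.specimens}
    # Establish landmark homology: every outline (truth and tracing) is
    # re-fit with EFA and re-emitted from the canonical start.
    K = len(dataset.specimens[0].landmarks)
    truth = {s.specimen_id: canonicalize(s.landmarks, H=H, K=K)
             for s in dataset.specimens}

    bundles = {}
    for s in dataset.specimens:
        traced = [canonicalize(t, H=H, K=K)
                  for t in dataset.tracings.get(s.specimen_id, [])]
        b = TracingBundle(specimen_id=s.specimen_id,
                          gold=truth[s.specimen_id], tracings=traced)
        bundles[s.specimen_id] = filter_tracings(b, consensus)

    # expert condition
    expert_feats = _fit_features(dataset, H, drop_normalized_entries, truth)
    expert_preds = loocv_predict(expert_feats, forest, seed=seed)
    reports = {"expert": evaluate(expert_preds, labels, "expert")}

    # consensus conditions
    cons, cons_expert = {}, {}
    for sid, b in bundles.items():
        kept = [t for t, k in zip(b.tracings, b.kept) if k]
        if kept:
            cons[sid] = mean_shape(kept)
            cons_expert[sid] = mean_shape(kept + [truth[sid]])
    n_dropped = len(labels) - len(cons)
    if n_dropped:
        log.warning("%d specimens had no usable tracings and were dropped "
                    "from worker conditions", n_dropped)
    for name, outlines in (("worker_consensus", cons),
                           ("consensus_plus_expert", cons_expert)):
        feats = _fit_features(dataset, H, drop_normalized_entries, outlines)
        preds = loocv_predict(feats, forest, seed=seed)
        sub_labels = {k: labels[k] for k in outlines}
        reports[name] = evaluate(preds, sub_labels, name, n_dropped=n_dropped)

    # single-worker sampling distribution
    losses = np.empty(R)
    for r in range(R):
        rng = np.random.default_rng([seed, 1000 + r])
        sampled = {}
        for sid, b in bundles.items():
            pool = [t for t, k in zip(b.tracings, b.kept) if k] \
                if sample_kept_only else list(b.tracings)
            if pool:
                sampled[sid] = pool[rng.integers(len(pool))]
        feats = _fit_features(dataset, H, drop_normalized_entries, sampled)
        preds = loocv_predict(feats, forest, seed=seed)
        losses[r] = log_loss(preds, {k: labels[k] for k in sampled})
    rep = evaluate(preds, {k: labels[k] for k in sampled},
                   "single_worker_sample",
                   n_dropped=len(labels) - len(sampled))
    reports["single_worker_sample"] = rep
    return ConditionResults(reports=reports, single_worker_log_losses=losses)
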