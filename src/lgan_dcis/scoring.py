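"""Patch classification and patient-level aggressive-ratio scoring.

A small patch classifier is re-tuned (optionally only its last k layers)
on real weakly-labelled patches together with generated aggressive patches
added until the two classes are balanced.  At inference, every core of a
patient is tiled with 50%-overlap patches (tissue filter >= 50%), each
patch receives an aggressiveness probability, and the patient score is the
fraction of patches called aggressive.  The operating threshold on that
fraction is calibrated by maximising Youden's J on labelled scores, and
discrimination is summarised by the Mann-Whitney AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import MLP, fit_binary
from .bayesnet import mann_whitney_auc
from .gan import patch_features
from .preprocess import extract_patches
from .types import CoreImage, Patch, PatientScore, TissueMask

__all__ = [
    "ClassifierConfig", "ClassifierHandle", "EvalMetrics",
    "finetune_classifier", "predict_patch", "predict_patches",
    "score_patient", "calibrate_ratio_threshold", "evaluate",
]


@dataclass
class ClassifierConfig:
    hidden: tuple = (64, 32)
    epochs: int = 80
    batch_size: int = 32
    lr: float = 2e-3
    seed: int = 0


class ClassifierHandle:
    """Trained patch classifier; prediction is deterministic.

    Input patches of any side length are accepted: the featuriser
    downscales to the model's working resolution (resampling is always
    active in this backbone).
    """

    def __init__(self, net: MLP, config: ClassifierConfig, k_retuned: int,
                 feat_mean, feat_sd, history: dict):
        self.net = net
        self.config = config
        self.k_retuned = k_retuned
        self.feat_mean = feat_mean
        self.feat_sd = feat_sd
        self.history = history

    def predict(self, patches) -> np.ndarray:
        if len(patches) == 0:
            return np.empty(0)
        X = (patch_features(patches) - self.feat_mean) / self.feat_sd
        return self.net.forward(X).ravel()


def finetune_classifier(real_patches, generated_patches, k: int | None = None,
                        config: ClassifierConfig | None = None
                        ) -> ClassifierHandle:
    """Re-tune the last ``k`` layers on real + generated-aggressive patches.

    The training set is the real patches plus generated patches (labelled
    aggressive) subsampled or oversampled so the class counts are equal;
    with no generated patches this reduces to plain fine-tuning of the real
    data.  Only the trailing ``k`` parameterised layers are updated (k=0
    freezes everything; default: all layers).  Real data are split 90/10
    into train/test and the held-out patch AUC is recorded in
    ``history['test_auc']``.
    """
    config = config or ClassifierConfig()
    labels = np.array([p.weak_label for p in real_patches])
    if len(set(labels) & {"aggressive", "non-aggressive"}) < 2:
        raise ValueError("real patches must carry both weak labels")
    X_real = patch_features(real_patches)
    y_real = (labels == "aggressive").astype(float)

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(X_real))
    n_train = int(round(0.9 * len(X_real)))
    tr, te = order[:n_train], order[n_train:]

    X_parts = [X_real[tr]]
    y_parts = [y_real[tr]]
    if len(generated_patches):
        n_pos = int(y_real[tr].sum())
        n_neg = int(len(tr) - n_pos)
        need = max(n_neg - n_pos, 0)
        if need > 0:
            idx = rng.permutation(len(generated_patches))
            take = np.resize(idx, need)  # oversample by cycling if short
            X_gen = patch_features([generated_patches[i] for i in take])
            X_parts.append(X_gen)
            y_parts.append(np.ones(need))
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    mu, sd = X.mean(axis=0), X.std(axis=0) + 1e-8

    net = MLP((X.shape[1],) + tuple(config.hidden) + (1,), out="sigmoid",
              seed=config.seed)
    if k is None:
        k = net.n_layers
    net.freeze_all_but_last(k)  # raises if k exceeds the layer count
    losses = fit_binary(net, (X - mu) / sd, y, epochs=config.epochs,
                        batch_size=config.batch_size, lr=config.lr,
                        seed=config.seed + 1)
    history = {"loss": losses, "n_pos": int(y.sum()),
               "n_neg": int(len(y) - y.sum()),
               "n_generated_used": int(len(y) - len(tr))}
    if len(te) and len(set(y_real[te])) == 2:
        probs = net.forward((X_real[te] - mu) / sd).ravel()
        history["test_auc"] = mann_whitney_auc(probs, y_real[te])
    return ClassifierHandle(net, config, k_retuned=k, feat_mean=mu,
                            feat_sd=sd, history=history)


def predict_patch(clf: ClassifierHandle, patch: Patch) -> float:
    """Probability that one patch is aggressive (deterministic)."""
    return float(clf.predict([patch])[0])


def predict_patches(clf: ClassifierHandle, patches) -> np.ndarray:
    return clf.predict(patches)


def score_patient(clf: ClassifierHandle, cores, masks,
                  patch_size: int = 256, decision_cutoff: float = 0.5,
                  min_tissue: float = 0.5) -> PatientScore:
    """Patient-level aggressive fraction from 50%-overlap tiling.

    All retained patches (tissue fraction >= ``min_tissue``) across the
    patient's cores are pooled; a patch counts as aggressive when its
    predicted probability reaches ``decision_cutoff``.  Raises when no
    patch survives the tissue filter.
    """
    if len(cores) == 0:
        raise ValueError("need at least one core")
    patches = []
    for core, mask in zip(cores, masks):
        patches.extend(extract_patches(core, mask, size=patch_size,
                                       stride=max(patch_size // 2, 1),
                                       min_tissue=min_tissue))
    if not patches:
        raise ValueError("no scorable tissue")
    probs = clf.predict(patches)
    n_aggressive = int(np.sum(probs >= decision_cutoff))
    return PatientScore(patient_id=cores[0].patient_id,
                        n_aggressive=n_aggressive, n_total=len(patches))


def calibrate_ratio_threshold(scores, labels) -> float:
    """Aggressive-fraction cut maximising Youden's J (sens + spec - 1).

    Candidates are the observed fractions; a patient is called high-risk
    when their fraction >= threshold.  Ties in J are broken toward the
    smaller threshold (higher sensitivity).
    """
    fracs = np.array([s.aggressive_fraction if isinstance(s, PatientScore)
                      else float(s) for s in scores])
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("need both outcome classes to calibrate")
    best_t, best_j = None, -np.inf
    for t in np.sort(np.unique(fracs)):
        pred = fracs >= t
        sens = float(pred[y == 1].mean())
        spec = float((~pred)[y == 0].mean())
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


@dataclass
class EvalMetrics:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    n_patients: int

    def to_dict(self) -> dict:
        return {"auc": self.auc, "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "threshold": self.threshold,
                "n_patients": self.n_patients}


def evaluate(scores, labels, threshold: float) -> EvalMetrics:
    """AUC (Mann-Whitney, ties 1/2) plus operating-point sensitivity and
    specificity of the aggressive fractions at ``threshold``."""
    fracs = np.array([s.aggressive_fraction if isinstance(s, PatientScore)
                      else float(s) for s in scores])
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("need both outcome classes to evaluate")
    pred = fracs >= threshold
    return EvalMetrics(
        auc=mann_whitney_auc(fracs, y),
        sensitivity=float(pred[y == 1].mean()),
        specificity=float((~pred)[y == 0].mean()),
        threshold=float(threshold),
        n_patients=len(y),
    )
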