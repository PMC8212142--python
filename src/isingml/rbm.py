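"""Classification RBM: one-hot label units joined to the visible layer.

Features are min-max rescaled to [0, 1] on the training data and treated as
Bernoulli activation probabilities.  Training is CD-1 with minibatches;
hidden units are binarized (Bernoulli samples of their sigmoid activation)
during training.  Prediction clamps the features and scores each candidate
label by the RBM free energy, which equals the exact conditional
Pr(label | features) obtained by summing out the hidden layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledDataset

__all__ = ["RBMModel", "rbm_train", "rbm_predict_proba", "rbm_predict",
           "rbm_to_json", "rbm_from_json"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass
class RBMModel:
    visible_hidden_weights: np.ndarray  # (M, H)
    label_hidden_weights: np.ndarray  # (K, H)
    visible_bias: np.ndarray  # (M,)
    label_bias: np.ndarray  # (K,)
    hidden_bias: np.ndarray  # (H,)
    feature_min: np.ndarray  # (M,) training min-max rescaling
    feature_range: np.ndarray  # (M,)
    class_names: list[str] = field(default_factory=list)
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for arr in (
            self.visible_hidden_weights,
            self.label_hidden_weights,
            self.visible_bias,
            self.label_bias,
            self.hidden_bias,
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite RBM parameters")

    @property
    def n_hidden(self) -> int:
        return self.hidden_bias.shape[0]

    @property
    def n_classes(self) -> int:
        return self.label_bias.shape[0]

    def rescale(self, x_mat: np.ndarray) -> np.ndarray:
        """Apply the training min-max transform, clipping to [0, 1]."""
        x2 = np.atleast_2d(np.asarray(x_mat, dtype=float))
        scaled = (x2 - self.feature_min) / self.feature_range
        return np.clip(scaled, 0.0, 1.0)


def rbm_train(
    dataset: LabeledDataset,
    n_hidden: int = 64,
    learning_rate: float = 0.1,
    n_epochs: int = 100,
    batch_size: int = 32,
    cd_k: int = 1,
    seed: int = 0,
) -> RBMModel:
    """Contrastive-divergence training of the joint [features || label] RBM."""
    if dataset.n_samples == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    m, k, h = dataset.n_features, dataset.n_classes, int(n_hidden)
    if h < 1:
        raise ValueError("n_hidden must be >= 1")

    feat_min = dataset.features.min(axis=0)
    feat_range = dataset.features.max(axis=0) - feat_min
    feat_range = np.where(feat_range == 0, 1.0, feat_range)
    x = np.clip((dataset.features - feat_min) / feat_range, 0.0, 1.0)
    labels_onehot = np.eye(k)[dataset.labels - 1]

    scale = 1.0 / np.sqrt(m + k + h)
    w = rng.uniform(-scale, scale, size=(m, h))
    u = rng.uniform(-scale, scale, size=(k, h))
    b_vis = np.zeros(m)
    b_lab = np.zeros(k)
    c_hid = np.zeros(h)

    n = dataset.n_samples
    for _ in range(n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            v0, l0 = x[idx], labels_onehot[idx]
            bsz = len(idx)

            h_prob = _sigmoid(v0 @ w + l0 @ u + c_hid)
            h_samp = (rng.random(h_prob.shape) < h_prob).astype(float)

            vk, lk, hk = v0, l0, h_samp
            for _ in range(cd_k):
                vk = _sigmoid(hk @ w.T + b_vis)
                lk_logits = hk @ u.T + b_lab
                lk_logits -= lk_logits.max(axis=1, keepdims=True)
                lk = np.exp(lk_logits)
                lk /= lk.sum(axis=1, keepdims=True)
                hk = _sigmoid(vk @ w + lk @ u + c_hid)

            lr = learning_rate / bsz
            w += lr * (v0.T @ h_samp - vk.T @ hk)
            u += lr * (l0.T @ h_samp - lk.T @ hk)
            b_vis += lr * (v0 - vk).sum(axis=0)
            b_lab += lr * (l0 - lk).sum(axis=0)
            c_hid += lr * (h_samp - hk).sum(axis=0)

    return RBMModel(
        visible_hidden_weights=w,
        label_hidden_weights=u,
        visible_bias=b_vis,
        label_bias=b_lab,
        hidden_bias=c_hid,
        feature_min=feat_min,
        feature_range=feat_range,
        class_names=list(dataset.class_names),
        hyperparams={
            "n_hidden": h,
            "learning_rate": learning_rate,
            "n_epochs": n_epochs,
            "batch_size": batch_size,
            "cd_k": cd_k,
            "seed": seed,
        },
    )


def rbm_predict_proba(model: RBMModel, x_mat: np.ndarray, rescale: bool = True) -> np.ndarray:
    """Pr(label | features) via free-energy scoring of each one-hot label.

    F(x, e_k) = -b_vis.x - b_lab[k] - sum_h softplus(c_h + (W^T x + U_k)_h);
    scores exp(-F) are normalized over k.
    """
    x2 = np.atleast_2d(np.asarray(x_mat, dtype=float))
    squeeze = np.asarray(x_mat).ndim == 1
    v = model.rescale(x2) if rescale else x2
    k = model.n_classes
    pre = v @ model.visible_hidden_weights  # (N, H)
    neg_free = np.empty((v.shape[0], k))
    for cls in range(k):
        act = pre + model.label_hidden_weights[cls]
        neg_free[:, cls] = (
            v @ model.visible_bias
            + model.label_bias[cls]
            + _softplus(act + model.hidden_bias).sum(axis=1)
        )
    neg_free -= neg_free.max(axis=1, keepdims=True)
    p = np.exp(neg_free)
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if squeeze else p


def rbm_predict(model: RBMModel, x_mat: np.ndarray) -> np.ndarray:
    p = np.atleast_2d(rbm_predict_proba(model, x_mat))
    return np.argmax(p, axis=1) + 1


def rbm_to_json(model: RBMModel) -> str:
    return json.dumps(
        {
            "visible_hidden_weights": model.visible_hidden_weights.tolist(),
            "label_hidden_weights": model.label_hidden_weights.tolist(),
            "visible_bias": model.visible_bias.tolist(),
            "label_bias": model.label_bias.tolist(),
            "hidden_bias": model.hidden_bias.tolist(),
            "feature_min": model.feature_min.tolist(),
            "feature_range": model.feature_range.tolist(),
            "class_names": model.class_names,
            "hyperparams": model.hyperparams,
        }
    )


def rbm_from_json(text: str) -> RBMModel:
    obj = json.loads(text)
    return RBMModel(
        visible_hidden_weights=np.asarray(obj["visible_hidden_weights"], dtype=float),
        label_hidden_weights=np.asarray(obj["label_hidden_weights"], dtype=float),
        visible_bias=np.asarray(obj["visible_bias"], dtype=float),
        label_bias=np.asarray(obj["label_bias"], dtype=float),
        hidden_bias=np.asarray(obj["hidden_bias"], dtype=float),
        feature_min=np.asarray(obj["feature_min"], dtype=float),
        feature_range=np.asarray(obj["feature_range"], dtype=float),
        class_names=list(obj["class_names"]),
        hyperparams=dict(obj["hyperparams"]),
    )
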