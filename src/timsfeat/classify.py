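"""Identifiability classification, threshold filtering, de-duplication and
cross-run feature matching.

The classifier predicts, from MS1 evidence alone, whether a detected feature
would be identified from its MS2 spectra.  Its four inputs are the feature's
deconvolution score, coelution coefficient, mobility coefficient and number of
isotopes.  The network is a feed-forward stack of 200-unit dense layers, each
followed by batch normalization, ReLU and 40% dropout, ending in a single
sigmoid unit; training minimizes binary cross-entropy with Adam on an 80/10/10
train/validation/test split with z-score standardization fit on the training
split.  All randomness (init, splits, batching, dropout) flows from one seed,
so runs are bit-reproducible.

Scored features below the identifiability threshold (default 0.2, chosen to
drop only the least likely to be identified) are removed, then duplicate
detections within 10 ppm, 20 scans and 5 s are collapsed keeping the
highest-scoring member of each connected group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import Feature

HIDDEN_WIDTH = 200
N_HIDDEN = 3
DROPOUT = 0.4
EPOCHS = 4000
BATCH_SIZE = 512
SPLIT = (0.8, 0.1, 0.1)
LEARNING_RATE = 1e-3
IDENTIFIABILITY_THRESHOLD = 0.2

DEDUP_PPM = 10.0
DEDUP_SCANS = 20
DEDUP_RT = 5.0

MATCH_TOL_PPM = 25.0
MATCH_TOL_RT = 5.0
MATCH_TOL_K0 = 0.05

INPUT_NAMES = (
    "deconvolution_score",
    "coelution_coefficient",
    "mobility_coefficient",
    "num_isotopes",
)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass
class ClassifierConfig:
    input_names: tuple[str, ...] = INPUT_NAMES
    hidden_width: int = HIDDEN_WIDTH
    n_hidden: int = N_HIDDEN
    dropout: float = DROPOUT
    epochs: int = EPOCHS
    batch_size: int = BATCH_SIZE
    split: tuple[float, float, float] = SPLIT
    seed: int = 0
    learning_rate: float = LEARNING_RATE

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.hidden_width < 1 or self.n_hidden < 1:
            raise ValueError("network dimensions must be positive")


class IdentifiabilityClassifier:
    """Feed-forward sigmoid classifier over the four feature attributes.

    Hidden blocks are dense -> batch norm -> ReLU -> dropout; the trainable
    parameter count is ``sum over dense layers of (fan_in*width + width) +
    2*width per batch norm + (width + 1)`` for the output unit.
    """

    def __init__(self, config: ClassifierConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        self.gamma: list[np.ndarray] = []
        self.beta: list[np.ndarray] = []
        self.run_mean: list[np.ndarray] = []
        self.run_var: list[np.ndarray] = []
        fan_in = len(config.input_names)
        for _ in range(config.n_hidden):
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(fan_in, config.hidden_width))
            self.W.append(w)
            self.b.append(np.zeros(config.hidden_width))
            self.gamma.append(np.ones(config.hidden_width))
            self.beta.append(np.zeros(config.hidden_width))
            self.run_mean.append(np.zeros(config.hidden_width))
            self.run_var.append(np.ones(config.hidden_width))
            fan_in = config.hidden_width
        self.W.append(rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(fan_in, 1)))
        self.b.append(np.zeros(1))
        # input standardization, fit on the training split
        self.x_mean = np.zeros(len(config.input_names))
        self.x_std = np.ones(len(config.input_names))
        self.trained = False

    # ---- architecture ----------------------------------------------------

    def n_parameters(self) -> int:
        """Trainable parameters: dense weights+biases plus batch-norm
        scale/shift pairs."""
        n = sum(w.size + b.size for w, b in zip(self.W, self.b))
        n += sum(g.size + bt.size for g, bt in zip(self.gamma, self.beta))
        return n

    # ---- forward / backward ---------------------------------------------

    def _forward(self, x, training, rng=None):
        cache = []
        h = x
        cfg = self.config
        for i in range(cfg.n_hidden):
            a = h @ self.W[i] + self.b[i]
            if training:
                mu = a.mean(axis=0)
                var = a.var(axis=0)
                self.run_mean[i] = _BN_MOMENTUM * self.run_mean[i] + (1 - _BN_MOMENTUM) * mu
                self.run_var[i] = _BN_MOMENTUM * self.run_var[i] + (1 - _BN_MOMENTUM) * var
            else:
                mu, var = self.run_mean[i], self.run_var[i]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (a - mu) * inv_std
            bn = self.gamma[i] * xhat + self.beta[i]
            relu = np.maximum(bn, 0.0)
            if training and cfg.dropout > 0:
                mask = (rng.random(relu.shape) >= cfg.dropout) / (1 - cfg.dropout)
                out = relu * mask
            else:
                mask = None
                out = relu
            cache.append((h, a, xhat, inv_std, bn, mask))
            h = out
        logits = h @ self.W[-1] + self.b[-1]
        p = 1.0 / (1.0 + np.exp(-logits))
        cache.append(h)
        return p, cache

    def _backward(self, p, y, cache):
        cfg = self.config
        B = len(y)
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        grads_g = [None] * cfg.n_hidden
        grads_bt = [None] * cfg.n_hidden
        h_last = cache[-1]
        dz = (p - y.reshape(-1, 1)) / B          # d(BCE)/d(logits)
        grads_W[-1] = h_last.T @ dz
        grads_b[-1] = dz.sum(axis=0)
        dh = dz @ self.W[-1].T
        for i in range(cfg.n_hidden - 1, -1, -1):
            h_in, a, xhat, inv_std, bn, mask = cache[i]
            if mask is not None:
                dh = dh * mask
            dh = dh * (bn > 0)                   # ReLU
            grads_g[i] = (dh * xhat).sum(axis=0)
            grads_bt[i] = dh.sum(axis=0)
            dxhat = dh * self.gamma[i]
            n = dh.shape[0]
            da = (inv_std / n) * (
                n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
            )
            grads_W[i] = h_in.T @ da
            grads_b[i] = da.sum(axis=0)
            dh = da @ self.W[i].T
        return grads_W, grads_b, grads_g, grads_bt

    # ---- inference -------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = (np.asarray(X, float) - self.x_mean) / self.x_std
        p, _ = self._forward(X, training=False)
        return p.ravel()

    # ---- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            arrays[f"W{i}"], arrays[f"b{i}"] = w, b
        for i in range(self.config.n_hidden):
            arrays[f"gamma{i}"] = self.gamma[i]
            arrays[f"beta{i}"] = self.beta[i]
            arrays[f"rmean{i}"] = self.run_mean[i]
            arrays[f"rvar{i}"] = self.run_var[i]
        arrays["x_mean"], arrays["x_std"] = self.x_mean, self.x_std
        cfg = self.config
        meta = dict(
            hidden_width=cfg.hidden_width, n_hidden=cfg.n_hidden,
            dropout=cfg.dropout, epochs=cfg.epochs, batch_size=cfg.batch_size,
            split=list(cfg.split), seed=cfg.seed, learning_rate=cfg.learning_rate,
            trained=self.trained,
        )
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "IdentifiabilityClassifier":
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        cfg = ClassifierConfig(
            hidden_width=meta["hidden_width"], n_hidden=meta["n_hidden"],
            dropout=meta["dropout"], epochs=meta["epochs"],
            batch_size=meta["batch_size"], split=tuple(meta["split"]),
            seed=meta["seed"], learning_rate=meta["learning_rate"],
        )
        model = cls(cfg)
        for i in range(len(model.W)):
            model.W[i] = data[f"W{i}"]
            model.b[i] = data[f"b{i}"]
        for i in range(cfg.n_hidden):
            model.gamma[i] = data[f"gamma{i}"]
            model.beta[i] = data[f"beta{i}"]
            model.run_mean[i] = data[f"rmean{i}"]
            model.run_var[i] = data[f"rvar{i}"]
        model.x_mean = data["x_mean"]
        model.x_std = data["x_std"]
        model.trained = meta["trained"]
        return model


def build_classifier(config: ClassifierConfig) -> IdentifiabilityClassifier:
    return IdentifiabilityClassifier(config)


def train_classifier(
    model: IdentifiabilityClassifier,
    X: np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig | None = None,
) -> tuple[IdentifiabilityClassifier, dict]:
    """Train with Adam on BCE; returns the model and metrics including
    held-out test accuracy and the per-epoch training-loss curve."""
    config = config or model.config
    X = np.asarray(X, float)
    y = np.asarray(y, np.int64)
    if len(X) < 50:
        raise ValueError("need at least 50 labelled features")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(X))
    n_train = int(round(config.split[0] * len(X)))
    n_val = int(round(config.split[1] * len(X)))
    tr, va, te = (perm[:n_train], perm[n_train:n_train + n_val],
                  perm[n_train + n_val:])

    model.x_mean = X[tr].mean(axis=0)
    model.x_std = X[tr].std(axis=0)
    model.x_std[model.x_std == 0] = 1.0
    Xs = (X - model.x_mean) / model.x_std

    params = model.W + model.b + model.gamma + model.beta
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(tr)
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            if len(batch) < 2:
                continue  # batch norm needs at least two rows
            p, cache = model._forward(Xs[batch], training=True, rng=rng)
            yb = y[batch]
            pc = np.clip(p.ravel(), 1e-12, 1 - 1e-12)
            losses.append(float(-np.mean(
                yb * np.log(pc) + (1 - yb) * np.log(1 - pc))))
            gW, gb, gg, gbt = model._backward(p, yb, cache)
            grads = gW + gb + gg + gbt
            step += 1
            for pi, (par, g) in enumerate(zip(params, grads)):
                m_t[pi] = beta1 * m_t[pi] + (1 - beta1) * g
                v_t[pi] = beta2 * v_t[pi] + (1 - beta2) * g * g
                mhat = m_t[pi] / (1 - beta1 ** step)
                vhat = v_t[pi] / (1 - beta2 ** step)
                par -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        history.append(float(np.mean(losses)) if losses else np.nan)

    model.trained = True

    def accuracy(idx):
        if len(idx) == 0:
            return np.nan
        p, _ = model._forward(Xs[idx], training=False)
        return float(np.mean((p.ravel() >= 0.5) == y[idx]))

    metrics = {
        "train_accuracy": accuracy(tr),
        "val_accuracy": accuracy(va),
        "test_accuracy": accuracy(te),
        "loss_history": history,
        "n_train": len(tr), "n_val": len(va), "n_test": len(te),
    }
    return model, metrics


# ---- filtering, de-duplication, matching --------------------------------


def classify_and_filter(
    features: list[Feature],
    model: IdentifiabilityClassifier,
    threshold: float = IDENTIFIABILITY_THRESHOLD,
) -> list[Feature]:
    """Annotate each feature with its identifiability score and drop those
    below the threshold, preserving order."""
    if not features:
        return []
    X = np.array([f.classifier_inputs for f in features], float)
    if not np.isfinite(X).all():
        raise ValueError("features carry non-finite classifier inputs")
    scores = model.predict_proba(X)
    out = []
    for f, s in zip(features, scores):
        f.identifiability_score = float(s)
        if s >= threshold:
            out.append(f)
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _dedup_linked(a: Feature, b: Feature, tol_ppm, tol_scans, tol_rt) -> bool:
    ppm = abs(a.mono_mz - b.mono_mz) / max(a.mono_mz, b.mono_mz) * 1e6
    return (
        ppm <= tol_ppm
        and abs(a.scan_apex - b.scan_apex) <= tol_scans
        and abs(a.rt_apex - b.rt_apex) <= tol_rt
    )


def deduplicate(
    features: list[Feature],
    tol_ppm: float = DEDUP_PPM,
    tol_scans: int = DEDUP_SCANS,
    tol_rt: float = DEDUP_RT,
) -> list[Feature]:
    """Collapse duplicate detections: among each single-linkage group of
    features within all three tolerances, keep the highest identifiability
    score (ties: higher intensity, then lower m/z).  Idempotent."""
    n = len(features)
    if n <= 1:
        return list(features)
    order = sorted(range(n), key=lambda i: features[i].mono_mz)
    uf = _UnionFind(n)
    for a_pos, i in enumerate(order):
        fi = features[i]
        for j in order[a_pos + 1:]:
            fj = features[j]
            if (fj.mono_mz - fi.mono_mz) / fj.mono_mz * 1e6 > tol_ppm:
                break
            if _dedup_linked(fi, fj, tol_ppm, tol_scans, tol_rt):
                uf.union(i, j)
    best: dict[int, int] = {}
    for i in range(n):
        root = uf.find(i)
        f = features[i]
        score = f.identifiability_score if f.identifiability_score is not None else 0.0
        key = (score, f.intensity, -f.mono_mz)
        if root not in best:
            best[root] = i
        else:
            g = features[best[root]]
            gscore = (g.identifiability_score
                      if g.identifiability_score is not None else 0.0)
            if key > (gscore, g.intensity, -g.mono_mz):
                best[root] = i
    keep = sorted(best.values())
    return [features[i] for i in keep]


def match_feature_sets(
    a: list[Feature],
    b: list[Feature],
    tol_ppm: float = MATCH_TOL_PPM,
    tol_rt: float = MATCH_TOL_RT,
    tol_inv_k0: float = MATCH_TOL_K0,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy one-to-one matching of two feature sets by apex proximity.

    A pair qualifies when apexes agree within `tol_ppm` m/z, `tol_rt` seconds
    and `tol_inv_k0` mobility; qualifying pairs are claimed closest-in-ppm
    first, each feature at most once.  Returns (pairs of indices, unmatched
    indices in `a`, unmatched indices in `b`).  Greedy matching can differ
    from the optimal assignment by at most a small margin on dense data.
    """
    cands = []
    for i, fa in enumerate(a):
        for j, fb in enumerate(b):
            ppm = abs(fa.mono_mz - fb.mono_mz) / max(fa.mono_mz, fb.mono_mz) * 1e6
            if ppm > tol_ppm:
                continue
            if abs(fa.rt_apex - fb.rt_apex) > tol_rt:
                continue
            ka, kb = fa.inv_k0_apex, fb.inv_k0_apex
            if ka is not None and kb is not None and abs(ka - kb) > tol_inv_k0:
                continue
            cands.append((ppm, i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    un_a = [i for i in range(len(a)) if i not in used_a]
    un_b = [j for j in range(len(b)) if j not in used_b]
    return pairs, un_a, un_b
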