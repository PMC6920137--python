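"""Four-class (bi)LSTM sequence classifier, implemented in NumPy.

The network is small — sequences of 3 time steps with 8 features (the 8x3
relative-power matrix with time as the sequence axis), one or two (optionally
bidirectional) LSTM layers of 20-200 hidden units, a fully connected layer
and a softmax over the four event classes.  Forward pass, backpropagation
through time and the Adam optimizer are written directly with NumPy: at this
scale that is fast, dependency-free and bit-for-bit reproducible from a seed.

The model object follows the fit/results convention: :class:`EventClassifier`
is built from training events and a config; ``fit()`` returns
:class:`EventClassifierResults` carrying the trained weights, the loss
history, prediction and evaluation methods and a ``summary()`` table.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .baseline_detector import CLASS_ORDER, EventLabel
from .evaluation import EvalReport, aggregate, compute_metrics, confusion_matrix
from .event_dataset import EventFeature, GroundTruthSet, SplitSpec, make_splits

_LABEL_INDEX = {lab: i for i, lab in enumerate(CLASS_ORDER)}


@dataclass
class LstmConfig:
    """Architecture and training hyperparameters.

    ``n_iterations`` counts optimizer steps (mini-batch updates).  Training
    uses Adam (lr 1e-3), batch size 128 and gradient clipping at global norm
    1; all exposed here.  ``log_transform`` applies log(1+x) to the relative
    powers before training, compressing the 1-50x dynamic range.
    """

    hidden_units: int = 200
    layers: int = 1
    bidirectional: bool = True
    dropout_p: float = 0.0
    n_iterations: int = 1000
    learning_rate: float = 1e-3
    batch_size: int = 128
    clip_norm: float = 1.0
    log_transform: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.layers not in (1, 2):
            raise ValueError("layers must be 1 or 2")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class _LstmDirection:
    """One direction of one LSTM layer.  Gate order: input, forget, cell, output."""

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int):
        h = hidden
        self.W = _glorot(rng, (d_in, 4 * h))
        self.U = _glorot(rng, (h, 4 * h))
        self.b = np.zeros(4 * h)
        self.b[h:2 * h] = 1.0  # unit forget-gate bias
        self.h = h

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.U, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, D) -> h_seq (B, T, H); caches intermediates."""
        B, T, _ = x.shape
        h = self.h
        hs = np.zeros((B, T + 1, h))
        cs = np.zeros((B, T + 1, h))
        gates = np.zeros((B, T, 4 * h))
        for t in range(T):
            z = x[:, t] @ self.W + hs[:, t] @ self.U + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            cs[:, t + 1] = f * cs[:, t] + i * g
            hs[:, t + 1] = o * np.tanh(cs[:, t + 1])
            gates[:, t] = np.concatenate([i, f, g, o], axis=1)
        self._cache = (x, hs, cs, gates)
        return hs[:, 1:]

    def backward(self, dh_seq: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """dh_seq: (B, T, H) gradient on every output step; returns
        (dx (B,T,D), [dW, dU, db])."""
        x, hs, cs, gates = self._cache
        B, T, _ = x.shape
        h = self.h
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :h]
            f = gates[:, t, h:2 * h]
            g = gates[:, t, 2 * h:3 * h]
            o = gates[:, t, 3 * h:]
            tanh_c = np.tanh(cs[:, t + 1])
            dh = dh_seq[:, t] + dh_next
            dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
            dzo = dh * tanh_c * o * (1.0 - o)
            dzi = dc * g * i * (1.0 - i)
            dzf = dc * cs[:, t] * f * (1.0 - f)
            dzg = dc * i * (1.0 - g ** 2)
            dz = np.concatenate([dzi, dzf, dzg, dzo], axis=1)
            dW += x[:, t].T @ dz
            dU += hs[:, t].T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return dx, [dW, dU, db]


class _LstmLayer:
    """(Bi)directional LSTM layer with 'sequence' or 'last' output mode."""

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int,
                 bidirectional: bool, return_sequences: bool):
        self.fwd = _LstmDirection(rng, d_in, hidden)
        self.bwd = _LstmDirection(rng, d_in, hidden) if bidirectional else None
        self.return_sequences = return_sequences
        self.d_out = hidden * (2 if bidirectional else 1)

    @property
    def params(self) -> list[np.ndarray]:
        p = self.fwd.params
        if self.bwd is not None:
            p = p + self.bwd.params
        return p

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)                        # (B, T, H)
        if self.bwd is None:
            return hf if self.return_sequences else hf[:, -1]
        hb_rev = self.bwd.forward(x[:, ::-1])           # reversed time
        hb = hb_rev[:, ::-1]
        if self.return_sequences:
            return np.concatenate([hf, hb], axis=2)
        # last forward state and the backward state that saw the whole sequence
        return np.concatenate([hf[:, -1], hb_rev[:, -1]], axis=1)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        h = self.fwd.h
        B = dout.shape[0]
        T = self.fwd._cache[0].shape[1]
        if self.return_sequences:
            df = dout[:, :, :h] if self.bwd is not None else dout
        else:
            df = np.zeros((B, T, h))
            df[:, -1] = dout[:, :h] if self.bwd is not None else dout
        dx, grads = self.fwd.backward(df)
        if self.bwd is not None:
            if self.return_sequences:
                db_rev = dout[:, ::-1, h:]
            else:
                db_rev = np.zeros((B, T, h))
                db_rev[:, -1] = dout[:, h:]
            dxb_rev, grads_b = self.bwd.backward(db_rev)
            dx = dx + dxb_rev[:, ::-1]
            grads = grads + grads_b
        return dx, grads


class _Network:
    """LSTM stack -> fully connected -> softmax over 4 classes."""

    def __init__(self, config: LstmConfig, n_features: int = 8):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.layers: list[_LstmLayer] = []
        d = n_features
        for li in range(config.layers):
            last = li == config.layers - 1
            layer = _LstmLayer(rng, d, config.hidden_units,
                               config.bidirectional, return_sequences=not last)
            self.layers.append(layer)
            d = layer.d_out
        self.Wfc = _glorot(rng, (d, len(CLASS_ORDER)))
        self.bfc = np.zeros(len(CLASS_ORDER))

    @property
    def params(self) -> list[np.ndarray]:
        p: list[np.ndarray] = []
        for layer in self.layers:
            p.extend(layer.params)
        p.extend([self.Wfc, self.bfc])
        return p

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Returns softmax probabilities (B, 4)."""
        p = self.config.dropout_p
        self._drop_masks = []
        for layer in self.layers:
            x = layer.forward(x)
            if p > 0 and train:
                mask = (rng.random(x.shape) >= p) / (1.0 - p)
                x = x * mask
                self._drop_masks.append(mask)
            else:
                self._drop_masks.append(None)
        self._fc_in = x
        logits = x @ self.Wfc + self.bfc
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, probs: np.ndarray, y_onehot: np.ndarray) -> list[np.ndarray]:
        """Gradients of mean cross-entropy; order matches ``params``."""
        B = probs.shape[0]
        dlogits = (probs - y_onehot) / B
        dWfc = self._fc_in.T @ dlogits
        dbfc = dlogits.sum(axis=0)
        dx = dlogits @ self.Wfc.T
        grads_rev: list[list[np.ndarray]] = []
        for li in range(len(self.layers) - 1, -1, -1):
            mask = self._drop_masks[li]
            if mask is not None:
                dx = dx * mask
            dx, g = self.layers[li].backward(dx)
            grads_rev.append(g)
        grads: list[np.ndarray] = []
        for g in reversed(grads_rev):
            grads.extend(g)
        grads.extend([dWfc, dbfc])
        return grads


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _clip_global_norm(grads: list[np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale


def events_to_arrays(events: list[EventFeature]) -> tuple[np.ndarray, np.ndarray]:
    """Stack events into (X (N, 3, 8) sequence-major, y (N,) class indices)."""
    X = np.stack([e.features.T for e in events])  # time axis first
    y = np.array([_LABEL_INDEX[e.label] for e in events], dtype=int)
    return X, y


def _data_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


class EventClassifier:
    """Model object: training data plus architecture/optimizer config.

    Build from a list of :class:`EventFeature` (or arrays via
    :meth:`from_arrays`), then call :meth:`fit`.
    """

    def __init__(self, train_events: list[EventFeature],
                 config: LstmConfig | None = None):
        config = config or LstmConfig()
        X, y = events_to_arrays(train_events)
        self._init(X, y, config)

    @classmethod
    def from_arrays(cls, X: np.ndarray, y: np.ndarray,
                    config: LstmConfig | None = None) -> "EventClassifier":
        obj = cls.__new__(cls)
        obj._init(np.asarray(X, float), np.asarray(y, int), config or LstmConfig())
        return obj

    def _init(self, X: np.ndarray, y: np.ndarray, config: LstmConfig) -> None:
        if X.ndim != 3 or X.shape[1:] != (3, 8):
            raise ValueError("X must have shape (n_events, 3, 8)")
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(np.unique(y)) < 2 and config.n_iterations > 0:
            raise ValueError("degenerate training set: a single class cannot "
                             "train a 4-class network")
        self.X, self.y, self.config = X, y, config

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return np.log1p(X) if self.config.log_transform else X

    def fit(self, seed: int | None = None) -> "EventClassifierResults":
        """Run ``n_iterations`` Adam steps of softmax cross-entropy training.

        Deterministic: the same data and seed give identical weights and
        predictions.  ``seed`` overrides ``config.seed`` for initialization
        and batch shuffling.
        """
        config = self.config if seed is None else replace(self.config, seed=seed)
        net = _Network(config)
        rng = np.random.default_rng(config.seed + 1)
        Xt = self._transform(self.X)
        y_onehot = np.eye(len(CLASS_ORDER))[self.y]
        opt = _Adam(net.params, config.learning_rate)
        n = len(Xt)
        order = rng.permutation(n)
        pos = 0
        losses = []
        params = net.params
        for _ in range(config.n_iterations):
            if pos + config.batch_size > n:
                order = rng.permutation(n)
                pos = 0
            idx = order[pos: pos + config.batch_size]
            pos += config.batch_size
            probs = net.forward(Xt[idx], train=True, rng=rng)
            loss = -np.mean(np.log(np.maximum(probs[np.arange(len(idx)),
                                                    self.y[idx]], 1e-12)))
            losses.append(float(loss))
            grads = net.backward(probs, y_onehot[idx])
            _clip_global_norm(grads, config.clip_norm)
            opt.step(params, grads)
        manifest = {
            "data_hash": _data_hash(self.X, self.y),
            "seed": config.seed,
            "n_iterations": config.n_iterations,
            "n_train": n,
        }
        return EventClassifierResults(self, net, np.array(losses), manifest)


class EventClassifierResults:
    """Trained classifier: weights, loss history, prediction and evaluation."""

    def __init__(self, model: EventClassifier, net: _Network,
                 loss_history: np.ndarray, manifest: dict):
        self.model = model
        self._net = net
        self.loss_history = loss_history
        self.manifest = manifest

    @property
    def n_params(self) -> int:
        return self._net.n_params()

    def predict_proba(self, events) -> np.ndarray:
        """Class probabilities, shape (n_events, 4)."""
        X = events if isinstance(events, np.ndarray) else events_to_arrays(events)[0]
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (3, 8):
            raise ValueError("events must be shaped (n, 3, 8)")
        return self._net.forward(self.model._transform(X), train=False)

    def predict(self, events) -> np.ndarray:
        """Class indices in the fixed order; exact ties break toward the
        first (spike-most) class, which argmax guarantees."""
        return np.argmax(self.predict_proba(events), axis=1)

    def predict_labels(self, events) -> list[EventLabel]:
        return [CLASS_ORDER[i] for i in self.predict(events)]

    def evaluate(self, events: list[EventFeature]) -> EvalReport:
        X, y = events_to_arrays(events)
        pred = self.predict(X)
        return compute_metrics(confusion_matrix(y, pred))

    def save(self, path) -> None:
        """Checkpoint weights + config + training manifest to an .npz file."""
        import json

        c = self.model.config
        arrays = {f"p{i}": p for i, p in enumerate(self._net.params)}
        meta = {"config": {k: getattr(c, k) for k in (
                    "hidden_units", "layers", "bidirectional", "dropout_p",
                    "n_iterations", "learning_rate", "batch_size", "clip_norm",
                    "log_transform", "seed")},
                "manifest": self.manifest}
        np.savez(path, _meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8),
            loss_history=self.loss_history, **arrays)

    @classmethod
    def load(cls, path) -> "EventClassifierResults":
        """Restore a checkpoint written by :meth:`save`.

        The returned results object predicts and evaluates; its ``model``
        holds the config but no training data.
        """
        import json

        with np.load(path) as z:
            meta = json.loads(bytes(z["_meta"]).decode())
            loss = z["loss_history"]
            arrays = [z[f"p{i}"] for i in range(sum(1 for k in z.files
                                                    if k.startswith("p")))]
        config = LstmConfig(**meta["config"])
        net = _Network(config)
        for p, saved in zip(net.params, arrays):
            p[...] = saved
        model = EventClassifier.__new__(EventClassifier)
        model.config = config
        model.X = model.y = None
        return cls(model, net, loss, meta["manifest"])

    def summary(self) -> str:
        c = self.model.config
        arch = f"{'bi' if c.bidirectional else ''}LSTM x{c.layers} (HU={c.hidden_units})"
        lines = [
            "EventClassifier results",
            "=" * 46,
            f"architecture : {arch} -> FC(4) -> softmax",
            f"parameters   : {self.n_params}",
            f"dropout      : {c.dropout_p}",
            f"iterations   : {c.n_iterations} (Adam lr={c.learning_rate}, "
            f"batch={c.batch_size})",
            f"train events : {self.manifest['n_train']}",
            f"data hash    : {self.manifest['data_hash']}",
            f"seed         : {self.manifest['seed']}",
        ]
        if len(self.loss_history):
            lines.append(f"loss         : {self.loss_history[0]:.4f} -> "
                         f"{self.loss_history[-1]:.4f}")
        return "\n".join(lines)


def lstm_parameter_count(hidden_units: int, n_features: int = 8,
                         bidirectional: bool = True, layers: int = 1,
                         n_classes: int = 4) -> int:
    """Closed-form parameter count of the LSTM stack plus the FC layer."""
    h = hidden_units
    ndir = 2 if bidirectional else 1
    total = 0
    d = n_features
    for _ in range(layers):
        total += ndir * 4 * (h * (d + h) + h)
        d = ndir * h
    total += d * n_classes + n_classes
    return total


def run_experiment(scenario: str, gt: GroundTruthSet, split: SplitSpec,
                   config: LstmConfig,
                   holdout_gt: GroundTruthSet | None = None,
                   ) -> dict:
    """Train/test per the validation scenarios and aggregate mean±SD.

    ``scenario``:

    * ``within_subject`` — one network per subject; keys = subject id.
    * ``between_subjects`` — train on one subject, test on every subject
      (diagonal = within-subject); keys = (train_subject, test_subject).
    * ``global`` — pool all subjects for training, evaluate per subject;
      keys = subject id.
    * ``cross_site`` — global training plus evaluation on every subject of a
      second, held-out dataset (``holdout_gt`` required).

    Returns a dict mapping keys to aggregated :class:`EvalReport`.
    """
    if scenario not in ("within_subject", "between_subjects", "global", "cross_site"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "cross_site" and holdout_gt is None:
        raise ValueError("cross_site scenario needs a held-out dataset")
    splits = make_splits(gt, split)
    subjects = gt.subjects
    per_key: dict = {}

    def _subject_events(events, subject):
        return [e for e in events if e.subject_id == subject]

    for r, (train, test) in enumerate(splits):
        seed_r = config.seed + 1000 * r
        cfg = replace(config, seed=seed_r)
        if scenario in ("global", "cross_site"):
            res = EventClassifier(train, cfg).fit()
            for s in subjects:
                ev = _subject_events(test, s)
                if ev:
                    per_key.setdefault(s, []).append(res.evaluate(ev))
            if holdout_gt is not None:
                rng = np.random.default_rng(split.seed + 7919 * (r + 1))
                for s in holdout_gt.subjects:
                    ev = []
                    for lab in CLASS_ORDER:
                        cell = holdout_gt.events(s, lab)
                        if not cell:
                            continue
                        k = min(split.n_test, len(cell))
                        idx = rng.choice(len(cell), size=k, replace=False)
                        ev.extend(cell[i] for i in idx)
                    if ev:
                        per_key.setdefault(s, []).append(res.evaluate(ev))
        elif scenario == "within_subject":
            for s in subjects:
                tr = _subject_events(train, s)
                te = _subject_events(test, s)
                if not tr or not te:
                    continue
                res = EventClassifier(tr, cfg).fit()
                per_key.setdefault(s, []).append(res.evaluate(te))
        else:  # between_subjects
            for s_train in subjects:
                tr = _subject_events(train, s_train)
                if not tr:
                    continue
                res = EventClassifier(tr, cfg).fit()
                for s_test in subjects:
                    te = _subject_events(test, s_test)
                    if te:
                        per_key.setdefault((s_train, s_test), []).append(
                            res.evaluate(te))
    return {k: aggregate(v) for k, v in per_key.items()}


def experiment_table(results: dict) -> "object":
    """Results dict -> tidy pandas DataFrame (one row per key x class, with
    mean and SD columns), shaped like the scenario grids."""
    import pandas as pd

    rows = []
    for key, rep in results.items():
        base = {"key": key if isinstance(key, str) else "/".join(key),
                "acc_mean": rep.acc, "acc_sd": rep.sd_acc}
        for i, name in enumerate(rep.class_names):
            rows.append({**base, "class": name,
                         "sens_mean": rep.sens[i], "sens_sd": rep.sd_sens[i],
                         "spec_mean": rep.spec[i], "spec_sd": rep.sd_spec[i]})
    return pd.DataFrame(rows)
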