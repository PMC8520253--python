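"""Small, seeded, pure-NumPy text classifiers: a multi-width convolutional
network and a bidirectional recurrent network.

Both train with softmax cross-entropy (the two-class equivalent of binary
cross-entropy) under Adam.  Everything is deterministic given the config
seed: weight init, batch shuffling and hence the fitted parameters.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ..preprocessing import PAD_ID, UNK_ID, EncodedExample


def _examples_to_matrix(examples: Sequence[EncodedExample]) -> np.ndarray:
    X = np.asarray([e.ids for e in examples], dtype=np.int64)
    if X.ndim != 2:
        raise ValueError("examples must share a single encoded length")
    return X


def _labels(examples: Sequence[EncodedExample]) -> np.ndarray:
    y = [e.label for e in examples]
    if any(v is None for v in y):
        raise ValueError("all training examples must be labeled")
    return np.asarray(y, dtype=np.int64)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_global(grads: dict[str, np.ndarray], max_norm: float = 5.0) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale


class _NumpyClassifierBase:
    """Shared fit loop; subclasses implement _init_params / _forward / _backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] | None = None
        self._L: int | None = None

    # -- subclass hooks -----------------------------------------------------
    def _init_params(self, vocab_size: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def _forward(self, X: np.ndarray, train: bool) -> tuple[np.ndarray, dict]:
        raise NotImplementedError

    def _backward(self, X: np.ndarray, probs: np.ndarray, y: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        raise NotImplementedError

    # -- public API ---------------------------------------------------------
    def fit(self, examples: Sequence[EncodedExample], cfg) -> "_NumpyClassifierBase":
        X = _examples_to_matrix(examples)
        y = _labels(examples)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        self._L = X.shape[1]
        vocab_size = int(X.max()) + 1
        self._vocab_size = max(vocab_size, 4)
        rng = np.random.default_rng(cfg.seed)
        self.params = self._init_params(self._vocab_size, rng)
        opt = _Adam(self.params, cfg.learning_rate)
        n = X.shape[0]
        for _epoch in range(self._epochs(cfg)):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                probs, cache = self._forward(X[idx], train=True)
                grads = self._backward(X[idx], probs, y[idx], cache)
                _clip_global(grads)
                opt.step(grads)
        return self

    def _epochs(self, cfg) -> int:
        return cfg.epochs_cnn_rnn

    def predict_proba(self, examples: Sequence[EncodedExample]) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("classifier not fitted")
        X = _examples_to_matrix(examples)
        if X.shape[1] != self._L:
            raise ValueError(f"encoded length {X.shape[1]} != fitted length {self._L}")
        X = np.where(X >= self._vocab_size, UNK_ID, X)  # ids unseen in training -> unk
        out = []
        for start in range(0, X.shape[0], 512):
            probs, _ = self._forward(X[start : start + 512], train=False)
            out.append(probs)
        return np.concatenate(out, axis=0) if out else np.zeros((0, 2))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "L": self._L,
            "vocab_size": self._vocab_size,
            "params": {k: v.tolist() for k, v in self.params.items()},
            "hyper": self._hyper(),
        }

    def _hyper(self) -> dict:
        return {}

    def _restore(self, d: dict) -> None:
        self._L = d["L"]
        self._vocab_size = d["vocab_size"]
        self.params = {k: np.asarray(v, dtype=np.float64) for k, v in d["params"].items()}


class CNNClassifier(_NumpyClassifierBase):
    """Embedding -> parallel 1-D convolutions -> ReLU -> global max-pool ->
    dense softmax.  Defaults: widths (3, 4, 5), 100 feature maps per width,
    embedding dim 100 trained from scratch."""

    def __init__(self, embedding_dim: int = 100, filter_widths: tuple[int, ...] = (3, 4, 5), filters_per_width: int = 100):
        super().__init__()
        self.embedding_dim = embedding_dim
        self.filter_widths = tuple(filter_widths)
        self.filters_per_width = filters_per_width

    def _hyper(self) -> dict:
        return {
            "embedding_dim": self.embedding_dim,
            "filter_widths": list(self.filter_widths),
            "filters_per_width": self.filters_per_width,
        }

    def _init_params(self, vocab_size: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        d, F = self.embedding_dim, self.filters_per_width
        params = {"E": rng.normal(0.0, 0.1, size=(vocab_size, d))}
        params["E"][PAD_ID] = 0.0
        for w in self.filter_widths:
            scale = np.sqrt(2.0 / (w * d))
            params[f"W{w}"] = rng.normal(0.0, scale, size=(w * d, F))
            params[f"b{w}"] = np.zeros(F)
        hidden = F * len(self.filter_widths)
        params["Wo"] = rng.normal(0.0, np.sqrt(1.0 / hidden), size=(hidden, 2))
        params["bo"] = np.zeros(2)
        return params

    def _windows(self, emb: np.ndarray, w: int) -> np.ndarray:
        B, L, d = emb.shape
        P = L - w + 1
        s0, s1, s2 = emb.strides
        view = np.lib.stride_tricks.as_strided(emb, shape=(B, P, w, d), strides=(s0, s1, s1, s2))
        return view.reshape(B, P, w * d)

    def _forward(self, X: np.ndarray, train: bool) -> tuple[np.ndarray, dict]:
        p = self.params
        emb = p["E"][X]  # (B, L, d)
        pooled_parts, cache_parts = [], {}
        for w in self.filter_widths:
            win = self._windows(emb, w)  # (B, P, w*d)
            z = win @ p[f"W{w}"] + p[f"b{w}"]  # (B, P, F)
            a = np.maximum(z, 0.0)
            am = a.argmax(axis=1)  # (B, F)
            pooled = np.take_along_axis(a, am[:, None, :], axis=1)[:, 0, :]
            pooled_parts.append(pooled)
            if train:
                cache_parts[w] = (win, z, am)
        h = np.concatenate(pooled_parts, axis=1)
        logits = h @ p["Wo"] + p["bo"]
        probs = _softmax(logits)
        return probs, {"emb": emb, "h": h, "parts": cache_parts}

    def _backward(self, X: np.ndarray, probs: np.ndarray, y: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        B, L = X.shape
        F = self.filters_per_width
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads = {"Wo": cache["h"].T @ dlogits, "bo": dlogits.sum(axis=0)}
        dh = dlogits @ p["Wo"].T
        demb = np.zeros_like(cache["emb"])
        for i, w in enumerate(self.filter_widths):
            win, z, am = cache["parts"][w]
            dpooled = dh[:, i * F : (i + 1) * F]  # (B, F)
            P = z.shape[1]
            dz = np.zeros_like(z)
            rows = np.arange(B)[:, None]
            cols = np.arange(F)[None, :]
            gate = (np.take_along_axis(z, am[:, None, :], axis=1)[:, 0, :] > 0).astype(z.dtype)
            dz[rows, am, cols] = dpooled * gate
            grads[f"W{w}"] = win.reshape(B * P, -1).T @ dz.reshape(B * P, F)
            grads[f"b{w}"] = dz.sum(axis=(0, 1))
            dwin = (dz @ p[f"W{w}"].T).reshape(B, P, w, self.embedding_dim)
            for j in range(w):
                demb[:, j : j + P, :] += dwin[:, :, j, :]
        dE = np.zeros_like(p["E"])
        np.add.at(dE, X, demb)
        dE[PAD_ID] = 0.0
        grads["E"] = dE
        return grads

    @classmethod
    def from_dict(cls, d: dict) -> "CNNClassifier":
        h = d["hyper"]
        obj = cls(h["embedding_dim"], tuple(h["filter_widths"]), h["filters_per_width"])
        obj._restore(d)
        return obj


class RNNClassifier(_NumpyClassifierBase):
    """Embedding -> bidirectional tanh recurrence (masked so padding does not
    advance the state) -> pooled states -> dense softmax.

    ``pooling`` picks the readout: "max" (per-unit max over valid
    timesteps, the default — a plain tanh recurrence forgets keywords far
    from the readout position), "mean" (masked mean of hidden states) or
    "final" (last valid state only).
    """

    def __init__(self, embedding_dim: int = 100, hidden_size: int = 128, pooling: str = "max"):
        super().__init__()
        if pooling not in ("max", "mean", "final"):
            raise ValueError(f"unknown pooling {pooling!r}")
        self.embedding_dim = embedding_dim
        self.hidden_size = hidden_size
        self.pooling = pooling

    def _hyper(self) -> dict:
        return {"embedding_dim": self.embedding_dim, "hidden_size": self.hidden_size, "pooling": self.pooling}

    def _init_params(self, vocab_size: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        d, H = self.embedding_dim, self.hidden_size
        params = {"E": rng.normal(0.0, 0.1, size=(vocab_size, d))}
        params["E"][PAD_ID] = 0.0
        for dir_ in ("f", "b"):
            params[f"Wx_{dir_}"] = rng.normal(0.0, np.sqrt(1.0 / d), size=(d, H))
            params[f"Wh_{dir_}"] = rng.normal(0.0, np.sqrt(1.0 / H), size=(H, H))
            params[f"bh_{dir_}"] = np.zeros(H)
        params["Wo"] = rng.normal(0.0, np.sqrt(1.0 / (2 * H)), size=(2 * H, 2))
        params["bo"] = np.zeros(2)
        return params

    @staticmethod
    def _reverse_valid(X: np.ndarray) -> np.ndarray:
        """Reverse each row's non-pad prefix, keeping pads at the end."""
        out = np.full_like(X, PAD_ID)
        lengths = (X != PAD_ID).sum(axis=1)
        for i, ln in enumerate(lengths):
            out[i, :ln] = X[i, :ln][::-1]
        return out

    def _run_direction(self, X: np.ndarray, dir_: str, train: bool) -> tuple[np.ndarray, dict]:
        p = self.params
        emb = p["E"][X]  # (B, L, d)
        mask = (X != PAD_ID).astype(np.float64)[:, :, None]  # (B, L, 1)
        B, L, _ = emb.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        hs = np.zeros((B, L + 1, H)) if train else None
        ts = np.zeros((B, L, H)) if train else None
        Wx, Wh, bh = p[f"Wx_{dir_}"], p[f"Wh_{dir_}"], p[f"bh_{dir_}"]
        xw = emb @ Wx  # (B, L, H), hoisted out of the loop
        hsum = np.zeros((B, H))
        all_h = np.zeros((B, L, H)) if self.pooling == "max" else None
        for t in range(L):
            u = np.tanh(xw[:, t, :] + h @ Wh + bh)
            h = mask[:, t] * u + (1.0 - mask[:, t]) * h
            hsum += mask[:, t] * h
            if all_h is not None:
                all_h[:, t, :] = h
            if train:
                ts[:, t, :] = u
                hs[:, t + 1, :] = h
        lengths = np.maximum(mask.sum(axis=1), 1.0)  # (B, 1)
        am = None
        if self.pooling == "max":
            hvalid = np.where(mask > 0, all_h, -np.inf)
            am = hvalid.argmax(axis=1)  # (B, H)
            out = np.take_along_axis(all_h, am[:, None, :], axis=1)[:, 0, :]
        elif self.pooling == "mean":
            out = hsum / lengths
        else:
            out = h
        cache = {"emb": emb, "mask": mask, "hs": hs, "ts": ts, "lengths": lengths, "am": am} if train else {}
        return out, cache

    def _forward(self, X: np.ndarray, train: bool) -> tuple[np.ndarray, dict]:
        p = self.params
        Xr = self._reverse_valid(X)
        hf, cf = self._run_direction(X, "f", train)
        hb, cb = self._run_direction(Xr, "b", train)
        h = np.concatenate([hf, hb], axis=1)
        logits = h @ p["Wo"] + p["bo"]
        probs = _softmax(logits)
        return probs, {"h": h, "f": cf, "b": cb, "Xr": Xr}

    def _bptt(self, X: np.ndarray, dir_: str, dh_out: np.ndarray, cache: dict, grads: dict, dE: np.ndarray) -> None:
        p = self.params
        emb, mask, hs, ts = cache["emb"], cache["mask"], cache["hs"], cache["ts"]
        B, L, _ = emb.shape
        Wx, Wh = p[f"Wx_{dir_}"], p[f"Wh_{dir_}"]
        gWx = np.zeros_like(Wx)
        gWh = np.zeros_like(Wh)
        gbh = np.zeros_like(p[f"bh_{dir_}"])
        demb = np.zeros_like(emb)
        lengths = cache["lengths"]
        if self.pooling == "max":
            # route the pooled gradient to each unit's argmax timestep
            dh_at = np.zeros((B, L, self.hidden_size))
            rows = np.arange(B)[:, None]
            cols = np.arange(self.hidden_size)[None, :]
            dh_at[rows, cache["am"], cols] = dh_out
        dh = dh_out if self.pooling == "final" else np.zeros_like(dh_out)
        for t in range(L - 1, -1, -1):
            m = mask[:, t]
            if self.pooling == "mean":
                dh = dh + dh_out * m / lengths
            elif self.pooling == "max":
                dh = dh + dh_at[:, t, :]
            du = dh * m * (1.0 - ts[:, t, :] ** 2)
            gbh += du.sum(axis=0)
            gWx += emb[:, t, :].T @ du
            gWh += hs[:, t, :].T @ du
            demb[:, t, :] = du @ Wx.T
            dh = dh * (1.0 - m) + du @ Wh.T
        grads[f"Wx_{dir_}"] = gWx
        grads[f"Wh_{dir_}"] = gWh
        grads[f"bh_{dir_}"] = gbh
        # scatter embedding grads back to token ids (X here is already the
        # direction's input ordering, so indices line up with demb)
        np.add.at(dE, X, demb)

    def _backward(self, X: np.ndarray, probs: np.ndarray, y: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        B = X.shape[0]
        H = self.hidden_size
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads: dict[str, np.ndarray] = {"Wo": cache["h"].T @ dlogits, "bo": dlogits.sum(axis=0)}
        dh = dlogits @ p["Wo"].T
        dE = np.zeros_like(p["E"])
        self._bptt(X, "f", dh[:, :H], cache["f"], grads, dE)
        self._bptt(cache["Xr"], "b", dh[:, H:], cache["b"], grads, dE)
        dE[PAD_ID] = 0.0
        grads["E"] = dE
        return grads

    @classmethod
    def from_dict(cls, d: dict) -> "RNNClassifier":
        h = d["hyper"]
        obj = cls(h["embedding_dim"], h["hidden_size"], h.get("pooling", "max"))
        obj._restore(d)
        return obj
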