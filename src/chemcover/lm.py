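"""Autoregressive SMILES language model.

Architecture: token embedding -> stacked gated recurrent layers (GRU or
LSTM) -> linear projection -> softmax over the vocabulary.  Training uses
teacher forcing: the loss at step ``k`` conditions on the *true* previous
tokens of the training sequence, and is the sequence NLL

    NLL = -sum_k ln P(token_k | token_1 .. token_{k-1}),

in nats, averaged over the sequences of a batch.  Optimization is ADAM with
a geometric learning-rate decay from ``lr_start`` to ``lr_end`` across the
configured epochs.  Sampling draws tokens multinomially from the softmax,
starting after the begin marker and stopping at the end marker or at
``max_sequence_length``.

The network and backpropagation-through-time are implemented directly on
NumPy arrays, with gradients verified against finite differences in the test
suite; everything is deterministic given the configured seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .tokenizer import Vocabulary, build_vocabulary, decode, encode

__all__ = [
    "ModelConfig",
    "PAPER_PROFILE",
    "TOY_PROFILE",
    "SequenceNll",
    "SampledSequence",
    "SmilesLM",
    "TrainingResult",
    "train",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the SMILES language model.

    Defaults are the toy profile used throughout the offline benchmark;
    :data:`PAPER_PROFILE` preserves the full-scale reference setting
    (256-dim embedding, 3x512 GRU, batch 128).
    """

    embedding_dim: int = 32
    hidden_dim: int = 64
    num_layers: int = 1
    cell_type: str = "GRU"  # "GRU" or "LSTM"
    max_sequence_length: int = 50
    batch_size: int = 16
    lr_start: float = 1e-2
    lr_end: float = 1e-4
    epochs: int = 60
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 42

    def __post_init__(self) -> None:
        if self.cell_type not in ("GRU", "LSTM"):
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if self.lr_end > self.lr_start:
            raise ValueError("lr_end must not exceed lr_start")
        if min(self.embedding_dim, self.hidden_dim, self.num_layers) < 1:
            raise ValueError("dimensions must be positive")

    def lr_at(self, epoch: int) -> float:
        """Geometric decay: lr_start * c**(epoch-1), spanning to lr_end."""
        if self.epochs <= 1:
            return self.lr_start
        c = (self.lr_end / self.lr_start) ** (1.0 / (self.epochs - 1))
        return self.lr_start * c ** (epoch - 1)


#: Full-scale reference profile (kept for configuration, not for CI runs).
PAPER_PROFILE = ModelConfig(
    embedding_dim=256,
    hidden_dim=512,
    num_layers=3,
    batch_size=128,
    max_sequence_length=140,
    lr_start=1e-3,
    lr_end=1e-5,
    epochs=200,
)

TOY_PROFILE = ModelConfig()


@dataclass(frozen=True)
class SequenceNll:
    smiles: str
    nll: float  # nats, >= 0


@dataclass(frozen=True)
class SampledSequence:
    smiles: str
    nll: float
    truncated: bool = False  # hit max_sequence_length without emitting '$'


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


class _Adam:
    """Plain ADAM; state keyed like the parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], beta1: float, beta2: float, eps: float):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


class SmilesLM:
    """A stacked-GRU/LSTM SMILES language model over a fixed vocabulary."""

    def __init__(
        self,
        config: ModelConfig,
        vocab: Vocabulary,
        params: dict[str, np.ndarray] | None = None,
        rng: np.random.Generator | None = None,
    ):
        self.config = config
        self.vocab = vocab
        if params is not None:
            self.params = params
        else:
            if rng is None:
                rng = np.random.default_rng(config.seed)
            self.params = self._init_params(rng)

    # -- parameters ---------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        V, D, H = len(self.vocab), self.config.embedding_dim, self.config.hidden_dim
        gates = 3 if self.config.cell_type == "GRU" else 4
        k = 1.0 / np.sqrt(H)
        p: dict[str, np.ndarray] = {
            "embedding": rng.uniform(-0.1, 0.1, size=(V, D)),
            "W_out": rng.uniform(-k, k, size=(H, V)),
            "b_out": np.zeros(V),
        }
        for layer in range(self.config.num_layers):
            in_dim = D if layer == 0 else H
            p[f"W_ih{layer}"] = rng.uniform(-k, k, size=(in_dim, gates * H))
            p[f"W_hh{layer}"] = rng.uniform(-k, k, size=(H, gates * H))
            p[f"b_ih{layer}"] = np.zeros(gates * H)
            p[f"b_hh{layer}"] = np.zeros(gates * H)
        return p

    # -- recurrent cells ----------------------------------------------------

    def _gru_step(self, x, h_prev, layer):
        H = self.config.hidden_dim
        p = self.params
        gi = x @ p[f"W_ih{layer}"] + p[f"b_ih{layer}"]
        gh = h_prev @ p[f"W_hh{layer}"] + p[f"b_hh{layer}"]
        r = _sigmoid(gi[:, :H] + gh[:, :H])
        z = _sigmoid(gi[:, H : 2 * H] + gh[:, H : 2 * H])
        hn = gh[:, 2 * H :]
        n = np.tanh(gi[:, 2 * H :] + r * hn)
        h = (1 - z) * n + z * h_prev
        return h, (x, h_prev, r, z, n, hn)

    def _gru_back(self, dh, cache, layer, grads):
        H = self.config.hidden_dim
        x, h_prev, r, z, n, hn = cache
        dn = dh * (1 - z)
        dz = dh * (h_prev - n)
        dh_prev = dh * z
        dn_pre = dn * (1 - n * n)
        dr = dn_pre * hn
        d_hn = dn_pre * r
        dr_pre = dr * r * (1 - r)
        dz_pre = dz * z * (1 - z)
        d_gi = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
        d_gh = np.concatenate([dr_pre, dz_pre, d_hn], axis=1)
        p = self.params
        dx = d_gi @ p[f"W_ih{layer}"].T
        dh_prev = dh_prev + d_gh @ p[f"W_hh{layer}"].T
        grads[f"W_ih{layer}"] += x.T @ d_gi
        grads[f"W_hh{layer}"] += h_prev.T @ d_gh
        grads[f"b_ih{layer}"] += d_gi.sum(axis=0)
        grads[f"b_hh{layer}"] += d_gh.sum(axis=0)
        return dx, dh_prev

    def _lstm_step(self, x, state, layer):
        H = self.config.hidden_dim
        h_prev, c_prev = state
        p = self.params
        a = (
            x @ p[f"W_ih{layer}"]
            + h_prev @ p[f"W_hh{layer}"]
            + p[f"b_ih{layer}"]
            + p[f"b_hh{layer}"]
        )
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        return (h, c), (x, h_prev, c_prev, i, f, g, o, c)

    def _lstm_back(self, dh, dc, cache, layer, grads):
        x, h_prev, c_prev, i, f, g, o, c = cache
        tc = np.tanh(c)
        do = dh * tc
        dc = dc + dh * o * (1 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_prev = dc * f
        d_a = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        p = self.params
        dx = d_a @ p[f"W_ih{layer}"].T
        dh_prev = d_a @ p[f"W_hh{layer}"].T
        grads[f"W_ih{layer}"] += x.T @ d_a
        grads[f"W_hh{layer}"] += h_prev.T @ d_a
        grads[f"b_ih{layer}"] += d_a.sum(axis=0)
        grads[f"b_hh{layer}"] += d_a.sum(axis=0)
        return dx, dh_prev, dc_prev

    # -- batched forward / backward ----------------------------------------

    def _forward(self, ids: np.ndarray, mask: np.ndarray, need_cache: bool):
        """Teacher-forced pass.

        ``ids``: (B, T) padded token ids; ``mask``: (B, T-1) marks real target
        positions (everything up to and including the end marker).  Returns
        per-sequence NLLs plus the caches needed for backprop.
        """
        cfg = self.config
        B, T = ids.shape
        H, is_gru = cfg.hidden_dim, cfg.cell_type == "GRU"
        x_ids = ids[:, :-1]
        targets = ids[:, 1:]
        emb = self.params["embedding"]
        h = [np.zeros((B, H)) for _ in range(cfg.num_layers)]
        c = [np.zeros((B, H)) for _ in range(cfg.num_layers)]
        caches: list[list] = []
        tops = np.empty((T - 1, B, H))
        for t in range(T - 1):
            inp = emb[x_ids[:, t]]
            step_caches = []
            for layer in range(cfg.num_layers):
                if is_gru:
                    h[layer], cache = self._gru_step(inp, h[layer], layer)
                else:
                    (h[layer], c[layer]), cache = self._lstm_step(
                        inp, (h[layer], c[layer]), layer
                    )
                step_caches.append(cache)
                inp = h[layer]
            tops[t] = h[-1]
            if need_cache:
                caches.append(step_caches)
        logits = tops @ self.params["W_out"] + self.params["b_out"]  # (T-1, B, V)
        logp = _log_softmax(logits)
        tok_nll = -np.take_along_axis(
            logp, targets.T[:, :, None], axis=2
        )[:, :, 0]  # (T-1, B)
        seq_nll = (tok_nll * mask.T).sum(axis=0)  # (B,)
        return seq_nll, (x_ids, targets, mask, logp, tops, caches)

    def _backward(self, fwd_cache) -> dict[str, np.ndarray]:
        """Gradient of mean-per-sequence NLL w.r.t. all parameters."""
        cfg = self.config
        x_ids, targets, mask, logp, tops, caches = fwd_cache
        Tm1, B, V = logp.shape
        H = cfg.hidden_dim
        is_gru = cfg.cell_type == "GRU"
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        probs = np.exp(logp)
        dlogits = probs.copy()
        np.put_along_axis(
            dlogits,
            targets.T[:, :, None],
            np.take_along_axis(dlogits, targets.T[:, :, None], axis=2) - 1.0,
            axis=2,
        )
        dlogits *= mask.T[:, :, None] / B
        grads["W_out"] = np.einsum("tbh,tbv->hv", tops, dlogits)
        grads["b_out"] = dlogits.sum(axis=(0, 1))
        dtops = dlogits @ self.params["W_out"].T  # (T-1, B, H)
        dh = [np.zeros((B, H)) for _ in range(cfg.num_layers)]
        dc = [np.zeros((B, H)) for _ in range(cfg.num_layers)]
        emb_grad = grads["embedding"]
        for t in range(Tm1 - 1, -1, -1):
            dh[-1] = dh[-1] + dtops[t]
            dx_next: np.ndarray | None = None
            for layer in range(cfg.num_layers - 1, -1, -1):
                if dx_next is not None:
                    dh[layer] = dh[layer] + dx_next
                if is_gru:
                    dx, dh[layer] = self._gru_back(
                        dh[layer], caches[t][layer], layer, grads
                    )
                else:
                    dx, dh[layer], dc[layer] = self._lstm_back(
                        dh[layer], dc[layer], caches[t][layer], layer, grads
                    )
                if layer > 0:
                    dx_next = dx
                else:
                    np.add.at(emb_grad, x_ids[:, t], dx)
            # dh/dc now hold the gradients flowing to step t-1
            for layer in range(cfg.num_layers):
                dh[layer] = dh[layer]
        return grads

    def _pad_batch(self, id_lists: Sequence[Sequence[int]]) -> tuple[np.ndarray, np.ndarray]:
        """Pad with the end-marker id; mask covers targets up to '$'."""
        end = self.vocab.end_id
        T = max(len(ids) for ids in id_lists)
        B = len(id_lists)
        ids = np.full((B, T), end, dtype=np.int64)
        mask = np.zeros((B, T - 1))
        for b, seq in enumerate(id_lists):
            ids[b, : len(seq)] = seq
            mask[b, : len(seq) - 1] = 1.0
        return ids, mask

    # -- public API ---------------------------------------------------------

    def nll_many(self, smiles: Sequence[str], batch_size: int = 256) -> np.ndarray:
        """Sequence NLLs (nats) for a list of SMILES, batched."""
        encoded = [encode(s, self.vocab).ids for s in smiles]
        out = np.empty(len(encoded))
        for start in range(0, len(encoded), batch_size):
            chunk = encoded[start : start + batch_size]
            ids, mask = self._pad_batch(chunk)
            seq_nll, _ = self._forward(ids, mask, need_cache=False)
            out[start : start + len(chunk)] = seq_nll
        return out

    def nll_of(self, smiles: str) -> SequenceNll:
        """NLL of one sequence, including the terminal '$' step."""
        return SequenceNll(smiles=smiles, nll=float(self.nll_many([smiles])[0]))

    def step_probs(self, prefix_ids: Sequence[int]) -> np.ndarray:
        """Next-token distribution after consuming ``prefix_ids`` (from '^')."""
        cfg = self.config
        H = cfg.hidden_dim
        h = [np.zeros((1, H)) for _ in range(cfg.num_layers)]
        c = [np.zeros((1, H)) for _ in range(cfg.num_layers)]
        emb = self.params["embedding"]
        for tok in prefix_ids:
            inp = emb[[tok]]
            for layer in range(cfg.num_layers):
                if cfg.cell_type == "GRU":
                    h[layer], _ = self._gru_step(inp, h[layer], layer)
                else:
                    (h[layer], c[layer]), _ = self._lstm_step(
                        inp, (h[layer], c[layer]), layer
                    )
                inp = h[layer]
        logits = h[-1] @ self.params["W_out"] + self.params["b_out"]
        return np.exp(_log_softmax(logits))[0]

    def sample(
        self, count: int, seed: int, batch_size: int = 512
    ) -> list[SampledSequence]:
        """Draw ``count`` sequences by multinomial sampling of the softmax.

        Each sequence starts after the '^' marker and stops at '$' or at
        ``max_sequence_length`` tokens (then flagged ``truncated``; truncated
        sequences are treated as invalid downstream).  Reproducible given
        ``seed``.
        """
        if count < 1:
            raise ValueError("count must be >= 1")
        rng = np.random.default_rng(seed)
        cfg = self.config
        out: list[SampledSequence] = []
        for start in range(0, count, batch_size):
            B = min(batch_size, count - start)
            out.extend(self._sample_batch(B, rng))
        return out

    def _sample_batch(self, B: int, rng: np.random.Generator) -> list[SampledSequence]:
        cfg = self.config
        H, V = cfg.hidden_dim, len(self.vocab)
        end, begin = self.vocab.end_id, self.vocab.begin_id
        h = [np.zeros((B, H)) for _ in range(cfg.num_layers)]
        c = [np.zeros((B, H)) for _ in range(cfg.num_layers)]
        emb = self.params["embedding"]
        tok = np.full(B, begin, dtype=np.int64)
        finished = np.zeros(B, dtype=bool)
        nll = np.zeros(B)
        seqs: list[list[int]] = [[] for _ in range(B)]
        for _ in range(cfg.max_sequence_length):
            inp = emb[tok]
            for layer in range(cfg.num_layers):
                if cfg.cell_type == "GRU":
                    h_new, _ = self._gru_step(inp, h[layer], layer)
                    h[layer] = np.where(finished[:, None], h[layer], h_new)
                else:
                    (h_new, c_new), _ = self._lstm_step(inp, (h[layer], c[layer]), layer)
                    h[layer] = np.where(finished[:, None], h[layer], h_new)
                    c[layer] = np.where(finished[:, None], c[layer], c_new)
                inp = h[layer]
            logits = h[-1] @ self.params["W_out"] + self.params["b_out"]
            logp = _log_softmax(logits)
            probs = np.exp(logp)
            cdf = np.cumsum(probs, axis=1)
            cdf[:, -1] = 1.0
            u = rng.random((B, 1))
            nxt = (cdf < u).sum(axis=1)
            step_nll = -logp[np.arange(B), nxt]
            nll = np.where(finished, nll, nll + step_nll)
            for b in range(B):
                if not finished[b] and nxt[b] != end:
                    seqs[b].append(int(nxt[b]))
            finished = finished | (nxt == end)
            tok = np.where(finished, end, nxt)
            if finished.all():
                break
        return [
            SampledSequence(
                smiles=decode([begin] + seqs[b] + [end], self.vocab),
                nll=float(nll[b]),
                truncated=not bool(finished[b]),
            )
            for b in range(B)
        ]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path, epoch: int | None = None) -> None:
        meta = {
            "config": asdict(self.config),
            "vocab": list(self.vocab.tokens),
            "epoch": epoch,
        }
        np.savez(Path(path), __meta__=np.array(json.dumps(meta)), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "SmilesLM":
        data = np.load(Path(path), allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(
            config=ModelConfig(**meta["config"]),
            vocab=Vocabulary(tokens=tuple(meta["vocab"])),
            params=params,
        )


def load_checkpoint(path: str | Path) -> SmilesLM:
    return SmilesLM.load(path)


@dataclass
class TrainingResult:
    model: SmilesLM
    checkpoints: list[Path]
    log: "object"  # pandas.DataFrame (epoch, lr, mean_train_nll, mean_valid_nll)
    vocab: Vocabulary


def _batches(
    encoded: list[tuple[int, ...]], batch_size: int, rng: np.random.Generator
) -> Iterator[list[tuple[int, ...]]]:
    order = rng.permutation(len(encoded))
    for start in range(0, len(encoded), batch_size):
        yield [encoded[i] for i in order[start : start + batch_size]]


def train(
    config: ModelConfig,
    training_set: Sequence[str],
    validation_set: Sequence[str],
    out_dir: str | Path | None = None,
    vocab: Vocabulary | None = None,
) -> TrainingResult:
    """Train a model with teacher forcing; one checkpoint and log row per epoch.

    The vocabulary defaults to the union of tokens in both sets.  Training
    and validation sets must be disjoint.  Raises on NaN loss with the epoch
    in the message.  Fully reproducible given ``config.seed``.
    """
    import pandas as pd

    if set(training_set) & set(validation_set):
        raise ValueError("training and validation sets overlap")
    if vocab is None:
        vocab = build_vocabulary(list(training_set) + list(validation_set))
    rng = np.random.default_rng(config.seed)
    model = SmilesLM(config, vocab, rng=rng)
    for s in list(training_set) + list(validation_set):
        if len(encode(s, vocab).ids) > config.max_sequence_length:
            raise ValueError(f"sequence longer than max_sequence_length: {s!r}")
    encoded = [encode(s, vocab).ids for s in training_set]
    opt = _Adam(model.params, config.adam_beta1, config.adam_beta2, config.adam_eps)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        vocab.to_json(out_path / "vocabulary.json")
    rows = []
    checkpoints: list[Path] = []
    for epoch in range(1, config.epochs + 1):
        lr = config.lr_at(epoch)
        total_nll, total_seqs = 0.0, 0
        for chunk in _batches(encoded, config.batch_size, rng):
            ids, mask = model._pad_batch(chunk)
            seq_nll, cache = model._forward(ids, mask, need_cache=True)
            loss = seq_nll.mean()
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (lr={lr:g})"
                )
            grads = model._backward(cache)
            opt.step(model.params, grads, lr)
            total_nll += float(seq_nll.sum())
            total_seqs += len(chunk)
        mean_train = total_nll / total_seqs
        mean_valid = float(model.nll_many(validation_set).mean())
        rows.append(
            {
                "epoch": epoch,
                "lr": lr,
                "mean_train_nll": mean_train,
                "mean_valid_nll": mean_valid,
            }
        )
        if out_path is not None:
            ckpt = out_path / f"epoch_{epoch:03d}.npz"
            model.save(ckpt, epoch=epoch)
            checkpoints.append(ckpt)
    log = pd.DataFrame(rows)
    if out_path is not None:
        log.to_csv(out_path / "loss_log.csv", index=False, quoting=csv.QUOTE_MINIMAL)
    return TrainingResult(model=model, checkpoints=checkpoints, log=log, vocab=vocab)
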