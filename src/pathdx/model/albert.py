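"""ALBERT-style transformer encoder for coded pathway sequences.

Architecture: factorized token embeddings (V×E projected E×H), learned
absolute position embeddings, and a post-norm transformer layer (multi-head
self-attention + GELU feed-forward) whose parameters are shared across all
layer applications — the parameter-reduction devices of A Lite BERT. Two heads
sit on top: a masked-code prediction head whose decoder is tied to the token
embedding, and a logistic classification head reading the final-layer [CLS]
vector.

The default configuration is the full six-layer/twelve-head, 768-hidden model;
``SequenceModelConfig.desk()`` is a first-class reduced preset for CPU-scale
experiments and tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from pathdx.model import autodiff as ad
from pathdx.model.autodiff import Tensor
from pathdx.pathways import CLS_ID, PAD_ID


@dataclass
class SequenceModelConfig:
    n_layers: int = 6
    n_heads: int = 12
    hidden_size: int = 768
    embedding_size: int = 128
    ffn_size: int | None = None  # defaults to 4*hidden_size
    max_len: int = 512
    vocab_size: int = 454
    dropout: float = 0.1
    share_layer_parameters: bool = True
    classifier_bias: bool = True
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.hidden_size % self.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")
        if self.embedding_size > self.hidden_size:
            raise ValueError("embedding_size must be <= hidden_size")
        if self.vocab_size < 5:
            raise ValueError("vocab_size must be >= 5 (4 specials + groups)")
        if self.ffn_size is None:
            self.ffn_size = 4 * self.hidden_size

    @classmethod
    def desk(cls, vocab_size: int = 454, **overrides) -> "SequenceModelConfig":
        """Reduced preset: 2 layers, 4 heads, H=64, E=32, max_len=128."""
        kw = dict(
            n_layers=2,
            n_heads=4,
            hidden_size=64,
            embedding_size=32,
            max_len=128,
            vocab_size=vocab_size,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class ForwardOutput:
    """Hidden states, attention maps and the pooled [CLS] representation."""

    hidden: Tensor  # (B, N, H) final-layer hidden states
    attentions: list[np.ndarray]  # per layer: (B, heads, N, N), row-stochastic
    cls: Tensor  # (B, H) final hidden state at position 0
    padding_mask: np.ndarray  # (B, N) True at real positions


def _init(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    return (rng.normal(0.0, 0.02, size=shape)).astype(dtype)


class SequenceModel:
    """The encoder plus masked-code and classification heads."""

    def __init__(self, config: SequenceModelConfig, seed: int = 0):
        self.config = config
        dt = np.dtype(config.dtype)
        rng = np.random.default_rng(seed)
        c = config
        p: dict[str, Tensor] = {}

        def param(name: str, shape: tuple[int, ...], zeros: bool = False, ones: bool = False):
            if ones:
                data = np.ones(shape, dtype=dt)
            elif zeros:
                data = np.zeros(shape, dtype=dt)
            else:
                data = _init(rng, shape, dt)
            p[name] = Tensor(data, requires_grad=True)

        param("tok_emb", (c.vocab_size, c.embedding_size))
        param("emb_proj", (c.embedding_size, c.hidden_size))
        param("pos_emb", (c.max_len, c.hidden_size))
        param("emb_ln_g", (c.hidden_size,), ones=True)
        param("emb_ln_b", (c.hidden_size,), zeros=True)

        n_blocks = 1 if c.share_layer_parameters else c.n_layers
        for b in range(n_blocks):
            pre = f"l{b}_"
            for w in ("wq", "wk", "wv", "wo"):
                param(pre + w, (c.hidden_size, c.hidden_size))
                param(pre + w + "_b", (c.hidden_size,), zeros=True)
            param(pre + "ln1_g", (c.hidden_size,), ones=True)
            param(pre + "ln1_b", (c.hidden_size,), zeros=True)
            param(pre + "w1", (c.hidden_size, c.ffn_size))
            param(pre + "b1", (c.ffn_size,), zeros=True)
            param(pre + "w2", (c.ffn_size, c.hidden_size))
            param(pre + "b2", (c.hidden_size,), zeros=True)
            param(pre + "ln2_g", (c.hidden_size,), ones=True)
            param(pre + "ln2_b", (c.hidden_size,), zeros=True)

        param("mlm_dense", (c.hidden_size, c.embedding_size))
        param("mlm_dense_b", (c.embedding_size,), zeros=True)
        param("mlm_ln_g", (c.embedding_size,), ones=True)
        param("mlm_ln_b", (c.embedding_size,), zeros=True)
        param("mlm_bias", (c.vocab_size,), zeros=True)

        param("cls_w", (c.hidden_size,))
        param("cls_b", (1,), zeros=True)

        self.params = p

    # -- utilities ------------------------------------------------------------

    def parameter_count(self) -> int:
        return int(sum(t.data.size for t in self.params.values()))

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()

    def reinit_classifier(self, rng: np.random.Generator) -> None:
        """Fresh classifier weights (used by fine-tuning restarts)."""
        dt = self.params["cls_w"].data.dtype
        self.params["cls_w"].data = rng.normal(0.0, 0.02, self.config.hidden_size).astype(dt)
        self.params["cls_b"].data = np.zeros(1, dtype=dt)

    def _block_names(self, layer: int) -> str:
        return "l0_" if self.config.share_layer_parameters else f"l{layer}_"

    # -- forward --------------------------------------------------------------

    def forward(
        self,
        ids: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> ForwardOutput:
        """Run the encoder on a padded batch of id sequences.

        ``ids`` is (B, N) int; [PAD] positions are excluded from attention.
        Deterministic in inference mode (``train=False``).
        """
        c = self.config
        p = self.params
        ids = np.asarray(ids)
        if ids.ndim == 1:
            ids = ids[None, :]
        if ids.max() >= c.vocab_size:
            raise ValueError(f"token id {int(ids.max())} >= vocab_size {c.vocab_size}")
        if ids.shape[1] > c.max_len:
            raise ValueError(f"sequence length {ids.shape[1]} > max_len {c.max_len}")
        B, N = ids.shape
        dt = p["tok_emb"].data.dtype
        real = ids != PAD_ID  # (B, N)
        drop_rng = rng if train else None
        drate = c.dropout if train else 0.0

        x = ad.gather(p["tok_emb"], ids) @ p["emb_proj"]
        x = x + ad.gather(p["pos_emb"], np.broadcast_to(np.arange(N), (B, N)))
        x = ad.layer_norm(x, p["emb_ln_g"], p["emb_ln_b"])
        x = ad.dropout(x, drate, drop_rng)

        # additive attention mask: 0 at real keys, -1e9 at padding keys
        bias = np.where(real, 0.0, -1e9).astype(dt)[:, None, None, :]
        d_head = c.hidden_size // c.n_heads
        scale = 1.0 / np.sqrt(d_head)
        attentions: list[np.ndarray] = []

        for layer in range(c.n_layers):
            pre = self._block_names(layer)

            def heads(t: Tensor) -> Tensor:
                return t.reshape(B, N, c.n_heads, d_head).swapaxes(1, 2)

            q = heads(x @ p[pre + "wq"] + p[pre + "wq_b"])
            k = heads(x @ p[pre + "wk"] + p[pre + "wk_b"])
            v = heads(x @ p[pre + "wv"] + p[pre + "wv_b"])
            scores = (q @ k.swapaxes(-1, -2)) * scale + Tensor(bias)
            attn = ad.softmax(scores, axis=-1)  # (B, heads, N, N)
            attentions.append(attn.data.copy())
            ctx = (attn @ v).swapaxes(1, 2).reshape(B, N, c.hidden_size)
            ctx = ad.dropout(ctx @ p[pre + "wo"] + p[pre + "wo_b"], drate, drop_rng)
            x = ad.layer_norm(x + ctx, p[pre + "ln1_g"], p[pre + "ln1_b"])

            h = ad.gelu(x @ p[pre + "w1"] + p[pre + "b1"])
            h = ad.dropout(h @ p[pre + "w2"] + p[pre + "b2"], drate, drop_rng)
            x = ad.layer_norm(x + h, p[pre + "ln2_g"], p[pre + "ln2_b"])

        return ForwardOutput(
            hidden=x, attentions=attentions, cls=x.take0(0), padding_mask=real
        )

    def mlm_logits(self, out: ForwardOutput) -> Tensor:
        """Per-position vocabulary scores, decoder tied to the token embedding."""
        p = self.params
        h = ad.gelu(out.hidden @ p["mlm_dense"] + p["mlm_dense_b"])
        h = ad.layer_norm(h, p["mlm_ln_g"], p["mlm_ln_b"])
        return h @ _transpose_param(p["tok_emb"]) + p["mlm_bias"]  # (B, N, V)

    def classify_logits(self, out: ForwardOutput) -> Tensor:
        """(B,) logit = C·W (+ bias unless disabled)."""
        p = self.params
        B = out.cls.shape[0]
        logit = (out.cls @ p["cls_w"].reshape(-1, 1)).reshape(B)
        if self.config.classifier_bias:
            logit = logit + p["cls_b"]
        return logit

    def classify(self, out: ForwardOutput) -> np.ndarray:
        """(B,) probability of lung cancer: sigmoid(C·W + b)."""
        return ad.sigmoid(self.classify_logits(out)).data

    def predict_proba(self, ids: np.ndarray) -> np.ndarray:
        return self.classify(self.forward(ids, train=False))


def _transpose_param(w: Tensor) -> Tensor:
    """Transposed view of an embedding matrix that routes gradients back."""
    out = Tensor(w.data.T, parents=(w,))

    def bwd(g):
        if w.requires_grad:
            w._accumulate(g.T)

    out._backward = bwd
    return out


def save_checkpoint(model: SequenceModel, path: str | Path) -> None:
    """Serialise config + weights (.npz alongside a .json)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **{k: t.data for k, t in model.params.items()})
    path.with_suffix(".json").write_text(json.dumps(asdict(model.config), indent=2))


def load_checkpoint(path: str | Path) -> SequenceModel:
    path = Path(path)
    config = SequenceModelConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = SequenceModel(config)
    with np.load(path.with_suffix(".npz")) as data:
        for k in model.params:
            model.params[k].data = data[k]
    return model
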