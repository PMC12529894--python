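"""Two-pass autoregressive transformer over discrete state tokens.

The network is a small GPT-style decoder: learned token + position
embeddings, a stack of causal self-attention blocks

    A = softmax(Q K^T / sqrt(d_q)) V          (contextual update)
    B = f_theta(H + A)                        (two-layer FFN + LayerNorm)
    H <- H + A + B                            (residual accumulation)

and a decoding head softmax(f_dec(H) D^T + b) that yields the next-state
distribution Q(x_{t+1} | x_{<=t}).

Training couples two such decoders through a scheduled sampler: the first
pass reads the ground-truth ("golden") token window; per position t the
second pass then receives either the golden token (with probability
p(i, t) = eps^{t (1 - k^i)}, decaying in both training step i and
position t) or a token sampled from the first pass's prediction.  This
progressively exposes the model to its own outputs, closing the gap
between teacher-forced training and free-running generation.

Everything is plain NumPy: the model is deliberately small (hidden width
<= 128, 2-3 blocks, window ~50), so explicit forward/backward code on
BLAS matmuls is fast enough on a CPU and keeps the package free of deep
learning framework dependencies.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "GptConfig",
    "GptCore",
    "NanoGpt",
    "MixedWindow",
    "schedule_probability",
    "softmax",
]

_LN_EPS = 1e-5


@dataclass
class GptConfig:
    """Hyperparameters of the two-pass model.

    ``epsilon`` and ``k_const`` are the constants of the sampling schedule
    p(i, t) = epsilon^{t (1 - k_const^i)}; both must lie in (0, 1).
    ``d_q`` is the per-head query/key width (defaults to d_x / n_heads).
    ``aux_pass1_weight`` adds a cross-entropy term on the first pass so
    the sampler draws from a trained predictor; set to 0 to supervise the
    second pass only.
    """

    vocab_size: int = 4
    d_x: int = 128
    n_blocks: int = 2
    n_heads: int = 4
    window_length: int = 50
    d_q: int | None = None
    ffn_mult: int = 4
    learning_rate: float = 0.0005
    batch_size: int = 32
    epsilon: float = 0.999
    k_const: float = 0.999
    share_passes: bool = False
    aux_pass1_weight: float = 1.0
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < 2:
            raise ValueError("vocab_size must be >= 2")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")
        if not 0.0 < self.k_const < 1.0:
            raise ValueError("k_const must be in (0, 1)")
        if self.d_x % self.n_heads:
            raise ValueError("d_x must be divisible by n_heads")
        if self.d_q is None:
            self.d_q = self.d_x // self.n_heads
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "GptConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def schedule_probability(i: int, t, epsilon: float, k_const: float):
    """Probability of keeping the golden token at training step i,
    decoding position t:  p = epsilon^{t (1 - k_const^i)}.

    p = 1 at i = 0 (full teacher forcing), decays monotonically in both
    i and t, and tends to epsilon^t as i -> inf.
    """
    if not (0.0 < epsilon < 1.0 and 0.0 < k_const < 1.0):
        raise ValueError("epsilon and k_const must be in (0, 1)")
    if i < 0 or np.any(np.asarray(t) < 0):
        raise ValueError("i and t must be non-negative")
    return epsilon ** (np.asarray(t, dtype=float) * (1.0 - k_const**i))


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _layernorm_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxh = dy * g
    dx = inv * (
        dxh
        - dxh.mean(-1, keepdims=True)
        - xhat * (dxh * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


class GptCore:
    """One decoder stack (embeddings, causal attention blocks, head).

    Parameters live in a flat dict of arrays (configured dtype) so the
    optimizer and checkpointing can treat them uniformly.
    """

    def __init__(self, config: GptConfig, rng: np.random.Generator):
        self.config = config
        self.dtype = np.dtype(config.dtype)
        c = config
        d, ff, K, L = c.d_x, c.ffn_mult * c.d_x, c.vocab_size, c.window_length

        def w(*shape, scale=0.02):
            return (rng.standard_normal(shape) * scale).astype(self.dtype)

        zeros = lambda n: np.zeros(n, dtype=self.dtype)
        ones = lambda n: np.ones(n, dtype=self.dtype)
        p: dict[str, np.ndarray] = {"wte": w(K, d), "wpe": w(L, d)}
        for l in range(c.n_blocks):
            p[f"b{l}.wq"] = w(d, d)
            p[f"b{l}.wk"] = w(d, d)
            p[f"b{l}.wv"] = w(d, d)
            p[f"b{l}.wo"] = w(d, d)
            p[f"b{l}.w1"] = w(d, ff)
            p[f"b{l}.b1"] = zeros(ff)
            p[f"b{l}.w2"] = w(ff, d)
            p[f"b{l}.b2"] = zeros(d)
            p[f"b{l}.ln_g"] = ones(d)
            p[f"b{l}.ln_b"] = zeros(d)
        p["dec.w1"] = w(d, ff)
        p["dec.b1"] = zeros(ff)
        p["dec.w2"] = w(ff, d)
        p["dec.b2"] = zeros(d)
        p["dec.ln_g"] = ones(d)
        p["dec.ln_b"] = zeros(d)
        p["head.D"] = w(K, d)
        p["head.b"] = zeros(K)
        self.params = p

    # ------------------------------------------------------------- forward
    def forward(
        self,
        tokens: np.ndarray,
        emb_noise: np.ndarray | None = None,
        restore_emb_positions=None,
        attn_restore: dict[int, tuple[np.ndarray, np.ndarray]] | None = None,
        last_only: bool = False,
    ):
        """Run the stack on integer tokens of shape (B, T) (or (T,)).

        Returns (logits (B, T, K), cache).  The intervention hooks support
        causal tracing: ``emb_noise`` is added to the token embeddings,
        ``restore_emb_positions`` zeroes that noise at the given positions,
        and ``attn_restore`` maps block index -> (positions, clean A
        values) to overwrite the attention output at those positions.
        """
        p = self.params
        c = self.config
        tokens = np.atleast_2d(np.asarray(tokens, dtype=np.int64))
        B, T = tokens.shape
        if T > c.window_length:
            raise ValueError(f"sequence length {T} exceeds window {c.window_length}")
        if tokens.min() < 0 or tokens.max() >= c.vocab_size:
            raise ValueError("token out of vocabulary")
        nh, dh = c.n_heads, c.d_x // c.n_heads

        emb = p["wte"][tokens]
        if emb_noise is not None:
            emb = emb + emb_noise.astype(self.dtype)
            if restore_emb_positions is not None:
                emb = emb.copy()
                for pos in restore_emb_positions:
                    emb[:, pos, :] = p["wte"][tokens[:, pos]]
        H = emb + p["wpe"][:T]
        mask = np.triu(np.full((T, T), -np.inf, dtype=self.dtype), k=1)

        cache: dict = {"tokens": tokens, "T": T, "blocks": [], "attn_out": []}
        for l in range(c.n_blocks):
            # in last_only mode the final block only ever feeds the last
            # position to the head, so restrict its queries to that position
            # (identical output, much cheaper during generation)
            tail = last_only and l == c.n_blocks - 1
            restore = attn_restore.get(l) if attn_restore else None
            H, A, block_cache = self.attention_block(
                H, l, mask=mask, tail=tail, attn_restore_entry=restore
            )
            cache["blocks"].append(block_cache)
            cache["attn_out"].append(A)

        if last_only:  # generation fast path: decode the final position only
            H = H[:, -1:, :]
        fd1 = H @ p["dec.w1"] + p["dec.b1"]
        rd = np.maximum(fd1, 0.0)
        fd2 = rd @ p["dec.w2"] + p["dec.b2"]
        S = H + fd2
        G, dec_ln = _layernorm_fwd(S, p["dec.ln_g"], p["dec.ln_b"])
        logits = G @ p["head.D"].T + p["head.b"]
        cache.update(H_final=H, fd1=fd1, rd=rd, G=G, dec_ln=dec_ln)
        return logits, cache

    def attention_block(
        self,
        H: np.ndarray,
        l: int,
        mask: np.ndarray | None = None,
        tail: bool = False,
        attn_restore_entry=None,
    ):
        """One causal self-attention block: H -> H + A + B.

        A is the multi-head attention update softmax(Q K^T / sqrt(d_q)) V
        (heads concatenated and mixed by the output projection), and
        B = f_theta(H + A) is the two-layer feed-forward network followed
        by LayerNorm.  Row-wise attention weights are non-negative and sum
        to 1 over the permitted (non-future) positions.

        Returns (H_out, A, cache); with ``tail`` only the last position's
        output is computed (used by the generation fast path).
        """
        p = self.params
        c = self.config
        nh, dh = c.n_heads, c.d_x // c.n_heads
        H = np.asarray(H, dtype=self.dtype)
        squeeze = H.ndim == 2
        if squeeze:
            H = H[None]
        B, T, _ = H.shape
        if mask is None:
            mask = np.triu(np.full((T, T), -np.inf, dtype=self.dtype), k=1)
        q = (H[:, -1:, :] if tail else H) @ p[f"b{l}.wq"]
        k = H @ p[f"b{l}.wk"]
        v = H @ p[f"b{l}.wv"]
        Tq = q.shape[1]
        qh = q.reshape(B, Tq, nh, dh).transpose(0, 2, 1, 3)
        kh = k.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
        vh = v.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
        scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh)
        if not tail:
            scores += mask  # the last position attends everywhere anyway
        att = softmax(scores)
        concat = (att @ vh).transpose(0, 2, 1, 3).reshape(B, Tq, c.d_x)
        A = concat @ p[f"b{l}.wo"]
        if attn_restore_entry is not None:
            positions, clean_A = attn_restore_entry
            A = A.copy()
            A[:, positions, :] = clean_A
        Z = (H[:, -1:, :] if tail else H) + A
        h1 = Z @ p[f"b{l}.w1"] + p[f"b{l}.b1"]
        r = np.maximum(h1, 0.0)
        f2 = r @ p[f"b{l}.w2"] + p[f"b{l}.b2"]
        Bv, ln_cache = _layernorm_fwd(f2, p[f"b{l}.ln_g"], p[f"b{l}.ln_b"])
        if not np.isfinite(Bv).all():
            raise FloatingPointError(f"NaN in activations at block {l}")
        H_out = Z + Bv
        cache = (H[0] if squeeze else H, att, qh, kh, vh, concat, Z, h1, r, ln_cache)
        if squeeze:
            return H_out[0], A[0], cache
        return H_out, A, cache

    def decode(self, logits: np.ndarray) -> np.ndarray:
        """Per-position probability distribution over states (softmax)."""
        if not np.isfinite(logits).all():
            raise FloatingPointError("non-finite logits")
        return softmax(logits)

    # ------------------------------------------------------------ backward
    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        c = self.config
        nh, dh = c.n_heads, c.d_x // c.n_heads
        B, T = cache["tokens"].shape
        g: dict[str, np.ndarray] = {}
        dlogits = dlogits.astype(self.dtype, copy=False)

        flat = lambda x: x.reshape(-1, x.shape[-1])
        g["head.D"] = flat(dlogits).T @ flat(cache["G"])
        g["head.b"] = dlogits.sum((0, 1))
        dG = dlogits @ p["head.D"]
        dS, g["dec.ln_g"], g["dec.ln_b"] = _layernorm_bwd(dG, cache["dec_ln"])
        dfd2 = dS
        g["dec.w2"] = flat(cache["rd"]).T @ flat(dfd2)
        g["dec.b2"] = dfd2.sum((0, 1))
        drd = dfd2 @ p["dec.w2"].T
        dfd1 = drd * (cache["fd1"] > 0)
        g["dec.w1"] = flat(cache["H_final"]).T @ flat(dfd1)
        g["dec.b1"] = dfd1.sum((0, 1))
        dH = dS + dfd1 @ p["dec.w1"].T

        for l in range(c.n_blocks - 1, -1, -1):
            H, att, qh, kh, vh, concat, Z, h1, r, ln_cache = cache["blocks"][l]
            # H_out = Z + LN(FFN(Z));  Z = H + A(H)
            dBv = dH
            df2, g[f"b{l}.ln_g"], g[f"b{l}.ln_b"] = _layernorm_bwd(dBv, ln_cache)
            g[f"b{l}.w2"] = flat(r).T @ flat(df2)
            g[f"b{l}.b2"] = df2.sum((0, 1))
            dr = df2 @ p[f"b{l}.w2"].T
            dh1 = dr * (h1 > 0)
            g[f"b{l}.w1"] = flat(Z).T @ flat(dh1)
            g[f"b{l}.b1"] = dh1.sum((0, 1))
            dZ = dH + dh1 @ p[f"b{l}.w1"].T
            # attention backward; dA = dZ
            dA = dZ
            g[f"b{l}.wo"] = flat(concat).T @ flat(dA)
            dconcat = dA @ p[f"b{l}.wo"].T
            dah = dconcat.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            datt = dah @ vh.transpose(0, 1, 3, 2)
            dvh = att.transpose(0, 1, 3, 2) @ dah
            dscores = att * (datt - (datt * att).sum(-1, keepdims=True))
            dscores /= np.sqrt(dh)
            dqh = dscores @ kh
            dkh = dscores.transpose(0, 1, 3, 2) @ qh
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, c.d_x)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, c.d_x)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, c.d_x)
            g[f"b{l}.wq"] = flat(H).T @ flat(dq)
            g[f"b{l}.wk"] = flat(H).T @ flat(dk)
            g[f"b{l}.wv"] = flat(H).T @ flat(dv)
            dH = (
                dZ
                + dq @ p[f"b{l}.wq"].T
                + dk @ p[f"b{l}.wk"].T
                + dv @ p[f"b{l}.wv"].T
            )

        g["wpe"] = np.zeros_like(p["wpe"])
        g["wpe"][:T] = dH.sum(0)
        g["wte"] = np.zeros_like(p["wte"])
        np.add.at(g["wte"], cache["tokens"].ravel(), flat(dH))
        return g


@dataclass
class MixedWindow:
    """Second-pass input assembled by the scheduled sampler.

    ``source_mask`` is True where the token is golden (ground truth) and
    False where it was sampled from the first pass's prediction.
    """

    tokens: np.ndarray
    source_mask: np.ndarray

    def __post_init__(self) -> None:
        self.tokens = np.atleast_2d(np.asarray(self.tokens, dtype=np.int64))
        self.source_mask = np.atleast_2d(np.asarray(self.source_mask, dtype=bool))
        if self.tokens.shape != self.source_mask.shape:
            raise ValueError("tokens and source_mask must have the same shape")


class NanoGpt:
    """The two-pass model: two decoder stacks linked by the scheduled sampler.

    With ``share_passes=False`` (default) the passes hold disjoint
    parameter sets; the second pass produces the final output and is the
    stack used for generation and tracing.
    """

    def __init__(self, config: GptConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.pass1 = GptCore(config, rng)
        self.pass2 = self.pass1 if config.share_passes else GptCore(config, rng)
        self.step = 0

    # -------------------------------------------------------------- passes
    @property
    def inference_core(self) -> GptCore:
        """The stack that yields the model's final output (second pass)."""
        return self.pass2

    def schedule_probability(self, i: int, t) -> np.ndarray:
        return schedule_probability(i, t, self.config.epsilon, self.config.k_const)

    def two_pass_forward(self, window: np.ndarray, step: int, rng: np.random.Generator):
        """Run both passes on a golden window (B, T) or (T,).

        Returns (pass-1 distributions, MixedWindow, pass-2 distributions),
        each distribution array of shape (B, T, K): position t predicts
        the state at t+1.  Position 0 of the mixed window is always the
        golden token (there is no pass-1 prediction for it; the schedule
        gives p = 1 at t = 0 anyway).
        """
        w = np.atleast_2d(np.asarray(window, dtype=np.int64))
        B, T = w.shape
        logits1, cache1 = self.pass1.forward(w)
        probs1 = softmax(logits1)

        keep_p = self.schedule_probability(step, np.arange(T))
        keep = rng.random((B, T)) < keep_p[None, :]
        keep[:, 0] = True
        mixed = w.copy()
        if not keep.all():
            # sample replacement tokens from pass-1's prediction of each
            # position (the distribution emitted at the previous position)
            cum = np.cumsum(probs1[:, :-1, :], axis=-1)
            u = rng.random((B, T - 1, 1))
            draws = (u > cum).sum(-1)
            draws = np.minimum(draws, self.config.vocab_size - 1)
            repl = ~keep[:, 1:]
            mixed[:, 1:][repl] = draws[repl]
        mw = MixedWindow(mixed, keep)

        logits2, cache2 = self.pass2.forward(mixed)
        probs2 = softmax(logits2)
        self._last_caches = (cache1, cache2, logits1, logits2)
        return probs1, mw, probs2

    def predict_proba(self, contexts: np.ndarray) -> np.ndarray:
        """Next-state distribution given integer contexts (B, t) or (t,)."""
        ctx = np.atleast_2d(np.asarray(contexts, dtype=np.int64))
        ctx = ctx[:, -self.config.window_length:]
        logits, _ = self.inference_core.forward(ctx, last_only=True)
        return softmax(logits[:, -1, :])

    # -------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Checkpoint: config + both parameter sets + training-step counter."""
        payload = {"config": json.dumps(asdict(self.config)), "step": self.step}
        arrays = {f"p1.{k}": v for k, v in self.pass1.params.items()}
        if not self.config.share_passes:
            arrays.update({f"p2.{k}": v for k, v in self.pass2.params.items()})
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(payload).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "NanoGpt":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg_raw = json.loads(meta["config"])
            model = cls(GptConfig(**cfg_raw))
            model.step = int(meta["step"])
            for k in model.pass1.params:
                model.pass1.params[k] = z[f"p1.{k}"].copy()
            if not model.config.share_passes:
                for k in model.pass2.params:
                    model.pass2.params[k] = z[f"p2.{k}"].copy()
        return model
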