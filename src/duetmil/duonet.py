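"""Dual-branch transformer aggregator for paired H&E/IHC tile-embedding bags.

One shared trunk — linear projection, a learned class token, ``n_layers``
pre-norm transformer blocks (multi-head self-attention + GELU feed-forward)
and a final layer norm — is applied to each modality's bag; the two final
class-token states are concatenated (H&E block first, a dropped or missing
branch contributing a zero block) and fed to a two-layer MLP head that emits
a single biomarker logit. Parameter sharing keeps the duet trunk exactly the
size of a single-branch trunk; branch dropout during training randomly omits
one modality so the head learns to tolerate single-stain inference.

There are no positional encodings: a bag is a set, so the output is
invariant to tile order. The implementation is plain NumPy with explicit
reverse-mode gradients for every operation (checked against finite
differences in the test suite), which keeps the model dependency-free and
bit-reproducible on CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterable

import numpy as np
from scipy.special import erf, expit

_LN_EPS = 1e-5
_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)

HE, IHC = "HE", "IHC"
MODES = ("HE_ONLY", "IHC_ONLY", "DUET")


@dataclass(frozen=True)
class DuoNetConfig:
    embed_dim_in: int = 768
    model_dim: int = 512
    n_layers: int = 2
    n_heads: int = 8
    mlp_hidden: int = 512
    p_branch_dropout: float = 0.3
    n_outputs: int = 1

    def __post_init__(self) -> None:
        if self.model_dim % self.n_heads != 0:
            raise ValueError("model_dim must be divisible by n_heads")
        if not 0.0 <= self.p_branch_dropout < 1.0:
            raise ValueError("p_branch_dropout must lie in [0, 1)")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.n_outputs != 1:
            raise ValueError("only a single binary logit is supported")


@dataclass
class ForwardTrace:
    """Everything one forward pass exposes: prediction, attention, gradients' cache."""

    probability: float
    logit: float
    attention: dict  # modality -> list over layers of (n_heads, T, T) row-stochastic arrays
    branch_kept: tuple
    branch_features: dict  # modality -> (model_dim,) final class-token state
    cache: dict | None = None  # retained only when training=True
    d_inputs: dict = field(default_factory=dict)  # filled by backward()


def branch_dropout_mask(available: Iterable[str], p: float,
                        rng: np.random.Generator) -> tuple:
    """Training-time branch dropout: with probability ``p`` omit one branch.

    When both modalities are available, some branch is dropped with
    probability ``p`` and the victim is chosen uniformly; a lone available
    branch is always kept. Never returns an empty set.
    """
    avail = tuple(m for m in (HE, IHC) if m in set(available))
    if not avail:
        raise ValueError("available branch set must be non-empty")
    if len(avail) == 1:
        return avail
    if rng.uniform() < p:
        victim = avail[int(rng.integers(2))]
        return tuple(m for m in avail if m != victim)
    return avail


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


def _layernorm(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _layernorm_backward(dy, cache, g):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


def _softmax(s: np.ndarray) -> np.ndarray:
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


class DuetTransformer:
    """The dual-modality aggregation model (shared trunk + MLP head)."""

    def __init__(self, config: DuoNetConfig = DuoNetConfig(), seed: int = 0):
        self.config = config
        c = config
        rng = np.random.default_rng(seed)

        def lin(n_in, n_out):
            return rng.standard_normal((n_in, n_out)) / np.sqrt(n_in)

        p: dict[str, np.ndarray] = {
            "proj_W": lin(c.embed_dim_in, c.model_dim),
            "proj_b": np.zeros(c.model_dim),
            "cls": rng.standard_normal(c.model_dim) * 0.02,
            "lnf_g": np.ones(c.model_dim),
            "lnf_b": np.zeros(c.model_dim),
            "head_W1": lin(2 * c.model_dim, c.mlp_hidden),
            "head_b1": np.zeros(c.mlp_hidden),
            "head_W2": lin(c.mlp_hidden, 1)[:, 0],
            "head_b2": np.zeros(1),
        }
        for l in range(c.n_layers):
            p[f"l{l}_ln1_g"] = np.ones(c.model_dim)
            p[f"l{l}_ln1_b"] = np.zeros(c.model_dim)
            for w in ("Wq", "Wk", "Wv", "Wo"):
                p[f"l{l}_{w}"] = lin(c.model_dim, c.model_dim)
            for b in ("bq", "bk", "bv", "bo"):
                p[f"l{l}_{b}"] = np.zeros(c.model_dim)
            p[f"l{l}_ln2_g"] = np.ones(c.model_dim)
            p[f"l{l}_ln2_b"] = np.zeros(c.model_dim)
            p[f"l{l}_W1"] = lin(c.model_dim, c.mlp_hidden)
            p[f"l{l}_b1"] = np.zeros(c.mlp_hidden)
            p[f"l{l}_W2"] = lin(c.mlp_hidden, c.model_dim)
            p[f"l{l}_b2"] = np.zeros(c.model_dim)
        self.params = p

    # -- trunk ----------------------------------------------------------------

    def _forward_branch(self, X: np.ndarray, need_cache: bool):
        c, p = self.config, self.params
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != c.embed_dim_in:
            raise ValueError(f"expected (N, {c.embed_dim_in}) embeddings, got {X.shape}")
        if not np.isfinite(X).all():
            raise ValueError("NaN or Inf in input embeddings")
        T = X.shape[0] + 1
        h, dh = c.n_heads, c.model_dim // c.n_heads
        x = np.vstack([p["cls"], X @ p["proj_W"] + p["proj_b"]])
        attn_all, layer_caches = [], []
        for l in range(c.n_layers):
            x_in = x
            xn, ln1c = _layernorm(x, p[f"l{l}_ln1_g"], p[f"l{l}_ln1_b"])
            Q = (xn @ p[f"l{l}_Wq"] + p[f"l{l}_bq"]).reshape(T, h, dh).transpose(1, 0, 2)
            K = (xn @ p[f"l{l}_Wk"] + p[f"l{l}_bk"]).reshape(T, h, dh).transpose(1, 0, 2)
            V = (xn @ p[f"l{l}_Wv"] + p[f"l{l}_bv"]).reshape(T, h, dh).transpose(1, 0, 2)
            A = _softmax(Q @ K.transpose(0, 2, 1) / np.sqrt(dh))  # (h, T, T)
            O = (A @ V).transpose(1, 0, 2).reshape(T, c.model_dim)
            attn_out = O @ p[f"l{l}_Wo"] + p[f"l{l}_bo"]
            x_mid = x_in + attn_out
            xn2, ln2c = _layernorm(x_mid, p[f"l{l}_ln2_g"], p[f"l{l}_ln2_b"])
            h1 = xn2 @ p[f"l{l}_W1"] + p[f"l{l}_b1"]
            a = _gelu(h1)
            x = x_mid + a @ p[f"l{l}_W2"] + p[f"l{l}_b2"]
            attn_all.append(A.copy())
            if need_cache:
                layer_caches.append(dict(xn=xn, ln1c=ln1c, Q=Q, K=K, V=V, A=A, O=O,
                                         ln2c=ln2c, xn2=xn2, h1=h1, a=a))
        yf, lnfc = _layernorm(x, p["lnf_g"], p["lnf_b"])
        feat = yf[0]
        cache = dict(X=X, T=T, layers=layer_caches, lnfc=lnfc, x_final=x) if need_cache else None
        return feat, attn_all, cache

    def _backward_branch(self, dfeat: np.ndarray, cache: dict, grads: dict) -> np.ndarray:
        c, p = self.config, self.params
        T = cache["T"]
        h, dh = c.n_heads, c.model_dim // c.n_heads
        dy = np.zeros((T, c.model_dim))
        dy[0] = dfeat
        dx, dg, db = _layernorm_backward(dy, cache["lnfc"], p["lnf_g"])
        grads["lnf_g"] += dg
        grads["lnf_b"] += db
        for l in reversed(range(c.n_layers)):
            lc = cache["layers"][l]
            # feed-forward sub-block
            da = dx @ p[f"l{l}_W2"].T
            grads[f"l{l}_W2"] += lc["a"].T @ dx
            grads[f"l{l}_b2"] += dx.sum(axis=0)
            dh1 = da * _gelu_grad(lc["h1"])
            grads[f"l{l}_W1"] += lc["xn2"].T @ dh1
            grads[f"l{l}_b1"] += dh1.sum(axis=0)
            dxn2 = dh1 @ p[f"l{l}_W1"].T
            dmid2, dg, db = _layernorm_backward(dxn2, lc["ln2c"], p[f"l{l}_ln2_g"])
            grads[f"l{l}_ln2_g"] += dg
            grads[f"l{l}_ln2_b"] += db
            dx_mid = dx + dmid2
            # attention sub-block
            dattn_out = dx_mid
            dO = (dattn_out @ p[f"l{l}_Wo"].T).reshape(T, h, dh).transpose(1, 0, 2)
            grads[f"l{l}_Wo"] += lc["O"].T @ dattn_out
            grads[f"l{l}_bo"] += dattn_out.sum(axis=0)
            A, Q, K, V = lc["A"], lc["Q"], lc["K"], lc["V"]
            dA = dO @ V.transpose(0, 2, 1)
            dV = A.transpose(0, 2, 1) @ dO
            dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
            dS /= np.sqrt(dh)
            dQ = dS @ K
            dK = dS.transpose(0, 2, 1) @ Q
            dq = dQ.transpose(1, 0, 2).reshape(T, c.model_dim)
            dk = dK.transpose(1, 0, 2).reshape(T, c.model_dim)
            dv = dV.transpose(1, 0, 2).reshape(T, c.model_dim)
            xn = lc["xn"]
            dxn = dq @ p[f"l{l}_Wq"].T + dk @ p[f"l{l}_Wk"].T + dv @ p[f"l{l}_Wv"].T
            grads[f"l{l}_Wq"] += xn.T @ dq
            grads[f"l{l}_bq"] += dq.sum(axis=0)
            grads[f"l{l}_Wk"] += xn.T @ dk
            grads[f"l{l}_bk"] += dk.sum(axis=0)
            grads[f"l{l}_Wv"] += xn.T @ dv
            grads[f"l{l}_bv"] += dv.sum(axis=0)
            dres, dg, db = _layernorm_backward(dxn, lc["ln1c"], p[f"l{l}_ln1_g"])
            grads[f"l{l}_ln1_g"] += dg
            grads[f"l{l}_ln1_b"] += db
            dx = dx_mid + dres
        grads["cls"] += dx[0]
        dT0 = dx[1:]
        grads["proj_W"] += cache["X"].T @ dT0
        grads["proj_b"] += dT0.sum(axis=0)
        return dT0 @ p["proj_W"].T  # gradient wrt the input embeddings

    # -- full model -----------------------------------------------------------

    @staticmethod
    def _bag_matrix(bag) -> np.ndarray:
        return bag.embeddings if hasattr(bag, "embeddings") else np.asarray(bag)

    def forward(self, he_bag=None, ihc_bag=None, mode: str = "DUET",
                training: bool = False, rng: np.random.Generator | None = None,
                allow_missing: bool = False) -> ForwardTrace:
        """Run the model on one case.

        ``mode`` selects which branches participate; in DUET mode a missing
        bag is an error unless ``allow_missing`` is set, in which case its
        feature block is zero-filled (the situation branch dropout trains the
        head for). During training with both bags present, branch dropout may
        omit one branch; inference is deterministic.
        """
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        want = {"HE_ONLY": (HE,), "IHC_ONLY": (IHC,), "DUET": (HE, IHC)}[mode]
        bags = {HE: he_bag, IHC: ihc_bag}
        present = tuple(m for m in want if bags[m] is not None)
        missing = tuple(m for m in want if bags[m] is None)
        if missing and not (mode == "DUET" and allow_missing):
            raise ValueError(f"mode {mode} requires bags for {missing}")
        if not present:
            raise ValueError("no usable branch input")
        kept = present
        if training and mode == "DUET" and len(present) == 2:
            if rng is None:
                raise ValueError("training-mode DUET forward needs an rng for branch dropout")
            kept = branch_dropout_mask(present, self.config.p_branch_dropout, rng)

        feats, attn, caches = {}, {}, {}
        for m in kept:
            f, a, cch = self._forward_branch(self._bag_matrix(bags[m]), need_cache=training)
            feats[m], attn[m], caches[m] = f, a, cch
        z_he = feats.get(HE, np.zeros(self.config.model_dim))
        z_ihc = feats.get(IHC, np.zeros(self.config.model_dim))
        z = np.concatenate([z_he, z_ihc])
        p = self.params
        h1 = z @ p["head_W1"] + p["head_b1"]
        a1 = _gelu(h1)
        logit = float(a1 @ p["head_W2"] + p["head_b2"][0])
        cache = dict(branch=caches, z=z, h1=h1, a1=a1) if training else None
        return ForwardTrace(
            probability=float(expit(logit)), logit=logit, attention=attn,
            branch_kept=kept, branch_features=feats, cache=cache,
        )

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def backward(self, trace: ForwardTrace, y: float) -> dict[str, np.ndarray]:
        """Gradients of the binary cross-entropy at label ``y`` for the traced pass.

        Also fills ``trace.d_inputs[modality]`` with the gradient wrt each
        kept branch's input embeddings (dropped branches receive none, i.e.
        an exactly zero gradient for the step).
        """
        if trace.cache is None:
            raise ValueError("backward needs a trace from a training=True forward pass")
        p = self.params
        grads = self.zero_grads()
        dlogit = float(expit(trace.logit)) - float(y)
        cache = trace.cache
        grads["head_b2"] += dlogit
        grads["head_W2"] += cache["a1"] * dlogit
        da1 = p["head_W2"] * dlogit
        dh1 = da1 * _gelu_grad(cache["h1"])
        grads["head_W1"] += np.outer(cache["z"], dh1)
        grads["head_b1"] += dh1
        dz = p["head_W1"] @ dh1
        D = self.config.model_dim
        dfeat = {HE: dz[:D], IHC: dz[D:]}
        for m, cch in cache["branch"].items():
            trace.d_inputs[m] = self._backward_branch(dfeat[m], cch, grads)
        return grads

    @staticmethod
    def bce_loss(logit: float, y: float) -> float:
        # log(1 + e^logit) - y*logit, computed stably
        return float(np.logaddexp(0.0, logit) - y * logit)

    # -- bookkeeping ----------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, path) -> None:
        meta = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "DuetTransformer":
        with np.load(path) as z:
            cfg = DuoNetConfig(**json.loads(bytes(z["__config__"]).decode()))
            model = cls(cfg, seed=0)
            model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return model


def count_parameters(model: DuetTransformer) -> dict[str, int]:
    """Parameter counts split into the shared trunk and the MLP head.

    Because the trunk is shared across branches, a duet model and a
    single-branch model of the same config have identical trunk counts; the
    head differs only through its ``2 * model_dim`` input width.
    """
    trunk = head = 0
    for k, v in model.params.items():
        if k.startswith("head_"):
            head += v.size
        else:
            trunk += v.size
    return {"trunk": trunk, "head": head, "total": trunk + head}
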