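"""Edge-weighted Graph Isomorphism Network in plain numpy.

The classifier stacks L GIN layers.  Layer k updates node v's representation
by a weighted sum aggregation followed by a small MLP::

    h_v(k) = MLP_k( (1 + eps_k) * h_v(k-1) + sum_{u in N(v)} w_uv * h_u(k-1) )

which in matrix form over all nodes is ``MLP_k(((1+eps_k) I + A_w) H)`` with
A_w the weighted adjacency.  eps_k is either frozen at zero (GIN-0) or a
learnable per-layer scalar (GIN-eps).  Node features at the input are one-hot
ROI identities, so the first aggregation is simply ``(1+eps) I + A_w``.

Each layer's node embeddings are collapsed to a graph embedding by gated
attention pooling: a learned linear gate is passed through a softmax across
nodes (independently per feature dimension, so each gate column sums to one
over nodes) and the graph embedding is the gate-weighted sum of node
embeddings::

    g(k) = sum_i softmax(f_gate(x_i(k))) * x_i(k)

The readout maps each layer's g(k) through its own linear layer to class
scores and sums the scores over layers; dropout is applied to each g(k)
at training time.  Training minimises the softmax cross-entropy with Adam.

Gradients are computed by hand-coded reverse passes for every block
(aggregation, linear, batch norm, ReLU, softmax gate, dropout, readout);
all graphs in a batch share the node count, so every pass is a handful of
batched matrix products.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

SCHEMA_VERSION = "1"
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the GIN classifier.

    Defaults follow the reference setting: 4 GIN layers of 2-layer MLPs,
    dropout 0.2 on the pooled embeddings, epsilon frozen at zero (GIN-0);
    ``epsilon_mode="learnable"`` with ``epsilon_init=0.1`` gives GIN-eps.
    """

    input_dim: int
    n_layers: int = 4
    mlp_depth: int = 2
    hidden_dim: int = 64
    epsilon_mode: str = "fixed_zero"  # or "learnable"
    epsilon_init: float = 0.1
    dropout_rate: float = 0.2
    n_classes: int = 2
    batch_norm: bool = True
    gate_mode: str = "vector"  # or "scalar"
    readout: str = "sum_scores"  # or "concat"
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.mlp_depth < 1 or self.hidden_dim < 1:
            raise ValueError("n_layers, mlp_depth and hidden_dim must be >= 1")
        if self.epsilon_mode not in ("fixed_zero", "learnable"):
            raise ValueError(f"unknown epsilon_mode {self.epsilon_mode!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.gate_mode not in ("vector", "scalar"):
            raise ValueError(f"unknown gate_mode {self.gate_mode!r}")
        if self.readout not in ("sum_scores", "concat"):
            raise ValueError(f"unknown readout {self.readout!r}")

    def layer_in_dim(self, k: int) -> int:
        return self.input_dim if k == 0 else self.hidden_dim

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class ModelState:
    """Learned parameters plus batch-norm running statistics."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    buffers: dict[str, np.ndarray]
    seed: int = 0


# ---------------------------------------------------------------------------
# initialisation

def _glorot(rng: np.random.Generator, n_in: int, n_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out)).astype(dtype)


def init_state(config: ModelConfig, seed: int = 0) -> ModelState:
    """Seeded Glorot-uniform initialisation of all parameters."""
    rng = np.random.default_rng(seed)
    dt = config.np_dtype
    params: dict[str, np.ndarray] = {}
    buffers: dict[str, np.ndarray] = {}
    d = config.hidden_dim
    for k in range(config.n_layers):
        d_in = config.layer_in_dim(k)
        for j in range(config.mlp_depth):
            nin = d_in if j == 0 else d
            params[f"gin{k}.lin{j}.W"] = _glorot(rng, nin, d, dt)
            params[f"gin{k}.lin{j}.b"] = np.zeros(d, dtype=dt)
            if config.batch_norm and j < config.mlp_depth - 1:
                params[f"gin{k}.bn{j}.gamma"] = np.ones(d, dtype=dt)
                params[f"gin{k}.bn{j}.beta"] = np.zeros(d, dtype=dt)
                buffers[f"gin{k}.bn{j}.running_mean"] = np.zeros(d, dtype=dt)
                buffers[f"gin{k}.bn{j}.running_var"] = np.ones(d, dtype=dt)
        if config.epsilon_mode == "learnable":
            params[f"gin{k}.eps"] = np.asarray(config.epsilon_init, dtype=dt)
        gate_out = d if config.gate_mode == "vector" else 1
        params[f"gate{k}.W"] = _glorot(rng, d, gate_out, dt)
        params[f"gate{k}.b"] = np.zeros(gate_out, dtype=dt)
        if config.readout == "sum_scores":
            params[f"read{k}.W"] = _glorot(rng, d, config.n_classes, dt)
            params[f"read{k}.b"] = np.zeros(config.n_classes, dtype=dt)
    if config.readout == "concat":
        params["read.W"] = _glorot(rng, config.n_layers * d, config.n_classes, dt)
        params["read.b"] = np.zeros(config.n_classes, dtype=dt)
    return ModelState(config=config, params=params, buffers=buffers, seed=seed)


def epsilon_of(state: ModelState, k: int) -> float:
    if state.config.epsilon_mode == "learnable":
        return float(state.params[f"gin{k}.eps"])
    return 0.0


# ---------------------------------------------------------------------------
# functional building blocks (single graph; batch handled by the classifier)

def gin_aggregate(h: np.ndarray, adj: np.ndarray, eps: float) -> np.ndarray:
    """Pre-MLP aggregate of one GIN layer: (1+eps) h_v + sum_u w_uv h_u."""
    return (1.0 + eps) * h + adj @ h


def attention_pool(
    x: np.ndarray, gate_w: np.ndarray, gate_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gated attention pooling of node embeddings x (N x d).

    Returns the graph embedding g (length d) and the post-softmax gate
    matrix S whose columns each sum to 1 over nodes.  A vector-valued gate
    (d x d map) weights each feature dimension separately; a scalar gate
    (d x 1 map) applies one weight per node.
    """
    if x.shape[0] < 1:
        raise ValueError("attention pooling needs at least one node")
    f = x @ gate_w + gate_b
    f = f - f.max(axis=0, keepdims=True)
    s = np.exp(f)
    s /= s.sum(axis=0, keepdims=True)
    g = (s * x).sum(axis=0)  # scalar gate (N x 1) broadcasts over feature dims
    return g, s


def readout_predict(
    gs: list[np.ndarray], state: ModelState, training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-layer linear class scores, summed over layers (single graph)."""
    cfg = state.config
    if len(gs) != cfg.n_layers:
        raise ValueError(f"expected {cfg.n_layers} layer embeddings, got {len(gs)}")
    gs = list(gs)
    if training and cfg.dropout_rate > 0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - cfg.dropout_rate
        gs = [g * (rng.random(g.shape) < keep) / keep for g in gs]
    if cfg.readout == "concat":
        return np.concatenate(gs) @ state.params["read.W"] + state.params["read.b"]
    logits = np.zeros(cfg.n_classes, dtype=gs[0].dtype)
    for k, g in enumerate(gs):
        logits = logits + g @ state.params[f"read{k}.W"] + state.params[f"read{k}.b"]
    return logits


# ---------------------------------------------------------------------------
# batched forward / backward

def _flat_gemm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(B, N, i) x (i, o) as one GEMM; faster than batched matmul."""
    out = a.reshape(-1, a.shape[-1]) @ b
    return out.reshape(*a.shape[:-1], b.shape[-1])


def _grad_gemm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """sum_b a_b^T b_b for (B, N, i), (B, N, o) stacks, as one GEMM."""
    return a.reshape(-1, a.shape[-1]).T @ b.reshape(-1, b.shape[-1])


def _softmax_nodes(f: np.ndarray) -> np.ndarray:
    # softmax over the node axis (axis=1) of a (B, N, *) tensor
    f = f - f.max(axis=1, keepdims=True)
    s = np.exp(f)
    return s / s.sum(axis=1, keepdims=True)


class GinClassifier:
    """The full model: L GIN layers, per-layer attention pooling, readout.

    Operates on batches of graphs sharing a node count, presented as a
    (B, N, N) stack of weighted adjacency matrices; input node features are
    the one-hot identity and are folded into the first aggregation.
    """

    def __init__(self, config: ModelConfig, seed: int = 0,
                 state: ModelState | None = None) -> None:
        self.config = config
        self.state = state if state is not None else init_state(config, seed)

    # -- forward ----------------------------------------------------------

    def forward(
        self,
        adj: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        keep_cache: bool = False,
        node_features: np.ndarray | None = None,
    ):
        """Run the network on a (B, N, N) adjacency stack.

        Returns ``(logits, gates, cache)`` where ``logits`` is (B, C),
        ``gates`` the list of per-layer post-softmax node-gate tensors
        (B, N, d_gate) used downstream for saliency, and ``cache`` the
        intermediate values needed by :meth:`backward` (None unless
        requested).

        ``node_features`` defaults to the one-hot identity (the standard
        input), for which the first aggregation reduces to (1+eps) I + A_w
        and is computed without a matrix product.  An explicit (N, input_dim)
        matrix — e.g. a row permutation of the identity when checking graph
        relabelings — is honoured when given.
        """
        cfg = self.config
        p = self.state.params
        adj = np.asarray(adj, dtype=cfg.np_dtype)
        if adj.ndim == 2:
            adj = adj[None]
        b, n, _ = adj.shape
        if n != cfg.input_dim:
            raise ValueError(
                f"graph has {n} nodes but model expects input_dim={cfg.input_dim}")
        if training and cfg.dropout_rate > 0 and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")

        cache: dict = {"adj": adj, "layers": []} if keep_cache else None
        gates: list[np.ndarray] = []
        gs: list[np.ndarray] = []
        h = None  # identity input folded into first aggregation
        if node_features is not None:
            h = np.asarray(node_features, dtype=cfg.np_dtype)
            if h.ndim == 2:
                h = np.broadcast_to(h, (b, *h.shape))
        for k in range(cfg.n_layers):
            eps = epsilon_of(self.state, k)
            if k == 0 and h is None:
                z = adj.copy()
                idx = np.arange(n)
                z[:, idx, idx] += 1.0 + eps
            else:
                z = (1.0 + eps) * h + adj @ h
            lc = {"z_in": h, "z": z} if keep_cache else None
            u = z
            for j in range(cfg.mlp_depth):
                lin_in = u
                u = _flat_gemm(u, p[f"gin{k}.lin{j}.W"]) + p[f"gin{k}.lin{j}.b"]
                bn_cache = None
                if cfg.batch_norm and j < cfg.mlp_depth - 1:
                    u, bn_cache = self._bn_forward(f"gin{k}.bn{j}", u, training)
                relu_mask = u > 0
                u = u * relu_mask
                if keep_cache:
                    lc[f"lin{j}.in"] = lin_in
                    lc[f"bn{j}.cache"] = bn_cache
                    lc[f"relu{j}.mask"] = relu_mask
            x = u  # (B, N, d)
            f = _flat_gemm(x, p[f"gate{k}.W"]) + p[f"gate{k}.b"]
            s = _softmax_nodes(f)
            g = (s * x).sum(axis=1)  # (B, d); scalar gate broadcasts
            gates.append(s)
            gs.append(g)
            if keep_cache:
                lc["x"] = x
                lc["s"] = s
                cache["layers"].append(lc)
            h = x

        # dropout on pooled embeddings, then readout
        gds = []
        masks = []
        for g in gs:
            if training and cfg.dropout_rate > 0:
                keep = 1.0 - cfg.dropout_rate
                mask = (rng.random(g.shape) < keep).astype(g.dtype) / keep
            else:
                mask = None
            masks.append(mask)
            gds.append(g * mask if mask is not None else g)
        if cfg.readout == "concat":
            logits = np.concatenate(gds, axis=1) @ p["read.W"] + p["read.b"]
        else:
            logits = np.zeros((b, cfg.n_classes), dtype=cfg.np_dtype)
            for k, gd in enumerate(gds):
                logits += gd @ p[f"read{k}.W"] + p[f"read{k}.b"]
        if keep_cache:
            cache["gs"] = gs
            cache["gds"] = gds
            cache["drop_masks"] = masks
        return logits, gates, cache

    def _bn_forward(self, name: str, u: np.ndarray, training: bool):
        p, buf = self.state.params, self.state.buffers
        gamma, beta = p[f"{name}.gamma"], p[f"{name}.beta"]
        flat = u.reshape(-1, u.shape[-1])
        if training:
            mu = flat.mean(axis=0)
            var = flat.var(axis=0)
            buf[f"{name}.running_mean"] *= 1.0 - _BN_MOMENTUM
            buf[f"{name}.running_mean"] += _BN_MOMENTUM * mu
            buf[f"{name}.running_var"] *= 1.0 - _BN_MOMENTUM
            buf[f"{name}.running_var"] += _BN_MOMENTUM * var
        else:
            mu = buf[f"{name}.running_mean"]
            var = buf[f"{name}.running_var"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        uhat = (u - mu) * inv_std
        out = gamma * uhat + beta
        return out, {"uhat": uhat, "inv_std": inv_std, "training": training}

    # -- loss and gradients ----------------------------------------------

    def loss_and_grad(
        self, adj: np.ndarray, labels: np.ndarray,
        rng: np.random.Generator | None = None, training: bool = True,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean softmax cross-entropy and its gradient w.r.t. every parameter."""
        logits, _, cache = self.forward(adj, training=training, rng=rng,
                                        keep_cache=True)
        b = logits.shape[0]
        y = np.asarray(labels, dtype=int)
        shifted = logits - logits.max(axis=1, keepdims=True)
        logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        loss = float(-logp[np.arange(b), y].mean())
        dlogits = np.exp(logp)
        dlogits[np.arange(b), y] -= 1.0
        dlogits /= b
        grads = self._backward(dlogits, cache)
        return loss, grads

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        cfg = self.config
        p = self.state.params
        adj = cache["adj"]
        b, n, _ = adj.shape
        grads: dict[str, np.ndarray] = {}

        # readout
        dgs: list[np.ndarray] = []
        if cfg.readout == "concat":
            gcat = np.concatenate(cache["gds"], axis=1)
            grads["read.W"] = gcat.T @ dlogits
            grads["read.b"] = dlogits.sum(axis=0)
            dgcat = dlogits @ p["read.W"].T
            dgs = list(np.split(dgcat, cfg.n_layers, axis=1))
        else:
            for k in range(cfg.n_layers):
                gd = cache["gds"][k]
                grads[f"read{k}.W"] = gd.T @ dlogits
                grads[f"read{k}.b"] = dlogits.sum(axis=0)
                dgs.append(dlogits @ p[f"read{k}.W"].T)
        for k in range(cfg.n_layers):
            mask = cache["drop_masks"][k]
            if mask is not None:
                dgs[k] = dgs[k] * mask

        # walk layers top-down; dh carries the gradient flowing into layer
        # k's output x from layer k+1's aggregation
        dh = None
        for k in reversed(range(cfg.n_layers)):
            lc = cache["layers"][k]
            x, s = lc["x"], lc["s"]
            dg = dgs[k][:, None, :]  # (B, 1, d)

            # pooling backward: g = sum_i s_i * x_i, s = softmax_nodes(f)
            if cfg.gate_mode == "scalar":
                ds = (dg * x).sum(axis=2, keepdims=True)
            else:
                ds = x * dg
            dx = s * dg
            df = s * (ds - (s * ds).sum(axis=1, keepdims=True))
            grads[f"gate{k}.W"] = _grad_gemm(x, df)
            grads[f"gate{k}.b"] = df.sum(axis=(0, 1))
            dx = dx + _flat_gemm(df, p[f"gate{k}.W"].T)
            if dh is not None:
                dx = dx + dh

            # MLP backward
            du = dx
            for j in reversed(range(cfg.mlp_depth)):
                du = du * lc[f"relu{j}.mask"]
                bn_cache = lc.get(f"bn{j}.cache")
                if bn_cache is not None:
                    du = self._bn_backward(f"gin{k}.bn{j}", du, bn_cache, grads)
                lin_in = lc[f"lin{j}.in"]
                grads[f"gin{k}.lin{j}.W"] = _grad_gemm(lin_in, du)
                grads[f"gin{k}.lin{j}.b"] = du.sum(axis=(0, 1))
                du = _flat_gemm(du, p[f"gin{k}.lin{j}.W"].T)
            dz = du

            # aggregation backward
            eps = epsilon_of(self.state, k)
            if cfg.epsilon_mode == "learnable":
                if lc["z_in"] is None:  # identity input folded into layer 0
                    idx = np.arange(n)
                    deps = dz[:, idx, idx].sum()
                else:
                    deps = float((lc["z_in"] * dz).sum())
                grads[f"gin{k}.eps"] = np.asarray(deps, dtype=cfg.np_dtype)
            if k > 0:
                # z = (1+eps) h + A h with A symmetric
                dh = (1.0 + eps) * dz + adj @ dz
            else:
                dh = None
        return grads

    def _bn_backward(self, name: str, dv: np.ndarray, bn_cache: dict,
                     grads: dict) -> np.ndarray:
        gamma = self.state.params[f"{name}.gamma"]
        uhat, inv_std = bn_cache["uhat"], bn_cache["inv_std"]
        grads[f"{name}.gamma"] = (dv * uhat).sum(axis=(0, 1))
        grads[f"{name}.beta"] = dv.sum(axis=(0, 1))
        duhat = dv * gamma
        if not bn_cache["training"]:
            return duhat * inv_std
        m = uhat.shape[0] * uhat.shape[1]
        duhat_flat_sum = duhat.sum(axis=(0, 1))
        duhat_uhat_sum = (duhat * uhat).sum(axis=(0, 1))
        return (inv_std / m) * (m * duhat - duhat_flat_sum - uhat * duhat_uhat_sum)

    # -- inference helpers -------------------------------------------------

    def predict(self, adj: np.ndarray) -> np.ndarray:
        """Class labels; exact logit ties resolve to the control class (0)."""
        logits, _, _ = self.forward(adj, training=False)
        return (logits[:, 1] > logits[:, 0]).astype(int)

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        save_state(self.state, path)

    @classmethod
    def load(cls, path) -> "GinClassifier":
        state = load_state(path)
        return cls(state.config, state=state)


class Adam:
    """Adam optimizer over a named-parameter dict (classic L2 weight decay)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.005,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for key, param in self.params.items():
            g = grads[key]
            if self.weight_decay:
                g = g + self.weight_decay * param
            self.m[key] = self.b1 * self.m[key] + (1.0 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1.0 - self.b2) * g * g
            mhat = self.m[key] / b1t
            vhat = self.v[key] / b2t
            param -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(param.dtype)


def save_state(state: ModelState, path) -> None:
    """Single-file checkpoint: config as JSON plus raw parameter arrays."""
    meta = {"schema_version": SCHEMA_VERSION, "seed": state.seed,
            "config": asdict(state.config)}
    arrays = {f"param/{k}": v for k, v in state.params.items()}
    arrays |= {f"buffer/{k}": v for k, v in state.buffers.items()}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_state(path) -> ModelState:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode("utf-8"))
        if meta.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"checkpoint schema {meta.get('schema_version')!r} not supported")
        params = {k[len("param/"):]: npz[k] for k in npz.files
                  if k.startswith("param/")}
        buffers = {k[len("buffer/"):]: npz[k] for k in npz.files
                   if k.startswith("buffer/")}
    config = ModelConfig(**meta["config"])
    return ModelState(config=config, params=params, buffers=buffers,
                      seed=meta["seed"])
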