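"""Graph-convolutional deep-clustering model for biotype detection.

The model is an autoencoder built from graph-convolution layers
H' = act(A_hat H W + b) on the population graph, with three coupled
objectives on the shared embedding Z:

* reconstruction loss L_rec — mean squared error between node features and
  their decoding, keeping embeddings faithful to the FNC input;
* diagnostic loss L_ce — binary cross-entropy of a one-logit head
  separating patients from controls, keeping embeddings group
  discriminative;
* clustering loss L_cluster — a differentiable deep K-means objective on
  patient embeddings, a soft-min over squared centroid distances whose
  inverse temperature alpha anneals toward the hard K-means objective.

Total objective: L = gamma_rec * L_rec + gamma_ce * L_ce
                     + gamma_cluster * L_cluster,
with defaults gamma = (0.01, 0.01, 0.1) and Adam at learning rate 1e-3.

Training is two-phase: (1) pretrain encoder/decoder/head without the
clustering term; (2) initialize centroids by greedy farthest-point seeding
plus classical K-means on the pretrained patient embeddings, then jointly
minimize the full objective, annealing alpha geometrically. Gradients are
computed analytically (verified against finite differences in the test
suite) and applied with a hand-rolled Adam optimizer; all randomness flows
from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .exceptions import (
    AssignmentError,
    ConfigurationError,
    DataShapeError,
    DivergenceError,
    EmptyClusterError,
)
from .graph import PopulationGraph, normalize_adjacency, require_trainable


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the joint objective and optimization schedule."""

    K: int = 2
    gamma_rec: float = 0.01
    gamma_ce: float = 0.01
    gamma_cluster: float = 0.1
    learning_rate: float = 0.001
    hidden_dims: tuple[int, ...] = (256,)
    embedding_dim: int = 64
    pretrain_epochs: int = 100
    joint_epochs: int = 200
    alpha_init: float = 1.0
    alpha_final: float = 1000.0
    embed_norm: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.gamma_rec, self.gamma_ce, self.gamma_cluster) < 0:
            raise ConfigurationError("loss weights must be non-negative")
        if self.K < 2:
            raise ConfigurationError("K must be at least 2")
        if self.embedding_dim <= 0 or any(h <= 0 for h in self.hidden_dims):
            raise ConfigurationError("layer widths must be positive")
        if self.alpha_init <= 0 or self.alpha_final < self.alpha_init:
            raise ConfigurationError("alpha schedule must be positive and non-decreasing")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LossBreakdown:
    """Per-epoch loss components; ``total`` is their gamma-weighted sum."""

    l_rec: float
    l_ce: float
    l_cluster: float
    total: float

    def __post_init__(self):
        if min(self.l_rec, self.l_ce, self.l_cluster) < -1e-12:
            raise ConfigurationError("loss components must be non-negative")


def total_loss(l_rec: float, l_ce: float, l_cluster: float, config: TrainingConfig) -> LossBreakdown:
    total = (
        config.gamma_rec * l_rec
        + config.gamma_ce * l_ce
        + config.gamma_cluster * l_cluster
    )
    return LossBreakdown(float(l_rec), float(l_ce), float(l_cluster), float(total))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def _resolve_activation(activation):
    if callable(activation):
        return activation
    if activation == "relu":
        return lambda x: np.maximum(x, 0.0)
    if activation == "linear":
        return lambda x: x
    raise ConfigurationError(f"unknown activation {activation!r}")


def gcn_layer(h: np.ndarray, a_hat, w: np.ndarray, activation="relu") -> np.ndarray:
    """One graph convolution: activation(A_hat @ H @ W)."""
    h = np.asarray(h, dtype=float)
    if h.shape[1] != np.asarray(w).shape[0]:
        raise DataShapeError(
            f"H has {h.shape[1]} columns but W has {np.asarray(w).shape[0]} rows"
        )
    if a_hat.shape[1] != h.shape[0]:
        raise DataShapeError("A_hat and H shapes do not conform")
    return _resolve_activation(activation)(a_hat @ h @ w)


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    x, x_hat = np.asarray(x, dtype=float), np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise DataShapeError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def diagnostic_ce_loss(logits: np.ndarray, y: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean binary cross-entropy of sigmoid(logits) vs labels over masked nodes."""
    logits = np.asarray(logits, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if logits.shape != y.shape:
        raise DataShapeError("logits and labels must align")
    if mask is None:
        mask = np.ones_like(y, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise DataShapeError("empty mask: no nodes to compute cross-entropy on")
    z, t = logits[mask], y[mask]
    # stable softplus(z) - t*z
    loss = np.logaddexp(0.0, z) - t * z
    return float(loss.mean())


def _soft_assignments(z: np.ndarray, centroids: np.ndarray, alpha: float):
    d2 = ((z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    logits = -alpha * d2
    logits -= logits.max(axis=1, keepdims=True)
    s = np.exp(logits)
    s /= s.sum(axis=1, keepdims=True)
    return d2, s


def deep_kmeans_loss(z_patients: np.ndarray, centroids: np.ndarray, alpha: float) -> float:
    """Soft-min clustering loss (1/p) sum_i sum_k softmax_k(-alpha d_ik) d_ik.

    As alpha -> inf this converges to the classical K-means objective
    (mean squared distance to the nearest centroid).
    """
    z = np.asarray(z_patients, dtype=float)
    mu = np.asarray(centroids, dtype=float)
    if alpha <= 0:
        raise ConfigurationError("alpha must be positive")
    if z.shape[0] < mu.shape[0]:
        raise ConfigurationError("need at least K points")
    if not np.all(np.isfinite(z)):
        raise DivergenceError("non-finite embeddings")
    d2, s = _soft_assignments(z, mu, alpha)
    return float((s * d2).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# parameters, forward and backward passes
# ---------------------------------------------------------------------------

def _layer_dims(d: int, config: TrainingConfig):
    enc = [d, *config.hidden_dims, config.embedding_dim]
    dec = [config.embedding_dim, *reversed(config.hidden_dims), d]
    return enc, dec


def _init_params(d: int, config: TrainingConfig, rng: np.random.Generator) -> dict:
    enc, dec = _layer_dims(d, config)
    params = {}
    for prefix, dims in (("enc", enc), ("dec", dec)):
        for l in range(len(dims) - 1):
            fan_in, fan_out = dims[l], dims[l + 1]
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            params[f"{prefix}_W_{l}"] = rng.uniform(-limit, limit, size=(fan_in, fan_out))
            params[f"{prefix}_b_{l}"] = np.zeros(fan_out)
    params["clf_w"] = rng.uniform(
        -np.sqrt(6.0 / (config.embedding_dim + 1)),
        np.sqrt(6.0 / (config.embedding_dim + 1)),
        size=config.embedding_dim,
    )
    params["clf_b"] = np.zeros(1)
    return params


def _stack_forward(h, a_hat, params, prefix, n_layers, cache, first_ah=None):
    """Forward through a stack of graph convolutions; ReLU except last layer."""
    for l in range(n_layers):
        ah = first_ah if (l == 0 and first_ah is not None) else a_hat @ h
        pre = ah @ params[f"{prefix}_W_{l}"] + params[f"{prefix}_b_{l}"]
        h = np.maximum(pre, 0.0) if l < n_layers - 1 else pre
        cache.append({"ah": ah, "pre": pre, "layer": l, "prefix": prefix})
    return h


def _stack_backward(grad_out, a_hat, params, cache, grads):
    """Backward through a stack; returns gradient wrt the stack input."""
    g = grad_out
    for entry in reversed(cache):
        l, prefix = entry["layer"], entry["prefix"]
        if l < _stack_len(cache) - 1:
            g = g * (entry["pre"] > 0)
        w = params[f"{prefix}_W_{l}"]
        grads[f"{prefix}_W_{l}"] = grads.get(f"{prefix}_W_{l}", 0.0) + entry["ah"].T @ g
        grads[f"{prefix}_b_{l}"] = grads.get(f"{prefix}_b_{l}", 0.0) + g.sum(axis=0)
        # A_hat is symmetric, so A_hat^T = A_hat
        g = a_hat @ (g @ w.T)
    return g


def _stack_len(cache):
    return max(e["layer"] for e in cache) + 1


def _forward(x, a_hat, params, n_enc, n_dec, ax_cache=None, embed_norm=True):
    enc_cache, dec_cache = [], []
    h = _stack_forward(x, a_hat, params, "enc", n_enc, enc_cache, first_ah=ax_cache)
    bn = None
    if embed_norm:
        # full-batch normalization of the embedding columns (no affine):
        # fixes the embedding variance budget so no loss term can win by
        # inflating scale along a single direction
        mu = h.mean(axis=0)
        sd = np.sqrt(h.var(axis=0) + 1e-8)
        z = (h - mu) / sd
        bn = {"sd": sd, "z": z}
    else:
        z = h
    x_hat = _stack_forward(z, a_hat, params, "dec", n_dec, dec_cache)
    logits = z @ params["clf_w"] + params["clf_b"][0]
    return {
        "z": z, "x_hat": x_hat, "logits": logits,
        "enc": enc_cache, "dec": dec_cache, "bn": bn,
    }


def _bn_backward(gz, bn):
    """Gradient through column-wise batch normalization."""
    z = bn["z"]
    return (gz - gz.mean(axis=0) - z * (gz * z).mean(axis=0)) / bn["sd"]


def _losses_and_grads(x, y, a_hat, params, fwd, config, ce_mask, cluster_idx, alpha, with_cluster):
    """Analytic gradients of the weighted objective wrt all parameters."""
    grads: dict[str, np.ndarray] = {}
    z, x_hat, logits = fwd["z"], fwd["x_hat"], fwd["logits"]

    l_rec = reconstruction_loss(x, x_hat)
    g_xhat = config.gamma_rec * 2.0 * (x_hat - x) / x.size
    gz = _stack_backward(g_xhat, a_hat, params, fwd["dec"], grads)

    l_ce = diagnostic_ce_loss(logits, y, ce_mask)
    p = 1.0 / (1.0 + np.exp(-logits))
    g_logit = np.zeros_like(logits)
    m = ce_mask.sum()
    g_logit[ce_mask] = config.gamma_ce * (p[ce_mask] - y[ce_mask]) / m
    grads["clf_w"] = z.T @ g_logit
    grads["clf_b"] = np.array([g_logit.sum()])
    gz = gz + np.outer(g_logit, params["clf_w"])

    l_cluster = 0.0
    if with_cluster:
        mu = params["centroids"]
        zp = z[cluster_idx]
        p_count = zp.shape[0]
        d2, s = _soft_assignments(zp, mu, alpha)
        l_cluster = float((s * d2).sum(axis=1).mean())
        inner = (s * d2).sum(axis=1, keepdims=True)
        coef = (config.gamma_cluster / p_count) * s * (1.0 - alpha * (d2 - inner))
        diff = zp[:, None, :] - mu[None, :, :]
        gz_cl = 2.0 * (coef[:, :, None] * diff).sum(axis=1)
        grads["centroids"] = -2.0 * (coef[:, :, None] * diff).sum(axis=0)
        gz_full = np.zeros_like(gz)
        gz_full[cluster_idx] = gz_cl
        gz = gz + gz_full

    if fwd["bn"] is not None:
        gz = _bn_backward(gz, fwd["bn"])
    _stack_backward(gz, a_hat, params, fwd["enc"], grads)
    parts = total_loss(l_rec, l_ce, l_cluster, config)
    return parts, grads


class _Adam:
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class BiotypeModel:
    """Trained model state and derived biotype structure.

    ``assignments`` maps every patient (in graph order) to a 1-based biotype
    label, relabeled so biotype 1 is the largest cluster; ``templates`` are
    per-biotype means of the raw FNC vectors (never of embeddings).
    """

    params: dict
    embeddings: np.ndarray
    centroids: np.ndarray
    assignments: np.ndarray
    patient_index: np.ndarray
    cluster_index: np.ndarray
    patient_ids: list[str]
    templates: np.ndarray
    config: TrainingConfig
    loss_history: list[LossBreakdown]
    graph: PopulationGraph


def farthest_point_seeds(points: np.ndarray, k: int) -> np.ndarray:
    """Greedy farthest-point centroid seeding; first seed is the point
    farthest from the data mean (deterministic)."""
    center = points.mean(axis=0)
    idx = [int(np.argmax(((points - center) ** 2).sum(axis=1)))]
    d2 = ((points - points[idx[0]]) ** 2).sum(axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))
        idx.append(nxt)
        d2 = np.minimum(d2, ((points - points[nxt]) ** 2).sum(axis=1))
    return points[idx].copy()


def _anneal(config: TrainingConfig, epoch: int) -> float:
    if config.joint_epochs <= 1:
        return config.alpha_final
    frac = epoch / (config.joint_epochs - 1)
    return float(config.alpha_init * (config.alpha_final / config.alpha_init) ** frac)


def _prepare(graph: PopulationGraph, config: TrainingConfig, train_mask, allow_disconnected=False):
    if not allow_disconnected:
        require_trainable(graph)
    if train_mask is None:
        train_mask = np.ones(graph.n_nodes, dtype=bool)
    train_mask = np.asarray(train_mask, dtype=bool)
    a_hat = sp.csr_matrix(normalize_adjacency(graph))
    cluster_idx = np.flatnonzero(graph.patient_mask & train_mask)
    # column-standardized node features: the shared population-mean FNC and
    # per-edge scale carry no subject information and would dominate both
    # the reconstruction objective and its conditioning
    x = np.asarray(graph.X, dtype=float)
    x = (x - x.mean(axis=0)) / np.maximum(x.std(axis=0), 1e-12)
    return a_hat, train_mask, cluster_idx, x


def pretrain_embeddings(
    graph: PopulationGraph,
    config: TrainingConfig,
    train_mask: np.ndarray | None = None,
    allow_disconnected: bool = False,
):
    """Phase-1 training (reconstruction + diagnostic CE, no clustering term).

    Returns (patient embeddings restricted to the training cluster set,
    all-node embeddings, parameters, loss history). Used for model
    selection and for the clustering-free autoencoder baseline.
    """
    a_hat, train_mask, cluster_idx, x = _prepare(graph, config, train_mask, allow_disconnected)
    y = graph.labels.astype(float)
    rng = np.random.default_rng(config.seed)
    params = _init_params(x.shape[1], config, rng)
    n_enc = len(config.hidden_dims) + 1
    opt = _Adam(config.learning_rate)
    history: list[LossBreakdown] = []
    ax = a_hat @ x
    for epoch in range(config.pretrain_epochs):
        fwd = _forward(x, a_hat, params, n_enc, n_enc, ax_cache=ax, embed_norm=config.embed_norm)
        parts, grads = _losses_and_grads(
            x, y, a_hat, params, fwd, config, train_mask, cluster_idx,
            alpha=1.0, with_cluster=False,
        )
        if not np.isfinite(parts.total):
            raise DivergenceError("non-finite loss during pretraining", epoch=epoch)
        opt.step(params, grads)
        history.append(parts)
    fwd = _forward(x, a_hat, params, n_enc, n_enc, ax_cache=ax, embed_norm=config.embed_norm)
    z = fwd["z"]
    return z[cluster_idx], z, params, history


def train(
    graph: PopulationGraph,
    config: TrainingConfig,
    train_mask: np.ndarray | None = None,
    allow_disconnected: bool = False,
) -> BiotypeModel:
    """Two-phase training of the full joint objective; returns the fitted model."""
    a_hat, train_mask, cluster_idx, x = _prepare(graph, config, train_mask, allow_disconnected)
    if config.K > cluster_idx.size:
        raise ConfigurationError(
            f"K={config.K} exceeds the {cluster_idx.size} patients available for clustering"
        )
    zp, _, params, history = pretrain_embeddings(graph, config, train_mask, allow_disconnected)

    seeds = farthest_point_seeds(zp, config.K)
    km = KMeans(n_clusters=config.K, init=seeds, n_init=1, random_state=config.seed)
    km.fit(zp)
    params["centroids"] = km.cluster_centers_.astype(float)

    y = graph.labels.astype(float)
    n_enc = len(config.hidden_dims) + 1
    opt = _Adam(config.learning_rate)
    ax = a_hat @ x
    reseeds = 0
    for epoch in range(config.joint_epochs):
        alpha = _anneal(config, epoch)
        fwd = _forward(x, a_hat, params, n_enc, n_enc, ax_cache=ax, embed_norm=config.embed_norm)
        parts, grads = _losses_and_grads(
            x, y, a_hat, params, fwd, config, train_mask, cluster_idx,
            alpha=alpha, with_cluster=True,
        )
        if not np.isfinite(parts.total):
            raise DivergenceError("non-finite loss during joint training", epoch=epoch)
        opt.step(params, grads)
        history.append(parts)

        zp_now = _forward(x, a_hat, params, n_enc, n_enc, ax_cache=ax, embed_norm=config.embed_norm)["z"][cluster_idx]
        d2 = ((zp_now[:, None, :] - params["centroids"][None, :, :]) ** 2).sum(axis=2)
        hard = d2.argmin(axis=1)
        missing = [k for k in range(config.K) if not np.any(hard == k)]
        if missing:
            reseeds += len(missing)
            if reseeds > 3:
                raise EmptyClusterError(
                    f"cluster(s) {missing} emptied repeatedly during joint training"
                )
            for k in missing:
                far = int(np.argmax(d2.min(axis=1)))
                params["centroids"][k] = zp_now[far]

    fwd = _forward(x, a_hat, params, n_enc, n_enc, ax_cache=ax, embed_norm=config.embed_norm)
    model = BiotypeModel(
        params=params,
        embeddings=fwd["z"],
        centroids=params["centroids"],
        assignments=np.empty(0, dtype=int),
        patient_index=np.flatnonzero(graph.patient_mask),
        cluster_index=cluster_idx,
        patient_ids=[graph.ids[i] for i in np.flatnonzero(graph.patient_mask)],
        templates=np.empty((0, x.shape[1])),
        config=config,
        loss_history=history,
        graph=graph,
    )
    assign_biotypes(model)
    return model


def assign_biotypes(model: BiotypeModel) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid biotype assignment with canonical relabeling.

    Labels are renumbered by descending cluster size on the training
    cluster set (ties broken by descending centroid norm); biotype 1 is the
    largest cluster. Templates are per-biotype means of the raw FNC vectors
    of training-set members. Updates the model in place and returns
    (assignments, templates).
    """
    z = model.embeddings[model.patient_index]
    mu = model.centroids
    d2 = ((z[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    hard = d2.argmin(axis=1)

    in_cluster_set = np.isin(model.patient_index, model.cluster_index)
    sizes = np.array([(hard[in_cluster_set] == k).sum() for k in range(mu.shape[0])])
    if np.any(sizes == 0):
        raise EmptyClusterError(
            f"biotype(s) {list(np.flatnonzero(sizes == 0))} have no members; "
            "rerun with a different seed or smaller K"
        )
    norms = np.linalg.norm(mu, axis=1)
    order = sorted(range(mu.shape[0]), key=lambda k: (-sizes[k], -norms[k]))
    relabel = np.empty(mu.shape[0], dtype=int)
    for new, old in enumerate(order):
        relabel[old] = new
    assignments = relabel[hard] + 1  # 1-based biotype labels

    x = model.graph.X
    templates = np.vstack(
        [
            x[model.cluster_index][assignments[in_cluster_set] == b].mean(axis=0)
            for b in range(1, mu.shape[0] + 1)
        ]
    )
    model.assignments = assignments
    model.centroids = mu[order]
    model.params["centroids"] = model.centroids
    model.templates = templates
    return assignments, templates


def nearest_centroid_labels(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """1-based nearest-centroid labels (no relabeling)."""
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1) + 1


def save_model(model: BiotypeModel, path) -> None:
    """Checkpoint: parameter container (.npz) + JSON metadata sidecar."""
    import pathlib

    path = pathlib.Path(path)
    np.savez(
        path,
        **{k: v for k, v in model.params.items()},
        embeddings=model.embeddings,
        assignments=model.assignments,
        templates=model.templates,
        patient_index=model.patient_index,
        cluster_index=model.cluster_index,
    )
    meta = {
        "config": model.config.to_dict(),
        "patient_ids": model.patient_ids,
        "loss_history": [asdict(h) for h in model.loss_history],
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
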