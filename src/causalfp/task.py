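"""Task fingerprinting with a five-layer graph attention classifier.

Each causal signature becomes a directed graph: the ``m`` state regions
are nodes, node ``i`` carries row ``i`` of ``R = [Q A B1 B2]`` as its
feature vector, and the row-normalized magnitude of ``A`` supplies
directed, weighted edges (``j -> i`` with the weight of region j's lagged
influence on region i).

The classifier mirrors a compact attention architecture: a GATv2 block
(4 heads x 32 features) summed with a linear skip path (128 channels),
top-k node pooling (ratio 0.8), a second GATv2 block (2 heads x 32) with a
64-channel skip, global mean pooling to a single 64-vector, and a linear
head with log-softmax over the task classes (8 by default). Attention
dropout 0.30 and per-epoch edge dropout 0.10 are active during training
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import CausalSignature
from .nn import Adam, Tensor, cat

__all__ = [
    "SignatureGraph",
    "TaskClassifierConfig",
    "build_signature_graph",
    "init_classifier",
    "TaskClassifier",
    "train_classifier",
    "predict_task",
]


def _normalize_adjacency(A: np.ndarray, scheme: str = "row") -> np.ndarray:
    """Turn the slow transition block into edge weights.

    ``"row"`` (default): |A| with each row divided by its absolute sum, so
    incoming influence on every region sums to one (all-zero rows stay
    zero). ``"sym"``: symmetric normalization D^-1/2 |A| D^-1/2.
    ``"maxabs"``: |A| scaled by its largest magnitude.
    """
    W = np.abs(np.asarray(A, dtype=float))
    if scheme == "row":
        sums = W.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        return W / sums
    if scheme == "sym":
        d = W.sum(axis=1)
        d[d == 0] = 1.0
        inv_sqrt = 1.0 / np.sqrt(d)
        return W * inv_sqrt[:, None] * inv_sqrt[None, :]
    if scheme == "maxabs":
        peak = W.max()
        return W / peak if peak > 0 else W
    raise ValueError(f"unknown adjacency scheme {scheme!r}")


@dataclass
class SignatureGraph:
    """Graph view of one signature: node features, weighted adjacency, label."""

    node_features: np.ndarray  # m x (2m + 2n)
    adjacency: np.ndarray  # m x m, entry (i, j) = weight of edge j -> i
    label: int

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        m = self.node_features.shape[0]
        if self.adjacency.shape != (m, m):
            raise ValueError("adjacency must be m x m")
        if not np.isfinite(self.adjacency).all():
            raise ValueError("adjacency contains non-finite weights")

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.node_features.shape[1]

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        """Directed edges as (source j, target i, weight), nonzero entries only."""
        tgt, src = np.nonzero(self.adjacency)
        return [(int(j), int(i), float(self.adjacency[i, j])) for i, j in zip(tgt, src)]


def build_signature_graph(
    sig: CausalSignature, label: int, adjacency_scheme: str = "row"
) -> SignatureGraph:
    """Convert a signature into a labeled graph for the classifier."""
    return SignatureGraph(
        node_features=sig.R,
        adjacency=_normalize_adjacency(sig.A, adjacency_scheme),
        label=int(label),
    )


@dataclass
class TaskClassifierConfig:
    """Architecture and training hyperparameters of the task classifier."""

    heads1: int = 4
    out1: int = 32
    skip1: int = 128
    pool_ratio: float = 0.8
    heads2: int = 2
    out2: int = 32
    skip2: int = 64
    attn_dropout: float = 0.30
    edge_dropout: float = 0.10
    classes: int = 8
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    patience: int = 20
    val_fraction: float = 0.2
    use_edge_weights: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.out1 * self.heads1 != self.skip1:
            raise ValueError("skip1 must equal out1 * heads1")
        if self.out2 * self.heads2 != self.skip2:
            raise ValueError("skip2 must equal out2 * heads2")
        if not (0.0 < self.pool_ratio <= 1.0):
            raise ValueError("pool_ratio must lie in (0, 1]")
        if self.classes < 2:
            raise ValueError("need at least two classes")


class _GATv2Block:
    """Dense batched GATv2 attention with a parallel linear skip path.

    Attention logits follow the GATv2 form
    ``e_ij = a^T LeakyReLU(W_s x_j + W_t x_i [+ w_e * adj_ij])`` for the
    directed edge j -> i; softmax over the in-neighborhood of i (self-loops
    added), output is the attention-weighted sum of transformed sources,
    heads concatenated, plus the skip projection of the raw features.
    """

    def __init__(self, rng, in_dim, out_dim, heads, use_edge_weights):
        def glorot(*shape):
            limit = math.sqrt(6.0 / (shape[0] + shape[-1]))
            return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)

        self.heads = heads
        self.out_dim = out_dim
        self.use_edge_weights = use_edge_weights
        self.W_src = [glorot(in_dim, out_dim) for _ in range(heads)]
        self.W_tgt = [glorot(in_dim, out_dim) for _ in range(heads)]
        self.attn = [glorot(out_dim, 1) for _ in range(heads)]
        self.w_edge = [
            Tensor(np.zeros(out_dim), requires_grad=True) for _ in range(heads)
        ]
        self.W_skip = glorot(in_dim, out_dim * heads)
        self.bias = Tensor(np.zeros(out_dim * heads), requires_grad=True)

    def params(self):
        out = [*self.W_src, *self.W_tgt, *self.attn, self.W_skip, self.bias]
        if self.use_edge_weights:
            out.extend(self.w_edge)
        return out

    def __call__(self, X: Tensor, adj: np.ndarray, *, rng=None, attn_dropout=0.0):
        B, N, _ = X.shape
        mask = adj != 0
        eye = np.eye(N, dtype=bool)
        mask = mask | eye  # self-loops always attend
        adj_sl = np.where(eye, 1.0, adj)
        neg = np.where(mask, 0.0, -1e9)

        head_outs = []
        for h in range(self.heads):
            S = X @ self.W_src[h]  # (B, N, F) source transform
            Tt = X @ self.W_tgt[h]  # (B, N, F) target transform
            # logits e[b, i, j]: target i on axis 1, source j on axis 2
            G = Tt.reshape(B, N, 1, self.out_dim) + S.reshape(B, 1, N, self.out_dim)
            if self.use_edge_weights:
                G = G + self.w_edge[h] * adj_sl[..., None]
            e = (G.leaky_relu(0.2) @ self.attn[h]).reshape(B, N, N) + neg
            alpha = e.softmax(axis=2)
            if attn_dropout > 0.0 and rng is not None:
                keep = rng.random((B, N, N)) >= attn_dropout
                alpha = alpha * (keep / (1.0 - attn_dropout))
            head_outs.append(alpha @ S)
        out = cat(head_outs, axis=-1) + X @ self.W_skip + self.bias
        return out.leaky_relu(0.01)


class _TopKPool:
    """Projection-score top-k node pooling with a tanh gate."""

    def __init__(self, rng, in_dim, ratio):
        limit = math.sqrt(6.0 / (in_dim + 1))
        self.proj = Tensor(rng.uniform(-limit, limit, size=(in_dim, 1)), requires_grad=True)
        self.ratio = ratio

    def params(self):
        return [self.proj]

    def __call__(self, X: Tensor, adj: np.ndarray):
        B, N, _ = X.shape
        k = math.ceil(self.ratio * N)
        score = X @ self.proj  # (B, N, 1)
        # descending by score, ties to the lowest node index (stable sort)
        order = np.argsort(-score.data[..., 0], axis=1, kind="stable")
        idx = np.sort(order[:, :k], axis=1)  # keep original node order
        Xk = X.gather_nodes(idx) * score.gather_nodes(idx).tanh()
        batch = np.arange(B)[:, None, None]
        adj_k = adj[batch, idx[:, :, None], idx[:, None, :]]
        return Xk, adj_k


class TaskClassifier:
    """Five-layer graph attention network for task identification."""

    def __init__(self, cfg: TaskClassifierConfig, feature_dim: int):
        self.cfg = cfg
        self.feature_dim = feature_dim
        rng = np.random.default_rng(cfg.seed)
        self.gat1 = _GATv2Block(rng, feature_dim, cfg.out1, cfg.heads1, cfg.use_edge_weights)
        self.pool = _TopKPool(rng, cfg.skip1, cfg.pool_ratio)
        self.gat2 = _GATv2Block(rng, cfg.skip1, cfg.out2, cfg.heads2, cfg.use_edge_weights)
        limit = math.sqrt(6.0 / (cfg.skip2 + cfg.classes))
        self.W_head = Tensor(
            rng.uniform(-limit, limit, size=(cfg.skip2, cfg.classes)), requires_grad=True
        )
        self.b_head = Tensor(np.zeros(cfg.classes), requires_grad=True)
        self.trained = False

    def params(self):
        return [
            *self.gat1.params(),
            *self.pool.params(),
            *self.gat2.params(),
            self.W_head,
            self.b_head,
        ]

    def forward(
        self,
        feats: np.ndarray,
        adj: np.ndarray,
        *,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Batched forward pass: (B, N, F) features -> (B, C) log-probs."""
        if feats.shape[-1] != self.feature_dim:
            raise ValueError(
                f"graph feature width {feats.shape[-1]} does not match "
                f"classifier input width {self.feature_dim}"
            )
        drop = self.cfg.attn_dropout if training else 0.0
        X = Tensor(feats)
        H = self.gat1(X, adj, rng=rng, attn_dropout=drop)
        Hk, adj_k = self.pool(H, adj)
        H2 = self.gat2(Hk, adj_k, rng=rng, attn_dropout=drop)
        pooled = H2.mean(axis=1)  # global mean pool -> (B, skip2)
        logits = pooled @ self.W_head + self.b_head
        return logits.log_softmax(axis=-1)


def init_classifier(cfg: TaskClassifierConfig, feature_dim: int) -> TaskClassifier:
    """Build a classifier with deterministic initialization under cfg.seed."""
    return TaskClassifier(cfg, feature_dim)


def _stack_graphs(graphs: list[SignatureGraph]):
    n_nodes = {g.num_nodes for g in graphs}
    n_feat = {g.feature_dim for g in graphs}
    if len(n_nodes) != 1 or len(n_feat) != 1:
        raise ValueError("all graphs in a batch must share node count and feature width")
    feats = np.stack([g.node_features for g in graphs])
    adj = np.stack([g.adjacency for g in graphs])
    labels = np.array([g.label for g in graphs], dtype=int)
    return feats, adj, labels


def _drop_edges(adj: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Zero out a random fraction of existing edges (weights not rescaled)."""
    if rate <= 0:
        return adj
    keep = rng.random(adj.shape) >= rate
    return np.where(adj != 0, adj * keep, adj)


def _nll(logp: Tensor, labels: np.ndarray) -> Tensor:
    onehot = np.zeros(logp.shape)
    onehot[np.arange(len(labels)), labels] = -1.0 / len(labels)
    return (logp * onehot).sum()


def train_classifier(
    clf: TaskClassifier,
    train_graphs: list[SignatureGraph],
    cfg: TaskClassifierConfig | None = None,
) -> dict:
    """Train by mini-batch NLL minimization with Adam and early stopping.

    Edge dropout (10%) is resampled once per epoch per graph; attention
    dropout (0.30) is resampled per forward pass. A validation split
    (``val_fraction`` of the training graphs) drives early stopping with
    the configured patience; the best-validation parameters are restored.
    Fully reproducible under ``cfg.seed``.

    Returns a history dict with per-epoch loss and accuracy.
    """
    cfg = cfg or clf.cfg
    labels_present = {g.label for g in train_graphs}
    if len(labels_present) < 2:
        raise ValueError("training set contains a single class")

    rng = np.random.default_rng(cfg.seed + 1)
    graphs = list(train_graphs)
    idx = rng.permutation(len(graphs))
    n_val = int(round(cfg.val_fraction * len(graphs)))
    val = [graphs[i] for i in idx[:n_val]]
    train = [graphs[i] for i in idx[n_val:]]
    if not train:
        train, val = graphs, []

    opt = Adam(clf.params(), lr=cfg.learning_rate)
    history = {"loss": [], "train_acc": [], "val_loss": []}
    best_val = np.inf
    best_state = None
    stall = 0

    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(train))
        epoch_loss = 0.0
        hits = 0
        for start in range(0, len(train), cfg.batch_size):
            batch = [train[i] for i in order[start : start + cfg.batch_size]]
            feats, adj, labels = _stack_graphs(batch)
            adj = _drop_edges(adj, cfg.edge_dropout, rng)
            logp = clf.forward(feats, adj, training=True, rng=rng)
            loss = _nll(logp, labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
            hits += int((logp.data.argmax(axis=1) == labels).sum())
        history["loss"].append(epoch_loss / len(train))
        history["train_acc"].append(hits / len(train))

        if val:
            feats, adj, labels = _stack_graphs(val)
            logp = clf.forward(feats, adj, training=False)
            val_loss = float(_nll(logp, labels).data)
        else:
            val_loss = history["loss"][-1]
        history["val_loss"].append(val_loss)

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = [p.data.copy() for p in clf.params()]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    if best_state is not None:
        for p, saved in zip(clf.params(), best_state):
            p.data = saved
    clf.trained = True
    return history


def predict_task(
    clf: TaskClassifier, graph: SignatureGraph
) -> tuple[int, np.ndarray]:
    """Predict the task of one graph: (argmax label, log-prob vector).

    Inference is deterministic (all dropout disabled); argmax ties break
    to the lowest class index.
    """
    if not clf.trained:
        raise RuntimeError("classifier has not been trained")
    feats, adj, _ = _stack_graphs([graph])
    logp = clf.forward(feats, adj, training=False).data[0]
    return int(np.argmax(logp)), logp


def evaluate_accuracy(clf: TaskClassifier, graphs: list[SignatureGraph]) -> float:
    """Fraction of graphs whose predicted task matches the label."""
    feats, adj, labels = _stack_graphs(graphs)
    logp = clf.forward(feats, adj, training=False).data
    return float((logp.argmax(axis=1) == labels).mean())


def save_classifier(clf: TaskClassifier, path) -> None:
    """Persist trained parameters and config to an .npz archive."""
    import dataclasses
    import json

    arrays = {f"param_{i}": p.data for i, p in enumerate(clf.params())}
    meta = json.dumps(
        {"cfg": dataclasses.asdict(clf.cfg), "feature_dim": clf.feature_dim,
         "trained": clf.trained}
    )
    np.savez(path, _meta=np.array(meta), **arrays)


def load_classifier(path) -> TaskClassifier:
    import json

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["_meta"]))
        clf = TaskClassifier(TaskClassifierConfig(**meta["cfg"]), meta["feature_dim"])
        for i, p in enumerate(clf.params()):
            p.data = archive[f"param_{i}"]
    clf.trained = bool(meta["trained"])
    return clf
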