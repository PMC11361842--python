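"""Step 1: regress per-gene SL connectivity with a multilayer encoder.

The stack mirrors how information about a gene accumulates: a *gene encoder*
embeds its omics profile (population-scope and cell-specific branches encoded
separately, then fused); a *multiview graph encoder* mixes each embedding
with its neighborhoods in several biological network views (symmetric
normalized adjacency with self-connections, one learned linear map per view
and layer); a *transformer encoder* applies dense multihead self-attention
over all gene tokens, so hubs can be recognized from global topology rather
than local neighborhoods alone; and an MLP head maps the final embedding to
a scalar connectivity prediction.

Connectivity counts are heavy-tailed (scale-free degrees), so the regression
runs on the log1p scale by default and predictions are mapped back with
expm1 and clipped at zero.  Training is full-batch Adam with MSE loss on the
training-gene rows, early-stopped on a held-out subset of training genes.
Everything is deterministic given ModelConfig.seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .autodiff import Adam, Tensor, concat_last, parameter, zeros_parameter
from .data_io import (
    DatasetBundle,
    NetworkView,
    StateError,
    compute_connectivity,
    standardize_features,
)

STAGES = ("gene_encoded", "graph_encoded", "transformer_encoded")


class TrainingError(RuntimeError):
    """Loss diverged; the partial history is attached as .history."""

    def __init__(self, message: str, history: list[dict]):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for the connectivity encoder stack.

    The optimization defaults (Adam at learning rate 5e-5, up to 1000 epochs
    with 200-epoch early-stopping patience, 50%/70% dropout between encoder
    and predictor layers) favor slow, convergent training on screen-scale
    data; `small()` provides a desk-scale preset for quick CPU runs.
    """

    embed_dim: int = 64
    n_graph_layers: int = 2
    n_attention_heads: int = 4
    n_transformer_layers: int = 1
    dropout_encoder: float = 0.5
    dropout_predictor: float = 0.7
    learning_rate: float = 5e-5
    max_epochs: int = 1000
    early_stop_patience_epochs: int = 200
    target_transform: str = "log1p"
    use_transformer: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.n_attention_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by "
                f"n_attention_heads {self.n_attention_heads}"
            )
        if not (0.0 <= self.dropout_encoder < 1.0
                and 0.0 <= self.dropout_predictor < 1.0):
            raise ValueError("dropouts must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.target_transform not in ("log1p", "identity"):
            raise ValueError(f"unknown target_transform {self.target_transform!r}")

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "ModelConfig":
        """Desk-scale preset: small dimensions, faster learning rate, short
        schedule, light dropout — for CPU experiments on synthetic bundles."""
        base = dict(
            embed_dim=16,
            n_graph_layers=1,
            n_attention_heads=2,
            n_transformer_layers=1,
            dropout_encoder=0.1,
            dropout_predictor=0.1,
            learning_rate=1e-2,
            max_epochs=400,
            early_stop_patience_epochs=60,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class GeneEmbeddings:
    """Per-gene embedding matrix tagged with its pipeline stage."""

    genes: tuple[str, ...]
    matrix: np.ndarray
    stage: str

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding matrix contains non-finite values")


def normalized_adjacency(view: NetworkView, genes: tuple[str, ...]) -> np.ndarray:
    """Dense D^-1/2 (A + I) D^-1/2 over the given gene order.

    Self-connections mean isolated nodes propagate their own features with
    weight one.
    """
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    A = np.eye(n)
    for a, b in view.edges:
        i, j = index[a], index[b]
        A[i, j] = 1.0
        A[j, i] = 1.0
    d = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A * inv_sqrt[:, None] * inv_sqrt[None, :]


def prepare_inputs(
    bundle: DatasetBundle, train_genes: Optional[Sequence[str]] = None
) -> dict:
    """Standardize features on training-gene statistics and build dense
    normalized adjacencies; returns the arrays the model consumes."""
    genes = bundle.genes
    train = tuple(train_genes) if train_genes is not None else genes
    by_scope: dict[str, list[np.ndarray]] = {"population": [], "cell_specific": []}
    for table in bundle.features:
        std = standardize_features(table, train)
        by_scope[std.scope].append(std.values)
    x_pop = (np.concatenate(by_scope["population"], axis=1)
             if by_scope["population"] else None)
    x_cell = (np.concatenate(by_scope["cell_specific"], axis=1)
              if by_scope["cell_specific"] else None)
    a_hats = [normalized_adjacency(v, genes) for v in bundle.networks]
    return {"genes": genes, "x_pop": x_pop, "x_cell": x_cell, "a_hats": a_hats}


class ConnectivityModel:
    """Parameter container + forward pass for the encoder stack."""

    def __init__(self, config: ModelConfig, n_pop: Optional[int],
                 n_cell: Optional[int], n_views: int):
        self.config = config
        self.n_pop, self.n_cell, self.n_views = n_pop, n_cell, n_views
        d = config.embed_dim
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(0,)))
        )
        p: dict[str, Tensor] = {}
        # gene encoder branches
        if n_pop:
            p["pop_W"] = parameter(rng, n_pop, d)
            p["pop_b"] = zeros_parameter((1, d))
        else:
            p["pop_const"] = parameter(rng, 1, d, shape=(1, d))
        if n_cell:
            p["cell_W"] = parameter(rng, n_cell, d)
            p["cell_b"] = zeros_parameter((1, d))
        else:
            p["cell_const"] = parameter(rng, 1, d, shape=(1, d))
        p["fuse_W"] = parameter(rng, 2 * d, d)
        p["fuse_b"] = zeros_parameter((1, d))
        # graph encoder: one linear map per view and layer
        for v in range(n_views):
            for l in range(config.n_graph_layers):
                p[f"gcn_{v}_{l}_W"] = parameter(rng, d, d)
                p[f"gcn_{v}_{l}_b"] = zeros_parameter((1, d))
        if n_views:
            p["view_W"] = parameter(rng, n_views * d, d)
            p["view_b"] = zeros_parameter((1, d))
        # transformer layers
        for l in range(config.n_transformer_layers):
            for name in ("q", "k", "v", "o"):
                p[f"attn_{l}_{name}W"] = parameter(rng, d, d)
                p[f"attn_{l}_{name}b"] = zeros_parameter((1, d))
            p[f"ff_{l}_W1"] = parameter(rng, d, 2 * d)
            p[f"ff_{l}_b1"] = zeros_parameter((1, 2 * d))
            p[f"ff_{l}_W2"] = parameter(rng, 2 * d, d)
            p[f"ff_{l}_b2"] = zeros_parameter((1, d))
        # MLP head
        p["head_W1"] = parameter(rng, d, d)
        p["head_b1"] = zeros_parameter((1, d))
        p["head_W2"] = parameter(rng, d, 1)
        p["head_b2"] = zeros_parameter((1, 1))
        self.params = p
        self.last_attention: list[np.ndarray] = []

    def trainable(self) -> list[Tensor]:
        return list(self.params.values())

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = state[k].copy()

    # -- forward stages --------------------------------------------------
    def _dropout(self, h: Tensor, rate: float, train: bool,
                 rng: Optional[np.random.Generator]) -> Tensor:
        if not train or rate <= 0.0:
            return h
        mask = (rng.random(h.shape) >= rate) / (1.0 - rate)
        return h * Tensor(mask)

    def gene_stage(self, x_pop, x_cell, n_genes: int, train=False, rng=None) -> Tensor:
        p = self.params
        ones = Tensor(np.ones((n_genes, 1)))
        if x_pop is not None:
            h_pop = (Tensor(x_pop) @ p["pop_W"] + p["pop_b"]).relu()
        else:
            h_pop = ones @ p["pop_const"]
        if x_cell is not None:
            h_cell = (Tensor(x_cell) @ p["cell_W"] + p["cell_b"]).relu()
        else:
            h_cell = ones @ p["cell_const"]
        h = concat_last([h_pop, h_cell]) @ p["fuse_W"] + p["fuse_b"]
        return self._dropout(h, self.config.dropout_encoder, train, rng)

    def graph_stage(self, h: Tensor, a_hats: list[np.ndarray],
                    train=False, rng=None) -> Tensor:
        if not a_hats:
            warnings.warn("no network views: graph encoder is a pass-through",
                          stacklevel=2)
            return h
        p = self.params
        outs = []
        for v, a_hat in enumerate(a_hats):
            hv = h
            A = Tensor(a_hat)
            for l in range(self.config.n_graph_layers):
                hv = (A @ hv @ p[f"gcn_{v}_{l}_W"] + p[f"gcn_{v}_{l}_b"]).relu()
            outs.append(hv)
        h = concat_last(outs) @ p["view_W"] + p["view_b"]
        return self._dropout(h, self.config.dropout_encoder, train, rng)

    def transformer_stage(self, h: Tensor, train=False, rng=None) -> Tensor:
        cfg = self.config
        d, nh = cfg.embed_dim, cfg.n_attention_heads
        dh = d // nh
        n = h.shape[0]
        p = self.params
        self.last_attention = []
        for l in range(cfg.n_transformer_layers):
            q = h @ p[f"attn_{l}_qW"] + p[f"attn_{l}_qb"]
            k = h @ p[f"attn_{l}_kW"] + p[f"attn_{l}_kb"]
            v = h @ p[f"attn_{l}_vW"] + p[f"attn_{l}_vb"]
            qh = q.reshape(n, nh, dh).transpose(1, 0, 2)
            kh = k.reshape(n, nh, dh).transpose(1, 0, 2)
            vh = v.reshape(n, nh, dh).transpose(1, 0, 2)
            scores = (qh @ kh.transpose(0, 2, 1)) * (1.0 / math.sqrt(dh))
            attn = scores.softmax_last()
            self.last_attention.append(attn.data.copy())
            ctx = (attn @ vh).transpose(1, 0, 2).reshape(n, d)
            out = ctx @ p[f"attn_{l}_oW"] + p[f"attn_{l}_ob"]
            h = (h + out).layer_norm()
            ff = ((h @ p[f"ff_{l}_W1"] + p[f"ff_{l}_b1"]).relu()
                  @ p[f"ff_{l}_W2"] + p[f"ff_{l}_b2"])
            h = (h + ff).layer_norm()
        return self._dropout(h, cfg.dropout_encoder, train, rng)

    def head_stage(self, h: Tensor, train=False, rng=None) -> Tensor:
        p = self.params
        h = self._dropout(h, self.config.dropout_predictor, train, rng)
        h = (h @ p["head_W1"] + p["head_b1"]).relu()
        return h @ p["head_W2"] + p["head_b2"]

    def forward(self, inputs: dict, train=False, rng=None) -> Tensor:
        n = len(inputs["genes"])
        h = self.gene_stage(inputs["x_pop"], inputs["x_cell"], n, train, rng)
        h = self.graph_stage(h, inputs["a_hats"], train, rng)
        if self.config.use_transformer:
            h = self.transformer_stage(h, train, rng)
        return self.head_stage(h, train, rng)


# ---------------------------------------------------------------------------
# Stateless stage wrappers (fresh seeded weights; evaluation mode)
# ---------------------------------------------------------------------------

def _fresh_model(bundle: DatasetBundle, config: ModelConfig) -> tuple:
    inputs = prepare_inputs(bundle)
    n_pop = inputs["x_pop"].shape[1] if inputs["x_pop"] is not None else 0
    n_cell = inputs["x_cell"].shape[1] if inputs["x_cell"] is not None else 0
    if n_pop == 0 or n_cell == 0:
        missing = "population" if n_pop == 0 else "cell_specific"
        warnings.warn(
            f"no {missing}-scope features: branch replaced by a learned "
            "constant vector", stacklevel=3,
        )
    model = ConnectivityModel(config, n_pop, n_cell, len(bundle.networks))
    return model, inputs


def encode_genes(bundle: DatasetBundle, config: ModelConfig) -> GeneEmbeddings:
    """Run the gene encoder with fresh seeded weights (evaluation mode)."""
    model, inputs = _fresh_model(bundle, config)
    h = model.gene_stage(inputs["x_pop"], inputs["x_cell"], len(bundle.genes))
    return GeneEmbeddings(bundle.genes, h.data, "gene_encoded")


def graph_encode(embeddings: GeneEmbeddings, networks: list[NetworkView],
                 config: ModelConfig) -> GeneEmbeddings:
    """Run the multiview graph encoder over existing gene-stage embeddings."""
    if embeddings.stage != "gene_encoded":
        raise StateError(f"expected gene_encoded stage, got {embeddings.stage}")
    model = ConnectivityModel(config, n_pop=config.embed_dim,
                              n_cell=config.embed_dim, n_views=len(networks))
    a_hats = [normalized_adjacency(v, embeddings.genes) for v in networks]
    h = model.graph_stage(Tensor(embeddings.matrix), a_hats)
    return GeneEmbeddings(embeddings.genes, h.data, "graph_encoded")


def transformer_encode(embeddings: GeneEmbeddings,
                       config: ModelConfig) -> GeneEmbeddings:
    """Run the transformer encoder over graph-stage embeddings."""
    if embeddings.stage != "graph_encoded":
        raise StateError(f"expected graph_encoded stage, got {embeddings.stage}")
    if embeddings.matrix.shape[1] != config.embed_dim:
        raise ValueError("embedding width must equal config.embed_dim")
    model = ConnectivityModel(config, n_pop=config.embed_dim,
                              n_cell=config.embed_dim, n_views=0)
    h = model.transformer_stage(Tensor(embeddings.matrix))
    return GeneEmbeddings(embeddings.genes, h.data, "transformer_encoded")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedConnectivityModel:
    """A fitted encoder stack with its configuration and training history."""

    config: ModelConfig
    model: ConnectivityModel
    inputs: dict
    history: list[dict]
    best_epoch: int

    def predict(self, genes: Optional[Sequence[str]] = None) -> np.ndarray:
        """Per-gene connectivity predictions on the count scale (>= 0)."""
        out = self.model.forward(self.inputs, train=False).data[:, 0]
        if self.config.target_transform == "log1p":
            out = np.expm1(out)
        out = np.clip(out, 0.0, None)
        if genes is None:
            return out
        index = {g: i for i, g in enumerate(self.inputs["genes"])}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes without predictions: {missing}")
        return out[[index[g] for g in genes]]

    def predictions_by_gene(self) -> dict[str, float]:
        return dict(zip(self.inputs["genes"], self.predict().tolist()))


def predict_connectivity(embeddings: GeneEmbeddings,
                         trained: TrainedConnectivityModel) -> np.ndarray:
    """Apply the fitted MLP head to transformer-stage embeddings."""
    if embeddings.stage != "transformer_encoded":
        raise StateError(
            f"expected transformer_encoded stage, got {embeddings.stage}"
        )
    out = trained.model.head_stage(Tensor(embeddings.matrix)).data[:, 0]
    if trained.config.target_transform == "log1p":
        out = np.expm1(out)
    return np.clip(out, 0.0, None)


def _transform_targets(counts: np.ndarray, transform: str) -> np.ndarray:
    return np.log1p(counts.astype(float)) if transform == "log1p" \
        else counts.astype(float)


def train_connectivity_model(bundle: DatasetBundle, split,
                             config: ModelConfig) -> TrainedConnectivityModel:
    """Fit the encoder stack to SL connectivity of the split's training genes.

    Connectivity targets come from training-side pairs only (test pairs
    never touch step-1 supervision).  Training genes are split 80/20 into a
    fit subset and an early-stopping monitor subset; the returned model
    carries the weights of the epoch with minimal monitor loss.
    """
    train_genes = sorted(split.train_genes)
    if not train_genes:
        raise ValueError("split has no training genes")
    train_side_pairs = set(split.train_pairs) | set(split.val_pairs)
    targets = compute_connectivity(bundle.screen, train_side_pairs)
    y_all = _transform_targets(targets.counts, config.target_transform)

    inputs = prepare_inputs(bundle, train_genes)
    n_pop = inputs["x_pop"].shape[1] if inputs["x_pop"] is not None else 0
    n_cell = inputs["x_cell"].shape[1] if inputs["x_cell"] is not None else 0
    model = ConnectivityModel(config, n_pop, n_cell, len(bundle.networks))

    gene_index = {g: i for i, g in enumerate(bundle.genes)}
    train_idx = np.array([gene_index[g] for g in train_genes])
    split_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    )
    perm = split_rng.permutation(len(train_idx))
    n_monitor = max(1, int(round(0.2 * len(train_idx))))
    monitor_idx = train_idx[perm[:n_monitor]]
    fit_idx = train_idx[perm[n_monitor:]]
    if fit_idx.size == 0:
        raise ValueError("training gene set too small to hold out a monitor subset")
    y_fit = Tensor(y_all[fit_idx][:, None])
    y_monitor = y_all[monitor_idx][:, None]

    drop_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    )
    optimizer = Adam(model.trainable(), lr=config.learning_rate)
    history: list[dict] = []
    best = {"epoch": -1, "val_loss": np.inf, "state": model.state_copy()}
    for epoch in range(config.max_epochs):
        pred = model.forward(inputs, train=True, rng=drop_rng)
        loss = (pred.gather_rows(fit_idx) - y_fit).square().mean()
        train_loss = float(loss.data)
        if not np.isfinite(train_loss):
            raise TrainingError(
                f"training loss diverged at epoch {epoch}", history
            )
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val_pred = model.forward(inputs, train=False).data[monitor_idx]
        val_loss = float(((val_pred - y_monitor) ** 2).mean())
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        if val_loss < best["val_loss"]:
            best = {"epoch": epoch, "val_loss": val_loss,
                    "state": model.state_copy()}
        elif epoch - best["epoch"] >= config.early_stop_patience_epochs:
            break
    model.load_state(best["state"])
    return TrainedConnectivityModel(config, model, inputs, history,
                                    best_epoch=best["epoch"])
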