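"""The multiscale interaction network: three convolutional pathways, fusion,
classifier head, and the class-balance-weighted focal loss.

Pathways
--------
* **Site (local)** — the (8, 30, 30, 30) occupancy grid through three 3-D
  convolution blocks (valid cross-correlation, LeakyReLU, 2x2x2 max pool),
  channel progression 8 -> 32 -> 64 -> 128 by default, flattened to ``XL``.
* **Sequence (global)** — tokens embedded to 128 x 1000, three 1-D
  convolution blocks (kernel 5; 64 -> 96 -> 128 filters; LeakyReLU; width-2
  max pool), flattened to ``XG``.
* **Molecule** — normalized graph convolution
  sigma(D~^{-1/2} (A+I) D~^{-1/2} H W) per layer with feature-space max
  pooling, then a global-max readout over atoms giving ``XM``.

The fused vector ``X = [XL, XG, XM]`` feeds a two-layer head ending in a
sigmoid probability.  Training minimizes the focal loss with class-balance
coefficients N/(P+N) (positive term) and P/(P+N) (negative term), where P
and N are the positive/negative sample counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .autograd import Adam, Tensor, concat, stack
from .molgraph import FEATURE_DIM, MolGraph
from .seq_encoder import EMBED_DIM, MAX_LEN, VOCAB_SIZE

logger = logging.getLogger(__name__)

LOSS_EPS = 1e-7


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.  Defaults: 3x3x3 kernels with channels
    8->32->64->128 on the site pathway, kernel-5 filters 64->96->128 on the
    sequence pathway, GCN widths 64->96->128, and a 256-unit head."""

    # site pathway
    conv3d_channels: tuple[int, ...] = (32, 64, 128)
    conv3d_kernel: int = 3
    conv3d_pool: int = 2
    site_downsample: int = 1          # average-pool factor on the input grid
    site_readout: str = "flatten"     # "flatten" | "global_max"
    grid_channels: int = 8
    grid_size: int = 30
    # sequence pathway
    max_len: int = MAX_LEN
    embed_dim: int = EMBED_DIM
    seq_filters: tuple[int, ...] = (64, 96, 128)
    seq_kernel: int = 5
    seq_pool: int = 2
    seq_readout: str = "flatten"      # "flatten" | "global_max"
    # molecular pathway
    gcn_widths: tuple[int, ...] = (64, 96, 128)
    gcn_feature_pool: int = 2
    # fusion / head / loss
    head_hidden: int = 256
    leaky_slope: float = 0.01
    gamma: float = 2.0
    use_site: bool = True
    use_seq: bool = True
    use_mol: bool = True

    @staticmethod
    def small() -> "NetworkConfig":
        """A desk-scale configuration: one narrow block per pathway and
        global-max readouts, for CPU-minute training on synthetic data."""
        return NetworkConfig(
            conv3d_channels=(8,),
            site_downsample=2,
            site_readout="global_max",
            embed_dim=16,
            seq_filters=(8,),
            seq_readout="global_max",
            gcn_widths=(16,),
            head_hidden=16,
        )

    # -- derived sizes ------------------------------------------------------
    def site_output_dim(self) -> int:
        n = self.grid_size // self.site_downsample
        for _ in self.conv3d_channels:
            n = (n - self.conv3d_kernel + 1) // self.conv3d_pool
            if n < 1:
                raise ValueError("site pathway shrinks below one voxel")
        c = self.conv3d_channels[-1]
        return c if self.site_readout == "global_max" else c * n ** 3

    def seq_output_dim(self) -> int:
        L = self.max_len
        for _ in self.seq_filters:
            L = (L - self.seq_kernel + 1) // self.seq_pool
            if L < 1:
                raise ValueError("sequence pathway shrinks below one position")
        f = self.seq_filters[-1]
        return f if self.seq_readout == "global_max" else f * L

    def mol_output_dim(self) -> int:
        w = FEATURE_DIM
        for width in self.gcn_widths:
            w = width // self.gcn_feature_pool
        return w

    def fusion_dim(self) -> int:
        dim = 0
        if self.use_site:
            dim += self.site_output_dim()
        if self.use_seq:
            dim += self.seq_output_dim()
        if self.use_mol:
            dim += self.mol_output_dim()
        if dim == 0:
            raise ValueError("at least one pathway must be enabled")
        return dim


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam)."""

    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-4
    seed: int = 0
    early_stop_patience: int | None = None  # epochs without val-AUC gain


# ---------------------------------------------------------------------------
# functional operations
# ---------------------------------------------------------------------------

def conv3d(cube: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid 3-D cross-correlation of one sample.

    ``cube`` has shape (channels, D, H, W); ``weight`` (filters, channels,
    P, Q, R); ``bias`` (filters,).  Pre-activation map only.
    """
    cube = np.asarray(cube, dtype=float)
    x = Tensor(cube[None])
    out = x.conv3d(Tensor(np.asarray(weight, dtype=float)), Tensor(np.asarray(bias, dtype=float)))
    return out.data[0]


def fuse(xl=None, xg=None, xm=None, *, ablation: bool = False) -> np.ndarray:
    """Concatenate the pathway outputs in the fixed order [XL, XG, XM].

    All three segments are required unless ``ablation=True`` is passed
    explicitly, in which case missing segments are dropped.
    """
    parts = [xl, xg, xm]
    if not ablation and any(p is None for p in parts):
        raise ValueError("all of XL, XG, XM are required unless ablation=True")
    kept = [np.asarray(p, dtype=float).ravel() for p in parts if p is not None]
    if not kept:
        raise ValueError("no pathway outputs to fuse")
    return np.concatenate(kept)


def focal_loss(y_prob, y_true, gamma: float = 2.0, pos_count: float = 1.0,
               neg_count: float = 1.0) -> float:
    """Class-balance-weighted focal loss, averaged over the batch.

    For a positive sample: -(N/(P+N)) (1-y')^gamma log y'; for a negative:
    -(P/(P+N)) y'^gamma log(1-y').  Probabilities are clamped to
    [1e-7, 1-1e-7] before the logarithm.
    """
    y_prob = np.clip(np.asarray(y_prob, dtype=float), LOSS_EPS, 1 - LOSS_EPS)
    y_true = np.asarray(y_true, dtype=float)
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    total = pos_count + neg_count
    if total <= 0:
        raise ValueError("P + N must be positive")
    w_pos = neg_count / total
    w_neg = pos_count / total
    per_sample = -(
        w_pos * y_true * (1 - y_prob) ** gamma * np.log(y_prob)
        + w_neg * (1 - y_true) * y_prob ** gamma * np.log(1 - y_prob)
    )
    return float(per_sample.mean())


def _focal_loss_tensor(probs: Tensor, labels: np.ndarray, gamma: float,
                       pos_count: float, neg_count: float) -> Tensor:
    y = np.asarray(labels, dtype=float)
    total = pos_count + neg_count
    w_pos = neg_count / total
    w_neg = pos_count / total
    p = probs.clip(LOSS_EPS, 1 - LOSS_EPS)
    pos_term = (1 - p) ** gamma * p.log() * y * (-w_pos)
    neg_term = p ** gamma * (1 - p).log() * (1 - y) * (-w_neg)
    return (pos_term + neg_term).mean()


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class CPINetwork:
    """Trainable multiscale interaction network.

    Parameters are plain float64 arrays wrapped in autograd tensors; a single
    integer seed drives their initialization.
    """

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        self.config = config or NetworkConfig()
        self.seed = int(seed)
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(self.seed))

    # -- initialization -----------------------------------------------------
    def _add(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self.params[name] = t
        return t

    def _init_params(self, rng: np.random.Generator):
        cfg = self.config
        k = cfg.conv3d_kernel
        if cfg.use_site:
            c_in = cfg.grid_channels
            for i, c_out in enumerate(cfg.conv3d_channels):
                scale = np.sqrt(2.0 / (c_in * k ** 3))
                self._add(f"site.conv{i}.w", rng.normal(0, scale, (c_out, c_in, k, k, k)))
                self._add(f"site.conv{i}.b", np.zeros(c_out))
                c_in = c_out
        if cfg.use_seq:
            emb = rng.normal(0, 0.1, (VOCAB_SIZE, cfg.embed_dim))
            emb[0] = 0.0  # padding row starts at zero
            self._add("seq.embedding", emb)
            c_in = cfg.embed_dim
            for i, f in enumerate(cfg.seq_filters):
                scale = np.sqrt(2.0 / (c_in * cfg.seq_kernel))
                self._add(f"seq.conv{i}.w", rng.normal(0, scale, (f, c_in, cfg.seq_kernel)))
                self._add(f"seq.conv{i}.b", np.zeros(f))
                c_in = f
        if cfg.use_mol:
            w_in = FEATURE_DIM
            for i, width in enumerate(cfg.gcn_widths):
                scale = np.sqrt(2.0 / w_in)
                self._add(f"mol.gcn{i}.w", rng.normal(0, scale, (w_in, width)))
                w_in = width // cfg.gcn_feature_pool
        fdim = cfg.fusion_dim()
        self._add("head.w1", rng.normal(0, np.sqrt(2.0 / fdim), (fdim, cfg.head_hidden)))
        self._add("head.b1", np.zeros(cfg.head_hidden))
        self._add("head.w2", rng.normal(0, np.sqrt(2.0 / cfg.head_hidden), (cfg.head_hidden, 1)))
        self._add("head.b2", np.zeros(1))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- pathways ------------------------------------------------------------
    def forward_site(self, grids: np.ndarray) -> Tensor:
        cfg = self.config
        x = Tensor(np.asarray(grids, dtype=float))
        if cfg.site_downsample > 1:
            x = x.avg_pool3d(cfg.site_downsample)
        for i in range(len(cfg.conv3d_channels)):
            x = x.conv3d(self.params[f"site.conv{i}.w"], self.params[f"site.conv{i}.b"])
            x = x.leaky_relu(cfg.leaky_slope)
            x = x.max_pool3d(cfg.conv3d_pool)
        B = x.shape[0]
        if cfg.site_readout == "global_max":
            return x.reshape(B, x.shape[1], -1).max(axis=2)
        return x.reshape(B, -1)

    def forward_seq(self, tokens: np.ndarray) -> Tensor:
        cfg = self.config
        tokens = np.asarray(tokens)
        emb = self.params["seq.embedding"].take_rows(tokens)  # B, L, E
        x = emb.transpose(0, 2, 1)  # B, E, L
        for i in range(len(cfg.seq_filters)):
            x = x.conv1d(self.params[f"seq.conv{i}.w"], self.params[f"seq.conv{i}.b"])
            x = x.leaky_relu(cfg.leaky_slope)
            x = x.max_pool1d(cfg.seq_pool)
        B = x.shape[0]
        if cfg.seq_readout == "global_max":
            return x.max(axis=2)
        return x.reshape(B, -1)

    def forward_mol(self, graphs: list[MolGraph]) -> Tensor:
        cfg = self.config
        outs = []
        for graph in graphs:
            if graph.n_atoms == 0:
                raise ValueError("cannot embed an empty molecular graph")
            S = Tensor(graph.norm_adjacency)
            H = Tensor(graph.features)
            for i in range(len(cfg.gcn_widths)):
                H = (S @ H) @ self.params[f"mol.gcn{i}.w"]
                H = H.leaky_relu(cfg.leaky_slope)
                n, w = H.shape
                pool = cfg.gcn_feature_pool
                H = H.reshape(n, w // pool, pool).max(axis=2)
            outs.append(H.max(axis=0))  # global max over atoms
        return stack(outs, axis=0)

    # -- fusion and head ------------------------------------------------------
    def forward(self, grids=None, tokens=None, graphs=None) -> Tensor:
        cfg = self.config
        segments = []
        if cfg.use_site:
            if grids is None:
                raise ValueError("site pathway enabled but no grids given")
            segments.append(self.forward_site(grids))
        if cfg.use_seq:
            if tokens is None:
                raise ValueError("sequence pathway enabled but no tokens given")
            segments.append(self.forward_seq(tokens))
        if cfg.use_mol:
            if graphs is None:
                raise ValueError("molecular pathway enabled but no graphs given")
            segments.append(self.forward_mol(graphs))
        fused = segments[0] if len(segments) == 1 else concat(segments, axis=1)
        h = (fused @ self.params["head.w1"] + self.params["head.b1"]).leaky_relu(
            cfg.leaky_slope
        )
        logit = h @ self.params["head.w2"] + self.params["head.b2"]
        return logit.reshape(logit.shape[0]).sigmoid()

    def predict(self, grids=None, tokens=None, graphs=None) -> np.ndarray:
        """Interaction probabilities in (0, 1); deterministic given params."""
        return self.forward(grids=grids, tokens=tokens, graphs=graphs).data.copy()

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: one ``.npz`` of parameters + a JSON manifest with the
        architecture, seed and a configuration hash."""
        import hashlib

        arrays = {name: t.data for name, t in self.params.items()}
        np.savez(path, **arrays)
        cfg_json = json.dumps(asdict(self.config), sort_keys=True)
        manifest = {
            "config": asdict(self.config),
            "seed": self.seed,
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
            "format_version": 1,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, path) -> "CPINetwork":
        with open(str(path) + ".json") as fh:
            manifest = json.load(fh)
        cfg_dict = dict(manifest["config"])
        for key in ("conv3d_channels", "seq_filters", "gcn_widths"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = cls(NetworkConfig(**cfg_dict), seed=manifest["seed"])
        npz_path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
        import os

        if not os.path.exists(npz_path):
            npz_path = str(path)
        with np.load(npz_path) as data:
            for name in model.params:
                model.params[name].data = data[name].astype(float)
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, t in self.params.items():
            t.data = state[name].copy()


# ---------------------------------------------------------------------------
# dataset container and training
# ---------------------------------------------------------------------------

@dataclass
class PairDataset:
    """Featurized sample pairs.  Targets and molecules are stored once and
    referenced by index, so repeated pairs share their grids and graphs."""

    grids: np.ndarray            # (T, 8, D, D, D)
    tokens: np.ndarray           # (T, L)
    graphs: list[MolGraph]       # length M
    target_index: np.ndarray     # (n,)
    mol_index: np.ndarray        # (n,)
    labels: np.ndarray           # (n,) in {0, 1}
    target_ids: list[str]
    mol_ids: list[str]

    def __len__(self) -> int:
        return len(self.labels)

    def batch(self, idx: np.ndarray):
        ti = self.target_index[idx]
        mi = self.mol_index[idx]
        return (
            self.grids[ti],
            self.tokens[ti],
            [self.graphs[j] for j in mi],
            self.labels[idx],
        )

    def pair_target_ids(self) -> list[str]:
        return [self.target_ids[i] for i in self.target_index]

    def subset(self, idx: np.ndarray) -> "PairDataset":
        idx = np.asarray(idx)
        return PairDataset(
            grids=self.grids,
            tokens=self.tokens,
            graphs=self.graphs,
            target_index=self.target_index[idx],
            mol_index=self.mol_index[idx],
            labels=self.labels[idx],
            target_ids=self.target_ids,
            mol_ids=self.mol_ids,
        )


def encode_dataset(pairs, grids: dict, tokens: dict, graphs: dict) -> PairDataset:
    """Assemble a :class:`PairDataset` from per-id featurizations.

    ``pairs`` is an iterable of (target_id, ligand_id, label); ``grids`` and
    ``tokens`` map target ids to arrays; ``graphs`` maps ligand ids to
    :class:`MolGraph`.  Pairs referencing missing featurizations raise
    ``KeyError`` naming the id.
    """
    target_ids = sorted(grids)
    mol_ids = sorted(graphs)
    t_idx = {t: i for i, t in enumerate(target_ids)}
    m_idx = {m: i for i, m in enumerate(mol_ids)}
    ti, mi, ys = [], [], []
    for target_id, ligand_id, label in pairs:
        if target_id not in t_idx:
            raise KeyError(f"no featurization for target {target_id!r}")
        if ligand_id not in m_idx:
            raise KeyError(f"no featurization for ligand {ligand_id!r}")
        ti.append(t_idx[target_id])
        mi.append(m_idx[ligand_id])
        ys.append(int(label))
    return PairDataset(
        grids=np.stack([grids[t] for t in target_ids]),
        tokens=np.stack([tokens[t] for t in target_ids]),
        graphs=[graphs[m] for m in mol_ids],
        target_index=np.array(ti, dtype=int),
        mol_index=np.array(mi, dtype=int),
        labels=np.array(ys, dtype=int),
        target_ids=target_ids,
        mol_ids=mol_ids,
    )


def predict_dataset(model: CPINetwork, data: PairDataset, batch_size: int = 64) -> np.ndarray:
    scores = np.empty(len(data))
    for start in range(0, len(data), batch_size):
        idx = np.arange(start, min(start + batch_size, len(data)))
        grids, tokens, graphs, _ = data.batch(idx)
        scores[idx] = model.predict(grids=grids, tokens=tokens, graphs=graphs)
    return scores


def train_model(
    model: CPINetwork,
    train_data: PairDataset,
    val_data: PairDataset | None = None,
    train_config: TrainConfig | None = None,
) -> list[dict]:
    """Minimize the balanced focal loss with Adam; returns per-epoch history.

    Each history record holds the epoch's mean loss and, when validation data
    is given, the validation ROC AUC.  A non-finite loss aborts with a
    diagnostic.  With ``early_stop_patience`` set, the best-validation-AUC
    parameters are restored at the end.
    """
    from .data_eval import roc_auc

    cfg = train_config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    n = len(train_data)
    P = float(train_data.labels.sum())
    N = float(n - P)
    gamma = model.config.gamma
    history: list[dict] = []
    best_auc, best_state, stale = -np.inf, None, 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            grids, tokens, graphs, labels = train_data.batch(idx)
            probs = model.forward(grids=grids, tokens=tokens, graphs=graphs)
            loss = _focal_loss_tensor(probs, labels, gamma, P, N)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch start {start}: {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        record = {"epoch": epoch, "loss": float(np.mean(losses))}
        if val_data is not None and len(val_data) > 0:
            scores = predict_dataset(model, val_data)
            if len(np.unique(val_data.labels)) < 2:
                logger.warning("validation set has a single class; AUC undefined")
                record["val_auc"] = None
            else:
                record["val_auc"] = roc_auc(scores, val_data.labels)
            if record["val_auc"] is not None and record["val_auc"] > best_auc:
                best_auc, best_state, stale = record["val_auc"], model.state_copy(), 0
            else:
                stale += 1
        history.append(record)
        logger.info("epoch %d: loss=%.5f%s", epoch, record["loss"],
                    f" val_auc={record['val_auc']:.4f}" if record.get("val_auc") is not None else "")
        if (
            cfg.early_stop_patience is not None
            and val_data is not None
            and stale >= cfg.early_stop_patience
        ):
            break
    if best_state is not None and cfg.early_stop_patience is not None:
        model.load_state(best_state)
    return history
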