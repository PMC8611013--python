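"""Per-pixel neural-network material decomposition.

Training samples are individual pixels of the per-bin reconstructions:
the feature vector of a pixel is its HU value in each energy bin (three
by default), standardized per bin.  Labels come from ROIs drawn in
regions of known composition — iodine and calcium solutions at several
concentrations plus water in the insert phantom, and white/gray matter
patches in the brain phantom.  Nine 25×25-pixel ROIs over three bins give
the canonical (25×25×9)×3 = 16,875 scalar training units.

The network is a fully connected multilayer perceptron with eight hidden
ReLU layers and linear outputs, one output channel per material, trained
by full-batch gradient descent (or Adam) on the mean squared error.
Solute channels use concentration-scaled targets (concentration divided
by the largest training concentration of that solute), so the decomposed
iodine map is monotone in iodine content; tissue channels are one-hot.
Water is the zero vector — the network maps plain water to no material.

Everything is plain numpy so the forward pass, gradients, and
initialization are fully deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from pcct.phantoms import ROISpec
from pcct.recon import ReconImage

__all__ = [
    "DEFAULT_MATERIALS",
    "TrainingSet",
    "TrainingConfig",
    "MLPModel",
    "MaterialMaps",
    "extract_training_set",
    "train",
    "decompose",
    "save_model",
    "load_model",
    "ModelFormatError",
]

DEFAULT_MATERIALS = ("iodine", "calcium", "white_matter", "gray_matter")

#: training ROI side in pixels (square patch)
ROI_SIDE = 25


@dataclass(frozen=True)
class TrainingSet:
    """Per-pixel features (one row per ROI pixel) and material targets."""

    features: np.ndarray = field(repr=False)   # (n_samples, n_bins)
    labels: np.ndarray = field(repr=False)     # (n_samples, n_materials)
    materials: tuple = DEFAULT_MATERIALS
    provenance: tuple = ()                     # (roi label, pixel index)

    def __post_init__(self):
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on sample count")
        if self.labels.shape[1] != len(self.materials):
            raise ValueError("label width must equal the number of materials")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_bins(self) -> int:
        return self.features.shape[1]

    @property
    def n_scalar_units(self) -> int:
        """Total scalar data units = ROI pixels × ROIs × bins."""
        return self.features.size

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = {f"bin{i + 1}_hu": self.features[:, i]
                for i in range(self.n_bins)}
        cols.update({m: self.labels[:, i]
                     for i, m in enumerate(self.materials)})
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.00005
    epochs: int = 4500
    seed: int = 0
    hidden_width: int = 64
    n_hidden: int = 8
    optimizer: str = "adam"        # "adam" or "gd" (full-batch)
    batch_size: int | None = None  # None = full batch

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.epochs < 1:
            raise ValueError("at least one epoch is required")
        if self.optimizer not in ("adam", "gd"):
            raise ValueError(f"unknown optimizer '{self.optimizer}'")


@dataclass(frozen=True)
class MLPModel:
    """Eight-hidden-layer ReLU network with linear outputs."""

    weights: tuple = field(repr=False)   # list of (in, out) float64 arrays
    biases: tuple = field(repr=False)
    materials: tuple = DEFAULT_MATERIALS
    feat_mean: np.ndarray = field(default=None, repr=False)
    feat_std: np.ndarray = field(default=None, repr=False)
    config: TrainingConfig | None = None

    @property
    def n_hidden(self) -> int:
        return len(self.weights) - 1

    @property
    def input_width(self) -> int:
        return self.weights[0].shape[0]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass on raw (unstandardized) features."""
        h = (X - self.feat_mean) / self.feat_std
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return h @ self.weights[-1] + self.biases[-1]


@dataclass(frozen=True)
class MaterialMaps:
    """Per-pixel material scores on the reconstruction grid."""

    scores: np.ndarray = field(repr=False)     # (n, n, n_materials)
    materials: tuple = DEFAULT_MATERIALS
    pixel_mm: float = 0.4

    def channel(self, material: str) -> np.ndarray:
        return self.scores[..., self.materials.index(material)]

    @property
    def iodine_map(self) -> np.ndarray:
        return self.channel("iodine")

    def argmax_map(self) -> np.ndarray:
        return np.argmax(self.scores, axis=-1)


def _roi_square_slices(image_shape, roi: ROISpec, pixel_mm: float,
                       side: int = ROI_SIDE):
    n = image_shape[0]
    half = (n - 1) / 2.0
    cx, cy = roi.center_mm
    col = cx / pixel_mm + half
    row = half - cy / pixel_mm
    r0 = int(round(row)) - side // 2
    c0 = int(round(col)) - side // 2
    if r0 < 0 or c0 < 0 or r0 + side > n or c0 + side > n:
        raise ValueError(
            f"ROI '{roi.label}' ({side}x{side} px at {roi.center_mm} mm) "
            f"falls outside the {n}x{n} image"
        )
    return slice(r0, r0 + side), slice(c0, c0 + side)


def _target_vector(roi: ROISpec, materials, conc_ref: dict) -> np.ndarray:
    y = np.zeros(len(materials))
    mat = roi.material
    if mat is None or mat == "water":
        return y
    if mat not in materials:
        raise ValueError(f"ROI material '{mat}' is not a model output "
                         f"channel {materials}")
    idx = materials.index(mat)
    conc = roi.concentration_mg_ml
    if conc is None:
        y[idx] = 1.0
    else:
        y[idx] = conc / conc_ref[mat] if conc_ref.get(mat) else 1.0
    return y


def extract_training_set(
    bin_images: list[ReconImage] | list[np.ndarray],
    rois: list[ROISpec],
    materials: tuple = DEFAULT_MATERIALS,
    *,
    side: int = ROI_SIDE,
) -> TrainingSet:
    """One training sample per ROI pixel; feature = per-bin values.

    Each ROI contributes a ``side×side`` axis-aligned square patch around
    its center.  Solute targets are scaled by the largest training
    concentration of that solute; water ROIs map to the zero vector.
    """
    arrays = [im.hu if isinstance(im, ReconImage) else np.asarray(im)
              for im in bin_images]
    pixel_mm = (bin_images[0].pixel_mm
                if isinstance(bin_images[0], ReconImage) else 1.0)
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("per-bin images must share one grid")

    conc_ref: dict[str, float] = {}
    for roi in rois:
        if roi.material and roi.concentration_mg_ml:
            conc_ref[roi.material] = max(conc_ref.get(roi.material, 0.0),
                                         roi.concentration_mg_ml)

    feats, labs, prov = [], [], []
    for roi in rois:
        rs, cs = _roi_square_slices(shape, roi, pixel_mm, side)
        patch = np.stack([a[rs, cs].ravel() for a in arrays], axis=1)
        feats.append(patch)
        labs.append(np.tile(_target_vector(roi, materials, conc_ref),
                            (patch.shape[0], 1)))
        prov.extend((roi.label, i) for i in range(patch.shape[0]))
    return TrainingSet(np.concatenate(feats), np.concatenate(labs),
                       tuple(materials), tuple(prov))


def _init_params(widths, rng):
    """He-style scaled-uniform initialization."""
    Ws, bs = [], []
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / n_in)
        Ws.append(rng.uniform(-limit, limit, size=(n_in, n_out)))
        bs.append(np.zeros(n_out))
    return Ws, bs


def _forward_cached(X, Ws, bs):
    acts = [X]
    h = X
    for W, b in zip(Ws[:-1], bs[:-1]):
        h = np.maximum(h @ W + b, 0.0)
        acts.append(h)
    out = h @ Ws[-1] + bs[-1]
    return out, acts


def _backward(out, Y, acts, Ws):
    n = out.shape[0]
    delta = 2.0 * (out - Y) / (n * Y.shape[1])
    gWs, gbs = [None] * len(Ws), [None] * len(Ws)
    for i in range(len(Ws) - 1, -1, -1):
        gWs[i] = acts[i].T @ delta
        gbs[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ Ws[i].T) * (acts[i] > 0)
    return gWs, gbs


def train(
    ts: TrainingSet, cfg: TrainingConfig = TrainingConfig()
) -> tuple[MLPModel, np.ndarray]:
    """Train the decomposition network; returns (model, per-epoch loss).

    Features are standardized per bin (constants stored in the model).
    The loss is the mean squared error between network outputs and the
    material target vectors; training is full-batch unless a batch size
    is configured.
    """
    distinct = {tuple(row) for row in ts.labels}
    if len(distinct) < 2:
        raise ValueError("degenerate training set: a single target class "
                         "cannot constrain the decomposition")
    mean = ts.features.mean(axis=0)
    std = ts.features.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    X = (ts.features - mean) / std
    Y = ts.labels

    rng = np.random.default_rng(cfg.seed)
    widths = [ts.n_bins] + [cfg.hidden_width] * cfg.n_hidden + [Y.shape[1]]
    Ws, bs = _init_params(widths, rng)

    m_w = [np.zeros_like(W) for W in Ws]
    v_w = [np.zeros_like(W) for W in Ws]
    m_b = [np.zeros_like(b) for b in bs]
    v_b = [np.zeros_like(b) for b in bs]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    n = X.shape[0]
    bsz = cfg.batch_size or n
    loss_history = np.empty(cfg.epochs)
    step = 0
    for epoch in range(cfg.epochs):
        if bsz >= n:
            batches = [(X, Y)]
        else:
            order = rng.permutation(n)
            batches = [(X[order[i:i + bsz]], Y[order[i:i + bsz]])
                       for i in range(0, n, bsz)]
        for Xb, Yb in batches:
            out, acts = _forward_cached(Xb, Ws, bs)
            gWs, gbs = _backward(out, Yb, acts, Ws)
            step += 1
            if cfg.optimizer == "adam" and cfg.learning_rate > 0:
                for i in range(len(Ws)):
                    m_w[i] = beta1 * m_w[i] + (1 - beta1) * gWs[i]
                    v_w[i] = beta2 * v_w[i] + (1 - beta2) * gWs[i] ** 2
                    m_b[i] = beta1 * m_b[i] + (1 - beta1) * gbs[i]
                    v_b[i] = beta2 * v_b[i] + (1 - beta2) * gbs[i] ** 2
                    mh = m_w[i] / (1 - beta1**step)
                    vh = v_w[i] / (1 - beta2**step)
                    Ws[i] -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)
                    mhb = m_b[i] / (1 - beta1**step)
                    vhb = v_b[i] / (1 - beta2**step)
                    bs[i] -= cfg.learning_rate * mhb / (np.sqrt(vhb) + eps)
            elif cfg.learning_rate > 0:
                for i in range(len(Ws)):
                    Ws[i] -= cfg.learning_rate * gWs[i]
                    bs[i] -= cfg.learning_rate * gbs[i]
        out, _ = _forward_cached(X, Ws, bs)
        loss_history[epoch] = np.mean((out - Y) ** 2)

    model = MLPModel(tuple(Ws), tuple(bs), ts.materials,
                     feat_mean=mean, feat_std=std, config=cfg)
    return model, loss_history


def decompose(
    bin_images: list[ReconImage] | list[np.ndarray], model: MLPModel
) -> MaterialMaps:
    """Apply the trained network to every pixel of the per-bin images.

    The per-bin images are flattened to one feature row per pixel, pushed
    through the network, and reshaped back to grid × materials; the
    iodine map is the iodine output channel.
    """
    arrays = [im.hu if isinstance(im, ReconImage) else np.asarray(im)
              for im in bin_images]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("per-bin images must share one grid")
    if len(arrays) != model.input_width:
        raise ValueError(
            f"model expects {model.input_width} energy bins, got {len(arrays)}"
        )
    X = np.stack([a.ravel() for a in arrays], axis=1)
    scores = model.forward(X).reshape(*shape, len(model.materials))
    pixel_mm = (bin_images[0].pixel_mm
                if isinstance(bin_images[0], ReconImage) else 0.4)
    return MaterialMaps(scores, model.materials, pixel_mm)


# ---------------------------------------------------------------------------
# Model persistence (HDF5)
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


class ModelFormatError(RuntimeError):
    pass


def save_model(model: MLPModel, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["materials"] = list(model.materials)
        f.attrs["feat_mean"] = model.feat_mean
        f.attrs["feat_std"] = model.feat_std
        if model.config is not None:
            f.attrs["learning_rate"] = model.config.learning_rate
            f.attrs["epochs"] = model.config.epochs
            f.attrs["seed"] = model.config.seed
            f.attrs["optimizer"] = model.config.optimizer
        layers = f.create_group("layers")
        for i, (W, b) in enumerate(zip(model.weights, model.biases)):
            g = layers.create_group(str(i))
            g.create_dataset("W", data=W)
            g.create_dataset("b", data=b)


def load_model(path) -> MLPModel:
    import h5py

    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != _FORMAT_VERSION:
                raise ModelFormatError(
                    f"unsupported model format version {version}"
                )
            layers = f["layers"]
            Ws, bs = [], []
            for i in range(len(layers)):
                Ws.append(layers[str(i)]["W"][...])
                bs.append(layers[str(i)]["b"][...])
            cfg = None
            if "learning_rate" in f.attrs:
                cfg = TrainingConfig(
                    learning_rate=float(f.attrs["learning_rate"]),
                    epochs=int(f.attrs["epochs"]),
                    seed=int(f.attrs["seed"]),
                    optimizer=str(f.attrs["optimizer"]),
                )
            return MLPModel(
                tuple(Ws), tuple(bs),
                tuple(str(m) for m in f.attrs["materials"]),
                feat_mean=f.attrs["feat_mean"][...],
                feat_std=f.attrs["feat_std"][...],
                config=cfg,
            )
    except (OSError, KeyError) as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
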