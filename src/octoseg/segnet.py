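"""Extended-depth U-Net for four-compartment OCT segmentation.

The network is a classic U-shaped encoder–decoder with skip connections at
every resolution level: per level a block of 3x3 same-padding convolutions
with ReLU, 2x2 max pooling on descent, learned 2x2 transposed-convolution
upsampling on ascent, channel doubling per level, and a final 1x1 convolution
to the four class logits.  Relative to the original five-level U-Net, one
additional resolution level is used so that the receptive field of an output
pixel covers the whole 512x512 input; with three convolutions per level the
theoretical receptive field at six levels is 596 px (>= 512), while a
four-level network (140 px) falls well short.  Coverage is validated by the
influence probe in :func:`receptive_field_support` rather than assumed.

Training follows a short fixed recipe: unweighted pixel-wise cross-entropy,
Adam, Xavier initialization, mini-batches of four images, learning rate 6e-5,
10 epochs, no further regularization.  An optional patience-based early stop
on validation loss is available.  Prediction applies a per-pixel softmax and
argmax (ties resolved to the lowest class index) and resizes the mask back to
the original image geometry with nearest-neighbour interpolation.

The scikit-learn estimator :class:`UNetSegmenter` is the primary interface;
:func:`build_network`, :func:`train` and :func:`predict` are thin functional
wrappers around it.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from skimage.transform import resize as _sk_resize

from . import nn
from .augment import resize_for_network
from .types import BScan, LabelMask, ValidationError

__all__ = [
    "NetConfig",
    "TrainConfig",
    "UNet",
    "UNetSegmenter",
    "build_network",
    "train",
    "predict",
    "receptive_field_support",
    "covers_input",
]


@dataclass
class NetConfig:
    """Architecture parameters.

    ``depth_levels`` counts resolution levels (6 = one more than the original
    U-Net's five); ``input_size`` must be divisible by ``2**(depth_levels-1)``.
    """

    input_size: int = 512
    n_classes: int = 4
    depth_levels: int = 6
    base_channels: int = 64
    convs_per_level: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        f = 2 ** (self.depth_levels - 1)
        if self.input_size % f != 0:
            raise ValidationError(
                f"input_size {self.input_size} not divisible by 2^(depth_levels-1)={f}"
            )
        if self.n_classes != 4:
            raise ValidationError("this segmenter is defined for exactly 4 classes")
        if self.depth_levels < 2 or self.base_channels < 1 or self.convs_per_level < 1:
            raise ValidationError("invalid architecture parameters")


@dataclass
class TrainConfig:
    """Training recipe (defaults follow the reference recipe exactly)."""

    learning_rate: float = 6e-5
    batch_size: int = 4
    epochs: int = 10
    patience: int | None = None  # early stop if val loss rises this many epochs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("learning_rate/batch_size/epochs must be positive")


class UNet:
    """The raw network: layer graph, forward/backward, parameter access."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, base, q = config.depth_levels, config.base_channels, config.convs_per_level

        def block(cin: int, cout: int) -> list:
            layers = []
            for i in range(q):
                layers.append(nn.Conv2D(cin if i == 0 else cout, cout, 3, rng))
                layers.append(nn.ReLU())
            return layers

        self.enc_blocks = []
        cin = 1
        for lvl in range(d):
            cout = base * 2**lvl
            self.enc_blocks.append(block(cin, cout))
            cin = cout
        self.pools = [nn.MaxPool2() for _ in range(d - 1)]
        self.upconvs = []
        self.concats = []
        self.dec_blocks = []
        for lvl in range(d - 2, -1, -1):
            cout = base * 2**lvl
            self.upconvs.append(nn.UpConv2(cout * 2, cout, rng))
            self.concats.append(nn.Concat())
            self.dec_blocks.append(block(cout * 2, cout))
        self.head = nn.Conv2D(base, config.n_classes, 1, rng)

    def _layers(self):
        for blk in self.enc_blocks:
            yield from blk
        yield from self.pools
        for up, cat, blk in zip(self.upconvs, self.concats, self.dec_blocks):
            yield up
            yield cat
            yield from blk
        yield self.head

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (n, s, s, 1) float32 -> logits (n, s, s, n_classes)."""
        skips = []
        d = self.config.depth_levels
        for lvl in range(d):
            for layer in self.enc_blocks[lvl]:
                x = layer.forward(x, train=train)
            if lvl < d - 1:
                skips.append(x)
                x = self.pools[lvl].forward(x, train=train)
        for i, lvl in enumerate(range(d - 2, -1, -1)):
            x = self.upconvs[i].forward(x, train=train)
            x = self.concats[i].forward(skips[lvl], x, train=train)
            for layer in self.dec_blocks[i]:
                x = layer.forward(x, train=train)
        return self.head.forward(x, train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.config.depth_levels
        g = self.head.backward(dlogits)
        dskips: dict[int, np.ndarray] = {}
        # reverse decoder (decoder step i was built for resolution level d-2-i)
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            for layer in reversed(self.dec_blocks[i]):
                g = layer.backward(g)
            dskip, g = self.concats[i].backward(g)
            lvl = d - 2 - i
            dskips[lvl] = dskip
            g = self.upconvs[i].backward(g)
        # reverse encoder
        for lvl in range(d - 1, -1, -1):
            if lvl < d - 1:
                g = self.pools[lvl].backward(g)
                g = g + dskips[lvl]
            for layer in reversed(self.enc_blocks[lvl]):
                g = layer.backward(g)


class UNetSegmenter(BaseEstimator):
    """Scikit-learn style U-Net compartment segmenter.

    Parameters mirror :class:`NetConfig` and :class:`TrainConfig`.  ``fit``
    accepts lists of :class:`BScan`/:class:`LabelMask` (or plain 2-D arrays)
    of arbitrary geometry; inputs are resized to ``input_size`` (bicubic for
    images, nearest for masks) and predictions are resized back.

    Fitted attributes: ``net_`` (the raw network), ``history_`` (per-epoch
    train loss, and validation loss/mean IOU when validation data is given),
    ``n_epochs_run_``.
    """

    def __init__(
        self,
        input_size: int = 512,
        depth_levels: int = 6,
        base_channels: int = 64,
        convs_per_level: int = 3,
        n_classes: int = 4,
        learning_rate: float = 6e-5,
        batch_size: int = 4,
        epochs: int = 10,
        patience: int | None = None,
        seed: int = 0,
        verbose: bool = False,
    ):
        self.input_size = input_size
        self.depth_levels = depth_levels
        self.base_channels = base_channels
        self.convs_per_level = convs_per_level
        self.n_classes = n_classes
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.seed = seed
        self.verbose = verbose

    # -- config plumbing ---------------------------------------------------
    def _net_config(self) -> NetConfig:
        return NetConfig(
            input_size=self.input_size,
            n_classes=self.n_classes,
            depth_levels=self.depth_levels,
            base_channels=self.base_channels,
            convs_per_level=self.convs_per_level,
            seed=self.seed,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            patience=self.patience,
            seed=self.seed,
        )

    # -- data plumbing -----------------------------------------------------
    def _to_network_arrays(
        self, X, y=None
    ) -> tuple[np.ndarray, np.ndarray | None, list[tuple[int, int]]]:
        s = self.input_size
        imgs, targs, shapes = [], [], []
        for i, xi in enumerate(X):
            scan = xi if isinstance(xi, BScan) else BScan(pixels=np.asarray(xi))
            mask = None
            if y is not None:
                yi = y[i]
                mask = yi if isinstance(yi, LabelMask) else LabelMask(labels=np.asarray(yi))
                if mask.labels.shape != scan.pixels.shape:
                    raise ValidationError(f"image/mask shape mismatch at index {i}")
            shapes.append(scan.pixels.shape)
            rs, rm = resize_for_network(scan, mask, size=(s, s))
            imgs.append(rs.pixels.astype(nn.F32))
            if rm is not None:
                targs.append(rm.labels.astype(np.int64))
        ximgs = np.stack(imgs)[..., None]
        ytargs = np.stack(targs) if targs else None
        return ximgs, ytargs, shapes

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y, validation_data=None):
        """Train on (images, masks); optional ``validation_data=(Xv, yv)``."""
        if len(X) == 0:
            raise ValidationError("training set is empty")
        net_cfg = self._net_config()
        tr_cfg = self._train_config()
        xtr, ytr, _ = self._to_network_arrays(X, y)
        present = np.unique(ytr)
        if len(present) < self.n_classes:
            missing = sorted(set(range(self.n_classes)) - set(present.tolist()))
            warnings.warn(
                f"classes {missing} absent from every training mask", stacklevel=2
            )
        xval = yval = None
        if validation_data is not None:
            xval, yval, _ = self._to_network_arrays(*validation_data)

        self.net_ = UNet(net_cfg)
        opt = nn.Adam(self.net_.params(), lr=tr_cfg.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence([tr_cfg.seed, 0x7EA1]))
        n = xtr.shape[0]
        self.history_ = {"train_loss": [], "val_loss": [], "val_mean_iou": []}
        best_val = np.inf
        since_best = 0
        for epoch in range(tr_cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, tr_cfg.batch_size):
                idx = order[start : start + tr_cfg.batch_size]
                logits = self.net_.forward(xtr[idx], train=True)
                loss, dlogits = nn.softmax_cross_entropy(logits, ytr[idx])
                self.net_.backward(dlogits)
                opt.step()
                losses.append(loss)
            self.history_["train_loss"].append(float(np.mean(losses)))
            if xval is not None:
                vloss, viou = self._evaluate(xval, yval)
                self.history_["val_loss"].append(vloss)
                self.history_["val_mean_iou"].append(viou)
                if self.verbose:
                    print(
                        f"epoch {epoch + 1}: train loss "
                        f"{self.history_['train_loss'][-1]:.4f} "
                        f"val loss {vloss:.4f} val mIOU {viou:.4f}"
                    )
                if vloss < best_val - 1e-9:
                    best_val, since_best = vloss, 0
                else:
                    since_best += 1
                    if tr_cfg.patience is not None and since_best >= tr_cfg.patience:
                        break
            elif self.verbose:
                print(
                    f"epoch {epoch + 1}: train loss "
                    f"{self.history_['train_loss'][-1]:.4f}"
                )
        self.n_epochs_run_ = len(self.history_["train_loss"])
        return self

    def _batched_logits(self, x: np.ndarray, batch: int = 4) -> np.ndarray:
        outs = [
            self.net_.forward(x[i : i + batch], train=False)
            for i in range(0, x.shape[0], batch)
        ]
        return np.concatenate(outs, axis=0)

    def _evaluate(self, xval: np.ndarray, yval: np.ndarray) -> tuple[float, float]:
        logits = self._batched_logits(xval)
        loss, _ = nn.softmax_cross_entropy(logits, yval)
        pred = logits.argmax(axis=-1)
        ious = []
        for k in range(self.n_classes):
            inter = ((pred == k) & (yval == k)).sum()
            union = ((pred == k) | (yval == k)).sum()
            ious.append(inter / union if union else 1.0)
        return loss, float(np.mean(ious))

    def predict_proba(self, X) -> np.ndarray:
        """Per-class probability maps at network resolution: (n, s, s, 4)."""
        x, _, _ = self._to_network_arrays(X)
        return nn.softmax(self._batched_logits(x), axis=-1)

    def predict(self, X) -> list[LabelMask]:
        """Predicted masks at each input's original geometry.

        Per-pixel argmax of the softmax output (ties go to the lowest class
        index); the network-resolution mask is resized back with nearest
        neighbour.  Column monotonicity is not enforced (raw network output).
        """
        x, _, shapes = self._to_network_arrays(X)
        logits = self._batched_logits(x)
        labels = logits.argmax(axis=-1).astype(np.uint8)
        out = []
        for lab, shape in zip(labels, shapes):
            if shape != lab.shape:
                lab = _sk_resize(
                    lab, shape, order=0, mode="edge", anti_aliasing=False,
                    preserve_range=True,
                ).astype(np.uint8)
            out.append(LabelMask(labels=lab))
        return out

    def score(self, X, y) -> float:
        """Mean IOU over the four compartments, pooled over all images."""
        from .agreement import compartment_iou

        preds = self.predict(X)
        masks = [
            yi if isinstance(yi, LabelMask) else LabelMask(labels=np.asarray(yi))
            for yi in y
        ]
        per_class = []
        for k in range(self.n_classes):
            vals = [compartment_iou(p, m, k) for p, m in zip(preds, masks)]
            per_class.append(float(np.mean(vals)))
        return float(np.mean(per_class))

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Pickle the fitted estimator plus a JSON sidecar of its configs."""
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        sidecar = {
            "net_config": asdict(self._net_config()),
            "train_config": asdict(self._train_config()),
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @staticmethod
    def load(path: str | Path) -> "UNetSegmenter":
        with open(path, "rb") as fh:
            return pickle.load(fh)


# -- functional wrappers ------------------------------------------------------

def build_network(config: NetConfig) -> UNet:
    """Construct the raw (untrained) network for a configuration."""
    return UNet(config)


def train(
    net_config: NetConfig,
    train_pairs: list[tuple[BScan, LabelMask]],
    val_pairs: list[tuple[BScan, LabelMask]] | None,
    config: TrainConfig,
) -> tuple[UNetSegmenter, dict]:
    """Train a segmenter on (image, mask) pairs; returns (model, history)."""
    model = UNetSegmenter(
        input_size=net_config.input_size,
        depth_levels=net_config.depth_levels,
        base_channels=net_config.base_channels,
        convs_per_level=net_config.convs_per_level,
        n_classes=net_config.n_classes,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        epochs=config.epochs,
        patience=config.patience,
        seed=config.seed,
    )
    X, y = [p[0] for p in train_pairs], [p[1] for p in train_pairs]
    val = None
    if val_pairs:
        val = ([p[0] for p in val_pairs], [p[1] for p in val_pairs])
    model.fit(X, y, validation_data=val)
    return model, model.history_


def predict(model: UNetSegmenter, image: BScan) -> LabelMask:
    """Predict the compartment mask of one B-scan."""
    return model.predict([image])[0]


# -- receptive-field (field-of-view) probe ------------------------------------

def receptive_field_support(
    config: NetConfig, probe_size: int | None = None
) -> np.ndarray:
    """Receptive field of the center output pixel, as a boolean input image.

    Replays the architecture's operation sequence backwards on a
    single-channel influence map seeded at the output center: the backward
    image of a 3x3 convolution is a 3x3 dilation; each output pixel of the
    2x2 stride-2 transposed convolution depends on exactly one coarse pixel
    (2x block-wise reduction); each 2x2-pooled pixel depends on its whole 2x2
    block (2x repeat); skip concatenation splits the requirement onto both
    paths (union at the encoder level).  Influence propagation is independent
    of channel counts and weight values, so the result is the exact set of
    input pixels that can affect the center output pixel for some
    weight/input configuration — the network's field of view.
    """
    from scipy.ndimage import binary_dilation

    s = probe_size or config.input_size
    f = 2 ** (config.depth_levels - 1)
    if s % f:
        raise ValidationError(f"probe_size {s} not divisible by {f}")
    struct = np.ones((3, 3), dtype=bool)

    def conv_block(m: np.ndarray) -> np.ndarray:
        for _ in range(config.convs_per_level):
            m = binary_dilation(m, structure=struct)
        return m

    def block_any(m: np.ndarray) -> np.ndarray:
        h, w = m.shape
        return m.reshape(h // 2, 2, w // 2, 2).any(axis=(1, 3))

    d = config.depth_levels
    sup = np.zeros((s, s), dtype=bool)
    sup[s // 2, s // 2] = True  # final 1x1 head adds nothing
    # decoder, walked backwards from fine to coarse levels
    skip_req: dict[int, np.ndarray] = {}
    for lvl in range(d - 1):
        sup = conv_block(sup)
        skip_req[lvl] = sup
        sup = block_any(sup)  # backward image of the 2x2 stride-2 up-conv
    # bottleneck block
    sup = conv_block(sup)
    # encoder, walked backwards from coarse to fine levels
    for lvl in range(d - 2, -1, -1):
        sup = np.repeat(np.repeat(sup, 2, axis=0), 2, axis=1)  # pool backward
        sup = sup | skip_req[lvl]
        sup = conv_block(sup)
    return sup


def covers_input(config: NetConfig, probe_size: int | None = None) -> bool:
    """True if the center output pixel's field of view spans the whole input."""
    return bool(receptive_field_support(config, probe_size).all())
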