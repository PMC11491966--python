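"""Two-stage cascaded 2-D U-Net for organ/tumor segmentation.

Each stage is a classic encoder–decoder with skip connections: four encoder
blocks (two 3×3 convolutions + ReLU, then 2×2 max pooling, feature count
doubling from ``base_features``), a bottleneck, four decoder blocks (2×2
up-convolution, concatenation with the matching encoder feature map, two
3×3 convolutions + ReLU) and a final 1×1 convolution producing one logit
channel.  Convolutions use 'same' padding, so the output logit map has the
input's spatial size and skip concatenation needs no cropping.

Stage I segments the pancreas and stage II the tumor, both from the whole
slice; :func:`fuse_predictions` merges the two binary outputs into a
{0 background, 1 pancreas, 2 tumor} label map with tumor taking precedence.

For swarm-based weight refinement the module provides a bijective mapping
between a chosen subset of layers and a flat parameter vector
(:func:`extract_parameter_vector` / :func:`inject_parameter_vector`), plus a
cached partial forward pass that re-evaluates only the stages a subset can
affect — the refinement loop's inner fitness calls then cost a few decoder
convolutions instead of a full forward pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Conv2d, MaxPool2, ReLU, UpConv2, sigmoid

#: layer subset refined by default: final decoder block + output 1×1 conv
FINAL_BLOCK_SUBSET = ("dec1", "out")


@dataclass(frozen=True)
class StageNetworkConfig:
    input_size: int = 64
    depth: int = 4
    base_features: int = 8
    kernel_size: int = 3
    pool_size: int = 2

    def __post_init__(self) -> None:
        if self.input_size % (self.pool_size ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"pool_size^depth = {self.pool_size ** self.depth}")

    @property
    def bottleneck_size(self) -> int:
        return self.input_size // (self.pool_size ** self.depth)


@dataclass
class ParameterVector:
    """Flat encoding of a layer subset; ``layout`` makes it bijective."""

    values: np.ndarray
    layout: list[tuple[str, str, tuple[int, ...], int]]  # (layer, param, shape, offset)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CascadePrediction:
    pancreas_mask: np.ndarray
    tumor_mask: np.ndarray
    fused_labels: np.ndarray


class StageNetwork:
    """One U-Net stage; see module docstring for the topology."""

    def __init__(self, config: StageNetworkConfig, rng: np.random.Generator):
        self.config = config
        c = config
        f = [c.base_features * 2 ** i for i in range(c.depth + 1)]  # per level
        self.layers: dict[str, Conv2d | UpConv2] = {}
        self.ops: dict[str, ReLU | MaxPool2] = {}

        def conv(name, cin, cout, k=c.kernel_size):
            self.layers[name] = Conv2d(cin, cout, k, rng)
            self.ops[name + ".relu"] = ReLU()

        cin = 1
        for i in range(1, c.depth + 1):
            conv(f"enc{i}.conv1", cin, f[i - 1])
            conv(f"enc{i}.conv2", f[i - 1], f[i - 1])
            self.ops[f"enc{i}.pool"] = MaxPool2()
            cin = f[i - 1]
        conv("bottleneck.conv1", f[c.depth - 1], f[c.depth])
        conv("bottleneck.conv2", f[c.depth], f[c.depth])
        for i in range(c.depth, 0, -1):
            src = f[i] if i == c.depth else f[i]
            self.layers[f"dec{i}.up"] = UpConv2(src, f[i - 1], rng)
            conv(f"dec{i}.conv1", 2 * f[i - 1], f[i - 1])
            conv(f"dec{i}.conv2", f[i - 1], f[i - 1])
        self.layers["out"] = Conv2d(f[0], 1, 1, rng)
        # linear stage plan used by the cached partial forward
        self.stage_names = ([f"enc{i}" for i in range(1, c.depth + 1)]
                            + ["bottleneck"]
                            + [f"dec{i}" for i in range(c.depth, 0, -1)]
                            + ["out"])

    # -- forward ----------------------------------------------------------

    def _double_conv(self, prefix: str, x: np.ndarray, train: bool) -> np.ndarray:
        for j in (1, 2):
            x = self.layers[f"{prefix}.conv{j}"].forward(x, train)
            x = self.ops[f"{prefix}.conv{j}.relu"].forward(x, train)
        return x

    def _run_stage(self, name: str, acts: dict[str, np.ndarray],
                   train: bool) -> None:
        d = self.config.depth
        if name.startswith("enc"):
            i = int(name[3:])
            x = acts["x"] if i == 1 else acts[f"p{i - 1}"]
            e = self._double_conv(name, x, train)
            acts[f"e{i}"] = e
            acts[f"p{i}"] = self.ops[f"enc{i}.pool"].forward(e, train)
        elif name == "bottleneck":
            acts["bott"] = self._double_conv(name, acts[f"p{d}"], train)
        elif name.startswith("dec"):
            i = int(name[3:])
            src = acts["bott"] if i == d else acts[f"d{i + 1}"]
            u = self.layers[f"dec{i}.up"].forward(src, train)
            cat = np.concatenate([u, acts[f"e{i}"]], axis=1)
            acts[f"d{i}"] = self._double_conv(name, cat, train)
        elif name == "out":
            acts["logits"] = self.layers["out"].forward(acts["d1"], train)
        else:  # pragma: no cover
            raise KeyError(name)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logit map for a batch (N, 1, H, W) -> (N, 1, H, W)."""
        s = self.config.input_size
        if x.ndim != 4 or x.shape[2:] != (s, s):
            raise ValueError(f"expected (N, 1, {s}, {s}) input, got {x.shape}")
        acts = {"x": x}
        for name in self.stage_names:
            self._run_stage(name, acts, train)
        return acts["logits"]

    def forward_with_cache(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        acts = {"x": x}
        for name in self.stage_names:
            self._run_stage(name, acts, False)
        return acts["logits"], acts

    def first_stage_of(self, layer_names: set[str]) -> str:
        """Earliest stage in the plan containing any of the given layers."""
        for name in self.stage_names:
            if any(ln == name or ln.startswith(name + ".") for ln in layer_names):
                return name
        raise KeyError(f"no stage owns any of {sorted(layer_names)}")

    def forward_from(self, acts: dict[str, np.ndarray], start: str) -> np.ndarray:
        """Re-run the plan from ``start`` on cached upstream activations.

        Valid when no parameter of a stage before ``start`` changed since
        the cache was built."""
        acts = dict(acts)
        i0 = self.stage_names.index(start)
        for name in self.stage_names[i0:]:
            self._run_stage(name, acts, False)
        return acts["logits"]

    # -- backward / training ---------------------------------------------

    def zero_grad(self) -> None:
        for layer in self.layers.values():
            layer.zero_grad()

    def backward(self, dlogits: np.ndarray) -> None:
        """Backprop a loss gradient on the logits through the whole net.

        Requires the immediately preceding ``forward(..., train=True)``."""
        c = self.config
        f = [c.base_features * 2 ** i for i in range(c.depth + 1)]
        d = self.layers["out"].backward(dlogits)
        dskip: dict[int, np.ndarray] = {}
        for i in range(1, c.depth + 1):  # dec1 .. dec4 (reverse of forward)
            for j in (2, 1):
                d = self.ops[f"dec{i}.conv{j}.relu"].backward(d)
                d = self.layers[f"dec{i}.conv{j}"].backward(d)
            cu = f[i - 1]  # up-conv output channels come first in the concat
            du, dskip[i] = d[:, :cu], d[:, cu:]
            d = self.layers[f"dec{i}.up"].backward(du)
        for j in (2, 1):
            d = self.ops[f"bottleneck.conv{j}.relu"].backward(d)
            d = self.layers[f"bottleneck.conv{j}"].backward(d)
        for i in range(c.depth, 0, -1):
            d = self.ops[f"enc{i}.pool"].backward(d) + dskip[i]
            for j in (2, 1):
                d = self.ops[f"enc{i}.conv{j}.relu"].backward(d)
                d = self.layers[f"enc{i}.conv{j}"].backward(d)

    def make_optimizer(self, lr: float) -> Adam:
        pairs = []
        for layer in self.layers.values():
            ps, gs = layer.params(), layer.grads()
            pairs.extend((ps[k], gs[k]) for k in ps)
        return Adam(pairs, lr=lr)

    # -- checkpointing ----------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for lname, layer in self.layers.items():
            for pname, arr in layer.params().items():
                arrays[f"{lname}/{pname}"] = arr
        cfg = json.dumps(self.config.__dict__)
        np.savez(path, __config__=np.array(cfg), **arrays)

    @classmethod
    def load(cls, path) -> "StageNetwork":
        with np.load(path) as data:
            cfg = StageNetworkConfig(**json.loads(str(data["__config__"])))
            net = cls(cfg, np.random.default_rng(0))
            for lname, layer in net.layers.items():
                for pname, arr in layer.params().items():
                    arr[...] = data[f"{lname}/{pname}"]
        return net


def build_stage_network(config: StageNetworkConfig,
                        rng: np.random.Generator | int) -> StageNetwork:
    """He-initialized stage network, deterministic under a fixed seed."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return StageNetwork(config, rng)


# ---------------------------------------------------------------------------
# parameter-vector round trip
# ---------------------------------------------------------------------------

def _resolve_subset(net: StageNetwork, subset) -> list[str]:
    if subset is None:
        return list(net.layers)
    names = []
    for sel in subset:
        matches = [ln for ln in net.layers
                   if ln == sel or ln.startswith(sel + ".")]
        if not matches:
            raise KeyError(f"subset selector {sel!r} matches no layer; "
                           f"known layers: {sorted(net.layers)}")
        names.extend(m for m in matches if m not in names)
    return names


def extract_parameter_vector(net: StageNetwork, subset=None) -> ParameterVector:
    """Flatten the parameters of the selected layers into one vector.

    ``subset`` is a list of layer names or block prefixes (e.g. ``"dec1"``
    selects the final decoder block's up-conv and both convolutions);
    ``None`` selects every layer."""
    names = _resolve_subset(net, subset)
    layout, chunks, offset = [], [], 0
    for lname in names:
        for pname, arr in net.layers[lname].params().items():
            layout.append((lname, pname, arr.shape, offset))
            chunks.append(arr.ravel())
            offset += arr.size
    return ParameterVector(values=np.concatenate(chunks), layout=layout)


def inject_parameter_vector(net: StageNetwork, vec: ParameterVector) -> StageNetwork:
    """Overwrite the laid-out subset in place; all other tensors untouched."""
    total = sum(int(np.prod(shape)) for _, _, shape, _ in vec.layout)
    if vec.values.size != total:
        raise ValueError(f"vector length {vec.values.size} != layout size {total}")
    for lname, pname, shape, offset in vec.layout:
        size = int(np.prod(shape))
        target = net.layers[lname].params()[pname]
        if target.shape != tuple(shape):
            raise ValueError(f"layout shape {shape} does not match "
                             f"{lname}/{pname} shape {target.shape}")
        target[...] = vec.values[offset:offset + size].reshape(shape)
    return net


# ---------------------------------------------------------------------------
# prediction and fusion
# ---------------------------------------------------------------------------

def predict_mask(net: StageNetwork, image: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Binarize the sigmoid of the network's logits at ``threshold``."""
    s = net.config.input_size
    image = np.asarray(image, dtype=float)
    if image.shape != (s, s):
        raise ValueError(f"expected a {s}×{s} image, got {image.shape}")
    logits = net.forward(image[None, None])
    return (sigmoid(logits[0, 0]) > threshold).astype(np.uint8)


def fuse_predictions(pancreas: np.ndarray, tumor: np.ndarray) -> CascadePrediction:
    """Merge the two stage outputs; tumor overrides pancreas on overlap.

    A tumor pixel outside the pancreas prediction is kept (labelled 2), not
    suppressed."""
    pancreas = np.asarray(pancreas)
    tumor = np.asarray(tumor)
    if pancreas.shape != tumor.shape:
        raise ValueError(f"shape mismatch: {pancreas.shape} vs {tumor.shape}")
    labels = np.zeros(pancreas.shape, dtype=np.uint8)
    labels[pancreas > 0] = 1
    labels[tumor > 0] = 2
    return CascadePrediction(pancreas_mask=(pancreas > 0).astype(np.uint8),
                             tumor_mask=(tumor > 0).astype(np.uint8),
                             fused_labels=labels)


class TruthOracleNetwork:
    """A drop-in stand-in for a StageNetwork that emits stored ground truth.

    Synthetic test double: it maps each known image (by raw bytes) to large
    ±10 logits reproducing the paired truth mask, so a pipeline wired to it
    must score 1.0 on every metric — an end-to-end identity check of
    prediction, fusion, I/O and metric plumbing, independent of training.
    """

    def __init__(self, config: StageNetworkConfig,
                 pairs: list[tuple[np.ndarray, np.ndarray]]):
        self.config = config
        self._truths = {np.asarray(img, dtype=float).tobytes():
                        np.asarray(mask) for img, mask in pairs}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.empty_like(x)
        for i in range(x.shape[0]):
            key = x[i, 0].tobytes()
            if key not in self._truths:
                raise KeyError("oracle has no truth for this image")
            out[i, 0] = np.where(self._truths[key] > 0, 10.0, -10.0)
        return out


def split_label_map(labels: np.ndarray, pancreas_includes_tumor: bool = True
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of fusion: {0,1,2} label map -> (pancreas_mask, tumor_mask).

    By default the tumor (label 2) also counts as pancreas for the stage-I
    ground truth, since the tumor lies within the organ."""
    labels = np.asarray(labels)
    bad = np.setdiff1d(np.unique(labels), [0, 1, 2])
    if bad.size:
        census = {int(v): int((labels == v).sum()) for v in bad}
        raise ValueError(f"unexpected label values (value: count): {census}")
    if pancreas_includes_tumor:
        pancreas = (labels >= 1).astype(np.uint8)
    else:
        pancreas = (labels == 1).astype(np.uint8)
    return pancreas, (labels == 2).astype(np.uint8)
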