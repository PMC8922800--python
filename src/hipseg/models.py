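"""The three networks of the segmentation system.

* ``build_upward_unet`` — a modified 2D U-Net that separates bone from soft
  tissue: two 2x2 max-pool stages, two stride-2 transposed convolutions, three
  3x3 convolutions per resolution block (five blocks), and a final 1x1
  projection — 18 parameterized layers in all (pooling carries no weights and
  is not counted).
* ``build_main_hourglass`` — the main femur segmenter: ``stack_count``
  encoder-decoder (hourglass) structures in sequence, with dense connections
  that feed every block the concatenation of all earlier same-resolution
  outputs across the whole stack, a fusion input from the bone separator
  concatenated at full resolution, and one sigmoid output head per decoder so
  intermediate decoders can be supervised directly.
* ``build_layer_classifier`` — a per-slice femur-presence classifier: a
  12-convolution trunk with four pooling stages, global average pooling, and
  two fully connected layers — 14 parameterized layers.

``count_parameterized_layers`` counts exactly the layers with trainable
weights (convolutions, transposed convolutions, fully connected); pooling,
activations and concatenations are excluded.  The counts are invariant to
channel width.  ``plan_*`` functions reproduce each architecture's layer table
by pure arithmetic, for independent parameter-count verification.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import engine as eg

ROLE_UPWARD = "upward"
ROLE_MAIN = "main"
ROLE_CLASSIFIER = "classifier"

_CLS_POOLS = 4  # classifier trunk pooling stages


@dataclasses.dataclass
class NetworkConfig:
    in_rows: int = 64
    in_cols: int = 32
    base_channels: int = 8
    stack_count: int = 2
    pool_levels: int = 2
    fusion_channels: int = 1
    dense_connections: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.stack_count < 1:
            raise ValueError("stack_count must be >= 1")
        if self.pool_levels != 2:
            raise ValueError("the encoder-decoder design uses exactly 2 pooling levels")
        d = 2 ** self.pool_levels
        if self.in_rows % d or self.in_cols % d:
            raise ValueError(
                f"input dims {(self.in_rows, self.in_cols)} must be divisible by {d}"
            )


@dataclasses.dataclass
class NetworkHandle:
    module: eg.Module
    role: str
    parameterized_layer_count: int
    config: NetworkConfig

    def __call__(self, *args, **kwargs):
        return self.module(*args, **kwargs)


def count_parameterized_layers(net) -> int:
    """Number of trainable-weight layers (conv / deconv / dense); pooling and
    other weight-free ops do not participate in backpropagation and are not
    counted."""
    module = net.module if isinstance(net, NetworkHandle) else net
    return len(module.weighted_layers())


def count_parameters(net) -> int:
    module = net.module if isinstance(net, NetworkHandle) else net
    return sum(p.data.size for p in module.parameters())


# ---------------------------------------------------------------------------
# upward bone/soft-tissue separator
# ---------------------------------------------------------------------------

class _UpwardUNet(eg.Module):
    def __init__(self, cfg: NetworkConfig):
        c = cfg.base_channels
        rng = np.random.default_rng(cfg.seed)

        def block(cin, cout):
            return [
                eg.Conv2d(cin, cout, 3, rng),
                eg.Conv2d(cout, cout, 3, rng),
                eg.Conv2d(cout, cout, 3, rng),
            ]

        self.enc0 = block(1, c)
        self.enc1 = block(c, 2 * c)
        self.bott = block(2 * c, 4 * c)
        self.up1 = eg.ConvTranspose2d(4 * c, 2 * c, rng)
        self.dec1 = block(4 * c, 2 * c)
        self.up0 = eg.ConvTranspose2d(2 * c, c, rng)
        self.dec0 = block(2 * c, c)
        self.head = eg.Conv2d(c, 1, 1, rng)

    @staticmethod
    def _run(blk, x):
        for lyr in blk:
            x = eg.relu(lyr(x))
        return x

    def __call__(self, x):
        """x: (N,1,H,W) in [0,1].  Returns (bone probability map, full-resolution
        feature tensor)."""
        e0 = self._run(self.enc0, x)
        e1 = self._run(self.enc1, eg.maxpool2x2(e0))
        b = self._run(self.bott, eg.maxpool2x2(e1))
        d1 = self._run(self.dec1, eg.concat_channels([self.up1(b), e1]))
        d0 = self._run(self.dec0, eg.concat_channels([self.up0(d1), e0]))
        prob = eg.sigmoid(self.head(d0))
        return prob, d0


def build_upward_unet(cfg: NetworkConfig) -> NetworkHandle:
    net = _UpwardUNet(cfg)
    return NetworkHandle(net, ROLE_UPWARD, count_parameterized_layers(net), cfg)


def plan_upward_unet(cfg: NetworkConfig):
    """Layer table (kind, k, in_ch, out_ch) derived by arithmetic alone."""
    c = cfg.base_channels
    plan = []

    def block(cin, cout):
        plan.append(("conv", 3, cin, cout))
        plan.append(("conv", 3, cout, cout))
        plan.append(("conv", 3, cout, cout))

    block(1, c)
    block(c, 2 * c)
    block(2 * c, 4 * c)
    plan.append(("deconv", 2, 4 * c, 2 * c))
    block(4 * c, 2 * c)
    plan.append(("deconv", 2, 2 * c, c))
    block(2 * c, c)
    plan.append(("conv", 1, c, 1))
    return plan


# ---------------------------------------------------------------------------
# main densely-connected stacked-hourglass femur segmenter
# ---------------------------------------------------------------------------

def _hourglass_channel_plan(cfg: NetworkConfig):
    """Channel bookkeeping shared by the plan and nothing else.

    Yields (kind, k, in_ch, out_ch) walking the stack exactly as the builder
    does, tracking the per-resolution dense registries.
    """
    c = cfg.base_channels
    dense = cfg.dense_connections
    r0 = [1 + cfg.fusion_channels]  # the fused input seeds the full-resolution registry
    r1, r2 = [], []
    plan = []

    def conv_pair(cin, cout):
        plan.append(("conv", 3, cin, cout))
        plan.append(("conv", 3, cout, cout))

    for s in range(cfg.stack_count):
        e0_in = sum(r0) if dense else r0[-1]
        conv_pair(e0_in, c)
        r0.append(c)
        e1_in = (c + sum(r1)) if dense else c
        conv_pair(e1_in, 2 * c)
        r1.append(2 * c)
        b_in = (2 * c + sum(r2)) if dense else 2 * c
        conv_pair(b_in, 4 * c)
        r2.append(4 * c)
        plan.append(("deconv", 2, 4 * c, 2 * c))
        d1_in = (2 * c + sum(r1)) if dense else 2 * c
        conv_pair(d1_in, 2 * c)
        r1.append(2 * c)
        plan.append(("deconv", 2, 2 * c, c))
        d0_in = (c + sum(r0)) if dense else c
        conv_pair(d0_in, c)
        r0.append(c)
        plan.append(("conv", 1, c, 1))
    return plan


def plan_main_hourglass(cfg: NetworkConfig):
    return _hourglass_channel_plan(cfg)


def planned_parameter_count(plan) -> int:
    """Sum of k*k*in_ch*out_ch + out_ch over a layer table."""
    return sum(k * k * cin * cout + cout for _, k, cin, cout in plan)


class _MainHourglass(eg.Module):
    def __init__(self, cfg: NetworkConfig):
        c = cfg.base_channels
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed + 1)
        dense = cfg.dense_connections
        r0 = [1 + cfg.fusion_channels]
        r1, r2 = [], []
        self.stages = []
        for s in range(cfg.stack_count):
            st = {}
            e0_in = sum(r0) if dense else r0[-1]
            st["e0"] = [eg.Conv2d(e0_in, c, 3, rng), eg.Conv2d(c, c, 3, rng)]
            r0.append(c)
            e1_in = (c + sum(r1)) if dense else c
            st["e1"] = [eg.Conv2d(e1_in, 2 * c, 3, rng), eg.Conv2d(2 * c, 2 * c, 3, rng)]
            r1.append(2 * c)
            b_in = (2 * c + sum(r2)) if dense else 2 * c
            st["b"] = [eg.Conv2d(b_in, 4 * c, 3, rng), eg.Conv2d(4 * c, 4 * c, 3, rng)]
            r2.append(4 * c)
            st["up1"] = eg.ConvTranspose2d(4 * c, 2 * c, rng)
            d1_in = (2 * c + sum(r1)) if dense else 2 * c
            st["d1"] = [eg.Conv2d(d1_in, 2 * c, 3, rng), eg.Conv2d(2 * c, 2 * c, 3, rng)]
            r1.append(2 * c)
            st["up0"] = eg.ConvTranspose2d(2 * c, c, rng)
            d0_in = (c + sum(r0)) if dense else c
            st["d0"] = [eg.Conv2d(d0_in, c, 3, rng), eg.Conv2d(c, c, 3, rng)]
            r0.append(c)
            st["head"] = eg.Conv2d(c, 1, 1, rng)
            self.stages.append(st)

    @staticmethod
    def _run(blk, x):
        for lyr in blk:
            x = eg.relu(lyr(x))
        return x

    def __call__(self, image, fusion):
        """image (N,1,H,W), fusion (N,fusion_channels,H,W) -> list of femur
        probability maps, one per decoder head (the last is the prediction)."""
        if image.data.shape[2:] != fusion.data.shape[2:]:
            raise ValueError(
                f"image {image.data.shape} and fusion {fusion.data.shape} spatial dims differ"
            )
        dense = self.cfg.dense_connections
        x = eg.concat_channels([image, fusion])
        r0, r1, r2 = [x], [], []
        heads = []
        for st in self.stages:
            e0 = self._run(st["e0"], eg.concat_channels(r0 if dense else [r0[-1]]))
            r0.append(e0)
            p0 = eg.maxpool2x2(e0)
            e1 = self._run(st["e1"], eg.concat_channels([p0] + (r1 if dense else [])))
            r1.append(e1)
            p1 = eg.maxpool2x2(e1)
            b = self._run(st["b"], eg.concat_channels([p1] + (r2 if dense else [])))
            r2.append(b)
            u1 = st["up1"](b)
            d1 = self._run(st["d1"], eg.concat_channels([u1] + (r1 if dense else [])))
            r1.append(d1)
            u0 = st["up0"](d1)
            d0 = self._run(st["d0"], eg.concat_channels([u0] + (r0 if dense else [])))
            r0.append(d0)
            heads.append(eg.sigmoid(st["head"](d0)))
        return heads


def build_main_hourglass(cfg: NetworkConfig) -> NetworkHandle:
    net = _MainHourglass(cfg)
    return NetworkHandle(net, ROLE_MAIN, count_parameterized_layers(net), cfg)


# ---------------------------------------------------------------------------
# downward slice classifier
# ---------------------------------------------------------------------------

class _LayerClassifier(eg.Module):
    def __init__(self, cfg: NetworkConfig):
        c = cfg.base_channels
        rng = np.random.default_rng(cfg.seed + 2)

        def block(cin, cout):
            return [
                eg.Conv2d(cin, cout, 3, rng),
                eg.Conv2d(cout, cout, 3, rng),
                eg.Conv2d(cout, cout, 3, rng),
            ]

        self.blocks = [block(1, c), block(c, 2 * c), block(2 * c, 4 * c),
                       block(4 * c, 4 * c)]
        self.fc1 = eg.Linear(4 * c, 16, rng)
        self.fc2 = eg.Linear(16, 1, rng)

    def __call__(self, x):
        """x (N,1,H,W) -> (N,1) femur-presence confidence in [0,1]."""
        for blk in self.blocks:
            for lyr in blk:
                x = eg.relu(lyr(x))
            x = eg.maxpool2x2(x)
        x = eg.global_avg_pool(x)
        x = eg.relu(self.fc1(x))
        return eg.sigmoid(self.fc2(x))


def build_layer_classifier(cfg: NetworkConfig) -> NetworkHandle:
    d = 2 ** _CLS_POOLS
    if cfg.in_rows % d or cfg.in_cols % d:
        raise ValueError(
            f"classifier input dims {(cfg.in_rows, cfg.in_cols)} must be divisible by {d}"
        )
    net = _LayerClassifier(cfg)
    return NetworkHandle(net, ROLE_CLASSIFIER, count_parameterized_layers(net), cfg)


def plan_layer_classifier(cfg: NetworkConfig):
    c = cfg.base_channels
    plan = []
    chans = [(1, c), (c, 2 * c), (2 * c, 4 * c), (4 * c, 4 * c)]
    for cin, cout in chans:
        plan.append(("conv", 3, cin, cout))
        plan.append(("conv", 3, cout, cout))
        plan.append(("conv", 3, cout, cout))
    plan.append(("dense", 1, 4 * c, 16))
    plan.append(("dense", 1, 16, 1))
    return plan


_BUILDERS = {
    ROLE_UPWARD: build_upward_unet,
    ROLE_MAIN: build_main_hourglass,
    ROLE_CLASSIFIER: build_layer_classifier,
}


def save_handle(handle: NetworkHandle, path) -> None:
    meta = json.dumps({"role": handle.role, "config": dataclasses.asdict(handle.config)})
    arrays = {f"p{i}": a for i, a in enumerate(handle.module.state_arrays())}
    np.savez(path, meta=np.array(meta), **arrays)


def load_handle(path) -> NetworkHandle:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        arrays = [z[f"p{i}"] for i in range(len(z.files) - 1)]
    cfg = NetworkConfig(**meta["config"])
    handle = _BUILDERS[meta["role"]](cfg)
    handle.module.load_state_arrays(arrays)
    return handle
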