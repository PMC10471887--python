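"""The DCFCNN dual-branch network and its ablation variants.

The network classifies H&E histopathology patches with two cooperating
pathways applied to the same pre-processed RGB image:

* a **spatial branch** of five residual stages (RS_1..RS_5, channel plan
  3 -> 32 -> 64 -> 128 -> 256 -> 512) whose first structure in every stage
  halves the spatial resolution through a stride-2 projection block;
* a **channel branch** opening with a multiscale stem (MSF: parallel 1x1,
  3x3, 5x5 and 7x7 convolutions of 64 filters each, fused element-wise)
  followed by a chain of multilevel 1x1-convolution blocks (MLF) with
  optional feature reuse.

The channel branch output is fused into the spatial branch by element-wise
sum at the unique stage where shapes coincide (after RS_{n_mlf+1}); the
fused map runs through the remaining residual stages and a 3x3x1024 head,
global average pooling and a fully connected classifier.

Bias/normalisation layout: batch normalisation follows every convolution.
Spatial-branch convolutions carry no bias (standard residual-network
practice); channel-branch and head convolutions carry a bias. This layout
reproduces the published trainable-parameter total of 20,949,378 exactly
(see docs/methods.md for the arbitration).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .exceptions import ChannelMismatchError, ConfigError, FusionShapeError

__all__ = [
    "ArchitectureConfig",
    "ResidualBlock",
    "RSStage",
    "MSF",
    "MLF",
    "Stem1x1",
    "DCFCNN",
    "build_residual_structure",
    "build_rs_layer",
    "build_msf",
    "build_mlf",
    "build_dcfcnn",
    "count_trainable_params",
    "shape_trace",
    "ablation_variants",
    "SPATIAL_CHANNEL_PLAN",
    "mlf_channel_plan",
]

#: spatial-branch channel plan: input RGB then one entry per residual stage
SPATIAL_CHANNEL_PLAN = (3, 32, 64, 128, 256, 512)


def mlf_channel_plan(n_mlf: int) -> list[tuple[int, int]]:
    """(in, out) channel pairs for the MLF chain after the 64-channel stem.

    The first MLF keeps 64 channels; each subsequent MLF doubles, ending at
    64 * 2**(n_mlf-1) so the chain output always matches the residual stage
    it fuses with (512 for a four-MLF chain).
    """
    if not 1 <= n_mlf <= 4:
        raise ConfigError(f"n_mlf must be in [1, 4], got {n_mlf}")
    pairs = []
    cin = 64
    for i in range(n_mlf):
        cout = 64 if i == 0 else cin * 2
        pairs.append((cin, cout))
        cin = cout
    return pairs


@dataclass(frozen=True)
class ArchitectureConfig:
    """All switches defining a DCFCNN variant."""

    n_mlf: int = 3
    feature_reuse: bool = True
    use_msf: bool = True
    use_channel_branch: bool = True
    rs1_first_stride: int = 2
    num_classes: int = 2
    input_channels: int = 3

    def __post_init__(self):
        if not 1 <= self.n_mlf <= 4:
            raise ConfigError(f"n_mlf must be in [1, 4], got {self.n_mlf}")
        if self.rs1_first_stride not in (1, 2):
            raise ConfigError(
                f"rs1_first_stride must be 1 or 2, got {self.rs1_first_stride}"
            )
        if self.num_classes < 2:
            raise ConfigError("num_classes must be >= 2")
        if self.input_channels != 3:
            raise ConfigError("only 3-channel RGB input is supported")


class ResidualBlock(nn.Module):
    """Two 3x3 convolutions with a shortcut.

    Variant A (``downsample=False``): stride-1, identity shortcut,
    shape-preserving; requires equal input/output channels.
    Variant B (``downsample=True``): the first convolution uses
    ``first_stride`` (2 by default) and the shortcut is a 1x1 convolution
    with the same stride so dimensions match.
    """

    def __init__(self, in_channels, out_channels, downsample, first_stride=2,
                 bias=False, dtype=np.float32):
        super().__init__()
        if not downsample and in_channels != out_channels:
            raise ChannelMismatchError(
                "shape-preserving residual structure requires equal channels, "
                f"got {in_channels} -> {out_channels}"
            )
        stride = first_stride if downsample else 1
        self.conv1 = self.register(
            nn.Conv2d(in_channels, out_channels, 3, stride, 1, bias=bias, dtype=dtype))
        self.bn1 = self.register(nn.BatchNorm2d(out_channels, dtype=dtype))
        self.relu1 = self.register(nn.ReLU())
        self.conv2 = self.register(
            nn.Conv2d(out_channels, out_channels, 3, 1, 1, bias=bias, dtype=dtype))
        self.bn2 = self.register(nn.BatchNorm2d(out_channels, dtype=dtype))
        self.downsample = downsample
        self.projection = downsample or in_channels != out_channels
        if self.projection:
            self.sc_conv = self.register(
                nn.Conv2d(in_channels, out_channels, 1, stride, 0, bias=bias, dtype=dtype))
            self.sc_bn = self.register(nn.BatchNorm2d(out_channels, dtype=dtype))
        self.relu_out = self.register(nn.ReLU())

    def out_shape(self, in_shape):
        return self.bn2.out_shape(
            self.conv2.out_shape(self.bn1.out_shape(self.conv1.out_shape(in_shape))))

    def forward(self, x, training=False, update_stats=True):
        kw = dict(training=training, update_stats=update_stats)
        a = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, **kw), **kw), **kw)
        b = self.bn2.forward(self.conv2.forward(a, **kw), **kw)
        s = (self.sc_bn.forward(self.sc_conv.forward(x, **kw), **kw)
             if self.projection else x)
        return self.relu_out.forward(b + s, **kw)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        db = self.bn2.backward(d)
        da = self.conv2.backward(db)
        dx = self.conv1.backward(self.bn1.backward(self.relu1.backward(da)))
        if self.projection:
            dx = dx + self.sc_conv.backward(self.sc_bn.backward(d))
        else:
            dx = dx + d
        return dx


class RSStage(nn.Module):
    """A residual stage: one downsampling structure then shape-preserving ones."""

    def __init__(self, index, in_channels, out_channels, first_stride=2,
                 dtype=np.float32):
        super().__init__()
        if not 1 <= index <= 5:
            raise ConfigError(f"residual stage index must be 1..5, got {index}")
        self.index = index
        n_blocks = 3 if index == 5 else 2
        blocks = [ResidualBlock(in_channels, out_channels, downsample=True,
                                first_stride=first_stride, dtype=dtype)]
        blocks += [ResidualBlock(out_channels, out_channels, downsample=False,
                                 dtype=dtype) for _ in range(n_blocks - 1)]
        self.blocks = [self.register(b) for b in blocks]

    def out_shape(self, in_shape):
        for b in self.blocks:
            in_shape = b.out_shape(in_shape)
        return in_shape

    def forward(self, x, training=False, update_stats=True):
        for b in self.blocks:
            x = b.forward(x, training=training, update_stats=update_stats)
        return x

    def backward(self, dout):
        for b in reversed(self.blocks):
            dout = b.backward(dout)
        return dout


class MSF(nn.Module):
    """Multiscale stem: parallel 1x1/3x3/5x5/7x7 convolutions, sum-fused.

    The 3x3/5x5/7x7 paths use stride 2 with same-dimension padding; the 1x1
    path runs at stride 1 and is brought to the common resolution by a 3x3
    max-pool with stride 2. Each path is conv -> BN -> ReLU; the four
    64-channel maps are fused element-wise.
    """

    PATHS = ("conv1x1", "conv3x3", "conv5x5", "conv7x7")

    def __init__(self, in_channels=3, filters=64, dtype=np.float32):
        super().__init__()
        self.cin = in_channels
        specs = {"conv1x1": (1, 1, 0), "conv3x3": (3, 2, 1),
                 "conv5x5": (5, 2, 2), "conv7x7": (7, 2, 3)}
        self.paths = {}
        for name, (k, s, p) in specs.items():
            seq = nn.Sequential(
                nn.Conv2d(in_channels, filters, k, s, p, bias=True, dtype=dtype),
                nn.BatchNorm2d(filters, dtype=dtype),
                nn.ReLU(),
            )
            self.paths[name] = self.register(seq)
        self.pool1x1 = self.register(nn.MaxPool2d(3, 2, 1))

    def out_shape(self, in_shape):
        if in_shape[0] != self.cin:
            raise ConfigError(f"MSF expects {self.cin}-channel input, got {in_shape[0]}")
        return self.paths["conv3x3"].out_shape(in_shape)

    def forward(self, x, training=False, update_stats=True, capture=None):
        if x.shape[1] != self.cin:
            raise ConfigError(f"MSF expects {self.cin}-channel input, got {x.shape[1]}")
        kw = dict(training=training, update_stats=update_stats)
        outs = []
        for name in self.PATHS:
            y = self.paths[name].forward(x, **kw)
            if name == "conv1x1":
                y = self.pool1x1.forward(y, **kw)
            if capture is not None and f"msf.{name}" in capture:
                capture[f"msf.{name}"] = y.copy()
            outs.append(y)
        fused = outs[0] + outs[1] + outs[2] + outs[3]
        if capture is not None and "msf.out" in capture:
            capture["msf.out"] = fused.copy()
        return fused

    def backward(self, dout):
        dx = self.pool1x1.backward(dout)
        dx = self.paths["conv1x1"].backward(dx)
        for name in self.PATHS[1:]:
            dx = dx + self.paths[name].backward(dout)
        return dx


class Stem1x1(nn.Module):
    """Minimal channel-branch stem replacing MSF in the no-MSF ablations.

    A single stride-1 1x1 convolution lifting RGB to 64 channels; no spatial
    reduction, which is why those ablations also set the first spatial
    stride to 1 to keep the branches alignable.
    """

    def __init__(self, in_channels=3, filters=64, dtype=np.float32):
        super().__init__()
        self.seq = self.register(nn.Sequential(
            nn.Conv2d(in_channels, filters, 1, 1, 0, bias=True, dtype=dtype),
            nn.BatchNorm2d(filters, dtype=dtype),
            nn.ReLU(),
        ))

    def out_shape(self, in_shape):
        return self.seq.out_shape(in_shape)

    def forward(self, x, training=False, update_stats=True, capture=None):
        return self.seq.forward(x, training=training, update_stats=update_stats)

    def backward(self, dout):
        return self.seq.backward(dout)


class MLF(nn.Module):
    """Multilevel 1x1-convolution block with optional feature reuse.

    Conv1 maps in->out channels; Conv2..Conv4 map out->out; each convolution
    is followed by BN and ReLU. With feature reuse on, Conv4 consumes the
    element-wise sum of the first three activations, otherwise Conv3's
    activation alone. A trailing 3x3 max-pool (stride 2, padding 1) halves
    the spatial dimensions. Only the wiring differs between the two modes;
    shapes and parameter counts are identical.
    """

    def __init__(self, in_channels, out_channels, feature_reuse=True, dtype=np.float32):
        super().__init__()
        if out_channels not in (in_channels, 2 * in_channels):
            raise ConfigError(
                "MLF output channels must equal or double the input channels, "
                f"got {in_channels} -> {out_channels}"
            )
        self.feature_reuse = feature_reuse
        chans = [(in_channels, out_channels)] + [(out_channels, out_channels)] * 3
        self.convs = []
        for i, (ci, co) in enumerate(chans, start=1):
            seq = nn.Sequential(
                nn.Conv2d(ci, co, 1, 1, 0, bias=True, dtype=dtype),
                nn.BatchNorm2d(co, dtype=dtype),
                nn.ReLU(),
            )
            self.convs.append(self.register(seq))
        self.pool = self.register(nn.MaxPool2d(3, 2, 1))

    def out_shape(self, in_shape):
        s = in_shape
        for seq in self.convs:
            s = seq.out_shape(s)
        return self.pool.out_shape(s)

    def forward(self, x, training=False, update_stats=True):
        kw = dict(training=training, update_stats=update_stats)
        a1 = self.convs[0].forward(x, **kw)
        a2 = self.convs[1].forward(a1, **kw)
        a3 = self.convs[2].forward(a2, **kw)
        z4 = a1 + a2 + a3 if self.feature_reuse else a3
        a4 = self.convs[3].forward(z4, **kw)
        return self.pool.forward(a4, **kw)

    def backward(self, dout):
        d4 = self.convs[3].backward(self.pool.backward(dout))
        if self.feature_reuse:
            d3 = self.convs[2].backward(d4)
            d2 = self.convs[1].backward(d3 + d4)
            d1 = self.convs[0].backward(d2 + d4)
        else:
            d3 = self.convs[2].backward(d4)
            d2 = self.convs[1].backward(d3)
            d1 = self.convs[0].backward(d2)
        return d1


class DCFCNN(nn.Module):
    """The assembled dual-branch network.

    ``forward`` runs the spatial stages up to the fusion point, adds the
    channel-branch output (when enabled), continues through the remaining
    stages, and applies the 3x3x1024 head, global average pooling and the
    fully connected classifier. ``backward`` propagates the logit gradient
    through both branches (the fusion sum duplicates the gradient).
    """

    def __init__(self, config: ArchitectureConfig | None = None, dtype=np.float32):
        super().__init__()
        cfg = config or ArchitectureConfig()
        self.config = cfg
        self.dtype = dtype
        plan = SPATIAL_CHANNEL_PLAN
        self.rs_stages = []
        for i in range(1, 6):
            stride = cfg.rs1_first_stride if i == 1 else 2
            self.rs_stages.append(self.register(
                RSStage(i, plan[i - 1], plan[i], first_stride=stride, dtype=dtype)))
        if cfg.use_channel_branch:
            self.stem = self.register(
                MSF(cfg.input_channels, dtype=dtype) if cfg.use_msf
                else Stem1x1(cfg.input_channels, dtype=dtype))
            self.mlfs = [self.register(MLF(ci, co, cfg.feature_reuse, dtype=dtype))
                         for ci, co in mlf_channel_plan(cfg.n_mlf)]
            self.fusion_stage = cfg.n_mlf + 1  # fuse after RS_{n_mlf+1}
        else:
            self.stem, self.mlfs, self.fusion_stage = None, [], None
        self.head_conv = self.register(nn.Conv2d(plan[5], 1024, 3, 1, 1, bias=True, dtype=dtype))
        self.head_bn = self.register(nn.BatchNorm2d(1024, dtype=dtype))
        self.head_relu = self.register(nn.ReLU())
        self.gap = self.register(nn.GlobalAvgPool())
        self.fc = self.register(nn.Linear(1024, cfg.num_classes, dtype=dtype))

    # -- shape bookkeeping -------------------------------------------------
    def channel_branch_shape(self, in_shape):
        s = self.stem.out_shape(in_shape)
        for m in self.mlfs:
            s = m.out_shape(s)
        return s

    def forward(self, x, training=False, update_stats=True, capture=None):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1] != self.config.input_channels:
            raise ConfigError(
                f"expected (N, {self.config.input_channels}, H, W) input, got {x.shape}")
        kw = dict(training=training, update_stats=update_stats)
        h = x
        for i, stage in enumerate(self.rs_stages, start=1):
            h = stage.forward(h, **kw)
            if self.fusion_stage is not None and i == self.fusion_stage:
                c = self.stem.forward(x, capture=capture, **kw)
                for m in self.mlfs:
                    c = m.forward(c, **kw)
                if c.shape != h.shape:
                    raise FusionShapeError(h.shape[1:], c.shape[1:])
                h = h + c
                if capture is not None and "fusion" in capture:
                    capture["fusion"] = h.copy()
        h = self.head_relu.forward(self.head_bn.forward(
            self.head_conv.forward(h, **kw), **kw), **kw)
        f = self.gap.forward(h, **kw)
        return self.fc.forward(f, **kw)

    def backward(self, dlogits):
        d = self.fc.backward(dlogits)
        d = self.gap.backward(d)
        d = self.head_conv.backward(self.head_bn.backward(self.head_relu.backward(d)))
        for i in range(5, 0, -1):
            if self.fusion_stage is not None and i == self.fusion_stage:
                # d is the gradient at the fusion sum: it flows unchanged into
                # both the channel branch and the spatial stage below
                dc = d
                for m in reversed(self.mlfs):
                    dc = m.backward(dc)
                self.stem.backward(dc)
            d = self.rs_stages[i - 1].backward(d)
        return d

    # -- introspection -----------------------------------------------------
    def capture_points(self):
        names = []
        if isinstance(self.stem, MSF):
            names += [f"msf.{p}" for p in MSF.PATHS] + ["msf.out"]
        if self.fusion_stage is not None:
            names.append("fusion")
        return tuple(names)

    def state_dict(self):
        d = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        stats = self._bn_stats()
        for i, (m, v) in enumerate(stats):
            d[f"bn_mean_{i}"], d[f"bn_var_{i}"] = m, v
        return d

    def load_state_dict(self, d):
        for i, p in enumerate(self.parameters()):
            p.data[...] = d[f"param_{i}"]
        for i, (bn, _) in enumerate(self._bn_modules()):
            bn.running_mean[...] = d[f"bn_mean_{i}"]
            bn.running_var[...] = d[f"bn_var_{i}"]

    def _bn_modules(self):
        out = []

        def walk(m):
            if isinstance(m, nn.BatchNorm2d):
                out.append((m, None))
            for c in m._children:
                walk(c)

        walk(self)
        return out

    def _bn_stats(self):
        return [(bn.running_mean.copy(), bn.running_var.copy())
                for bn, _ in self._bn_modules()]


# ---------------------------------------------------------------------------
# Builder functions (thin, explicit surface over the classes above)
# ---------------------------------------------------------------------------

def build_residual_structure(in_channels, out_channels, downsample, first_stride=2):
    """A single residual structure (variant A or B)."""
    return ResidualBlock(in_channels, out_channels, downsample, first_stride=first_stride)


def build_rs_layer(index, in_channels, out_channels, first_stride=2):
    """Residual stage ``RS_index``: downsampling block then identity blocks."""
    return RSStage(index, in_channels, out_channels, first_stride=first_stride)


def build_msf():
    return MSF()


def build_mlf(in_channels, out_channels, feature_reuse=True):
    return MLF(in_channels, out_channels, feature_reuse)


def build_dcfcnn(config: ArchitectureConfig | None = None, seed: int | None = None,
                 dtype=np.float32) -> DCFCNN:
    """Construct (and optionally initialise) a DCFCNN variant."""
    model = DCFCNN(config, dtype=dtype)
    if seed is not None:
        model.initialize(np.random.default_rng(seed))
    return model


def count_trainable_params(module: nn.Module) -> int:
    """Total element count of all trainable tensors in ``module``."""
    return module.param_count()


def shape_trace(model: DCFCNN, input_shape=(3, 448, 448)):
    """Symbolic per-module shape records for a given input.

    Returns an ordered list of ``(module_name, input_shape, output_shape)``
    with shapes as ``(H, W, C)`` tuples (channels last, the convention used
    for printed layer tables); the pooled and fully connected records use
    ``(1, C)``.
    """
    c, h, w = input_shape
    if c != model.config.input_channels:
        raise ConfigError(f"expected {model.config.input_channels}-channel input")

    def hwc(s):
        return (s[1], s[2], s[0])

    records = []
    if model.fusion_stage is not None:
        name = "MSF" if isinstance(model.stem, MSF) else "Conv1x1 stem"
        s_in = (c, h, w)
        s_out = model.stem.out_shape(s_in)
        records.append((name, hwc(s_in), hwc(s_out)))
        for i, m in enumerate(model.mlfs, start=1):
            s_next = m.out_shape(s_out)
            records.append((f"MLF_{i}", hwc(s_out), hwc(s_next)))
            s_out = s_next
        channel_out = s_out
    s = (c, h, w)
    for i, stage in enumerate(model.rs_stages, start=1):
        s_next = stage.out_shape(s)
        records.append((f"RS_{i}", hwc(s), hwc(s_next)))
        if model.fusion_stage is not None and i == model.fusion_stage:
            if s_next != channel_out:
                raise FusionShapeError(s_next, channel_out)
        s = s_next
    s_head = model.head_bn.out_shape(model.head_conv.out_shape(s))
    records.append(("Conv", hwc(s), hwc(s_head)))
    records.append(("AdaptiveAvgPool", hwc(s_head), (1, s_head[0])))
    records.append(("Fully connect", (1, s_head[0]), (1, model.config.num_classes)))
    return records


def ablation_variants() -> dict[str, ArchitectureConfig]:
    """The five published ablation rows as ready-made configurations.

    Rows without the multiscale stem set the first spatial stride to 1 so the
    (stride-1) 1x1 stem replacement still lines up with the spatial branch.
    """
    base = ArchitectureConfig()
    return {
        "spatial_only": replace(base, use_channel_branch=False,
                                feature_reuse=False, use_msf=False),
        "mlf": replace(base, use_msf=False, feature_reuse=False, rs1_first_stride=1),
        "mlf_reuse": replace(base, use_msf=False, feature_reuse=True, rs1_first_stride=1),
        "msf_mlf": replace(base, feature_reuse=False),
        "full": base,
    }
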