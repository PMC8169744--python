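"""Two-head slice-wise segmentation model.

One encoder–decoder CNN maps a preprocessed axial slice to a 5-channel
per-pixel output: channel 0 through a logistic squashing gives ``p_calc``
(is this pixel calcified coronary plaque?), channels 1–4 through a per-pixel
softmax give the artery membership ``(p_lca, p_lad, p_lcx, p_rca)`` with
``p_lca + p_lad + p_lcx + p_rca = 1`` at every pixel.  Non-coronary
calcifications (aortic wall, valves) have no class of their own: the model
must learn to suppress them through low ``p_calc``.

The encoder is a stack of squeeze-and-excitation residual stages with
grouped 3x3 convolutions (SE-ResNeXt style); the full 50-layer stage plan
(3, 4, 6, 3) is available, and shallow variants keep the identical output
contract for desk-scale work.  The decoder is 4 blocks, each a 3x3
convolution, a 4x4 stride-2 transposed convolution (2x upsampling) and a
second 3x3 convolution; three U-Net-style skip connections concatenate
encoder features into the decoder, leaving the deepest decoder block
unskipped.  Both heads share the whole trunk and split only at the final
1x1 projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from skimage.transform import resize

from . import _nn
from ._nn import Module, Conv2d, ConvTranspose2d, GroupNorm, SEBlock, relu, \
    sigmoid, softmax_channels, concat_channels
from .ct_io import CTVolume, PreprocessConfig, preprocess_slice

__all__ = [
    "ModelConfig",
    "ProbabilityVolume",
    "SegModel",
    "build_model",
    "predict_volume",
    "save_model",
    "load_model",
]

VESSELS = ("LCA", "LAD", "LCX", "RCA")

# encoder residual blocks per stage, by nominal depth
_STAGE_PLANS = {10: (1, 1, 1, 1), 18: (2, 2, 2, 2), 50: (3, 4, 6, 3)}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``encoder_depth`` selects the stage plan (50 = full model; 10 and 18 are
    reduced variants with the same output contract).  ``base_channels``
    scales every width; the published model corresponds to 64, desk-scale
    tests use 4–8.  ``decoder_channels`` are the four decoder block widths
    (halving per block by default).  Cardinality and SE reduction follow the
    cited encoder family and are clipped to the available width.
    """

    encoder_depth: int = 50
    base_channels: int = 64
    decoder_channels: tuple[int, int, int, int] = (256, 128, 64, 32)
    n_vessel_classes: int = 4
    skip_levels: int = 3
    cardinality: int = 32
    se_reduction: int = 16
    use_pretrained_encoder: bool = False
    encoder_weights: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.encoder_depth not in _STAGE_PLANS:
            raise ValueError(
                f"encoder_depth must be one of {sorted(_STAGE_PLANS)}")
        if self.skip_levels != 3:
            raise ValueError("the architecture uses exactly 3 skip levels")
        if len(self.decoder_channels) != 4:
            raise ValueError("decoder has exactly 4 blocks")
        if self.n_vessel_classes != 4:
            raise ValueError("four coronary territories are modelled")

    @classmethod
    def reduced(cls, seed: int = 0) -> "ModelConfig":
        """A small configuration for CPU-scale experiments and tests."""
        return cls(encoder_depth=10, base_channels=8,
                   decoder_channels=(32, 16, 8, 8), cardinality=2,
                   se_reduction=4, seed=seed)


@dataclass
class ProbabilityVolume:
    """Per-pixel model output for a whole exam.

    ``calc`` is ``(n_slices, H, W)`` with values in (0, 1); ``vessel`` is
    ``(n_slices, 4, H, W)`` ordered (LCA, LAD, LCX, RCA) and summing to 1
    over the channel axis at every pixel.
    """

    calc: np.ndarray
    vessel: np.ndarray

    def __post_init__(self):
        self.calc = np.asarray(self.calc, dtype=np.float64)
        self.vessel = np.asarray(self.vessel, dtype=np.float64)
        if self.calc.ndim != 3 or self.vessel.ndim != 4:
            raise ValueError("calc must be rank 3 and vessel rank 4")
        if self.vessel.shape[1] != 4:
            raise ValueError("vessel axis must have 4 channels")
        if (self.calc.shape[0] != self.vessel.shape[0]
                or self.calc.shape[1:] != self.vessel.shape[2:]):
            raise ValueError("calc/vessel shapes disagree")

    @property
    def n_slices(self) -> int:
        return self.calc.shape[0]

    def validate(self, atol: float = 1e-6) -> None:
        """Assert the probability invariants (range and per-pixel simplex)."""
        if self.calc.size and not (
                (self.calc > 0).all() and (self.calc < 1).all()):
            raise ValueError("p_calc must lie strictly in (0, 1)")
        if self.vessel.size:
            if not ((self.vessel > 0).all() and (self.vessel < 1).all()):
                raise ValueError("vessel probabilities must lie in (0, 1)")
            s = self.vessel.sum(axis=1)
            if not np.allclose(s, 1.0, atol=atol):
                raise ValueError("vessel probabilities must sum to 1")


class _ResidualSEBlock(Module):
    """Grouped 3x3 double conv with SE gating and a (projected) shortcut."""

    def __init__(self, rng, cin, cout, stride, cardinality, se_reduction):
        groups = int(np.gcd(np.gcd(cin, cout), cardinality))
        self.conv1 = Conv2d(rng, cin, cout, k=3, stride=stride, groups=groups)
        self.norm1 = GroupNorm(cout)
        self.conv2 = Conv2d(rng, cout, cout, k=3, groups=groups)
        self.norm2 = GroupNorm(cout)
        self.se = SEBlock(rng, cout, reduction=se_reduction)
        if cin != cout or stride != 1:
            self.proj = Conv2d(rng, cin, cout, k=1, stride=stride, pad=0)
        else:
            self.proj = None

    def __call__(self, x):
        h = self.norm2(self.conv2(relu(self.norm1(self.conv1(x)))))
        h = self.se(h)
        sc = self.proj(x) if self.proj is not None else x
        return relu(h + sc)


class _DecoderBlock(Module):
    """conv3x3 -> 4x4 stride-2 transposed conv (2x up) -> conv3x3."""

    def __init__(self, rng, cin, cout):
        self.conv_in = Conv2d(rng, cin, cout, k=3)
        self.norm_in = GroupNorm(cout)
        self.up = ConvTranspose2d(rng, cout, cout)
        self.norm_up = GroupNorm(cout)
        self.conv_out = Conv2d(rng, cout, cout, k=3)
        self.norm_out = GroupNorm(cout)

    def __call__(self, x):
        h = relu(self.norm_in(self.conv_in(x)))
        h = relu(self.norm_up(self.up(h)))
        return relu(self.norm_out(self.conv_out(h)))


class SegModel(Module):
    """The assembled two-head network (see module docstring)."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        plan = _STAGE_PLANS[cfg.encoder_depth]
        c = cfg.base_channels
        widths = (c, 2 * c, 4 * c, 8 * c)

        self.stem = Conv2d(rng, 1, c, k=3)  # full resolution
        self.stem_norm = GroupNorm(c)
        self.stages = []
        cin = c
        for width, n_blocks in zip(widths, plan):
            blocks = []
            for bi in range(n_blocks):
                blocks.append(_ResidualSEBlock(
                    rng, cin, width, stride=2 if bi == 0 else 1,
                    cardinality=cfg.cardinality,
                    se_reduction=cfg.se_reduction))
                cin = width
            self.stages.append(blocks)
        # encoder feature maps: stage outputs at 1/2, 1/4, 1/8, 1/16

        dch = cfg.decoder_channels
        # The deepest decoder block is unskipped; the three skips join at
        # 1/4 (stage 2), 1/2 (stage 1) and full resolution (stem), so the
        # head sees undecimated features for pixel-exact boundaries.
        self.dec1 = _DecoderBlock(rng, widths[3], dch[0])            # 1/16->1/8
        self.dec2 = _DecoderBlock(rng, dch[0], dch[1])               # 1/8->1/4
        self.dec3 = _DecoderBlock(rng, dch[1] + widths[1], dch[2])   # 1/4->1/2
        self.dec4 = _DecoderBlock(rng, dch[2] + widths[0], dch[3])   # 1/2->1/1
        self.head = Conv2d(rng, dch[3] + c, 1 + cfg.n_vessel_classes,
                           k=1, pad=0)
        # Rare-foreground initialization: start the calcium head at a low
        # background prior so the Dice gradient is not swamped by a dense
        # p~0.5 field.
        self.head.b.data[0] = -4.0

        if cfg.use_pretrained_encoder:
            if cfg.encoder_weights is None:
                raise ValueError("use_pretrained_encoder needs encoder_weights")
            self.load_encoder_weights(cfg.encoder_weights)

    # -- parameter grouping -------------------------------------------------
    def encoder_parameters(self):
        out = self.stem.parameters(prefix="stem.")
        out.update(self.stem_norm.parameters(prefix="stem_norm."))
        for i, blocks in enumerate(self.stages):
            for j, blk in enumerate(blocks):
                out.update(blk.parameters(prefix=f"stages.{i}.{j}."))
        return out

    def parameters(self, prefix=""):
        out = self.encoder_parameters()
        for name in ("dec1", "dec2", "dec3", "dec4", "head"):
            out.update(getattr(self, name).parameters(prefix=name + "."))
        return {prefix + k: v for k, v in out.items()}

    def load_encoder_weights(self, path):
        """Load externally supplied encoder weights from an ``.npz`` archive
        keyed by the names of :meth:`encoder_parameters`."""
        archive = np.load(str(path))
        params = self.encoder_parameters()
        for name, tensor in params.items():
            if name not in archive:
                raise ValueError(f"encoder weight {name!r} missing")
            if archive[name].shape != tensor.data.shape:
                raise ValueError(f"encoder weight {name!r} has wrong shape")
            tensor.data = archive[name].astype(np.float64)

    # -- forward ------------------------------------------------------------
    def forward(self, x: np.ndarray):
        """Map ``(N, 1, H, W)`` preprocessed input to probability tensors
        ``(p_calc (N,1,H,W), p_vessel (N,4,H,W))`` as autograd tensors."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("input must be (N, 1, H, W)")
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("input spatial size must be divisible by 16")
        s0 = relu(self.stem_norm(self.stem(_nn.constant(x))))
        h, feats = s0, []
        for blocks in self.stages:
            for blk in blocks:
                h = blk(h)
            feats.append(h)
        e2, e4, e8, e16 = feats
        d = self.dec1(e16)
        d = self.dec2(d)
        d = self.dec3(concat_channels([d, e4]))
        d = self.dec4(concat_channels([d, e2]))
        logits = self.head(concat_channels([d, s0]))
        p_calc = sigmoid(_slice_channels(logits, 0, 1))
        p_vessel = softmax_channels(_slice_channels(logits, 1, 5))
        return p_calc, p_vessel

    def predict_slice(self, x: np.ndarray):
        """Probabilities for one preprocessed slice (H, W) as arrays."""
        pc, pv = self.forward(x[None, None])
        return pc.data[0, 0], pv.data[0]


def _slice_channels(t, lo, hi):
    out = _nn.Tensor(t.data[:, lo:hi], requires_grad=t.requires_grad,
                     parents=(t,) if t.requires_grad else ())
    if t.requires_grad:
        def backward(g):
            full = np.zeros_like(t.data)
            full[:, lo:hi] = g
            t._accum(full)
        out._backward = backward
    return out


def build_model(cfg: ModelConfig) -> SegModel:
    """Construct the model; random init unless pretrained encoder weights
    are supplied through the config."""
    return SegModel(cfg)


def predict_volume(model: SegModel, volume: CTVolume,
                   cfg: PreprocessConfig = PreprocessConfig()
                   ) -> ProbabilityVolume:
    """Run the model slice-by-slice over an exam.

    Each slice is preprocessed independently (no inter-slice state), and the
    probability maps are resampled back to the original slice resolution so
    they align with the raw HU volume used for scoring.  Linear
    interpolation preserves the per-pixel simplex of the vessel channels.
    """
    h, w = volume.slices.shape[1:] if volume.n_slices else (0, 0)
    calc, vessel = [], []
    for sl in volume.slices:
        x, _ = preprocess_slice(sl, cfg)
        pc, pv = model.predict_slice(x)
        if pc.shape != (h, w):
            pc = resize(pc, (h, w), order=1, preserve_range=True,
                        anti_aliasing=False)
            pv = np.stack([resize(ch, (h, w), order=1, preserve_range=True,
                                  anti_aliasing=False) for ch in pv])
            pv /= pv.sum(axis=0, keepdims=True)
        calc.append(pc)
        vessel.append(pv)
    if not calc:
        return ProbabilityVolume(np.zeros((0, h, w)), np.zeros((0, 4, h, w)))
    return ProbabilityVolume(np.stack(calc), np.stack(vessel))


def save_model(model: SegModel, path) -> None:
    """Serialize weights + config to one ``.npz`` archive."""
    arrays = {k: v.data for k, v in model.parameters().items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_model(path) -> SegModel:
    archive = np.load(str(path))
    cfg_dict = json.loads(bytes(archive["__config__"]).decode())
    cfg_dict["decoder_channels"] = tuple(cfg_dict["decoder_channels"])
    cfg_dict["use_pretrained_encoder"] = False
    cfg_dict["encoder_weights"] = None
    model = SegModel(ModelConfig(**cfg_dict))
    for name, tensor in model.parameters().items():
        tensor.data = archive[name].astype(np.float64)
    return model
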