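"""ACAU-Net assembly: stem, dense encoder, DAC/RMP bottleneck, ACAU decoder.

Layout (spatial scale relative to the input):

    stem 7x7/2 ................. 1/2   -> finest skip
    maxpool 3x3/2 .............. 1/4
    dense block 1 .............. 1/4   -> skip
    transition ................. 1/8
    dense block 2 .............. 1/8   -> skip
    transition ................. 1/16
    dense block 3 .............. 1/16  -> skip
    transition ................. 1/32
    dense block 4 + DAC + RMP .. 1/32  (bottleneck)
    4 x ACAU stages ............ 1/16, 1/8, 1/4, 1/2
    head: deconv/2, ReLU, 3x3 conv, sigmoid ... 1/1

Total downsampling before the head is 32, so input sides must be divisible
by 32.  The prediction head is single-channel sigmoid, giving per-pixel
disc probabilities in [0,1].
"""

from __future__ import annotations

import io

import numpy as np

from .blocks import ACAUBlock, DAC, DenseBlock, RMP, Transition, _norm
from .config import NetworkConfig
from .grad import Tensor, nn

__all__ = ["ACAUNet", "build_network", "predict_mask"]


class ACAUNet(nn.Module):
    """The full segmentation network; see the module docstring for layout."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        bc = config.blocks
        norm = bc.norm

        stem_w = config.stem_width
        self.stem = nn.Sequential(
            nn.Conv2d(config.in_channels, stem_w, 7, stride=2, padding=3,
                      bias=False, rng=rng),
            _norm(norm, stem_w),
            nn.ReLU(),
        )
        self.pool = nn.MaxPool2d(3, stride=2, padding=1)

        # encoder: 4 dense blocks, transitions between them
        skip_channels = [stem_w]
        c = stem_w
        for i, n_layers in enumerate(bc.layers_per_block):
            block = DenseBlock(c, n_layers, bc.growth_rate, bc.bn_size, norm, rng=rng)
            setattr(self, f"enc{i}", block)
            c = block.out_channels
            if i < len(bc.layers_per_block) - 1:
                skip_channels.append(c)
                trans = Transition(c, max(1, int(c * bc.compression)), norm, rng=rng)
                setattr(self, f"trans{i}", trans)
                c = trans.out_channels

        self.dac = DAC(c, bc.dac_dilations, rng=rng)
        self.rmp = RMP(c, bc.rmp_pool_sizes, rng=rng)
        c = self.rmp.out_channels

        # decoder: coarsest skip first
        self._skip_channels = skip_channels  # [stem, enc0, enc1, enc2]
        for i, width in enumerate(config.decoder_widths):
            low_c = skip_channels[len(skip_channels) - 1 - i]
            if low_c % bc.se_reduction:
                raise ValueError(
                    f"se_reduction {bc.se_reduction} does not divide skip "
                    f"channel count {low_c} (decoder stage {i})"
                )
            stage = ACAUBlock(low_c, c, width, bc.se_reduction, bc.pk,
                              config.upsample, norm, rng=rng)
            setattr(self, f"dec{i}", stage)
            c = width

        self.head = nn.Sequential(
            nn.ConvTranspose2d(c, c, 2, stride=2, rng=rng),
            nn.ReLU(),
            nn.Conv2d(c, 1, 3, padding=1, rng=rng),
            nn.Sigmoid(),
        )

    # ------------------------------------------------------------------ forward
    def forward(self, image: Tensor | np.ndarray) -> Tensor:
        x = image if isinstance(image, Tensor) else Tensor(image)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N,{self.config.in_channels},H,W) input, got {x.shape}"
            )
        f = self.config.downsample_factor
        if x.shape[2] % f or x.shape[3] % f:
            raise ValueError(
                f"input spatial size {x.shape[2:]} not divisible by {f}"
            )
        skips = []
        h = self.stem(x)
        skips.append(h)
        h = self.pool(h)
        n_blocks = len(self.config.blocks.layers_per_block)
        for i in range(n_blocks):
            h = getattr(self, f"enc{i}")(h)
            if i < n_blocks - 1:
                skips.append(h)
                h = getattr(self, f"trans{i}")(h)
        h = self.rmp(self.dac(h))
        for i in range(len(self.config.decoder_widths)):
            low = skips[len(skips) - 1 - i]
            h = getattr(self, f"dec{i}")(low, h)
        return self.head(h)

    # ------------------------------------------------------------------ misc
    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def summary(self) -> str:
        """Plain-text architecture summary."""
        bc = self.config.blocks
        buf = io.StringIO()
        print("ACAU-Net", file=buf)
        print(f"  input: {self.config.in_channels} x {self.config.input_size}"
              f" x {self.config.input_size}", file=buf)
        print(f"  stem: 7x7/2 -> {self.config.stem_width} ch; 3x3/2 max-pool "
              "(total downsampling 32)", file=buf)
        for i, n_layers in enumerate(bc.layers_per_block):
            block: DenseBlock = getattr(self, f"enc{i}")
            print(f"  encoder stage {i + 1}: dense block x{n_layers} "
                  f"(growth {bc.growth_rate}) -> {block.out_channels} ch", file=buf)
        print(f"  bottleneck: DAC dilations {list(bc.dac_dilations)}; "
              f"RMP pools {list(bc.rmp_pool_sizes)} -> {self.rmp.out_channels} ch",
              file=buf)
        for i, width in enumerate(self.config.decoder_widths):
            print(f"  decoder stage {i + 1}: ACAU (pk={bc.pk}, r={bc.se_reduction})"
                  f" -> {width} ch", file=buf)
        print("  head: deconv/2, ReLU, 3x3 conv, sigmoid -> 1 ch", file=buf)
        print(f"  parameters: {self.parameter_count()}", file=buf)
        return buf.getvalue()

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))


def build_network(config: NetworkConfig, seed: int = 0) -> ACAUNet:
    """Construct an :class:`ACAUNet`; identical (config, seed) pairs yield
    identical parameter vectors.  If ``config.pretrained_encoder`` names a
    ``.npz`` state dict, matching encoder entries are loaded over the random
    initialisation."""
    net = ACAUNet(config, seed=seed)
    if config.pretrained_encoder:
        with np.load(config.pretrained_encoder) as data:
            own = dict(net.named_parameters())
            for key in data.files:
                if key in own and own[key].shape == data[key].shape:
                    own[key].data = data[key].astype(np.float32).copy()
    return net


def predict_mask(probabilities: Tensor | np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map to a binary mask; ties go to foreground."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0,1)")
    p = probabilities.data if isinstance(probabilities, Tensor) else np.asarray(probabilities)
    return (p >= threshold).astype(np.uint8)
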