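"""Rotation-invariant multi-depth CNN feature pooling.

Each patch is expanded into its 8 dihedral variations (4 rotations of the
original and 4 rotations of the horizontal flip).  A backbone extractor
returns post-activation feature maps at a fixed set of tap points; each map
is reduced to per-channel spatial means (global average pooling) and the
taps are concatenated into one vector per variation.  The 8 vectors are
fused per dimension with p-norm pooling,

    f_pool = ((1/N) * sum_i f_i^p) ** (1/p),   p = 3 by default,

which is permutation-invariant in its inputs, so the fused vector is
invariant under any dihedral transform of the patch.

The three named backbone specs (vgg16, resnet50, inceptionv3) describe the
tap layout of the ImageNet architectures the features are designed around;
their pooled dimensionalities are 4224, 15168 and 10048.  Extractors are
pluggable callables — the package ships a deterministic random-convolution
:class:`FixtureExtractor` so every code path runs without pretrained
weights; adapters for real backbones can implement the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .errors import ContractViolationError, InvalidInputError, InvalidParameterError

#: Fixed order of the 8 dihedral variations: rotations of the original,
#: then rotations of the horizontally flipped image.
VARIATION_ORDER = ("r0", "r90", "r180", "r270", "f0", "f90", "f180", "f270")


@dataclass(frozen=True)
class BackboneSpec:
    """Tap layout of a feature-extraction backbone."""

    name: str
    tap_points: tuple[tuple[str, int], ...]

    @property
    def total_dim(self) -> int:
        return sum(c for _, c in self.tap_points)


def _vgg16_spec() -> BackboneSpec:
    # All 13 post-ReLU convolution outputs.
    channels = (64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512)
    return BackboneSpec(
        "vgg16", tuple((f"conv{i + 1}", c) for i, c in enumerate(channels))
    )


def _resnet50_spec() -> BackboneSpec:
    # Stem output plus the 16 post-residual-addition block outputs.
    channels = (64,) + (256,) * 3 + (512,) * 4 + (1024,) * 6 + (2048,) * 3
    return BackboneSpec(
        "resnet50", tuple((f"block{i}", c) for i, c in enumerate(channels))
    )


def _inceptionv3_spec() -> BackboneSpec:
    # The 11 inception-module concatenation outputs.
    channels = (256, 288, 288, 768, 768, 768, 768, 768, 1280, 2048, 2048)
    return BackboneSpec(
        "inceptionv3", tuple((f"mixed{i}", c) for i, c in enumerate(channels))
    )


def _fixture_spec() -> BackboneSpec:
    return BackboneSpec("fixture", (("conv1", 8), ("conv2", 16), ("conv3", 32)))


BACKBONE_SPECS: dict[str, BackboneSpec] = {
    s.name: s
    for s in (_vgg16_spec(), _resnet50_spec(), _inceptionv3_spec(), _fixture_spec())
}


def get_backbone_spec(name: str) -> BackboneSpec:
    try:
        return BACKBONE_SPECS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown backbone {name!r}; known: {sorted(BACKBONE_SPECS)}"
        ) from None


@dataclass(frozen=True)
class PoolingConfig:
    """p-norm pooling settings: norm order and number of dihedral variations."""

    p: float = 3.0
    n_variations: int = 8

    def __post_init__(self):
        if self.p < 1:
            raise InvalidParameterError(f"pooling norm p must be >= 1, got {self.p}")
        if self.n_variations not in (1, 4, 8):
            raise InvalidParameterError(
                f"n_variations must be 1, 4 or 8, got {self.n_variations}"
            )


def generate_variations(image: np.ndarray) -> list[np.ndarray]:
    """Return the 8 dihedral variations of a square patch.

    Order is ``VARIATION_ORDER``: rotations by 0/90/180/270 degrees of the
    original, then of the horizontally flipped image.  Pixel values are
    untouched.
    """
    image = np.asarray(image)
    if image.ndim < 2 or image.shape[0] != image.shape[1]:
        raise InvalidInputError(
            f"variations require a square image, got shape {image.shape}"
        )
    out = [np.rot90(image, k).copy() for k in range(4)]
    flipped = np.fliplr(image)
    out += [np.rot90(flipped, k).copy() for k in range(4)]
    return out


def extract_features(image, extractor, spec: BackboneSpec) -> np.ndarray:
    """Globally average-pool the extractor's tap activations and concatenate.

    ``extractor(image)`` must return one (H, W, C) post-activation map per
    tap point, in spec order; a channel-count mismatch is a contract
    violation by the extractor.
    """
    maps = extractor(image)
    if len(maps) != len(spec.tap_points):
        raise ContractViolationError(
            f"extractor returned {len(maps)} maps, spec {spec.name} "
            f"defines {len(spec.tap_points)} taps"
        )
    parts = []
    for m, (tap, channels) in zip(maps, spec.tap_points):
        m = np.asarray(m, dtype=np.float64)
        if m.ndim != 3 or m.shape[2] != channels:
            raise ContractViolationError(
                f"tap {tap!r}: expected (H, W, {channels}) map, got {m.shape}"
            )
        parts.append(m.mean(axis=(0, 1)))
    vec = np.concatenate(parts)
    if not np.all(np.isfinite(vec)):
        raise ContractViolationError("extractor produced non-finite activations")
    return vec


def pnorm_pool(vectors, p: float = 3.0) -> np.ndarray:
    """Fuse feature vectors per dimension: ((1/N) sum f_i^p)^(1/p).

    Requires nonnegative entries (features are post-activation).  The
    per-dimension values are sorted before accumulation so the result is
    bit-identical under any permutation of the inputs.
    """
    if len(vectors) == 0:
        raise InvalidInputError("cannot pool an empty list of vectors")
    if p < 1:
        raise InvalidParameterError(f"pooling norm p must be >= 1, got {p}")
    stack = np.asarray(vectors, dtype=np.float64)
    if stack.ndim != 2:
        raise InvalidInputError("vectors must share one length")
    if np.any(stack < 0):
        raise InvalidInputError("p-norm pooling requires nonnegative features")
    stack = np.sort(stack, axis=0)  # canonical summation order
    return (np.power(stack, p).mean(axis=0)) ** (1.0 / p)


def featurize_patch(
    image,
    extractor,
    spec: BackboneSpec,
    pooling: PoolingConfig = PoolingConfig(),
) -> np.ndarray:
    """Full patch featurization: variations -> tap GAP features -> p-norm pool.

    By dihedral-group closure the variation *set* of any rotated/flipped
    copy of the patch equals that of the patch itself, and pooling is
    permutation-invariant, so the output is identical for all 8 transforms
    of the input.
    """
    variations = generate_variations(image)[: pooling.n_variations]
    vectors = [extract_features(v, extractor, spec) for v in variations]
    if len(vectors) == 1:
        return vectors[0]
    return pnorm_pool(vectors, pooling.p)


class FixtureExtractor:
    """Deterministic random-convolution backbone for the ``fixture`` spec.

    A three-stage stack — 1x1 channel mixing, then two 3x3 convolutions
    with reflect padding, each followed by ReLU and 2x mean pooling — with
    weights drawn once from a seeded generator.  It has no trained
    semantics, but its global-average-pooled taps respond to color and
    local texture statistics, which is what the downstream models consume.
    Input patches are resized to ``input_size`` first, so cost is
    independent of patch size.
    """

    spec = BACKBONE_SPECS["fixture"]

    def __init__(self, seed: int = 0, input_size: int = 32):
        rng = np.random.default_rng(seed)
        self.input_size = int(input_size)
        scale = 0.6
        self.w1 = rng.normal(0, scale, size=(3, 8))
        self.b1 = rng.normal(0, 0.1, size=8)
        self.w2 = rng.normal(0, scale / 3.0, size=(3, 3, 8, 16))
        self.b2 = rng.normal(0, 0.1, size=16)
        self.w3 = rng.normal(0, scale / 3.0, size=(3, 3, 16, 32))
        self.b3 = rng.normal(0, 0.1, size=32)

    @staticmethod
    def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        pad = np.pad(x, ((1, 1), (1, 1), (0, 0)), mode="reflect")
        win = np.lib.stride_tricks.sliding_window_view(pad, (3, 3), axis=(0, 1))
        # win: (H, W, Cin, 3, 3); w: (3, 3, Cin, Cout)
        return np.einsum("hwcij,ijco->hwo", win, w, optimize=True) + b

    @staticmethod
    def _pool2(x: np.ndarray) -> np.ndarray:
        h, w, c = x.shape
        return x[: h - h % 2, : w - w % 2].reshape(h // 2, 2, w // 2, 2, c).mean(
            axis=(1, 3)
        )

    def __call__(self, image: np.ndarray) -> list[np.ndarray]:
        x = np.asarray(image, dtype=np.float64)
        if x.ndim != 3 or x.shape[2] != 3:
            raise InvalidInputError(f"expected RGB image, got shape {x.shape}")
        if x.max() > 1.5:
            x = x / 255.0
        if x.shape[:2] != (self.input_size, self.input_size):
            x = resize(
                x,
                (self.input_size, self.input_size),
                order=1,
                preserve_range=True,
                anti_aliasing=True,
            )
        a1 = np.maximum(x @ self.w1 + self.b1, 0.0)
        a2 = np.maximum(self._conv3x3(self._pool2(a1), self.w2, self.b2), 0.0)
        a3 = np.maximum(self._conv3x3(self._pool2(a2), self.w3, self.b3), 0.0)
        return [a1, a2, a3]
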