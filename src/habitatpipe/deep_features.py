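"""Deterministic 3D residual-network descriptor of the tumor ROI.

A ResNet-18-style volumetric network (stem convolution, four residual stages
of two basic blocks each with stride-2 downsampling, global average pooling)
emitting a fixed 512-dimensional feature vector.  The forward pass is pure
numpy: convolutions are im2col matrix products, so the extractor is
bit-reproducible on a platform and needs no deep-learning runtime.

Weights are drawn once from a He (variance-scaled) initializer under a fixed
seed (``weights_mode="fixed_random"`` — an untrained random-projection
descriptor, the documented default since no trained weights are published for
this architecture), or loaded from an ``.npz`` file
(``weights_mode="file"``).  Residual sums are rescaled by 1/sqrt(2) to keep
activation variance stable through depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging_io import CTVolume, Mask

__all__ = [
    "ExtractorConfig",
    "ResNet3DExtractor",
    "preprocess_roi",
    "build_extractor",
    "extract_deep_features",
    "deep_feature_names",
]

N_DEEP_FEATURES = 512


@dataclass
class ExtractorConfig:
    input_shape: tuple[int, int, int] = (64, 64, 64)
    stage_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    blocks_per_stage: tuple[int, int, int, int] = (2, 2, 2, 2)
    init_seed: int = 17
    weights_mode: str = "fixed_random"  # or "file"
    weights_file: str | None = None

    def __post_init__(self) -> None:
        if self.stage_widths[-1] != N_DEEP_FEATURES:
            raise ValueError("final stage width must be 512")
        if self.weights_mode not in ("fixed_random", "file"):
            raise ValueError("weights_mode must be 'fixed_random' or 'file'")
        if self.weights_mode == "file" and not self.weights_file:
            raise ValueError("weights_mode='file' requires weights_file")


def preprocess_roi(
    volume: CTVolume, mask: Mask, out_shape: tuple[int, int, int] = (64, 64, 64)
) -> np.ndarray:
    """Crop the mask's bounding box with a 10% margin, zero the background
    outside the mask, rescale intensities to [0, 1] (by ROI min/max) and
    trilinearly resize to ``out_shape``.

    The crop makes the tensor invariant to translations of the tumor within
    the scan.
    """
    m = mask.data > 0
    if not m.any():
        raise ValueError("empty mask")
    idx = np.where(m)
    lo, hi = [], []
    for c, n in zip(idx, m.shape):
        a, b = int(c.min()), int(c.max()) + 1
        margin = max(1, int(round(0.1 * (b - a))))
        lo.append(max(0, a - margin))
        hi.append(min(n, b + margin))
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    roi = volume.data[box] * m[box]
    rmin, rmax = roi.min(), roi.max()
    roi = (roi - rmin) / (rmax - rmin) if rmax > rmin else np.zeros_like(roi)
    zoom = [o / s for o, s in zip(out_shape, roi.shape)]
    out = ndimage.zoom(roi, zoom, order=1, mode="nearest")
    # zoom rounding can be off by one voxel; crop/pad to exact shape
    out = out[: out_shape[0], : out_shape[1], : out_shape[2]]
    pad = [(0, t - s) for t, s in zip(out_shape, out.shape)]
    if any(p[1] for p in pad):
        out = np.pad(out, pad, mode="edge")
    return out.astype(np.float64)


def _he_init(rng: np.random.Generator, c_out: int, c_in: int, k: int) -> np.ndarray:
    fan_in = c_in * k**3
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k))


def _conv3d(x: np.ndarray, w: np.ndarray, stride: int = 1) -> np.ndarray:
    """'Same'-padded 3D convolution; x is (C, D, H, W), w is (Cout, Cin, k, k, k)."""
    c_out, c_in, k, _, _ = w.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    win = win[:, ::stride, ::stride, ::stride]  # (C, D', H', W', k, k, k)
    _, d, h, wd = win.shape[:4]
    cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(d * h * wd, c_in * k**3)
    out = cols @ w.reshape(c_out, -1).T
    return out.T.reshape(c_out, d, h, wd)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    c, d, h, w = x.shape
    d2, h2, w2 = d // 2 * 2, h // 2 * 2, w // 2 * 2
    v = x[:, :d2, :h2, :w2].reshape(c, d2 // 2, 2, h2 // 2, 2, w2 // 2, 2)
    return v.max(axis=(2, 4, 6))


class ResNet3DExtractor:
    """Fixed-weight volumetric residual network; call :meth:`features`."""

    def __init__(self, config: ExtractorConfig):
        self.config = config
        if config.weights_mode == "file":
            archive = np.load(config.weights_file)
            self.weights = {k: archive[k] for k in archive.files}
        else:
            self.weights = self._init_weights()

    def _init_weights(self) -> dict[str, np.ndarray]:
        cfg = self.config
        rng = np.random.default_rng(cfg.init_seed)
        w: dict[str, np.ndarray] = {"stem": _he_init(rng, cfg.stage_widths[0], 1, 3)}
        c_in = cfg.stage_widths[0]
        for s, (width, n_blocks) in enumerate(zip(cfg.stage_widths, cfg.blocks_per_stage)):
            for b in range(n_blocks):
                first = b == 0
                w[f"s{s}b{b}c1"] = _he_init(rng, width, c_in if first else width, 3)
                w[f"s{s}b{b}c2"] = _he_init(rng, width, width, 3)
                if first and (c_in != width or s > 0):
                    w[f"s{s}b{b}proj"] = _he_init(rng, width, c_in, 1)
                if first:
                    c_in = width
        return w

    def features(self, tensor: np.ndarray) -> np.ndarray:
        """512-vector from a (D, H, W) ROI tensor matching ``input_shape``."""
        cfg = self.config
        if tensor.shape != tuple(cfg.input_shape):
            raise ValueError(
                f"input shape {tensor.shape} != configured {tuple(cfg.input_shape)}"
            )
        w = self.weights
        x = tensor[None].astype(np.float64)
        x = np.maximum(_conv3d(x, w["stem"], stride=2), 0.0)
        x = _maxpool2(x)
        for s in range(len(cfg.stage_widths)):
            for b in range(cfg.blocks_per_stage[s]):
                stride = 2 if (s > 0 and b == 0) else 1
                h = np.maximum(_conv3d(x, w[f"s{s}b{b}c1"], stride=stride), 0.0)
                h = _conv3d(x=h, w=w[f"s{s}b{b}c2"])
                if f"s{s}b{b}proj" in w:
                    skip = _conv3d(x, w[f"s{s}b{b}proj"], stride=stride)
                else:
                    skip = x
                x = np.maximum((h + skip) / np.sqrt(2.0), 0.0)
        return x.mean(axis=(1, 2, 3))  # global average pool -> (512,)


def build_extractor(config: ExtractorConfig | None = None) -> ResNet3DExtractor:
    return ResNet3DExtractor(config or ExtractorConfig())


def extract_deep_features(extractor: ResNet3DExtractor, tensor: np.ndarray) -> dict[str, float]:
    """Named 512-dimensional deep descriptor, ``deep_000`` .. ``deep_511``."""
    vec = extractor.features(tensor)
    if vec.shape != (N_DEEP_FEATURES,) or not np.all(np.isfinite(vec)):
        raise RuntimeError("extractor produced an invalid feature vector")
    return {f"deep_{i:03d}": float(v) for i, v in enumerate(vec)}


def deep_feature_names() -> list[str]:
    return [f"deep_{i:03d}" for i in range(N_DEEP_FEATURES)]
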