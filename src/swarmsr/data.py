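"""Synthetic HR image corpora and HR/LR pair machinery.

Procedural stand-in for a small natural-image training set: a mix of
band-limited noise textures, linear gradients, and anti-aliased geometric
shapes, all with intensities in [0, 1].  LR counterparts are produced by
separable bicubic resampling (two-lobe Keys kernel, a = −0.5) with an
anti-alias pre-filter when decimating, the standard degradation model of
the super-resolution training literature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = [
    "CorpusSpec",
    "ImagePair",
    "TrainingBatch",
    "generate_corpus",
    "bicubic_kernel",
    "bicubic_resample",
    "make_pair",
    "extract_patch_pairs",
    "read_png",
    "write_png",
]


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for a deterministic procedural HR corpus."""

    n_images: int = 16
    size: int = 64
    #: proportions of content types; normalized internally
    mix: dict = field(default_factory=lambda: {
        "bandlimited": 0.4375, "gradient": 0.125, "shapes": 0.4375})
    noise_level: float = 0.01
    #: spectral cutoff of band-limited content, in HR cycles/pixel; the
    #: default sits at the LR Nyquist frequency for scale 2, so textures
    #: carry energy a plain interpolator cannot restore sharply
    cutoff: float = 0.25
    seed: int = 0


@dataclass(frozen=True)
class ImagePair:
    """Aligned HR/LR raster pair; HR dims are exactly scale × LR dims."""

    hr: np.ndarray
    lr: np.ndarray
    scale_factor: int

    def __post_init__(self):
        sh, sl = self.hr.shape, self.lr.shape
        if sh != (sl[0] * self.scale_factor, sl[1] * self.scale_factor):
            raise ValueError("HR dims must equal scale × LR dims")


@dataclass(frozen=True)
class TrainingBatch:
    """Stacked aligned patches: lr (N,1,h,w) and hr (N,1,s·h,s·w)."""

    lr: np.ndarray
    hr: np.ndarray
    scale_factor: int
    #: (row, col) LR offsets each patch was cut at
    offsets: np.ndarray

    def __len__(self):
        return self.lr.shape[0]


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def _bandlimited(size, rng, cutoff=0.25):
    """Gaussian noise low-passed in the Fourier domain below ``cutoff``."""
    spec = np.fft.fft2(rng.standard_normal((size, size)))
    f = np.fft.fftfreq(size)
    radius = np.hypot(*np.meshgrid(f, f, indexing="ij"))
    img = np.real(np.fft.ifft2(spec * (radius <= cutoff)))
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) if hi > lo else np.full_like(img, 0.5)


def _gradient(size, rng):
    theta = rng.uniform(0, 2 * np.pi)
    r, c = np.meshgrid(np.linspace(0, 1, size), np.linspace(0, 1, size),
                       indexing="ij")
    ramp = np.cos(theta) * r + np.sin(theta) * c
    lo, hi = ramp.min(), ramp.max()
    return (ramp - lo) / (hi - lo)


def _shapes(size, rng, n_shapes=12, supersample=4):
    """Random ellipses and rectangles, anti-aliased by supersampled rendering."""
    big = size * supersample
    canvas = np.full((big, big), rng.uniform(0.2, 0.8))
    r, c = np.meshgrid(np.arange(big), np.arange(big), indexing="ij")
    for _ in range(n_shapes):
        value = rng.uniform(0, 1)
        cy, cx = rng.uniform(0, big, 2)
        if rng.uniform() < 0.5:
            ay, ax = rng.uniform(0.02, 0.15, 2) * big
            mask = ((r - cy) / ay) ** 2 + ((c - cx) / ax) ** 2 <= 1.0
        else:
            hy, hx = rng.uniform(0.02, 0.15, 2) * big
            mask = (np.abs(r - cy) <= hy) & (np.abs(c - cx) <= hx)
        canvas[mask] = value
    # box-average back to target size: anti-aliased edges
    return canvas.reshape(size, supersample, size, supersample).mean(axis=(1, 3))


_CONTENT = {"bandlimited": _bandlimited, "gradient": _gradient,
            "shapes": _shapes}


def generate_corpus(spec: CorpusSpec) -> list[np.ndarray]:
    """Deterministic list of HR images in [0, 1] honoring the content mix."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([spec.mix.get(k, 0.0) for k in _CONTENT])
    if weights.sum() <= 0:
        raise ValueError("content mix must have positive total weight")
    counts = np.floor(weights / weights.sum() * spec.n_images).astype(int)
    # distribute the remainder in mix order
    for i in range(spec.n_images - counts.sum()):
        counts[i % len(counts)] += 1
    images = []
    for kind, cnt in zip(_CONTENT, counts):
        for _ in range(cnt):
            if kind == "bandlimited":
                img = _bandlimited(spec.size, rng, spec.cutoff)
            else:
                img = _CONTENT[kind](spec.size, rng)
            if spec.noise_level > 0:
                img = img + rng.normal(0, spec.noise_level, img.shape)
            images.append(np.clip(img, 0.0, 1.0))
    return images


# ---------------------------------------------------------------------------
# bicubic resampling
# ---------------------------------------------------------------------------

def bicubic_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Two-lobe Keys cubic kernel with parameter ``a`` (support [-2, 2])."""
    t = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    near = t <= 1
    far = (t > 1) & (t < 2)
    out[near] = (a + 2) * t[near] ** 3 - (a + 3) * t[near] ** 2 + 1
    out[far] = a * t[far] ** 3 - 5 * a * t[far] ** 2 + 8 * a * t[far] - 4 * a
    return out


def _resample_matrix(n_in: int, n_out: int, ratio: float) -> np.ndarray:
    """Row-stochastic 1-D resampling matrix with center-aligned grids.

    For decimation (ratio > 1) the kernel is stretched by the ratio — the
    anti-alias pre-filter folded into the resampling weights.  Out-of-range
    taps are clamped to the edge (replicate padding), and each row is
    normalized so constants are reproduced exactly.
    """
    scale = max(ratio, 1.0)
    support = 2.0 * scale
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        center = (i + 0.5) * ratio - 0.5
        lo = int(np.floor(center - support)) + 1
        hi = int(np.ceil(center + support))
        taps = np.arange(lo, hi)
        weights = bicubic_kernel((taps - center) / scale)
        np.add.at(w[i], np.clip(taps, 0, n_in - 1), weights)
        w[i] /= w[i].sum()
    return w


def bicubic_resample(image: np.ndarray, factor: int,
                     direction: str = "down") -> np.ndarray:
    """Separable bicubic down- or upsampling by an integer factor.

    Downsampling requires dimensions divisible by the factor (crop first);
    a constant image round-trips exactly, and band-limited content survives
    a down/up round trip with high fidelity.
    """
    if factor not in (2, 3, 4):
        raise ValueError("factor must be 2, 3, or 4")
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if direction == "down":
        if h % factor or w % factor:
            raise ValueError("image dims must be divisible by the factor")
        out_h, out_w, ratio = h // factor, w // factor, float(factor)
    elif direction == "up":
        out_h, out_w, ratio = h * factor, w * factor, 1.0 / factor
    else:
        raise ValueError("direction must be 'down' or 'up'")
    if min(h, w) < 4:
        raise ValueError("image smaller than the kernel support")
    rows = _resample_matrix(h, out_h, ratio)
    cols = _resample_matrix(w, out_w, ratio)
    return rows @ image @ cols.T


def make_pair(hr: np.ndarray, scale_factor: int) -> ImagePair:
    """Crop HR to a multiple of the scale and attach its bicubic LR."""
    hr = np.asarray(hr, dtype=float)
    h = hr.shape[0] - hr.shape[0] % scale_factor
    w = hr.shape[1] - hr.shape[1] % scale_factor
    hr = hr[:h, :w]
    lr = bicubic_resample(hr, scale_factor, "down")
    return ImagePair(hr=hr, lr=lr, scale_factor=scale_factor)


def extract_patch_pairs(pair: ImagePair, lr_patch_size: int, stride: int,
                        seed: int | None = None) -> TrainingBatch:
    """Aligned LR/HR patches on a regular grid, optionally shuffled.

    The HR patch is the scale× footprint of its LR patch, cut at scale× the
    LR offset, so the stacks stay pixel-aligned.
    """
    s = pair.scale_factor
    lh, lw = pair.lr.shape
    if lr_patch_size > min(lh, lw):
        raise ValueError("image too small for the requested patch size")
    offsets = [(r, c)
               for r in range(0, lh - lr_patch_size + 1, stride)
               for c in range(0, lw - lr_patch_size + 1, stride)]
    if seed is not None:
        np.random.default_rng(seed).shuffle(offsets)
    lr_stack, hr_stack = [], []
    for r, c in offsets:
        lr_stack.append(pair.lr[r:r + lr_patch_size, c:c + lr_patch_size])
        hr_stack.append(pair.hr[s * r:s * (r + lr_patch_size),
                                s * c:s * (c + lr_patch_size)])
    return TrainingBatch(lr=np.asarray(lr_stack)[:, None],
                         hr=np.asarray(hr_stack)[:, None],
                         scale_factor=s, offsets=np.asarray(offsets))


def concat_batches(batches: list[TrainingBatch]) -> TrainingBatch:
    """Stack patch batches of equal scale and patch geometry."""
    s = batches[0].scale_factor
    return TrainingBatch(
        lr=np.concatenate([b.lr for b in batches]),
        hr=np.concatenate([b.hr for b in batches]),
        scale_factor=s,
        offsets=np.concatenate([b.offsets for b in batches]))


# ---------------------------------------------------------------------------
# PNG I/O ([0,1] float convention, 8-bit on disk, round-half-even)
# ---------------------------------------------------------------------------

def read_png(path) -> np.ndarray:
    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:  # luminance of RGB(A)
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    return img / 255.0


def write_png(path, image: np.ndarray) -> None:
    q = np.rint(np.clip(image, 0.0, 1.0) * 255.0).astype(np.uint8)
    iio.imwrite(path, q)


def write_manifest(path, spec: CorpusSpec, files: list[str]) -> None:
    payload = {"n_images": spec.n_images, "size": spec.size,
               "mix": spec.mix, "noise_level": spec.noise_level,
               "seed": spec.seed, "files": files}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
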