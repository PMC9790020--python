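"""Seeded synthetic images and masks with controllable complexity.

Three generators stand in for the kinds of data a segmentation study
meets, so every stage of the toolkit is testable without downloads:

* ``make_blob_mask`` — unions of filled ellipses: compact, low-complexity
  foregrounds in the spirit of optic-disc, lung or lesion annotations.
* ``make_vessel_mask`` — a recursive branching tree of strokes of
  decreasing width: thin, high-complexity foregrounds in the spirit of
  retinal-vessel annotations.  Strokes are rasterized on the integer grid
  (no anti-aliasing) so masks are strictly binary.
* ``make_spectral_image`` — isotropic noise with power spectrum ~ f^-beta,
  giving direct control over spectral complexity: beta = 0 is white noise
  (median frequency near 0.25), larger beta concentrates power at low
  frequencies and drives MNF/MDF down.

All generators are driven by :class:`numpy.random.Generator` (PCG64) with
explicit integer seeds; identical specs produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skimage import draw as _skdraw

from .errors import ValidationError

__all__ = [
    "FixtureSpec",
    "make_blob_mask",
    "make_vessel_mask",
    "make_spectral_image",
    "make_fixture",
    "make_mask_battery",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic fixture."""

    kind: str  # 'blob' | 'vessel' | 'spectral'
    size: tuple[int, int] = (256, 256)  # (width, height)
    seed: int = 0
    parameters: dict[str, Any] = field(default_factory=dict)


def make_fixture(spec: FixtureSpec) -> np.ndarray:
    """Dispatch a :class:`FixtureSpec` to the matching generator."""
    makers = {
        "blob": make_blob_mask,
        "vessel": make_vessel_mask,
        "spectral": make_spectral_image,
    }
    try:
        maker = makers[spec.kind]
    except KeyError:
        raise ValidationError(
            f"unknown fixture kind {spec.kind!r}; choose from {sorted(makers)}"
        ) from None
    return maker(size=spec.size, seed=spec.seed, **spec.parameters)


def make_blob_mask(
    size: tuple[int, int] = (256, 256),
    n_blobs: int = 3,
    radius: float = 32.0,
    seed: int = 0,
    disjoint: bool = True,
    radius_jitter: float = 0.25,
    max_tries: int = 2000,
) -> np.ndarray:
    """Union of filled ellipses at seeded random positions.

    Ellipse semi-axes vary uniformly within ``radius * (1 +/- radius_jitter)``
    (``radius_jitter=0`` gives congruent disks).  With ``disjoint=True``
    blobs are placed without touching; an infeasible packing raises a
    validation error.
    """
    w, h = size
    if radius < 2:
        raise ValidationError(f"radius must be >= 2, got {radius}")
    if not 0 <= radius_jitter < 1:
        raise ValidationError(f"radius_jitter must be in [0, 1), got {radius_jitter}")
    if 2 * radius * (1 + radius_jitter) >= min(w, h):
        raise ValidationError(f"radius {radius} does not fit in frame {size}")
    rng = np.random.default_rng(seed)
    mask = np.zeros((h, w), dtype=np.uint8)
    placed: list[tuple[float, float, float]] = []  # (row, col, bounding radius)
    for _ in range(n_blobs):
        for attempt in range(max_tries):
            ry = radius * rng.uniform(1 - radius_jitter, 1 + radius_jitter)
            rx = radius * rng.uniform(1 - radius_jitter, 1 + radius_jitter)
            bound = max(rx, ry)
            r = rng.uniform(bound + 1, h - bound - 1)
            c = rng.uniform(bound + 1, w - bound - 1)
            if disjoint and any(
                np.hypot(r - pr, c - pc) <= bound + pb + 2 for pr, pc, pb in placed
            ):
                continue
            rr, cc = _skdraw.ellipse(r, c, ry, rx, shape=mask.shape)
            mask[rr, cc] = 1
            placed.append((r, c, bound))
            break
        else:
            raise ValidationError(
                f"could not place {n_blobs} disjoint blobs of radius {radius} "
                f"in frame {size} after {max_tries} tries"
            )
    return mask


def _stroke(mask: np.ndarray, p: np.ndarray, q: np.ndarray, width: int) -> None:
    """Rasterize a straight stroke of the given integer width onto *mask*."""
    if width <= 1:
        rr, cc = _skdraw.line(*np.round(p).astype(int), *np.round(q).astype(int))
        inside = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
        mask[rr[inside], cc[inside]] = 1
        return
    d = q - p
    norm = np.hypot(*d)
    if norm == 0:
        return
    n = np.array([-d[1], d[0]]) / norm * (width / 2.0)
    corners = np.array([p + n, q + n, q - n, p - n])
    rr, cc = _skdraw.polygon(corners[:, 0], corners[:, 1], shape=mask.shape)
    mask[rr, cc] = 1
    # round the joint so consecutive segments connect cleanly
    for end in (p, q):
        rr, cc = _skdraw.disk(end, max(width / 2.0, 1.0), shape=mask.shape)
        mask[rr, cc] = 1


def make_vessel_mask(
    size: tuple[int, int] = (256, 256),
    depth: int = 6,
    width: int = 3,
    seed: int = 0,
    n_roots: int = 2,
) -> np.ndarray:
    """Recursive branching tree of strokes of decreasing width.

    Each root starts at a random border point heading inward; at every
    level the branch takes a jittered step, then splits in two with
    diverging headings, and the stroke width shrinks toward 1 pixel.
    """
    w, h = size
    if width < 1:
        raise ValidationError(f"width must be >= 1, got {width}")
    if depth < 1:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    mask = np.zeros((h, w), dtype=np.uint8)
    step = 0.16 * min(w, h)

    def grow(pos: np.ndarray, angle: float, level: int, wd: float) -> None:
        if level <= 0:
            return
        length = step * rng.uniform(0.7, 1.3) * (0.97**level)
        nxt = pos + length * np.array([np.sin(angle), np.cos(angle)])
        nxt = np.clip(nxt, 0, [h - 1, w - 1])
        _stroke(mask, pos, nxt, max(1, int(round(wd))))
        spread = rng.uniform(0.35, 0.75)
        child_w = max(1.0, wd * 0.8)
        grow(nxt, angle - spread + rng.normal(0, 0.08), level - 1, child_w)
        grow(nxt, angle + spread + rng.normal(0, 0.08), level - 1, child_w)

    for _ in range(n_roots):
        side = rng.integers(4)
        t = rng.uniform(0.2, 0.8)
        if side == 0:  # bottom, heading up
            pos, angle = np.array([h - 1.0, t * w]), np.pi
        elif side == 1:  # top, heading down
            pos, angle = np.array([0.0, t * w]), 0.0
        elif side == 2:  # left, heading right
            pos, angle = np.array([t * h, 0.0]), np.pi / 2
        else:  # right, heading left
            pos, angle = np.array([t * h, w - 1.0]), -np.pi / 2
        grow(pos, angle + rng.normal(0, 0.15), depth, float(width))

    if mask.sum() == 0:  # cannot happen with depth >= 1, but keep the contract
        raise ValidationError("vessel generator produced an empty mask")
    return mask


def make_spectral_image(
    size: tuple[int, int] = (256, 256),
    beta: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Seeded noise with isotropic power spectrum ~ f^-beta, scaled to [0, 255].

    beta = 0 reproduces white noise; larger beta shifts power toward low
    frequencies (smoother, lower-MDF textures).
    """
    if beta < 0:
        raise ValidationError(f"beta must be >= 0, got {beta}")
    w, h = size
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((h, w))
    if beta == 0:
        img = white
    else:
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.fftfreq(w)[None, :]
        radius = np.hypot(fy, fx)
        shaping = np.zeros_like(radius)
        nonzero = radius > 0
        shaping[nonzero] = radius[nonzero] ** (-beta / 2.0)
        img = np.real(np.fft.ifft2(np.fft.fft2(white) * shaping))
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) * 255.0


def make_mask_battery(
    seed: int = 0,
    size: tuple[int, int] = (256, 256),
    n_per_set: int = 8,
) -> dict[str, list[np.ndarray]]:
    """Six synthetic mask datasets spanning low to high shape complexity.

    Three blob families (single large, a few medium, many small) and three
    vessel families (thick/shallow through thin/deep trees).  Per-set seeds
    are spawned from *seed* so the battery is reproducible as a whole.
    """
    configs: list[tuple[str, FixtureSpec]] = []
    for name, kind, params in [
        ("blob_single", "blob", {"n_blobs": 1, "radius": 48.0}),
        ("blob_few", "blob", {"n_blobs": 3, "radius": 28.0}),
        ("blob_many", "blob", {"n_blobs": 6, "radius": 16.0}),
        ("vessel_thick", "vessel", {"depth": 5, "width": 4}),
        ("vessel_medium", "vessel", {"depth": 6, "width": 2}),
        ("vessel_thin", "vessel", {"depth": 7, "width": 1}),
    ]:
        configs.append((name, FixtureSpec(kind=kind, size=size, parameters=params)))
    children = np.random.SeedSequence(seed).spawn(len(configs))
    battery: dict[str, list[np.ndarray]] = {}
    for (name, spec), child in zip(configs, children):
        seeds = child.generate_state(n_per_set) % (2**31)
        battery[name] = [
            make_fixture(FixtureSpec(spec.kind, spec.size, int(s), spec.parameters))
            for s in seeds
        ]
    return battery
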