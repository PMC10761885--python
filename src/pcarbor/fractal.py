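"""Box-counting (Sierpinski-triangle method) fractal dimension.

The morphology's dendritic arbor is projected on its dominant plane, drawn
into a 1024x1024 binary raster (aspect preserved, 2% margin) with each section
stroked at its local diameter — spiny sections widened by a spine halo, since
imaged spiny dendrites appear thickened by their spine envelope — and the
box-counting dimension is the least-squares slope of log N(s) versus log(1/s)
over 40 box sizes log-spaced on [0.01, 1] of the image extent. The fit uses
the linear regime: saturated scales (N equal to the foreground pixel count),
nearly exhausted coverings (N <= 4), and the coarse regime (< 8 boxes per
side, where integer covering counts bias the slope) are excluded. Grids are
anchored at the image origin, so the count is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .morphology import MorphologyError, NeuronMorphology

__all__ = [
    "ProjectionImage",
    "BoxCountFit",
    "rasterize",
    "box_count_dimension",
    "sierpinski_raster",
]


@dataclass
class ProjectionImage:
    pixels: np.ndarray  # bool, (size, size)
    um_per_pixel: float
    plane: tuple[int, int]  # axis indices projected onto (0=x, 1=y, 2=z)

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class BoxCountFit:
    scales: np.ndarray  # box side as fraction of image extent
    box_sizes_px: np.ndarray
    counts: np.ndarray
    dimension: float
    r_squared: float
    used: np.ndarray  # mask of scales included in the fit
    degenerate: bool = False


def _draw_line(img: np.ndarray, r0: int, c0: int, r1: int, c1: int) -> None:
    """Bresenham line rasterization into a boolean image."""
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    n = max(dr, dc) + 1
    rr = np.rint(np.linspace(r0, r1, n)).astype(int)
    cc = np.rint(np.linspace(c0, c1, n)).astype(int)
    img[rr, cc] = True


def rasterize(
    morph: NeuronMorphology,
    plane: tuple[int, int] | None = None,
    size: int = 1024,
    include_soma: bool = True,
    stroke_diameters: bool = True,
    spine_halo_um: float = 2.0,
) -> ProjectionImage:
    """Project the dendritic arbor on a plane as a binary raster.

    ``plane`` defaults to the two axes of largest dendritic extent (Purkinje
    arbors are nearly planar). The drawing is rescaled to fit the image with a
    2% margin, preserving aspect ratio. Sections are stroked with their local
    diameter (at least 1 pixel), emulating how reconstruction renders draw
    processes as tubes; ``stroke_diameters=False`` gives a 1-pixel skeleton.
    The axon is excluded; the soma is included as a filled disk (or its traced
    contour) unless ``include_soma=False``.
    """
    polylines, widths = [], []
    for sec in morph.dendrites():
        polylines.append(np.array([p.xyz for p in sec.points]))
        w = sec.mean_diameter
        # spiny dendrites are imaged with their spines: widen the stroke by
        # one spine length (neck + head, ~1 µm) on each side
        if w < 1.6:
            w += spine_halo_um
        widths.append(w)
    if not polylines:
        raise MorphologyError("no dendrites to rasterize")

    allpts = np.vstack(polylines)
    if plane is None:
        ext = allpts.max(axis=0) - allpts.min(axis=0)
        keep = tuple(sorted(np.argsort(ext)[-2:]))
    else:
        keep = tuple(plane)
    pts2 = allpts[:, keep]
    lo, hi = pts2.min(axis=0), pts2.max(axis=0)
    span = float(max(hi - lo))
    if span <= 0:
        raise MorphologyError("degenerate (zero-extent) morphology")

    margin = 0.02 * size
    scale = (size - 1 - 2 * margin) / span

    # group polylines by stroke radius in pixels, dilate each layer once
    layers: dict[int, np.ndarray] = {}
    for poly, w in zip(polylines, widths):
        r_px = (
            max(0, int(round(w * scale / 2.0 - 0.5))) if stroke_diameters else 0
        )
        layer = layers.setdefault(r_px, np.zeros((size, size), dtype=bool))
        q = np.clip(np.rint((poly[:, keep] - lo) * scale + margin), 0, size - 1)
        q = q.astype(int)
        for (c0, r0), (c1, r1) in zip(q[:-1], q[1:]):
            _draw_line(layer, r0, c0, r1, c1)

    img = np.zeros((size, size), dtype=bool)
    for r_px, layer in layers.items():
        if r_px > 0:
            layer = ndimage.binary_dilation(layer, iterations=r_px)
        img |= layer

    if include_soma:
        soma = morph.root
        if len(soma.points) > 1:
            q = np.array([p.xyz for p in soma.points])[:, keep]
            q = np.clip(np.rint((q - lo) * scale + margin), 0, size - 1).astype(int)
            for (c0, r0), (c1, r1) in zip(q[:-1], q[1:]):
                _draw_line(img, r0, c0, r1, c1)
        else:
            p = soma.points[0]
            cx, cy = np.clip(
                np.rint((p.xyz[list(keep)] - lo) * scale + margin), 0, size - 1
            )
            r = max(1.0, p.diameter * scale / 2.0)
            yy, xx = np.ogrid[:size, :size]
            img |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r

    return ProjectionImage(img, um_per_pixel=1.0 / scale, plane=keep)


def box_count_dimension(
    img: ProjectionImage | np.ndarray,
    n_scales: int = 40,
    scale_range: tuple[float, float] = (0.01, 1.0),
) -> BoxCountFit:
    """Box-counting dimension of a binary raster.

    Counts occupied boxes at ``n_scales`` log-spaced box sizes and fits the
    slope of log N versus log(1/s) by least squares over the non-saturated
    regime.
    """
    pixels = img.pixels if isinstance(img, ProjectionImage) else np.asarray(img)
    pixels = pixels.astype(bool)
    fg = int(pixels.sum())
    if fg == 0:
        raise ValueError("image has no foreground pixels")
    size = max(pixels.shape)
    fractions = np.logspace(
        math.log10(scale_range[0]), math.log10(scale_range[1]), n_scales
    )
    box_px = np.maximum(1, np.rint(fractions * size).astype(int))
    counts = np.empty(n_scales, dtype=int)
    for i, b in enumerate(box_px):
        counts[i] = _occupied_boxes(pixels, int(b))

    if fg == 1:
        return BoxCountFit(
            fractions, box_px, counts, 0.0, 1.0,
            np.zeros(n_scales, dtype=bool), degenerate=True,
        )

    # linear regime: drop saturated scales (N == foreground pixels), nearly
    # exhausted coverings (N <= 4), and the coarse regime (< 8 boxes per image
    # side) where integer covering counts bias the slope
    used = (counts > 4) & (counts < fg) & (box_px <= size // 8)
    if used.sum() < 2:  # tiny images: fall back to all informative scales
        used = counts > 0
    x = np.log(1.0 / (box_px[used] / size))
    y = np.log(counts[used])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BoxCountFit(fractions, box_px, counts, float(slope), r2, used)


def _occupied_boxes(pixels: np.ndarray, box: int) -> int:
    if box == 1:
        return int(pixels.sum())
    h, w = pixels.shape
    nh, nw = -(-h // box), -(-w // box)
    padded = np.zeros((nh * box, nw * box), dtype=bool)
    padded[:h, :w] = pixels
    blocks = padded.reshape(nh, box, nw, box)
    return int(blocks.any(axis=(1, 3)).sum())


def sierpinski_raster(depth: int) -> np.ndarray:
    """Binary raster of a Sierpinski triangle of the given recursion depth.

    Uses the Pascal-triangle parity construction on a 2**depth grid; its
    analytic box-counting dimension is log 3 / log 2 ~ 1.585.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n = 2 ** depth
    i = np.arange(n)
    return (i[:, None] & i[None, :]) == 0
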