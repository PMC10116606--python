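"""Ancestry painting: convert sampled haplotype tracts into fixed-size
binary images with bounding-box annotations.

Each image row is one sampled haplotype, each column a genomic interval;
pixel value 1 ("black") marks ancestry from source 1, the source carrying
the beneficial allele, and 0 ("white") the other source.  Columns may be
laid out in physical coordinates (bp) or genetic-map coordinates (cM); a
pixel's value is the length-weighted majority ancestry over its interval,
with ties broken by the ancestry at the interval midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .simulate import RecombinationMap, SampleSet

__all__ = [
    "CoordinateMap",
    "AncestryImage",
    "BBox",
    "Detection",
    "AimPanel",
    "draw_aim_panel",
    "rasterize_full",
    "rasterize_aims",
    "target_bbox",
    "split_image",
]

DEFAULT_WIDTH = 200


@dataclass(frozen=True)
class BBox:
    """Half-open pixel rectangle [x_min, x_max) x [y_min, y_max), optionally
    carrying a detection confidence score."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("degenerate bbox")
        if self.score is not None and not 0 <= self.score <= 1:
            raise ValueError("score must be in [0, 1]")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    def contains_x(self, pixel: int) -> bool:
        return self.x_min <= pixel < self.x_max

    def x_pixels(self, width: int) -> np.ndarray:
        out = np.zeros(width, dtype=bool)
        out[max(self.x_min, 0) : min(self.x_max, width)] = True
        return out


Detection = BBox  # a Detection is a BBox whose score is set


@dataclass(frozen=True)
class CoordinateMap:
    """Monotone position-to-pixel mapping over a half-open axis domain.

    In ``physical`` mode the axis is basepairs.  In ``genetic`` mode the
    axis is centimorgans and basepair positions are first transformed
    through the recombination map, so pixels are equally spaced in genetic
    distance (recombination-dense regions get more pixels).
    """

    start: float
    end: float
    width: int = DEFAULT_WIDTH
    mode: str = "physical"
    genetic_map: RecombinationMap | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"physical", "genetic"}:
            raise ValueError("mode must be 'physical' or 'genetic'")
        if self.mode == "genetic" and self.genetic_map is None:
            raise ValueError("genetic mode requires a recombination map")
        if not self.end > self.start:
            raise ValueError("empty coordinate domain")
        if self.width < 1:
            raise ValueError("width must be >= 1")

    @classmethod
    def physical(cls, length: float, width: int = DEFAULT_WIDTH) -> "CoordinateMap":
        return cls(0.0, float(length), width, "physical")

    @classmethod
    def genetic(cls, rmap: RecombinationMap, width: int = DEFAULT_WIDTH) -> "CoordinateMap":
        total_cm = float(rmap.cumulative_cm(rmap.length))
        return cls(0.0, total_cm, width, "genetic", rmap)

    @property
    def pixel_size(self) -> float:
        return (self.end - self.start) / self.width

    def to_axis(self, position_bp):
        """Basepair position(s) -> axis units (bp or cM)."""
        if self.mode == "physical":
            return np.asarray(position_bp, dtype=float)
        return self.genetic_map.cumulative_cm(position_bp)

    def from_axis(self, axis_pos):
        if self.mode == "physical":
            return np.asarray(axis_pos, dtype=float)
        return self.genetic_map.cm_to_bp(axis_pos)

    def position_to_pixel(self, position_bp) -> np.ndarray | int:
        x = self.to_axis(position_bp)
        p = np.floor((x - self.start) / self.pixel_size).astype(int)
        p = np.clip(p, 0, self.width - 1)
        return int(p) if p.ndim == 0 else p

    def pixel_boundaries(self) -> np.ndarray:
        """Axis positions of the W+1 pixel edges."""
        return self.start + np.arange(self.width + 1) * self.pixel_size

    def pixel_midpoint_position(self, pixel) -> np.ndarray | float:
        x = self.start + (np.asarray(pixel) + 0.5) * self.pixel_size
        out = self.from_axis(x)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AimPanel:
    """A fixed panel of ancestry-informative marker positions (bp).

    Drawn once per demographic model and reused across all simulations so
    that images are comparable ("internally consistent" markers).
    """

    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 1 or len(pos) == 0:
            raise ValueError("panel must be a nonempty 1-D position array")
        if len(np.unique(pos)) != len(pos):
            raise ValueError("panel positions must be unique")
        object.__setattr__(self, "positions", np.sort(pos))

    def __len__(self) -> int:
        return len(self.positions)


def draw_aim_panel(
    length: float, n_markers: int = 100, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AimPanel:
    """Draw an i.i.d.-uniform marker panel with a dedicated seed, then freeze."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return AimPanel(rng.uniform(0.0, length, n_markers))


@dataclass
class AncestryImage:
    """W x H binary raster of sampled haplotypes.

    ``pixels[i, p]`` is 1 where haplotype i carries majority ancestry 1
    (black) over pixel p's interval.  Row order equals the sample order.
    The source SampleSet is retained so the image can be re-rasterized over
    sub-domains (see :func:`split_image`).
    """

    pixels: np.ndarray
    cmap: CoordinateMap
    samples: SampleSet | None = None
    panel: AimPanel | None = None
    meta: dict = field(default_factory=dict)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _rasterize_row(ends_axis, anc, cmap: CoordinateMap) -> np.ndarray:
    """Length-weighted majority ancestry per pixel for one haplotype.

    ``ends_axis`` are the tract end positions already transformed to axis
    units; starts are implicit (domain start, then previous end).
    """
    boundaries = cmap.pixel_boundaries()
    # cumulative ancestry-1 length measured from the chromosome start (axis 0)
    starts = np.concatenate(([0.0], ends_axis[:-1]))
    seg_black = anc.astype(float) * (ends_axis - starts)
    knots = np.concatenate(([0.0], ends_axis))
    cum = np.concatenate(([0.0], np.cumsum(seg_black)))
    black_len = np.diff(np.interp(boundaries, knots, cum))
    frac = black_len / cmap.pixel_size
    row = frac > 0.5
    ties = np.abs(frac - 0.5) <= 1e-9
    if np.any(ties):
        mids = boundaries[:-1][ties] + 0.5 * cmap.pixel_size
        idx = np.minimum(np.searchsorted(ends_axis, mids, side="right"), len(anc) - 1)
        row[ties] = anc[idx] == 1
    return row.astype(np.uint8)


def rasterize_full(samples: SampleSet, cmap: CoordinateMap, chromosome: int = 0) -> AncestryImage:
    """Paint full local ancestry: every position contributes to its pixel."""
    rows = np.empty((samples.n, cmap.width), dtype=np.uint8)
    for i, hap in enumerate(samples.haplotypes):
        ends, anc = hap.tracts[chromosome]
        rows[i] = _rasterize_row(cmap.to_axis(ends), anc, cmap)
    return AncestryImage(rows, cmap, samples, meta={"chromosome": chromosome, "mode": "full"})


def _aim_step_tracts(hap, panel: AimPanel, length: float, chromosome: int):
    """Reduce a haplotype to a left-nearest-marker step function.

    Every position takes the ancestry of the nearest marker at or to its
    left; positions left of the first marker take the first marker's
    ancestry.  Returns un-normalized step tracts (ends, ancestry).
    """
    marker_anc = hap.ancestry_at(chromosome, panel.positions)
    ends = np.concatenate((panel.positions[1:], [length]))
    return ends, marker_anc.astype(np.int8)


def rasterize_aims(
    samples: SampleSet, panel: AimPanel, cmap: CoordinateMap, chromosome: int = 0
) -> AncestryImage:
    """Paint sparse ancestry known only at a fixed marker panel."""
    length = samples.chrom_lengths[chromosome]
    if np.any(panel.positions < 0) or np.any(panel.positions >= length):
        raise ValueError("panel marker outside the chromosome")
    rows = np.empty((samples.n, cmap.width), dtype=np.uint8)
    for i, hap in enumerate(samples.haplotypes):
        ends, anc = _aim_step_tracts(hap, panel, length, chromosome)
        rows[i] = _rasterize_row(cmap.to_axis(ends), anc, cmap)
    return AncestryImage(
        rows, cmap, samples, panel, meta={"chromosome": chromosome, "mode": "aims"}
    )


def target_bbox(
    variant_position: float, cmap: CoordinateMap, half_width: int = 5, height: int = DEFAULT_WIDTH
) -> BBox:
    """Training target: a full-height box of ``2*half_width + 1`` pixels
    centered on the pixel containing the variant, clamped to the image."""
    c = int(cmap.position_to_pixel(variant_position))
    return BBox(
        max(c - half_width, 0), 0, min(c + half_width + 1, cmap.width), height
    )


def split_image(image: AncestryImage, k: int) -> list[AncestryImage]:
    """Re-rasterize the image as ``k`` full-width images over equal
    sub-domains of the axis, so each chunk gains resolution."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return [image]
    if image.samples is None:
        raise ValueError("split requires the source SampleSet")
    cmap = image.cmap
    edges = np.linspace(cmap.start, cmap.end, k + 1)
    out = []
    for i in range(k):
        sub = replace(cmap, start=float(edges[i]), end=float(edges[i + 1]))
        if image.panel is not None:
            out.append(rasterize_aims(image.samples, image.panel, sub,
                                      image.meta.get("chromosome", 0)))
        else:
            out.append(rasterize_full(image.samples, sub, image.meta.get("chromosome", 0)))
    return out
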