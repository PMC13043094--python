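"""Net-tissue-area standardization of microdissection regions.

Histological sections differ in tissue density ("dense" strictured vs
"loose" non-strictured tissue), so equal drawn areas do not contain equal
amounts of tissue.  Sample input is therefore standardized by net
foreground coverage: a layer region's lateral extent is adjusted until the
foreground area inside it reaches a fixed target (44 mm^2 by default),
optionally accumulating over serial sections when a single section does
not hold enough tissue.

Regions are axis-aligned rectangles in mask coordinates: rows are the
radial (wall-depth) axis and stay fixed; columns are the lateral axis and
are tuned.  Pixel indexing is 0-based with half-open intervals; a region's
column span is ``[col_center - halfwidth, col_center + halfwidth)`` so the
lateral width in pixels is ``2 * halfwidth``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

DEFAULT_TARGET_MM2 = 44.0
DEFAULT_TOL_FRACTION = 0.005  # half a percent of the target


class InsufficientTissueError(ValueError):
    """Target net area exceeds the foreground available in the row span."""

    def __init__(self, target_mm2: float, attainable_mm2: float):
        self.target_mm2 = target_mm2
        self.attainable_mm2 = attainable_mm2
        super().__init__(
            f"target {target_mm2:g} mm^2 exceeds attainable foreground "
            f"{attainable_mm2:.4f} mm^2; supply additional serial sections"
        )


@dataclass
class TissueMask:
    """Binary tissue mask (True = foreground tissue) with a physical scale."""

    pixels: np.ndarray = field(repr=False)
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D pixel grid")
        if not np.isfinite(self.um_per_px) or self.um_per_px <= 0:
            raise ValueError("um_per_px must be finite and positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def save(self, path: str | Path) -> None:
        """Write the mask as an 8-bit PNG plus a sidecar JSON with the scale."""
        import imageio.v3 as iio

        path = Path(path)
        iio.imwrite(path, (self.pixels.astype(np.uint8) * 255))
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"um_per_px": self.um_per_px})
        )

    @classmethod
    def load(cls, path: str | Path, um_per_px: float | None = None) -> "TissueMask":
        import imageio.v3 as iio

        path = Path(path)
        img = np.asarray(iio.imread(path))
        if img.ndim == 3:  # collapse any color channels
            img = img[..., 0]
        if um_per_px is None:
            sidecar = path.with_suffix(path.suffix + ".json")
            if sidecar.exists():
                um_per_px = json.loads(sidecar.read_text())["um_per_px"]
            else:
                raise ValueError("um_per_px not given and no sidecar JSON found")
        return cls(pixels=img > 0, um_per_px=float(um_per_px))


@dataclass
class LayerRegion:
    """A rectangular layer region: fixed radial row span, tunable lateral extent."""

    row_start: int
    row_stop: int
    col_center: int
    lateral_halfwidth: int
    net_area_mm2: float | None = None
    residual_mm2: float | None = None

    def col_span(self, mask_width: int) -> tuple[int, int]:
        lo = max(0, self.col_center - self.lateral_halfwidth)
        hi = min(mask_width, self.col_center + self.lateral_halfwidth)
        return lo, hi

    @property
    def lateral_width_px(self) -> int:
        return 2 * self.lateral_halfwidth


def _column_counts(mask: TissueMask, region: LayerRegion) -> np.ndarray:
    r0 = max(0, region.row_start)
    r1 = min(mask.shape[0], region.row_stop)
    if r0 >= r1:
        raise ValueError("region row span lies outside the mask")
    return mask.pixels[r0:r1].sum(axis=0)


def measure_net_tissue_area(mask: TissueMask, region: LayerRegion) -> float:
    """Foreground area inside the region, in mm^2.

    area = (foreground pixel count) * (um_per_px)^2 / 1e6.
    """
    counts = _column_counts(mask, region)
    c0, c1 = region.col_span(mask.shape[1])
    if c0 >= c1 and region.lateral_halfwidth > 0:
        raise ValueError("region lies fully outside the mask")
    n_fg = int(counts[c0:c1].sum())
    return n_fg * mask.um_per_px ** 2 / 1e6


def standardize_region(
    mask: TissueMask,
    seed_region: LayerRegion,
    target_mm2: float = DEFAULT_TARGET_MM2,
    tol: float | None = None,
) -> LayerRegion:
    """Tune the lateral halfwidth until net foreground area reaches the target.

    Net area is monotone non-decreasing in the halfwidth, so the smallest
    halfwidth whose area reaches ``target - tol`` is found by bisection on
    the integer halfwidth (at most log2(width) + 1 iterations).  If no
    integer halfwidth lands within ``tol`` of the target (density is
    discrete), the smallest halfwidth with area >= target - tol is returned
    and the residual is recorded on the region.

    Raises :class:`InsufficientTissueError` when the row span does not hold
    enough foreground; the attainable area is reported so the caller can
    fall back to accumulating serial sections.
    """
    if target_mm2 <= 0:
        raise ValueError("target_mm2 must be positive")
    if tol is None:
        tol = DEFAULT_TOL_FRACTION * target_mm2
    if tol <= 0:
        raise ValueError("tol must be positive")

    counts = _column_counts(mask, seed_region)
    px_area = mask.um_per_px ** 2 / 1e6
    width = mask.shape[1]
    h_max = max(seed_region.col_center, width - seed_region.col_center)

    def area(h: int) -> float:
        lo = max(0, seed_region.col_center - h)
        hi = min(width, seed_region.col_center + h)
        return float(counts[lo:hi].sum()) * px_area

    attainable = area(h_max)
    if attainable < target_mm2 - tol:
        raise InsufficientTissueError(target_mm2, attainable)

    def smallest_reaching(threshold: float) -> int:
        # smallest integer halfwidth with area(h) >= threshold (monotone)
        if area(0) >= threshold:
            return 0
        lo_h, hi_h = 0, h_max
        while hi_h - lo_h > 1:
            mid = (lo_h + hi_h) // 2
            if area(mid) >= threshold:
                hi_h = mid
            else:
                lo_h = mid
        return hi_h

    h = smallest_reaching(target_mm2) if attainable >= target_mm2 else h_max
    got = area(h)
    if got - target_mm2 > tol or attainable < target_mm2:
        # discrete columns overshoot the target (or the target itself is just
        # out of reach): settle for the smallest halfwidth within the lower
        # tolerance band and report any residual
        h = smallest_reaching(target_mm2 - tol)
        got = area(h)
    residual = got - target_mm2 if abs(got - target_mm2) > tol else None
    return replace(
        seed_region,
        lateral_halfwidth=int(h),
        net_area_mm2=got,
        residual_mm2=residual,
    )


def accumulate_sections(
    masks: list[TissueMask],
    seed_regions: list[LayerRegion],
    target_mm2: float = DEFAULT_TARGET_MM2,
    tol: float | None = None,
) -> list[LayerRegion]:
    """Fill the area target greedily over serial sections.

    Each section contributes up to its full available foreground; once the
    running total reaches the target, remaining sections are left untouched
    (zero halfwidth).  Raises :class:`InsufficientTissueError` if the
    combined foreground cannot reach the target.
    """
    if not masks:
        raise ValueError("need at least one mask")
    if len(masks) != len(seed_regions):
        raise ValueError("masks and seed_regions must align")
    if tol is None:
        tol = DEFAULT_TOL_FRACTION * target_mm2

    regions: list[LayerRegion] = []
    total = 0.0
    for mask, seed in zip(masks, seed_regions):
        remaining = target_mm2 - total
        if remaining <= tol:
            regions.append(replace(seed, lateral_halfwidth=0, net_area_mm2=0.0))
            continue
        try:
            reg = standardize_region(mask, seed, remaining, tol)
        except InsufficientTissueError as err:
            # use everything this section has and move on
            width = mask.shape[1]
            h_max = max(seed.col_center, width - seed.col_center)
            reg = replace(
                seed, lateral_halfwidth=int(h_max), net_area_mm2=err.attainable_mm2
            )
        regions.append(reg)
        total += reg.net_area_mm2 or 0.0
    if total < target_mm2 - tol:
        raise InsufficientTissueError(target_mm2, total)
    return regions
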