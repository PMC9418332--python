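"""Ring layouts and annulus/sector pixel geometry.

The angular convention is shared by the renderer and the unbending
analyzer: with the image displayed row 0 at top, sector index increases
clockwise, sector 0 starting at 12 o'clock.  Subunit/sector index ``i``
spans 22.5 degrees; bond ``b`` lies between sectors ``b`` and ``b+1``
(mod 16).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SECTOR_COUNT = 16
SECTOR_DEG = 360.0 / SECTOR_COUNT


class LayoutCapacityError(ValueError):
    """Requested rings do not fit in the image."""


@dataclass
class RingLayout:
    """Ring centers in nm (row, col) plus the raster geometry.

    The ring radius is a rendering choice (the recordings print only
    heights, not lateral ring dimensions); default 10 nm with a 4 nm wide
    annulus.
    """

    centers: np.ndarray
    ring_radius: float = 10.0
    annulus_width: float = 4.0
    sector_count: int = SECTOR_COUNT
    image_shape: tuple[int, int] = (64, 64)
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        pad = self.ring_radius + self.annulus_width / 2.0
        h = self.image_shape[0] * self.pixel_size
        w = self.image_shape[1] * self.pixel_size
        if np.any(self.centers[:, 0] < pad) or np.any(self.centers[:, 0] > h - pad) or np.any(
            self.centers[:, 1] < pad
        ) or np.any(self.centers[:, 1] > w - pad):
            raise LayoutCapacityError("ring(s) extend outside the image bounds")

    @property
    def n_rings(self) -> int:
        return self.centers.shape[0]


def _hex_spiral(n: int) -> np.ndarray:
    """First ``n`` axial hex-grid coordinates spiralling out from the origin."""
    coords = [(0, 0)]
    directions = [(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)]
    ring = 1
    while len(coords) < n:
        q, r = -ring, ring  # start cell of this ring
        for dq, dr in directions:
            for _ in range(ring):
                coords.append((q, r))
                q, r = q + dq, r + dr
        ring += 1
    return np.array(coords[:n], dtype=float)


def make_hex_layout(
    n_rings: int,
    image_size: int | tuple[int, int] | None = None,
    pixel_size: float = 1.0,
    ring_radius: float = 10.0,
    annulus_width: float = 4.0,
    margin: float = 4.0,
) -> RingLayout:
    """Hexagonally packed layout of ``n_rings`` rings.

    Center spacing is ``2*ring_radius + margin``.  When ``image_size`` (in
    pixels) is omitted the image is sized to fit; when given, a layout that
    does not fit raises :class:`LayoutCapacityError`.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    d = 2.0 * ring_radius + margin
    axial = _hex_spiral(n_rings)
    # axial -> cartesian: col = d*(q + r/2), row = d*sqrt(3)/2*r
    cols = d * (axial[:, 0] + axial[:, 1] / 2.0)
    rows = d * (np.sqrt(3.0) / 2.0) * axial[:, 1]
    pad = ring_radius + annulus_width / 2.0 + 2.0
    rows -= rows.min() - pad
    cols -= cols.min() - pad
    if image_size is None:
        shape = (
            int(np.ceil((rows.max() + pad) / pixel_size)),
            int(np.ceil((cols.max() + pad) / pixel_size)),
        )
    else:
        shape = (image_size, image_size) if np.isscalar(image_size) else tuple(image_size)
        if rows.max() + pad > shape[0] * pixel_size or cols.max() + pad > shape[1] * pixel_size:
            raise LayoutCapacityError(
                f"{n_rings} rings at spacing {d} nm do not fit in {shape} px"
            )
        # center the lattice in the given image
        rows += (shape[0] * pixel_size - (rows.max() + rows.min())) / 2.0
        cols += (shape[1] * pixel_size - (cols.max() + cols.min())) / 2.0
    return RingLayout(
        centers=np.column_stack([rows, cols]),
        ring_radius=ring_radius,
        annulus_width=annulus_width,
        image_shape=shape,
        pixel_size=pixel_size,
    )


def sector_pixel_map(
    image_shape: tuple[int, int],
    center_nm: np.ndarray,
    radius_nm: float,
    width_nm: float,
    pixel_size: float = 1.0,
    n_sectors: int = SECTOR_COUNT,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixels of one ring annulus and their sector indices.

    Returns ``(rows, cols, sector)`` index arrays for pixels whose center
    lies within ``radius +/- width/2`` of the ring center.  Sector 0 starts
    at 12 o'clock; the index increases clockwise on screen (row 0 at top).
    """
    r0, c0 = float(center_nm[0]), float(center_nm[1])
    if not (0 <= r0 <= image_shape[0] * pixel_size and 0 <= c0 <= image_shape[1] * pixel_size):
        raise ValueError("ring center lies outside the image")
    lo = max(0, int((r0 - radius_nm - width_nm) / pixel_size))
    hi = min(image_shape[0], int((r0 + radius_nm + width_nm) / pixel_size) + 2)
    lo_c = max(0, int((c0 - radius_nm - width_nm) / pixel_size))
    hi_c = min(image_shape[1], int((c0 + radius_nm + width_nm) / pixel_size) + 2)
    rr, cc = np.meshgrid(np.arange(lo, hi), np.arange(lo_c, hi_c), indexing="ij")
    dr = (rr + 0.5) * pixel_size - r0
    dc = (cc + 0.5) * pixel_size - c0
    rad = np.hypot(dr, dc)
    mask = (rad >= radius_nm - width_nm / 2.0) & (rad <= radius_nm + width_nm / 2.0)
    phi = np.degrees(np.arctan2(dc[mask], -dr[mask])) % 360.0
    sector = (phi // (360.0 / n_sectors)).astype(np.int64) % n_sectors
    return rr[mask], cc[mask], sector
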