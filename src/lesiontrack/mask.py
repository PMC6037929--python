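"""Binary lesion masks: compression, contour extraction, components.

A lesion segmentation is a binary voxel grid aligned to a CT series
(background 0, lesion 1).  Masks are persisted as DEFLATE streams of the
raw slice-major byte grid, and rendered as closed rectilinear contours
traced along pixel edges (the "crack" boundary between foreground and
background).  With contour vertices on pixel corners, the signed polygon
area of a slice's contours (outers positive, holes negative) equals its
foreground pixel count exactly — an identity the tests rely on.

Conventions: 2-D foreground is 4-connected and background 8-connected
(so diagonally touching pixels trace as separate contours); 3-D
component labelling is 26-connected.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import ImageGeometry

__all__ = [
    "LesionMask",
    "SliceContour",
    "CompressedMask",
    "MaskError",
    "compress_mask",
    "decompress_mask",
    "extract_contours",
    "rasterize_contours",
    "label_components",
]

ORGAN_LABELS = ("lung", "liver", "lymph_node", "other")


class MaskError(ValueError):
    """Raised for invalid mask payloads or contour sets."""


@dataclass(eq=False)
class LesionMask:
    """Binary voxel volume tied to a series, a lesion label and a reader."""

    geometry: ImageGeometry
    voxels: np.ndarray
    lesion_id: str = ""
    series_uid: str = ""
    user_id: str = ""
    organ_label: str = "other"

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.shape != self.geometry.shape:
            raise MaskError(
                f"mask shape {v.shape} does not match geometry shape {self.geometry.shape}"
            )
        if v.dtype != np.uint8:
            if not np.isin(v, (0, 1)).all():
                raise MaskError("mask voxels must be exactly 0 or 1")
            v = v.astype(np.uint8)
        elif v.max(initial=0) > 1:
            raise MaskError("mask voxels must be exactly 0 or 1")
        self.voxels = v
        if self.organ_label not in ORGAN_LABELS:
            raise MaskError(f"organ_label must be one of {ORGAN_LABELS}")

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not self.voxels.any()


@dataclass
class SliceContour:
    """Closed rectilinear polygon on pixel corners, one slice.

    ``vertices`` is an (n, 2) array of (col, row) corner coordinates;
    the closing edge back to the first vertex is implicit.  Outer
    contours are wound counter-clockwise (positive shoelace area in
    (col, row) axes), holes clockwise.
    """

    slice_index: int
    vertices: np.ndarray
    is_hole: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)

    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class CompressedMask:
    """DEFLATE stream of the packed binary grid plus its geometry binding."""

    payload: bytes
    dims: tuple[int, int, int]  # (n_cols, n_rows, n_slices)
    geometry_digest: str
    lesion_id: str = ""


# ----------------------------------------------------------------------
# compression

def compress_mask(m: LesionMask, level: int = 6) -> CompressedMask:
    """Serialize slice-major, one byte per voxel, then DEFLATE."""
    raw = np.ascontiguousarray(m.voxels, dtype=np.uint8).tobytes()
    return CompressedMask(
        payload=zlib.compress(raw, level),
        dims=(m.geometry.n_cols, m.geometry.n_rows, m.geometry.n_slices),
        geometry_digest=m.geometry.digest(),
        lesion_id=m.lesion_id,
    )


def decompress_mask(c: CompressedMask, g: ImageGeometry, **identity) -> LesionMask:
    """Inverse of :func:`compress_mask`; validates dims, values and geometry."""
    if c.geometry_digest != g.digest():
        raise MaskError(
            f"lesion {c.lesion_id or '<unknown>'}: compressed mask was built for a "
            "different geometry (digest mismatch)"
        )
    try:
        raw = zlib.decompress(c.payload)
    except zlib.error as exc:
        raise MaskError(f"lesion {c.lesion_id or '<unknown>'}: corrupted DEFLATE stream: {exc}")
    n_cols, n_rows, n_slices = c.dims
    expected = n_cols * n_rows * n_slices
    if len(raw) != expected:
        raise MaskError(
            f"lesion {c.lesion_id or '<unknown>'}: payload decodes to {len(raw)} voxels, "
            f"expected {expected}"
        )
    voxels = np.frombuffer(raw, dtype=np.uint8).reshape(n_slices, n_rows, n_cols)
    if voxels.max(initial=0) > 1:
        raise MaskError(f"lesion {c.lesion_id or '<unknown>'}: non-binary voxel values")
    kwargs = {"lesion_id": c.lesion_id, **identity}
    return LesionMask(geometry=g, voxels=voxels.copy(), **kwargs)


# ----------------------------------------------------------------------
# contour tracing (crack boundary)

# directed boundary edges keep foreground on the inside so that outer
# cycles come out counter-clockwise in (col, row) axes:
#   top side    (c, r)     -> (c+1, r)
#   right side  (c+1, r)   -> (c+1, r+1)
#   bottom side (c+1, r+1) -> (c, r+1)
#   left side   (c, r+1)   -> (c, r)


def _boundary_edges(fg: np.ndarray) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    padded = np.pad(fg, 1, constant_values=False)
    core = padded[1:-1, 1:-1]
    edges: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for exposed, start_off, end_off in (
        (core & ~padded[:-2, 1:-1], (0, 0), (1, 0)),   # top
        (core & ~padded[1:-1, 2:], (1, 0), (1, 1)),    # right
        (core & ~padded[2:, 1:-1], (1, 1), (0, 1)),    # bottom
        (core & ~padded[1:-1, :-2], (0, 1), (0, 0)),   # left
    ):
        for r, c in np.argwhere(exposed):
            edges.append(
                ((int(c) + start_off[0], int(r) + start_off[1]),
                 (int(c) + end_off[0], int(r) + end_off[1]))
            )
    return edges


def _merge_collinear(cycle: list[tuple[int, int]]) -> np.ndarray:
    pts = np.asarray(cycle)
    d_in = pts - np.roll(pts, 1, axis=0)
    d_out = np.roll(pts, -1, axis=0) - pts
    keep = ~np.all(d_in == d_out, axis=1)
    return pts[keep]


def extract_contours(m: LesionMask, slice_index: int) -> list[SliceContour]:
    """Trace the crack boundary of one slice into closed polygons.

    Returns outer contours (counter-clockwise) and holes (clockwise);
    an empty slice yields an empty list.  The enclosed pixel set (outers
    minus holes) is exactly the slice's foreground.
    """
    if not 0 <= slice_index < m.geometry.n_slices:
        raise MaskError(f"slice_index {slice_index} out of range")
    fg = m.voxels[slice_index].astype(bool)
    return trace_slice_contours(fg, slice_index)


def trace_slice_contours(fg: np.ndarray, slice_index: int = 0) -> list[SliceContour]:
    """Crack-boundary tracing of a 2-D boolean array (rows, cols)."""
    if not fg.any():
        return []
    edges = _boundary_edges(fg)
    outgoing: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for start, end in edges:
        outgoing.setdefault(start, []).append(end)
    for ends in outgoing.values():
        ends.sort()

    contours = []
    for start, _ in edges:
        if not outgoing.get(start):
            continue
        cycle = [start]
        current = outgoing[start].pop()
        prev = start
        while current != start:
            cycle.append(current)
            candidates = outgoing[current]
            if len(candidates) == 1:
                nxt = candidates.pop()
            else:
                # ambiguous corner (diagonally touching pixels): take the
                # left turn so 4-connected regions trace as separate cycles
                din = (current[0] - prev[0], current[1] - prev[1])
                nxt = None
                for cand in candidates:
                    dout = (cand[0] - current[0], cand[1] - current[1])
                    if din[0] * dout[1] - din[1] * dout[0] > 0:
                        nxt = cand
                        break
                if nxt is None:
                    nxt = candidates[0]
                candidates.remove(nxt)
            prev, current = current, nxt
        vertices = _merge_collinear(cycle)
        contour = SliceContour(slice_index=slice_index, vertices=vertices)
        contour.is_hole = contour.signed_area() < 0
        contours.append(contour)
    return contours


def rasterize_contours(
    contours: list[SliceContour], g: ImageGeometry, **identity
) -> LesionMask:
    """Fill contours back into a binary mask (inverse of extraction).

    A pixel is set iff its centre has positive winding number over all
    contours of its slice — inside an outer contour and not inside a
    hole.  Rejects self-intersecting or non-rectilinear polygons.
    """
    voxels = np.zeros(g.shape, dtype=np.uint8)
    # winding contribution per (slice, row, corner-column)
    contrib = np.zeros((g.n_slices, g.n_rows, g.n_cols + 1), dtype=np.int32)
    for contour in contours:
        k = contour.slice_index
        if not 0 <= k < g.n_slices:
            raise MaskError(f"contour slice index {k} out of range")
        verts = contour.vertices
        if len(verts) < 4:
            raise MaskError("a rectilinear closed polygon needs at least 4 vertices")
        # a polygon may legitimately pass through one corner twice (a
        # region pinched at a diagonal), but re-walking a crack edge
        # means self-intersection
        used_segments: set[frozenset] = set()
        nxt = np.roll(verts, -1, axis=0)
        for (x0, y0), (x1, y1) in zip(verts, nxt):
            if x0 != x1 and y0 != y1:
                raise MaskError("polygon edge is not axis-aligned")
            if x0 == x1 and y0 == y1:
                raise MaskError("degenerate zero-length polygon edge")
            x0i, y0i, x1i, y1i = (int(round(v)) for v in (x0, y0, x1, y1))
            if x0i == x1i:
                step = 1 if y1i > y0i else -1
                units = [frozenset(((x0i, y), (x0i, y + step)))
                         for y in range(y0i, y1i, step)]
            else:
                step = 1 if x1i > x0i else -1
                units = [frozenset(((x, y0i), (x + step, y0i)))
                         for x in range(x0i, x1i, step)]
            for seg in units:
                if seg in used_segments:
                    raise MaskError("self-intersecting polygon (crack edge reused)")
                used_segments.add(seg)
            if x0i != x1i:
                continue  # horizontal edges never cross a horizontal ray
            r0, r1 = min(y0i, y1i), max(y0i, y1i)
            sign = 1 if y1i < y0i else -1  # upward edges add, downward subtract
            contrib[k, r0:r1, x0i] += sign
    winding = np.cumsum(contrib, axis=2)[:, :, : g.n_cols]
    voxels[winding > 0] = 1
    return LesionMask(geometry=g, voxels=voxels, **identity)


# ----------------------------------------------------------------------
# connected components

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def label_components(m: LesionMask) -> list[LesionMask]:
    """Split a mask into 26-connected components.

    Components are sorted by descending voxel count, ties broken by the
    smallest (slice, row, col) index of the component.  Identity fields
    are inherited; ``lesion_id`` gets a ``#<n>`` suffix when splitting.
    """
    if m.is_empty():
        return []
    labels, n = ndimage.label(m.voxels, structure=_STRUCT_26)
    if n == 1:
        return [m]
    order = []
    flat = labels.reshape(-1)
    for lab in range(1, n + 1):
        where = np.flatnonzero(flat == lab)
        order.append((-len(where), int(where[0]), lab))
    order.sort()
    out = []
    for rank, (_, _, lab) in enumerate(order, start=1):
        out.append(
            LesionMask(
                geometry=m.geometry,
                voxels=(labels == lab).astype(np.uint8),
                lesion_id=f"{m.lesion_id}#{rank}" if m.lesion_id else f"#{rank}",
                series_uid=m.series_uid,
                user_id=m.user_id,
                organ_label=m.organ_label,
            )
        )
    return out
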