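"""Scattered-data field reconstruction on masked regular grids.

Cross-sections use natural-neighbor (Sibson) interpolation: the value at a
query point is the convex combination of neighboring probe values weighted by
the Voronoi-cell area the inserted query point "steals" from each site.  The
weights are nonnegative and sum to one, so reconstructed fields are exact at
probes and bounded by the data — appropriate for gas concentrations that must
stay within physical limits.

Longitudinal sections use radial-basis-function (RBF) interpolation with a
low-order polynomial term, better suited to the strongly anisotropic 50 m x
~2.5 m domain (probe spacing along the axis is two orders of magnitude
coarser than vertically).

Boundary conditions outside the pile are the composition of atmospheric air
for the gases and the outside temperature of the day, applied on a ring of
points along the outline; the three aeration-channel positions on the base
carry channel measurements when available, else the forced-air (ambient)
values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from shapely import contains_xy
from shapely.geometry import Polygon

from . import geometry
from .geometry import CrossSectionOutline, PileSpec
from .measurements_io import RANGES, AmbientConditions

logger = logging.getLogger(__name__)

__all__ = [
    "FieldGrid",
    "BoundarySet",
    "sibson_weights",
    "natural_neighbor_interpolate",
    "rbf_interpolate",
    "assemble_boundary",
    "cross_section_field",
    "longitudinal_field",
]

VARIABLES = ("temp_C", "o2_pct", "co2_pct", "co_ppm")

#: Post-hoc clamping bounds for reconstructed fields (RBF can overshoot).
CLAMP_BOUNDS = {
    "o2_pct": RANGES["o2_pct"],
    "co2_pct": RANGES["co2_pct"],
    "co_ppm": (0.0, float("inf")),
}

DEFAULT_CELL_SIZE_M = 0.1
DEFAULT_N_BOUNDARY = 24


@dataclass
class FieldGrid:
    """A masked regular-grid field over a cross-section or longitudinal plane.

    ``values[row, col]`` maps to plane coordinates with row 0 at the bottom;
    node (row, col) is the cell center
    ``origin + cell_size * (col + 0.5, row + 0.5)``.  Values are defined
    (non-NaN) exactly where ``mask`` is true.
    """

    plane: str
    variable: str
    origin: tuple[float, float]
    cell_size_m: float
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def node_position(self, row: float, col: float) -> tuple[float, float]:
        """Plane coordinates of a (possibly fractional) node index."""
        return (
            self.origin[0] + (col + 0.5) * self.cell_size_m,
            self.origin[1] + (row + 0.5) * self.cell_size_m,
        )

    def node_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids of horizontal/vertical cell-center coordinates."""
        cols = self.origin[0] + (np.arange(self.n_cols) + 0.5) * self.cell_size_m
        rows = self.origin[1] + (np.arange(self.n_rows) + 0.5) * self.cell_size_m
        return np.meshgrid(cols, rows)

    @classmethod
    def empty(cls, plane, variable, origin, cell_size_m, n_rows, n_cols, mask=None):
        if mask is None:
            mask = np.ones((n_rows, n_cols), dtype=bool)
        return cls(plane, variable, origin, cell_size_m,
                   np.full((n_rows, n_cols), np.nan), mask)


@dataclass
class BoundarySet:
    """Boundary-condition points (on the outline or at channel mouths) with
    per-variable values."""

    points: np.ndarray  # (m, 2) plane coordinates
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.points)


# --- natural-neighbor (Sibson) interpolation --------------------------------

def _clip_halfplane(poly: np.ndarray, n: np.ndarray, c: float) -> np.ndarray:
    """Clip a convex polygon to the half-plane n . p <= c (Sutherland-Hodgman)."""
    if len(poly) == 0:
        return poly
    d = poly @ n - c
    out: list[np.ndarray] = []
    k = len(poly)
    for i in range(k):
        p, q = poly[i], poly[(i + 1) % k]
        dp, dq = d[i], d[(i + 1) % k]
        if dp <= 0:
            out.append(p)
            if dq > 0:
                out.append(p + (q - p) * (dp / (dp - dq)))
        elif dq <= 0:
            out.append(p + (q - p) * (dp / (dp - dq)))
    return np.asarray(out) if out else np.empty((0, 2))


def _polygon_area(poly: np.ndarray) -> float:
    if len(poly) < 3:
        return 0.0
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _bisector(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Half-plane of points at least as close to ``a`` as to ``b``."""
    n = b - a
    c = 0.5 * (b @ b - a @ a)
    return n, c


def sibson_weights(sites: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Sibson (area-stealing) weights of ``query`` with respect to ``sites``.

    The query's prospective Voronoi cell is intersected with each site's
    existing cell; the stolen areas, normalized, are the weights.  Requires
    the query strictly inside (or on the hull of) the site set for the
    prospective cell to be bounded; callers guarantee this via the boundary
    ring.  A query coincident with a site gets that site's full weight.
    """
    sites = np.asarray(sites, dtype=float)
    query = np.asarray(query, dtype=float)
    n_sites = len(sites)
    d2 = np.einsum("ij,ij->i", sites - query, sites - query)
    hit = np.argmin(d2)
    if d2[hit] < 1e-18:
        w = np.zeros(n_sites)
        w[hit] = 1.0
        return w
    # Clip a bounding box down to the query's prospective cell.  A query
    # barely inside the site hull has a bounded but very elongated cell, so
    # the box is grown until the cell no longer touches it (queries on or
    # outside the hull never close; the cap leaves a truncated cell, which
    # callers avoid by hull-testing first).
    lo = np.minimum(sites.min(axis=0), query) - 1.0
    hi = np.maximum(sites.max(axis=0), query) + 1.0
    mid = (lo + hi) / 2.0
    span = float((hi - lo).max()) * 4.0
    order = np.argsort(d2)  # clipping near-to-far shrinks the cell fastest
    for _ in range(40):
        box = np.array([
            [mid[0] - span, mid[1] - span],
            [mid[0] + span, mid[1] - span],
            [mid[0] + span, mid[1] + span],
            [mid[0] - span, mid[1] + span],
        ])
        qcell = box
        for j in order:
            n, c = _bisector(query, sites[j])
            qcell = _clip_halfplane(qcell, n, c)
        if len(qcell) < 3:
            w = np.zeros(n_sites)
            w[hit] = 1.0
            return w
        if (np.abs(qcell - mid) < span * (1.0 - 1e-9)).all():
            break
        span *= 8.0
    # every stolen piece lies inside the query cell, hence within its
    # circumradius R of the query; triangle inequalities bound which sites
    # can contribute (d <= 2R + d_hit) and which bisectors can cut a piece
    # (d <= 4R + d_hit)
    radius = float(np.sqrt(((qcell - query) ** 2).sum(axis=1).max()))
    d = np.sqrt(d2)
    d_hit = d[hit]
    candidates = np.flatnonzero(d <= 2.0 * radius + d_hit + 1e-12)
    relevant = np.flatnonzero(d <= 4.0 * radius + d_hit + 1e-12)
    weights = np.zeros(n_sites)
    for i in candidates:
        piece = qcell
        for j in relevant:
            if j == i:
                continue
            n, c = _bisector(sites[i], sites[j])
            piece = _clip_halfplane(piece, n, c)
            if len(piece) < 3:
                break
        weights[i] = _polygon_area(piece)
    total = weights.sum()
    if total <= 0:
        w = np.zeros(n_sites)
        w[hit] = 1.0
        return w
    return weights / total


def _dedupe_sites(points: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse exactly coincident sites; conflicting values are an error."""
    tree = cKDTree(points)
    pairs = tree.query_pairs(1e-9, output_type="ndarray")
    if len(pairs) == 0:
        return points, values
    drop = set()
    for i, j in pairs:
        if abs(values[i] - values[j]) > 1e-9 * max(1.0, abs(values[i])):
            raise ValueError(
                f"duplicate site at {points[i]} with conflicting values "
                f"{values[i]} vs {values[j]}"
            )
        drop.add(int(max(i, j)))
    keep = np.array([k for k in range(len(points)) if k not in drop])
    return points[keep], values[keep]


def natural_neighbor_interpolate(
    points: np.ndarray,
    values: np.ndarray,
    queries: np.ndarray,
) -> np.ndarray:
    """Natural-neighbor interpolation of scattered values at query points.

    Exact at sites; each output is a convex combination of site values, so
    results never leave ``[min(values), max(values)]``.  Queries outside the
    sites' convex hull (where Sibson coordinates are undefined) fall back to
    the nearest site's value with a logged warning.

    Raises ``ValueError`` for fewer than 3 distinct sites or an all-collinear
    configuration — add boundary points before interpolating.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    points, values = _dedupe_sites(points, values)
    if len(points) < 3:
        raise ValueError(
            "natural-neighbor interpolation needs >= 3 distinct sites; "
            "add boundary points"
        )
    try:
        tri = Delaunay(points)
    except Exception as exc:  # QhullError on collinear input
        raise ValueError(
            "sites are collinear; natural-neighbor interpolation undefined — "
            "add boundary points"
        ) from exc
    inside = tri.find_simplex(queries) >= 0
    if not inside.all():
        logger.warning(
            "%d of %d queries outside the site hull; using nearest-site fallback",
            int((~inside).sum()), len(queries),
        )
    out = np.empty(len(queries))
    tree = cKDTree(points)
    for k, q in enumerate(queries):
        if inside[k]:
            w = sibson_weights(points, q)
            out[k] = w @ values
        else:
            out[k] = values[tree.query(q)[1]]
    return out


# --- radial-basis-function interpolation ------------------------------------

KERNELS = ("multiquadric", "thin-plate", "gaussian")


def _kernel_matrix(kind: str, r: np.ndarray, c: float) -> np.ndarray:
    if kind == "multiquadric":
        return np.sqrt(r * r + c * c)
    if kind == "thin-plate":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = r * r * np.log(r)
        return np.where(r > 0, out, 0.0)
    if kind == "gaussian":
        return np.exp(-((r / c) ** 2))
    raise ValueError(f"unknown RBF kernel {kind!r}; choose from {KERNELS}")


def _poly_basis(points: np.ndarray, degree: int) -> np.ndarray:
    if degree == 0:
        return np.ones((len(points), 1))
    return np.column_stack([np.ones(len(points)), points])


def rbf_interpolate(
    points: np.ndarray,
    values: np.ndarray,
    queries: np.ndarray,
    kernel: str = "multiquadric",
    shape_param: float | None = None,
    cond_threshold: float = 1e12,
) -> np.ndarray:
    """RBF interpolation with polynomial augmentation.

    The interpolant is ``sum_i w_i phi(|x - x_i|) + p(x)`` with a linear
    polynomial ``p`` and the side conditions ``P^T w = 0``, so constant and
    affine fields are reproduced exactly (given >= 3 non-collinear sites;
    degenerate configurations drop to a constant term).  The default shape
    parameter is the mean nearest-neighbor site spacing.

    Duplicate sites are an error.  A system conditioned worse than
    ``cond_threshold`` gets a small ridge on the kernel diagonal, with a
    logged warning (exactness then holds only approximately).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float)
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    n = len(points)
    if n == 0:
        raise ValueError("RBF interpolation needs at least one site")
    if n > 1:
        tree = cKDTree(points)
        nn_d, _ = tree.query(points, k=2)
        if np.any(nn_d[:, 1] < 1e-12):
            raise ValueError("duplicate sites make the RBF system singular")
        default_shape = float(nn_d[:, 1].mean())
    else:
        default_shape = 1.0
    c = float(shape_param) if shape_param is not None else default_shape
    if c <= 0:
        raise ValueError("shape parameter must be positive")
    # linear polynomial only if the sites can determine one
    degree = 1
    if n < 3 or np.linalg.matrix_rank(points - points.mean(axis=0), tol=1e-10) < 2:
        degree = 0
    P = _poly_basis(points, degree)
    r = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    phi = _kernel_matrix(kernel, r, c)
    m = P.shape[1]
    A = np.zeros((n + m, n + m))
    A[:n, :n] = phi
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.concatenate([values, np.zeros(m)])
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > cond_threshold:
        ridge = 1e-10 * max(1.0, float(np.abs(phi).max()))
        logger.warning(
            "RBF system ill-conditioned (cond=%.3g); adding ridge %.3g", cond, ridge
        )
        A[:n, :n] += ridge * np.eye(n)
    sol = np.linalg.solve(A, rhs)
    w, p = sol[:n], sol[n:]
    rq = np.linalg.norm(queries[:, None, :] - points[None, :, :], axis=-1)
    return _kernel_matrix(kernel, rq, c) @ w + _poly_basis(queries, degree) @ p


# --- boundary conditions and section fields ---------------------------------

def assemble_boundary(
    outline: CrossSectionOutline | Polygon,
    ambient: AmbientConditions,
    channel_records=None,
    n_boundary: int = DEFAULT_N_BOUNDARY,
) -> BoundarySet:
    """Boundary points for a cross-section: an ambient ring plus channels.

    ``n_boundary`` points are evenly spaced (by arc length) along the outline
    and carry ambient values for every variable.  Each aeration-channel
    position carries the matching channel record's values when provided,
    otherwise the forced-air values (ambient gases at ambient temperature).
    """
    poly = outline.polygon if isinstance(outline, CrossSectionOutline) else outline
    ring = poly.exterior
    pts = [ring.interpolate(i / n_boundary, normalized=True) for i in range(n_boundary)]
    points = [(p.x, p.y) for p in pts]
    values = {v: [ambient.value(v)] * n_boundary for v in VARIABLES}
    channels = (
        outline.channel_positions if isinstance(outline, CrossSectionOutline) else ()
    )
    channel_records = list(channel_records or [])
    for k, (cy, cz) in enumerate(channels):
        points.append((cy, cz))
        rec = channel_records[k] if k < len(channel_records) else None
        for v in VARIABLES:
            raw = getattr(rec, v, None) if rec is not None else None
            values[v].append(ambient.value(v) if raw is None else float(raw))
    return BoundarySet(
        points=np.asarray(points, dtype=float),
        values={v: np.asarray(vals, dtype=float) for v, vals in values.items()},
    )


def _clamp(values: np.ndarray, variable: str, context: str) -> np.ndarray:
    bounds = CLAMP_BOUNDS.get(variable)
    if bounds is None:
        return values
    lo, hi = bounds
    clamped = np.clip(values, lo, hi)
    n_bad = int(np.sum(values != clamped))
    if n_bad:
        logger.info("%s: clamped %d %s nodes to [%g, %g]", context, n_bad, variable, lo, hi)
    return clamped


def _interior_sites(records, pile: PileSpec, variable: str, outline=None):
    sites, vals = [], []
    for rec in records:
        if rec.side not in ("left", "right", "deep"):
            continue
        raw = getattr(rec, variable)
        if raw is None:
            continue
        _, y, z = geometry.probe_coordinates(
            pile, rec.distance_m, rec.side, rec.level, outline=outline
        )
        sites.append((y, z))
        vals.append(float(raw))
    return sites, vals


def cross_section_field(
    records,
    pile: PileSpec,
    variable: str,
    ambient: AmbientConditions,
    distance_m: float | None = None,
    cell_size_m: float = DEFAULT_CELL_SIZE_M,
    channel_records=None,
    n_boundary: int = DEFAULT_N_BOUNDARY,
) -> FieldGrid | None:
    """Natural-neighbor field of one variable over a cross-section outline.

    ``records`` are the probe measurements of one (pile, day, distance);
    sites are their tip positions plus the ambient/channel boundary set.
    Returns ``None`` (with a logged warning) when no interior record carries
    the variable, mirroring how incomplete sections are dropped from
    campaign reports rather than fabricated.
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    outline = geometry.cross_section_outline(pile)
    if distance_m is None:
        distances = {float(r.distance_m) for r in records}
        distance_m = distances.pop() if len(distances) == 1 else float("nan")
    sites, vals = _interior_sites(records, pile, variable, outline)
    if not sites:
        logger.warning(
            "%s d=%s: no interior %s records; section skipped", pile.pile_id,
            distance_m, variable,
        )
        return None
    boundary = assemble_boundary(outline, ambient, channel_records, n_boundary)
    pts = np.vstack([np.asarray(sites), boundary.points])
    v = np.concatenate([np.asarray(vals), boundary.values[variable]])
    half_w = pile.width_m / 2.0
    n_cols = math.ceil(pile.width_m / cell_size_m)
    n_rows = math.ceil(pile.height_m / cell_size_m)
    grid = FieldGrid.empty(
        plane=f"cross-section@{distance_m:g}m", variable=variable,
        origin=(-half_w, 0.0), cell_size_m=cell_size_m,
        n_rows=n_rows, n_cols=n_cols,
    )
    Y, Z = grid.node_coords()
    mask = contains_xy(outline.polygon, Y.ravel(), Z.ravel()).reshape(Y.shape)
    grid.mask = mask
    out = np.full(Y.shape, np.nan).ravel()
    flat = mask.ravel()
    queries = np.column_stack([Y.ravel()[flat], Z.ravel()[flat]])
    out[flat] = _clamp(
        natural_neighbor_interpolate(pts, v, queries), variable,
        grid.plane,
    )
    grid.values = out.reshape(Y.shape)
    return grid


def longitudinal_field(
    records,
    pile: PileSpec,
    side: str,
    variable: str,
    ambient: AmbientConditions,
    cell_size_m: float = DEFAULT_CELL_SIZE_M,
    channel_records=None,
    kernel: str = "multiquadric",
    shape_param: float | None = None,
    n_boundary_per_edge: int = 12,
) -> FieldGrid:
    """RBF field of one variable on the (x, z) plane along one flank.

    ``records`` must span at least two cross-section distances.  Boundary
    points carry ambient values along the top and both ends; the base carries
    channel values (ambient forced air when no channel records are given).
    Gas fields are clamped to physical bounds after reconstruction.
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    if side not in ("left", "right"):
        raise ValueError(f"longitudinal side must be left or right, got {side!r}")
    sites, vals = [], []
    for rec in records:
        if rec.side != side:
            continue
        raw = getattr(rec, variable)
        if raw is None:
            continue
        sites.append((float(rec.distance_m), pile.level_height(rec.level)))
        vals.append(float(raw))
    distances = {s[0] for s in sites}
    if len(distances) < 2:
        raise ValueError(
            f"longitudinal section needs records from >= 2 distances, got {len(distances)}"
        )
    L, H = pile.length_m, pile.height_m
    xs = np.linspace(0.0, L, n_boundary_per_edge)
    zs = np.linspace(0.0, H, max(3, n_boundary_per_edge // 3))
    boundary_pts: list[tuple[float, float]] = []
    boundary_vals: list[float] = []
    for x in xs:  # membrane top
        boundary_pts.append((float(x), H))
        boundary_vals.append(ambient.value(variable))
    for z in zs[1:-1]:  # fan end and far end
        for x in (0.0, L):
            boundary_pts.append((x, float(z)))
            boundary_vals.append(ambient.value(variable))
    channel_records = list(channel_records or [])
    base_val = ambient.value(variable)
    if channel_records:
        chan_vals = [
            float(getattr(r, variable)) for r in channel_records
            if getattr(r, variable, None) is not None
        ]
        if chan_vals:
            base_val = float(np.mean(chan_vals))
    for x in xs:  # aerated base
        boundary_pts.append((float(x), 0.0))
        boundary_vals.append(base_val)
    pts = np.vstack([np.asarray(sites), np.asarray(boundary_pts)])
    v = np.concatenate([np.asarray(vals), np.asarray(boundary_vals)])
    n_cols = math.ceil(L / cell_size_m)
    n_rows = math.ceil(H / cell_size_m)
    grid = FieldGrid.empty(
        plane=f"longitudinal-{side}", variable=variable,
        origin=(0.0, 0.0), cell_size_m=cell_size_m,
        n_rows=n_rows, n_cols=n_cols,
    )
    X, Z = grid.node_coords()
    queries = np.column_stack([X.ravel(), Z.ravel()])
    out = rbf_interpolate(pts, v, queries, kernel=kernel, shape_param=shape_param)
    grid.values = _clamp(out, variable, grid.plane).reshape(X.shape)
    return grid
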