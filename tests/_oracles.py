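"""Independent oracles used by the interpolation tests.

Both deliberately avoid the implementation's code paths: Sibson weights are
recomputed by clipping GEOS-built Voronoi diagrams, and RBF predictions by
assembling and solving the dense augmented system directly.
"""

import numpy as np
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram


def sibson_weights_oracle(sites: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Brute-force area-stealing weights from GEOS Voronoi diagrams.

    Valid for queries strictly inside the sites' convex hull (elsewhere the
    inserted cell is unbounded and the weights depend on the clip envelope).
    """
    sites = np.asarray(sites, dtype=float)
    span = float(np.ptp(sites, axis=0).max()) + 1.0

    def cells(points, big):
        diagram = voronoi_diagram(MultiPoint([Point(*p) for p in points]), envelope=big)
        out = [None] * len(points)
        for geom in diagram.geoms:
            for i, p in enumerate(points):
                if geom.contains(Point(*p)):
                    out[i] = geom.intersection(big)
        return out

    # a query close to the hull has a bounded but very elongated cell: grow
    # the clip envelope until the query cell no longer touches it
    factor = 10.0
    for _ in range(40):
        lo = sites.min(axis=0) - factor * span
        hi = sites.max(axis=0) + factor * span
        big = box(lo[0], lo[1], hi[0], hi[1])
        new = cells(np.vstack([sites, query]), big)
        query_cell = new[-1]
        b = query_cell.bounds
        if (b[0] > lo[0] and b[1] > lo[1] and b[2] < hi[0] and b[3] < hi[1]):
            break
        factor *= 8.0
    old = cells(sites, big)
    stolen = np.array([old[i].intersection(query_cell).area for i in range(len(sites))])
    return stolen / stolen.sum()


def rbf_dense_oracle(
    sites: np.ndarray,
    values: np.ndarray,
    queries: np.ndarray,
    kernel: str,
    shape: float,
) -> np.ndarray:
    """Direct dense solve of the polynomial-augmented RBF system."""
    sites = np.asarray(sites, float)
    queries = np.atleast_2d(np.asarray(queries, float))
    n = len(sites)

    def phi(r):
        if kernel == "multiquadric":
            return np.sqrt(r**2 + shape**2)
        if kernel == "thin-plate":
            with np.errstate(divide="ignore", invalid="ignore"):
                out = r**2 * np.log(r)
            return np.where(r > 0, out, 0.0)
        if kernel == "gaussian":
            return np.exp(-((r / shape) ** 2))
        raise ValueError(kernel)

    r = np.linalg.norm(sites[:, None] - sites[None, :], axis=-1)
    P = np.column_stack([np.ones(n), sites])
    A = np.block([[phi(r), P], [P.T, np.zeros((3, 3))]])
    sol = np.linalg.solve(A, np.concatenate([values, np.zeros(3)]))
    rq = np.linalg.norm(queries[:, None] - sites[None, :], axis=-1)
    return phi(rq) @ sol[:n] + np.column_stack([np.ones(len(queries)), queries]) @ sol[n:]
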