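"""Layouts, KDE contour overlays, and figure rendering.

Contours outline each significant cluster (domain) with the iso-line of a
Gaussian kernel density estimate, drawn at the density value below which
a fraction ``level`` of the cluster's members fall — so the polygon
encloses at least ``level`` of the members. Degenerate clusters (fewer
than 3 points, or collinear/coincident points) fall back to a convex
hull, or to a buffered capsule around the point set.

Rendering is deterministic for a fixed seed and spec: the SVG hash salt
and metadata are pinned so identical inputs produce byte-identical SVG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import matplotlib
import numpy as np

matplotlib.use("Agg")  # headless; must precede pyplot import

import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.collections import LineCollection  # noqa: E402
from scipy import stats as sps  # noqa: E402

import networkx as nx  # noqa: E402

from .domains import DomainMap  # noqa: E402
from .network import Network  # noqa: E402

logger = logging.getLogger(__name__)

__all__ = ["PlotSpec", "layout", "contours", "render", "DEFAULT_PALETTE"]

DEFAULT_PALETTE = (
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
    "#a65628", "#f781bf", "#17becf", "#bcbd22", "#8c564b",
)


@dataclass
class PlotSpec:
    layout: str = "fruchterman-reingold"
    layout_seed: int = 42
    iterations: int = 50
    node_size: float = 12.0
    palette: tuple = DEFAULT_PALETTE
    contour_level: float = 0.67
    contour_bandwidth: float | None = None  # None = Scott's rule
    dpi: int = 150
    format: str = "svg"

    def __post_init__(self):
        if not 0 < self.contour_level < 1:
            raise ValueError("contour_level must be strictly between 0 and 1")
        if self.dpi < 72:
            raise ValueError("dpi must be >= 72")


def layout(
    net: Network, method: str = "fruchterman-reingold", seed: int = 42,
    iterations: int = 50,
) -> dict[str, tuple[float, float]]:
    """2-D node coordinates; deterministic for a fixed seed.

    ``fruchterman-reingold`` (alias ``fr``, ``spring``) is the default
    spring-embedded layout; ``forceatlas2`` (alias ``fa2``) is delegated
    to networkx; ``precomputed`` returns the network's own coordinates.
    """
    method = method.lower()
    g = net.to_networkx()
    if method in ("fruchterman-reingold", "fr", "spring"):
        pos = nx.spring_layout(g, seed=seed, iterations=iterations)
    elif method in ("forceatlas2", "fa2"):
        pos = nx.forceatlas2_layout(g, seed=seed, max_iter=max(iterations, 100))
    elif method == "precomputed":
        if not net.coords:
            raise ValueError("network carries no precomputed coordinates")
        return dict(net.coords)
    else:
        raise ValueError(f"unknown layout method {method!r}")
    out = {str(v): (float(x), float(y)) for v, (x, y) in pos.items()}
    bad = [v for v, (x, y) in out.items() if not (np.isfinite(x) and np.isfinite(y))]
    if bad:
        raise RuntimeError(f"layout produced non-finite coordinates for {bad[:5]}")
    return out


# ----------------------------------------------------------------------
# contours


def _capsule(P: np.ndarray, radius: float, n_arc: int = 16) -> np.ndarray:
    """Closed capsule polygon around the principal axis of a degenerate
    point set."""
    center = P.mean(axis=0)
    Q = P - center
    if len(P) > 1 and np.abs(Q).max() > 0:
        _, _, vt = np.linalg.svd(Q, full_matrices=False)
        axis = vt[0]
        t = Q @ axis
        lo, hi = t.min(), t.max()
    else:
        axis = np.array([1.0, 0.0])
        lo = hi = 0.0
    normal = np.array([-axis[1], axis[0]])
    a = center + lo * axis
    b = center + hi * axis
    angles_b = np.linspace(-np.pi / 2, np.pi / 2, n_arc)
    angles_a = np.linspace(np.pi / 2, 3 * np.pi / 2, n_arc)
    arc_b = b + radius * (
        np.outer(np.cos(angles_b), axis) + np.outer(np.sin(angles_b), normal)
    )
    arc_a = a + radius * (
        np.outer(np.cos(angles_a), axis) + np.outer(np.sin(angles_a), normal)
    )
    poly = np.vstack([arc_b, arc_a, arc_b[:1]])
    return poly


def _kde_polygons(P: np.ndarray, level: float, bandwidth, grid: int = 120):
    """Iso-density polygons enclosing >= ``level`` of the points."""
    kde = sps.gaussian_kde(P.T, bw_method=bandwidth)
    dens = kde(P.T)
    thresh = np.quantile(dens, 1.0 - level)
    pad = 3.0 * P.std(axis=0).max() + 1e-9
    xs = np.linspace(P[:, 0].min() - pad, P[:, 0].max() + pad, grid)
    ys = np.linspace(P[:, 1].min() - pad, P[:, 1].max() + pad, grid)
    XX, YY = np.meshgrid(xs, ys)
    ZZ = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(XX.shape)
    from contourpy import contour_generator

    gen = contour_generator(x=XX, y=YY, z=ZZ)
    lines = gen.lines(thresh)
    polys = []
    for line in lines:
        line = np.asarray(line)
        if len(line) < 3:
            continue
        if not np.allclose(line[0], line[-1]):
            line = np.vstack([line, line[:1]])
        polys.append(line)
    if not polys:
        raise ValueError("no closed iso-line found")
    return polys


def contours(
    coords: dict,
    dm: DomainMap,
    part,
    level: float = 0.67,
    bandwidth: float | None = None,
) -> dict[int, list[np.ndarray]]:
    """Per-domain closed polygons outlining the cluster's KDE iso-line.

    Clusters with < 3 members or degenerate geometry fall back to a
    convex hull / capsule (logged).
    """
    if not 0 < level < 1:
        raise ValueError("level must be strictly between 0 and 1")
    groups = part.clusters()
    span = np.array([coords[v] for v in part.assignment])
    default_radius = 0.03 * max(np.ptp(span, axis=0).max(), 1e-6)
    out: dict[int, list[np.ndarray]] = {}
    for cid in sorted(dm.significant_clusters):
        P = np.array([coords[v] for v in groups[cid]], dtype=float)
        polys = None
        if len(P) >= 3 and np.linalg.matrix_rank(P - P.mean(axis=0)) == 2:
            try:
                polys = _kde_polygons(P, level, bandwidth)
            except (np.linalg.LinAlgError, ValueError) as e:
                logger.warning("cluster %d: KDE contour failed (%s); hull fallback",
                               cid, e)
        if polys is None:
            try:
                from scipy.spatial import ConvexHull

                hull = ConvexHull(P)
                poly = P[hull.vertices]
                polys = [np.vstack([poly, poly[:1]])]
            except Exception:
                polys = [_capsule(P, default_radius)]
        out[cid] = polys
    return out


# ----------------------------------------------------------------------
# rendering


def render(
    net: Network,
    coords: dict,
    dm: DomainMap | None,
    spec: PlotSpec,
    path,
    part=None,
) -> None:
    """Render the annotated network to ``path`` in the spec's format.

    Nodes of significant clusters are colored by palette order (cycling
    with a brightness shift past the palette length); everything else is
    grey. Contour overlays and a domain legend are drawn when a non-empty
    DomainMap and partition are supplied.
    """
    with matplotlib.rc_context({"svg.hashsalt": str(spec.layout_seed)}):
        fig, ax = plt.subplots(figsize=(8, 8), dpi=spec.dpi)
        ax.set_axis_off()
        segs = [
            (coords[u], coords[v]) for (u, v) in sorted(net.edges)
        ]
        ax.add_collection(
            LineCollection(segs, colors="#cccccc", linewidths=0.4, zorder=1)
        )

        order = net.nodes
        X = np.array([coords[v] for v in order])
        colors = ["#aaaaaa"] * len(order)
        legend_handles = []
        if dm is not None and part is not None and dm.significant_clusters:
            for rank, cid in enumerate(sorted(dm.significant_clusters)):
                colors_idx = _domain_color(rank, spec.palette)
                for i, v in enumerate(order):
                    if part.assignment[v] == cid:
                        colors[i] = colors_idx
                legend_handles.append(
                    plt.Line2D(
                        [], [], marker="o", linestyle="", color=colors_idx,
                        label=f"{cid}: {dm.best_label(cid)}",
                    )
                )
            polys = contours(
                coords, dm, part, spec.contour_level, spec.contour_bandwidth
            )
            for rank, cid in enumerate(sorted(polys)):
                for poly in polys[cid]:
                    ax.plot(
                        poly[:, 0], poly[:, 1],
                        color=_domain_color(rank, spec.palette),
                        linewidth=1.2, zorder=3,
                    )
        ax.scatter(
            X[:, 0], X[:, 1], s=spec.node_size, c=colors, zorder=2,
            linewidths=0,
        )
        if legend_handles:
            ax.legend(handles=legend_handles, loc="upper right", fontsize=7,
                      frameon=False)
        ax.autoscale()
        fig.savefig(
            path, format=spec.format, dpi=spec.dpi,
            metadata=_stable_metadata(spec.format), bbox_inches="tight",
        )
        plt.close(fig)


def _domain_color(rank: int, palette) -> str:
    """Palette color by rank; cycles with a brightness shift when domains
    outnumber the palette."""
    base = palette[rank % len(palette)]
    cycle = rank // len(palette)
    if cycle == 0:
        return base
    rgb = matplotlib.colors.to_rgb(base)
    factor = 0.6**cycle
    return matplotlib.colors.to_hex(tuple(c * factor for c in rgb))


def _stable_metadata(fmt: str):
    if fmt == "svg":
        return {"Date": None}
    if fmt == "pdf":
        return {"CreationDate": None}
    return None
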