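"""Three-loci survival-zone inference from pairwise distance extremes.

Model
-----
Across a population of fixed cells, each of the three loci r (class II
gene), g (class I gene) and b (TNFα, class III) occupies a position
inside its own confinement sphere — its *survival zone* (SZ) — of radius
R_r, R_g, R_b about a fixed center.  For a pair (i, j) with center
separation c_ij, the observed (diameter-normalized) distances then range
over [c_ij - R_i - R_j, c_ij + R_i + R_j]; as the number of cells grows,
the observed min and max of each pairwise distance converge to these
bounds from the inside.  Solving the three pairwise-sum equations

    R_i + R_j = (d_ij_max - d_ij_min) / 2

gives the closed forms

    R_g = (d_rg_max + d_gb_max + d_rb_min - d_rb_max - d_rg_min - d_gb_min) / 4
    R_b = (d_rb_max + d_gb_max + d_rg_min - d_rg_max - d_rb_min - d_gb_min) / 4
    R_r = (d_rg_max + d_rb_max + d_gb_min - d_gb_max - d_rg_min - d_rb_min) / 4

and the center separations c_ij = (d_ij_max + d_ij_min) / 2.  All
quantities here are dimensionless (distances normalized by the nucleus
diameter).  Noise can make a closed-form radius negative; such radii are
clamped to 0 with a flag, and the raw values retained for diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: order of the three locus pairs in all (n, 3) distance-triple arrays
PAIR_ORDER = ("rg", "rb", "gb")
LOCI = ("r", "g", "b")


@dataclass
class PairwiseExtremes:
    """Min/max of the three pairwise distances over n cells."""

    d_rg_min: float
    d_rg_max: float
    d_rb_min: float
    d_rb_max: float
    d_gb_min: float
    d_gb_max: float
    n: int

    def __post_init__(self):
        for pair in PAIR_ORDER:
            lo = getattr(self, f"d_{pair}_min")
            hi = getattr(self, f"d_{pair}_max")
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid extremes for pair {pair}: min={lo}, max={hi}")
        if self.n < 2:
            raise ValueError("extremes require at least 2 cells")

    def span(self, pair: str) -> float:
        return getattr(self, f"d_{pair}_max") - getattr(self, f"d_{pair}_min")

    def center_distance(self, pair: str) -> float:
        return 0.5 * (getattr(self, f"d_{pair}_max") + getattr(self, f"d_{pair}_min"))


@dataclass
class SurvivalZoneModel:
    """Fitted SZ radii, raw (unclamped) values, 2D center layout, provenance."""

    R_r: float
    R_g: float
    R_b: float
    raw_radii: tuple[float, float, float]  # (R_r, R_g, R_b) before clamping
    centers: dict[str, np.ndarray]  # locus -> (2,) point, canonical frame
    clamped: dict[str, bool]
    extremes: PairwiseExtremes

    def radius(self, locus: str) -> float:
        return {"r": self.R_r, "g": self.R_g, "b": self.R_b}[locus]

    def to_dict(self) -> dict:
        return {
            "radii": {"r": self.R_r, "g": self.R_g, "b": self.R_b},
            "raw_radii": dict(zip(LOCI, self.raw_radii)),
            "clamped": self.clamped,
            "centers": {k: list(map(float, v)) for k, v in self.centers.items()},
            "extremes": {
                f"d_{p}_{m}": getattr(self.extremes, f"d_{p}_{m}")
                for p in PAIR_ORDER
                for m in ("min", "max")
            },
            "n": self.extremes.n,
        }


def pairwise_extremes(triples: np.ndarray, q: float = 0.0) -> PairwiseExtremes:
    """Per-pair extremes of the distance triples over cells.

    Parameters
    ----------
    triples:
        (n, 3) array of per-cell distances in ``PAIR_ORDER`` = (rg, rb, gb).
    q:
        0 (default) takes the strict min/max; 0 < q < 0.5 takes the
        (q, 1-q) empirical quantiles instead, a robustness option against
        gross outliers.
    """
    t = np.asarray(triples, dtype=float)
    if t.ndim != 2 or t.shape[1] != 3:
        raise ValueError("triples must be (n, 3) in PAIR_ORDER")
    if t.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    if not (0 <= q < 0.5):
        raise ValueError("q must satisfy 0 <= q < 0.5")
    if q == 0:
        lo, hi = t.min(axis=0), t.max(axis=0)
    else:
        lo = np.quantile(t, q, axis=0)
        hi = np.quantile(t, 1 - q, axis=0)
    kw = {}
    for i, pair in enumerate(PAIR_ORDER):
        kw[f"d_{pair}_min"] = float(lo[i])
        kw[f"d_{pair}_max"] = float(hi[i])
    return PairwiseExtremes(n=t.shape[0], **kw)


def sz_radii(ext: PairwiseExtremes) -> tuple[float, float, float]:
    """Closed-form SZ radii (R_g, R_b, R_r) from the pairwise extremes.

    Raw values (before the clamping applied in :func:`fit`); may be
    negative when the data violate the sphere model.
    """
    rg_min, rg_max = ext.d_rg_min, ext.d_rg_max
    rb_min, rb_max = ext.d_rb_min, ext.d_rb_max
    gb_min, gb_max = ext.d_gb_min, ext.d_gb_max
    R_g = (rg_max + gb_max + rb_min - rb_max - rg_min - gb_min) / 4.0
    R_b = (rb_max + gb_max + rg_min - rg_max - rb_min - gb_min) / 4.0
    R_r = (rg_max + rb_max + gb_min - gb_max - rg_min - rb_min) / 4.0
    return (R_g, R_b, R_r)


def sz_centers(ext: PairwiseExtremes, tolerance: float = 1e-9) -> dict[str, np.ndarray]:
    """Canonical 2D layout of the three SZ centers by trilateration.

    Center separations c_ij = (d_ij_max + d_ij_min)/2; frame: r at the
    origin, g on the positive x-axis at c_rg, b in the upper half-plane.
    """
    c_rg = ext.center_distance("rg")
    c_rb = ext.center_distance("rb")
    c_gb = ext.center_distance("gb")
    sides = {"rg": c_rg, "rb": c_rb, "gb": c_gb}
    s_max = max(sides.values())
    if s_max > sum(sides.values()) - s_max + tolerance * max(s_max, 1.0):
        raise ValueError(
            f"center distances violate the triangle inequality: "
            f"c_rg={c_rg:.6g}, c_rb={c_rb:.6g}, c_gb={c_gb:.6g}"
        )
    if c_rg == 0:
        raise ValueError("r and g centers coincide; canonical frame undefined")
    x_b = (c_rb**2 - c_gb**2 + c_rg**2) / (2.0 * c_rg)
    y_sq = c_rb**2 - x_b**2
    y_b = float(np.sqrt(max(0.0, y_sq)))
    return {
        "r": np.array([0.0, 0.0]),
        "g": np.array([c_rg, 0.0]),
        "b": np.array([x_b, y_b]),
    }


def fit(triples: np.ndarray, q: float = 0.0) -> SurvivalZoneModel:
    """Fit the survival-zone model from per-cell distance triples.

    Computes extremes, the closed-form radii (negatives clamped to 0 and
    flagged), and the canonical 2D center layout.
    """
    return fit_from_extremes(pairwise_extremes(triples, q=q))


def fit_from_extremes(ext: PairwiseExtremes) -> SurvivalZoneModel:
    """Build the model from precomputed extremes (see :func:`fit`)."""
    R_g, R_b, R_r = sz_radii(ext)
    raw = (R_r, R_g, R_b)
    clamped = {loc: val < 0 for loc, val in zip(LOCI, raw)}
    if any(clamped.values()):
        log.warning("negative SZ radius clamped to 0 (raw: r=%.4g g=%.4g b=%.4g)", *raw)
    return SurvivalZoneModel(
        R_r=max(0.0, R_r),
        R_g=max(0.0, R_g),
        R_b=max(0.0, R_b),
        raw_radii=raw,
        centers=sz_centers(ext),
        clamped=clamped,
        extremes=ext,
    )


def _embed_triangle(d_rg: float, d_rb: float, d_gb: float) -> np.ndarray:
    """Embed a triangle with the given side lengths in 2D (rows: r, g, b)."""
    sides = (d_rg, d_rb, d_gb)
    s_max = max(sides)
    if s_max > sum(sides) - s_max + 1e-9 * max(s_max, 1.0):
        raise ValueError(f"triangle inequality violated: rg={d_rg}, rb={d_rb}, gb={d_gb}")
    if d_rg == 0:
        return np.array([[0.0, 0.0], [0.0, 0.0], [d_rb, 0.0]])
    x_b = (d_rb**2 - d_gb**2 + d_rg**2) / (2.0 * d_rg)
    y_b = float(np.sqrt(max(0.0, d_rb**2 - x_b**2)))
    return np.array([[0.0, 0.0], [d_rg, 0.0], [x_b, y_b]])


def _align(points: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, float]:
    """Rigidly align `points` to `targets` (rotation+translation, reflection
    searched), minimizing the sum of squared vertex deviations (Kabsch)."""
    best = None
    for reflect in (False, True):
        pts = points.copy()
        if reflect:
            pts[:, 1] = -pts[:, 1]
        pc = pts - pts.mean(axis=0)
        tc = targets - targets.mean(axis=0)
        H = pc.T @ tc
        U, _, Vt = np.linalg.svd(H)
        D = np.diag([1.0, float(np.sign(np.linalg.det(Vt.T @ U.T)))])
        R = Vt.T @ D @ U.T
        aligned = pc @ R.T + targets.mean(axis=0)
        resid = float(np.sum((aligned - targets) ** 2))
        if best is None or resid < best[1]:
            best = (aligned, resid)
    return best


def reconstruct_positions(triples: np.ndarray, model: SurvivalZoneModel):
    """Per-cell 2D locus positions inside the fitted survival zones.

    Each cell's distance triple is embedded as a 2D triangle and rigidly
    aligned (rotation + translation + reflection) to the SZ centers by
    least squares.  Returns ``(positions, residuals, outside_fraction,
    skipped)`` where positions is (n_kept, 3, 2) with vertex rows in
    LOCI order, residuals the per-cell sum of squared deviations, and
    outside_fraction the fraction of reconstructed points falling outside
    their SZ circle.  Cells violating the triangle inequality are skipped
    and logged.
    """
    t = np.asarray(triples, dtype=float)
    targets = np.vstack([model.centers[loc] for loc in LOCI])
    positions, residuals, skipped = [], [], []
    for i, (d_rg, d_rb, d_gb) in enumerate(t):
        try:
            tri = _embed_triangle(d_rg, d_rb, d_gb)
        except ValueError:
            skipped.append(i)
            continue
        aligned, resid = _align(tri, targets)
        positions.append(aligned)
        residuals.append(resid)
    if skipped:
        log.info("reconstruct_positions skipped %d cells (triangle inequality)", len(skipped))
    positions = np.array(positions) if positions else np.empty((0, 3, 2))
    residuals = np.array(residuals)
    outside = 0
    total = positions.shape[0] * 3
    for j, loc in enumerate(LOCI):
        radius = model.radius(loc)
        if positions.size:
            d = np.linalg.norm(positions[:, j, :] - model.centers[loc], axis=1)
            outside += int(np.sum(d > radius + 1e-12))
    outside_fraction = outside / total if total else 0.0
    return positions, residuals, outside_fraction, skipped


def position_density(points: np.ndarray, bandwidth: float | None = None,
                     grid_size: int = 64, padding: float = 0.3):
    """Gaussian-kernel 2D density of reconstructed points on a regular grid.

    Returns ``(xx, yy, density)``; the density integrates to 1 over the
    grid (within ~1e-3 for a grid that covers the mass).  Degenerate
    all-identical point sets concentrate the unit mass in the grid cell
    containing the point.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("position_density needs an (n >= 5, 2) point array")
    lo = pts.min(axis=0) - padding
    hi = pts.max(axis=0) + padding
    x = np.linspace(lo[0], hi[0], grid_size)
    y = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(x, y)
    cell = (x[1] - x[0]) * (y[1] - y[0])
    spread = pts.std(axis=0)
    if np.all(spread < 1e-12):
        # singular covariance: all mass in the cell nearest the point
        density = np.zeros_like(xx)
        i = int(np.argmin(np.abs(y - pts[0, 1])))
        j = int(np.argmin(np.abs(x - pts[0, 0])))
        density[i, j] = 1.0 / cell
        return xx, yy, density
    from scipy.stats import gaussian_kde

    kde = gaussian_kde(pts.T, bw_method=bandwidth)
    density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    density /= density.sum() * cell  # renormalize truncation to the grid
    return xx, yy, density


def plot_model(model: SurvivalZoneModel, positions: np.ndarray, path,
               grid_size: int = 64) -> None:
    """SZ circles with reconstructed point clouds and their 2D KDE."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"r": "tab:red", "g": "tab:green", "b": "tab:blue"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for j, loc in enumerate(LOCI):
        c = model.centers[loc]
        if positions.size:
            pts = positions[:, j, :]
            ax.scatter(pts[:, 0], pts[:, 1], s=4, alpha=0.3, color=colors[loc])
            if pts.shape[0] >= 5 and np.any(pts.std(axis=0) > 1e-12):
                xx, yy, dens = position_density(pts, grid_size=grid_size)
                ax.contour(xx, yy, dens, levels=4, colors=colors[loc], linewidths=0.7)
        circle = plt.Circle(c, model.radius(loc), fill=False, linestyle=":",
                            color=colors[loc], linewidth=1.5)
        ax.add_patch(circle)
        ax.annotate(f"{loc} (R={model.radius(loc):.3f})", c, color=colors[loc])
    ax.set_aspect("equal")
    ax.set_xlabel("x (normalized)")
    ax.set_ylabel("y (normalized)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
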