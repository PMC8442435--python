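"""Synthetic 3D-FISH populations with known ground truth.

The generator emulates the study conditions the analysis assumes: per
condition on the order of 60–88 nuclei, each a near-spherical nucleus
carrying two MHC alleles, each allele marked by one spot per MHC class
(I, II, III).  Within an allele, each locus is drawn uniformly inside its
own confinement sphere ("survival zone") placed relative to the allele
anchor; allele compaction states are imposed geometrically (rescaling the
triplet about its centroid across the spot-radius threshold) so the
ground-truth labels are unambiguous; the activated condition adds extra
separation to one configurable locus pair; Gaussian measurement noise is
added last.

Randomness: one ``numpy.random.SeedSequence`` per run, spawned into one
child stream per nucleus in index order, so enlarging a population never
perturbs the nuclei already generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_model import (
    CHANNELS,
    CellRecord,
    NucleusGeometry,
    Spot,
    voxel_to_physical,
    write_spot_table,
)

CONDITIONS = ("resting", "activated")

#: survival-zone locus labels mapped to FISH channels:
#: r = class II gene, g = class I gene, b = TNFα (class III)
LOCUS_CHANNEL = {"r": "classII", "g": "classI", "b": "classIII"}


class ConfigError(ValueError):
    """A simulation configuration that cannot produce valid nuclei."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic population (all lengths in μm)."""

    n_nuclei: int = 75
    nucleus_radius_mean: float = 4.0
    nucleus_radius_sd: float = 0.3
    #: survival-zone centers per locus, allele-template frame
    sz_centers: dict = field(
        default_factory=lambda: {
            "r": (0.0, 0.0, 0.0),
            "g": (0.9, 0.0, 0.0),
            "b": (0.5, 0.6, 0.0),
        }
    )
    #: confinement radii per locus
    sz_radii: dict = field(default_factory=lambda: {"r": 0.3, "g": 0.3, "b": 0.3})
    spot_radius: float = 0.25
    frac_decompacted: float = 0.5
    #: extra separation applied to this channel pair under "activated"
    activation_pair: tuple = ("classI", "classIII")
    activation_shift: float = 0.4
    measurement_noise_sd: float = 0.05
    seed: int = 0
    voxel_size: tuple = (0.079, 0.079, 0.244)
    species: str = "pig"

    def __post_init__(self):
        if self.n_nuclei < 1:
            raise ConfigError("n_nuclei must be >= 1")
        if not (0.0 <= self.frac_decompacted <= 1.0):
            raise ConfigError("frac_decompacted must lie in [0, 1]")
        if self.spot_radius <= 0 or self.nucleus_radius_mean <= 0:
            raise ConfigError("radii must be > 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigError("voxel sizes must be > 0")
        if any(r <= 0 for r in self.sz_radii.values()):
            raise ConfigError("sz radii must be > 0")
        self._validate_fit()

    @property
    def radius_floor(self) -> float:
        """Lower truncation of the nucleus-radius draw."""
        return max(self.nucleus_radius_mean - 3 * self.nucleus_radius_sd,
                   0.1 * self.nucleus_radius_mean)

    def _template(self) -> dict[str, np.ndarray]:
        """SZ centers re-expressed about the template centroid."""
        pts = {k: np.asarray(v, dtype=float) for k, v in self.sz_centers.items()}
        centroid = np.mean(list(pts.values()), axis=0)
        return {k: v - centroid for k, v in pts.items()}

    def _validate_fit(self) -> None:
        # alleles are anchored at +- half the nucleus radius, so each SZ
        # sphere (plus spot size, shift and noise headroom) must fit in
        # the remaining half radius of the smallest admissible nucleus
        budget = 0.5 * self.radius_floor
        slack = self.spot_radius + 4 * self.measurement_noise_sd + 0.5 * self.activation_shift
        for locus, center in self._template().items():
            need = float(np.linalg.norm(center)) + self.sz_radii[locus] + slack
            if need > budget:
                raise ConfigError(
                    f"survival zone {locus!r} (reach {need:.2f} μm) cannot fit "
                    f"inside the nucleus (allele budget {budget:.2f} μm)"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sz_centers"] = {k: list(v) for k, v in self.sz_centers.items()}
        return d


@dataclass
class GroundTruth:
    """Per-nucleus true allele states and locus positions plus the config."""

    config: dict
    condition: str
    nuclei: list = field(default_factory=list)  # dicts, one per nucleus

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "condition": self.condition, "nuclei": self.nuclei},
            indent=1, default=float))


def _uniform_in_ball(rng: np.random.Generator, radius: float, size: int = 1) -> np.ndarray:
    v = rng.normal(size=(size, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.random(size)[:, None] ** (1.0 / 3.0)
    return radius * v * u


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


def _enforce_state(pos: dict[str, np.ndarray], decompacted: bool, threshold: float) -> dict:
    """Rescale a triplet about its centroid across the compaction threshold.

    Decompacted: every pairwise distance pushed to >= 1.2 x threshold;
    compacted: every pairwise distance pulled to <= 0.8 x threshold.
    """
    pts = np.vstack([pos[ch] for ch in CHANNELS])
    centroid = pts.mean(axis=0)
    d = [np.linalg.norm(pts[i] - pts[j]) for i in range(3) for j in range(i + 1, 3)]
    d_min, d_max = min(d), max(d)
    scale = 1.0
    if decompacted and d_min < 1.2 * threshold:
        scale = (1.2 * threshold) / d_min if d_min > 0 else 1.0
    elif not decompacted and d_max > 0.8 * threshold:
        scale = (0.8 * threshold) / d_max
    if scale != 1.0:
        pts = centroid + scale * (pts - centroid)
    return {ch: pts[i] for i, ch in enumerate(CHANNELS)}


def _apply_activation_shift(pos: dict[str, np.ndarray], pair: tuple[str, str],
                            shift: float) -> dict:
    """Lengthen the distance of one channel pair by `shift`, leaving the
    other two pairwise distances unchanged.

    The two paired loci move apart along their axis; the third locus is
    then repositioned (trilateration, nearest solution to its old
    position) so its distances to both stay exactly what they were.  If
    the lengthened pair would break the triangle inequality the shift is
    reduced to the largest feasible value.
    """
    c1, c2 = pair
    (c3,) = [ch for ch in CHANNELS if ch not in pair]
    p1, p2, p3 = pos[c1], pos[c2], pos[c3]
    u = p2 - p1
    length = np.linalg.norm(u)
    if length == 0:
        return pos
    u = u / length
    d13 = float(np.linalg.norm(p3 - p1))
    d23 = float(np.linalg.norm(p3 - p2))
    max_len = 0.98 * (d13 + d23)
    new_len = min(length + shift, max(max_len, length))
    q1 = p1 - 0.5 * (new_len - length) * u
    q2 = p2 + 0.5 * (new_len - length) * u
    # trilaterate the third locus: distance d13 from q1 and d23 from q2
    x = (d13**2 - d23**2 + new_len**2) / (2.0 * new_len)
    h = float(np.sqrt(max(0.0, d13**2 - x**2)))
    v = p3 - p1
    w = v - (v @ u) * u  # in-plane perpendicular toward the old position
    n_w = np.linalg.norm(w)
    w = w / n_w if n_w > 0 else _any_perpendicular(u)
    q3 = q1 + x * u + h * w
    return {c1: q1, c2: q2, c3: q3}


def _any_perpendicular(u: np.ndarray) -> np.ndarray:
    v = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    w = np.cross(u, v)
    return w / np.linalg.norm(w)


def _state_of(pos: dict[str, np.ndarray], threshold: float) -> str:
    d = [float(np.linalg.norm(pos[c1] - pos[c2]))
         for i, c1 in enumerate(CHANNELS) for c2 in CHANNELS[i + 1:]]
    if all(x >= threshold for x in d):
        return "D"
    if all(x < threshold for x in d):
        return "C"
    return "ambiguous"


def simulate_population(config: SimulationConfig, condition: str) -> tuple[list[CellRecord], GroundTruth]:
    """Simulate one condition's population of nuclei with ground truth.

    Returns ``n_nuclei`` cell records (6 spots each, 2 per channel, all
    inside the nucleus) and the matching :class:`GroundTruth`.  Fixed
    ``config.seed`` reproduces the population bit-identically.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    template = config._template()
    threshold = 2.0 * config.spot_radius
    children = np.random.SeedSequence(config.seed).spawn(config.n_nuclei)
    records: list[CellRecord] = []
    truth = GroundTruth(config=config.to_dict(), condition=condition)

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        radius = float(np.clip(
            rng.normal(config.nucleus_radius_mean, config.nucleus_radius_sd),
            config.radius_floor, None))
        center = np.array([radius + 1.0, radius + 1.0, radius + 1.0])
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        spots: list[Spot] = []
        allele_truth: list[int] = []
        truth_nucleus = {"nucleus_id": f"{condition}_{i:04d}", "radius": radius,
                         "center": center.tolist(), "alleles": []}
        for a, sign in enumerate((+1.0, -1.0)):
            anchor = center + sign * 0.5 * radius * axis
            rot = _random_rotation(rng)
            decompacted = bool(rng.random() < config.frac_decompacted)
            pos = {}
            for locus, ch in LOCUS_CHANNEL.items():
                offset = template[locus] + _uniform_in_ball(rng, config.sz_radii[locus])[0]
                pos[ch] = anchor + rot @ offset
            pos = _enforce_state(pos, decompacted, threshold)
            if condition == "activated" and config.activation_shift > 0:
                pos = _apply_activation_shift(pos, config.activation_pair,
                                              config.activation_shift)
            state = _state_of(pos, threshold)
            truth_nucleus["alleles"].append({
                "state": state,
                "decompacted_drawn": decompacted,
                "positions": {ch: p.tolist() for ch, p in pos.items()},
            })
            for ch in CHANNELS:
                noisy = pos[ch] + rng.normal(0, config.measurement_noise_sd, 3)
                # keep measured centroids inside the nucleus envelope
                v = noisy - center
                r_v = np.linalg.norm(v)
                if r_v > radius:
                    noisy = center + v * (radius / r_v) * 0.999
                spots.append(Spot(channel=ch, position=noisy, radius=config.spot_radius))
                allele_truth.append(a)
        rec = CellRecord(
            nucleus_id=truth_nucleus["nucleus_id"],
            species=config.species,
            condition=condition,
            geometry=NucleusGeometry(center=center, radius=radius),
            spots=spots,
            allele_truth=allele_truth,
        )
        records.append(rec)
        truth.nuclei.append(truth_nucleus)
    return records, truth


def sample_confined_triples(centers: np.ndarray, radii, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Distance triples from loci drawn uniformly in three spheres.

    `centers` is (3, k) for loci in order (r, g, b), k = 2 or 3; returns
    an (n, 3) array of distances in survival-zone pair order (rg, rb, gb).
    Used as the known-truth input for survival-zone recovery checks.
    """
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if centers.shape[0] != 3 or radii.shape != (3,):
        raise ValueError("need 3 centers and 3 radii (loci r, g, b)")
    k = centers.shape[1]
    pts = np.empty((n, 3, k))
    for j in range(3):
        v = rng.normal(size=(n, k))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        u = rng.random(n)[:, None] ** (1.0 / k)
        pts[:, j, :] = centers[j] + radii[j] * v * u
    d_rg = np.linalg.norm(pts[:, 0] - pts[:, 1], axis=1)
    d_rb = np.linalg.norm(pts[:, 0] - pts[:, 2], axis=1)
    d_gb = np.linalg.norm(pts[:, 1] - pts[:, 2], axis=1)
    return np.column_stack([d_rg, d_rb, d_gb])


# ---------------------------------------------------------------------------
# image rendering and minimal spot detection


def render_image(record: CellRecord, config: SimulationConfig,
                 shape: tuple[int, int, int] | None = None,
                 noise_sd: float = 0.0, poisson: bool = False,
                 rng: np.random.Generator | None = None):
    """Render a cell as a 3-channel (class I, II, III) 3D intensity stack.

    Each spot becomes an anisotropy-aware Gaussian blob (σ = spot radius,
    in μm, identical in physical space on every axis) at its physical
    position.  Axis order is (z, y, x) per channel.  Returns
    ``(stack, origin)`` where `origin` is the physical position of the
    corner of voxel (0,0,0); a detected position plus `origin` is in the
    record's coordinate frame.

    Raises a size error if a caller-supplied `shape` cannot contain the
    nucleus.
    """
    vs = np.asarray(config.voxel_size, dtype=float)  # (x, y, z)
    geom = record.geometry
    pad = 3.0 * config.spot_radius + 0.5
    extent = 2 * (geom.radius + pad)
    needed = np.ceil(extent / vs).astype(int)  # (nx, ny, nz)
    if shape is None:
        shape = (int(needed[2]), int(needed[1]), int(needed[0]))  # (z, y, x)
    else:
        have = np.array([shape[2], shape[1], shape[0]])
        if np.any(have * vs < 2 * geom.radius):
            raise ValueError(
                f"volume of shape {shape} (physical {have * vs} μm) is too "
                f"small for a nucleus of radius {geom.radius} μm")
    origin = geom.center - 0.5 * np.array([shape[2], shape[1], shape[0]]) * vs
    nz, ny, nx = shape
    zc = (np.arange(nz) + 0.5) * vs[2] + origin[2]
    yc = (np.arange(ny) + 0.5) * vs[1] + origin[1]
    xc = (np.arange(nx) + 0.5) * vs[0] + origin[0]
    stack = np.zeros((3, nz, ny, nx), dtype=np.float32)
    sigma = config.spot_radius
    for s in record.spots:
        ci = CHANNELS.index(s.channel)
        gz = np.exp(-0.5 * ((zc - s.position[2]) / sigma) ** 2)
        gy = np.exp(-0.5 * ((yc - s.position[1]) / sigma) ** 2)
        gx = np.exp(-0.5 * ((xc - s.position[0]) / sigma) ** 2)
        stack[ci] += gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    if poisson or noise_sd > 0:
        rng = rng or np.random.default_rng(config.seed)
        if poisson:
            stack = rng.poisson(stack * 100.0).astype(np.float32) / 100.0
        if noise_sd > 0:
            stack = stack + rng.normal(0, noise_sd, stack.shape).astype(np.float32)
    return stack, origin


def detect_spots(stack: np.ndarray, voxel_size, threshold: float) -> list[Spot]:
    """Minimal blob detector for rendered stacks.

    Per channel: threshold, 26-connected components, intensity-weighted
    centroid mapped to μm (voxel-center convention), and an equivalent-
    sphere radius from the component's voxel volume.  A channel with no
    component above threshold yields no spots (logged, not an error).
    Positions are in the stack frame; add the render origin to compare
    with physical truth.
    """
    import logging

    from scipy import ndimage

    log = logging.getLogger(__name__)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    vs = np.asarray(voxel_size, dtype=float)
    voxel_volume = float(np.prod(vs))
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    spots: list[Spot] = []
    for ci, ch in enumerate(CHANNELS):
        chan = stack[ci]
        mask = chan > threshold
        labels, n = ndimage.label(mask, structure=structure)
        if n == 0:
            log.warning("channel %s: no component above threshold %.3g", ch, threshold)
            continue
        for lbl in range(1, n + 1):
            sel = labels == lbl
            w = np.where(sel, chan, 0.0)
            com = ndimage.center_of_mass(w)  # (z, y, x) fractional indices
            pos = voxel_to_physical((com[2], com[1], com[0]), vs)
            vol = float(sel.sum()) * voxel_volume
            radius = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
            spots.append(Spot(channel=ch, position=pos, radius=max(radius, 1e-6)))
    return spots


def write_population(records: list[CellRecord], truth: GroundTruth,
                     table_path: str | Path, truth_path: str | Path) -> None:
    """Write the spot table (TSV) and ground truth (JSON) side by side."""
    write_spot_table(records, table_path)
    truth.to_json(truth_path)


def write_stack_tiff(stack: np.ndarray, path: str | Path, voxel_size) -> None:
    """Save a rendered stack as a channel-major multi-page TIFF with the
    voxel size recorded in the image metadata."""
    import tifffile

    vs = list(map(float, voxel_size))
    tifffile.imwrite(
        path,
        np.asarray(stack, dtype=np.float32),
        metadata={"axes": "CZYX", "voxel_size_um_xyz": vs},
    )
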