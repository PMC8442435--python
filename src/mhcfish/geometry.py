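"""Normalized radial positions, normalized pair distances, and triangle angles.

Angle/vertex convention
-----------------------
The angle labels follow the figure convention of the study design, which is
the *reverse* of the textbook "angle A opposite side a" rule:

* ``a`` = distance class I – class II, ``A`` = angle at the class III vertex
  (so A is the angle *opposite* side a);
* ``b`` = distance class II – class III, ``B`` = angle at the class I vertex
  (opposite side b);
* ``c`` = distance class I – class III, ``C`` = angle at the class II vertex
  (opposite side c).

Hence numerically each labelled angle *is* opposite its same-letter side,
but the letters name vertices (MHC classes), not sides.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .io_model import CHANNELS, CellRecord, NucleusGeometry, Spot

log = logging.getLogger(__name__)


def radial_position(spot: Spot, geom: NucleusGeometry, tolerance: float = 0.05) -> float:
    """Normalized radial position of a spot: |spot - center| / local radius.

    0 is the nucleus center, 1 the periphery.  For the default spherical
    envelope the local radius is the nucleus radius; for the ellipsoid
    option it is the envelope distance along the center-to-spot ray.
    Values within `tolerance` (relative) above 1 are clipped to 1 (logged);
    farther outside raises.
    """
    if geom.radius <= 0:
        raise ValueError("nucleus radius must be > 0")
    v = spot.position - geom.center
    local_r = geom.local_radius(v)
    d = float(np.linalg.norm(v)) / local_r
    if d > 1.0 + tolerance:
        raise ValueError(
            f"spot at {spot.position} lies {d:.3f} local radii from the center "
            f"(beyond tolerance {tolerance})"
        )
    if d > 1.0:
        log.warning("radial position %.4f clipped to 1", d)
        d = 1.0
    return d


def normalized_pair_distance(s1: Spot, s2: Spot, geom: NucleusGeometry) -> float:
    """Center-to-center 3D distance normalized by the nucleus diameter.

    The diameter is twice the equivalent-sphere radius of that nucleus;
    the normalization makes cells of different sizes comparable.
    """
    if geom.radius <= 0:
        raise ValueError("nucleus diameter must be > 0")
    return float(np.linalg.norm(s1.position - s2.position)) / (2.0 * geom.radius)


def internal_angles(a: float, b: float, c: float, tolerance: float = 1e-9) -> tuple[float, float, float]:
    """Internal angles (degrees) of the triangle with sides a, b, c.

    Returns ``(A, B, C)`` where A is at the class III vertex (opposite
    side a = I–II), B at class I (opposite b = II–III), C at class II
    (opposite c = I–III); see module docstring.  Degenerate triangles with
    a zero side return 0° at the two touching vertices and 180° at the
    third.  Angles are invariant to jointly rescaling a, b, c.
    """
    sides = (a, b, c)
    if any(s < 0 for s in sides):
        raise ValueError(f"negative side length in {sides}")
    s_max = max(sides)
    if s_max == 0:
        raise ValueError("all three sides are zero; angles undefined")
    if s_max > (sum(sides) - s_max) + tolerance * s_max:
        raise ValueError(f"triangle inequality violated for sides a={a}, b={b}, c={c}")

    def angle_opposite(opp: float, s1: float, s2: float) -> float:
        cos_t = (s1 * s1 + s2 * s2 - opp * opp) / (2.0 * s1 * s2)
        return math.degrees(math.acos(min(1.0, max(-1.0, cos_t))))

    if min(sides) == 0:
        # one zero side: two loci coincide.  Convention: 0° at the two
        # touching vertices, 180° at the third (the vertex opposite the
        # zero side), keeping the 180° sum.
        out = [0.0, 0.0, 0.0]
        out[sides.index(0.0)] = 180.0
        return (out[0], out[1], out[2])

    A = angle_opposite(a, b, c)
    B = angle_opposite(b, a, c)
    C = angle_opposite(c, a, b)
    return (A, B, C)


def triangle_metrics(spots: list[Spot], geom: NucleusGeometry) -> dict[str, float]:
    """Normalized distances a, b, c and angles A, B, C for one allele triplet.

    `spots` must contain exactly one spot per channel.
    """
    by_ch = {s.channel: s for s in spots}
    if sorted(by_ch) != sorted(CHANNELS) or len(spots) != 3:
        raise ValueError("triangle_metrics needs exactly one spot per channel")
    a = normalized_pair_distance(by_ch["classI"], by_ch["classII"], geom)
    b = normalized_pair_distance(by_ch["classII"], by_ch["classIII"], geom)
    c = normalized_pair_distance(by_ch["classI"], by_ch["classIII"], geom)
    A, B, C = internal_angles(a, b, c, tolerance=1e-6)
    return {"a": a, "b": b, "c": c, "A": A, "B": B, "C": C}


def radial_positions_table(records: list[CellRecord], tolerance: float = 0.05):
    """Tidy per-spot radial positions: one row per spot with labels."""
    import pandas as pd

    rows = []
    for rec in records:
        for s in rec.spots:
            rows.append(
                {
                    "nucleus_id": rec.nucleus_id,
                    "species": rec.species,
                    "condition": rec.condition,
                    "channel": s.channel,
                    "radial": radial_position(s, rec.geometry, tolerance=tolerance),
                }
            )
    return pd.DataFrame(rows)
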