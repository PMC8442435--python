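"""Allele pairing, compaction classification, nucleus patterns, chi-squared tests.

Each nucleus carries two alleles of the MHC, each marked by three FISH
spots (class I, II, III).  The six spots are paired into two triplets,
each triplet is classified as compacted (C) or decompacted (D) from its
physical pairwise distances against the spot-radius threshold, and per
condition the C-C / C-D / D-D nucleus patterns are counted and tested
against the independent-equiprobable null (25% / 50% / 25%).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_model import CHANNELS, CellRecord, Spot

log = logging.getLogger(__name__)

COMPACTED = "C"
DECOMPACTED = "D"
AMBIGUOUS = "ambiguous"


@dataclass
class Allele:
    """One allele: a triplet of spots (one per channel) and its state."""

    spots: dict[str, Spot]
    state: str = AMBIGUOUS

    def __post_init__(self):
        if sorted(self.spots) != sorted(CHANNELS):
            raise ValueError("an allele needs exactly one spot per channel")

    def pairwise_distances(self) -> dict[tuple[str, str], float]:
        out = {}
        for c1, c2 in itertools.combinations(CHANNELS, 2):
            out[(c1, c2)] = float(
                np.linalg.norm(self.spots[c1].position - self.spots[c2].position)
            )
        return out


@dataclass
class PatternCounts:
    """C-C / C-D / D-D nucleus counts for one condition, with exclusions."""

    n_CC: int = 0
    n_CD: int = 0
    n_DD: int = 0
    n_excluded: int = 0
    species: str = ""
    condition: str = ""
    exclusion_reasons: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.n_CC + self.n_CD + self.n_DD + self.n_excluded

    def as_array(self) -> np.ndarray:
        return np.array([self.n_CC, self.n_CD, self.n_DD])


class PairingRejection(Exception):
    """A nucleus whose two alleles cannot be clearly differentiated."""

    def __init__(self, reason_code: str, message: str):
        self.reason_code = reason_code
        super().__init__(message)


def _partitions(by_ch: dict[str, list[Spot]]):
    """The 4 distinct one-spot-per-channel partitions into two triplets.

    Fixing spot 0 of class I in the first triplet removes the triplet-swap
    symmetry; the 2 x 2 choices for class II and III give 4 partitions.
    """
    s1 = by_ch["classI"]
    s2 = by_ch["classII"]
    s3 = by_ch["classIII"]
    for j, k in itertools.product((0, 1), repeat=2):
        t1 = {"classI": s1[0], "classII": s2[j], "classIII": s3[k]}
        t2 = {"classI": s1[1], "classII": s2[1 - j], "classIII": s3[1 - k]}
        yield t1, t2


def _partition_score(t1: dict[str, Spot], t2: dict[str, Spot]) -> float:
    """Total within-triplet pairwise distance over both triplets."""
    score = 0.0
    for trip in (t1, t2):
        for c1, c2 in itertools.combinations(CHANNELS, 2):
            score += float(np.linalg.norm(trip[c1].position - trip[c2].position))
    return score


def pair_spots(record: CellRecord, separability_margin: float = 0.2) -> tuple[Allele, Allele]:
    """Pair the six spots of a nucleus into its two alleles.

    Among the 4 distinct one-per-channel partitions into two triplets,
    the one minimizing the total within-triplet pairwise distance wins.
    If the best and second-best scores differ by less than
    `separability_margin` (relative to the best score) the nucleus is
    rejected as not clearly differentiated.

    Raises
    ------
    PairingRejection
        reason ``missing_spots`` when any channel does not have exactly
        2 spots; reason ``not_separable`` when the margin rule fails.
    """
    by_ch = record.spots_by_channel()
    bad = {ch: len(s) for ch, s in by_ch.items() if len(s) != 2}
    if bad:
        raise PairingRejection(
            "missing_spots",
            f"nucleus {record.nucleus_id}: channels with != 2 spots: {bad}",
        )
    scored = sorted(
        ((_partition_score(t1, t2), t1, t2) for t1, t2 in _partitions(by_ch)),
        key=lambda t: t[0],
    )
    best, second = scored[0][0], scored[1][0]
    if best <= 0 or (second - best) / best < separability_margin:
        raise PairingRejection(
            "not_separable",
            f"nucleus {record.nucleus_id}: best partitions score {best:.4g} vs "
            f"{second:.4g}; alleles not clearly differentiated",
        )
    return Allele(spots=scored[0][1]), Allele(spots=scored[0][2])


def classify_allele(allele: Allele, rule: str = "pairwise") -> str:
    """Classify an allele as compacted (C), decompacted (D), or ambiguous.

    Two loci count as *separated* when their center-to-center distance is
    at least the pair threshold.  With ``rule="pairwise"`` (default) the
    threshold for each pair is r_i + r_j, the sum of the two spot radii
    (which reduces to 2r when all radii are equal); ``rule="global2r"``
    uses 2 x the mean spot radius for every pair.

    State D when every pair is separated; C when no pair is separated
    (all distances strictly below threshold); otherwise ``ambiguous``
    (default handling: excluded from pattern counts, logged).  The
    ``majority`` rule instead assigns the state of the majority of the
    three pairs, never returning ambiguous.
    """
    dists = allele.pairwise_distances()
    majority = rule == "majority"
    radii = {ch: allele.spots[ch].radius for ch in CHANNELS}
    if any(r is None or not np.isfinite(r) for r in radii.values()):
        raise ValueError("classify_allele requires a radius on every spot")
    if rule == "global2r":
        thr = {pair: 2.0 * float(np.mean(list(radii.values()))) for pair in dists}
    else:
        thr = {(c1, c2): radii[c1] + radii[c2] for (c1, c2) in dists}
    separated = [dists[p] >= thr[p] for p in dists]
    if all(separated):
        return DECOMPACTED
    if not any(separated):
        return COMPACTED
    if majority:
        return DECOMPACTED if sum(separated) >= 2 else COMPACTED
    log.info("allele with mixed pair separations -> ambiguous")
    return AMBIGUOUS


def nucleus_pattern(state1: str, state2: str) -> str:
    """Unordered allele-state pair -> nucleus pattern C-C / C-D / D-D.

    Any ambiguous allele excludes the nucleus (returns ``"excluded"``).
    """
    states = {state1, state2}
    if AMBIGUOUS in states:
        return "excluded"
    if states == {COMPACTED}:
        return "C-C"
    if states == {DECOMPACTED}:
        return "D-D"
    return "C-D"


def count_patterns(
    records: list[CellRecord],
    separability_margin: float = 0.2,
    rule: str = "pairwise",
    species: str = "",
    condition: str = "",
) -> PatternCounts:
    """Run pairing + classification over records and tally nucleus patterns."""
    pc = PatternCounts(species=species, condition=condition)
    for rec in records:
        try:
            a1, a2 = pair_spots(rec, separability_margin=separability_margin)
        except PairingRejection as exc:
            pc.n_excluded += 1
            pc.exclusion_reasons.append(f"{rec.nucleus_id}:{exc.reason_code}")
            continue
        pattern = nucleus_pattern(classify_allele(a1, rule), classify_allele(a2, rule))
        if pattern == "C-C":
            pc.n_CC += 1
        elif pattern == "C-D":
            pc.n_CD += 1
        elif pattern == "D-D":
            pc.n_DD += 1
        else:
            pc.n_excluded += 1
            pc.exclusion_reasons.append(f"{rec.nucleus_id}:ambiguous_allele")
    return pc


def theoretical_pattern_probs() -> tuple[float, float, float]:
    """(P_CC, P_CD, P_DD) under independent equiprobable allele states.

    Enumerating the four equally likely ordered state pairs (CC, CD, DC,
    DD) gives 25% C-C, 50% C-D, 25% D-D.
    """
    outcomes = list(itertools.product((COMPACTED, DECOMPACTED), repeat=2))
    p = 1.0 / len(outcomes)
    p_cc = sum(p for o in outcomes if o == (COMPACTED, COMPACTED))
    p_dd = sum(p for o in outcomes if o == (DECOMPACTED, DECOMPACTED))
    p_cd = 1.0 - p_cc - p_dd
    return (p_cc, p_cd, p_dd)


def chisq_given_probs(counts, probs) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of `counts` against given probabilities.

    Returns (chi2, df, p) with df = k - 1 and no continuity correction.
    """
    counts = np.asarray(counts, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("counts must be non-negative with positive sum")
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("probabilities must sum to 1")
    expected = counts.sum() * probs
    if np.any(expected == 0):
        raise ValueError("an expected count is 0; test undefined")
    chi2, p = stats.chisquare(counts, f_exp=expected)
    return float(chi2), counts.size - 1, float(p)


def compare_conditions(resting: PatternCounts, activated: PatternCounts) -> tuple[float, int, float]:
    """Pearson chi-squared on the 3x2 pattern-by-condition contingency table."""
    table = np.vstack([resting.as_array(), activated.as_array()]).T
    if table.sum(axis=0).min() == 0:
        raise ValueError("a condition has 0 classified nuclei")
    if np.any(table.sum(axis=1) == 0):
        raise ValueError("a pattern row is all zero; collapse it before testing")
    res = stats.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq < 5):
        log.warning("expected counts below 5; chi-squared approximation is weak")
    return float(res.statistic), int(res.dof), float(res.pvalue)
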