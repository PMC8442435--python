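"""Cumulative-frequency analysis of radial positions and distances.

Implements the analytic random-placement null for radial positions —
for points uniform in a sphere the normalized radial distance d has
CDF P(X < d) = d**3 on [0, 1] — and the two-sample comparisons used to
contrast genes, species and activation states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class DistanceSample:
    """A named sample of dimensionless measurements (radials or distances)."""

    values: np.ndarray
    species: str = ""
    condition: str = ""
    measure: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be 1-D")
        if np.any(v < 0):
            raise ValueError("distance/radial values must be non-negative")
        self.values = v


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    n_x: int
    n_y: int
    method: str


def empirical_cdf(sample: DistanceSample | np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Right-continuous empirical CDF of `sample` evaluated on `grid`.

    CDF(g) = fraction of values <= g; CDF at or beyond the sample maximum
    is exactly 1.
    """
    values = sample.values if isinstance(sample, DistanceSample) else np.asarray(sample, float)
    if values.size == 0:
        raise ValueError("empirical_cdf of an empty sample")
    grid = np.asarray(grid, dtype=float)
    return np.searchsorted(np.sort(values), grid, side="right") / values.size


def random_radial_cdf(d):
    """Analytic CDF of the radial position under uniform placement: d**3.

    Accepts scalars or arrays in [0, 1].
    """
    d = np.asarray(d, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("radial position d must lie in [0, 1]")
    out = d**3
    return float(out) if out.ndim == 0 else out


def compare_samples(x: DistanceSample, y: DistanceSample, method: str = "student") -> TestResult:
    """Two-sided two-sample comparison of the raw measurement values.

    Methods: ``student`` (pooled-variance t, the default), ``welch``
    (unequal variances), ``ks`` (two-sample Kolmogorov–Smirnov as a
    distribution-shape alternative).
    """
    xv, yv = x.values, y.values
    if xv.size < 2 or yv.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if method == "student":
        res = stats.ttest_ind(xv, yv, equal_var=True)
    elif method == "welch":
        res = stats.ttest_ind(xv, yv, equal_var=False)
    elif method == "ks":
        res = stats.ks_2samp(xv, yv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_x=int(xv.size),
        n_y=int(yv.size),
        method=method,
    )


def holm_correction(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; raw p-values by default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def plot_cumulative(samples: list[DistanceSample], path, with_null: bool = False,
                    title: str = "") -> None:
    """Cumulative-frequency plot of one or more samples, optionally with
    the d³ random-placement null overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.linspace(0, max(1.0, max(float(s.values.max()) for s in samples)), 256)
    fig, ax = plt.subplots(figsize=(5, 4))
    for s in samples:
        label = " ".join(t for t in (s.measure, s.species, s.condition) if t)
        ax.plot(grid, empirical_cdf(s, grid), label=label or None, drawstyle="steps-post")
    if with_null:
        null_grid = np.linspace(0, 1, 256)
        ax.plot(null_grid, random_radial_cdf(null_grid), "k--", label="random (d³)")
    ax.set_xlabel("normalized position / distance")
    ax.set_ylabel("cumulative frequency")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
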