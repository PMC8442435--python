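"""Gene-to-gene distances and internal angles; activation comparisons.

Pairs each nucleus's six spots into two alleles, computes the
diameter-normalized distances a (I-II), b (II-III), c (I-III) and the
internal angles A (at class III), B (at class I), C (at class II), and
tests each measure between resting and activated cells per species
(Student's t).  Writes results/distances/.
"""

from pathlib import Path

import pandas as pd

from mhcfish.cli import triangle_table
from mhcfish.io_model import read_spot_table
from mhcfish.radial_stats import DistanceSample, compare_samples, plot_cumulative

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "distances"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    df = pd.concat([triangle_table(read_spot_table(p))
                    for p in sorted(DATA.glob("population_*.tsv"))],
                   ignore_index=True)
    df.to_csv(OUT / "triangle_metrics.tsv", sep="\t", index=False)

    print("mean normalized distances / angles per group:")
    print(df.groupby(["species", "condition"])[["a", "b", "c", "A", "B", "C"]]
          .mean().round(3).to_string())

    rows = []
    for species, grp in df.groupby("species"):
        for measure in ("a", "b", "c"):
            by_cond = {c: g[measure].to_numpy() for c, g in grp.groupby("condition")}
            res = compare_samples(
                DistanceSample(by_cond["resting"], species, "resting", measure),
                DistanceSample(by_cond["activated"], species, "activated", measure))
            rows.append({"species": species, "measure": measure,
                         "t": res.statistic, "pvalue": res.pvalue,
                         "n_resting": res.n_x, "n_activated": res.n_y})
            plot_cumulative(
                [DistanceSample(by_cond[c], species, c, measure) for c in by_cond],
                OUT / f"distance_cdf_{species}_{measure}.png",
                title=f"{species}: {measure}")
    tests = pd.DataFrame(rows)
    tests.to_csv(OUT / "distance_tests.tsv", sep="\t", index=False)
    sig = tests[tests.pvalue < 0.01]
    print("\nmeasures changed by activation (p < 0.01):")
    print(sig.to_string(index=False) if len(sig) else "  none")


if __name__ == "__main__":
    main()
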