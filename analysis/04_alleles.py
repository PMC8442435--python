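"""Single-nucleus allele conformation patterns (C-C / C-D / D-D).

Classifies each allele as compacted or decompacted against the
spot-radius threshold, tallies nucleus patterns per species x condition,
tests the resting counts against the theoretical 25/50/25 null, and the
resting-vs-activated pattern distributions against each other.
Writes results/alleles/.
"""

import json
from pathlib import Path

import pandas as pd

from mhcfish import allele_analysis as aa
from mhcfish.io_model import read_spot_table

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "alleles"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts: dict[tuple[str, str], aa.PatternCounts] = {}
    rows = []
    for path in sorted(DATA.glob("population_*.tsv")):
        records = read_spot_table(path)
        species, condition = records[0].species, records[0].condition
        pc = aa.count_patterns(records, species=species, condition=condition)
        counts[(species, condition)] = pc
        chi2, df_, p = aa.chisq_given_probs(pc.as_array(),
                                            aa.theoretical_pattern_probs())
        classified = pc.n_CC + pc.n_CD + pc.n_DD
        rows.append({
            "species": species, "condition": condition,
            "n_CC": pc.n_CC, "n_CD": pc.n_CD, "n_DD": pc.n_DD,
            "n_excluded": pc.n_excluded,
            "pct_CD": round(100 * pc.n_CD / classified, 1),
            "chi2_vs_25_50_25": round(chi2, 3), "pvalue": round(p, 4),
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "pattern_counts.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    comparisons = {}
    for species in {s for s, _ in counts}:
        chi2, df_, p = aa.compare_conditions(counts[(species, "resting")],
                                             counts[(species, "activated")])
        comparisons[species] = {"chi2": chi2, "df": df_, "pvalue": p}
        print(f"\n{species}: resting vs activated pattern distribution: "
              f"chi2={chi2:.2f}, df={df_}, p={p:.2g}")
    (OUT / "condition_comparisons.json").write_text(json.dumps(comparisons, indent=1))


if __name__ == "__main__":
    main()
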