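"""Generate the synthetic study populations.

Builds resting and activated macrophage populations for two species-like
parameter sets (a "pig-like" template with near-equal class I-II and
II-III separations, and a "human-like" template with a shorter class
II-III arm), 75 nuclei per condition, and writes spot tables plus ground
truth under results/data/.
"""

import sys
from pathlib import Path

from mhcfish import synthetic_data as sd

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "data"

SPECIES_TEMPLATES = {
    "pig": dict(
        sz_centers={"r": (0.0, 0.0, 0.0), "g": (0.9, 0.0, 0.0), "b": (0.5, 0.6, 0.0)},
        activation_pair=("classI", "classIII"),  # class I-III decompacts
    ),
    "human": dict(
        # short class II-III arm (b ~ 0.6 x a, c), as in the human complex
        sz_centers={"r": (0.0, 0.0, 0.0), "g": (0.9, 0.0, 0.0), "b": (0.17, 0.52, 0.0)},
        sz_radii={"r": 0.22, "g": 0.22, "b": 0.22},
        activation_pair=("classI", "classII"),  # class I-II decompacts
    ),
}


def main(seed: int = 20240901) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, (species, tweaks) in enumerate(SPECIES_TEMPLATES.items()):
        cfg = sd.SimulationConfig(seed=(seed + i) % 2**31, species=species, **tweaks)
        for condition in sd.CONDITIONS:
            records, truth = sd.simulate_population(cfg, condition)
            table = OUT / f"population_{species}_{condition}.tsv"
            sd.write_population(records, truth, table,
                                OUT / f"truth_{species}_{condition}.json")
            n_spots = sum(len(r.spots) for r in records)
            print(f"{species} {condition}: {len(records)} nuclei, "
                  f"{n_spots} spots -> {table.relative_to(ROOT)}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 20240901)
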