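"""Build the two diet panels and tabulate their molarity ladders.

Seven AA:C molar ratios (0:1 ... 1:10) at 0.5 mol/L sucrose, once with the
built-in equimolar ten-AA mix and once with a synthetic pollen-style mix.
Writes results/diets_<mix>.csv.
"""

from pathlib import Path

from nutrigeo.diet_design import (
    STANDARD_RATIOS,
    build_diet_panel,
    diets_to_frame,
    equimolar_mix,
    load_mix,
    total_bees,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    pollen_style = load_mix(ROOT / "analysis/config/pollen_mix_synthetic.tsv")
    for mix, cages_per_diet in ((equimolar_mix(), 5), (pollen_style, 15)):
        panel = build_diet_panel(STANDARD_RATIOS, sucrose_molarity=0.5, mix=mix)
        frame = diets_to_frame(panel)
        out = RESULTS / f"diets_{mix.name}.csv"
        frame.to_csv(out, index=False)
        n = total_bees(cages_per_diet, 5, len(panel))
        print(f"\n{mix.name} mix: {len(panel)} diets, {cages_per_diet} cages/diet -> {n} bees")
        print(frame.to_string(index=False))
    print("\nThe AA molarity ladder spans 0 to 0.05 mol/L; the 1:10 diet is the")
    print("reference point: 0.5 x 1/10 = 0.05 mol/L total amino acids.")


if __name__ == "__main__":
    main()
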