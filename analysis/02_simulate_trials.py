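"""Simulate two full feeding trials at the study's design sizes.

Agents feed under the closest-distance rule of compromise toward a target of
(0.025 mmol AA, 3.0 mmol C) per bee over 7 days: the equimolar-mix trial with
5 micro-colonies per diet, the pollen-style trial with 15.  Raw tube masses,
evaporation controls and the generating truth go to results/sim_<mix>/.
"""

from pathlib import Path

from nutrigeo.diet_design import equimolar_mix, load_mix
from nutrigeo.synthetic_data import SimConfig, simulate_trial

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    pollen_style = load_mix(ROOT / "analysis/config/pollen_mix_synthetic.tsv")
    for mix, cages, seed in ((equimolar_mix(), 5, 101), (pollen_style, 15, 102)):
        cfg = SimConfig(
            rule="closest_distance",
            mix=mix,
            n_cages_per_diet=cages,
            seed=seed,
        )
        sim = simulate_trial(cfg)
        out = RESULTS / f"sim_{mix.name}"
        out.mkdir(parents=True, exist_ok=True)
        sim.feeding.to_csv(out / "feeding_records.csv", index=False)
        sim.controls.to_csv(out / "controls.csv", index=False)
        sim.truth.to_csv(out / "truth.csv", index=False)
        sim.deaths.to_csv(out / "deaths.csv", index=False)
        n_deaths = int(sim.deaths["n_deaths"].sum()) if len(sim.deaths) else 0
        print(
            f"{mix.name}: {len(sim.feeding)} cage-days over {len(sim.diets)} diets, "
            f"{n_deaths} deaths -> {out.relative_to(ROOT)}/"
        )


if __name__ == "__main__":
    main()
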