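"""Parameter-recovery study: can the pipeline identify the generating rule?

For each rule of compromise, simulates 20 seeded replicate trials at the
benchmark noise level (0.02 g weighing noise, 30 cages/diet) and reports how
often the pipeline ranks the generating rule first and how accurately it
recovers the intake target.  Writes results/rule_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nutrigeo.intake_geometry import RULES
from nutrigeo.synthetic_data import SimConfig, recovery_report, simulate_trial

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

N_REP = 20


def main() -> None:
    rows = []
    for rule in RULES:
        hits, errors, slopes = 0, [], []
        for i in range(N_REP):
            cfg = SimConfig(
                rule=rule, n_cages_per_diet=30, mass_noise_sd=0.02, seed=5_000 + 100 * RULES.index(rule) + i
            )
            rep = recovery_report(simulate_trial(cfg))
            hits += rep.rank1_rule == rule
            errors.append(rep.target_rel_error)
            slopes.append(rep.array.slope)
        rows.append(
            {
                "rule": rule,
                "n_replicates": N_REP,
                "rank1_rate": hits / N_REP,
                "median_target_rel_error": float(np.median(errors)),
                "mean_slope": float(np.mean(slopes)),
            }
        )
        print(
            f"{rule:<18} rank-1 in {hits}/{N_REP}, median target error "
            f"{np.median(errors):.3f}, mean slope {np.mean(slopes):+.3f}"
        )
    pd.DataFrame(rows).to_csv(RESULTS / "rule_recovery.csv", index=False)
    print(
        "\nNote: the no-interaction and closest-distance rules produce nearly\n"
        "identical arrays on carbohydrate-dominated rails, and the equal-distance\n"
        "target is identified only up to the sum of its coordinates; rank-1 rates\n"
        "and target errors should be read with those identifiability limits in mind."
    )


if __name__ == "__main__":
    main()
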