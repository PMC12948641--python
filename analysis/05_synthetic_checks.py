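"""Synthetic-cohort checks: parameter recovery and the dependence effect.

Generates a large cohort under conditional independence at the published
operating points, verifies the generator's rates are recovered, and shows
that independence over-predicts the composite sensitivity relative to the
observed joint behaviour — the predictors in the real cohort must
co-occur more than independence allows.
"""

from pathlib import Path

import pandas as pd

from airwayscore import (
    SyntheticCohortConfig,
    analytic_composite_sensitivity,
    generate,
    recover_parameters,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
N = 20_000
SEED = 42


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    config = SyntheticCohortConfig(n=N, dependence=0.0, seed=SEED)
    recovered = recover_parameters(generate(config))

    rows = []
    for j, name in enumerate(recovered.per_predictor):
        m = recovered.per_predictor[name]
        rows.append(
            {
                "predictor": name,
                "true_sensitivity": config.sensitivities[j],
                "est_sensitivity": m.sensitivity.value,
                "true_specificity": config.specificities[j],
                "est_specificity": m.specificity.value,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "simulation_recovery.csv", index=False, float_format="%.4f")
    print(frame.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

    analytic = analytic_composite_sensitivity()
    observed_joint = 65 / 82
    est = recovered.composite.sensitivity.value
    print(f"\ncomposite sensitivity under conditional independence: "
          f"analytic {analytic:.4f}, simulated {est:.4f} (n={N})")
    print(f"observed joint sensitivity in the study cohort: {observed_joint:.4f}")
    print("independence over-predicts the composite sensitivity: the real "
          "predictors are positively dependent (shared anatomical causes); "
          "the generator's dependence weight exists to emulate that")

    dep = recover_parameters(
        generate(SyntheticCohortConfig(n=N, dependence=0.8, seed=SEED))
    )
    print(f"with dependence=0.8 the simulated composite sensitivity falls to "
          f"{dep.composite.sensitivity.value:.4f}")


if __name__ == "__main__":
    main()
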