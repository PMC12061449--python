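#!/usr/bin/env python
"""Driver-recovery power of the detectors on replicated synthetic scenes.

Experiment 1 plants a single dominant factor (TWI, beta = 2, all other
effects zero) and asks whether the factor detector ranks it first.
Experiment 2 plants only a TWI x Pre_1 interaction (beta = 3) and asks
whether the interaction detector ranks that pair first with the
nonlinear-enhancement category.  Both use the per-attempt colonization
frequency response (events per exposure-year), which conditions away the
wave-arrival-time confound of the raw density response.
"""

from pathlib import Path

from treeline_drivers.experiments import dominant_factor_recovery, interaction_recovery

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    factor = dominant_factor_recovery(n_replicates=20, seed0=0)
    factor.to_csv(RESULTS / "recovery_dominant_factor.csv", index=False)
    print(f"dominant-factor experiment: {factor['recovered'].sum()}/20 replicates "
          f"rank the planted TWI driver first "
          f"(median top q = {factor['top_q'].median():.3f})")

    pair = interaction_recovery(n_replicates=20, seed0=100)
    pair.to_csv(RESULTS / "recovery_interaction.csv", index=False)
    print(f"interaction experiment: {pair['recovered'].sum()}/20 replicates "
          f"rank TWI x Pre_1 first as nonlinear enhancement "
          f"(median top q_ab = {pair['top_q_ab'].median():.3f})")


if __name__ == "__main__":
    main()
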