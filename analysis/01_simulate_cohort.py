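"""Generate the default synthetic biobank-style cohort.

Writes the participant-level cohort CSV plus the generating scenario under
results/.  The scenario mirrors the structure of the real cross-sectional
cohorts this analysis emulates: ages 40-70, ~54% female, 14 medications at
1-20% prevalence (one deliberately below the 1% inclusion threshold), four
continuous cognitive tests sharing a latent-cognition factor, and one
binary prospective-memory test with a ~77% base rate.
"""

import sys
from pathlib import Path

from cogfoot import default_scenario, generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main(n: int = 20_000, seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    spec = default_scenario(n_participants=n, seed=seed)
    spec.save(OUT / "scenario.yaml")
    cohort = generate_cohort(spec)
    cohort.to_csv(OUT / "cohort.csv")
    prev = cohort.exposures().mean().sort_values(ascending=False)
    print(f"cohort: {cohort.n} participants, {len(prev)} medications")
    print("exposure prevalence (top 5):")
    print(prev.head().to_string(float_format="%.3f"))
    missing = cohort.data[cohort.outcome_cols].isna().mean()
    print("outcome missingness:")
    print(missing.to_string(float_format="%.3f"))


if __name__ == "__main__":
    n = int(sys.argv[1]) if len(sys.argv) > 1 else 20_000
    seed = int(sys.argv[2]) if len(sys.argv) > 2 else 1
    main(n, seed)
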