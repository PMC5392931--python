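#!/usr/bin/env python
"""Monte-Carlo recovery of the permeability through the full pipeline.

Generates 200 synthetic chemostat observations (diffusion mechanism,
true permeability log-uniform in 0.03-3 m/h, triplicates, 5%
multiplicative measurement noise), averages replicates, and re-estimates
the permeability via speciation + deconvolution + flux inversion.
Writes results/recovery.csv and prints the error summary.
"""

import argparse
from pathlib import Path

from ammoflux import recovery_study

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n", type=int, default=200)
    args = parser.parse_args()

    study = recovery_study(n_observations=args.n, noise_cv=0.05, seed=args.seed)
    OUT.mkdir(exist_ok=True)
    study.to_csv(OUT / "recovery.csv", index=False)
    finite = study[study["feasible"]]
    print(
        f"{len(finite)}/{len(study)} observations feasible; "
        f"median |P_hat/P - 1| = {study['rel_error'].median():.1%}, "
        f"90th percentile = {study['rel_error'].quantile(0.9):.1%}"
    )
    print(
        "recovery error is set by the cytosol/EC NH3 ratio, not by the "
        "permeability itself: conditions with a small relative gradient "
        "(ratio near 1) propagate measurement noise into the difference."
    )


if __name__ == "__main__":
    main()
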