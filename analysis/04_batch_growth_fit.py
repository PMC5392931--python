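#!/usr/bin/env python
"""Batch permeability from micro-titer growth curves (synthetic plates).

The batch assay's raw growth-rate points exist only as a figure, so
this analysis runs on synthetic plates generated with the reported
batch-fit permeability (P = 0.0115 m/h): duplicate wells over a
two-fold (NH4)2SO4 dose ladder at initial pH 5/6/7, OD read every
0.25 h, growth capped at mu_max = 0.21 1/h, 10% well-to-well rate
noise.  Growth rates are extracted by sliding-window log-linear
regression and the permeability is re-fit by least squares through the
origin in the linear region.

Writes results/batch_fit.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ammoflux import (
    SyntheticConfig,
    TransportParams,
    fit_permeability_from_growth,
    growth_rate_from_od,
    simulate_microtiter,
)
from ammoflux.speciation import nh3_fraction

OUT = Path(__file__).resolve().parents[1] / "results"
P_TRUE = 0.0115  # m/h, the reported batch estimate


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    config = SyntheticConfig(true_permeability=P_TRUE, noise_cv=0.10, seed=args.seed)
    curves, truth = simulate_microtiter(config, mu_max=0.21)
    records = []
    for curve in curves:
        fit = growth_rate_from_od(curve)
        records.append(
            dict(
                well_id=curve.well_id, pH=curve.ph_initial,
                NHX_mM=curve.nhx_dose_mM,
                nh3_mM=curve.nhx_dose_mM * nh3_fraction(curve.ph_initial),
                mu_1ph=fit.mu, window_r2=fit.r_squared,
            )
        )
    wells = pd.DataFrame(records)
    fit = fit_permeability_from_growth(
        wells[["nh3_mM", "mu_1ph"]], TransportParams(mu_max=0.21)
    )
    OUT.mkdir(exist_ok=True)
    wells.assign(in_linear_region=list(fit.selected)).to_csv(
        OUT / "batch_fit.csv", index=False
    )
    print(wells.head(8).to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(
        f"\nfit over {fit.n_points} linear-region wells: "
        f"P = {fit.permeability:.4f} m/h (truth {P_TRUE}), "
        f"slope = {fit.slope:.3f} L/mmol/h, R^2 = {fit.r_squared:.3f}"
    )
    print(
        "recovered within "
        f"{abs(fit.permeability / P_TRUE - 1):.1%} of the generating value; "
        "two orders of magnitude below the bilayer literature value "
        "(1.728 m/h), as the neglected cytosolic NH3 makes the batch "
        "estimate a lower limit."
    )


if __name__ == "__main__":
    main()
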