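"""Derivation of the generator's calibration constants.

PLACEMENT_GAIN and REPULSION_FACTOR in equicatch.synthetic_data were
fixed with this pilot. The placement-intensity mechanism is attenuated
by two effects: base repulsion flattens the realised resource density
relative to the target intensity, and the catchment median decile is a
smoothed proxy for deprivation at the base. The pilot measures, over
seeded replicates of the standard recovery scenario:

* mean fitted slope (bias against the target true_slope),
* empirical sd of the slope vs the mean OLS standard error (a ratio
  near 1 means OLS inference on generated data is honest),
* CI coverage of true_slope and the fraction of p < 0.05.

Run, from the repository root:

    python scripts/calibrate_slope.py [--reps 100]

The shipped constants were chosen so that at true_slope = -0.20 the mean
estimate is within 0.05 of the target with >= 90% CI coverage, and at
true_slope = 0 the rejection rate is ~5%. Findings from the wider search
(not rerun here): without repulsion, spatially correlated catchment-size
noise inflates the slope's sampling variance ~1.3x over the OLS SE,
breaking coverage and type-I error; shrinking the deprivation
correlation range makes it worse because small catchments then carry
noisy extreme median deciles exactly where ln(population) is low. Hard
repulsion (0.6) plus heavy-tailed iid unit populations (noise_sd = 2.0)
restores a ratio ~1.0, at the price of a larger gain (2.95) to undo the
repulsion-induced attenuation.
"""

import argparse

import numpy as np

from equicatch.aggregate import summarize
from equicatch.catchment import assign_units
from equicatch.equity_stats import fit_loglinear
from equicatch.synthetic_data import generate, recovery_config


def measure(true_slope: float, reps: int) -> dict:
    ests, ses, cover, sig = [], [], 0, 0
    for seed in range(reps):
        cfg = recovery_config(seed, true_slope)
        units, resources, _ = generate(cfg)
        assignment = assign_units(units, resources)
        summaries = summarize(units, assignment, resources)
        est = fit_loglinear(summaries, ["median_decile"]).predictors["median_decile"]
        ests.append(est.coef)
        ses.append(est.se)
        cover += est.ci_low <= true_slope <= est.ci_high
        sig += est.p_value < 0.05
    return {
        "true_slope": true_slope,
        "mean": float(np.mean(ests)),
        "emp_sd": float(np.std(ests)),
        "mean_se": float(np.mean(ses)),
        "ratio": float(np.std(ests) / np.mean(ses)),
        "coverage": cover / reps,
        "reject_rate": sig / reps,
    }


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    parser.add_argument("--reps", type=int, default=100)
    args = parser.parse_args()
    for beta in (-0.20, 0.0):
        m = measure(beta, args.reps)
        print(
            f"true_slope={m['true_slope']:+.2f}: mean={m['mean']:+.4f} "
            f"emp_sd={m['emp_sd']:.4f} mean_se={m['mean_se']:.4f} "
            f"ratio={m['ratio']:.2f} coverage={m['coverage']:.2f} "
            f"reject_rate={m['reject_rate']:.2f}"
        )


if __name__ == "__main__":
    main()
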