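"""Fit the seven candidate log-log models per mouthpart response, select by
AIC, and parameterize the allometric power functions.

Reads the specimen table from 01_simulate_data.py (or any CSV with the same
columns) and writes results/model_selection.csv (candidates sorted by AIC,
best flagged) and results/power_function_coefficients.csv (per-family
intercepts and IT scaling coefficients, natural-log scale).
"""

import argparse

from beeallometry import pipeline as pl


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--specimens", default="results/synthetic_inputs/specimens.csv")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    config = pl.PipelineConfig(specimens_csv=args.specimens, seed=args.seed,
                               outdir=args.outdir)
    paths = pl.run_fit(config)
    cand = pl.read_report(paths["candidates"])
    for response, block in cand.groupby("response"):
        best = block[block["selected"]].iloc[0]
        print(f"{response}: best model '{best['model']}' "
              f"(AIC {best['aic']:.2f}, adj R^2 {best['adj_r2']:.3f}, "
              f"n={best['n']})")
    coeffs = pl.read_report(paths["coefficients"])
    print("\npower-function coefficients (ln scale):")
    print(coeffs.to_string(index=False,
                           float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
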