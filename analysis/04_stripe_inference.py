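"""Threshold sweep of the stripe-versus-rest R1 comparison with
surrogate permutation inference.

Runs the full analysis on a desk-scale effect-calibrated cohort: residualize
R1 within V2 (mean centring plus curvature regression), define thin/thick
ROIs at z in {0, 0.5, ..., 4.5}, compute the pooled stripe-versus-rest
statistics, and test each against ROIs rebuilt from variogram-matched
surrogate activation maps. Writes the sweep table, permutation JSON, and a
figure of both statistics with significance stars and the null band.
"""

import argparse
from pathlib import Path

from v2qstripes.cohort import CohortConfig, paper_effect_mode
from v2qstripes.pipeline import RunConfig, run_full_analysis


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/stripe_inference"))
    ap.add_argument("--n-perm", type=int, default=1000)
    args = ap.parse_args()

    # desk-scale geometry keeps thousands of surrogate rebuilds tractable
    cohort = paper_effect_mode(
        CohortConfig(
            patch_width_mm=24.0,
            patch_height_mm=12.0,
            spacing_mm=0.8,
            seed=args.seed,
        )
    )
    cfg = RunConfig(
        cohort=cohort,
        n_permutations=args.n_perm,
        seed=args.seed,
        out_dir=str(args.out),
    )
    out = run_full_analysis(cfg)
    sweep = out["sweep"]
    cols = ["threshold", "d_thin", "d_thick", "p_thin", "p_thick", "stars_thin", "stars_thick"]
    print(sweep[cols].round(5).to_string(index=False))
    row = sweep[sweep.threshold == 2.0].iloc[0] if (sweep.threshold == 2.0).any() else sweep.iloc[4]
    print(f"\nnear z~2: pooled d_thin={row.d_thin:.5f} 1/s, d_thick={row.d_thick:.5f} 1/s "
          f"(both negative: thin/thick R1 below the pale-containing surround)")
    print(f"report bundle in {args.out}")


if __name__ == "__main__":
    main()
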