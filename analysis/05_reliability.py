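"""Between-session reliability of activation maps with a spatial null.

Simulates two independent sessions of the color-contrast mapping for one
hemisphere (shared stripe effect, independent noise), correlates them
within V2 (Spearman), and evaluates significance against variogram-matched
surrogates of the second session. A control comparison correlates the color
session with an independent disparity session, which should not exceed the
spatial null.
"""

import argparse
from pathlib import Path

import pandas as pd

from v2qstripes.cohort import CohortConfig, generate_activation_maps, generate_cohort
from v2qstripes.stripestats import reliability_correlation
from v2qstripes.surrogates import SurrogateGenerator


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/reliability"))
    ap.add_argument("--n-perm", type=int, default=1000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = CohortConfig(
        n_subjects=1, hemispheres_per_subject=1,
        patch_width_mm=16.0, patch_height_mm=8.0, spacing_mm=0.8,
        seed=args.seed,
    )
    h = generate_cohort(cfg).hemispheres[0]
    sessions = [
        generate_activation_maps(h.patch, h.stripes, cfg.effect_z,
                                 cfg.noise_corr_length_mm, cfg.z_noise_sd, seed=args.seed + k)
        for k in (10, 20)
    ]
    gen = SurrogateGenerator(h.patch.pairwise_dist())

    rows = []
    for label, m1, m2 in [
        ("color s1 vs color s2", sessions[0][0], sessions[1][0]),
        ("disparity s1 vs disparity s2", sessions[0][1], sessions[1][1]),
        ("color s1 vs disparity s2", sessions[0][0], sessions[1][1]),
    ]:
        res = reliability_correlation(m1, m2, h.patch.v2_mask, surrogate_gen=gen,
                                      n=args.n_perm, seed=args.seed)
        rows.append({"comparison": label, "spearman_r": res.r,
                     "p_corrected": res.p_corrected, "k": res.k, "n": res.n})
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "reliability.csv", index=False)
    print(df.round(4).to_string(index=False))
    print("(same-contrast sessions correlate; the cross-contrast control "
          "stays within the spatial null, as interdigitated stripes imply)")
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
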