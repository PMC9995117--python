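"""Recover eccentricity phase maps from simulated traveling-wave runs.

Simulates noisy phase-encoded runs in both sweep directions on a synthetic
patch with a known eccentricity ramp, runs the preprocessing chain (percent
signal change, discrete-cosine high-pass, quarter-cycle discard), combines
the opposite-direction Fourier coefficients to cancel the hemodynamic delay,
and builds the foveal exclusion mask from the recovered phase. Writes phase
recovery errors and mask coverage under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from v2qstripes import (
    generate_patch,
    generate_retino_timeseries,
    preprocess_timeseries,
    fourier_coefficient,
    combine_directions,
    foveal_exclusion_mask,
)

PERIOD, TR = 32.0, 2.0


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/retinotopy"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    patch = generate_patch(16.0, 8.0, 0.4)
    # eccentricity phase ramps across the patch width through one full cycle
    x = patch.vertex_coords[:, 0]
    phase_true = 2 * np.pi * x / x.max() - np.pi

    rows = []
    for noise_sd in (0.0, 0.5, 1.0):
        runs = {}
        for direction in ("forward", "reverse"):
            ts = generate_retino_timeseries(
                patch, phase_true, PERIOD, TR, hemo_delay_s=5.0,
                noise_sd=noise_sd, drift_psc=3.0, direction=direction,
                seed=args.seed if direction == "forward" else args.seed + 1,
            )
            pre = preprocess_timeseries(ts, TR, PERIOD)
            drop_s = (ts.shape[-1] - pre.shape[-1]) * TR
            runs[direction] = fourier_coefficient(pre, 1 / PERIOD, TR, t_start_s=drop_s)
        pm = combine_directions(runs["forward"], runs["reverse"])
        err = np.abs(np.angle(np.exp(1j * (pm.phase - phase_true))))
        mask = foveal_exclusion_mask(pm.phase, phase_origin=-np.pi)
        rows.append(
            {
                "noise_sd": noise_sd,
                "median_phase_error_rad": float(np.median(err)),
                "p95_phase_error_rad": float(np.quantile(err, 0.95)),
                "median_coherence": float(np.median(pm.coherence)),
                "retained_fraction": float(mask.mean()),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "phase_recovery.csv", index=False)
    print(df.round(4).to_string(index=False))
    print("(retained_fraction ~ 2/3: the inner third of the eccentricity "
          "cycle is excluded as foveal)")
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
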