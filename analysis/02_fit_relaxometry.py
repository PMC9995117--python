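"""Forward-simulate the multi-echo FLASH protocol and refit the parameter maps.

Checks the relaxometry chain on a synthetic hemisphere: simulate dual-contrast
multi-echo signals (with a smooth B1+ inhomogeneity field and thermal noise),
fit R2* with the shared-decay log-linear model, recover R1 and the amplitude
through the dual-flip-angle approximation with B1+ correction, and calibrate
proton density against a designated white-matter-like vertex set. Also writes
the documented error grid of the rational R1 approximation against exact
Ernst inversion.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from v2qstripes.cohort import CohortConfig, generate_cohort, generate_flash_signals
from v2qstripes.patch import gaussian_random_field
from v2qstripes.relaxometry import FlashProtocol, fit_qmri, flash_signal, dfa_fit


def approximation_error_grid(protocol: FlashProtocol) -> pd.DataFrame:
    rows = []
    for r1_true in np.arange(0.3, 1.2001, 0.05):
        s_pd = flash_signal(1.0, r1_true, 0.0, protocol.nominal_fa_rad[0], protocol.tr_s[0], 0.0)
        s_t1 = flash_signal(1.0, r1_true, 0.0, protocol.nominal_fa_rad[1], protocol.tr_s[1], 0.0)

        def mismatch(r1):
            f_pd = flash_signal(1.0, r1, 0.0, protocol.nominal_fa_rad[0], protocol.tr_s[0], 0.0)
            f_t1 = flash_signal(1.0, r1, 0.0, protocol.nominal_fa_rad[1], protocol.tr_s[1], 0.0)
            return f_t1 / f_pd - s_t1 / s_pd

        exact = brentq(mismatch, 1e-4, 20.0, xtol=1e-12)
        approx, _, _ = dfa_fit(np.array([[s_pd], [s_t1]]), protocol)
        rows.append(
            {
                "r1_true": round(float(r1_true), 3),
                "r1_exact_inversion": exact,
                "r1_rational_approx": float(approx[0]),
                "rel_error_pct": 100 * abs(approx[0] - exact) / exact,
            }
        )
    return pd.DataFrame(rows)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/relaxometry"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = CohortConfig(n_subjects=1, hemispheres_per_subject=1, seed=args.seed)
    h = generate_cohort(cfg).hemispheres[0]
    rng = np.random.default_rng(args.seed)
    b1 = 1.0 + gaussian_random_field(h.patch.grid_shape, cfg.spacing_mm, 8.0, rng, sd=0.05)
    noiseless = generate_flash_signals(h.qmri, b1_efficiency=b1, noise_sd=0.0)
    snr = 50.0  # relative to the mean first-echo PDw signal
    signals = generate_flash_signals(
        h.qmri, b1_efficiency=b1,
        noise_sd=float(noiseless.signal[0, 0].mean()) / snr, seed=args.seed,
    )
    wm_like = rng.random(h.patch.n_vertices) < 0.25
    maps = fit_qmri(signals, wm_mask=wm_like)

    ok = maps.valid
    err_r1 = 100 * np.abs(maps.r1[ok] - h.qmri.r1[ok]) / h.qmri.r1[ok]
    err_r2s = 100 * np.abs(maps.r2s[ok] - h.qmri.r2s[ok]) / h.qmri.r2s[ok]
    summary = pd.DataFrame(
        {
            "metric": ["median |R1 error| %", "median |R2* error| %",
                       "mean PD over WM-like mask (pu)", "invalid locations"],
            "value": [float(np.median(err_r1)), float(np.median(err_r2s)),
                      float(np.mean(maps.pd[wm_like])), maps.n_invalid],
        }
    )
    summary.to_csv(args.out / "fit_summary.csv", index=False)
    grid = approximation_error_grid(signals.protocol)
    grid.to_csv(args.out / "dfa_error_grid.csv", index=False)

    print(summary.to_string(index=False))
    print(f"\nDFA rational-approximation error vs exact inversion: "
          f"{grid.rel_error_pct.min():.2f}% (R1=1.2) to {grid.rel_error_pct.max():.2f}% (R1=0.3)")
    print(f"tables written to {args.out}")


if __name__ == "__main__":
    main()
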