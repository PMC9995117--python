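"""Calibration and validation experiments used by the analysis scripts,
the acceptance checks, and the test suite.

These run the library end to end on synthetic cohorts at desk scale:
effect-recovery replicates, noise-calibration checks, and the type-I-error
calibration of the full surrogate-permutation pipeline.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cohort import CohortConfig, generate_cohort, paper_effect_mode
from .stripestats import (
    observed_pooled_statistics,
    permutation_test,
    prepare_hemisphere_maps,
)
from .surrogates import SurrogateGenerator


def recover_paper_effects(
    n_cohorts: int = 20,
    threshold: float = 1.96,
    base_seed: int = 0,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Pooled stripe-statistic recovery on effect-calibrated cohorts.

    Each replicate simulates a default cohort (4 subjects x 2 hemispheres)
    with stripe R1 offsets calibrated so the ideal-label statistics equal
    the reference contrasts, defines ROIs at the given z threshold from the
    noisy activation maps, and records the pooled thin and thick statistics.
    """
    base = config if config is not None else CohortConfig()
    rows = []
    for i in range(n_cohorts):
        cfg = paper_effect_mode(replace(base, seed=int(base_seed + i)))
        cohort = generate_cohort(cfg)
        hemis = prepare_hemisphere_maps(cohort, qparam="r1")
        d_thin, d_thick = observed_pooled_statistics(hemis, threshold)
        rows.append({"cohort": i, "d_thin": d_thin, "d_thick": d_thick})
    return pd.DataFrame(rows)


def r1_cv_experiment(n_seeds: int = 10, base_seed: int = 0, config: CohortConfig | None = None):
    """Coefficient of variation (%) of simulated V2 R1, one hemisphere per seed."""
    base = config if config is not None else CohortConfig()
    cvs = []
    for i in range(n_seeds):
        cfg = replace(base, n_subjects=1, hemispheres_per_subject=1, seed=int(base_seed + i))
        cohort = generate_cohort(cfg)
        h = cohort.hemispheres[0]
        r1 = h.qmri.r1[h.patch.v2_mask]
        cvs.append(100.0 * r1.std() / r1.mean())
    return float(np.mean(cvs)), cvs


def null_cohort_config(seed: int = 0) -> CohortConfig:
    """Small null cohort (no stripe effects) for pipeline calibration runs.

    Desk-scale geometry: a single hemisphere on a 16 x 8 mm patch at 0.8 mm
    spacing (231 vertices) keeps hundreds of full permutation tests cheap
    while retaining two full stripe cycles.
    """
    return CohortConfig(
        n_subjects=1,
        hemispheres_per_subject=1,
        patch_width_mm=16.0,
        patch_height_mm=8.0,
        spacing_mm=0.8,
        effect_z=0.0,
        delta_thin=0.0,
        delta_thick=0.0,
        seed=seed,
    )


def type_i_error_experiment(
    n_cohorts: int = 500,
    n_perm: int = 200,
    threshold: float = 1.0,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> dict:
    """False-positive rate of the full surrogate-permutation pipeline.

    Simulates null cohorts (no stripe effect in either the activation or the
    R1 maps), runs the complete test (residualize, surrogate ROIs, pooled
    statistic, 3-sigma-corrected p) and reports the fraction of cohorts
    rejected at ``alpha`` for each statistic. The threshold z=1 keeps null
    ROIs comfortably non-empty on the small patch.
    """
    surrogate_gen = None
    rej_thin = rej_thick = n_valid = 0
    for i in range(n_cohorts):
        cfg = null_cohort_config(seed=int(base_seed + i))
        cohort = generate_cohort(cfg)
        if surrogate_gen is None:
            surrogate_gen = SurrogateGenerator(cohort.hemispheres[0].patch.pairwise_dist())
        hemis = prepare_hemisphere_maps(cohort, qparam="r1", surrogate_gen=surrogate_gen)
        res = permutation_test(
            hemis, threshold, n=n_perm, seed=int(base_seed + 100_000 + i), sided="one"
        )
        p_thin, p_thick = res["thin"].p_corrected, res["thick"].p_corrected
        if np.isnan(p_thin) or np.isnan(p_thick):
            continue
        n_valid += 1
        rej_thin += p_thin < alpha
        rej_thick += p_thick < alpha
    return {
        "n_valid": n_valid,
        "rate_thin": rej_thin / max(n_valid, 1),
        "rate_thick": rej_thick / max(n_valid, 1),
        "alpha": alpha,
    }
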