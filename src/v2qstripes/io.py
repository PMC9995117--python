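"""File interfaces: GIFTI surfaces and per-vertex maps, NIfTI volumes, CSV.

Synthetic cohorts are written one directory per subject/hemisphere with the
mesh as a GIFTI surface, per-vertex maps as GIFTI functional files (or a CSV
fallback), the generator configuration echoed as YAML, and FLASH signals as
a 4D NIfTI echo stack when requested.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import nibabel as nib
import yaml


def save_vertex_map_gifti(path, values: np.ndarray) -> None:
    darr = nib.gifti.GiftiDataArray(
        np.asarray(values, dtype=np.float32), intent="NIFTI_INTENT_NONE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[darr]), str(path))


def load_vertex_map_gifti(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, dtype=float)


def save_surface_gifti(path, coords: np.ndarray, faces: np.ndarray) -> None:
    coords = np.asarray(coords, dtype=np.float32)
    if coords.shape[1] == 2:
        coords = np.column_stack([coords, np.zeros(len(coords), dtype=np.float32)])
    da_c = nib.gifti.GiftiDataArray(coords, intent="NIFTI_INTENT_POINTSET")
    da_f = nib.gifti.GiftiDataArray(
        np.asarray(faces, dtype=np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[da_c, da_f]), str(path))


def load_surface_gifti(path):
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, dtype=float), np.asarray(
        img.darrays[1].data, dtype=int
    )


def save_vertex_map_csv(path, values: np.ndarray, name: str = "value") -> None:
    np.savetxt(path, np.asarray(values, dtype=float), header=name, comments="# ")


def load_vertex_map_csv(path) -> np.ndarray:
    return np.loadtxt(path)


def save_echo_stack_nifti(path, signal: np.ndarray, affine=None) -> None:
    """FLASH signals (2, n_echoes, N) as a 4D NIfTI, echoes stacked last."""
    sig = np.asarray(signal, dtype=np.float32)
    n = sig.shape[-1]
    vol = sig.reshape(2 * sig.shape[1], n).T.reshape(n, 1, 1, -1)
    nib.save(nib.Nifti1Image(vol, affine if affine is not None else np.eye(4)), str(path))


def load_echo_stack_nifti(path, n_echoes: int) -> np.ndarray:
    """Inverse of :func:`save_echo_stack_nifti`; returns (2, n_echoes, N)."""
    vol = np.asarray(nib.load(str(path)).get_fdata())
    n = vol.shape[0]
    return vol.reshape(n, 2 * n_echoes).T.reshape(2, n_echoes, n)


def save_surrogate_ensemble(path_prefix, ensemble) -> None:
    """Compressed array container plus a JSON sidecar (seed, scales, SSE)."""
    import json

    path_prefix = Path(path_prefix)
    np.savez_compressed(path_prefix.with_suffix(".npz"), maps=ensemble.maps)
    sidecar = {
        "seed": repr(ensemble.seed),
        "kernel_scale": np.asarray(ensemble.kernel_scale).tolist(),
        "fit_sse": np.asarray(ensemble.fit_sse).tolist(),
    }
    with open(path_prefix.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)


def load_surrogate_ensemble(path_prefix):
    import json

    from .surrogates import SurrogateEnsemble

    path_prefix = Path(path_prefix)
    maps = np.load(path_prefix.with_suffix(".npz"))["maps"]
    with open(path_prefix.with_suffix(".json")) as fh:
        side = json.load(fh)
    return SurrogateEnsemble(
        maps=maps,
        fit_sse=np.asarray(side["fit_sse"]),
        kernel_scale=np.asarray(side["kernel_scale"]),
        seed=side["seed"],
    )


def write_cohort(cohort, outdir, file_format: str = "gifti") -> Path:
    """Write one directory per subject/hemisphere plus the config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .cohort import config_to_dict

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(cohort.config), fh, sort_keys=True)
    for h in cohort:
        d = outdir / f"sub-{h.subject:02d}" / f"hemi-{h.hemi}"
        d.mkdir(parents=True, exist_ok=True)
        maps = {
            "zcolor": h.z_color,
            "zdisp": h.z_disp,
            "r1": h.qmri.r1,
            "r2s": h.qmri.r2s,
            "pd": h.qmri.pd,
            "curv": h.patch.curvature,
            "labels": h.stripes.labels.astype(float),
        }
        if file_format == "gifti":
            save_surface_gifti(d / "patch.surf.gii", h.patch.vertex_coords, h.patch.faces)
            for name, vals in maps.items():
                save_vertex_map_gifti(d / f"{name}.func.gii", vals)
        elif file_format == "csv":
            np.savetxt(d / "vertices.csv", h.patch.vertex_coords, delimiter=",")
            np.savetxt(d / "faces.csv", h.patch.faces, fmt="%d", delimiter=",")
            for name, vals in maps.items():
                save_vertex_map_csv(d / f"{name}.csv", vals, name)
        else:
            raise ValueError(f"unknown cohort format {file_format!r}")
    return outdir
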