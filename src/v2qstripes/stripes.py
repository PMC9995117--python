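"""Periodic pale-thin-pale-thick stripe geometry.

V2 is tiled by repeating cycles of cytochrome-oxidase stripe types. In
macaque the cycle (center-to-center distance of same-type stripes) is about
4 mm with individual stripe widths 0.7-1.3 mm; in human these dimensions are
roughly doubled, giving the defaults used here: an 8 mm cycle with 2.0 mm
thin and 2.6 mm thick stripes, the remaining width split equally between the
two pale bands of a cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patch import CorticalPatch

PALE, THIN, THICK = 0, 1, 2
LABEL_NAMES = {PALE: "pale", THIN: "thin", THICK: "thick"}


@dataclass
class StripeModel:
    """Ground-truth stripe labels for a synthetic patch.

    ``labels`` holds one integer per vertex (0 pale, 1 thin, 2 thick). The
    label pattern tiles periodically along the axis at ``orientation``
    radians from the patch x axis, in pale-thin-pale-thick order.
    """

    labels: np.ndarray
    cycle_width_mm: float
    thin_width_mm: float
    thick_width_mm: float
    orientation: float = 0.0
    phase_mm: float = 0.0

    @property
    def pale_width_mm(self) -> float:
        return 0.5 * (self.cycle_width_mm - self.thin_width_mm - self.thick_width_mm)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def area_fractions(self, patch: CorticalPatch, mask: np.ndarray | None = None):
        """Area-weighted (pale, thin, thick) fractions over ``mask`` (default V2)."""
        if mask is None:
            mask = patch.v2_mask
        w = patch.vertex_area * mask
        total = w.sum()
        return tuple(float(w[self.labels == lab].sum() / total) for lab in (PALE, THIN, THICK))


def generate_stripe_labels(
    patch: CorticalPatch,
    cycle_width_mm: float = 8.0,
    thin_width_mm: float = 2.0,
    thick_width_mm: float = 2.6,
    orientation: float = 0.0,
    phase_mm: float = 0.0,
) -> StripeModel:
    """Assign stripe labels by position along the stripe axis modulo the cycle.

    Within one cycle the bands are laid out as
    ``pale [0, p) | thin [p, p+t) | pale [p+t, 2p+t) | thick [2p+t, cycle)``
    with ``p`` the shared pale width. Band intervals are half-open, so a
    vertex exactly on a boundary takes the label of the band it starts.
    """
    if cycle_width_mm <= 0:
        raise ValueError("cycle width must be positive")
    if thin_width_mm + thick_width_mm >= cycle_width_mm:
        raise ValueError("thin + thick widths must be smaller than the cycle")
    pale = 0.5 * (cycle_width_mm - thin_width_mm - thick_width_mm)
    u = (
        patch.vertex_coords[:, 0] * np.cos(orientation)
        + patch.vertex_coords[:, 1] * np.sin(orientation)
        - phase_mm
    ) % cycle_width_mm
    labels = np.full(patch.n_vertices, PALE, dtype=np.int8)
    labels[(u >= pale) & (u < pale + thin_width_mm)] = THIN
    labels[u >= 2 * pale + thin_width_mm] = THICK
    return StripeModel(
        labels=labels,
        cycle_width_mm=cycle_width_mm,
        thin_width_mm=thin_width_mm,
        thick_width_mm=thick_width_mm,
        orientation=orientation,
        phase_mm=phase_mm,
    )
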