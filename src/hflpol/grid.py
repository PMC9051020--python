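"""Canonical eccentricity grid and geometric constants shared pipeline-wide."""

from __future__ import annotations

import numpy as np

#: Retinal angular-to-linear conversion (microns per degree of eccentricity).
UM_PER_DEGREE = 320.0

#: Canonical eccentricity grid: 12 points, 0.25 deg to 3.00 deg in 0.25 deg steps.
#: The 0 deg point is excluded (thickness and retardance both vanish there).
CANONICAL_GRID = np.round(np.arange(1, 13) * 0.25, 2)

#: Half-width of the annular averaging band (deg); annuli tile without overlap.
ANNULUS_HALF_WIDTH_DEG = 0.125

#: Meridian labels in canonical order.
MERIDIANS = ("temporal", "superior", "nasal", "inferior")


def is_canonical(grid: np.ndarray) -> bool:
    """True if ``grid`` equals the canonical 12-point eccentricity grid."""
    grid = np.asarray(grid, dtype=float)
    return grid.shape == CANONICAL_GRID.shape and np.allclose(grid, CANONICAL_GRID)
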