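"""The 2-D soil profile grid shared by roots and rootworms.

One representative corn plant is simulated in a vertical soil cross-section
of 76 × 100 cm (row spacing 76 cm × 1 m depth), at 1-cm³ patch resolution.
Horizontal coordinates x ∈ 0..75 wrap at the profile edges (the single root
system stands for the average plant of a uniform field), vertical
coordinates y ∈ 1..100 cm clamp at the surface and at depth.
"""

from __future__ import annotations

import numpy as np

GRID_WIDTH = 76    # x patches, 0..75
GRID_DEPTH = 100   # y patches (depth cm), 1..100
CENTER_X = 38      # horizontal centre of the profile (plant row)
SOWING_DEPTH_CM = 5


def wrap_x(x):
    """Periodic horizontal boundary: leaving one side re-enters the other."""
    return np.mod(x, GRID_WIDTH)


def clamp_y(y):
    """Vertical coordinates clamp to the 1..100 cm profile."""
    return np.clip(y, 1, GRID_DEPTH)
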