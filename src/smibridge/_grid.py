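"""Fixed subpixel coordinate grid.

All FOV-local and global coordinates are maintained on a 1/256-px grid.
With coordinates on this grid, adding or subtracting an integer FOV offset
is exact in float64 (the sum needs at most ~40 significand bits), so the
local <-> global transform round-trips bit for bit and GeoJSON output
reproduces its inputs exactly.  The 2^-9 px quantization is orders of
magnitude below the instrument's optical resolution.
"""

import numpy as np

SUBPIXEL_DENOM = 256.0


def snap(values):
    """Snap coordinates to the 1/256-px grid (returns float64)."""
    return np.round(np.asarray(values, dtype=np.float64) * SUBPIXEL_DENOM) / SUBPIXEL_DENOM
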