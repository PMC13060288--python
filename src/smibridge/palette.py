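"""Deterministic categorical color assignment for cell types and genes."""

from __future__ import annotations

#: fixed 12-color categorical cycle (RGB, 0-255), cycled for >12 labels
CATEGORICAL_12 = (
    (31, 119, 180),
    (255, 127, 14),
    (44, 160, 44),
    (214, 39, 40),
    (148, 103, 189),
    (140, 86, 75),
    (227, 119, 194),
    (127, 127, 127),
    (188, 189, 34),
    (23, 190, 207),
    (174, 199, 232),
    (255, 187, 120),
)


def assign_colors(labels, overrides: dict | None = None) -> dict:
    """Map each label to an RGB triple, assigned by sorted label order.

    *overrides* (label -> (r, g, b)) take precedence; remaining labels get
    the fixed cycle.  Deterministic for any input order.
    """
    overrides = dict(overrides or {})
    out = {}
    i = 0
    for label in sorted({str(l) for l in labels}):
        if label in overrides:
            out[label] = tuple(int(v) for v in overrides[label])
        else:
            out[label] = CATEGORICAL_12[i % len(CATEGORICAL_12)]
            i += 1
    return out
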