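"""Simple built-in pseudotime fallback.

Pseudotime is normally a consumed input computed by a dedicated
trajectory tool; this fallback orders cells along the dominant principal
component, which is adequate when the activation axis carries most of
the variance (as it does for the synthetic populations here).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .containers import EmbeddingState


def fallback_pseudotime(
    e: EmbeddingState,
    orient_by: Optional[np.ndarray] = None,
    activated_label: str = "activated",
) -> np.ndarray:
    """Pseudotime = PC1 coordinate shifted to start at 0.

    When ``orient_by`` (a per-cell timepoint array) is given, the axis
    is flipped if needed so that cells labeled ``activated_label`` have
    the larger mean pseudotime.
    """
    axis = e.coordinates[:, 0].astype(float).copy()
    if orient_by is not None:
        orient_by = np.asarray(orient_by)
        act = axis[orient_by == activated_label]
        rest = axis[orient_by != activated_label]
        if len(act) and len(rest) and act.mean() < rest.mean():
            axis = -axis
    return axis - axis.min()
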