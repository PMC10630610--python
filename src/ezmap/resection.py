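"""Resected/spared labelling from pre/post-operative regional volumes.

A region counts as resected when its post-operative volume dropped by
strictly more than the threshold fraction (default 10%) of the
pre-operative volume.  Raising the threshold can only shrink the
resected set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["label_resected"]

DEFAULT_THRESHOLD = 0.10


def label_resected(volumes: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Label regions resected by the strict >threshold volume-reduction rule.

    ``volumes`` needs columns region_id, volume_pre, volume_post (mm^3).
    Returns the table with added ``resected`` and ``threshold_used``
    columns.  A non-positive pre-operative volume raises, naming the
    region; post-operative growth is allowed (labelled spared).
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be a fraction in [0, 1)")
    required = {"region_id", "volume_pre", "volume_post"}
    missing = required - set(volumes.columns)
    if missing:
        raise ValueError(f"volume table missing columns: {sorted(missing)}")
    if volumes["region_id"].duplicated().any():
        raise ValueError("duplicate region ids in volume table")
    pre = volumes["volume_pre"].to_numpy(dtype=float)
    post = volumes["volume_post"].to_numpy(dtype=float)
    if np.any(post < 0):
        raise ValueError("negative post-operative volume")
    if np.any(pre <= 0):
        bad = volumes["region_id"].iloc[int(np.argmax(pre <= 0))]
        raise ValueError(f"non-positive pre-operative volume for region {bad!r}")
    reduction = (pre - post) / pre
    out = volumes.copy()
    out["resected"] = reduction > threshold
    out["threshold_used"] = threshold
    return out
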