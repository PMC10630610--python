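"""Region parcellation metadata: ids, centroids, tissue class, volumes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RegionParcellation"]

TISSUE_CLASSES = ("grey", "white", "subcortical")


@dataclass
class RegionParcellation:
    """Atlas regions with representative points for contact assignment.

    ``table`` columns: region_id, x, y, z (mm), tissue_class,
    volume_mm3.  Centroids are the default representative points; a
    denser per-region point cloud may be attached for nearest-point
    distances.
    """

    table: pd.DataFrame
    point_clouds: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"region_id", "x", "y", "z", "tissue_class", "volume_mm3"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        ids = self.table["region_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate region ids in parcellation")
        xyz = self.table[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite region centroid")
        bad = set(self.table["tissue_class"]) - set(TISSUE_CLASSES)
        if bad:
            raise ValueError(f"unknown tissue classes: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def region_ids(self) -> list[str]:
        return list(self.table["region_id"])

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def centroids(self) -> dict[str, np.ndarray]:
        return {
            row.region_id: np.array([row.x, row.y, row.z], dtype=float)
            for row in self.table.itertuples()
        }

    def grey_matter_ids(self) -> list[str]:
        t = self.table
        return list(t.loc[t["tissue_class"] == "grey", "region_id"])

    def representative_points(self, region_id: str) -> np.ndarray:
        """Point cloud if attached, else the centroid as a single point."""
        if region_id in self.point_clouds:
            return np.atleast_2d(self.point_clouds[region_id])
        row = self.table.loc[self.table["region_id"] == region_id].iloc[0]
        return np.array([[row["x"], row["y"], row["z"]]], dtype=float)
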