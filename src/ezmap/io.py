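"""Tabular I/O for the analysis formats.

All data are plain CSV with explicit headers; regions and contacts are
identified by string id everywhere, never by position.  Round-trips are
lossless (pandas writes shortest-round-trip float representations).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .ieeg import BAND_NAMES, BandPowerTable
from .parcellation import RegionParcellation

__all__ = [
    "write_connectivity_csv",
    "read_connectivity_csv",
    "write_mask_csv",
    "read_mask_csv",
    "write_parcellation_csv",
    "read_parcellation_csv",
    "write_band_power_csv",
    "read_band_power_csv",
    "write_table",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "write_patient_bundle",
    "read_patient_bundle",
    "write_json_report",
]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# -- connectivity ------------------------------------------------------------


def write_connectivity_csv(cm: ConnectivityMatrix, path: str | Path) -> None:
    """Square CSV with region-id header row and column."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(cm.weights, index=cm.region_ids, columns=cm.region_ids).to_csv(path)


def _read_square(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: header row and column region ids differ")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate region ids")
    return df


def read_connectivity_csv(
    path: str | Path,
    age: float,
    sex: int,
    batch: str,
    mask: np.ndarray | None = None,
    region_order: list[str] | None = None,
    subject_id: str | None = None,
) -> ConnectivityMatrix:
    """Read a square weight matrix; region identity is by id, not position.

    With ``region_order`` given (e.g. the parcellation's order), rows
    and columns are reindexed by id so a permuted file loads
    identically.  Asymmetry raises a schema error naming the cell.
    """
    df = _read_square(path)
    if region_order is not None:
        missing = set(region_order) - set(df.index)
        if missing:
            raise ValueError(f"{path}: regions absent from matrix: {sorted(missing)}")
        df = df.loc[region_order, region_order]
    w = df.to_numpy(dtype=float)
    if not np.allclose(w, w.T):
        i, j = np.argwhere(~np.isclose(w, w.T))[0]
        raise ValueError(
            f"{path}: asymmetric weights at ({df.index[i]}, {df.columns[j]})"
        )
    ids = list(df.index)
    if mask is None:
        mask = w > 0
        np.fill_diagonal(mask, False)
        mask |= mask.T
    return ConnectivityMatrix(
        subject_id=subject_id or Path(path).stem,
        region_ids=ids,
        weights=(w + w.T) / 2.0,
        present_mask=mask,
        age=age,
        sex=sex,
        batch=batch,
    )


def write_mask_csv(mask: np.ndarray, region_ids: list[str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(mask.astype(int), index=region_ids, columns=region_ids).to_csv(path)


def read_mask_csv(path: str | Path, region_order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    df = _read_square(path)
    if region_order is not None:
        df = df.loc[region_order, region_order]
    m = df.to_numpy(dtype=int).astype(bool)
    if not np.array_equal(m, m.T):
        raise ValueError(f"{path}: asymmetric mask")
    return m, list(df.index)


# -- parcellation ------------------------------------------------------------


def write_parcellation_csv(parc: RegionParcellation, path: str | Path) -> None:
    write_table(parc.table, path)


def read_parcellation_csv(path: str | Path) -> RegionParcellation:
    return RegionParcellation(pd.read_csv(path, dtype={"region_id": str}))


# -- band power --------------------------------------------------------------


def write_band_power_csv(bp: BandPowerTable, path: str | Path) -> None:
    """Tidy CSV: unit_id, band, value."""
    long = (
        bp.values.rename_axis("unit_id")
        .reset_index()
        .melt(id_vars="unit_id", var_name="band", value_name="value")
    )
    write_table(long, path)


def read_band_power_csv(path: str | Path) -> BandPowerTable:
    long = pd.read_csv(path, dtype={"unit_id": str, "band": str})
    wide = long.pivot(index="unit_id", columns="band", values="value")
    return BandPowerTable(wide[list(BAND_NAMES)])


# -- time series -------------------------------------------------------------


def write_timeseries_csv(rec, path: str | Path) -> None:
    """Wide CSV (one column per contact) preceded by a '# fs=<Hz>' line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs}\n")
        pd.DataFrame(rec.data.T, columns=rec.contact_ids).to_csv(fh, index=False)


def read_timeseries_csv(path: str | Path):
    from .ieeg import IeegRecording

    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' metadata line")
        fs = float(header.split("=", 1)[1])
        df = pd.read_csv(fh)
    return IeegRecording(list(df.columns), df.to_numpy(dtype=float).T, fs)


# -- patient bundles ---------------------------------------------------------


def write_patient_bundle(bundle, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_connectivity_csv(bundle.connectome, d / "connectome.csv")
    write_mask_csv(
        bundle.connectome.present_mask, bundle.connectome.region_ids, d / "mask.csv"
    )
    write_band_power_csv(bundle.contact_bp, d / "contact_band_power.csv")
    write_table(bundle.contacts, d / "contacts.csv")
    write_table(bundle.volumes, d / "volumes.csv")
    meta = {
        "patient_id": bundle.patient_id,
        "age": bundle.connectome.age,
        "sex": bundle.connectome.sex,
        "batch": bundle.connectome.batch,
        "ilae": bundle.ilae,
        "ez_regions": sorted(bundle.ez_regions),
        "implanted_regions": sorted(bundle.implanted_regions),
        "true_resected": sorted(bundle.true_resected),
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2))


def read_patient_bundle(directory: str | Path):
    from .synthetic import PatientBundle

    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    mask, ids = read_mask_csv(d / "mask.csv")
    cm = read_connectivity_csv(
        d / "connectome.csv",
        age=meta["age"],
        sex=meta["sex"],
        batch=meta["batch"],
        mask=mask,
        region_order=ids,
        subject_id=meta["patient_id"],
    )
    return PatientBundle(
        patient_id=meta["patient_id"],
        connectome=cm,
        contact_bp=read_band_power_csv(d / "contact_band_power.csv"),
        contacts=pd.read_csv(d / "contacts.csv", dtype={"contact_id": str}),
        volumes=pd.read_csv(d / "volumes.csv", dtype={"region_id": str}),
        ez_regions=set(meta["ez_regions"]),
        implanted_regions=set(meta["implanted_regions"]),
        true_resected=set(meta["true_resected"]),
        ilae=meta["ilae"],
    )


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
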