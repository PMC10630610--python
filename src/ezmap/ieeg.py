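"""Interictal iEEG band-power abnormality mapping.

Converts multi-channel interictal recordings into per-region relative
band powers and z-scores them against a normative map:

    z_fkj = (b_fkj - mu_fk) / sigma_fk ,   B_kj = max_f |z_fkj|

with b the relative band power of band f in region k for patient j, and
(mu, sigma) the normative mean and SD for that band/region.  Processing
follows the fixed order: common average reference, Welch power spectral
density, mean band power in five canonical bands (delta 1-4, theta 4-8,
alpha 8-13, beta 13-30, gamma 30-80 Hz), log10 transform, and
normalisation of the five log powers to sum to 1 per contact.  Contacts
are assigned to the closest grey-matter region within 5 mm; regional
band power is the mean over assigned contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps_signal

from .parcellation import RegionParcellation

__all__ = [
    "BAND_EDGES",
    "BAND_NAMES",
    "IeegRecording",
    "BandPowerTable",
    "IeegNormativeMap",
    "IeegRegionalAbnormality",
    "common_average_reference",
    "welch_psd",
    "band_powers",
    "linear_band_fractions",
    "relative_band_power",
    "assign_contacts",
    "regional_band_power",
    "fit_ieeg_normative_map",
    "ieeg_regional_abnormality",
]

# canonical band edges in Hz; interiors non-overlapping, gamma closed at 80
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}
BAND_NAMES = tuple(BAND_EDGES)

MIN_DURATION_S = 70.0
MIN_FS_HZ = 160.0  # Nyquist for the 80 Hz gamma edge

WELCH_SEGMENT_S = 2.0
WELCH_OVERLAP = 0.5


@dataclass
class IeegRecording:
    """Multi-contact time series in microvolts, one row per contact."""

    contact_ids: list[str]
    data: np.ndarray  # (n_contacts, n_samples)
    fs: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.contact_ids) != self.data.shape[0]:
            raise ValueError("contact_ids do not match data rows")
        if len(set(self.contact_ids)) != len(self.contact_ids):
            raise ValueError("duplicate contact ids")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")
        if self.fs < MIN_FS_HZ:
            raise ValueError(
                f"sampling rate {self.fs} Hz below {MIN_FS_HZ} Hz (gamma extends to 80 Hz)"
            )

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class BandPowerTable:
    """Relative band power per unit (contact or region); rows sum to 1."""

    values: pd.DataFrame  # index: unit_id, columns: BAND_NAMES

    def __post_init__(self) -> None:
        v = self.values
        if list(v.columns) != list(BAND_NAMES):
            raise ValueError(f"band columns must be {BAND_NAMES}, got {list(v.columns)}")
        if v.index.duplicated().any():
            raise ValueError("duplicate unit ids in band-power table")
        sums = v.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = sums.index[~np.isclose(sums, 1.0, atol=1e-9)][0]
            raise ValueError(f"band powers of {bad!r} do not sum to 1")

    @property
    def unit_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class IeegNormativeMap:
    """Normative mean/SD of relative band power per band and region."""

    mu: pd.DataFrame  # index region_id, columns bands
    sigma: pd.DataFrame
    n: pd.Series  # samples per region
    degenerate: pd.Series = field(default=None)  # sigma==0 or n<2 anywhere

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = (self.n < 2) | (self.sigma <= 0).any(axis=1)


@dataclass
class IeegRegionalAbnormality:
    """Per-region band z-scores and their max-absolute summary B_kj."""

    z: pd.DataFrame  # index region_id, columns bands
    b: pd.Series  # max_f |z|
    n_excluded: int = 0  # patient regions absent from the normative map

    def score_by_region(self) -> dict[str, float]:
        return {str(k): float(v) for k, v in self.b.items()}


# ---------------------------------------------------------------------------
# signal path


def common_average_reference(rec: IeegRecording) -> IeegRecording:
    """Subtract the across-contact mean at every sample.

    After referencing the cross-contact mean is identically zero; the
    operation is idempotent.  A single contact cannot be referenced.
    """
    if rec.data.shape[0] < 2:
        raise ValueError("common average reference needs at least 2 contacts")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return IeegRecording(list(rec.contact_ids), data, rec.fs)


def welch_psd(rec: IeegRecording) -> tuple[np.ndarray, np.ndarray]:
    """Averaged-periodogram PSD (2 s Hann segments, 50% overlap)."""
    nperseg = int(round(WELCH_SEGMENT_S * rec.fs))
    freqs, psd = sps_signal.welch(
        rec.data,
        fs=rec.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * WELCH_OVERLAP),
        detrend="constant",
        axis=-1,
    )
    return freqs, psd


def _band_mask(freqs: np.ndarray, lo: float, hi: float, closed: bool) -> np.ndarray:
    return (freqs >= lo) & ((freqs <= hi) if closed else (freqs < hi))


def band_powers(rec: IeegRecording, min_duration: float = MIN_DURATION_S) -> pd.DataFrame:
    """Mean PSD per canonical band, per contact (linear units, uV^2/Hz).

    The analysis epoch must be at least 70 s long.
    """
    if rec.duration < min_duration - 1e-9:
        raise ValueError(
            f"recording is {rec.duration:.1f} s; at least {min_duration:.0f} s required"
        )
    freqs, psd = welch_psd(rec)
    cols = {}
    for i, (name, (lo, hi)) in enumerate(BAND_EDGES.items()):
        m = _band_mask(freqs, lo, hi, closed=(i == len(BAND_EDGES) - 1))
        cols[name] = psd[:, m].mean(axis=1)
    return pd.DataFrame(cols, index=rec.contact_ids)


def linear_band_fractions(rec: IeegRecording, **kw) -> pd.DataFrame:
    """Bandwidth-integrated power fractions (linear scale, rows sum to 1)."""
    bp = band_powers(rec, **kw)
    widths = np.array([hi - lo for lo, hi in BAND_EDGES.values()])
    integrated = bp * widths
    return integrated.div(integrated.sum(axis=1), axis=0)


def relative_band_power(rec: IeegRecording, min_duration: float = MIN_DURATION_S) -> BandPowerTable:
    """Per-contact relative band power: log10 band powers normalised to sum 1.

    Raises on non-positive band power or a log-power sum within 1e-9 of
    zero (the normalisation would be undefined), naming the contact.
    """
    bp = band_powers(rec, min_duration=min_duration)
    vals = bp.to_numpy()
    if np.any(vals <= 0):
        bad = bp.index[np.any(vals <= 0, axis=1)][0]
        raise ValueError(f"non-positive band power for contact {bad!r}")
    logs = np.log10(vals)
    sums = logs.sum(axis=1)
    if np.any(np.abs(sums) < 1e-9):
        bad = bp.index[np.abs(sums) < 1e-9][0]
        raise ValueError(f"degenerate log-power sum for contact {bad!r}")
    rel = logs / sums[:, None]
    return BandPowerTable(pd.DataFrame(rel, index=bp.index, columns=list(BAND_NAMES)))


# ---------------------------------------------------------------------------
# spatial assignment and regional aggregation


def assign_contacts(
    contacts: pd.DataFrame,
    parcellation: RegionParcellation,
    radius: float = 5.0,
) -> dict[str, str | None]:
    """Map each contact to the closest grey-matter region within ``radius`` mm.

    ``contacts`` needs columns contact_id, x, y, z.  Distances are to
    region representative points (centroid, or nearest point of an
    attached cloud).  Contacts farther than ``radius`` from every
    grey-matter region are unassigned (None).  Exact distance ties break
    to the lexicographically smaller region id.
    """
    if radius <= 0:
        raise ValueError("assignment radius must be positive")
    grey = parcellation.grey_matter_ids()
    if not grey:
        raise ValueError("parcellation has no grey-matter regions")
    if contacts["contact_id"].duplicated().any():
        raise ValueError("duplicate contact ids")
    region_points = {rid: parcellation.representative_points(rid) for rid in grey}
    out: dict[str, str | None] = {}
    for row in contacts.itertuples():
        p = np.array([row.x, row.y, row.z], dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError(f"non-finite coordinate for contact {row.contact_id!r}")
        best: tuple[float, str] | None = None
        for rid in sorted(grey):
            d = float(np.min(np.linalg.norm(region_points[rid] - p, axis=1)))
            if best is None or d < best[0]:  # ties keep the earlier (smaller) id
                best = (d, rid)
        out[row.contact_id] = best[1] if best[0] < radius else None
    return out


def regional_band_power(
    contact_bp: BandPowerTable, mapping: dict[str, str | None]
) -> BandPowerTable:
    """Mean relative band power over the contacts assigned to each region.

    Unassigned contacts are dropped; regions without contacts are simply
    absent from the output.
    """
    rows = contact_bp.values
    assigned = {c: r for c, r in mapping.items() if r is not None and c in rows.index}
    if not assigned:
        raise ValueError("no assigned contacts with band power")
    grouped = rows.loc[list(assigned)].groupby(pd.Series(assigned), sort=True).mean()
    grouped.index.name = "region_id"
    return BandPowerTable(grouped)


# ---------------------------------------------------------------------------
# normative map and abnormality


def fit_ieeg_normative_map(samples: list[BandPowerTable]) -> IeegNormativeMap:
    """Normative mean and SD of relative band power per band and region.

    Each sample is one normative participant's regional band-power
    table; mean/SD are taken across the participants that cover a
    region.  Regions covered by fewer than two participants, or with
    zero spread in any band, are flagged degenerate (flags carried
    downstream, not raised here).
    """
    if not samples:
        raise ValueError("empty normative cohort")
    long = pd.concat([s.values for s in samples], axis=0)
    g = long.groupby(level=0, sort=True)
    mu = g.mean()
    sigma = g.std(ddof=1).fillna(0.0)
    n = g.size()
    return IeegNormativeMap(mu=mu, sigma=sigma, n=n)


def ieeg_regional_abnormality(
    patient_bp: BandPowerTable, nmap: IeegNormativeMap
) -> IeegRegionalAbnormality:
    """z-score a patient's regional band powers against the normative map.

    B_kj is the maximum absolute z across the five bands.  Patient
    regions absent from the map are excluded (counted); a patient region
    that is present but degenerate in the map raises, naming the region.
    """
    pv = patient_bp.values
    present = pv.index.intersection(nmap.mu.index)
    excluded = len(pv.index) - len(present)
    if len(present) == 0:
        raise ValueError("no patient regions present in the normative map")
    degen = nmap.degenerate.loc[present]
    if degen.any():
        raise ValueError(
            f"normative map degenerate for region {degen.index[degen][0]!r}"
        )
    z = (pv.loc[present] - nmap.mu.loc[present]) / nmap.sigma.loc[present]
    b = z.abs().max(axis=1)
    return IeegRegionalAbnormality(z=z, b=b, n_excluded=excluded)
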