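"""Synthetic cohort generator.

Emulates the study conditions the analysis assumes: a healthy-control
connectome cohort split over two scanner batches with age and sex
effects, patients carrying focal FA reductions on connections incident
to a small epileptogenic region set (EZ), a normative iEEG band-power
cohort, electrode implantations with a 5 mm contact-assignment radius
(plus a small fraction of stray contacts), resections that cover or
miss the EZ, and seizure outcomes tied to EZ coverage.

All randomness derives from ``SimulationConfig.seed`` through
independent, tagged generator streams, so identical configs reproduce
identical cohorts element for element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .ieeg import BAND_EDGES, BAND_NAMES, BandPowerTable, IeegRecording
from .parcellation import RegionParcellation

__all__ = [
    "SimulationConfig",
    "ControlPopulationParams",
    "PatientBundle",
    "generate_parcellation",
    "generate_connection_mask",
    "generate_control_population_params",
    "generate_control_connectomes",
    "generate_patient",
    "generate_ieeg_normative_cohort",
    "generate_timeseries_for_bandpower",
    "sample_ez",
]

# stream tags keeping the per-op generators independent
_T_PARC, _T_MASK, _T_POP, _T_CONTROLS, _T_NORMAT, _T_PATIENT, _T_EZ = range(7)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters (defaults = study conditions).

    The study cohort sizes are the defaults where stated: 96 healthy
    controls in two scanner batches, 43 patients, a 234-participant
    normative iEEG cohort, 5 mm contact-assignment radius.  The synthetic
    atlas defaults to 32 regions for desk-scale runs; the study's 128
    regions are one config away.
    """

    n_regions: int = 32
    n_controls: int = 96
    n_patients: int = 43
    # per-batch (additive shift, noise scale); two scanning protocols
    batch_effects: dict = field(
        default_factory=lambda: {"site_a": (0.0, 1.0), "site_b": (0.05, 1.1)}
    )
    age_range: tuple[float, float] = (18.0, 60.0)
    base_fa_range: tuple[float, float] = (0.3, 0.6)
    age_slope_sd: float = 0.002  # FA per year
    sex_effect_sd: float = 0.02  # FA
    noise_sd: float = 0.05  # FA
    connection_density: float = 0.35
    ez_size: int = 3
    ez_effect: float = 2.5  # in control-SD units, applied as FA reduction
    ieeg_band_profile: tuple[float, ...] = (0.30, 0.25, 0.20, 0.15, 0.10)
    band_spread: float = 0.02
    contact_jitter: float = 0.005
    ez_band_shift: float = 2.5  # in normative-SD units
    n_ieeg_normative: int = 234
    coverage_fraction: float = 0.3
    assignment_radius: float = 5.0
    contacts_per_region: int = 2
    stray_contact_fraction: float = 0.05
    resect_hit_prob: float = 0.8
    resection_extra: int = 2  # penumbra regions beyond the EZ core
    penumbra_weight: float = 0.5  # effect fraction in the penumbra
    outcome_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_regions": self.n_regions,
            "n_controls": self.n_controls,
            "n_patients": self.n_patients,
            "ez_size": self.ez_size,
            "n_ieeg_normative": self.n_ieeg_normative,
            "contacts_per_region": self.contacts_per_region,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_regions < 4:
            raise ValueError("n_regions must be at least 4")
        probs = {
            "coverage_fraction": self.coverage_fraction,
            "stray_contact_fraction": self.stray_contact_fraction,
            "resect_hit_prob": self.resect_hit_prob,
            "outcome_noise": self.outcome_noise,
            "connection_density": self.connection_density,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.assignment_radius <= 0:
            raise ValueError("assignment_radius must be positive")
        if len(self.ieeg_band_profile) != len(BAND_NAMES):
            raise ValueError("ieeg_band_profile must have five entries")
        if len(self.batch_effects) < 1:
            raise ValueError("at least one scanner batch required")

    def rng(self, *tags: int) -> np.random.Generator:
        return np.random.default_rng([self.seed & 0x7FFFFFFF, *tags])

    @property
    def batch_labels(self) -> list[str]:
        return sorted(self.batch_effects)


def _region_ids(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"roi_{i:0{width}d}" for i in range(n)]


def generate_parcellation(config: SimulationConfig) -> RegionParcellation:
    """Random grey-matter parcellation in a 100 mm box.

    Region centroids are kept at least 3x the assignment radius apart so
    that contact-to-region assignment is unambiguous by construction.
    """
    rng = config.rng(_T_PARC)
    n = config.n_regions
    min_sep = 3.0 * config.assignment_radius
    pts: list[np.ndarray] = []
    while len(pts) < n:
        cand = rng.uniform(0.0, 100.0, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
    xyz = np.array(pts)
    volumes = rng.uniform(2000.0, 8000.0, size=n)  # mm^3, cortical-ROI scale
    table = pd.DataFrame(
        {
            "region_id": _region_ids(n),
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "tissue_class": "grey",
            "volume_mm3": volumes,
        }
    )
    return RegionParcellation(table)


def generate_connection_mask(config: SimulationConfig) -> np.ndarray:
    """Fixed atlas-present connection mask (symmetric, zero diagonal).

    Every region keeps at least one present connection so regional
    averaging is defined everywhere.
    """
    rng = config.rng(_T_MASK)
    n = config.n_regions
    m = np.zeros((n, n), dtype=bool)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < config.connection_density
    m[iu[keep], ju[keep]] = True
    m |= m.T
    for k in np.flatnonzero(m.sum(axis=1) == 0):
        other = (k + 1) % n
        m[k, other] = m[other, k] = True
    return m


@dataclass(frozen=True)
class ControlPopulationParams:
    """Per-connection latent population parameters, fixed per config."""

    base: np.ndarray  # baseline FA per present edge
    beta_age: np.ndarray  # FA/year
    beta_sex: np.ndarray  # FA
    batch_shift: dict  # label -> per-edge additive shift
    batch_scale: dict  # label -> per-edge multiplicative noise scale
    age_ref: float

    def pooled_noise_sd(self, config: SimulationConfig, batch_sizes: dict) -> np.ndarray:
        """Per-edge control SD implied by the batch mixture."""
        total = sum(batch_sizes.values())
        var = np.zeros_like(self.base)
        for lab, n_b in batch_sizes.items():
            var += (n_b / total) * (self.batch_scale[lab] * config.noise_sd) ** 2
        return np.sqrt(var)


def generate_control_population_params(
    config: SimulationConfig, mask: np.ndarray
) -> ControlPopulationParams:
    rng = config.rng(_T_POP)
    iu, ju = np.triu_indices(config.n_regions, k=1)
    n_edges = int(mask[iu, ju].sum())
    base = rng.uniform(*config.base_fa_range, size=n_edges)
    beta_age = rng.normal(0.0, config.age_slope_sd, size=n_edges)
    beta_sex = rng.normal(0.0, config.sex_effect_sd, size=n_edges)
    shift, scale = {}, {}
    for lab in config.batch_labels:
        s, sc = config.batch_effects[lab]
        shift[lab] = rng.normal(s, 0.005, size=n_edges)
        scale[lab] = np.clip(rng.normal(sc, 0.05, size=n_edges), 0.2, None)
    return ControlPopulationParams(
        base=base,
        beta_age=beta_age,
        beta_sex=beta_sex,
        batch_shift=shift,
        batch_scale=scale,
        age_ref=float(np.mean(config.age_range)),
    )


def _edges_to_matrix(edges: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n = mask.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = mask[iu, ju]
    w = np.zeros((n, n))
    w[iu[keep], ju[keep]] = edges
    w += w.T
    return w


def _simulate_connectome(
    config: SimulationConfig,
    params: ControlPopulationParams,
    mask: np.ndarray,
    subject_id: str,
    age: float,
    sex: int,
    batch: str,
    rng: np.random.Generator,
) -> ConnectivityMatrix:
    eps = rng.normal(0.0, config.noise_sd, size=params.base.size)
    edges = (
        params.base
        + params.beta_age * (age - params.age_ref)
        + params.beta_sex * sex
        + params.batch_shift[batch]
        + params.batch_scale[batch] * eps
    )
    np.clip(edges, 0.0, 1.0, out=edges)
    return ConnectivityMatrix(
        subject_id=subject_id,
        region_ids=_region_ids(config.n_regions),
        weights=_edges_to_matrix(edges, mask),
        present_mask=mask.copy(),
        age=age,
        sex=sex,
        batch=batch,
    )


def control_batch_sizes(config: SimulationConfig) -> dict:
    """Controls split as evenly as possible over the configured batches."""
    labels = config.batch_labels
    n, k = config.n_controls, len(labels)
    return {lab: n // k + (1 if i < n % k else 0) for i, lab in enumerate(labels)}


def generate_control_connectomes(
    config: SimulationConfig,
    parcellation: RegionParcellation,
    mask: np.ndarray | None = None,
    params: ControlPopulationParams | None = None,
) -> list[ConnectivityMatrix]:
    """Healthy-control connectome cohort with age/sex/batch structure."""
    if parcellation.n_regions != config.n_regions:
        raise ValueError("parcellation size does not match config")
    mask = generate_connection_mask(config) if mask is None else mask
    params = (
        generate_control_population_params(config, mask) if params is None else params
    )
    rng = config.rng(_T_CONTROLS)
    sizes = control_batch_sizes(config)
    out = []
    i = 0
    for lab in config.batch_labels:
        for _ in range(sizes[lab]):
            age = float(rng.uniform(*config.age_range))
            sex = int(rng.integers(0, 2))
            out.append(
                _simulate_connectome(
                    config, params, mask, f"control_{i:03d}", age, sex, lab, rng
                )
            )
            i += 1
    return out


def sample_ez(
    config: SimulationConfig, parcellation: RegionParcellation, patient_index: int
) -> set[str]:
    """Draw a patient's epileptogenic region set (size ez_size)."""
    rng = config.rng(_T_EZ, patient_index)
    ids = parcellation.region_ids
    return {str(r) for r in rng.choice(ids, size=config.ez_size, replace=False)}


@dataclass
class PatientBundle:
    """Everything generated for one synthetic patient."""

    patient_id: str
    connectome: ConnectivityMatrix
    contact_bp: BandPowerTable  # per-contact relative band power
    contacts: pd.DataFrame  # contact_id, x, y, z
    volumes: pd.DataFrame  # region_id, volume_pre, volume_post
    ez_regions: set[str]
    implanted_regions: set[str]
    true_resected: set[str]
    ilae: int

    @property
    def seizure_free(self) -> bool:
        return self.ilae <= 2


def generate_patient(
    config: SimulationConfig,
    parcellation: RegionParcellation,
    ez_regions: set[str],
    mask: np.ndarray | None = None,
    params: ControlPopulationParams | None = None,
    patient_index: int = 0,
) -> PatientBundle:
    """One synthetic patient: connectome, iEEG, implantation, resection, outcome.

    The pathological zone is the EZ core plus a penumbra of
    ``resection_extra`` surrounding regions carrying the effect at
    ``penumbra_weight`` strength.  Connections incident to an affected
    region are reduced by (region weight x ez_effect) control SDs, and
    affected regions' band powers are shifted by (weight x
    ez_band_shift) normative SDs.  The implantation always samples the
    pathological zone plus surrounding coverage; the resection removes
    the whole zone (EZ + penumbra) with probability resect_hit_prob,
    otherwise an off-target set of the same size.  The outcome is
    seizure-free iff the EZ is fully resected, flipped with probability
    outcome_noise.
    """
    if not ez_regions:
        raise ValueError("ez_regions must be non-empty")
    ids = parcellation.region_ids
    unknown = set(ez_regions) - set(ids)
    if unknown:
        raise ValueError(f"ez regions not in parcellation: {sorted(unknown)}")
    mask = generate_connection_mask(config) if mask is None else mask
    params = (
        generate_control_population_params(config, mask) if params is None else params
    )
    rng = config.rng(_T_PATIENT, patient_index)
    pid = f"patient_{patient_index:03d}"
    age = float(rng.uniform(*config.age_range))
    sex = int(rng.integers(0, 2))
    batch = config.batch_labels[0]
    cm = _simulate_connectome(config, params, mask, pid, age, sex, batch, rng)

    # pathological zone: EZ core (weight 1) + penumbra (penumbra_weight)
    non_ez = [r for r in ids if r not in ez_regions]
    n_extra = min(config.resection_extra, len(non_ez))
    penumbra = (
        {str(r) for r in rng.choice(non_ez, size=n_extra, replace=False)}
        if n_extra
        else set()
    )
    weight = {r: 1.0 for r in ez_regions}
    weight.update({r: config.penumbra_weight for r in penumbra})

    # focal FA reduction on connections incident to affected regions, in
    # units of the pooled control SD so downstream z-scores centre near
    # -(weight x ez_effect)
    pooled_sd = params.pooled_noise_sd(config, control_batch_sizes(config))
    iu, ju = np.triu_indices(config.n_regions, k=1)
    keep = mask[iu, ju]
    w_region = np.array([weight.get(r, 0.0) for r in ids])
    edge_w = np.maximum(w_region[iu[keep]], w_region[ju[keep]])
    edges = cm.weights[iu[keep], ju[keep]].copy()
    edges -= edge_w * config.ez_effect * pooled_sd
    np.clip(edges, 0.0, 1.0, out=edges)
    cm = ConnectivityMatrix(
        subject_id=pid,
        region_ids=ids,
        weights=_edges_to_matrix(edges, mask),
        present_mask=mask.copy(),
        age=age,
        sex=sex,
        batch=batch,
    )

    # resection: removes the pathological zone or an off-target set
    hit = bool(rng.random() < config.resect_hit_prob)
    if hit:
        resected = set(ez_regions) | penumbra
    else:
        candidates = [r for r in non_ez if r not in penumbra]
        size = min(config.ez_size + n_extra, len(candidates))
        resected = {str(r) for r in rng.choice(candidates, size=size, replace=False)}

    # implantation: pathological zone always sampled, resected regions
    # w.h.p., then fill to the coverage target
    n_target = max(int(math.ceil(config.coverage_fraction * len(ids))), config.ez_size + 2)
    implanted = set(ez_regions) | penumbra
    for r in sorted(resected):
        if rng.random() < 0.9:
            implanted.add(r)
    remaining = [r for r in ids if r not in implanted]
    n_fill = max(0, n_target - len(implanted))
    if n_fill:
        implanted |= {
            str(r)
            for r in rng.choice(remaining, size=min(n_fill, len(remaining)), replace=False)
        }

    # contacts within the assignment radius of their region centroid,
    # plus strays beyond the radius of every region
    centroids = parcellation.centroids()
    rows = []
    ci = 0
    for r in sorted(implanted):
        for _ in range(config.contacts_per_region):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            offset = direction * rng.uniform(0.0, 0.8 * config.assignment_radius)
            x, y, z = centroids[r] + offset
            rows.append((f"{pid}_c{ci:03d}", x, y, z, r))
            ci += 1
    n_stray = int(round(config.stray_contact_fraction * len(rows)))
    for s in range(n_stray):
        x, y, z = rng.uniform(-600.0, -500.0, size=3)  # far outside the atlas box
        rows.append((f"{pid}_c{ci:03d}", x, y, z, None))
        ci += 1
    contacts = pd.DataFrame(rows, columns=["contact_id", "x", "y", "z", "true_region"])

    # per-contact relative band power with EZ band shift (delta band)
    profile = np.asarray(config.ieeg_band_profile, dtype=float)
    bp_rows, bp_ids = [], []
    for row in contacts.itertuples():
        latent = profile + rng.normal(0.0, config.band_spread, size=profile.size)
        if row.true_region is not None:
            shift = weight.get(row.true_region, 0.0) * config.ez_band_shift
            latent[0] += shift * config.band_spread
        latent = latent + rng.normal(0.0, config.contact_jitter, size=profile.size)
        latent = np.clip(latent, 1e-6, None)
        bp_rows.append(latent / latent.sum())
        bp_ids.append(row.contact_id)
    contact_bp = BandPowerTable(
        pd.DataFrame(bp_rows, index=bp_ids, columns=list(BAND_NAMES))
    )

    # volumes implementing the >10% reduction rule downstream
    vol_pre = parcellation.table.set_index("region_id")["volume_mm3"]
    post = []
    for r in ids:
        if r in resected:
            post.append(vol_pre[r] * rng.uniform(0.2, 0.6))
        else:
            post.append(vol_pre[r] * rng.uniform(0.97, 1.02))
    volumes = pd.DataFrame(
        {"region_id": ids, "volume_pre": vol_pre.loc[ids].to_numpy(), "volume_post": post}
    )

    sf = ez_regions <= resected
    if rng.random() < config.outcome_noise:
        sf = not sf
    ilae = int(rng.integers(1, 3)) if sf else int(rng.integers(3, 6))
    return PatientBundle(
        patient_id=pid,
        connectome=cm,
        contact_bp=contact_bp,
        contacts=contacts[["contact_id", "x", "y", "z"]].copy(),
        volumes=volumes,
        ez_regions=set(ez_regions),
        implanted_regions=implanted,
        true_resected=resected,
        ilae=ilae,
    )


def generate_ieeg_normative_cohort(
    config: SimulationConfig, parcellation: RegionParcellation
) -> list[BandPowerTable]:
    """Normative iEEG cohort: per-participant regional relative band power.

    Each participant covers every region (full coverage keeps the
    downstream map defined everywhere); each 5-vector is a noisy draw
    around the configured band profile, normalised to sum to 1.
    """
    if config.n_ieeg_normative < 2:
        raise ValueError("normative cohort needs at least 2 participants")
    rng = config.rng(_T_NORMAT)
    profile = np.asarray(config.ieeg_band_profile, dtype=float)
    ids = parcellation.region_ids
    out = []
    for _ in range(config.n_ieeg_normative):
        latent = profile[None, :] + rng.normal(
            0.0, config.band_spread, size=(len(ids), profile.size)
        )
        latent = np.clip(latent, 1e-6, None)
        rel = latent / latent.sum(axis=1, keepdims=True)
        out.append(BandPowerTable(pd.DataFrame(rel, index=ids, columns=list(BAND_NAMES))))
    return out


def generate_timeseries_for_bandpower(
    target_band_fractions,
    fs: float = 256.0,
    duration: float = 70.0,
    n_contacts: int = 4,
    seed: int = 0,
    noise_floor: float = 1e-3,
    total_power: float = 1e6,
) -> IeegRecording:
    """Band-limited noise whose integrated band-power fractions are known.

    Each contact is an independent sum of spectrally shaped white-noise
    components, one per canonical band, scaled so the linear
    (bandwidth-integrated) power proportions match
    ``target_band_fractions``, plus a small broadband floor
    (``noise_floor`` of the total) keeping every band power positive.
    The overall variance is ``total_power`` (uV^2), large enough that
    log10 band powers stay positive downstream.
    """
    fracs = np.asarray(target_band_fractions, dtype=float)
    if fracs.size != len(BAND_NAMES) or np.any(fracs < 0) or fracs.sum() <= 0:
        raise ValueError("target_band_fractions must be five non-negative values")
    fracs = fracs / fracs.sum()
    if fs < 2 * 80.0:
        raise ValueError(f"fs={fs} Hz aliases the 30-80 Hz gamma band (need >= 160 Hz)")
    if duration < 70.0:
        raise ValueError("duration must be at least 70 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    data = np.empty((n_contacts, n))
    lo_all, hi_all = 1.0, 80.0
    broad_mask = (freqs >= lo_all) & (freqs <= hi_all)
    for c in range(n_contacts):
        sig = np.zeros(n)
        for (name, (lo, hi)), frac in zip(BAND_EDGES.items(), fracs):
            power = (1.0 - noise_floor) * frac * total_power
            if power <= 0:
                continue
            spec = np.fft.rfft(rng.standard_normal(n))
            m = (freqs >= lo) & (freqs < hi)
            spec[~m] = 0.0
            comp = np.fft.irfft(spec, n)
            comp *= math.sqrt(power) / max(comp.std(), 1e-30)
            sig += comp
        spec = np.fft.rfft(rng.standard_normal(n))
        spec[~broad_mask] = 0.0
        floor = np.fft.irfft(spec, n)
        floor *= math.sqrt(noise_floor * total_power) / max(floor.std(), 1e-30)
        data[c] = sig + floor
    return IeegRecording([f"c{c:02d}" for c in range(n_contacts)], data, fs)
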