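"""End-to-end cohort pipeline.

Ties the stages together: simulate (or accept) a cohort, harmonize the
connectomes across scanner batches, fit the normative control model,
score every patient's connectivity and iEEG abnormalities, label
resections from regional volumes, compute per-patient D_RS in both
modalities, the SVM separability / maximal-abnormality call, and the
cohort-level statistics (tendency contingency, outcome AUCs, two-cut
decision tree with LOOCV).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import (
    combat_harmonize,
    connection_abnormalities,
    fit_normative_connectome,
    regional_abnormality,
)
from .ieeg import (
    assign_contacts,
    fit_ieeg_normative_map,
    ieeg_regional_abnormality,
    regional_band_power,
)
from .resection import label_resected
from .stats import (
    PatientOutcomeRecord,
    classify_tendency,
    compute_drs,
    fit_two_cut_tree,
    loocv_tree,
    outcome_auc,
    svm_separability,
)
from .synthetic import (
    SimulationConfig,
    generate_connection_mask,
    generate_control_connectomes,
    generate_control_population_params,
    generate_ieeg_normative_cohort,
    generate_parcellation,
    generate_patient,
    sample_ez,
)

logger = logging.getLogger("ezmap")

__all__ = ["PipelineConfig", "CohortReport", "simulate_cohort", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings; every study threshold is a documented field."""

    resection_threshold: float = 0.10  # >10% regional volume reduction
    assignment_radius: float = 5.0  # mm, contact-to-region rule
    clamp_positive_scores: bool = False
    min_controls: int = 10
    use_ieeg: bool = True  # False degrades to connectivity-only outputs

    def __post_init__(self) -> None:
        if not 0 <= self.resection_threshold < 1:
            raise ValueError("resection_threshold must be in [0, 1)")
        if self.assignment_radius <= 0:
            raise ValueError("assignment_radius must be positive")


@dataclass
class CohortReport:
    """Per-patient records plus cohort-level statistics and provenance."""

    patients: pd.DataFrame
    tendency: object | None
    auc_conn: float | None
    auc_conn_p: float | None
    auc_ieeg: float | None
    auc_ieeg_p: float | None
    tree: object | None
    tree_accuracy: float | None
    loocv: tuple | None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "patients": self.patients.to_dict(orient="records"),
            "auc_conn": self.auc_conn,
            "auc_conn_p": self.auc_conn_p,
            "auc_ieeg": self.auc_ieeg,
            "auc_ieeg_p": self.auc_ieeg_p,
            "tree_accuracy": self.tree_accuracy,
            "loocv": self.loocv,
            "provenance": self.provenance,
        }
        if self.tendency is not None:
            t = self.tendency
            d["tendency"] = {
                "table": [t.table.a, t.table.b, t.table.c, t.table.d],
                "odds_ratio": t.odds_ratio,
                "ci": [t.ci_low, t.ci_high],
                "chi2": t.chi2,
                "chi2_p": t.chi2_p,
                "n_separable": t.n_separable,
                "nonseparable": [t.n_nonseparable_sf, t.n_nonseparable_nsf],
                "nonseparable_binomial_p": t.nonseparable_binomial_p,
            }
        if self.tree is not None:
            d["tree"] = asdict(self.tree)
        return d


def simulate_cohort(config: SimulationConfig):
    """Generate the full synthetic study: controls, patients, normative iEEG."""
    parc = generate_parcellation(config)
    mask = generate_connection_mask(config)
    params = generate_control_population_params(config, mask)
    controls = generate_control_connectomes(config, parc, mask, params)
    patients = [
        generate_patient(
            config, parc, sample_ez(config, parc, i), mask, params, patient_index=i
        )
        for i in range(config.n_patients)
    ]
    normative_ieeg = generate_ieeg_normative_cohort(config, parc)
    return parc, controls, patients, normative_ieeg


def run_pipeline(
    sim_config: SimulationConfig,
    pipe_config: PipelineConfig | None = None,
) -> CohortReport:
    """Run the complete abnormality-mapping and outcome analysis.

    Returns a :class:`CohortReport` with one row per patient (D_RS in
    both modalities, separability, maximal-abnormality call, outcome)
    and the cohort statistics.  Deterministic for a fixed config.
    """
    pc = pipe_config or PipelineConfig()
    parc, controls, patients, normative_ieeg = simulate_cohort(sim_config)
    logger.info(
        "cohort: %d controls, %d patients, %d regions",
        len(controls), len(patients), parc.n_regions,
    )

    stage = "harmonization"
    try:
        controls_h = combat_harmonize(controls)
        patient_cms = combat_harmonize([p.connectome for p in patients], fit_cohort=controls)
        stage = "normative connectome fit"
        model = fit_normative_connectome(controls_h, min_controls=pc.min_controls)
        stage = "iEEG normative map"
        nmap = fit_ieeg_normative_map(normative_ieeg) if pc.use_ieeg else None
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    records: list[PatientOutcomeRecord] = []
    rows = []
    for bundle, cm in zip(patients, patient_cms):
        pid = bundle.patient_id
        try:
            a_map = connection_abnormalities(cm, model)
            regional = regional_abnormality(a_map, clamp_positive=pc.clamp_positive_scores)
            conn_scores = regional.score_by_region()

            resection_table = label_resected(bundle.volumes, pc.resection_threshold)
            resected_ids = set(
                resection_table.loc[resection_table["resected"], "region_id"]
            )

            if pc.use_ieeg:
                mapping = assign_contacts(
                    bundle.contacts, parc, radius=pc.assignment_radius
                )
                patient_regional_bp = regional_band_power(bundle.contact_bp, mapping)
                ieeg_ab = ieeg_regional_abnormality(patient_regional_bp, nmap)
                ieeg_scores = ieeg_ab.score_by_region()
            else:
                ieeg_scores = {}

            # connectivity D_RS over all scored regions; iEEG D_RS over
            # implanted regions only
            conn_ids = sorted(conn_scores)
            drs_conn = compute_drs(
                [conn_scores[r] for r in conn_ids],
                [r in resected_ids for r in conn_ids],
            )
            ieeg_ids = sorted(ieeg_scores)
            ieeg_flags = [r in resected_ids for r in ieeg_ids]
            drs_ieeg = (
                compute_drs([ieeg_scores[r] for r in ieeg_ids], ieeg_flags)
                if any(ieeg_flags) and not all(ieeg_flags)
                else None
            )

            # SVM separability on implanted regions with both scores
            both = [r for r in ieeg_ids if r in conn_scores]
            pts = [(ieeg_scores[r], conn_scores[r]) for r in both]
            flags = [r in resected_ids for r in both]
            if pc.use_ieeg:
                try:
                    separable, maximal = svm_separability(pts, flags)
                except ValueError:
                    separable, maximal = None, "undefined"
            else:
                separable, maximal = None, "undefined"
        except Exception as err:
            raise RuntimeError(f"pipeline failed for patient {pid}: {err}") from err

        rec = PatientOutcomeRecord(
            patient_id=pid,
            drs_conn=drs_conn,
            drs_ieeg=drs_ieeg,
            separable=separable,
            maximal_resected=maximal,
            ilae=bundle.ilae,
            extras={"ez_hit": bundle.ez_regions <= resected_ids},
        )
        logger.info(
            "%s: drs_conn=%.3f drs_ieeg=%s separable=%s",
            pid, drs_conn, f"{drs_ieeg:.3f}" if drs_ieeg is not None else "NA", separable,
        )
        records.append(rec)
        rows.append(
            {
                "patient_id": pid,
                "drs_conn": drs_conn,
                "drs_ieeg": drs_ieeg,
                "separable": separable,
                "maximal_resected": maximal,
                "ilae": bundle.ilae,
                "seizure_free": rec.seizure_free,
                "ez_resected": bundle.ez_regions <= resected_ids,
            }
        )
    table = pd.DataFrame(rows)

    # cohort statistics; partial inputs degrade to nulls rather than crash
    tendency = None
    if any(r.separable for r in records):
        tendency = classify_tendency(records)
    auc_conn = auc_conn_p = auc_ieeg = auc_ieeg_p = None
    sf = table["seizure_free"].to_numpy(dtype=bool)
    if 0 < sf.sum() < len(sf):
        auc_conn, auc_conn_p = outcome_auc(table["drs_conn"].to_numpy(), sf)
        ok = table["drs_ieeg"].notna().to_numpy()
        if 0 < (sf & ok).sum() and 0 < (~sf & ok).sum():
            auc_ieeg, auc_ieeg_p = outcome_auc(
                table.loc[ok, "drs_ieeg"].to_numpy(dtype=float), sf[ok]
            )
    tree = tree_acc = loocv = None
    complete = table["drs_ieeg"].notna().to_numpy()
    pts = table.loc[complete, ["drs_conn", "drs_ieeg"]].to_numpy(dtype=float)
    y = sf[complete]
    if y.sum() >= 2 and (~y).sum() >= 2:
        tree = fit_two_cut_tree(pts, y)
        tree_acc = tree.training_accuracy
        loocv = loocv_tree(pts, y)

    cfg_json = json.dumps(
        {"sim": asdict(sim_config), "pipe": asdict(pc)}, sort_keys=True, default=str
    )
    provenance = {
        "software_version": __version__,
        "seed": sim_config.seed,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "settings": {
            "resection_threshold": pc.resection_threshold,
            "assignment_radius_mm": pc.assignment_radius,
            "clamp_positive_scores": pc.clamp_positive_scores,
            "drs_tie_credit": 0.5,
            "svm": "linear, C=1e6, separable = 100% training accuracy",
            "chi_square": "Yates continuity correction",
            "odds_ratio_ci": "Wald log-normal",
        },
    }
    return CohortReport(
        patients=table,
        tendency=tendency,
        auc_conn=auc_conn,
        auc_conn_p=auc_conn_p,
        auc_ieeg=auc_ieeg,
        auc_ieeg_p=auc_ieeg_p,
        tree=tree,
        tree_accuracy=tree_acc,
        loocv=loocv,
        provenance=provenance,
    )
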