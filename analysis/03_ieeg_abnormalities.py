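#!/usr/bin/env python
"""iEEG band-power abnormality mapping on the synthetic cohort.

Fits the normative band-power map, assigns an example patient's contacts
to grey-matter regions (<5 mm rule), averages contact band powers per
region, and z-scores them against the map.  Also pushes a band-limited
synthetic recording through the full signal path (common average
reference, Welch PSD, log relative band power) to confirm the dominant
band survives the processing.  Writes the example patient's regional
abnormalities under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from ezmap import SimulationConfig
from ezmap.ieeg import (
    BAND_NAMES,
    assign_contacts,
    common_average_reference,
    fit_ieeg_normative_map,
    ieeg_regional_abnormality,
    regional_band_power,
    relative_band_power,
)
from ezmap.io import write_table
from ezmap.pipeline import simulate_cohort
from ezmap.synthetic import generate_timeseries_for_bandpower

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    parc, _, patients, normative = simulate_cohort(cfg)
    nmap = fit_ieeg_normative_map(normative)
    print(f"normative map: {len(nmap.mu)} regions x {len(BAND_NAMES)} bands "
          f"from {len(normative)} participants")

    bundle = patients[0]
    mapping = assign_contacts(bundle.contacts, parc, radius=cfg.assignment_radius)
    n_unassigned = sum(1 for v in mapping.values() if v is None)
    print(f"{bundle.patient_id}: {len(mapping)} contacts, "
          f"{n_unassigned} unassigned (> {cfg.assignment_radius:.0f} mm from every region)")

    regional = regional_band_power(bundle.contact_bp, mapping)
    ab = ieeg_regional_abnormality(regional, nmap)
    table = ab.z.copy()
    table["max_abs_z"] = ab.b
    write_table(table.rename_axis("region_id").reset_index(),
                OUT / f"{bundle.patient_id}_regional_ieeg.csv")
    top = ab.b.sort_values(ascending=False).head(3)
    print("most abnormal implanted regions (max |z| over bands):")
    for rid, v in top.items():
        flag = "EZ" if rid in bundle.ez_regions else "  "
        print(f"  {rid}  B = {v:.2f}  {flag}")

    # signal-path check: alpha-dominant synthetic recording
    rec = generate_timeseries_for_bandpower(
        (0.02, 0.03, 0.7, 0.15, 0.1), fs=256.0, duration=70.0, n_contacts=4,
        seed=args.seed,
    )
    rel = relative_band_power(common_average_reference(rec))
    print(f"signal path: alpha-dominant synthetic recording -> "
          f"dominant band per contact: {rel.values.idxmax(axis=1).tolist()}")


if __name__ == "__main__":
    main()
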