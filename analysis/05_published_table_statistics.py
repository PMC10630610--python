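#!/usr/bin/env python
"""Recompute the published cohort statistics from their printed counts.

The study prints the full 2x2 patient-count tables for sex, resection
type, side, and MRI status against seizure outcome, the separable-cohort
tendency table marginals, and the non-separable outcome split.  This
driver recomputes every statistic from those counts with the package's
contingency machinery and writes them to results/published_stats.json.
"""

import json
from pathlib import Path

from ezmap.stats import TwoByTwoTable, exact_binomial_p, odds_ratio_ci, yates_chi_square

OUT = Path(__file__).resolve().parent.parent / "results"

TABLES = {
    "sex_male_female": (12, 13, 13, 5),
    "type_temporal_extratemporal": (16, 9, 10, 8),
    "side_left_right": (15, 10, 6, 12),
    "mri_nonlesional_lesional": (10, 15, 10, 8),
}


def main() -> None:
    report = {}
    print("cohort characteristic tables (Yates chi-square):")
    for name, cells in TABLES.items():
        chi2, p = yates_chi_square(TwoByTwoTable(*cells))
        report[name] = {"cells": cells, "chi2": round(chi2, 2), "p": round(p, 2)}
        print(f"  {name}: chi2 = {chi2:.2f}, p = {p:.2f}")

    t = TwoByTwoTable(12, 4, 2, 10)
    or_, lo, hi = odds_ratio_ci(t)
    chi2, p = yates_chi_square(t)
    report["separable_tendency"] = {
        "cells": (12, 4, 2, 10),
        "odds_ratio": round(or_, 2),
        "ci": [round(lo, 2), round(hi, 2)],
        "chi2_p": round(p, 3),
    }
    print(f"separable cohort: OR = {or_:.2f}, 95% CI [{lo:.2f}, {hi:.2f}], p = {p:.3f}")

    p_ns = exact_binomial_p(11, 15)
    report["nonseparable_binomial"] = {"split": [11, 4], "p": round(p_ns, 2)}
    print(f"non-separable outcomes 11:4 -> exact binomial p = {p_ns:.2f}")

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "published_stats.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
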