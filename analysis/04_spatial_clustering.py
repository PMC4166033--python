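#!/usr/bin/env python
"""Spatial clustering of preferred textures.

Measured vs expected k-nearest-neighbor probabilities (k = 1..4; closed
form for k = 1, label-permutation null for k >= 2) and the Monte-Carlo
intra-group-distance test (1000 uniform redraws, 5% threshold) on the
simulated experiment's preferring neurons.
"""

import json
from pathlib import Path

import pandas as pd

from texturemap import selectivity as sel
from texturemap import spatial_stats as ss
from texturemap import synthetic_data as sd

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 1


def main() -> None:
    classes = pd.read_csv(SIM / "classes.csv")
    pop = pd.read_csv(SIM / "population.csv")
    merged = classes.merge(pop, on="neuron_id")
    pref = merged[merged["class"] == sel.CLASS_PREFERRING]
    pos = pref[["x_px", "y_px"]].to_numpy()
    lab = pref["preferred"].to_numpy()
    n_resp = int((classes["class"] != sel.CLASS_NON_RESPONSIVE).sum())

    conditions = ("P120", "P320", "P600", "P1000")
    expected_k1 = ss.expected_neighbor_probability(ss.label_counts(lab, conditions), n_resp)
    report = {"expected_k1": expected_k1, "measured": {}, "expected_empirical": {}}
    for k in (1, 2, 3, 4):
        report["measured"][k] = ss.measured_neighbor_probability(pos, lab, k=k)
        report["expected_empirical"][k] = ss.expected_neighbor_probability_empirical(
            pos, lab, k=k, n_perm=500, seed=SEED + k
        )
        print(f"k={k}: measured {100 * report['measured'][k]:5.1f}%  vs  "
              f"chance {100 * report['expected_empirical'][k]:5.1f}%")
    print(f"closed-form expected (k=1): {100 * expected_k1:.1f}%")

    poly = sd.default_barrel_polygon()
    null = ss.monte_carlo_cluster_test(pos, lab, runs=1000, seed=SEED + 10, region=poly)
    print(f"Monte-Carlo 5% threshold distance: {null.threshold:.1f} px")
    for l, d in null.observed.items():
        mark = "clustered" if null.significant[l] else "not significant"
        print(f"  {l}: observed intra-group distance {d:6.1f} px -> {mark}")

    report["monte_carlo"] = {
        "threshold_px": null.threshold,
        "observed_px": null.observed,
        "significant": null.significant,
    }
    (SIM / "clustering.json").write_text(json.dumps(report, indent=2, default=str))
    print(f"wrote {SIM / 'clustering.json'}")


if __name__ == "__main__":
    main()
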