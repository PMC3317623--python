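#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

The study's raw inputs (chromatogram-derived 16S fragments, the measurement
supplement, the stream count sheets) are not publicly available, so seeded
generators with recorded ground truth stand in for them.  Writes FASTA/CSV
plus truth tables under results/simulated/.
"""

from pathlib import Path

from rheotad.io import write_fasta, write_measurements
from rheotad.synthdata import (
    generate_community,
    generate_habitat_matrix,
    generate_morphometrics,
    generate_sequences,
)

SEED = 178
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    records, seq_truth = generate_sequences(
        base_length=550, divergences=(0.01, 0.04, 0.10), n_per_level=2, seed=SEED
    )
    write_fasta(records, OUT / "sequences.fasta")
    seq_truth.to_csv(OUT / "sequences_truth.csv", index=False)
    print(f"sequences: base + {len(records) - 1} derived at 1/4/10% divergence")

    all_records = []
    for cluster_id in (1, 2, 3):
        recs, truth = generate_morphometrics(cluster_id, n=20, jitter=0.1, seed=SEED)
        all_records.extend(recs)
        truth.to_csv(OUT / f"morphometrics_truth_cluster{cluster_id}.csv", index=False)
    write_measurements(all_records, OUT / "morphometrics.csv")
    print(f"morphometrics: {len(all_records)} records, 20 per cluster, 10% jitter")

    table, community_truth = generate_community(
        n_streams=33,
        preference_weights={
            "sp_A": [3, 2, 1, 1, 1, 0.3, 1, 1],  # rheophilous: prefers fast rock
            "sp_B": [2, 2, 1, 1, 1, 0.3, 1, 1],
            "sp_C": [1, 1, 1, 1, 1, 0.3, 1, 2],  # generalist, avoids slow gravel
        },
        mean_abundance=10.0,
        seed=SEED,
    )
    table.to_long().to_csv(OUT / "community_counts.csv", index=False)
    avail = table.availability.stack().rename("proportion").reset_index()
    avail.columns = ["stream", "microhabitat", "proportion"]
    parts = avail["microhabitat"].str.split("_", n=1, expand=True)
    avail["velocity"], avail["substrate"] = parts[0], parts[1]
    avail[["stream", "velocity", "substrate", "proportion"]].to_csv(
        OUT / "community_availability.csv", index=False
    )
    community_truth.expected_E.to_csv(OUT / "community_truth_E.csv")
    print(f"community: 33 streams x 3 species x 8 microhabitats, "
          f"{int(table.counts.to_numpy().sum())} specimens total")

    matrix, habitat_truth = generate_habitat_matrix(
        n_streams=33, n_vars=10, n_factors=2, noise=0.3, seed=SEED
    )
    matrix.to_csv(OUT / "habitat_matrix.csv")
    habitat_truth.loadings.to_csv(OUT / "habitat_truth_loadings.csv")
    print("habitat: 33 streams x 10 variables, planted 2-factor structure")


if __name__ == "__main__":
    main()
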