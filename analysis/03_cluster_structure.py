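"""Do classifier outputs cluster by emotion category?

Z-scores the five probability features, reports the NMI curve for k = 2..10
under complete linkage, the k=5 contingency table against the validated
categories, and the majority-category labeling of each cluster.
"""

import argparse
from pathlib import Path

from affectdim import (
    complete_linkage_cluster,
    contingency,
    majority_cluster_labels,
    nmi,
    nmi_curve,
    read_stimulus_table,
    zscore_columns,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument(
        "--stimuli", type=Path, default=Path("results/data/stimuli_discrete.csv")
    )
    parser.add_argument("--out-dir", type=Path, default=Path("results/cluster"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    table = read_stimulus_table(args.stimuli)
    z = zscore_columns(table.probabilities)
    curve = nmi_curve(z, table.categories, range(2, 11))
    curve.to_csv(args.out_dir / "nmi_curve_5d.csv", index=False)
    print("NMI by number of clusters (complete linkage, z-scored 5-D features):")
    print(curve.round(4).to_string(index=False))

    res = complete_linkage_cluster(z, 5)
    tab = contingency(res.assignments, table.categories)
    tab.to_frame().to_csv(args.out_dir / "contingency_k5.csv")
    labels = majority_cluster_labels(tab)
    print(f"\nk=5 solution: NMI = {nmi(tab):.4f}")
    print("majority category per cluster:", labels.mapping)
    if labels.tied_clusters:
        print("ties resolved canonically for clusters:", labels.tied_clusters)


if __name__ == "__main__":
    main()
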