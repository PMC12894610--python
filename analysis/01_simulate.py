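"""Generate one synthetic dataset per generative regime.

The discrete regime draws classifier probability vectors from five
category-specific Dirichlet centroids; the core-affect regime makes them a
noisy softmax of an affine map of latent (valence, arousal). Both tables,
subject-level ratings and the ground-truth sidecars are written under
results/data/.
"""

import argparse
import json
from pathlib import Path

from affectdim import (
    SyntheticConfig,
    generate,
    generate_subject_ratings,
    write_stimulus_table,
    write_subject_ratings,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for regime in ("discrete", "core_affect"):
        cfg = SyntheticConfig(regime=regime, seed=args.seed)
        table, truth = generate(cfg)
        ratings = generate_subject_ratings(cfg, table)
        write_stimulus_table(table, args.out_dir / f"stimuli_{regime}.csv")
        write_subject_ratings(ratings, args.out_dir / f"ratings_{regime}.csv")
        (args.out_dir / f"ground_truth_{regime}.json").write_text(
            json.dumps(
                {
                    "regime": truth.regime,
                    "affect_means": truth.affect_means.tolist(),
                    "centroids": None
                    if truth.centroids is None
                    else truth.centroids.tolist(),
                    "seed": truth.seed,
                },
                indent=2,
            )
        )
        print(
            f"{regime}: {len(table)} stimuli across 5 categories, "
            f"{cfg.n_subjects} rating subjects -> {args.out_dir}"
        )


if __name__ == "__main__":
    main()
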