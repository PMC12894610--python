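"""Are the aggregated valence/arousal stimulus ratings reliable?

Runs the split-half procedure on the subject-level ratings: random half
splits of the rater sample, per-video means per half, correlation across
videos, averaged over runs.
"""

import argparse
import json
from pathlib import Path

from affectdim import read_subject_ratings, split_half_bootstrap


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument(
        "--ratings", type=Path, default=Path("results/data/ratings_discrete.csv")
    )
    parser.add_argument("--runs", type=int, default=10)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/reliability.json"))
    args = parser.parse_args()

    res = split_half_bootstrap(
        read_subject_ratings(args.ratings), n_runs=args.runs, seed=args.seed
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(
        json.dumps(
            {"mean_correlation": res.mean_correlation.to_dict(), "n_runs": res.n_runs},
            indent=2,
        )
    )
    print(f"mean split-half correlation over {res.n_runs} runs:")
    print(res.mean_correlation.round(4).to_string())


if __name__ == "__main__":
    main()
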