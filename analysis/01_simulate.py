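#!/usr/bin/env python
"""Simulate an NHI-style synthetic claims dataset with planted episodes.

Generates claims for 3,000 patients over the 2007-2011 study window with
the default fragmentation mix (monthly billing splits, transfers, early
readmissions) and separation guaranteed, and writes the blind claims table
plus the ground-truth episode labels under results/.
"""

import argparse
from pathlib import Path

from amiepisodes.claims_io import write_claims
from amiepisodes.synthetic_claims import GeneratorConfig, generate, write_truth

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-patients", type=int, default=3000)
    args = parser.parse_args()

    config = GeneratorConfig(seed=args.seed, n_patients=args.n_patients)
    claims, truth = generate(config)
    RESULTS.mkdir(exist_ok=True)
    write_claims(claims, RESULTS / "synthetic_claims.csv")
    write_truth(claims, truth, RESULTS / "synthetic_truth.csv")
    n_multi = sum(
        1
        for ep, members in truth.partition().items()
        if len(members) > 1
    )
    print(
        f"simulated {len(claims)} claims for {args.n_patients} patients: "
        f"{len(truth.planted_episodes)} planted episodes "
        f"({n_multi} spanning multiple claims)"
    )
    print(f"wrote {RESULTS / 'synthetic_claims.csv'} and {RESULTS / 'synthetic_truth.csv'}")


if __name__ == "__main__":
    main()
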