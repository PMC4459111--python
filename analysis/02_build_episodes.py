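#!/usr/bin/env python
"""Select qualifying AMI claims and collapse them into admission episodes.

Reads the simulated claims from results/, applies the I21 case definition,
runs the three-condition merge (28-day admission window, 3-day discharge
window, under-3-day short stay), writes the episodes CSV, and scores the
recovered partition against the planted ground truth.
"""

from pathlib import Path

from amiepisodes.claims_io import read_claims, select_ami_claims
from amiepisodes.episode_builder import build_episodes, write_episodes
from amiepisodes.synthetic_claims import read_truth

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    claims = read_claims(RESULTS / "synthetic_claims.csv")
    qualifying = select_ami_claims(claims)
    episodes = build_episodes(qualifying)
    write_episodes(episodes, RESULTS / "episodes.csv")
    print(
        f"claims read={len(claims)} qualifying={len(qualifying)} "
        f"episodes={len(episodes)}"
    )
    assert sum(e.n_claims for e in episodes) == len(qualifying), "claims lost"

    truth = read_truth(RESULTS / "synthetic_truth.csv")
    built = {frozenset(e.member_claim_ids) for e in episodes}
    planted = set(truth.partition().values())
    exact = built == planted
    print(
        f"planted episodes={len(planted)} recovered={len(built)} "
        f"exact partition match={exact}"
    )
    print(f"wrote {RESULTS / 'episodes.csv'}")


if __name__ == "__main__":
    main()
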