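#!/usr/bin/env python
"""Tabulate the built episodes: counts, ED and invasive proportions, trends.

Produces the stratum tables (by year, by sex, by age band) with Wald 95%
confidence intervals and the yearly trend figure, all under results/.
"""

from pathlib import Path

from amiepisodes.episode_builder import read_episodes
from amiepisodes.tabulate import plot_trends, tabulate_by, trend_series

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    episodes = read_episodes(RESULTS / "episodes.csv")
    for strata, name in (
        (["year"], "table_by_year.csv"),
        (["sex"], "table_by_sex.csv"),
        (["age_band"], "table_by_age.csv"),
        (["year", "sex"], "table_by_year_sex.csv"),
    ):
        table = tabulate_by(episodes, strata)
        table.to_csv(RESULTS / name)
    year_table = tabulate_by(episodes, ["year"])
    total = year_table.total
    print(
        f"{total.n_episodes} episodes: ED {total.ed.display()}%, "
        f"invasive {total.invasive.display()}%"
    )
    series = trend_series(year_table)
    series.to_csv(RESULTS / "trend_series.csv", index=False)
    scratch = RESULTS.parent / "scratch"
    scratch.mkdir(exist_ok=True)
    plot_trends(series, scratch / "trends.png")
    print(series.to_string(index=False))
    print(f"wrote stratum tables and trend series under {RESULTS}")


if __name__ == "__main__":
    main()
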