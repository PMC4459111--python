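"""Published Korean NHI AMI admission counts, 2007–2011.

The study population behind this package — all Korean National Health
Insurance hospitalization claims with ICD-10 I21.X as primary or secondary
diagnosis, 2007–2011 — is not publicly deposited. What is public are the
printed summary tables: total claim/patient/episode counts and, by year and
sex, the number of admission episodes, the number admitted through the
emergency department, and the number with an invasive coronary procedure,
each with a percentage and 95% confidence interval.

This module stores those printed numbers as input data so the arithmetic
(episode-count identities, proportions, confidence intervals, trends) can be
recomputed and checked without access to the raw claims.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = [
    "HEADLINE_COUNTS",
    "TABLE1_TOTALS",
    "YEAR_SEX_ROWS",
    "YearSexRow",
    "PrintedCI",
    "AGE_BAND_COUNTS",
]

#: Headline counts of the claims-to-episodes reduction.
HEADLINE_COUNTS = {
    "total_claims": 513_886,
    "total_patients": 269_843,
    "single_claim_patients": 180_597,  # one claim -> one episode each
    "multi_claim_patients": 89_246,
    "multi_claim_claims": 333_289,
    "multi_claim_episodes": 114_404,
    "total_episodes": 295_001,
}

#: Overall episode counts: total, through the ED, with an invasive procedure.
TABLE1_TOTALS = {
    "n_episodes": 295_001,
    "n_ed": 157_633,
    "pct_ed": 53.4,
    "n_invasive": 81_487,
    "pct_invasive": 27.6,
    "n_male": 166_081,
    "n_female": 128_920,
}


class PrintedCI(NamedTuple):
    """A printed "% (95% CI)" triple."""

    percent: float
    ci_low: float
    ci_high: float


class YearSexRow(NamedTuple):
    """One published year x sex-group row of counts and CI triples."""

    group: str  # "Total" | "male" | "female"
    year: int
    n_total: int
    n_ed: int
    ed: PrintedCI
    n_invasive: int
    invasive: PrintedCI


#: Admissions by year within sex group: totals, ED and invasive counts with
#: their printed percentage and 95% CI (30 CI triples in all).
YEAR_SEX_ROWS = [
    YearSexRow("Total", 2007, 66_883, 38_118, PrintedCI(57.0, 56.6, 57.4), 15_342, PrintedCI(22.9, 22.6, 23.3)),
    YearSexRow("Total", 2008, 62_331, 34_350, PrintedCI(55.1, 54.7, 55.5), 15_741, PrintedCI(25.3, 24.9, 25.6)),
    YearSexRow("Total", 2009, 61_002, 31_698, PrintedCI(52.0, 51.6, 52.4), 16_126, PrintedCI(26.4, 26.1, 26.8)),
    YearSexRow("Total", 2010, 57_129, 29_466, PrintedCI(51.6, 51.2, 52.0), 16_773, PrintedCI(29.4, 29.0, 29.7)),
    YearSexRow("Total", 2011, 47_656, 24_001, PrintedCI(50.4, 49.9, 50.8), 17_505, PrintedCI(36.7, 36.3, 37.2)),
    YearSexRow("male", 2007, 37_521, 22_136, PrintedCI(59.0, 58.5, 59.5), 10_848, PrintedCI(28.9, 28.5, 29.4)),
    YearSexRow("male", 2008, 34_814, 20_135, PrintedCI(57.8, 57.3, 58.4), 11_190, PrintedCI(32.1, 31.7, 32.6)),
    YearSexRow("male", 2009, 34_388, 18_884, PrintedCI(54.9, 54.4, 55.4), 11_544, PrintedCI(33.6, 33.1, 34.1)),
    YearSexRow("male", 2010, 32_176, 17_928, PrintedCI(55.7, 55.2, 56.3), 12_136, PrintedCI(37.7, 37.2, 38.2)),
    YearSexRow("male", 2011, 27_182, 15_161, PrintedCI(55.8, 55.2, 56.4), 12_637, PrintedCI(46.5, 45.9, 47.1)),
    YearSexRow("female", 2007, 29_362, 15_982, PrintedCI(54.4, 53.9, 55.0), 4_494, PrintedCI(15.3, 14.9, 15.7)),
    YearSexRow("female", 2008, 27_517, 14_215, PrintedCI(51.7, 51.1, 52.2), 4_551, PrintedCI(16.5, 16.1, 17.0)),
    YearSexRow("female", 2009, 26_614, 12_814, PrintedCI(48.1, 47.5, 48.7), 4_582, PrintedCI(17.2, 16.8, 17.7)),
    YearSexRow("female", 2010, 24_953, 11_538, PrintedCI(46.2, 45.6, 46.9), 4_637, PrintedCI(18.6, 18.1, 19.1)),
    YearSexRow("female", 2011, 20_474, 8_840, PrintedCI(43.2, 42.5, 43.9), 4_868, PrintedCI(23.8, 23.2, 24.4)),
]

#: Published per-age-band episode counts (all years pooled), used as the
#: generator's default age mix. Bands as in tabulate.AGE_BANDS. (The printed
#: column-percent cells are internally inconsistent with these counts, so the
#: counts are taken as authoritative.)
AGE_BAND_COUNTS = [341, 2_053, 4_710, 11_503, 31_631, 50_333, 64_707, 80_912, 48_791]
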