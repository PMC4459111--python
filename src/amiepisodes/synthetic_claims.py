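"""Synthetic NHI-style claims with planted ground-truth episodes.

Real Korean NHI claims are not public, so every downstream stage is
exercised on synthetic claims that emulate the fragmentation mechanisms by
which one clinical AMI hospitalization becomes several billing claims:

``monthly_split``
    hospitals bill inpatient care monthly, so a long stay is cut at
    calendar-month boundaries into abutting claims;
``transfer``
    an inter-hospital transfer emits two overlapping claims from distinct
    providers;
``early_readmission``
    a second admission within the 28-day window of the first;
``none``
    a single claim.

Each generated claim carries its true episode label in a separate
ground-truth table (never in the claims file, keeping the pipeline blind).
With ``guarantee_separation=True`` (the default) distinct planted episodes
of a patient are spaced so that no merge condition can fire across an
episode boundary, making the planted partition exactly recoverable by the
episode builder; ``stress_generate`` relaxes this to quantify the
over-/under-merging bias of the date-window rules.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple

import numpy as np

from .claims_io import CaseDefinition, ClaimRecord
from .episode_builder import MergeRule
from .reference_tables import AGE_BAND_COUNTS
from .tabulate import AGE_BANDS, assign_age_band

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "PlantedEpisode",
    "GenerationError",
    "generate",
    "stress_generate",
    "write_truth",
    "read_truth",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = ["claim_id", "patient_id", "true_episode_id", "true_ed", "true_invasive"]

_DX_PRIMARY = ("I21.0", "I21.1", "I21.2", "I21.4", "I21.9")
_DX_COMORBID = ("I10", "E78.5", "E11.9", "J44.9")


class GenerationError(RuntimeError):
    """Requested episode structure does not fit the study window."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic claims generator.

    Defaults emulate the published study population: a 2007–2011 study
    window, 56.3% male, the published pooled age-band mix, sex-specific
    emergency-department (56.7% male / 49.2% female) and invasive-procedure
    (35.1% / 17.9%) rates, and 2.4% missing admission routes. Probability
    maps are keyed by ``(sex, age_band)``, then ``sex``, then ``"default"``.
    """

    seed: int = 0
    n_patients: int = 200
    study_start: dt.date = dt.date(2007, 1, 1)
    study_end: dt.date = dt.date(2011, 12, 31)
    #: categorical over episode counts per patient
    episodes_per_patient: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.22, 3: 0.08}
    )
    #: categorical over planted total length of stay (days)
    los_distribution: Mapping[int, float] = field(
        default_factory=lambda: {
            0: 0.02, 1: 0.05, 2: 0.08, 3: 0.10, 4: 0.10, 5: 0.12, 6: 0.10,
            7: 0.10, 10: 0.10, 14: 0.08, 21: 0.06, 35: 0.05, 60: 0.04,
        }
    )
    fragmentation_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "none": 0.55, "monthly_split": 0.20, "transfer": 0.10, "early_readmission": 0.15
        }
    )
    p_male: float = 0.563
    p_ed_route: Mapping[object, float] = field(
        default_factory=lambda: {"male": 0.567, "female": 0.492, "default": 0.534}
    )
    p_invasive: Mapping[object, float] = field(
        default_factory=lambda: {"male": 0.351, "female": 0.179, "default": 0.276}
    )
    p_route_missing: float = 0.024
    #: days between a split claim's discharge and the next claim's admission
    split_gap_days: int = 1
    guarantee_separation: bool = True
    #: with guarantee_separation=False: chance that a planted episode pair or
    #: index stay violates the separation constraints (0 -> same behaviour as
    #: the guaranteed generator)
    p_separation_violation: float = 0.3

    def __post_init__(self) -> None:
        for name in ("p_male", "p_route_missing", "p_separation_violation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = sum(self.fragmentation_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fragmentation_mix must sum to 1, got {total}")
        unknown = set(self.fragmentation_mix) - {
            "none", "monthly_split", "transfer", "early_readmission"
        }
        if unknown:
            raise ValueError(f"unknown fragmentation mechanisms: {sorted(unknown)}")
        if self.study_end < self.study_start:
            raise ValueError("study_end precedes study_start")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")


class PlantedEpisode(NamedTuple):
    patient_id: str
    true_episode_id: str
    index_date: dt.date
    true_ed: bool
    true_invasive: bool


@dataclass(frozen=True)
class GroundTruth:
    """Planted episode labels for a generated claims set."""

    planted_episodes: tuple[PlantedEpisode, ...]
    claim_to_episode: Mapping[str, str]

    def partition(self) -> dict[str, frozenset[str]]:
        """true_episode_id -> frozenset of member claim_ids."""
        groups: dict[str, set[str]] = {}
        for claim_id, ep_id in self.claim_to_episode.items():
            groups.setdefault(ep_id, set()).add(claim_id)
        return {k: frozenset(v) for k, v in groups.items()}


def _lookup_p(table: Mapping[object, float], sex: str, band: str) -> float:
    for key in ((sex, band), sex, "default"):
        if key in table:
            return float(table[key])
    raise KeyError(f"no probability for stratum ({sex}, {band}) and no 'default'")


def _sample_categorical(rng: np.random.Generator, table: Mapping) -> object:
    keys = list(table.keys())
    probs = np.asarray([table[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _month_end(day: dt.date) -> dt.date:
    if day.month == 12:
        return dt.date(day.year, 12, 31)
    return dt.date(day.year, day.month + 1, 1) - dt.timedelta(days=1)


def _fragment(
    rng: np.random.Generator,
    mechanism: str,
    admission: dt.date,
    los: int,
    rule: MergeRule,
    split_gap: int,
) -> list[tuple[dt.date, dt.date, bool]]:
    """Cut one planted stay into claim (admission, discharge, new_provider) spans.

    Every returned consecutive pair satisfies at least one merge condition,
    so fragmentation never splits a planted episode.
    """
    discharge = admission + dt.timedelta(days=los)
    gap = max(1, min(split_gap, rule.discharge_window_days))  # keep C2 satisfied
    if (
        mechanism == "monthly_split"
        and _month_end(admission) < discharge
        and rule.discharge_window_days >= 1
    ):
        spans: list[tuple[dt.date, dt.date, bool]] = []
        start = admission
        while start <= discharge:
            cut = min(_month_end(start), discharge)
            spans.append((start, cut, False))
            start = cut + dt.timedelta(days=gap)
        return spans
    if mechanism == "transfer" and los >= 2:
        mid = admission + dt.timedelta(days=int(rng.integers(1, los)))
        # same-day transfer: second admission on the first claim's discharge day
        return [(admission, mid, False), (mid, discharge, True)]
    if mechanism == "early_readmission" and los >= 2:
        los1 = int(rng.integers(1, los))
        hi = rule.admission_window_days
        if los1 + 1 <= hi:
            gap_days = int(rng.integers(los1 + 1, hi + 1))  # after discharge, within C1
            a2 = admission + dt.timedelta(days=gap_days)
            return [
                (admission, admission + dt.timedelta(days=los1), False),
                (a2, a2 + dt.timedelta(days=los - los1), False),
            ]
    return [(admission, discharge, False)]


def generate(
    config: GeneratorConfig,
    rule: MergeRule | None = None,
    case_def: CaseDefinition | None = None,
) -> tuple[list[ClaimRecord], GroundTruth]:
    """Generate claims and ground truth; bit-reproducible for a fixed seed.

    ``rule`` supplies the date windows the separation guarantee is built
    against (defaults to the standard 28/3/3 rule). Episodes that cannot fit
    before ``study_end`` are simply not planted; a config whose window cannot
    hold even a single median stay raises :class:`GenerationError`.
    """
    rule = rule or MergeRule()
    case_def = case_def or CaseDefinition()
    rng = np.random.default_rng(config.seed)
    window_days = (config.study_end - config.study_start).days
    if window_days < max(config.los_distribution):
        raise GenerationError(
            f"study window of {window_days} days cannot hold a "
            f"{max(config.los_distribution)}-day stay"
        )
    band_probs = np.asarray(AGE_BAND_COUNTS, dtype=float)
    band_probs /= band_probs.sum()
    ang = sorted(case_def.angiography_codes)
    rev = sorted(case_def.revascularization_codes)

    claims: list[ClaimRecord] = []
    planted: list[PlantedEpisode] = []
    claim_to_episode: dict[str, str] = {}
    claim_counter = 0

    for p in range(config.n_patients):
        patient_id = f"P{p:05d}"
        sex = "male" if rng.random() < config.p_male else "female"
        band_idx = int(rng.choice(len(AGE_BANDS), p=band_probs))
        lo = band_idx * 10
        age = int(rng.integers(lo, lo + 10)) if band_idx < 8 else int(rng.integers(80, 100))
        band = assign_age_band(age)
        n_episodes = int(_sample_categorical(rng, config.episodes_per_patient))
        provider = f"H{int(rng.integers(0, 500)):03d}"

        prev_last_admission: dt.date | None = None
        prev_final_discharge: dt.date | None = None
        for k in range(n_episodes):
            los = int(_sample_categorical(rng, config.los_distribution))
            separated = False  # placed under the separation constraints?
            if prev_last_admission is None:
                latest_start = config.study_end - dt.timedelta(days=los)
                if latest_start < config.study_start:
                    continue
                offset = int(rng.integers(0, (latest_start - config.study_start).days + 1))
                admission = config.study_start + dt.timedelta(days=offset)
            else:
                # draw unconditionally so the stream matches between the
                # guaranteed and zero-violation stress configurations
                u = rng.random()
                violate = (not config.guarantee_separation) and (
                    u < config.p_separation_violation
                )
                if violate:
                    # deliberately close: may merge across the planted boundary
                    admission = prev_final_discharge + dt.timedelta(
                        days=int(rng.integers(1, rule.admission_window_days + 1))
                    )
                else:
                    # no condition can fire across the boundary:
                    # C1: > admission_window from the previous episode's last
                    #     admission; C2: > discharge_window past its discharge;
                    # C3: handled below by forcing a long-enough index stay.
                    earliest = max(
                        prev_last_admission
                        + dt.timedelta(days=rule.admission_window_days + 1),
                        prev_final_discharge
                        + dt.timedelta(days=rule.discharge_window_days + 1),
                    )
                    admission = earliest + dt.timedelta(days=int(rng.integers(0, 90)))
                    los = max(los, rule.short_stay_days)  # defeat C3 at the boundary
                    separated = True
                if admission + dt.timedelta(days=los) > config.study_end:
                    break  # no room for another planted episode

            mechanism = str(_sample_categorical(rng, config.fragmentation_mix))
            spans = _fragment(rng, mechanism, admission, los, rule, config.split_gap_days)
            if separated and (spans[0][1] - spans[0][0]).days < rule.short_stay_days:
                # C3 compares the NEXT episode's index-claim stay against the
                # short-stay threshold; a short index fragment would merge this
                # episode into the previous one, so keep it a single claim.
                spans = [(admission, admission + dt.timedelta(days=los), False)]
            episode_id = f"{patient_id}-T{k + 1:03d}"

            # route: intent applies to the index claim, then missingness
            intended_ed = rng.random() < _lookup_p(config.p_ed_route, sex, band)
            routes = []
            for i in range(len(spans)):
                route = ("emergency" if intended_ed else "other") if i == 0 else "other"
                if rng.random() < config.p_route_missing:
                    route = "unknown"
                routes.append(route)
            true_ed = routes[0] == "emergency"

            # procedures: angiography on one member claim; often followed by
            # revascularization (possibly on a later claim of the episode)
            proc_by_claim: dict[int, list[str]] = {}
            invasive = rng.random() < _lookup_p(config.p_invasive, sex, band)
            if invasive and ang:
                i_ang = int(rng.integers(0, len(spans)))
                proc_by_claim.setdefault(i_ang, []).append(str(ang[int(rng.integers(0, len(ang)))]))
                if rev and rng.random() < 0.7:
                    i_rev = int(rng.integers(i_ang, len(spans)))
                    proc_by_claim.setdefault(i_rev, []).append(
                        str(rev[int(rng.integers(0, len(rev)))])
                    )
            true_invasive = bool(proc_by_claim)

            dx = str(_DX_PRIMARY[int(rng.integers(0, len(_DX_PRIMARY)))])
            for i, (a, d, new_provider) in enumerate(spans):
                claim_id = f"C{claim_counter:06d}"
                claim_counter += 1
                secondary: list[str] = []
                if rng.random() < 0.30:
                    secondary.append(str(_DX_COMORBID[int(rng.integers(0, len(_DX_COMORBID)))]))
                if rng.random() < 0.10:
                    # AMI coded as secondary on this claim
                    dx_primary_i, secondary = secondary[0] if secondary else "I20.0", [dx]
                else:
                    dx_primary_i = dx
                claims.append(
                    ClaimRecord(
                        claim_id=claim_id,
                        patient_id=patient_id,
                        provider_id=f"H{int(rng.integers(0, 500)):03d}" if new_provider else provider,
                        sex=sex,
                        age_years=age,
                        admission_date=a,
                        discharge_date=d,
                        admission_route=routes[i],
                        dx_primary=dx_primary_i,
                        dx_secondary=tuple(secondary),
                        proc_codes=tuple(proc_by_claim.get(i, ())),
                    )
                )
                claim_to_episode[claim_id] = episode_id
            planted.append(
                PlantedEpisode(patient_id, episode_id, admission, true_ed, true_invasive)
            )
            prev_last_admission = max(a for a, _, _ in spans)
            prev_final_discharge = max(d for _, d, _ in spans)

    truth = GroundTruth(tuple(planted), claim_to_episode)
    return claims, truth


def stress_generate(
    config: GeneratorConfig,
    rule: MergeRule | None = None,
    case_def: CaseDefinition | None = None,
) -> tuple[list[ClaimRecord], GroundTruth]:
    """Generate without the separation guarantee, for bias studies.

    Planted episode boundaries may fall inside the merge windows, so the
    episode builder can under-count (a close pair of true episodes merges)
    relative to the planted truth. With ``p_separation_violation=0`` the
    output matches :func:`generate` on the same config.
    """
    return generate(replace(config, guarantee_separation=False), rule, case_def)


# -- truth CSV I/O -----------------------------------------------------------


def write_truth(claims: list[ClaimRecord], truth: GroundTruth, path) -> None:
    """Truth table keyed by claim: one row per generated claim."""
    ed_by_ep = {e.true_episode_id: e.true_ed for e in truth.planted_episodes}
    inv_by_ep = {e.true_episode_id: e.true_invasive for e in truth.planted_episodes}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRUTH_COLUMNS)
        for c in claims:
            ep = truth.claim_to_episode[c.claim_id]
            writer.writerow(
                [c.claim_id, c.patient_id, ep, str(ed_by_ep[ep]).lower(), str(inv_by_ep[ep]).lower()]
            )


def read_truth(path) -> GroundTruth:
    planted: dict[str, PlantedEpisode] = {}
    claim_to_episode: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            ep_id = row["true_episode_id"]
            claim_to_episode[row["claim_id"]] = ep_id
            if ep_id not in planted:
                planted[ep_id] = PlantedEpisode(
                    patient_id=row["patient_id"],
                    true_episode_id=ep_id,
                    index_date=dt.date.min,  # index date not stored per claim
                    true_ed=row["true_ed"] == "true",
                    true_invasive=row["true_invasive"] == "true",
                )
    return GroundTruth(tuple(planted.values()), claim_to_episode)
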