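"""Collapse qualifying claims into discrete AMI admission episodes.

One clinical AMI hospitalization can generate several insurance claims:
monthly billing splits of long stays, inter-hospital transfers, and early
readmissions. Two adjacent claims of the same patient (sorted by admission
date) are treated as the same episode when at least one of three conditions
holds:

C1. the second admission is within ``admission_window_days`` (default 28)
    of the first admission;
C2. the second admission is within ``discharge_window_days`` (default 3)
    of the first discharge;
C3. the length of stay of the second claim is under ``short_stay_days``
    (default 3).

All window comparisons are inclusive ("within N days" means <= N), C2
accepts negative gaps (overlapping claims from a transfer), and C3 is
applied literally — a short second claim merges regardless of the time gap,
which can join arbitrarily distant short claims. Episodes inherit year, sex,
age and (by default) the admission route from their index claim; the
invasive-procedure flag is true when any member claim carries one.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .claims_io import CaseDefinition, ClaimRecord, classify_procedures

__all__ = [
    "MergeRule",
    "MergeDecision",
    "Episode",
    "compute_los",
    "merge_condition",
    "build_episodes",
    "attribute_episode",
    "oracle_build_episodes",
    "write_episodes",
    "read_episodes",
    "EPISODE_COLUMNS",
]

logger = logging.getLogger(__name__)

EPISODE_COLUMNS = [
    "episode_id",
    "patient_id",
    "n_claims",
    "member_claim_ids",
    "index_admission_date",
    "final_discharge_date",
    "year",
    "sex",
    "age_years",
    "ed_admission",
    "has_invasive",
]


@dataclass(frozen=True)
class MergeRule:
    """Date-window parameters of the episode-merging algorithm.

    ``anchor`` chooses what C1 compares the new claim's admission against:
    ``"rolling"`` (default) uses the immediately preceding claim, so merges
    chain transitively; ``"index"`` re-anchors C1 to the episode's first
    claim. ``los_counts_both_ends`` switches the length-of-stay convention
    from discharge − admission (same-day stay = 0, the default) to
    discharge − admission + 1.
    """

    admission_window_days: int = 28
    discharge_window_days: int = 3
    short_stay_days: int = 3
    anchor: str = "rolling"
    los_counts_both_ends: bool = False

    def __post_init__(self) -> None:
        for name in ("admission_window_days", "discharge_window_days", "short_stay_days"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
        if self.anchor not in ("rolling", "index"):
            raise ValueError(f"anchor must be 'rolling' or 'index', got {self.anchor!r}")


class MergeDecision(NamedTuple):
    merge: bool
    conditions_met: frozenset[str]


@dataclass(frozen=True)
class Episode:
    """A discrete AMI admission episode aggregated from >=1 claims."""

    episode_id: str
    patient_id: str
    member_claim_ids: tuple[str, ...]
    index_admission_date: dt.date
    final_discharge_date: dt.date
    year: int
    sex: str
    age_years: int
    ed_admission: bool
    has_invasive: bool

    @property
    def n_claims(self) -> int:
        return len(self.member_claim_ids)


def compute_los(claim: ClaimRecord, rule: MergeRule | None = None) -> int:
    """Length of stay in whole days (same-day discharge -> 0 by default)."""
    days = (claim.discharge_date - claim.admission_date).days
    if rule is not None and rule.los_counts_both_ends:
        days += 1
    return days


def merge_condition(
    first: ClaimRecord, second: ClaimRecord, rule: MergeRule | None = None
) -> MergeDecision:
    """Evaluate the three merge conditions for an ordered claim pair.

    Requires both claims to belong to the same patient and
    ``second.admission_date >= first.admission_date`` (claims pre-sorted).
    """
    rule = rule or MergeRule()
    if first.patient_id != second.patient_id:
        raise ValueError(
            f"merge_condition called across patients "
            f"({first.patient_id!r} vs {second.patient_id!r})"
        )
    if second.admission_date < first.admission_date:
        raise ValueError(
            f"claims out of order: {second.claim_id} admitted before {first.claim_id}"
        )
    met = set()
    if (second.admission_date - first.admission_date).days <= rule.admission_window_days:
        met.add("C1")
    if (second.admission_date - first.discharge_date).days <= rule.discharge_window_days:
        met.add("C2")
    if compute_los(second, rule) < rule.short_stay_days:
        met.add("C3")
    return MergeDecision(bool(met), frozenset(met))


def _sort_key(claim: ClaimRecord):
    # Deterministic tie-break: admission date, then discharge, then claim_id.
    return (claim.admission_date, claim.discharge_date, claim.claim_id)


def attribute_episode(
    member_claims: Sequence[ClaimRecord],
    *,
    case_def: CaseDefinition | None = None,
    ed_policy: str = "index",
    episode_id: str = "",
) -> Episode:
    """Aggregate an ordered group of claims into an attributed Episode.

    Year, sex and age come from the index (earliest-admitted) claim; under
    the default ``index`` policy the emergency-department flag does too,
    while ``any`` marks the episode as an ED admission if any member claim
    was. The invasive flag is true when any member claim carries an
    angiography or revascularization code. Sex/age disagreements across a
    patient's claims are logged and resolved in favour of the index claim.
    """
    if not member_claims:
        raise ValueError("attribute_episode requires at least one member claim")
    if ed_policy not in ("index", "any"):
        raise ValueError(f"ed_policy must be 'index' or 'any', got {ed_policy!r}")
    patient_ids = {c.patient_id for c in member_claims}
    if len(patient_ids) != 1:
        raise ValueError(f"member claims span multiple patients: {sorted(patient_ids)}")
    index = member_claims[0]
    if {c.sex for c in member_claims} != {index.sex} or {
        c.age_years for c in member_claims
    } != {index.age_years}:
        logger.warning(
            "patient %s: sex/age differ across claims of one episode; "
            "using index claim %s",
            index.patient_id,
            index.claim_id,
        )
    if ed_policy == "index":
        ed = index.admission_route == "emergency"
    else:
        ed = any(c.admission_route == "emergency" for c in member_claims)
    has_invasive = any(
        classify_procedures(c, case_def).has_invasive for c in member_claims
    )
    return Episode(
        episode_id=episode_id or f"{index.patient_id}-E1",
        patient_id=index.patient_id,
        member_claim_ids=tuple(c.claim_id for c in member_claims),
        index_admission_date=index.admission_date,
        final_discharge_date=max(c.discharge_date for c in member_claims),
        year=index.admission_date.year,
        sex=index.sex,
        age_years=index.age_years,
        ed_admission=ed,
        has_invasive=has_invasive,
    )


def _group_by_patient(claims: Iterable[ClaimRecord]) -> dict[str, list[ClaimRecord]]:
    groups: dict[str, list[ClaimRecord]] = {}
    for claim in claims:
        groups.setdefault(claim.patient_id, []).append(claim)
    for members in groups.values():
        members.sort(key=_sort_key)
    return groups


def _attribute_groups(
    grouped: dict[str, list[list[ClaimRecord]]],
    case_def: CaseDefinition | None,
    ed_policy: str,
) -> list[Episode]:
    episodes: list[Episode] = []
    for patient_id in sorted(grouped):
        for k, members in enumerate(grouped[patient_id], start=1):
            episodes.append(
                attribute_episode(
                    members,
                    case_def=case_def,
                    ed_policy=ed_policy,
                    episode_id=f"{patient_id}-E{k:03d}",
                )
            )
    return episodes


def build_episodes(
    claims: Iterable[ClaimRecord],
    rule: MergeRule | None = None,
    *,
    case_def: CaseDefinition | None = None,
    ed_policy: str = "index",
) -> list[Episode]:
    """Partition qualifying claims into episodes by a sequential scan.

    Per patient, claims are sorted by (admission date, discharge date,
    claim id); each claim merges into the current episode when
    :func:`merge_condition` against the anchor claim fires, otherwise it
    opens a new episode. The output is invariant to input row order and
    every claim belongs to exactly one episode.
    """
    rule = rule or MergeRule()
    grouped_eps: dict[str, list[list[ClaimRecord]]] = {}
    for patient_id, members in _group_by_patient(claims).items():
        patient_eps: list[list[ClaimRecord]] = []
        current: list[ClaimRecord] = []
        for claim in members:
            if not current:
                current = [claim]
                continue
            anchor = current[0] if rule.anchor == "index" else current[-1]
            if rule.anchor == "index":
                # C1 against the episode's first claim; C2/C3 still compare
                # with the immediately preceding claim.
                decision_index = merge_condition(anchor, claim, rule)
                decision_prev = merge_condition(current[-1], claim, rule)
                met = (decision_index.conditions_met & {"C1"}) | (
                    decision_prev.conditions_met & {"C2", "C3"}
                )
                merge = bool(met)
            else:
                merge = merge_condition(anchor, claim, rule).merge
            if merge:
                current.append(claim)
            else:
                patient_eps.append(current)
                current = [claim]
        if current:
            patient_eps.append(current)
        grouped_eps[patient_id] = patient_eps
    return _attribute_groups(grouped_eps, case_def, ed_policy)


class _UnionFind:
    """Minimal union-find for the verification oracle."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def oracle_build_episodes(
    claims: Iterable[ClaimRecord],
    rule: MergeRule | None = None,
    *,
    case_def: CaseDefinition | None = None,
    ed_policy: str = "index",
) -> list[Episode]:
    """Test-support oracle: connected components over consecutive-pair edges.

    Per patient, builds the graph on sorted claims with an edge between each
    consecutive pair satisfying :func:`merge_condition`, and returns its
    connected components as episodes. Must equal :func:`build_episodes`
    output exactly (with the rolling anchor); kept as an independent
    implementation for equivalence testing.
    """
    rule = rule or MergeRule()
    grouped_eps: dict[str, list[list[ClaimRecord]]] = {}
    for patient_id, members in _group_by_patient(claims).items():
        uf = _UnionFind(len(members))
        for i in range(len(members) - 1):
            if merge_condition(members[i], members[i + 1], rule).merge:
                uf.union(i, i + 1)
        components: dict[int, list[ClaimRecord]] = {}
        for i, claim in enumerate(members):
            components.setdefault(uf.find(i), []).append(claim)
        grouped_eps[patient_id] = [
            components[root] for root in sorted(components)
        ]
    return _attribute_groups(grouped_eps, case_def, ed_policy)


# -- episode CSV I/O ---------------------------------------------------------


def write_episodes(episodes: Iterable[Episode], path) -> None:
    """Write episodes as CSV (ISO dates, semicolon-joined member claim ids)."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EPISODE_COLUMNS)
        for e in episodes:
            writer.writerow(
                [
                    e.episode_id,
                    e.patient_id,
                    e.n_claims,
                    ";".join(e.member_claim_ids),
                    e.index_admission_date.isoformat(),
                    e.final_discharge_date.isoformat(),
                    e.year,
                    e.sex,
                    e.age_years,
                    str(e.ed_admission).lower(),
                    str(e.has_invasive).lower(),
                ]
            )


def read_episodes(path) -> list[Episode]:
    import csv

    episodes = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            episodes.append(
                Episode(
                    episode_id=row["episode_id"],
                    patient_id=row["patient_id"],
                    member_claim_ids=tuple(row["member_claim_ids"].split(";")),
                    index_admission_date=dt.date.fromisoformat(row["index_admission_date"]),
                    final_discharge_date=dt.date.fromisoformat(row["final_discharge_date"]),
                    year=int(row["year"]),
                    sex=row["sex"],
                    age_years=int(row["age_years"]),
                    ed_admission=row["ed_admission"] == "true",
                    has_invasive=row["has_invasive"] == "true",
                )
            )
    return episodes
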