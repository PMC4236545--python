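"""Domain types for ego-centric survey records and the shared category codebooks.

A survey wave in this design interviews every eligible resident of a small
township.  Each respondent (the *ego*) fills two rosters: a spouse roster
(one entry if living with a spouse) and a discussion roster of up to five
*alters* — "people with whom you most often discussed things that were
important to you".  For every named member the ego reports identifying
information (a three-token name, gender, age, district of residence) and tie
attributes (relationship type, cohabitation, a 4-level emotional-closeness
code and an 8-level contact-frequency code), plus a member-by-member
acquaintance matrix.

The types here are shared by the synthetic generator, the metric modules and
the entity-resolution stage; the codebook pins down the category recodes
(contact days/year, kin grouping, 3-group self-rated health, age bins) so
every stage agrees on them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GENDERS",
    "MARITAL_STATUSES",
    "EDUCATION_LEVELS",
    "RELATIONSHIPS",
    "SLOTS",
    "CONTACT_LABELS",
    "PersonRecord",
    "AlterReport",
    "EgoNetwork",
    "Codebook",
    "default_codebook",
    "validate_survey",
    "response_rate_percent",
    "write_survey_csv",
    "read_survey_csv",
    "SurveyParseError",
]

GENDERS = ("male", "female")
MARITAL_STATUSES = ("living_with_spouse", "separated_divorced_widowed", "never_married")
EDUCATION_LEVELS = ("none", "elementary_or_seodang", "middle_school_plus")
RELATIONSHIPS = (
    "spouse",
    "parent",
    "child",
    "sibling",
    "relative_in_law",
    "neighbor",
    "friend",
    "clergy",
    "health_professional",
    "social_worker",
    "other",
)
SLOTS = ("spouse", "d1", "d2", "d3", "d4", "d5")
DISCUSSION_SLOTS = SLOTS[1:]

#: Labels of the 8-point contact-frequency scale, most to least frequent.
CONTACT_LABELS = (
    "every_day",
    "several_times_a_week",
    "once_a_week",
    "a_couple_times_a_month",
    "once_a_month",
    "several_times_a_year",
    "a_couple_times_a_year",
    "less_than_once_a_year",
)


@dataclass(frozen=True)
class PersonRecord:
    """One roster individual of the township population."""

    person_id: str
    name: tuple[str, str, str]
    gender: str
    age: int
    district: str
    marital_status: str
    education: str
    srh: int  # self-rated health, 1 (poor) .. 5 (excellent)
    n_chronic: int
    years_in_village: int
    is_respondent: bool

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.srh not in {1, 2, 3, 4, 5}:
            raise ValueError(f"srh must be in 1..5, got {self.srh}")
        if not self.district:
            raise ValueError("district must be non-empty")


@dataclass(frozen=True)
class AlterReport:
    """One ego's description of one network member (identity + tie attributes)."""

    ego_id: str
    slot: str  # "spouse" or "d1".."d5"
    name: tuple[str, str, str]
    gender: str
    age: int
    district: str
    relationship: str
    cohabiting: bool
    closeness: int  # 1 (not very close) .. 4 (extremely close)
    contact_category: int  # 1 (every day) .. 8 (less than once per year)

    def __post_init__(self) -> None:
        if self.slot not in SLOTS:
            raise ValueError(f"unknown slot {self.slot!r}")
        if self.closeness not in {1, 2, 3, 4}:
            raise ValueError(f"closeness must be in 1..4, got {self.closeness}")
        if self.contact_category not in range(1, 9):
            raise ValueError(
                f"contact_category must be in 1..8, got {self.contact_category}"
            )


@dataclass
class EgoNetwork:
    """An ego, its named members and the member-member acquaintance matrix.

    ``acquaintance[i, j] == 1`` means members ``i`` and ``j`` have spoken to
    each other (per the ego's report); the matrix is symmetric with a zero
    diagonal, ordered as ``members``.
    """

    ego: PersonRecord
    members: list[AlterReport]
    acquaintance: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.members)
        self.acquaintance = np.asarray(self.acquaintance, dtype=int).reshape(m, m)

    @property
    def size(self) -> int:
        return len(self.members)

    def has_spouse(self) -> bool:
        return any(r.slot == "spouse" for r in self.members)


@dataclass
class Codebook:
    """Category recodes shared by all pipeline stages.

    ``contact_days`` maps the 8 contact-frequency categories to approximate
    days of contact per year and must be strictly decreasing from category 1
    ("every day") to category 8 ("less than once per year").
    ``kin_relationships`` is the set of relationship labels counted as kin in
    the proportion-of-kin measure; the default includes the spouse (a
    deliberate, documented convention — drop ``"spouse"`` from the set to
    change it).
    """

    contact_days: dict[int, float]
    kin_relationships: frozenset[str]
    srh_3group: dict[int, str]
    age_bin_edges: tuple[int, int] = (64, 75)  # <=64 | 65-74 | >=75

    def __post_init__(self) -> None:
        days = [self.contact_days[c] for c in range(1, 9)]
        if any(nxt >= prev for prev, nxt in zip(days, days[1:])):
            raise ValueError("contact_days must be strictly decreasing over 1..8")
        unmapped = set(self.srh_3group) - {1, 2, 3, 4, 5}
        if unmapped or set(self.srh_3group) != {1, 2, 3, 4, 5}:
            raise ValueError("srh_3group must map exactly the codes 1..5")

    def age_group(self, age: int) -> str:
        lo, hi = self.age_bin_edges
        if age <= lo:
            return f"<={lo}"
        if age < hi:
            return f"{lo + 1}-{hi - 1}"
        return f">={hi}"

    def is_kin(self, relationship: str) -> bool:
        return relationship in self.kin_relationships

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = {
            "contact_days": {int(k): float(v) for k, v in self.contact_days.items()},
            "kin_relationships": sorted(self.kin_relationships),
            "srh_3group": {int(k): v for k, v in self.srh_3group.items()},
            "age_bin_edges": list(self.age_bin_edges),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Codebook":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            contact_days={int(k): float(v) for k, v in data["contact_days"].items()},
            kin_relationships=frozenset(data["kin_relationships"]),
            srh_3group={int(k): str(v) for k, v in data["srh_3group"].items()},
            age_bin_edges=tuple(data["age_bin_edges"]),
        )


def default_codebook() -> Codebook:
    """The default codebook.

    Contact days/year pin the four conventional anchors (every day = 365,
    several times a week = 182, once a month = 12, a couple times a year = 2)
    and fill the remaining categories monotonically: once a week = 52, a
    couple times a month = 30, several times a year = 6, less than once per
    year = 0.5.  Self-rated health codes 1-2 collapse to "poor/somewhat
    poor", 3 stays "good", 4-5 collapse to "very good/excellent".
    """
    return Codebook(
        contact_days={1: 365.0, 2: 182.0, 3: 52.0, 4: 30.0, 5: 12.0, 6: 6.0, 7: 2.0, 8: 0.5},
        kin_relationships=frozenset(
            {"spouse", "parent", "child", "sibling", "relative_in_law"}
        ),
        srh_3group={
            1: "poor_somewhat_poor",
            2: "poor_somewhat_poor",
            3: "good",
            4: "very_good_excellent",
            5: "very_good_excellent",
        },
    )


def response_rate_percent(n_completed: int, n_eligible: int) -> float:
    """Survey response rate, in percent, rounded to two decimals."""
    if n_eligible <= 0:
        raise ValueError("n_eligible must be positive")
    return round(100.0 * n_completed / n_eligible, 2)


def validate_survey(
    roster: Sequence[PersonRecord], surveys: Sequence[EgoNetwork]
) -> list[str]:
    """Check the survey invariants; returns violations as strings (empty = clean).

    Checks: ego ids resolve to roster respondents, at most one spouse slot and
    five discussion slots per ego, acquaintance matrices square/symmetric with
    zero diagonal, all category codes in range.  Violations are data, not
    exceptions: the list describes every problem found.
    """
    problems: list[str] = []
    roster_ids = {p.person_id for p in roster}
    seen_egos: set[str] = set()
    for net in surveys:
        eid = net.ego.person_id
        if eid not in roster_ids:
            problems.append(f"ego {eid}: not on roster")
        if eid in seen_egos:
            problems.append(f"ego {eid}: duplicate survey")
        seen_egos.add(eid)
        n_spouse = sum(1 for r in net.members if r.slot == "spouse")
        n_disc = sum(1 for r in net.members if r.slot != "spouse")
        if n_spouse > 1:
            problems.append(f"ego {eid}: {n_spouse} spouse slots")
        if n_disc > 5:
            problems.append(f"ego {eid}: {n_disc} discussion alters (max 5)")
        slots = [r.slot for r in net.members]
        if len(set(slots)) != len(slots):
            problems.append(f"ego {eid}: repeated slot labels")
        for r in net.members:
            if r.ego_id != eid:
                problems.append(f"ego {eid}: member report carries ego_id {r.ego_id}")
            if r.gender not in GENDERS:
                problems.append(f"ego {eid} slot {r.slot}: unknown gender {r.gender!r}")
            if r.relationship not in RELATIONSHIPS:
                problems.append(
                    f"ego {eid} slot {r.slot}: unknown relationship {r.relationship!r}"
                )
        m = len(net.members)
        A = net.acquaintance
        if A.shape != (m, m):
            problems.append(f"ego {eid}: acquaintance matrix shape {A.shape} != ({m}, {m})")
            continue
        if m and np.any(np.diag(A) != 0):
            problems.append(f"ego {eid}: acquaintance diagonal not zero")
        if not np.array_equal(A, A.T):
            problems.append(f"ego {eid}: acquaintance matrix not symmetric")
        if m and not np.isin(A, (0, 1)).all():
            problems.append(f"ego {eid}: acquaintance entries not 0/1")
    return problems


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

ROSTER_COLUMNS = [
    "person_id",
    "name_token1",
    "name_token2",
    "name_token3",
    "gender",
    "age",
    "district",
    "marital_status",
    "education",
    "srh",
    "n_chronic",
    "years_in_village",
    "is_respondent",
]
EGONET_COLUMNS = [
    "ego_id",
    "slot",
    "name_token1",
    "name_token2",
    "name_token3",
    "gender",
    "age",
    "district",
    "relationship",
    "cohabiting",
    "closeness",
    "contact_category",
]
ACQUAINT_COLUMNS = ["ego_id", "slot_a", "slot_b", "acquainted"]


class SurveyParseError(ValueError):
    """Raised when a survey CSV file does not conform to the documented schema."""


def write_survey_csv(
    roster: Sequence[PersonRecord],
    surveys: Sequence[EgoNetwork],
    path: str | Path,
) -> dict[str, Path]:
    """Write ``roster.csv``, ``egonet.csv`` and ``acquaint.csv`` under ``path``.

    All files are UTF-8, comma-delimited, with a header row; acquaintance is
    stored in long form over unordered slot pairs (slot_a < slot_b in roster
    order).  Output is deterministic for identical inputs.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    roster_rows = [
        {
            "person_id": p.person_id,
            "name_token1": p.name[0],
            "name_token2": p.name[1],
            "name_token3": p.name[2],
            "gender": p.gender,
            "age": p.age,
            "district": p.district,
            "marital_status": p.marital_status,
            "education": p.education,
            "srh": p.srh,
            "n_chronic": p.n_chronic,
            "years_in_village": p.years_in_village,
            "is_respondent": int(p.is_respondent),
        }
        for p in roster
    ]
    ego_rows = []
    acq_rows = []
    for net in surveys:
        for r in net.members:
            ego_rows.append(
                {
                    "ego_id": r.ego_id,
                    "slot": r.slot,
                    "name_token1": r.name[0],
                    "name_token2": r.name[1],
                    "name_token3": r.name[2],
                    "gender": r.gender,
                    "age": r.age,
                    "district": r.district,
                    "relationship": r.relationship,
                    "cohabiting": int(r.cohabiting),
                    "closeness": r.closeness,
                    "contact_category": r.contact_category,
                }
            )
        for i in range(net.size):
            for j in range(i + 1, net.size):
                acq_rows.append(
                    {
                        "ego_id": net.ego.person_id,
                        "slot_a": net.members[i].slot,
                        "slot_b": net.members[j].slot,
                        "acquainted": int(net.acquaintance[i, j]),
                    }
                )
    paths = {
        "roster": outdir / "roster.csv",
        "egonet": outdir / "egonet.csv",
        "acquaint": outdir / "acquaint.csv",
    }
    pd.DataFrame(roster_rows, columns=ROSTER_COLUMNS).to_csv(paths["roster"], index=False)
    pd.DataFrame(ego_rows, columns=EGONET_COLUMNS).to_csv(paths["egonet"], index=False)
    pd.DataFrame(acq_rows, columns=ACQUAINT_COLUMNS).to_csv(paths["acquaint"], index=False)
    return paths


def _require_columns(df: pd.DataFrame, cols: Sequence[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SurveyParseError(f"{fname}: missing required column(s) {missing}")


def read_survey_csv(path: str | Path) -> tuple[list[PersonRecord], list[EgoNetwork]]:
    """Read the three survey CSV files back into domain objects.

    Inverse of :func:`write_survey_csv`.  Malformed rows raise
    :class:`SurveyParseError` with the file name and (1-based, header
    included) line number of the offending row.
    """
    indir = Path(path)
    roster_df = pd.read_csv(indir / "roster.csv", dtype=str, keep_default_na=False)
    ego_df = pd.read_csv(indir / "egonet.csv", dtype=str, keep_default_na=False)
    acq_df = pd.read_csv(indir / "acquaint.csv", dtype=str, keep_default_na=False)
    _require_columns(roster_df, ROSTER_COLUMNS, "roster.csv")
    _require_columns(ego_df, EGONET_COLUMNS, "egonet.csv")
    _require_columns(acq_df, ACQUAINT_COLUMNS, "acquaint.csv")

    roster: list[PersonRecord] = []
    for idx, row in roster_df.iterrows():
        try:
            roster.append(
                PersonRecord(
                    person_id=row["person_id"],
                    name=(row["name_token1"], row["name_token2"], row["name_token3"]),
                    gender=row["gender"],
                    age=int(row["age"]),
                    district=row["district"],
                    marital_status=row["marital_status"],
                    education=row["education"],
                    srh=int(row["srh"]),
                    n_chronic=int(row["n_chronic"]),
                    years_in_village=int(row["years_in_village"]),
                    is_respondent=bool(int(row["is_respondent"])),
                )
            )
        except (ValueError, KeyError) as exc:
            raise SurveyParseError(f"roster.csv line {idx + 2}: {exc}") from exc
    by_id = {p.person_id: p for p in roster}

    reports: dict[str, list[AlterReport]] = {}
    for idx, row in ego_df.iterrows():
        try:
            rep = AlterReport(
                ego_id=row["ego_id"],
                slot=row["slot"],
                name=(row["name_token1"], row["name_token2"], row["name_token3"]),
                gender=row["gender"],
                age=int(row["age"]),
                district=row["district"],
                relationship=row["relationship"],
                cohabiting=bool(int(row["cohabiting"])),
                closeness=int(row["closeness"]),
                contact_category=int(row["contact_category"]),
            )
        except (ValueError, KeyError) as exc:
            raise SurveyParseError(f"egonet.csv line {idx + 2}: {exc}") from exc
        reports.setdefault(rep.ego_id, []).append(rep)

    acq_pairs: dict[str, dict[tuple[str, str], int]] = {}
    for idx, row in acq_df.iterrows():
        try:
            acq_pairs.setdefault(row["ego_id"], {})[(row["slot_a"], row["slot_b"])] = int(
                row["acquainted"]
            )
        except (ValueError, KeyError) as exc:
            raise SurveyParseError(f"acquaint.csv line {idx + 2}: {exc}") from exc

    # an ego with a roster row and any survey content gets an EgoNetwork;
    # respondents with zero members still get an (empty) one
    surveys: list[EgoNetwork] = []
    ego_ids = [p.person_id for p in roster if p.is_respondent]
    known = set(ego_ids)
    for eid in reports:
        if eid not in known:
            raise SurveyParseError(f"egonet.csv: ego_id {eid!r} not a roster respondent")
    slot_order = {s: k for k, s in enumerate(SLOTS)}
    for eid in ego_ids:
        members = sorted(reports.get(eid, []), key=lambda r: slot_order[r.slot])
        m = len(members)
        A = np.zeros((m, m), dtype=int)
        pairs = acq_pairs.get(eid, {})
        index = {r.slot: k for k, r in enumerate(members)}
        for (sa, sb), v in pairs.items():
            if sa not in index or sb not in index:
                raise SurveyParseError(
                    f"acquaint.csv: ego {eid} pair ({sa}, {sb}) names unknown slot"
                )
            A[index[sa], index[sb]] = v
            A[index[sb], index[sa]] = v
        surveys.append(EgoNetwork(ego=by_id[eid], members=members, acquaintance=A))
    return roster, surveys
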