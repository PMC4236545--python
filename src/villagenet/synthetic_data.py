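"""Synthetic township generator with planted ground truth.

Emulates a complete-population social survey of a rural township of older
adults: a roster of residents aged 60+ and their spouses, each respondent's
ego-centric network (spouse roster plus up to five discussion alters with
possibly misreported identifiers), and the alter-alter acquaintance matrix.
Because every downstream stage (entity resolution, complete-network metrics,
component typology, health-association tables) is exercised on this output,
the generator also emits the ground truth it planted: which canonical person
each alter mention denotes, the directed ego→alter ties at person level, and
the membership of an optionally planted, socially segregated district.

Design notes
------------
* Names are three tokens from a finite alphabet — an abstraction of
  three-character Korean names that keeps the "two of three tokens" duplicate
  rule exact without any text handling.  A duplicate mention perturbs at most
  one token, and misreports age by at most ``age_report_noise_max`` years, so
  every mention stays matchable to its canonical person under the default
  match rule.
* Self-rated health (5-point) is drawn from a latent Gaussian whose mean
  increases with the person's network size (``srh_network_effect`` per
  member) and drops by ``segregated_srh_penalty`` inside the segregated
  district, then rounded and clipped to 1..5.  This plants the
  size→health and segregation→health associations downstream stages are
  meant to recover.
* A fraction ``p_outside_alter`` of discussion alters are persons living
  outside the township (grown children, distant kin); each is a distinct
  canonical person with a unique outside district, and they are what the
  complete-network exclusion filter removes.
* If ``segregated_district`` is set, members of that district name alters
  only among themselves (and their spouses), and nobody outside names them:
  the district forms its own weak component by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .survey_io import (
    AlterReport,
    EgoNetwork,
    PersonRecord,
    read_survey_csv,
    write_survey_csv,
)

__all__ = [
    "TownshipConfig",
    "GroundTruth",
    "ConfigError",
    "generate_township",
    "district_labels",
    "write_survey_csv",
    "read_survey_csv",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


def district_labels(n_districts: int) -> list[str]:
    return [f"R{i + 1}" for i in range(n_districts)]


@dataclass
class TownshipConfig:
    """Parameters of the synthetic township.

    Defaults emulate a complete survey of a rural township of older adults:
    860 eligible residents, ten districts ("Ri"), 70% living with a spouse,
    mean network size ≈ 3.1 (spouse plus ≈ 2.4 discussion alters), very dense
    ego networks (target 0.98), roughly 700 contact-days/year per ego, and a
    ~95% response rate.
    """

    n_population: int = 860
    n_districts: int = 10
    district_weights: Sequence[float] | None = None  # default: uniform
    p_married: float = 0.70
    p_respondent: float = 0.9465
    mean_alters: float = 2.37  # expected discussion alters per ego, in [0, 5]
    within_district_tie_prob: float = 0.85  # relative alter-choice weights
    between_district_tie_prob: float = 0.15
    acquaintance_density_target: float = 0.98
    p_outside_alter: float = 0.15  # alter lives outside the township
    # household-level outward orientation: some households' discussion ties
    # point almost entirely outside the township (grown children who moved
    # away) and their members are rarely named by other residents -- the
    # mechanism behind dyadic components (both spouses outward) and lone
    # nodes in the retained network
    p_outward_household: float = 0.12
    outward_alter_prob: float = 0.90
    outward_named_weight: float = 0.02
    name_token_alphabet_size: int = 60
    p_name_perturbation: float = 0.20  # one token of a mention altered
    age_report_noise_max: int = 2  # max |misreport| in years, must stay < 5
    segregated_district: int | None = None  # 0-based district index
    segregated_srh_penalty: float = 0.0
    # latent link from network size to self-rated health (see module notes)
    srh_base: float = 1.95
    srh_network_effect: float = 0.20
    srh_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_population < 0:
            raise ConfigError("n_population: must be >= 0")
        if self.n_districts < 1:
            raise ConfigError("n_districts: must be >= 1")
        if self.district_weights is not None:
            w = np.asarray(self.district_weights, dtype=float)
            if len(w) != self.n_districts:
                raise ConfigError("district_weights: length must equal n_districts")
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ConfigError("district_weights: must be >= 0 and sum to 1")
        if not 0.0 <= self.mean_alters <= 5.0:
            raise ConfigError("mean_alters: must be in [0, 5]")
        for name in (
            "p_married",
            "p_respondent",
            "within_district_tie_prob",
            "between_district_tie_prob",
            "acquaintance_density_target",
            "p_outside_alter",
            "p_outward_household",
            "outward_alter_prob",
            "outward_named_weight",
            "p_name_perturbation",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1]")
        if self.name_token_alphabet_size < 3:
            raise ConfigError("name_token_alphabet_size: must be >= 3")
        if not 0 <= self.age_report_noise_max < 5:
            raise ConfigError(
                "age_report_noise_max: must be in [0, 5) so duplicates stay matchable"
            )
        if self.segregated_district is not None and not (
            0 <= self.segregated_district < self.n_districts
        ):
            raise ConfigError("segregated_district: out of range")

    def weights(self) -> np.ndarray:
        if self.district_weights is None:
            return np.full(self.n_districts, 1.0 / self.n_districts)
        return np.asarray(self.district_weights, dtype=float)


@dataclass
class GroundTruth:
    """What the generator planted, keyed for downstream scoring.

    ``identity_map`` sends every alter mention ``(ego_id, slot)`` to the
    canonical person id it denotes (roster id or outside-person id);
    ``true_tie_list`` is the directed ego→alter relation at person level;
    ``planted_component_members`` are the roster ids of the segregated
    district (empty when none was planted).  ``outside_persons`` carries the
    canonical records of non-township alters so resolution accuracy can be
    scored over every mention.
    """

    identity_map: dict[tuple[str, str], str] = field(default_factory=dict)
    planted_component_members: list[str] = field(default_factory=list)
    true_tie_list: list[tuple[str, str]] = field(default_factory=list)
    outside_persons: dict[str, PersonRecord] = field(default_factory=dict)


# relationship / closeness / contact-frequency distributions; chosen to give
# kin share ~0.55 (spouse included), mean closeness ~3.3 and contact volume
# ~700 days/year at the default roster composition
_ROSTER_ALTER_RELATIONSHIPS = ("neighbor", "friend", "sibling", "relative_in_law", "other")
_ROSTER_ALTER_REL_P = (0.40, 0.25, 0.20, 0.10, 0.05)
_OUTSIDE_ALTER_RELATIONSHIPS = ("child", "relative_in_law", "friend", "other")
_OUTSIDE_ALTER_REL_P = (0.70, 0.10, 0.10, 0.10)
_SPOUSE_CLOSENESS_P = (0.02, 0.08, 0.35, 0.55)
_ALTER_CLOSENESS_P = (0.03, 0.12, 0.45, 0.40)
_LOCAL_CONTACT_P = (0.35, 0.30, 0.15, 0.10, 0.05, 0.03, 0.015, 0.005)
_OUTSIDE_CONTACT_P = (0.02, 0.08, 0.15, 0.20, 0.25, 0.15, 0.10, 0.05)
_EDUCATION_P = (0.30, 0.41, 0.29)
EDU = ("none", "elementary_or_seodang", "middle_school_plus")


def _token_pool(size: int) -> list[str]:
    return [f"T{i:02d}" for i in range(size)]


def generate_township(
    config: TownshipConfig,
) -> tuple[list[PersonRecord], list[EgoNetwork], GroundTruth]:
    """Generate (roster, surveys, ground truth) for one synthetic township.

    Identical configs (including seed) produce identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tokens = _token_pool(config.name_token_alphabet_size)
    districts = district_labels(config.n_districts)
    weights = config.weights()
    seg_label = (
        districts[config.segregated_district]
        if config.segregated_district is not None
        else None
    )

    # ---- roster: singles and married couples ---------------------------
    # p_married is the person-level share living with a spouse, so the
    # couple count is fixed up front rather than drawn per household
    n_couples = int(round(config.n_population * config.p_married / 2))
    people: list[dict] = []

    # planted identities must stay distinguishable under the duplicate rule:
    # redraw a name whenever someone of the same district and gender within
    # the rule's age window (widened by the maximum misreport both ways)
    # would share two or more positional tokens
    taken: dict[tuple[str, str], list[tuple[tuple, int]]] = {}
    age_window = 5 + 2 * config.age_report_noise_max

    def draw_name(district: str, gender: str, age: int) -> tuple[str, str, str]:
        block = taken.setdefault((district, gender), [])
        for _ in range(100):
            name = tuple(tokens[i] for i in rng.integers(0, len(tokens), size=3))
            confusable = any(
                sum(a == b for a, b in zip(name, other)) >= 2
                and abs(age - other_age) < age_window
                for other, other_age in block
            )
            if not confusable:
                block.append((name, age))
                return name
        block.append((name, age))
        return name  # tiny alphabets may not admit a clash-free name
    while len(people) < config.n_population:
        married = (
            len(people) < 2 * n_couples and config.n_population - len(people) >= 2
        )
        district = districts[rng.choice(config.n_districts, p=weights)]
        outward = (
            rng.random() < config.p_outward_household and district != seg_label
        )
        age = int(np.clip(round(rng.normal(72.0, 7.0)), 60, 100))
        gender = "male" if rng.random() < 0.5 else "female"
        name = draw_name(district, gender, age)
        base = {
            "district": district,
            "outward": outward,
            "education": EDU[rng.choice(3, p=_EDUCATION_P)],
            "n_chronic": int(rng.poisson(2.07)),
        }
        person = dict(base, age=age, gender=gender, name=name)
        if married:
            spouse_age = int(np.clip(age + round(rng.normal(0.0, 4.0)), 55, 100))
            spouse_gender = "female" if gender == "male" else "male"
            spouse = dict(
                base,
                age=spouse_age,
                gender=spouse_gender,
                name=draw_name(district, spouse_gender, spouse_age),
                education=EDU[rng.choice(3, p=_EDUCATION_P)],
                n_chronic=int(rng.poisson(2.07)),
            )
            person["marital"] = spouse["marital"] = "living_with_spouse"
            person["spouse_idx"] = len(people) + 1
            spouse["spouse_idx"] = len(people)
            people.append(person)
            people.append(spouse)
        else:
            person["marital"] = (
                "never_married" if rng.random() < 0.03 else "separated_divorced_widowed"
            )
            person["spouse_idx"] = None
            people.append(person)

    n = len(people)
    for i, p in enumerate(people):
        p["person_id"] = f"P{i:04d}"
        p["years_in_village"] = int(np.clip(round(rng.normal(48.0, 15.0)), 1, p["age"]))
        p["is_respondent"] = bool(rng.random() < config.p_respondent)

    # ---- discussion alters (person-level ties) -------------------------
    district_members: dict[str, list[int]] = {d: [] for d in districts}
    for i, p in enumerate(people):
        district_members[p["district"]].append(i)

    n_alters = rng.binomial(5, config.mean_alters / 5.0, size=n) if n else np.array([], int)
    outside_count = 0
    alter_targets: list[list[str]] = [[] for _ in range(n)]
    truth = GroundTruth()
    if seg_label is not None:
        truth.planted_component_members = [
            p["person_id"] for p in people if p["district"] == seg_label
        ]

    for i, p in enumerate(people):
        k = int(n_alters[i])
        if k == 0:
            continue
        in_seg = p["district"] == seg_label
        if in_seg:
            candidates = [
                j for j in district_members[seg_label] if j != i and j != p["spouse_idx"]
            ]
        else:
            candidates = [
                j
                for j in range(n)
                if j != i
                and j != p["spouse_idx"]
                and people[j]["district"] != seg_label
            ]
        cand_w = np.array(
            [
                (
                    config.within_district_tie_prob
                    if people[j]["district"] == p["district"]
                    else config.between_district_tie_prob
                )
                * (config.outward_named_weight if people[j]["outward"] else 1.0)
                for j in candidates
            ],
            dtype=float,
        )
        p_outside = (
            config.outward_alter_prob if p["outward"] else config.p_outside_alter
        )
        chosen: list[str] = []
        for _ in range(k):
            if in_seg and not candidates:
                break  # isolation of the planted block takes precedence
            if (
                not in_seg
                and rng.random() < p_outside
            ) or not candidates:
                # a distinct person outside the township (e.g. a grown child)
                oid = f"O{outside_count:04d}"
                outside_count += 1
                rec = PersonRecord(
                    person_id=oid,
                    name=tuple(tokens[t] for t in rng.integers(0, len(tokens), size=3)),
                    gender="male" if rng.random() < 0.5 else "female",
                    age=int(np.clip(round(rng.normal(48.0, 12.0)), 20, 90)),
                    district=f"OUT{outside_count:04d}",
                    marital_status="living_with_spouse",
                    education="middle_school_plus",
                    srh=3,
                    n_chronic=0,
                    years_in_village=1,
                    is_respondent=False,
                )
                truth.outside_persons[oid] = rec
                chosen.append(oid)
            else:
                total = cand_w.sum()
                pick = (
                    int(rng.choice(len(candidates), p=cand_w / total))
                    if total > 0
                    else int(rng.integers(0, len(candidates)))
                )
                chosen.append(people[candidates[pick]]["person_id"])
                del candidates[pick]
                cand_w = np.delete(cand_w, pick)
        alter_targets[i] = chosen

    # ---- self-rated health via latent link on network size -------------
    for i, p in enumerate(people):
        size = len(alter_targets[i]) + (1 if p["spouse_idx"] is not None else 0)
        latent = (
            config.srh_base
            + config.srh_network_effect * size
            + rng.normal(0.0, config.srh_noise_sd)
        )
        if p["district"] == seg_label:
            latent -= config.segregated_srh_penalty
        p["srh"] = int(np.clip(round(latent), 1, 5))

    roster = [
        PersonRecord(
            person_id=p["person_id"],
            name=p["name"],
            gender=p["gender"],
            age=p["age"],
            district=p["district"],
            marital_status=p["marital"],
            education=p["education"],
            srh=p["srh"],
            n_chronic=p["n_chronic"],
            years_in_village=p["years_in_village"],
            is_respondent=p["is_respondent"],
        )
        for p in people
    ]
    by_id = {p.person_id: p for p in roster}

    # ---- survey reports with identifier noise --------------------------
    def report(ego: dict, slot: str, target: PersonRecord, relationship: str,
               cohabiting: bool, closeness_p, contact_p) -> AlterReport:
        name = list(target.name)
        if rng.random() < config.p_name_perturbation:
            pos = int(rng.integers(0, 3))
            alternatives = [t for t in tokens if t != name[pos]]
            name[pos] = alternatives[int(rng.integers(0, len(alternatives)))]
        noise = (
            int(rng.integers(-config.age_report_noise_max, config.age_report_noise_max + 1))
            if config.age_report_noise_max
            else 0
        )
        return AlterReport(
            ego_id=ego["person_id"],
            slot=slot,
            name=tuple(name),
            gender=target.gender,
            age=max(0, target.age + noise),
            district=target.district,
            relationship=relationship,
            cohabiting=cohabiting,
            closeness=int(rng.choice(4, p=closeness_p)) + 1,
            contact_category=int(rng.choice(8, p=contact_p)) + 1,
        )

    surveys: list[EgoNetwork] = []
    for i, p in enumerate(people):
        if not p["is_respondent"]:
            continue
        members: list[AlterReport] = []
        if p["spouse_idx"] is not None:
            spouse = by_id[people[p["spouse_idx"]]["person_id"]]
            members.append(
                report(p, "spouse", spouse, "spouse", True, _SPOUSE_CLOSENESS_P,
                       (1.0, 0, 0, 0, 0, 0, 0, 0))
            )
            truth.identity_map[(p["person_id"], "spouse")] = spouse.person_id
            truth.true_tie_list.append((p["person_id"], spouse.person_id))
        for s, target_id in enumerate(alter_targets[i]):
            slot = f"d{s + 1}"
            outside = target_id.startswith("O")
            target = truth.outside_persons[target_id] if outside else by_id[target_id]
            if outside:
                rel = _OUTSIDE_ALTER_RELATIONSHIPS[
                    rng.choice(len(_OUTSIDE_ALTER_REL_P), p=_OUTSIDE_ALTER_REL_P)
                ]
                cohab = bool(rng.random() < 0.15)
                contact_p = _OUTSIDE_CONTACT_P
            else:
                rel = _ROSTER_ALTER_RELATIONSHIPS[
                    rng.choice(len(_ROSTER_ALTER_REL_P), p=_ROSTER_ALTER_REL_P)
                ]
                cohab = False
                contact_p = _LOCAL_CONTACT_P
            members.append(
                report(p, slot, target, rel, cohab, _ALTER_CLOSENESS_P, contact_p)
            )
            truth.identity_map[(p["person_id"], slot)] = target_id
            truth.true_tie_list.append((p["person_id"], target_id))
        m = len(members)
        A = np.zeros((m, m), dtype=int)
        for a in range(m):
            for b in range(a + 1, m):
                A[a, b] = A[b, a] = int(
                    rng.random() < config.acquaintance_density_target
                )
        surveys.append(EgoNetwork(ego=by_id[p["person_id"]], members=members, acquaintance=A))

    return roster, surveys, truth
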