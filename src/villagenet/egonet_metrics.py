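"""Ego-centric network measures.

Six measures per respondent, computed from the ego's own report alone:
network size (spouse plus discussion alters, 0..6), composition (proportion
female / kin / cohabiting), average emotional closeness (1..4), overall
contact volume (days/year summed over members), ego-network density
(acquainted member pairs over all possible pairs) and bridging potential
(indicator that some member is acquainted with no other member).

Density and bridging potential are undefined for networks of fewer than two
members; composition and closeness are undefined for empty networks.
Undefined values are carried as ``NaN`` and propagate — they are never
coerced to zero — so grouped means run over valid respondents only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .survey_io import Codebook, EgoNetwork

__all__ = [
    "EgoMetrics",
    "network_size",
    "composition",
    "average_closeness",
    "contact_volume",
    "ego_density",
    "bridging_potential",
    "compute_ego_metrics",
    "metrics_frame",
]

_UNDEF = float("nan")


@dataclass(frozen=True)
class EgoMetrics:
    ego_id: str
    size: int
    prop_female: float
    prop_kin: float
    prop_cohab: float
    avg_closeness: float
    contact_volume: float
    density: float
    bridging_potential: float  # 0.0 / 1.0 / NaN


def network_size(ego: EgoNetwork) -> int:
    """Member count: spouse (if any) plus discussion alters, in 0..6."""
    return len(ego.members)


def composition(ego: EgoNetwork, codebook: Codebook) -> tuple[float, float, float]:
    """(proportion female, proportion kin, proportion cohabiting) among members.

    Undefined (NaN triple) for an empty network: a proportion over zero
    members is indeterminate, not zero.
    """
    m = len(ego.members)
    if m == 0:
        return (_UNDEF, _UNDEF, _UNDEF)
    f = sum(1 for r in ego.members if r.gender == "female") / m
    k = sum(1 for r in ego.members if codebook.is_kin(r.relationship)) / m
    c = sum(1 for r in ego.members if r.cohabiting) / m
    return (f, k, c)


def average_closeness(ego: EgoNetwork) -> float:
    """Mean of the members' 4-level closeness codes, spouse included.

    Members with a missing code are excluded with a warning; all missing (or
    an empty network) yields NaN.
    """
    codes = []
    for r in ego.members:
        if r.closeness is None:
            warnings.warn(
                f"ego {ego.ego.person_id} slot {r.slot}: missing closeness code, excluded"
            )
            continue
        codes.append(r.closeness)
    return float(np.mean(codes)) if codes else _UNDEF


def contact_volume(ego: EgoNetwork, codebook: Codebook) -> float:
    """Total contact days/year summed over members; 0 for an empty network."""
    total = 0.0
    for r in ego.members:
        if r.contact_category not in codebook.contact_days:
            raise KeyError(
                f"unknown contact category {r.contact_category} "
                f"(ego {ego.ego.person_id}, slot {r.slot})"
            )
        total += codebook.contact_days[r.contact_category]
    return total


def ego_density(ego: EgoNetwork) -> float:
    """Acquainted member pairs / C(size, 2); NaN when size < 2."""
    m = len(ego.members)
    if m < 2:
        return _UNDEF
    A = ego.acquaintance
    acquainted = int(np.triu(A, 1).sum())
    return acquainted / (m * (m - 1) // 2)


def bridging_potential(ego: EgoNetwork) -> float:
    """1.0 iff some member is acquainted with no other member; NaN when size < 2.

    A member with zero acquaintance ties is someone only the ego connects to
    the rest of the personal network, so the ego holds a bridging position.
    A fully dense network (density 1) therefore always scores 0.
    """
    m = len(ego.members)
    if m < 2:
        return _UNDEF
    row_ties = ego.acquaintance.sum(axis=1)
    return 1.0 if (row_ties == 0).any() else 0.0


def compute_ego_metrics(ego: EgoNetwork, codebook: Codebook) -> EgoMetrics:
    f, k, c = composition(ego, codebook)
    return EgoMetrics(
        ego_id=ego.ego.person_id,
        size=network_size(ego),
        prop_female=f,
        prop_kin=k,
        prop_cohab=c,
        avg_closeness=average_closeness(ego),
        contact_volume=contact_volume(ego, codebook),
        density=ego_density(ego),
        bridging_potential=bridging_potential(ego),
    )


def metrics_frame(surveys: Sequence[EgoNetwork], codebook: Codebook) -> pd.DataFrame:
    """One row per ego with all six measures, indexed by ego_id (NaN = undefined)."""
    rows = [compute_ego_metrics(net, codebook).__dict__ for net in surveys]
    df = pd.DataFrame(
        rows,
        columns=[
            "ego_id",
            "size",
            "prop_female",
            "prop_kin",
            "prop_cohab",
            "avg_closeness",
            "contact_volume",
            "density",
            "bridging_potential",
        ],
    )
    return df.set_index("ego_id")
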