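import numpy as np
import pytest

from villagenet import (
    EgoNetwork,
    PersonRecord,
    AlterReport,
    TownshipConfig,
    default_codebook,
    generate_township,
)


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def township():
    """A mid-sized synthetic township shared by read-only tests."""
    cfg = TownshipConfig(n_population=300, seed=1)
    roster, surveys, truth = generate_township(cfg)
    return cfg, roster, surveys, truth


def make_person(pid="P0000", **kw):
    defaults = dict(
        person_id=pid,
        name=("T01", "T02", "T03"),
        gender="female",
        age=70,
        district="R1",
        marital_status="living_with_spouse",
        education="none",
        srh=3,
        n_chronic=1,
        years_in_village=40,
        is_respondent=True,
    )
    defaults.update(kw)
    return PersonRecord(**defaults)


def make_report(ego_id="P0000", slot="d1", **kw):
    defaults = dict(
        ego_id=ego_id,
        slot=slot,
        name=("T04", "T05", "T06"),
        gender="male",
        age=68,
        district="R1",
        relationship="friend",
        cohabiting=False,
        closeness=3,
        contact_category=2,
    )
    defaults.update(kw)
    return AlterReport(**defaults)


def make_ego_network(ego=None, members=(), acquaintance=None):
    ego = ego or make_person()
    members = list(members)
    m = len(members)
    if acquaintance is None:
        acquaintance = np.zeros((m, m), dtype=int)
    return EgoNetwork(ego=ego, members=members, acquaintance=np.asarray(acquaintance))
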