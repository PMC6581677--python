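import datetime as dt

import numpy as np
import pytest

from herdnet.herd_data import Composition, Individual


@pytest.fixture
def rng():
    return np.random.default_rng(20150414)


def make_individual(iid, sex="F", birth="2010-07-01", residences=()):
    return Individual(
        id=iid,
        sex=sex,
        birth_date=dt.date.fromisoformat(birth),
        residences=tuple(
            (loc, dt.date.fromisoformat(s),
             dt.date.fromisoformat(e) if e else None)
            for loc, s, e in residences
        ),
    )


def make_composition(cid="C1", members=("a", "b", "c"), group="g",
                     start="2015-04-14", end="2015-05-24", **kw):
    return Composition(
        id=cid, group=group, members=frozenset(members),
        start_date=dt.date.fromisoformat(start),
        end_date=dt.date.fromisoformat(end), **kw,
    )


def random_symmetric(rng, n, integer=False):
    """Random symmetric non-negative matrix with zero diagonal."""
    m = rng.integers(0, 10, (n, n)).astype(float) if integer \
        else rng.random((n, n)) * 10
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m
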