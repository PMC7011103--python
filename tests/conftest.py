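import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oxlip.library import enumerate_candidates, load_curated_reference


def brute_force_bh(p):
    """Independent step-up BH oracle: q_(i) = min over j>=i of p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted


def brute_force_rule_b_violations(species):
    """Oracle: labels involved in any within-(class, extra-O) pair that
    violates the dominance elution order. ``species``: iterable of
    (label, class, extraO, carbons, double_bonds, rt)."""
    bad = set()
    for a, b in itertools.permutations(species, 2):
        if a[1] != b[1] or a[2] != b[2]:
            continue
        (ca, da), (cb, db) = (a[3], a[4]), (b[3], b[4])
        if ca <= cb and da >= db and (ca, da) != (cb, db) and a[5] > b[5]:
            bad.add(a[0])
            bad.add(b[0])
    return bad

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def candidates():
    """Default candidate library (273 species-compositions)."""
    return enumerate_candidates()


@pytest.fixture(scope="session")
def candidate_by_composition(candidates):
    return {(c.lipid_class.name, c.chain_composition): c for c in candidates}


@pytest.fixture(scope="session")
def curated():
    return load_curated_reference()
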