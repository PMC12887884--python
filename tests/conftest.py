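"""Shared fixtures: synthetic structures and the steering BD run.

The steering fixture is the package's standard two-ladder test system: a
straight cross-section with an arginine ladder flanked by a glutamate
ladder at one end and a lone lysine ladder at the other, so electrostatic
steering should concentrate binding on the unobstructed Lys ladder.  The
BD ensembles here use desk-scale run sizes (150 trajectories per glycan, a
2b escape sphere, 15k step cap, 0.1 ps near timestep).
"""

import numpy as np
import pytest

import gagbind as g
from gagbind.bd_engine import BDParams, run_ensemble

TWO_LADDER_SEQUENCE = "REAAAK"
LYS_SITE = 6     # residue number of the lone lysine ladder
ARG_SITE = 1     # arginine ladder, adjacent to the glutamate ladder


@pytest.fixture(scope="session")
def two_ladder_fibril():
    template = g.build_cross_section(TWO_LADDER_SEQUENCE, layout="ladder_line")
    return g.build_fibril(template, n_layers=8, rise=4.8)


@pytest.fixture(scope="session")
def tau_fibril():
    return g.build_fibril(g.tau_core_template(), n_layers=10, rise=4.8)


@pytest.fixture(scope="session")
def octasaccharide():
    return g.build_glycan(8, "full")


@pytest.fixture(scope="session")
def steering_params(two_ladder_fibril):
    b = BDParams().resolved_radii(two_ladder_fibril)[0]
    return BDParams(dt_near=0.1, b_radius=b, q_radius=2.0 * b,
                    max_steps=15_000, seed=2026)


@pytest.fixture(scope="session")
def steering_runs(two_ladder_fibril, steering_params):
    """BD ensembles for three glycan variants on the two-ladder fibril.

    Keys: 'full8' (octasaccharide, fully sulfated), 'full4' (tetrasaccharide),
    'd6O8' (octasaccharide, 6-O-desulfated).  Values: (glycan, outcomes).
    """
    runs = {}
    for key, n, pattern in [("full8", 8, "full"), ("full4", 4, "full"),
                            ("d6O8", 8, "desulfated_6O")]:
        glycan = g.build_glycan(n, pattern)
        outcomes = run_ensemble([two_ladder_fibril], [glycan], 150,
                                steering_params)
        runs[key] = (glycan, outcomes)
    return runs


def random_pose_near(fibril, rng, max_offset=10.0):
    """Random rigid pose with its translation near the fibril surface."""
    from gagbind.geometry import Pose, random_rotation
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    radius = fibril.bounding_radius * rng.uniform(0.3, 1.0) + \
        rng.uniform(0, max_offset)
    return Pose(random_rotation(rng), fibril.centroid + radius * direction)
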