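import numpy as np
import pytest

import lrvalidate as lv
from lrvalidate.blup import solve_for_phenotypes
from lrvalidate.simulate import _scenario_structure, chol_A, sample_phenotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240308)


def tiny_pedigree():
    """Two founders, two full sibs, one inbred offspring of a parent-offspring mating."""
    return lv.pedigree_from_records(
        animals=[1, 2, 3, 4, 5],
        sires=[0, 0, 1, 1, 1],
        dams=[0, 0, 2, 2, 3],
    )


@pytest.fixture
def sibs_ped():
    return tiny_pedigree()


def make_scenario(founders=60, generations=4, matings=30, offspring=2,
                  prop=0.5, h2=0.3, ped_seed=7, assign_seed=11):
    """Fixed small scenario: pedigree, dataset skeleton, and PEV structure."""
    ped = lv.generate_pedigree(
        lv.PedigreeParams(founders=founders, generations=generations,
                          matings=matings, offspring_per_mating=offspring),
        ped_seed)
    A = lv.additive_relationship(ped)
    L = chol_A(A.values)
    data = lv.assign_phenotypes(ped, prop, assign_seed)
    struct = _scenario_structure(ped, A, L, data, h2, prop, 1.0)
    Z = np.zeros((len(data), len(ped)))
    Z[np.arange(len(data)), ped.positions(data.animals)] = 1.0
    return ped, A, L, data, Z, struct


def draw_ebv_replicates(struct, data, L, Z, n_reps, seed):
    """Replicate whole/partial solves; returns (uhat_w, uhat_p, u_true) stacks."""
    rng = np.random.default_rng(seed)
    n = len(struct.focal)
    UW = np.empty((n_reps, n))
    UP = np.empty((n_reps, n))
    UT = np.empty((n_reps, n))
    keep = ~struct.focal_mask
    for r in range(n_reps):
        y, u = sample_phenotypes(L, Z, np.zeros(Z.shape[0]), struct.model, rng)
        _, uw = solve_for_phenotypes(struct.mme_w, data, y)
        _, up = solve_for_phenotypes(struct.mme_p, data, y[keep])
        UW[r] = uw[struct.focal_pos]
        UP[r] = up[struct.focal_pos]
        UT[r] = u[struct.focal_pos]
    return UW, UP, UT


@pytest.fixture(scope="session")
def replicated_scenario():
    """240-animal scenario with 2000 phenotype replicates (shared across tests)."""
    ped, A, L, data, Z, struct = make_scenario(
        founders=60, generations=4, matings=30, offspring=2,
        prop=0.5, h2=0.3)
    UW, UP, UT = draw_ebv_replicates(struct, data, L, Z, n_reps=2000, seed=99)
    return struct, UW, UP, UT
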