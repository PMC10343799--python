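import numpy as np
import pytest

import pntkit as pk
from pntkit import manipulator as mdm


@pytest.fixture(scope="session")
def ff_unit_L():
    return pk.build_ff_unit("L")


@pytest.fixture(scope="session")
def chain24():
    return pk.build_linear_chain("L", 24, 10.0)


@pytest.fixture()
def small_chain():
    return pk.build_linear_chain("L", 3, 10.0)


@pytest.fixture()
def right_helix():
    return pk.build_parametric_helix(params=pk.HelixParams(n_units=24))


def point_helix(n=24, radius=2.0, pitch=3.0, handedness="right", phase=0.0):
    """Ideal helix of points around z (independent fixture generator)."""
    sign = 1.0 if handedness == "right" else -1.0
    t = sign * (np.arange(n) * 2.0 * np.pi / 6.0) + phase
    z = np.arange(n) * pitch / 6.0
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), z])


def two_atom_oscillator(separation=3.0, rest=2.0, stiffness=1.0):
    asm = pk.Assembly(
        names=["X1", "X2"], elements=["C", "C"], unit_ids=[1, 2],
        residue_ids=[1, 1], res_names=["UNK", "UNK"],
        coords=[[0.0, 0.0, 0.0], [separation, 0.0, 0.0]],
    )
    spring = mdm.SpringSpec(atom_a=1, atom_b=2, stiffness=stiffness,
                            rest_length=rest, kind=mdm.CONTACT)
    return asm, spring


def free_gas(n=125, box=50.0, seed=0):
    rng = np.random.default_rng(seed)
    return pk.Assembly(
        names=[f"X{i}" for i in range(n)], elements=["C"] * n,
        unit_ids=np.arange(1, n + 1), residue_ids=[1] * n,
        res_names=["UNK"] * n, coords=rng.uniform(0.0, box, (n, 3)),
    )
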