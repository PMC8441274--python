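"""Shared fixtures: reference curves and cohort specs, all seeded."""

import math

import numpy as np
import pytest

from ossindent import (
    IndentationCurve,
    IndentationProtocol,
    IndenterSpec,
    MaterialTruth,
)
from ossindent.protocols import CONE_EPSILON, MN_NM2_PER_GPA
from ossindent.synthetic import generate_curve


@pytest.fixture
def protocol() -> IndentationProtocol:
    return IndentationProtocol()


@pytest.fixture
def indenter() -> IndenterSpec:
    return IndenterSpec()


@pytest.fixture
def clean_truth() -> MaterialTruth:
    """Reference bone-like truth without creep, drift or noise."""
    return MaterialTruth(E_s=16.2, H_true=1.178, creep_amp=0.0,
                         drift_rate=0.0, noise_sd=0.0)


@pytest.fixture
def realistic_truth() -> MaterialTruth:
    """Reference truth with creep, drift and 1% (5 nm) depth noise."""
    return MaterialTruth(E_s=16.2, H_true=1.178, creep_amp=5.0,
                         drift_rate=0.05, noise_sd=5.0)


@pytest.fixture
def clean_curve(clean_truth, protocol):
    return generate_curve(clean_truth, protocol, seed=42)


def sneddon_cone_curve(E_r_gpa: float = 20.0, h_max: float = 500.0,
                       n: int = 4000) -> IndentationCurve:
    """Closed-form elastic cone (Sneddon) load–depth curve.

    ``P = (2/pi) E_r tan(psi) h^2`` loaded to ``h_max`` and unloaded along
    the identical path to zero, sampled at the protocol loading rate.
    """
    C_e = (2.0 / math.pi) * E_r_gpa * MN_NM2_PER_GPA * math.tan(math.radians(70.3))
    h = np.linspace(0.0, h_max, n)
    P = C_e * h**2
    rate = 0.25
    t_load = P / rate
    h_u = h[::-1][1:]
    P_u = C_e * h_u**2
    t_u = t_load[-1] + (P[-1] - P_u) / rate
    return IndentationCurve(
        np.concatenate([t_load, t_u]),
        np.concatenate([P, P_u]),
        np.concatenate([h, h_u]),
    )


@pytest.fixture
def cone_indenter() -> IndenterSpec:
    """Indenter spec with the exact conical geometry factor."""
    return IndenterSpec(epsilon=CONE_EPSILON)
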