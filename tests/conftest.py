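import numpy as np
import pytest

from shuttlekit import diffusion as dif
from shuttlekit import ms


@pytest.fixture
def acnq():
    """Neutral formula of the 2-amino-3-carboxy-1,4-naphthoquinone shuttle."""
    return ms.parse_formula("C11H7NO4")


@pytest.fixture
def acnq_labile_profile():
    """Functional groups with exchangeable hydrogens: 2-amino + 3-carboxy."""
    return ms.LabileHydrogenProfile(primary_amine=1, carboxylic_acid=1)


def plane_source_config(
    dx: float = 0.01,
    t_end: float = 1e4,
    D: float = 5e-6,
    q: float = 1e-12,
    domain_length: float = 10.0,
) -> tuple[dif.DiffusionConfig, int]:
    """Config with a one-cell plane source of areal strength q at the centre.

    Returns the config and the index of the source cell.
    """
    probe = dif.DiffusionConfig(
        t_end=t_end, diffusion_coefficient=D, dx=dx, domain_length=domain_length
    )
    n = probe.n_nodes
    centre = n // 2
    p = np.zeros(n)
    p[centre] = q / dx
    cfg = dif.DiffusionConfig(
        t_end=t_end,
        diffusion_coefficient=D,
        dx=dx,
        domain_length=domain_length,
        source=p,
        output_times=[t_end],
    )
    return cfg, centre
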