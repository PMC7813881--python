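"""Shared fixtures: small tissues and parameter sets for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from hepamet.params import (
    Domain,
    MechanicsParams,
    PhenotypeParams,
    ScenarioConfig,
    SeedingSpec,
    TissueParams,
    TransportParams,
)


@pytest.fixture()
def mech_params() -> MechanicsParams:
    return MechanicsParams()


@pytest.fixture()
def phen_params() -> PhenotypeParams:
    return PhenotypeParams()


@pytest.fixture()
def transport_params() -> TransportParams:
    return TransportParams()


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """A 0.1 cm x 0.1 cm scenario, cheap enough for unit tests."""
    return ScenarioConfig(
        domain=Domain(1000.0, 1000.0),
        seed=42,
        duration_days=1.0,
        diffusion_substeps=12,
        dt_mech=1.0,
    )


@pytest.fixture(scope="session")
def small_tissue(small_config):
    from hepamet.tissue_gen import generate_tissue

    return generate_tissue(small_config)


def bare_field(
    n: int,
    dx: float = 20.0,
    value: float = 38.0,
    params: TransportParams | None = None,
    dirichlet: bool = False,
):
    """Uniform substrate field without tissue machinery."""
    from hepamet.perfusion import SubstrateField

    p = params or TransportParams()
    return SubstrateField(
        dx=dx,
        nx=n,
        ny=n,
        thickness=30.0,
        values=np.full((n, n), value),
        dirichlet_mask=np.full((n, n), dirichlet),
        dirichlet_values=np.full((n, n), value),
        disrupted_mask=np.zeros((n, n), dtype=bool),
        params=p,
    )
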