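"""Shared fixtures: small phantoms and kinetic parameters used across tests."""

import pytest

import nafsim as nf


@pytest.fixture(scope="session")
def printed_params() -> nf.KineticParameters:
    """The measured one-site constants at the clinical incubation concentration."""
    return nf.KineticParameters(k_on=4.5e9, k_off=0.0027, ligand_conc=1e-11)


@pytest.fixture(scope="session")
def single_sphere_phantom() -> nf.PlaquePhantom:
    """One macro sphere, R = 500 μm, 10 μm voxels — the analytic-oracle phantom."""
    cfg = nf.PhantomConfig(
        domain_size_um=(1200.0, 1200.0, 1200.0),
        voxel_size_um=10.0,
        n_micro=0,
        n_macro=1,
        macro_radius_um=(500.0, 500.0),
        mineral_density_range=(1.0, 1.0),
    )
    return nf.generate_phantom(cfg, seed=1)


@pytest.fixture(scope="session")
def mixed_phantom() -> nf.PlaquePhantom:
    """A small 3D phantom with both deposit classes."""
    cfg = nf.PhantomConfig(
        domain_size_um=(2200.0, 2200.0, 1100.0),
        voxel_size_um=10.0,
        n_micro=5,
        n_macro=3,
        micro_radius_um=(12.0, 24.0),
        macro_radius_um=(100.0, 400.0),
    )
    return nf.generate_phantom(cfg, seed=2)


@pytest.fixture(scope="session")
def default_study():
    """The default 8×8 mm plaque section with unsectioned uptake and HU truth.

    One fixed phantom (default generation parameters, fixed seed) shared by
    the multi-resolution comparisons.
    """
    phantom = nf.generate_phantom(nf.PhantomConfig(), seed=12345)
    activity = nf.simulate_uptake(phantom, nf.KineticParameters())
    hu = nf.mineral_to_hu(phantom)
    return phantom, activity, hu


@pytest.fixture(scope="session")
def small_run_config() -> nf.RunConfig:
    """A reduced end-to-end configuration sized for fast tests."""
    return nf.RunConfig(
        seed=5,
        phantom=dict(
            domain_size_um=(4000.0, 4000.0),
            voxel_size_um=5.0,
            n_micro=30,
            n_macro=3,
            macro_radius_um=(150.0, 500.0),
        ),
    )
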