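import numpy as np
import pytest

from sonolfa import acoustics, synthetic


@pytest.fixture(scope="session")
def water():
    return acoustics.water_at_298k()


@pytest.fixture(scope="session")
def gold_40nm():
    return acoustics.ParticleSpec(radius=20e-9, density_p=19320.0, compressibility_p=0.0)


@pytest.fixture(scope="session")
def fundamental_field(water):
    """Half-wavelength resonant cavity at 700 kHz in water."""
    lam = water.sound_speed / 700e3
    return acoustics.StandingWaveField.for_medium(
        water, pressure_amplitude=1e5, frequency=700e3, cavity_length=lam / 2.0
    )


@pytest.fixture(scope="session")
def pbs_ladder():
    """The default PBS dataset: 9 levels x 15 replicates, seed 1."""
    return synthetic.generate_dataset(synthetic.LADDER_NG_ML, 15, matrix="PBS", seed=1)


@pytest.fixture(scope="session")
def pbs_arrays(pbs_ladder):
    rgb = np.array([r.rgb for r in pbs_ladder], dtype=float)
    labels = np.array([r.class_label for r in pbs_ladder])
    conc = np.array([r.true_conc for r in pbs_ladder], dtype=float)
    return rgb, labels, conc
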