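import numpy as np
import pytest

from hpdhac import kinetics, processing, pulses, synth


@pytest.fixture(scope="session")
def designed_pulses() -> dict[int, pulses.SPSPPulse]:
    """The three reference-spec pulses, designed once per session."""
    return {pid: pulses.design_pulse(spec)
            for pid, spec in pulses.reference_pulse_specs().items()}


@pytest.fixture(scope="session")
def roundtrip_setup():
    """Shared generator/quantifier configuration for ratio round trips."""
    resonances = synth.roundtrip_resonances()
    cfg = processing.ProcessingConfig(
        regions=processing.regions_from_resonances(resonances))
    return {
        "resonances": resonances,
        "windows": synth.default_windows(),
        "assignments": synth.default_assignments(resonances),
        "ground_truth": dict(synth.TABLE1_RATIOS),
        "config": cfg,
    }


@pytest.fixture()
def two_pool_network() -> kinetics.MetabolicNetwork:
    return kinetics.MetabolicNetwork(
        pool_names=["A", "B"],
        rates={"A->B": 0.01},
        t1={"A": np.inf, "B": np.inf},
        shift_ppm={"A": 100.0, "B": 50.0},
        substrate="A",
    )


@pytest.fixture()
def quiet_schedule() -> kinetics.AcquisitionSchedule:
    """No RF events; continuous evolution to 30 s."""
    return kinetics.AcquisitionSchedule(
        start_delay=30.0, tr=1.0, frames=0, events_per_frame=())
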