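import numpy as np
import pytest

from gapcircuit import (
    CircuitParameters,
    DivisionSchedule,
    GeneNetworkSpec,
    ParameterMask,
    StateMatrix,
    build_lattice,
    load_boundary_table_fixture,
)


@pytest.fixture(scope="session")
def spec():
    return GeneNetworkSpec()


@pytest.fixture(scope="session")
def trunk_c13(spec):
    return build_lattice("C13", spec.ap_range)


@pytest.fixture(scope="session")
def trunk_c14a(spec):
    return build_lattice("C14A", spec.ap_range)


@pytest.fixture(scope="session")
def packaged_dataset():
    return load_boundary_table_fixture()


def make_toy_circuit(n_genes=2, n_inputs=1, seed=0, mask=None, **overrides):
    """Small circuit with mild random weights for structural tests."""
    genes = tuple(f"g{i}" for i in range(n_genes))
    inputs = tuple(f"m{i}" for i in range(n_inputs))
    spec = GeneNetworkSpec(gap_genes=genes, external_inputs=inputs,
                           ap_range=(0.0, 100.0))
    rng = np.random.default_rng(seed)
    fields = dict(
        W=rng.uniform(-0.05, 0.05, (n_genes, n_genes)),
        E=rng.uniform(0.0, 0.05, (n_inputs, n_genes)),
        R=np.full(n_genes, 10.0),
        D=np.full(n_genes, 0.02),
        lam=np.full(n_genes, 0.08),
        h=np.full(n_genes, -2.5),
    )
    fields.update(overrides)
    return CircuitParameters(spec=spec, mask=mask or ParameterMask.all_free(spec),
                             **fields)


@pytest.fixture
def toy_circuit():
    return make_toy_circuit()


def toy_schedule(t_end=10.0, times=None):
    times = times or {"t1": 5.0, "t2": 10.0}
    return DivisionSchedule(t_start=0.0, t_end=t_end, mitosis=None,
                            data_times=times)


def toy_state(params, n_axis=10, value=0.0):
    lat = build_lattice("toy", (0.0, 100.0), n_axis=n_axis)
    return StateMatrix(
        np.full((params.spec.n_genes, lat.n_nuclei), float(value)), lat, 0.0
    )
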