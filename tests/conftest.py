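import numpy as np
import pytest

from epivariant import probe_map
from epivariant.simulate import (
    SimulationParams,
    make_probes,
    simulate_array_signal,
    simulate_genomes,
)
from epivariant import tiling_chip


@pytest.fixture(scope="session")
def params():
    return SimulationParams(rng_seed=1)


@pytest.fixture(scope="session")
def cohort(params):
    return simulate_genomes(params)


@pytest.fixture(scope="session")
def probes_and_design(cohort, params):
    return make_probes(cohort.genome_A, params)


@pytest.fixture(scope="session")
def admissions(cohort, probes_and_design):
    """Admitted probe-id sets per mode (placements cached on the probes)."""
    probes, _ = probes_and_design
    idx_a = probe_map.GenomeSeedIndex(cohort.genome_A)
    idx_b = probe_map.GenomeSeedIndex(cohort.genome_B)
    out = {}
    for mode in probe_map.MODES:
        adm = probe_map.admit_probes(probes, idx_a, idx_b, mode)
        out[mode] = {a.probe_id for a in adm if a.admitted_differential}
    return out


@pytest.fixture(scope="session")
def normalized_signal(cohort, params, probes_and_design):
    _, design = probes_and_design
    raw = simulate_array_signal(cohort.annotation, cohort.state_spec, params, design)
    return tiling_chip.normalize(raw)


@pytest.fixture(scope="session")
def array_targets(cohort, normalized_signal):
    out = {}
    for acc in ("A", "B"):
        positive = tiling_chip.call_positive_probes(normalized_signal, acc)
        out[acc] = tiling_chip.call_gene_targets(
            positive, normalized_signal, cohort.annotation.genes, sample=acc
        )
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
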