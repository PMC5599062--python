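import numpy as np
import pytest

from fivec_locus import synthetic_data as sd
from fivec_locus.io_formats import ContactMatrix, Probe, ProbeMap


@pytest.fixture(scope="session")
def small_region():
    return sd.RegionSpec("chr3", 1_000_000, 1_400_000, "toy")


@pytest.fixture(scope="session")
def small_probe_map(small_region):
    """40 alternating probes on 10 kb fragments over 400 kb."""
    return sd.make_probe_map(small_region, mean_fragment_kb=10, seed=0,
                             phase="forward", length_jitter=0.0)


@pytest.fixture(scope="session")
def probe_map_6():
    """Hand-built 3 forward / 3 reverse probe map."""
    probes = []
    for k in range(6):
        orient = "forward" if k % 2 == 0 else "reverse"
        pid = f"{'F' if k % 2 == 0 else 'R'}{k // 2 + 1:02d}"
        probes.append(Probe(pid, orient, "chr3", 1000 * k, 1000 * (k + 1)))
    return ProbeMap(probes)


def power_law_matrix(probe_map, c=1e6, exponent=-1.0):
    """Deterministic matrix with counts exactly c * d^exponent."""
    d = probe_map.distance_grid()
    return ContactMatrix(probe_map, c * np.maximum(d, 1.0) ** exponent,
                         library_label="powerlaw")


@pytest.fixture(scope="session")
def decay_matrix(small_probe_map):
    return power_law_matrix(small_probe_map)


@pytest.fixture(scope="session")
def study_probe_map():
    """Full-scale probe map mirroring the 5.3 Mb alternating design."""
    return sd.make_probe_map(sd.default_region())
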