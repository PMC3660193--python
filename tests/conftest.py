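import numpy as np
import pytest

from meiomap.simulate import CrossDesign, simulate_cross, uniform_true_map


def f1_parent(n_markers: int) -> dict:
    """Selfed F1 hybrid: haplotype 0 from one grandparent, 1 from the other."""
    return {"F1": np.vstack([np.zeros(n_markers, np.int8),
                             np.ones(n_markers, np.int8)])}


def tc_parents(n_markers: int) -> dict:
    """Mother heterozygous everywhere, father homozygous (1:1 maternal loci)."""
    return {"mother": np.vstack([np.zeros(n_markers, np.int8),
                                 np.ones(n_markers, np.int8)]),
            "father": np.zeros((2, n_markers), dtype=np.int8)}


@pytest.fixture(scope="session")
def small_f2():
    """One 90-cM group, 10 markers, 200 selfed offspring, no noise."""
    tmap = uniform_true_map(1, 90.0, 10.0)
    gm = simulate_cross(
        CrossDesign("F2_SELF", f1_parent(len(tmap.markers)), 200, 42), tmap)
    return tmap, gm


@pytest.fixture(scope="session")
def small_cp():
    """One 90-cM group, 10 maternal testcross markers, 300 offspring."""
    tmap = uniform_true_map(1, 90.0, 10.0)
    gm = simulate_cross(
        CrossDesign("CP", tc_parents(len(tmap.markers)), 300, 7), tmap)
    return tmap, gm
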