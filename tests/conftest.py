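import numpy as np
import pytest

from dnatraffic.helix_guide import build_guide
from dnatraffic.structures_io import DnaSegmentSpec
from dnatraffic.synthetic_data import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def guide60():
    return build_guide(n_bp=60)


def duplex_segment(n_bp: int, start_resnum: int, n_pairs: int) -> DnaSegmentSpec:
    """Segment spec on a generated ideal duplex (chains A/B, A:i pairs B:n+1-i)."""
    pairs = [(("A", i), ("B", n_bp + 1 - i))
             for i in range(start_resnum, start_resnum + n_pairs)]
    role = {5: "downstream-5bp", 6: "shoulder-6bp"}.get(n_pairs, "other")
    return DnaSegmentSpec(pairs, role=role)


@pytest.fixture(scope="session")
def sphere_toys(guide60):
    """Two single-sphere toy complexes with closed-form contact geometry."""
    spec_a = ToyComplexSpec(dna_n_bp=20, protein_radius=5.0, anchor_bp=10, seed=1)
    spec_b = ToyComplexSpec(dna_n_bp=20, protein_radius=5.0, anchor_bp=10, seed=2)
    ma, meta_a = make_toy_complex(spec_a, guide60)
    mb, meta_b = make_toy_complex(spec_b, guide60)
    return (ma, meta_a), (mb, meta_b)


def random_atoms(n: int, seed: int, box: float = 30.0, offset=(0.0, 0.0, 0.0)):
    from dnatraffic.structures_io import AtomRecord
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box, size=(n, 3)) + np.asarray(offset)
    elements = rng.choice(["C", "N", "O", "S"], size=n)
    from dnatraffic.structures_io import vdw_radius
    return [
        AtomRecord(i + 1, f"A{i}", el, "GLY", i + 1, "X", p, vdw_radius(el))
        for i, (el, p) in enumerate(zip(elements, pos))
    ]
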