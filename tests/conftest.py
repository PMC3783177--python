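import numpy as np
import pytest

from ecscan.fold import EnergyModel
from ecscan.msa_io import Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def model():
    return EnergyModel()


@pytest.fixture
def pair_only_model():
    """Uniform pair-only scoring: every canonical pair -1, no stacking."""
    return EnergyModel(
        pair_energies={p: -1.0 for p in ("GC", "CG", "AU", "UA", "GU", "UG")},
        stack_bonus=0.0,
    )


@pytest.fixture
def compensatory_alignment():
    """Alignment with a clear compensatory helix: columns 0-2 pair with
    8-6 as GC/AU/UA variants across rows."""
    return Alignment.from_strings(
        [
            ("a", "GGGAAACCC"),
            ("b", "GGCAAAGCC"),
            ("c", "GCGAAACGC"),
            ("d", "AGGAAACCU"),
        ]
    )


def random_rna(rng, n, alphabet="ACGU"):
    return "".join(rng.choice(list(alphabet), size=n))
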