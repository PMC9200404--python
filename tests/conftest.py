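import numpy as np
import pytest

from spncat import build_montage
from spncat.simulate import SynthConfig
from spncat.vibration import DEFAULT_CLUSTERS

SPN_CLUSTER = ("PO7", "O1", "O2", "PO8")
SPN_WINDOW = (300.0, 1000.0)


@pytest.fixture(scope="session")
def montage64():
    return build_montage("biosemi64")


@pytest.fixture(scope="session")
def posterior16(montage64):
    """The 16-electrode bilateral posterior montage used to keep synthetic
    catalogues small; contains the PO7/O1/O2/PO8 SPN cluster."""
    return montage64.restrict(DEFAULT_CLUSTERS["Cluster3"])


def fast_config(**kw) -> SynthConfig:
    """Generator config with a short (1.3 s) epoch for quick tests; the
    standard 300-1000 ms extraction window still fits."""
    kw.setdefault("seed", 0)
    kw.setdefault("epoch_end", 1100.0)
    return SynthConfig(**kw)


@pytest.fixture(scope="session")
def posterior20(montage64):
    """Posterior montage including the midline (Pz/POz/Oz/Iz) so the two
    hemispheres form one connected adjacency component."""
    return montage64.restrict(DEFAULT_CLUSTERS["Cluster3"] + ("Pz", "POz", "Oz", "Iz"))


@pytest.fixture(scope="session")
def tiny_montage():
    """Four electrodes on the unit sphere, ring adjacency."""
    table = {
        "A": (1.0, 0.0, 0.0),
        "B": (0.0, 1.0, 0.0),
        "C": (-1.0, 0.0, 0.0),
        "D": (0.0, -1.0, 0.0),
    }
    return build_montage(table, threshold=np.pi / 2 + 0.01)
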