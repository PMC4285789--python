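import numpy as np
import pytest

from kinkscan import HelixSpec, build_helix, build_ideal_helix
from kinkscan.helix_extraction import Helix
from kinkscan.structure_model import ChainModel


@pytest.fixture(scope="session")
def ideal_chain():
    """Noiseless 30-residue ideal helix (construction dihedrals populated)."""
    return build_ideal_helix(HelixSpec(length=30))


@pytest.fixture
def make_kinked():
    """Factory for a single-kink helix chain."""

    def _make(position=15, angle=40.0, azimuth=0.0, length=30, noise_sd=0.0, seed=0):
        return build_helix(
            HelixSpec(
                length=length,
                kinks=[(position, angle, azimuth)],
                noise_sd=noise_sd,
                seed=seed,
            )
        )

    return _make


def as_helix(chain: ChainModel, start=0, end=None) -> Helix:
    """Wrap a chain (or a span of it) as a Helix for direct geometry calls."""
    if end is None:
        end = len(chain.residues) - 1
    return Helix.from_chain(chain, start, end)


def mark_all_helical(chain: ChainModel) -> ChainModel:
    for r in chain.residues:
        r.ss_state = "H"
    return chain


@pytest.fixture
def helix_of():
    return as_helix


@pytest.fixture
def all_helical():
    return mark_all_helical


def rigid_transform(chain: ChainModel, seed=0) -> ChainModel:
    """Random rotation + translation applied to every coordinate, in place."""
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(m)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    for res in chain.residues:
        for a in ("N", "CA", "C", "O"):
            xyz = getattr(res, f"coords_{a}")
            if xyz is not None:
                setattr(res, f"coords_{a}", q @ xyz + t)
        for k, v in res.extra_atoms.items():
            res.extra_atoms[k] = q @ v + t
    return chain
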