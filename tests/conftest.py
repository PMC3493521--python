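import numpy as np
import pytest

from globulomer.peptides import (
    FluctuationSpec,
    build_dodecamer_fixture,
    default_sigma_profile,
    simulate_trajectory,
)
from globulomer.sasa import SasaParams
from globulomer.structures import Atom, Chain, Residue, Structure


def toy_structure(coords, names=None, elements=None, resnums=None, chain_ids=None):
    """Assemble a Structure from bare coordinates for oracle tests."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    names = names or [f"C{i}" for i in range(n)]
    elements = elements or ["C"] * n
    resnums = resnums or [1] * n
    chain_ids = chain_ids or ["A"] * n
    chains: dict[str, dict[int, list[Atom]]] = {}
    for i in range(n):
        atom = Atom(i + 1, names[i], elements[i], coords[i],
                    is_hydrogen=elements[i] == "H")
        chains.setdefault(chain_ids[i], {}).setdefault(resnums[i], []).append(atom)
    return Structure(
        [
            Chain(cid, [Residue("UNK", rn, atoms) for rn, atoms in sorted(res.items())])
            for cid, res in sorted(chains.items())
        ]
    )


@pytest.fixture(scope="session")
def dodecamer():
    """The standard synthetic dodecamer fixture (helical N-termini)."""
    return build_dodecamer_fixture()


@pytest.fixture(scope="session")
def unwind_trajectory(dodecamer):
    """A short fluctuation trajectory with progressive N-terminal
    unwinding, shared across tests that need ensemble input."""
    spec = FluctuationSpec(
        per_residue_sigma=default_sigma_profile(),
        n_frames=8,
        frame_interval=10.0,
        unwind_nterm=True,
        seed=11,
    )
    return simulate_trajectory(dodecamer, spec)


@pytest.fixture(scope="session")
def sasa_fast():
    """Reduced point count for tests where 1% accuracy is not the point."""
    return SasaParams(n_points=240)
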