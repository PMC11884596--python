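import numpy as np
import pytest

from funcphos.io import ProteinRecord
from funcphos.synth import SynthConfig, generate_dataset


def make_protein(
    coords: np.ndarray,
    sequence: str | None = None,
    plddt: np.ndarray | None = None,
    accession: str = "TEST1",
) -> ProteinRecord:
    """Hand-rolled ProteinRecord with sidechains offset +1 Å along x."""
    coords = np.asarray(coords, float)
    n = len(coords)
    sequence = sequence or "A" * n
    sidechains = coords + np.array([1.0, 0.0, 0.0])
    for i, letter in enumerate(sequence):
        if letter == "G":
            sidechains[i] = np.nan
    return ProteinRecord(
        accession=accession,
        sequence=sequence,
        ca_coords=coords,
        sidechain_centers=sidechains,
        plddt=plddt if plddt is not None else np.full(n, 80.0),
    )


def straight_chain(n: int, step: float = 3.8) -> np.ndarray:
    return np.stack([step * np.arange(n), np.zeros(n), np.zeros(n)], axis=1)


def ideal_helix(n: int) -> np.ndarray:
    t = np.arange(n) * np.deg2rad(100.0)
    return np.stack(
        [2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)], axis=1
    )


def random_protein(rng: np.random.Generator, n: int, accession: str = "RND") -> ProteinRecord:
    """Self-avoiding-ish random walk protein for brute-force comparisons."""
    coords = [np.zeros(3)]
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    for _ in range(n - 1):
        step = direction + rng.standard_normal(3)
        step /= np.linalg.norm(step)
        coords.append(coords[-1] + 3.8 * step)
        direction = step
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
    return make_protein(np.array(coords), seq, accession=accession)


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-protein synthetic dataset shared by pipeline-level tests."""
    return generate_dataset(SynthConfig(n_proteins=40, seed=11))
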