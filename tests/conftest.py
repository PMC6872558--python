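import numpy as np
import pytest

from barcodeval.seqdata import DistanceMatrix, MarkerAlignment, SampleRecord


def make_alignment(seqs, species=None, marker="m", ids=None):
    """Build a MarkerAlignment from raw sequence strings."""
    n = len(seqs)
    species = species or [f"sp{i}" for i in range(n)]
    ids = ids or [f"s{i}" for i in range(n)]
    return MarkerAlignment(
        marker=marker,
        records=[
            SampleRecord(sample_id=i, species=sp, marker=marker, residues=s)
            for i, sp, s in zip(ids, species, seqs)
        ],
    )


def make_dm(values, species, labels=None):
    """Build a DistanceMatrix from a full square array and species labels."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    labels = labels or [f"s{i}" for i in range(n)]
    return DistanceMatrix(
        labels=labels,
        species=list(species),
        values=values,
        n_effective=np.full((n, n), 100, dtype=int),
    )


def random_alignment(rng, n_seqs, n_cols, missing_rate=0.0, n_species=None):
    """Random alignment over ACGT with optional gaps, for property tests."""
    bases = np.array(list("ACGT-"))
    probs = [(1 - missing_rate) / 4] * 4 + [missing_rate]
    mat = rng.choice(bases, size=(n_seqs, n_cols), p=probs)
    seqs = ["".join(row) for row in mat]
    if n_species:
        species = [f"sp{rng.integers(n_species)}" for _ in range(n_seqs)]
    else:
        species = None
    return make_alignment(seqs, species=species)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
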