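import logging

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True,
                                     deadline=None)
hypothesis_settings.load_profile("deterministic")

from kmerlasso.feature_grouping import GroupAssignment
from kmerlasso.kmer_features import FeatureMatrix, FeatureSpace, KmerPattern, revcomp

logging.getLogger("kmerlasso").setLevel(logging.ERROR)


def make_matrix(X, y, names=None, tasks=None) -> FeatureMatrix:
    """Wrap a dense count array + labels into a FeatureMatrix."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if names is None:
        # synthetic placeholder patterns; only their count columns matter
        names = [f"F{i:04d}" for i in range(p)]
    patterns = [KmerPattern(nm, nm == revcomp(nm) if set(nm) <= set("ACGT.") else False)
                for nm in names]
    space = FeatureSpace(k=len(names[0]), max_run=0, patterns=patterns)
    return FeatureMatrix(example_ids=[f"e{i}" for i in range(n)],
                         labels=np.asarray(y, dtype=np.int64),
                         counts=sp.csr_matrix(X), space=space, tasks=tasks)


def make_groups(group_of) -> GroupAssignment:
    group_of = np.asarray(group_of, dtype=np.int64)
    return GroupAssignment(group_of=group_of, G=int(group_of.max()))


@pytest.fixture(scope="session")
def recovery_runs():
    """Ten seeded end-to-end planted-motif runs, shared across tests."""
    from kmerlasso.benchmark import recovery_benchmark

    return [recovery_benchmark(seed) for seed in range(10)]


@pytest.fixture(scope="session")
def tiny_genome(tmp_path_factory):
    """A two-chromosome FASTA with reproducible random sequence."""
    rng = np.random.default_rng(42)
    path = tmp_path_factory.mktemp("genome") / "genome.fa"
    with open(path, "w") as fh:
        for name, length in [("chr1", 5000), ("chr2", 3000)]:
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
            fh.write(f">{name}\n{seq}\n")
    return path
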