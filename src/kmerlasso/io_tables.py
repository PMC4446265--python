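"""Feature-matrix serialization: sparse triplet TSV + JSON sidecar header."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from kmerlasso.kmer_features import FeatureMatrix, FeatureSpace, KmerPattern, revcomp


def save_feature_matrix(M: FeatureMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.counts.tsv`` (row, col, count) and ``<prefix>.header.json``."""
    coo = M.counts.tocoo()
    pd.DataFrame({"row": coo.row, "col": coo.col,
                  "count": coo.data.astype(np.int64)}).to_csv(
        f"{prefix}.counts.tsv", sep="\t", index=False)
    header = {
        "k": M.space.k,
        "max_run": M.space.max_run,
        "features": M.space.pattern_strings,
        "example_ids": M.example_ids,
        "labels": M.labels.tolist(),
        "tasks": M.tasks,
        "shape": list(M.counts.shape),
    }
    with open(f"{prefix}.header.json", "w") as fh:
        json.dump(header, fh)


def load_feature_matrix(prefix: str | Path) -> FeatureMatrix:
    with open(f"{prefix}.header.json") as fh:
        header = json.load(fh)
    trip = pd.read_csv(f"{prefix}.counts.tsv", sep="\t")
    counts = sp.csr_matrix(
        (trip["count"].to_numpy(dtype=np.float64),
         (trip["row"].to_numpy(), trip["col"].to_numpy())),
        shape=tuple(header["shape"]))
    space = FeatureSpace(
        k=header["k"], max_run=header["max_run"],
        patterns=[KmerPattern(p, is_palindromic=p == revcomp(p))
                  for p in header["features"]])
    return FeatureMatrix(
        example_ids=header["example_ids"],
        labels=np.asarray(header["labels"], dtype=np.int64),
        counts=counts, space=space, tasks=header["tasks"])
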