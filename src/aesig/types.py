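"""Shared containers for the pipeline.

The pipeline moves three kinds of objects between stages: drug-by-AE report
count matrices (plain :class:`pandas.DataFrame`, AE rows x drug columns),
drug-drug similarity networks, and cluster assignments.  Similarity networks
carry a ``stage`` tag recording where in the three-stage construction
(first -> imputed second -> fused) they were produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-10

VALID_STAGES = ("first", "second", "fused")


@dataclass
class SimilarityNetwork:
    """Square symmetric drug-drug similarity matrix with entries in [0, 1].

    Parameters
    ----------
    ids : list of str
        Drug identifiers, one per row/column.
    matrix : ndarray
        Square similarity matrix; symmetric, unit diagonal.
    source : str
        Data source tag, e.g. ``"ae"``, ``"bioassay"``, ``"chemical"``,
        ``"expression"``, or ``"fused"``.
    stage : str
        One of ``"first"``, ``"second"``, ``"fused"``.
    """

    ids: list
    matrix: np.ndarray
    source: str = "unknown"
    stage: str = "first"

    def __post_init__(self):
        self.ids = [str(d) for d in self.ids]
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate drug identifiers in similarity network")
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} identifiers"
            )
        if self.stage not in VALID_STAGES:
            raise ValueError(f"unknown stage tag {self.stage!r}")
        if not np.allclose(self.matrix, self.matrix.T, atol=SYMMETRY_TOL, rtol=0):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=SYMMETRY_TOL, rtol=0):
            raise ValueError("similarity matrix diagonal must be exactly 1")
        if self.matrix.min() < -SYMMETRY_TOL or self.matrix.max() > 1 + SYMMETRY_TOL:
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, drug: str) -> int:
        try:
            return self.ids.index(drug)
        except ValueError:
            raise KeyError(f"drug {drug!r} not in network") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "unknown",
                   stage: str = "first") -> "SimilarityNetwork":
        if list(df.index) != list(df.columns):
            raise ValueError("similarity frame must have identical row/column ids")
        return cls(ids=list(df.index), matrix=df.to_numpy(dtype=float),
                   source=source, stage=stage)

    def reindex(self, ids: list) -> "SimilarityNetwork":
        """Restrict/permute the network to ``ids`` (all must be present)."""
        idx = [self.index_of(d) for d in ids]
        return SimilarityNetwork(ids=list(ids),
                                 matrix=self.matrix[np.ix_(idx, idx)],
                                 source=self.source, stage=self.stage)


@dataclass
class ClusterAssignment:
    """Drug -> cluster label in {1..k}, with provenance.

    ``provenance`` is ``"observed"`` for drugs labeled directly from the
    factorization of their AE counts and ``"propagated"`` for drugs whose
    label came from the fused-network neighbor vote.  For propagated drugs
    ``votes`` records the supporting neighbors and their vote weights.
    """

    labels: "pd.Series"
    provenance: "pd.Series"
    votes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = pd.Series(self.labels, dtype=int)
        self.provenance = pd.Series(self.provenance, dtype=object)
        if not self.labels.index.equals(self.provenance.index):
            raise ValueError("labels and provenance must share a drug index")
        bad = set(self.provenance) - {"observed", "propagated"}
        if bad:
            raise ValueError(f"invalid provenance values: {bad}")
        if (self.labels < 1).any():
            raise ValueError("cluster labels must be >= 1")

    @property
    def drugs(self) -> list:
        return list(self.labels.index)

    def observed(self) -> "pd.Series":
        return self.labels[self.provenance == "observed"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cluster": self.labels, "provenance": self.provenance})


def check_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a drug-by-AE count matrix (AE rows, drug columns)."""
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("count matrix must be numeric")
    if (arr < 0).any():
        raise ValueError("count matrix must be nonnegative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("count matrix must hold integer report counts")
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("duplicate AE or drug identifiers in count matrix")
    return counts
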