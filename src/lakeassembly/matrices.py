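"""Square pairwise-matrix container shared by the beta-diversity stages."""

from __future__ import annotations

import numpy as np
import pandas as pd


class DissimilarityMatrix:
    """Symmetric square matrix over samples with a zero diagonal.

    Used for Bray-Curtis dissimilarities (values in [0, 1]), for betaMNTD
    (patristic units) and, with ``hollow=False`` relaxed semantics, for
    signed pairwise scores such as betaNTI.
    """

    def __init__(self, data, ids, check_hollow: bool = True):
        data = np.asarray(data, dtype=float)
        ids = list(ids)
        if data.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match number of ids")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids")
        finite = np.isfinite(data)
        if not np.allclose(
            np.where(finite, data, 0.0), np.where(finite.T, data.T, 0.0),
            atol=1e-12, rtol=0.0,
        ):
            raise ValueError("matrix is not symmetric")
        if check_hollow and not np.allclose(np.diag(data), 0.0, atol=1e-12):
            raise ValueError("diagonal is not zero")
        self.data = data
        self.ids = ids

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def shape(self):
        return self.data.shape

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy 'condensed' order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.data[iu]

    def between(self, a: str, b: str) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.data[ia, ib])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, check_hollow: bool = True) -> "DissimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), list(df.index.astype(str)), check_hollow)

    def similarity_percent(self) -> pd.DataFrame:
        """(1 - dissimilarity) x 100, for matrices on the [0, 1] scale."""
        if self.data.min() < -1e-12 or self.data.max() > 1 + 1e-12:
            raise ValueError("similarity%% only defined for values in [0, 1]")
        return pd.DataFrame(
            (1.0 - self.data) * 100.0, index=self.ids, columns=self.ids
        )

    def subset(self, ids) -> "DissimilarityMatrix":
        ids = list(ids)
        idx = [self.ids.index(i) for i in ids]
        return DissimilarityMatrix(
            self.data[np.ix_(idx, idx)], ids, check_hollow=False
        )


def pair_index(ids) -> list[tuple[str, str]]:
    """Sample-id pairs in condensed (upper-triangle) order."""
    ids = list(ids)
    return [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]
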