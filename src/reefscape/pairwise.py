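"""Symmetric site-by-site matrices shared by every analysis stage.

A :class:`PairwiseMatrix` holds one pairwise metric over a fixed ordered set
of sites: genetic differentiation (G''ST), a Jaccard dissimilarity component,
or an in-water distance in km.  Undefined cells are ``nan`` (e.g. a site pair
where a family has no members on either side); unreachable distances are
``inf``.  Both are treated as "flagged" and dropped when the matrix is
stacked into a long-form pair table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


@dataclass
class PairwiseMatrix:
    site_ids: list[str]
    values: np.ndarray
    metric: str
    sd: np.ndarray | None = None
    n_iter: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.site_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} site ids"
            )
        finite = np.isfinite(self.values)
        both = finite & finite.T
        if not np.allclose(self.values[both], self.values.T[both]):
            raise ValueError("pairwise matrix must be symmetric")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def get(self, site_i: str, site_j: str) -> float:
        i = self.site_ids.index(site_i)
        j = self.site_ids.index(site_j)
        return float(self.values[i, j])

    def pairs(self) -> Iterator[tuple[str, str, float]]:
        """Yield (site_i, site_j, value) over unordered pairs, i < j."""
        for i in range(self.n_sites):
            for j in range(i + 1, self.n_sites):
                yield self.site_ids[i], self.site_ids[j], float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in pair order (i < j)."""
        iu = np.triu_indices(self.n_sites, k=1)
        return self.values[iu]

    def to_long(self) -> pd.DataFrame:
        rows = []
        iu = np.triu_indices(self.n_sites, k=1)
        for i, j in zip(*iu):
            rows.append(
                {
                    "site_i": self.site_ids[i],
                    "site_j": self.site_ids[j],
                    "metric": self.metric,
                    "value": self.values[i, j],
                    "sd": self.sd[i, j] if self.sd is not None else np.nan,
                    "n_iter": self.n_iter,
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.site_ids)

    def to_csv(self, path, square: bool = False) -> None:
        if square:
            self.to_frame().to_csv(path)
        else:
            self.to_long().to_csv(path, index=False)


def aggregate_matrices(matrices: Sequence[PairwiseMatrix]) -> PairwiseMatrix:
    """Cell-wise mean and sd over resampling iterations.

    All matrices must share the same ordered site set and metric.  Cells
    flagged (non-finite) in an iteration are excluded from that cell's mean;
    a cell flagged in every iteration stays ``nan``.
    """
    if not matrices:
        raise ValueError("no matrices to aggregate")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.site_ids != ref.site_ids:
            raise ValueError("matrices do not share the same site set")
        if m.metric != ref.metric:
            raise ValueError("matrices do not share the same metric")
    stack = np.array([m.values for m in matrices])
    with np.errstate(invalid="ignore"):
        finite = np.isfinite(stack)
        counts = finite.sum(axis=0)
        vals = np.where(finite, stack, 0.0)
        mean = np.divide(
            vals.sum(axis=0), counts, out=np.full(ref.values.shape, np.nan),
            where=counts > 0,
        )
        sq = np.divide(
            (np.where(finite, (stack - mean) ** 2, 0.0)).sum(axis=0),
            np.maximum(counts - 1, 1),
            out=np.zeros(ref.values.shape),
            where=counts > 0,
        )
    sd = np.sqrt(sq)
    sd[counts == 0] = np.nan
    np.fill_diagonal(sd, 0.0)
    return PairwiseMatrix(
        site_ids=list(ref.site_ids),
        values=mean,
        metric=ref.metric,
        sd=sd,
        n_iter=len(matrices),
    )
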