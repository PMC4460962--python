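"""Single-sample KS enrichment of gene sets.

For one sample, genes are ranked by expression (rank 1 = highest by
default).  For a gene set of size ``t`` whose members sit at sorted rank
positions ``V(1) < ... < V(t)`` among ``N`` measured genes, the signed KS
enrichment score is

    a  = max_j [ j/t − V(j)/N ]
    b  = max_j [ V(j)/N − (j−1)/t ]
    KS = a   if a > b
       = −b  if a < b
       = 0   if a = b

``a`` measures how far the set's rank distribution runs ahead of uniform
(enrichment at the top of the ranking), ``b`` how far it lags behind
(enrichment at the bottom).  The score lies in [−1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

RankDirection = Literal["descending", "ascending"]

DEFAULT_MIN_SET_SIZE = 5


@dataclass
class EnrichmentMatrix:
    """Gene-set x sample matrix of KS enrichment scores."""

    scores: pd.DataFrame  # sets x samples, values in [-1, 1]

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)

    def to_tsv(self, path, header_lines=None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.scores.to_csv(fh, sep="\t", index_label="gene_set", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path) -> "EnrichmentMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(scores=df)


def rank_sample(values: pd.Series, direction: RankDirection = "descending") -> pd.Series:
    """1-based rank positions of one sample's expression vector.

    With the default descending direction, rank 1 is the highest-expressed
    gene.  Ties are broken by ascending gene identifier so ranking is
    bit-reproducible.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("expression vector must have length >= 2")
    if not np.all(np.isfinite(vals)):
        bad = values.index[~np.isfinite(vals)][0]
        raise ValueError(f"non-finite expression value for gene {bad!r}")
    ids = np.asarray(values.index, dtype=object)
    key = -vals if direction == "descending" else vals
    # lexsort: last key is primary; ties fall back to ascending gene id
    order = np.lexsort((np.argsort(np.argsort(ids, kind="stable"), kind="stable"), key))
    positions = np.empty(vals.size, dtype=np.int64)
    positions[order] = np.arange(1, vals.size + 1)
    return pd.Series(positions, index=values.index)


def _rank_matrix(values: pd.DataFrame, direction: RankDirection) -> np.ndarray:
    """Rank every column of a genes x samples matrix (vectorised rank_sample)."""
    vals = values.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        g, s = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(
            f"non-finite expression value at gene {values.index[g]!r}, "
            f"sample {values.columns[s]!r}"
        )
    id_rank = np.argsort(np.argsort(values.index.to_numpy(), kind="stable"), kind="stable")
    key = -vals if direction == "descending" else vals
    positions = np.empty(vals.shape, dtype=np.int64)
    rows = np.arange(1, vals.shape[0] + 1)
    for j in range(vals.shape[1]):
        order = np.lexsort((id_rank, key[:, j]))
        positions[order, j] = rows
    return positions


def ks_score(positions, n_genes: int) -> float:
    """KS enrichment score for a set whose members occupy ``positions``
    (1-based, distinct) in a ranking of ``n_genes`` genes."""
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    t = pos.size
    if t == 0:
        raise ValueError("empty gene set after intersection")
    if t > n_genes:
        raise ValueError(f"set size {t} exceeds profile size {n_genes}")
    if pos[0] < 1 or pos[-1] > n_genes:
        raise ValueError("rank positions must lie in [1, N]")
    if np.unique(pos).size != t:
        raise ValueError("duplicate rank positions")
    j = np.arange(1, t + 1, dtype=float)
    v = pos / n_genes
    a = np.max(j / t - v)
    b = np.max(v - (j - 1) / t)
    if a > b:
        return float(a)
    if a < b:
        return float(-b)
    return 0.0


def enrich(
    cohort_values: pd.DataFrame,
    collection: GeneSetCollection,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    direction: RankDirection = "descending",
) -> EnrichmentMatrix:
    """Score every gene set of ``collection`` in every sample.

    Each set is first intersected with the measured genes; sets with fewer
    than ``min_set_size`` surviving members are excluded (and logged).
    ``N`` is the number of measured genes in the cohort.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    n_genes = cohort_values.shape[0]
    positions = _rank_matrix(cohort_values, direction)
    gene_index = {g: i for i, g in enumerate(cohort_values.index)}

    kept_names: list[str] = []
    rows: list[np.ndarray] = []
    n_excluded = 0
    for gs in collection:
        idx = [gene_index[g] for g in gs.members if g in gene_index]
        t = len(idx)
        if t < min_set_size:
            n_excluded += 1
            logger.debug("set %r excluded: %d measured members < %d", gs.name, t, min_set_size)
            continue
        p = np.sort(positions[idx, :], axis=0) / n_genes  # t x samples
        j = np.arange(1, t + 1, dtype=float)[:, None]
        a = np.max(j / t - p, axis=0)
        b = np.max(p - (j - 1) / t, axis=0)
        ks = np.where(a > b, a, np.where(b > a, -b, 0.0))
        kept_names.append(gs.name)
        rows.append(ks)
    if n_excluded:
        logger.info(
            "enrich: excluded %d/%d sets with < %d measured members",
            n_excluded, len(collection), min_set_size,
        )
    if not kept_names:
        raise ValueError("all gene sets excluded: no set has enough measured members")
    scores = pd.DataFrame(np.vstack(rows), index=kept_names, columns=cohort_values.columns)
    return EnrichmentMatrix(scores=scores)
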