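"""Copy-number analyses: OG x species count matrix, family/genome
ratios, z-score standardisation and WPGMA (McQuitty) clustering.

The copy-number heatmap standardises each OG's counts across species
(row z-scores) and clusters OGs by Euclidean distance with WPGMA: at
each agglomeration the closest pair merges and the distance of the new
node to any other node is the plain average of its two parts,
``d(ij,k) = (d(i,k) + d(j,k)) / 2``; the merge is drawn at height
``d(i,j) / 2`` so leaf-to-node path lengths read as distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Table1Fixture
from .og_inference import OrthologousGroup

SPECIES_ORDER = ["Vv", "At", "Os", "Ma"]


@dataclass(frozen=True)
class LinkageTree:
    """Ordered merges of an agglomerative clustering.

    ``merges[k] = (node_i, node_j, height, new_node)``; leaves are
    ``0..n-1``, internal nodes ``n..2n-2`` in merge order (the scipy
    linkage convention, with heights halved as described above).
    """

    n_leaves: int
    merges: tuple[tuple[int, int, float, int], ...]
    labels: tuple[str, ...] = ()

    def newick(self) -> str:
        nodes: dict[int, tuple[str, float]] = {
            i: (self.labels[i] if self.labels else f"L{i}", 0.0)
            for i in range(self.n_leaves)
        }
        for i, j, h, new in self.merges:
            ni, hi = nodes.pop(i)
            nj, hj = nodes.pop(j)
            nodes[new] = (f"({ni}:{h - hi:g},{nj}:{h - hj:g})", h)
        (tree, _), = nodes.values()
        return tree + ";"


def build_count_matrix(ogs: list[OrthologousGroup] | Table1Fixture,
                       species: list[str] | None = None,
                       include_pseudogenes: bool = False) -> pd.DataFrame:
    """Per-OG x species member counts.

    Accepts either inferred groups or the packaged published-table
    fixture.  Pseudogene-flagged members (fixture only) are excluded by
    default.
    """
    if isinstance(ogs, Table1Fixture):
        rows: dict[str, dict[str, int]] = {}
        for og, sp, _mid, pseudo in ogs.rows:
            if pseudo and not include_pseudogenes:
                continue
            rows.setdefault(og, {})[sp] = rows.setdefault(og, {}).get(sp, 0) + 1
        og_ids = ogs.og_ids
    else:
        rows = {og.og_id: {sp: len(m) for sp, m in og.members.items()}
                for og in ogs}
        og_ids = [og.og_id for og in ogs]
    if species is None:
        found = {sp for r in rows.values() for sp in r}
        species = [sp for sp in SPECIES_ORDER if sp in found] or sorted(found)
    df = pd.DataFrame(0, index=pd.Index(og_ids, name="og_id"),
                      columns=species, dtype=int)
    for og_id, counts in rows.items():
        for sp, n in counts.items():
            if sp in df.columns:
                df.loc[og_id, sp] = n
    return df


def family_ratio(n_family: int, n_total_genes: int) -> float:
    """Family size over total annotated genes of a genome."""
    if n_total_genes <= 0:
        raise ValueError("total gene count must be positive")
    if n_family > n_total_genes:
        raise ValueError("family larger than the genome inventory")
    return n_family / n_total_genes


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (summary convention)."""
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def zscore_rows(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardise each row: (x - row mean) / row SD.

    Sample SD (``ddof=1``) by default, matching common heatmap software;
    zero-variance rows map to all-zeros.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two columns")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def euclidean_distances(matrix: pd.DataFrame) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(matrix.to_numpy(dtype=float), metric="euclidean"))


def wpgma(dist: np.ndarray, labels: list[str] | None = None) -> LinkageTree:
    """WPGMA (McQuitty) agglomeration of a symmetric distance matrix.

    Ties in closest-pair selection break on the smallest (row, col)
    index pair for determinism.  Merge heights are ``d(i,j)/2``.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be square, symmetric, zero-diagonal")
    active: dict[int, dict[int, float]] = {
        i: {j: d[i, j] for j in range(n) if j != i} for i in range(n)
    }
    heights = {i: 0.0 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_node = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active[i]):
                if j <= i:
                    continue
                cand = (active[i][j], i, j)
                if best is None or cand < best:
                    best = cand
        dij, i, j = best
        h = dij / 2.0
        new_d = {
            k: (active[i][k] + active[j][k]) / 2.0
            for k in active
            if k not in (i, j)
        }
        del active[i], active[j]
        for k in list(active):
            active[k].pop(i, None)
            active[k].pop(j, None)
            active[k][next_node] = new_d[k]
        active[next_node] = new_d
        heights[next_node] = h
        merges.append((i, j, h, next_node))
        next_node += 1
    return LinkageTree(n_leaves=n, merges=tuple(merges),
                       labels=tuple(labels) if labels else ())
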