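"""Drug-centric disease taxonomy.

Diseases are characterized by the set of drugs they have adopted.  For a
pair of diseases the co-adoption pattern over the drug universe defines a
two-dimensional Bernoulli distribution; the mutual information of that
distribution (in nats) measures how similar the diseases' drug portfolios
are.  Converting similarity to a distance and applying Ward's
minimum-variance hierarchical clustering yields a disease taxonomy that can
be exported as a Newick tree.  Drug *exclusivity* -- the fraction of a
disease's drugs adopted by no other disease in the set -- quantifies how
differentiated a disease's therapies are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .events_io import AdoptionRecord

__all__ = [
    "DiseaseDrugSets",
    "BernoulliJoint",
    "Dendrogram",
    "build_drug_sets",
    "bernoulli_joint",
    "mutual_information",
    "mi_similarity_matrix",
    "mi_to_distance",
    "ward_cluster",
    "exclusivity",
    "newick_string",
    "export_newick",
]

_MI_TOL = 1e-12


@dataclass(frozen=True)
class DiseaseDrugSets:
    """Per-disease adopted-drug sets over a common drug universe.

    Only diseases that met the inclusion threshold are present; the
    universe is the union of drugs adopted by the included diseases.
    """

    sets: Mapping[str, frozenset]
    universe: frozenset

    def __post_init__(self):
        for d, s in self.sets.items():
            if not s <= self.universe:
                raise ValueError(f"drug set of {d!r} not contained in universe")

    @property
    def diseases(self) -> list[str]:
        return sorted(self.sets)


@dataclass(frozen=True)
class BernoulliJoint:
    """2x2 co-adoption counts for a disease pair over the drug universe.

    Cell layout (x = membership in d^i, y = membership in d^j):
    ``counts[0, 0]`` = neither, ``counts[0, 1]`` = j only,
    ``counts[1, 0]`` = i only, ``counts[1, 1]`` = both.  Probabilities are
    the counts divided (once) by the universe size, so they sum to 1
    exactly.
    """

    counts: np.ndarray
    n: int

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (2, 2) or np.any(c < 0):
            raise ValueError("counts must be a non-negative 2x2 table")
        if int(c.sum()) != self.n:
            raise ValueError("counts must sum to the universe size")

    @property
    def probs(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n


@dataclass(frozen=True)
class Dendrogram:
    """Ward-linkage merge tree over disease leaves.

    ``linkage_matrix`` is in scipy's standard form: one row per merge with
    (left, right, height, size).  Heights are non-decreasing.
    """

    linkage_matrix: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        Z = np.asarray(self.linkage_matrix)
        if len(self.labels) < 2:
            raise ValueError("a dendrogram needs at least 2 leaves")
        if Z.shape != (len(self.labels) - 1, 4):
            raise ValueError("linkage matrix shape inconsistent with labels")

    @property
    def heights(self) -> np.ndarray:
        return np.asarray(self.linkage_matrix)[:, 2]


def build_drug_sets(adoptions: Iterable[AdoptionRecord], min_drugs: int = 50) -> DiseaseDrugSets:
    """Group adoptions into per-disease drug sets, keeping only diseases
    that adopted at least ``min_drugs`` drugs; the universe is recomputed
    over the included diseases only."""
    raw: dict[str, set] = {}
    for a in adoptions:
        raw.setdefault(a.disease_id, set()).add(a.drug_id)
    kept = {d: frozenset(s) for d, s in raw.items() if len(s) >= min_drugs}
    if not kept:
        sizes = {d: len(s) for d, s in sorted(raw.items())}
        raise ValueError(
            f"no disease adopted >= {min_drugs} drugs (set sizes: {sizes})"
        )
    universe = frozenset().union(*kept.values())
    return DiseaseDrugSets(sets=kept, universe=universe)


def bernoulli_joint(sets: DiseaseDrugSets, i: str, j: str) -> BernoulliJoint:
    """Co-adoption 2x2 table for diseases ``i`` and ``j``."""
    if i == j:
        raise ValueError("bernoulli_joint requires two distinct diseases")
    try:
        di, dj = sets.sets[i], sets.sets[j]
    except KeyError as exc:
        raise KeyError(f"unknown disease: {exc.args[0]!r}") from exc
    n = len(sets.universe)
    both = len(di & dj)
    i_only = len(di) - both
    j_only = len(dj) - both
    neither = n - both - i_only - j_only
    counts = np.array([[neither, j_only], [i_only, both]], dtype=int)
    return BernoulliJoint(counts=counts, n=n)


def mutual_information(joint: BernoulliJoint) -> float:
    """Mutual information of a 2x2 joint, in nats; 0*log 0 := 0.

    The exact value is non-negative; tiny negative rounding is clamped.
    """
    p = joint.probs
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    total = 0.0
    for x in (0, 1):
        for y in (0, 1):
            if p[x, y] > 0:
                total += p[x, y] * math.log(p[x, y] / (px[x] * py[y]))
    if total < 0:
        if total < -_MI_TOL:
            raise AssertionError(f"mutual information below -tolerance: {total}")
        total = 0.0
    return total


def _binary_entropy(p: float) -> float:
    if p <= 0 or p >= 1:
        return 0.0
    return -p * math.log(p) - (1 - p) * math.log(1 - p)


def mi_similarity_matrix(sets: DiseaseDrugSets) -> pd.DataFrame:
    """Symmetric disease-by-disease mutual information matrix (nats).

    The diagonal holds each disease's marginal entropy H(D_i), the upper
    bound of any off-diagonal entry in its row.
    """
    diseases = sets.diseases
    n = len(diseases)
    m = np.zeros((n, n))
    for a in range(n):
        m[a, a] = _binary_entropy(len(sets.sets[diseases[a]]) / len(sets.universe))
        for b in range(a + 1, n):
            mi = mutual_information(bernoulli_joint(sets, diseases[a], diseases[b]))
            m[a, b] = m[b, a] = mi
    return pd.DataFrame(m, index=diseases, columns=diseases)


def mi_to_distance(similarity: pd.DataFrame) -> pd.DataFrame:
    """Order-reversing transform d(i,j) = I_max - I(i,j) with I_max the
    maximum off-diagonal similarity; the diagonal is 0."""
    m = similarity.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T):
        raise ValueError("similarity matrix must be square and symmetric")
    off = ~np.eye(m.shape[0], dtype=bool)
    i_max = float(m[off].max()) if off.any() else 0.0
    d = i_max - m
    np.fill_diagonal(d, 0.0)
    d[off] = np.maximum(d[off], 0.0)
    return pd.DataFrame(d, index=similarity.index, columns=similarity.columns)


def ward_cluster(distance: pd.DataFrame) -> Dendrogram:
    """Ward minimum-variance hierarchical clustering of a distance matrix.

    Ties between equal merge candidates are resolved deterministically
    (lowest condensed index, i.e. lexicographically smallest pair).
    """
    d = distance.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be 0")
    if np.any(d < 0):
        raise ValueError("distance matrix must be non-negative")
    condensed = squareform(d, checks=False)
    Z = linkage(condensed, method="ward")
    return Dendrogram(linkage_matrix=Z, labels=tuple(str(c) for c in distance.columns))


def exclusivity(sets: DiseaseDrugSets) -> pd.DataFrame:
    """Per disease: number of drugs, number adopted by no other included
    disease, and the exclusive fraction."""
    diseases = sets.diseases
    rows = []
    for d in diseases:
        mine = sets.sets[d]
        others = frozenset().union(*(sets.sets[o] for o in diseases if o != d)) if len(diseases) > 1 else frozenset()
        n_excl = len(mine - others)
        rows.append((d, len(mine), n_excl, n_excl / len(mine)))
    return pd.DataFrame(
        rows, columns=["disease_id", "n_drugs", "n_exclusive", "fraction_exclusive"]
    ).set_index("disease_id")


def newick_string(dendrogram: Dendrogram) -> str:
    """Serialize to Newick; branch lengths are merge-height differences
    (leaves sit at height 0)."""
    Z = np.asarray(dendrogram.linkage_matrix)
    labels = dendrogram.labels
    n = len(labels)
    height = {i: 0.0 for i in range(n)}

    def node_repr(idx: int) -> str:
        if idx < n:
            return labels[idx]
        row = Z[idx - n]
        left, right = int(row[0]), int(row[1])
        h = float(row[2])
        parts = []
        for child in (left, right):
            parts.append(f"{node_repr(child)}:{h - height[child]:g}")
        height[idx] = h
        return "(" + ",".join(parts) + ")"

    return node_repr(2 * n - 2) + ";"


def export_newick(dendrogram: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(newick_string(dendrogram) + "\n")
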