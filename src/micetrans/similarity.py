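"""Dyadic microbiota similarity: Jaccard, Bray-Curtis, shared counts.

Operates on a samples x ASV count table. Presence is any positive
proportion after per-sample normalization (no minimum-abundance
threshold). Phenotype-restricted Jaccard variants use only ASVs whose
genus has known aerotolerance and sporulation labels, and proportion
responses destined for beta regression are squeezed off the [0, 1]
boundary with the (y * (n - 1) + 0.5) / n transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._metrics import bray_curtis_similarity, jaccard, shared_count  # noqa: F401

logger = logging.getLogger(__name__)

SUBSETS = ("anaerobic", "aerotolerant", "spore", "non_spore")


@dataclass
class SimilarityMatrix:
    """Symmetric sample-pair similarity values."""

    ids: list
    values: np.ndarray
    metric: str = ""

    def value(self, a, b) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                rows.append({"sample_a": self.ids[i], "sample_b": self.ids[j],
                             "metric": self.metric, "value": self.values[i, j]})
        return pd.DataFrame(rows)


def proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances (rows sum to 1; empty rows stay 0)."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1)
    return counts.div(totals.where(totals > 0, 1.0), axis=0)


def presence(counts: pd.DataFrame) -> pd.DataFrame:
    """Boolean presence table (proportion > 0)."""
    return counts > 0


def jaccard_matrix(counts: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise Jaccard over presence/absence; 0 for two empty samples."""
    B = presence(counts).to_numpy().astype(np.float64)
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return SimilarityMatrix(list(counts.index), J, "jaccard")


def bray_curtis_matrix(counts: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise Bray-Curtis similarity on per-sample proportions."""
    P = proportions(counts).to_numpy()
    n = P.shape[0]
    m = np.empty((n, n))
    for i in range(n):
        diff = np.abs(P[i] - P).sum(axis=1)
        tot = (P[i] + P).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            m[i] = np.where(tot > 0, 1.0 - diff / np.maximum(tot, 1e-300), 0.0)
    return SimilarityMatrix(list(counts.index), m, "bray_curtis")


def shared_count_matrix(counts: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise counts of shared (co-present) ASVs."""
    B = presence(counts).to_numpy().astype(np.int64)
    return SimilarityMatrix(list(counts.index), B @ B.T, "shared_count")


def scale_count(values) -> np.ndarray:
    """Min-max scale shared counts to [0, 1] over the dyadic dataset."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        logger.warning("constant shared counts: scaled to 0")
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def known_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Genera usable for phenotype analyses (known aerotolerance + sporulation)."""
    if "known" in pheno.columns:
        return pheno[pheno["known"].astype(bool)]
    return pheno.dropna(subset=["aerotolerant", "spore_forming"])


def subset_asvs(genus_map: pd.Series, pheno: pd.DataFrame, subset: str) -> pd.Index:
    """ASV ids whose genus has a known phenotype matching ``subset``."""
    known = known_phenotypes(pheno)
    if subset == "anaerobic":
        genera = known.index[known["aerotolerant"] == 0]
    elif subset == "aerotolerant":
        genera = known.index[known["aerotolerant"] == 1]
    elif subset == "spore":
        genera = known.index[known["spore_forming"] == 1]
    elif subset == "non_spore":
        genera = known.index[known["spore_forming"] == 0]
    elif subset == "all":
        genera = known.index
    else:
        raise ValueError(f"unknown subset {subset!r}")
    return genus_map.index[genus_map.isin(set(genera))]


def subset_jaccard(counts: pd.DataFrame, genus_map: pd.Series, pheno: pd.DataFrame,
                   subset: str) -> SimilarityMatrix:
    """Jaccard over the ASVs of one phenotypic subset.

    Raises ``ValueError`` when the subset selects no ASVs; samples left
    with empty restricted presence sets are logged.
    """
    keep = subset_asvs(genus_map, pheno, subset)
    if len(keep) == 0:
        raise ValueError(f"phenotype subset {subset!r} selects no ASVs")
    restricted = counts.loc[:, counts.columns.intersection(keep)]
    empty = restricted.sum(axis=1) == 0
    if empty.any():
        logger.info("subset %s: %d samples have no ASVs in subset",
                    subset, int(empty.sum()))
    sim = jaccard_matrix(restricted)
    sim.metric = f"jaccard_{subset}"
    return sim


def smithson_verkuilen(j, n: int):
    """Squeeze a [0, 1] proportion into (0, 1): (j * (n - 1) + 0.5) / n."""
    arr = np.asarray(j, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("values must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    out = (arr * (n - 1) + 0.5) / n
    return float(out) if np.isscalar(j) else out


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel(m1: np.ndarray, m2: np.ndarray, n_perm: int = 999, seed=None):
    """Mantel correlation between two symmetric dyadic matrices.

    Pearson r over off-diagonal upper-triangle pairs; two-sided p from
    joint row/column permutations with add-one correction:
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm).
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and conformable")
    v1, v2 = _offdiag(m1), _offdiag(m2)
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("Mantel r undefined for a constant matrix")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    n = m1.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = np.corrcoef(v1, _offdiag(m2[np.ix_(perm, perm)]))[0, 1]
        if abs(r_p) >= abs(r_obs) - 1e-12:
            hits += 1
    return r_obs, (hits + 1) / (n_perm + 1)
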