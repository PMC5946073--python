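"""Entropy / information-gain kernel on genotype-phenotype contingency tables.

Synergy between two SNPs is the interaction information

    Syn = I(SNP1, SNP2; Y) - I(SNP1; Y) - I(SNP2; Y)

where Y is the case/control phenotype and the joint term treats the pair as a
single 9-level genotype variable. Positive synergy means the pair carries
information about the phenotype beyond the additive single-locus null;
negative synergy means the two SNPs are redundant (typical of residual LD).

All estimates are plug-in (maximum likelihood) in bits by default; the base
is configurable and every identity used downstream is base-invariant. A
Miller-Madow small-sample correction is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .core_data import MISSING

_LOG2 = np.log(2.0)


@dataclass(frozen=True)
class InfoDecomposition:
    """Additive decomposition of a SNP pair's information about the phenotype.

    ``syn`` is a derived quantity, identically ``i_joint - i1 - i2``.
    """

    i_joint: float
    i1: float
    i2: float
    n_used: int = 0
    i3: float | None = None  # populated for 3-locus decompositions only

    @property
    def syn(self) -> float:
        extra = self.i3 if self.i3 is not None else 0.0
        return self.i_joint - self.i1 - self.i2 - extra


def entropy(counts, base: float = 2.0) -> float:
    """Plug-in Shannon entropy of a count (or probability) vector.

    ``0 * log 0`` is taken as 0. Raises on an all-zero input.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if np.any(c < 0):
        raise ValueError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValueError("entropy of an all-zero count vector is undefined")
    p = c / total
    return float(-(xlogy(p, p)).sum() / np.log(base))


def _complete_mask(*columns) -> np.ndarray:
    mask = np.ones(len(columns[0]), dtype=bool)
    for col in columns:
        arr = np.asarray(col)
        if arr.dtype.kind in "fc":
            mask &= ~np.isnan(arr)
        if arr.dtype.kind in "iu" or arr.dtype.kind in "fc":
            mask &= np.asarray(arr) != MISSING
    return mask


def _contingency(feature: np.ndarray, y01: np.ndarray) -> np.ndarray:
    levels, inv = np.unique(feature, return_inverse=True)
    table = np.zeros((len(levels), 2), dtype=float)
    np.add.at(table, (inv, y01), 1.0)
    return table


def _mi_from_table(table: np.ndarray, base: float = 2.0) -> float:
    """I(rows; cols) of a 2-way count table: H(rows) + H(cols) - H(rows, cols)."""
    return (
        entropy(table.sum(axis=1), base)
        + entropy(table.sum(axis=0), base)
        - entropy(table, base)
    )


def _phenotype01(phenotype) -> np.ndarray:
    arr = np.asarray(phenotype)
    if arr.dtype.kind in "iub":
        return arr.astype(np.intp)
    return (arr == "case").astype(np.intp)


def information_gain(
    feature,
    phenotype,
    base: float = 2.0,
    miller_madow: bool = False,
) -> float:
    """Mutual information I(feature; phenotype) over complete cases, in bits.

    ``feature`` is a small-cardinality code vector (single-SNP calls use
    levels {0,1,2}; a pair call passes the 9-level joint genotype).
    ``phenotype`` is the case/control label vector (or a 0/1 vector).
    """
    feature = np.asarray(feature)
    y01 = _phenotype01(phenotype)
    mask = _complete_mask(feature, y01)
    f, y = feature[mask], y01[mask]
    if len(f) < 2:
        raise ValueError("need at least 2 complete cases")
    if len(np.unique(y)) < 2:
        raise ValueError("only one phenotype class after missing-data removal")
    table = _contingency(f, y)
    mi = _mi_from_table(table, base)
    if miller_madow:
        # Miller-Madow adds (K-1)/(2n) nats to each plug-in entropy;
        # MI = H(f) + H(y) - H(f,y) combines three corrected terms.
        n = table.sum()
        k_joint = int((table > 0).sum())
        k_f = int((table.sum(axis=1) > 0).sum())
        k_y = int((table.sum(axis=0) > 0).sum())
        mi += ((k_f - 1) + (k_y - 1) - (k_joint - 1)) / (2.0 * n * np.log(base))
    return mi


def synergy(
    snp1,
    snp2,
    phenotype,
    min_complete: int = 30,
    base: float = 2.0,
    pair_id: str = "",
) -> InfoDecomposition:
    """Interaction-information decomposition for one SNP pair.

    I1, I2 and the joint information are all computed on the same
    pairwise-complete subject set (listwise within the pair). ``syn`` may be
    negative, indicating redundant information between the SNPs.
    """
    g1 = np.asarray(snp1)
    g2 = np.asarray(snp2)
    y01 = _phenotype01(phenotype)
    mask = _complete_mask(g1, g2, y01)
    g1, g2, y = g1[mask].astype(np.intp), g2[mask].astype(np.intp), y01[mask]
    n = len(y)
    if n < min_complete:
        name = f" for pair {pair_id}" if pair_id else ""
        raise ValueError(
            f"only {n} complete cases{name}; minimum is {min_complete}"
        )
    if len(np.unique(y)) < 2:
        raise ValueError("only one phenotype class after missing-data removal")
    counts = np.zeros((3, 3, 2), dtype=float)
    np.add.at(counts, (g1, g2, y), 1.0)
    return decomposition_from_counts(counts, base=base)


def decomposition_from_counts(
    counts: np.ndarray, base: float = 2.0
) -> InfoDecomposition:
    """Decomposition from a (3, 3, 2) genotype x genotype x phenotype table.

    Accepts raw counts or probabilities (entropies normalise internally).
    Also accepts a (3, 3, 3, 2) table for a 3-locus decomposition, in which
    case ``i3`` is populated and ``syn`` subtracts all three marginals.
    """
    counts = np.asarray(counts, dtype=float)
    k = counts.ndim - 1
    if k not in (2, 3) or counts.shape != (3,) * k + (2,):
        raise ValueError("expected a (3,)*k + (2,) table with k in {2, 3}")
    n_used = int(round(counts.sum())) if counts.sum() > 1.5 else 0
    flat = counts.reshape(-1, 2)
    i_joint = _mi_from_table(flat, base)
    singles = []
    for axis in range(k):
        other = tuple(a for a in range(k) if a != axis)
        singles.append(_mi_from_table(counts.sum(axis=other), base))
    if k == 2:
        return InfoDecomposition(i_joint, singles[0], singles[1], n_used=n_used)
    return InfoDecomposition(
        i_joint, singles[0], singles[1], n_used=n_used, i3=singles[2]
    )
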