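"""Exhaustive pairwise synergy screen with permutation significance and FDR.

For every unordered SNP pair in scope the screen computes the interaction
information decomposition (I, I1, I2, Syn) on that pair's complete cases,
then assigns a one-sided permutation p-value in the synergistic direction:
phenotype labels are shuffled once per replicate and the same shuffled
vector is applied to every pair (preserving the inter-pair dependence that
the Benjamini-Yekutieli correction is designed for). Significant records
are assembled into an interaction network whose edges are classified as
intra-gene, intra-pathway or inter-pathway; intra-gene edges are flagged as
possible residual LD below the tagging r-squared cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .core_data import MISSING, GenotypeStudy, SnpAnnotationTable
from .infotheory import InfoDecomposition

logger = logging.getLogger(__name__)

_MISS_CODE = 3  # internal 4-level recoding of MISSING for vectorized counting


@dataclass(frozen=True)
class SynergyRecord:
    """One SNP pair's decomposition, permutation p, FDR q and edge category."""

    snp1: str
    snp2: str
    gene1: str
    gene2: str
    pathway1: str
    pathway2: str
    decomposition: InfoDecomposition
    p_perm: float
    fdr_q: float
    category: str  # intra_gene | intra_pathway | inter_pathway
    n_perm_used: int = 0

    @property
    def syn(self) -> float:
        return self.decomposition.syn


@dataclass
class InteractionNetwork:
    """Significant synergy edges with intra/inter-pathway bookkeeping."""

    graph: nx.Graph
    edges: list[SynergyRecord]
    category_counts: dict[str, int] = field(default_factory=dict)
    pathway_pair_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_table(self) -> pd.DataFrame:
        return records_to_table(self.edges)

    def write_edges(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_dot(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("graph synergy {\n")
            for node, data in self.graph.nodes(data=True):
                fh.write(f'  "{node}" [label="{data.get("label", node)}"];\n')
            for u, v, data in self.graph.edges(data=True):
                fh.write(f'  "{u}" -- "{v}" [weight={data.get("syn", 0):.4g}];\n')
            fh.write("}\n")


def benjamini_yekutieli(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up FDR adjustment (harmonic-sum factor).

    Valid under arbitrary dependence between tests; returns adjusted values
    capped at 1, monotone non-decreasing in the p-value ranks.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1]


def _classify(gene1: str, gene2: str, pathway1: str, pathway2: str) -> str:
    if gene1 and gene1 == gene2:
        return "intra_gene"
    if pathway1 and pathway1 == pathway2:
        return "intra_pathway"
    return "inter_pathway"


# ------------------------------------------------------- vectorized kernel


def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Row-wise entropy in bits of a (P, L) count array (0 log 0 = 0)."""
    tot = counts.sum(axis=1)
    safe = np.where(tot > 0, tot, 1.0)
    plogp = xlogy(counts, counts).sum(axis=1)
    return (np.log(safe) - plogp / safe) / np.log(2.0)


def _pair_counts(
    g_recoded: np.ndarray, y01: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray
) -> np.ndarray:
    """(P, 4, 4, 2) genotype x genotype x phenotype counts for P pairs.

    ``g_recoded`` holds codes {0,1,2} with missing recoded to 3 so that
    incomplete cells can be masked after a single bincount pass.
    """
    p = len(i_idx)
    codes = (g_recoded[:, i_idx].astype(np.int64) * 4 + g_recoded[:, j_idx]) * 2 + y01[
        :, None
    ]
    offsets = codes + 32 * np.arange(p, dtype=np.int64)[None, :]
    flat = np.bincount(offsets.ravel(), minlength=32 * p)
    return flat.reshape(p, 4, 4, 2).astype(float)


def _decomps_from_counts(counts: np.ndarray):
    """Per-pair I, I1, I2, syn, n_used from (P, 4, 4, 2) masked-count arrays."""
    valid = counts[:, :3, :3, :]  # drop cells where either genotype is missing
    p = valid.shape[0]
    n_used = valid.sum(axis=(1, 2, 3))
    h_joint_y = _entropy_rows(valid.reshape(p, 18))
    h_joint = _entropy_rows(valid.sum(axis=3).reshape(p, 9))
    h_y = _entropy_rows(valid.sum(axis=(1, 2)))
    i_joint = h_joint + h_y - h_joint_y

    g1y = valid.sum(axis=2)  # (P, 3, 2)
    g2y = valid.sum(axis=1)
    i1 = _entropy_rows(g1y.sum(axis=2)) + h_y - _entropy_rows(g1y.reshape(p, 6))
    i2 = _entropy_rows(g2y.sum(axis=2)) + h_y - _entropy_rows(g2y.reshape(p, 6))
    syn = i_joint - i1 - i2
    return i_joint, i1, i2, syn, n_used.astype(int)


def pairwise_synergy(
    genotypes: np.ndarray, phenotype01: np.ndarray, pairs: list[tuple[int, int]]
):
    """Vectorized interaction-information decomposition for many pairs.

    Returns arrays (i_joint, i1, i2, syn, n_used) aligned with ``pairs``.
    Complete-case analysis is listwise within each pair.
    """
    g = np.where(genotypes == MISSING, _MISS_CODE, genotypes).astype(np.int8)
    i_idx = np.fromiter((i for i, _ in pairs), dtype=np.int64, count=len(pairs))
    j_idx = np.fromiter((j for _, j in pairs), dtype=np.int64, count=len(pairs))
    counts = _pair_counts(g, phenotype01.astype(np.int64), i_idx, j_idx)
    return _decomps_from_counts(counts)


# --------------------------------------------------------------- screening


def _pairs_in_scope(
    snp_ids: list[str], ann: SnpAnnotationTable | None, scope: str
) -> list[tuple[int, int]]:
    all_pairs = list(combinations(range(len(snp_ids)), 2))
    if scope == "all":
        return all_pairs
    if ann is None:
        raise ValueError(f"scope {scope!r} requires an annotation table")
    pw = [ann.pathway(s) for s in snp_ids]
    if scope == "within_pathway":
        return [(i, j) for i, j in all_pairs if pw[i] and pw[i] == pw[j]]
    if scope == "between_pathways":
        return [(i, j) for i, j in all_pairs if pw[i] != pw[j]]
    raise ValueError(f"unknown scope {scope!r}")


def screen_pairs(
    study: GenotypeStudy,
    ann: SnpAnnotationTable | None = None,
    n_perm: int = 10_000,
    scope: str = "all",
    seed: int = 0,
    min_complete: int = 30,
    early_stop: bool = True,
    shared_streams: bool = True,
) -> list[SynergyRecord]:
    """Screen every in-scope unordered SNP pair for synergistic interaction.

    The permutation p-value is one-sided in the synergy direction:
    p = (b + 1) / (n_perm + 1) with b the number of phenotype-permutation
    replicates whose synergy meets or exceeds the observed value. With
    ``early_stop`` pairs whose running estimate exceeds 0.2 after 200
    replicates are frozen at their current resolution (the full ``n_perm``
    is honoured for any pair still in contention). ``n_perm = 0`` skips the
    permutation stage entirely (records carry p = NaN), which is enough for
    ranking by synergy.

    Output is sorted by ascending FDR q then descending synergy.
    """
    study.require_both_groups()
    if n_perm and n_perm < 100:
        raise ValueError("n_perm must be 0 (ranking only) or at least 100")
    pairs = _pairs_in_scope(study.snp_ids, ann, scope)
    if not pairs:
        raise ValueError(f"scope {scope!r} yields zero pairs")

    y01 = (study.phenotype == "case").astype(np.int64)
    g = np.where(study.genotypes == MISSING, _MISS_CODE, study.genotypes).astype(
        np.int8
    )
    i_idx = np.array([i for i, _ in pairs], dtype=np.int64)
    j_idx = np.array([j for _, j in pairs], dtype=np.int64)

    counts = _pair_counts(g, y01, i_idx, j_idx)
    i_joint, i1, i2, syn_obs, n_used = _decomps_from_counts(counts)

    ok = n_used >= min_complete
    n_low = int((~ok).sum())
    if n_low:
        logger.warning(
            "dropping %d pairs with fewer than %d complete cases", n_low, min_complete
        )
    keep = np.where(ok)[0]
    if keep.size == 0:
        raise ValueError("no pair has enough complete cases")

    p_perm = np.full(len(pairs), np.nan)
    n_perm_used = np.zeros(len(pairs), dtype=int)
    if n_perm:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(keep.size, dtype=np.int64)
        done = np.zeros(keep.size, dtype=np.int64)
        active = np.arange(keep.size)
        batch = 100
        reps = 0
        while reps < n_perm and active.size:
            take = min(batch, n_perm - reps)
            ii = i_idx[keep[active]]
            jj = j_idx[keep[active]]
            for _ in range(take):
                if shared_streams:
                    y_shuf = rng.permutation(y01)
                    c = _pair_counts(g, y_shuf, ii, jj)
                else:
                    # independent per-pair streams: shuffle anew for each pair
                    c = np.stack(
                        [
                            _pair_counts(
                                g, rng.permutation(y01), ii[k : k + 1], jj[k : k + 1]
                            )[0]
                            for k in range(active.size)
                        ]
                    )
                _, _, _, syn_p, _ = _decomps_from_counts(c)
                exceed[active] += syn_p >= syn_obs[keep[active]] - 1e-12
            done[active] += take
            reps += take
            if early_stop and reps >= 200:
                p_hat = (exceed[active] + 1) / (done[active] + 1)
                active = active[p_hat <= 0.2]
        p_perm[keep] = (exceed + 1) / (done + 1)
        n_perm_used[keep] = done

    fdr_q = np.full(len(pairs), np.nan)
    if n_perm:
        fdr_q[keep] = benjamini_yekutieli(p_perm[keep])

    records: list[SynergyRecord] = []
    for k in keep:
        i, j = pairs[k]
        s1, s2 = study.snp_ids[i], study.snp_ids[j]
        if s2 < s1:  # canonical unordered-pair orientation
            s1, s2 = s2, s1
            d = InfoDecomposition(
                float(i_joint[k]), float(i2[k]), float(i1[k]), int(n_used[k])
            )
        else:
            d = InfoDecomposition(
                float(i_joint[k]), float(i1[k]), float(i2[k]), int(n_used[k])
            )
        g1 = ann.gene(s1) if ann else ""
        g2 = ann.gene(s2) if ann else ""
        p1 = ann.pathway(s1) if ann else ""
        p2 = ann.pathway(s2) if ann else ""
        records.append(
            SynergyRecord(
                snp1=s1,
                snp2=s2,
                gene1=g1,
                gene2=g2,
                pathway1=p1,
                pathway2=p2,
                decomposition=d,
                p_perm=float(p_perm[k]),
                fdr_q=float(fdr_q[k]),
                category=_classify(g1, g2, p1, p2),
                n_perm_used=int(n_perm_used[k]),
            )
        )
    records.sort(
        key=lambda r: (
            r.fdr_q if not np.isnan(r.fdr_q) else 2.0,
            -r.syn,
            r.snp1,
            r.snp2,
        )
    )
    return records


def records_to_table(records: list[SynergyRecord]) -> pd.DataFrame:
    """Ranked table with the published column layout (Syn, I, p, FDR, ...)."""
    return pd.DataFrame(
        {
            "syn": [r.syn for r in records],
            "i": [r.decomposition.i_joint for r in records],
            "p_perm": [r.p_perm for r in records],
            "fdr_q": [r.fdr_q for r in records],
            "snp1": [r.snp1 for r in records],
            "gene1": [r.gene1 for r in records],
            "pathway1": [r.pathway1 for r in records],
            "snp2": [r.snp2 for r in records],
            "gene2": [r.gene2 for r in records],
            "pathway2": [r.pathway2 for r in records],
            "i1": [r.decomposition.i1 for r in records],
            "i2": [r.decomposition.i2 for r in records],
            "n_used": [r.decomposition.n_used for r in records],
            "category": [r.category for r in records],
        }
    )


def build_network(
    records: list[SynergyRecord],
    fdr_max: float = 0.005,
    p_max: float = 1e-4,
) -> InteractionNetwork:
    """Retain records passing both thresholds and build the interaction network.

    Nodes are SNPs labelled by gene symbol (falling back to the SNP id when
    no gene is assigned); intra-gene edges carry ``ld_flag=True`` marking
    them for residual-LD review.
    """
    sig = [
        r
        for r in records
        if not np.isnan(r.fdr_q) and r.fdr_q <= fdr_max and r.p_perm <= p_max
    ]
    graph = nx.Graph()
    category_counts: dict[str, int] = {}
    pathway_pair_counts: dict[tuple[str, str], int] = {}
    for r in sig:
        for snp, gene in ((r.snp1, r.gene1), (r.snp2, r.gene2)):
            graph.add_node(snp, label=gene or snp)
        graph.add_edge(
            r.snp1,
            r.snp2,
            syn=r.syn,
            fdr_q=r.fdr_q,
            category=r.category,
            ld_flag=r.category == "intra_gene",
        )
        category_counts[r.category] = category_counts.get(r.category, 0) + 1
        pw = tuple(sorted((r.pathway1, r.pathway2)))
        pathway_pair_counts[pw] = pathway_pair_counts.get(pw, 0) + 1
    return InteractionNetwork(
        graph=graph,
        edges=sig,
        category_counts=category_counts,
        pathway_pair_counts=pathway_pair_counts,
    )
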