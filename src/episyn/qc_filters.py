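"""Marker-level quality control for case-control SNP panels.

Filters applied, in order: per-SNP call rate, minor allele frequency
(whole sample by default), Hardy-Weinberg exact test in the control group,
and greedy within-chromosome pruning of pairs that are either closer than a
minimum base-pair distance or correlated above a genotypic r-squared cutoff
(the higher-MAF member of a conflicting pair is retained as the tag).

The HWE test is the conditional exact test: given the observed allele
counts, the two-sided p-value sums the probabilities of all heterozygote
counts whose conditional probability does not exceed that of the observed
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import MISSING, GenotypeStudy, SnpAnnotationTable

logger = logging.getLogger(__name__)


def minor_allele_frequency(column) -> float:
    """MAF of a genotype-code column over non-missing alleles, folded to <= 0.5."""
    col = np.asarray(column)
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValueError("all-missing genotype column")
    freq = obs.sum() / (2.0 * obs.size)
    return float(min(freq, 1.0 - freq))


def call_rate(column) -> float:
    col = np.asarray(column)
    return float((col != MISSING).mean()) if col.size else 0.0


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the observed allele counts, enumerates all heterozygote
    counts of the same parity and sums the probabilities of tables no more
    probable than the observed one. Uses the standard stable recurrence on
    the conditional distribution of the heterozygote count.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotype")
    rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)  # copies of the rarer allele
    het_max = min(rare, 2 * n - rare)
    # heterozygote count shares the parity of the rare-allele count
    hets = np.arange(rare % 2, het_max + 1, 2)
    if hets.size == 0:  # only achievable when n == 0, guarded above
        return 1.0
    probs = np.empty(hets.size, dtype=float)
    probs[0] = 1.0
    for i in range(1, hets.size):
        h = hets[i]  # moving h-2 -> h: split one rare-hom and one common-hom
        rare_hom = (rare - h) // 2 + 1
        common_hom = (2 * n - rare - h) // 2 + 1
        probs[i] = probs[i - 1] * 4.0 * rare_hom * common_hom / (h * (h - 1))
    probs /= probs.sum()
    obs_idx = int(np.where(hets == n_Aa)[0][0])
    p = float(probs[probs <= probs[obs_idx] * (1.0 + 1e-10)].sum())
    return min(p, 1.0)


def genotypic_r2(col1, col2) -> float:
    """Squared Pearson correlation of genotype codes over pairwise-complete subjects.

    Returns 0.0 when either column is constant on the shared subjects (no
    linear association measurable).
    """
    a = np.asarray(col1, dtype=float)
    b = np.asarray(col2, dtype=float)
    mask = (a != MISSING) & (b != MISSING)
    a, b = a[mask], b[mask]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class QcReport:
    """Per-SNP QC decisions plus the LD pruning map (dropped -> retained tag)."""

    table: pd.DataFrame
    prune_map: dict[str, tuple[str, float]] = field(default_factory=dict)

    @property
    def kept_snps(self) -> list[str]:
        return list(self.table.loc[self.table["kept"], "snp_id"])

    @property
    def dropped_snps(self) -> list[str]:
        return list(self.table.loc[~self.table["kept"], "snp_id"])

    def drop_reason(self, snp_id: str) -> str:
        row = self.table.loc[self.table["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(snp_id)
        return str(row["drop_reason"].iloc[0])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def apply_marker_qc(
    study: GenotypeStudy,
    ann: SnpAnnotationTable | None = None,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.001,
    r2_max: float = 0.8,
    min_distance_bp: int = 60,
    max_missing: float = 0.10,
    maf_controls_only: bool = False,
) -> tuple[GenotypeStudy, QcReport]:
    """Run the full marker QC and return the filtered study plus a report.

    MAF is computed over the whole sample by default (``maf_controls_only``
    restricts it to controls); the HWE exact test always uses controls only,
    since departures in cases can reflect true association rather than
    genotyping error. Pruning considers within-chromosome pairs only and
    requires annotation positions; without an annotation the distance rule
    is skipped and all SNPs are treated as one linkage group.
    """
    study.require_both_groups()
    control_mask = ~study.case_mask
    n_snps = study.n_snps

    maf = np.empty(n_snps)
    hwe_p = np.ones(n_snps)
    rate = np.empty(n_snps)
    reason = np.array(["none"] * n_snps, dtype=object)

    maf_rows = control_mask if maf_controls_only else np.ones(
        study.n_subjects, dtype=bool
    )
    for j in range(n_snps):
        col = study.genotypes[:, j]
        rate[j] = call_rate(col)
        sub = col[maf_rows]
        maf[j] = minor_allele_frequency(sub) if np.any(sub != MISSING) else 0.0
        ctrl = col[control_mask]
        ctrl = ctrl[ctrl != MISSING]
        if ctrl.size:
            n_hom_ref = int(np.sum(ctrl == 0))
            n_het = int(np.sum(ctrl == 1))
            n_hom_alt = int(np.sum(ctrl == 2))
            hwe_p[j] = hwe_exact_test(n_hom_ref, n_het, n_hom_alt)

    reason[rate < 1.0 - max_missing] = "call_rate"
    maf_fail = (maf < maf_min) & (reason == "none")
    reason[maf_fail] = "maf"
    hwe_fail = (hwe_p < hwe_alpha) & (reason == "none")
    reason[hwe_fail] = "hwe"

    # Greedy within-chromosome pruning among survivors: process in descending
    # MAF (snp_id as tie-break, so column order never changes the result);
    # drop a SNP conflicting with an already-retained tag.
    prune_map: dict[str, tuple[str, float]] = {}
    survivors = [j for j in range(n_snps) if reason[j] == "none"]

    def chrom_of(snp: str) -> str:
        if ann is not None and snp in ann:
            return ann.get(snp).chromosome
        return "?"

    def pos_of(snp: str) -> int | None:
        if ann is not None and snp in ann:
            return ann.get(snp).position
        return None

    by_chrom: dict[str, list[int]] = {}
    for j in survivors:
        by_chrom.setdefault(chrom_of(study.snp_ids[j]), []).append(j)

    for chrom, idxs in by_chrom.items():
        order = sorted(idxs, key=lambda j: (-maf[j], study.snp_ids[j]))
        kept_here: list[int] = []
        for j in order:
            snp_j = study.snp_ids[j]
            conflict = None
            for k in kept_here:
                snp_k = study.snp_ids[k]
                pj, pk = pos_of(snp_j), pos_of(snp_k)
                too_close = (
                    pj is not None and pk is not None and abs(pj - pk) < min_distance_bp
                )
                r2 = genotypic_r2(study.genotypes[:, j], study.genotypes[:, k])
                if too_close or r2 >= r2_max:
                    conflict = (snp_k, r2)
                    break
            if conflict is None:
                kept_here.append(j)
            else:
                reason[j] = "ld_redundant"
                prune_map[snp_j] = conflict

    kept = reason == "none"
    tag_of = [prune_map.get(s, ("", np.nan))[0] for s in study.snp_ids]
    r2_col = [prune_map.get(s, ("", np.nan))[1] for s in study.snp_ids]
    report = QcReport(
        table=pd.DataFrame(
            {
                "snp_id": study.snp_ids,
                "maf": maf,
                "hwe_p": hwe_p,
                "call_rate": rate,
                "kept": kept,
                "drop_reason": reason,
                "tag_of": tag_of,
                "r2": r2_col,
            }
        ),
        prune_map=prune_map,
    )
    kept_ids = [s for s, k in zip(study.snp_ids, kept) if k]
    if not kept_ids:
        raise ValueError("marker QC removed every SNP")
    logger.info(
        "marker QC: kept %d/%d SNPs (%s)",
        len(kept_ids),
        n_snps,
        ", ".join(
            f"{r}={int((reason == r).sum())}"
            for r in ("call_rate", "maf", "hwe", "ld_redundant")
            if (reason == r).any()
        )
        or "no drops",
    )
    return study.subset_snps(kept_ids), report
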