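"""Synthetic case-control genotype studies with planted epistatic effects.

The generator emulates the design the pipeline targets: two phenotype
groups filled by case-control ascertainment (rejection sampling from a
superpopulation), a pathway-structured candidate SNP panel with genotypes
drawn from Hardy-Weinberg proportions at MAF >= 5%, optional block LD by
conditional copying, planted marginal (logistic) and pairwise/3-way
interaction (logistic or penetrance-table) effects, genotype-dependent
censored survival in the case group, and uniform missingness. Ground truth
— planted loci, their analytic information decomposition, and true hazard
ratios — is returned alongside every study so recovery can be scored
without re-deriving it.

Sex composition defaults to the nonagenarian-cohort pattern (71% female
cases, 50% female controls). The default panel is a test-scale version of
a three-pathway candidate panel: 20 SNPs each in IIS, pro/antioxidant and
DNA-repair; ``full_scale_panel`` gives the full 317/260/481 layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .core_data import (
    DEFAULT_PATHWAYS,
    GenotypeCombination,
    GenotypeStudy,
    MISSING,
    SnpAnnotation,
    SnpAnnotationTable,
)
from .infotheory import InfoDecomposition, decomposition_from_counts

TEST_SCALE_PANEL: tuple[tuple[str, int], ...] = (
    ("IIS", 20),
    ("pro_antioxidant", 20),
    ("DNA_repair", 20),
)


def full_scale_panel() -> tuple[tuple[str, int], ...]:
    """Cohort-scale three-pathway panel layout (317 / 260 / 481 SNPs)."""
    return (("IIS", 317), ("pro_antioxidant", 260), ("DNA_repair", 481))


# ----------------------------------------------------------------- effects


@dataclass(frozen=True)
class PenetranceEffect:
    """Explicit penetrance table over the genotype cells of ``loci``.

    ``table[g1, g2, ...]`` is P(case | cell) before case-control
    ascertainment. ``mafs`` optionally pins the planted loci's minor allele
    frequencies (e.g. 0.5 to null out marginal effects of an XOR table).
    """

    loci: tuple[int, ...]
    table: tuple  # nested tuples, shape (3,)*k
    mafs: tuple[float, ...] | None = None

    @property
    def k(self) -> int:
        return len(self.loci)

    def table_array(self) -> np.ndarray:
        arr = np.asarray(self.table, dtype=float)
        if arr.shape != (3,) * self.k:
            raise ValueError(f"penetrance table must have shape {(3,) * self.k}")
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("penetrance values must lie in [0, 1]")
        return arr


@dataclass(frozen=True)
class LogisticEffect:
    """Additive/interaction effect on the log-odds of being a case.

    Contributes ``intercept + sum_i beta[i] * g_i + beta_int * prod_i g_i``
    to the logit of the case probability.
    """

    loci: tuple[int, ...]
    beta: tuple[float, ...] = ()
    beta_int: float = 0.0
    intercept: float = 0.0


@dataclass(frozen=True)
class SurvivalEffect:
    """Multiplicative hazard for carriers of a genotype condition in cases."""

    loci: tuple[int, ...]
    conditions: tuple[frozenset, ...]
    hazard_ratio: float


def xor_penetrance(
    p_low: float = 0.3, p_high: float = 0.7, k: int = 2
) -> tuple:
    """Pure-epistasis (parity/XOR-flavoured) penetrance table.

    Cells with an odd total minor-allele count get ``p_high``, even cells
    ``p_low``; at MAF = 0.5 the marginal single-locus effects vanish.
    """
    shape = (3,) * k
    arr = np.empty(shape)
    for cell in np.ndindex(shape):
        arr[cell] = p_high if sum(cell) % 2 else p_low
    return tuple(map(tuple, arr)) if k == 2 else tuple(
        tuple(map(tuple, plane)) for plane in arr
    )


# ------------------------------------------------------------------ config


@dataclass(frozen=True)
class SimConfig:
    """Full recipe for one synthetic study (the seed covers all randomness)."""

    n_cases: int = 400
    n_controls: int = 300
    panel: tuple[tuple[str, int], ...] = TEST_SCALE_PANEL
    maf_law: tuple[float, float] = (0.10, 0.45)
    ld_blocks: tuple[tuple[int, float], ...] = ()  # (block size, target r)
    effects: tuple = ()
    survival_effects: tuple[SurvivalEffect, ...] = ()
    median_survival_months: float = 36.0
    censor_window: tuple[float, float] = (6.0, 120.0)
    female_frac_cases: float = 0.71
    female_frac_controls: float = 0.50
    missing_rate: float = 0.01
    base_rate: float = 0.5
    snps_per_gene: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.maf_law[0] < 0.05:
            raise ValueError("maf_law lower bound must be >= 0.05")
        for frac in (
            self.female_frac_cases,
            self.female_frac_controls,
            self.missing_rate,
            self.base_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        n_snps = sum(n for _, n in self.panel)
        for eff in self.effects:
            if max(eff.loci) >= n_snps:
                raise ValueError("planted effect references a locus outside the panel")


@dataclass
class GroundTruth:
    """Planted effects with their analytic quantities, for recovery scoring."""

    seed: int
    planted: list[dict] = field(default_factory=list)
    survival: list[dict] = field(default_factory=list)

    def planted_pairs(self) -> list[tuple[str, str]]:
        out = []
        for rec in self.planted:
            ids = rec["snp_ids"]
            if len(ids) == 2:
                out.append(tuple(sorted(ids)))
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "planted": self.planted,
                    "survival": self.survival,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


# ----------------------------------------------------------- analytic oracle


def hwe_genotype_probs(maf: float) -> np.ndarray:
    q = float(maf)
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def analytic_decomposition(
    table, mafs: Sequence[float], case_fraction: float = 0.5
) -> InfoDecomposition:
    """Exact population-level information decomposition of a penetrance table.

    The joint genotype law is the product of per-locus HWE proportions at
    the given MAFs; the phenotype margin reflects case-control sampling at
    ``case_fraction`` (the composition the plug-in estimates on a sampled
    study converge to), not the population prevalence.
    """
    arr = np.asarray(table, dtype=float)
    k = arr.ndim
    if arr.shape != (3,) * k or len(mafs) != k:
        raise ValueError("table shape and number of MAFs disagree")
    cell_p = np.ones((3,) * k)
    for axis, maf in enumerate(mafs):
        shape = [1] * k
        shape[axis] = 3
        cell_p = cell_p * hwe_genotype_probs(maf).reshape(shape)
    p_case_and_cell = cell_p * arr
    p_ctrl_and_cell = cell_p * (1.0 - arr)
    joint = np.zeros((3,) * k + (2,))
    joint[..., 1] = case_fraction * p_case_and_cell / p_case_and_cell.sum()
    joint[..., 0] = (1 - case_fraction) * p_ctrl_and_cell / p_ctrl_and_cell.sum()
    return decomposition_from_counts(joint)


# ------------------------------------------------------------- simulation


def _panel_layout(config: SimConfig):
    """SNP ids, annotation rows and per-SNP block membership for the panel."""
    snp_ids: list[str] = []
    records: list[SnpAnnotation] = []
    chrom_cycle = [str(c) for c in range(1, 23)]
    chrom_pos: dict[str, int] = {c: 0 for c in chrom_cycle}
    gene_counter = 0
    snp_counter = 0
    for pathway, n in config.panel:
        for i in range(n):
            if i % config.snps_per_gene == 0:
                gene_counter += 1
            gene = f"{pathway[:3].upper()}G{gene_counter:03d}"
            chrom = chrom_cycle[(gene_counter - 1) % len(chrom_cycle)]
            chrom_pos[chrom] += 50_000
            snp_id = f"rs{snp_counter:06d}"
            snp_ids.append(snp_id)
            records.append(
                SnpAnnotation(
                    snp_id=snp_id,
                    gene=gene,
                    pathway=pathway,
                    chromosome=chrom,
                    position=chrom_pos[chrom],
                )
            )
            snp_counter += 1
    # LD blocks claim consecutive SNPs from the start of the panel
    block_of = np.full(len(snp_ids), -1, dtype=int)
    block_r: list[float] = []
    cursor = 0
    for b, (size, r) in enumerate(config.ld_blocks):
        if cursor + size > len(snp_ids):
            raise ValueError("LD blocks exceed panel size")
        block_of[cursor : cursor + size] = b
        block_r.append(float(r))
        cursor += size
    return snp_ids, records, block_of, block_r


def _draw_genotypes(
    rng, batch: int, mafs: np.ndarray, block_of: np.ndarray, block_r: list[float]
) -> np.ndarray:
    m = len(mafs)
    g = rng.binomial(2, mafs[None, :], size=(batch, m)).astype(np.int8)
    # within-block conditional copying: copy the previous SNP with prob r,
    # which yields genotypic correlation r for identical marginals
    for j in range(1, m):
        if block_of[j] >= 0 and block_of[j] == block_of[j - 1]:
            r = block_r[block_of[j]]
            copy = rng.random(batch) < r
            g[copy, j] = g[copy, j - 1]
    return g


def _case_probability(g: np.ndarray, config: SimConfig) -> np.ndarray:
    eta = np.full(g.shape[0], logit(config.base_rate))
    for eff in config.effects:
        if isinstance(eff, PenetranceEffect):
            arr = eff.table_array()
            cells = tuple(g[:, i] for i in eff.loci)
            eta += logit(np.clip(arr[cells], 1e-9, 1 - 1e-9)) - logit(config.base_rate)
        elif isinstance(eff, LogisticEffect):
            eta += eff.intercept
            for b, i in zip(eff.beta, eff.loci):
                eta += b * g[:, i]
            if eff.beta_int:
                prod = np.ones(g.shape[0])
                for i in eff.loci:
                    prod *= g[:, i]
                eta += eff.beta_int * prod
        else:
            raise TypeError(f"unknown effect type {type(eff).__name__}")
    return expit(eta)


def simulate_study(
    config: SimConfig, max_draw_factor: int = 500
) -> tuple[GenotypeStudy, SnpAnnotationTable, GroundTruth]:
    """Simulate one study under ``config``; byte-reproducible from its seed.

    Case/control quotas are filled by rejection from a superpopulation:
    genotypes are drawn, the planted model assigns the case probability,
    and subjects are kept until both quotas are met (mirroring case-control
    ascertainment). Raises if quotas are unsatisfiable within
    ``max_draw_factor`` times the requested sample size.
    """
    rng = np.random.default_rng(config.seed)
    snp_ids, ann_records, block_of, block_r = _panel_layout(config)
    m = len(snp_ids)

    mafs = rng.uniform(config.maf_law[0], config.maf_law[1], size=m)
    for j in range(m):
        b = block_of[j]
        if b >= 0:  # block members share the first member's MAF
            first = int(np.argmax(block_of == b))
            mafs[j] = mafs[first]
    for eff in config.effects:
        if isinstance(eff, PenetranceEffect) and eff.mafs is not None:
            for locus, maf in zip(eff.loci, eff.mafs):
                mafs[locus] = maf

    n_total = config.n_cases + config.n_controls
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    drawn = 0
    while len(cases) < config.n_cases or len(controls) < config.n_controls:
        batch = max(256, n_total)
        g = _draw_genotypes(rng, batch, mafs, block_of, block_r)
        p = _case_probability(g, config)
        is_case = rng.random(batch) < p
        drawn += batch
        for row, c in zip(g, is_case):
            if c and len(cases) < config.n_cases:
                cases.append(row)
            elif not c and len(controls) < config.n_controls:
                controls.append(row)
        if drawn > max_draw_factor * n_total:
            raise RuntimeError(
                "case/control quotas unsatisfiable: planted model is degenerate"
            )

    genotypes = np.vstack([np.stack(cases), np.stack(controls)])
    phenotype = np.array(
        ["case"] * config.n_cases + ["control"] * config.n_controls, dtype=object
    )
    female = np.concatenate(
        [
            rng.random(config.n_cases) < config.female_frac_cases,
            rng.random(config.n_controls) < config.female_frac_controls,
        ]
    )
    sex = np.where(female, "female", "male").astype(object)
    subject_ids = [f"S{i:05d}" for i in range(n_total)]

    # survival for cases: exponential baseline, carrier hazard ratios, uniform censoring
    truth = GroundTruth(seed=config.seed)
    rate = np.log(2.0) / config.median_survival_months
    hazard_mult = np.ones(config.n_cases)
    for eff in config.survival_effects:
        cols = genotypes[: config.n_cases, list(eff.loci)]
        matches = np.ones(config.n_cases, dtype=bool)
        for d, cond in enumerate(eff.conditions):
            matches &= np.isin(cols[:, d], sorted(cond))
        hazard_mult[matches] *= eff.hazard_ratio
        truth.survival.append(
            {
                "snp_ids": [snp_ids[i] for i in eff.loci],
                "conditions": [sorted(c) for c in eff.conditions],
                "hazard_ratio": eff.hazard_ratio,
                "n_carriers": int(matches.sum()),
            }
        )
    t_death = rng.exponential(1.0 / (rate * hazard_mult))
    censor = rng.uniform(*config.censor_window, size=config.n_cases)
    event_case = (t_death <= censor).astype(float)
    months_case = np.maximum(1.0, np.rint(np.minimum(t_death, censor)))
    survival_months = np.concatenate(
        [months_case, np.full(config.n_controls, np.nan)]
    )
    event = np.concatenate([event_case, np.full(config.n_controls, np.nan)])

    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes = np.where(mask, MISSING, genotypes).astype(np.int8)

    for eff in config.effects:
        rec = {
            "type": type(eff).__name__,
            "snp_ids": [snp_ids[i] for i in eff.loci],
            "mafs": [float(mafs[i]) for i in eff.loci],
        }
        if isinstance(eff, PenetranceEffect):
            rec["table"] = eff.table_array().tolist()
            case_fraction = config.n_cases / n_total
            d = analytic_decomposition(
                eff.table_array(),
                [float(mafs[i]) for i in eff.loci],
                case_fraction=case_fraction,
            )
            rec["analytic"] = {
                "i_joint": d.i_joint,
                "i1": d.i1,
                "i2": d.i2,
                "syn": d.syn,
            }
        else:
            rec["beta"] = list(eff.beta)
            rec["beta_int"] = eff.beta_int
        truth.planted.append(rec)

    study = GenotypeStudy(
        subject_ids=subject_ids,
        phenotype=phenotype,
        sex=sex,
        genotypes=genotypes,
        snp_ids=snp_ids,
        survival_months=survival_months,
        event=event,
    )
    ann = SnpAnnotationTable(ann_records, pathways=DEFAULT_PATHWAYS)
    return study, ann, truth


def survival_combination(
    truth_record: dict,
) -> GenotypeCombination:
    """Rebuild the planted survival combination from a ground-truth record."""
    loci = tuple(
        (snp, frozenset(cond))
        for snp, cond in zip(truth_record["snp_ids"], truth_record["conditions"])
    )
    comb = GenotypeCombination(loci=loci)
    return GenotypeCombination(loci=loci, label=comb.default_label())
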