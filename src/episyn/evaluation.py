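"""Calibration and recovery experiments for the pipeline's statistics.

These routines re-run the pipeline's stages on freshly simulated studies
under controlled conditions — a global null, a planted pure-epistasis
pair, a planted carrier hazard ratio — and report the rates a correctly
implemented method must achieve (uniform permutation p-values, ~alpha
type-I error, high recovery of the planted signal, ~95% CI coverage).

``REFERENCE_DECOMPOSITIONS`` holds published pairwise synergy
decompositions (I, I1, I2, Syn, in bits) from a nonagenarian case-control
candidate-gene screen; they serve as worked examples for the additive
decomposition identity Syn = I - I1 - I2.
"""

from __future__ import annotations

import numpy as np

from .infotheory import InfoDecomposition
from .mdr import run_mdr
from .survival_followup import cox_hr
from .synergy_screen import screen_pairs
from .synthetic_data import (
    PenetranceEffect,
    SimConfig,
    SurvivalEffect,
    simulate_study,
    survival_combination,
    xor_penetrance,
)

#: (label, I, I1, I2, printed Syn) for five published SNP-pair decompositions.
REFERENCE_DECOMPOSITIONS: tuple[tuple[str, float, float, float, float], ...] = (
    ("ERCC1_rs3212961_rs762562", 0.0246, 0.0034, 0.0013, 0.0199),
    ("GHRHR_rs2267723_rs4988505", 0.0297, 0.0112, 0.0004, 0.0181),
    ("PTPN1_rs2038526_rs6067484", 0.0214, 0.0001, 0.0054, 0.0159),
    ("ERCC1_rs3212961_rs3212964", 0.0178, 0.0034, 0.0001, 0.0143),
    ("NBN_rs12680687_rs2735385", 0.0182, 0.0041, 0.0001, 0.0140),
)


def reference_decomposition_syns() -> dict[str, float]:
    """Recompute Syn = I - I1 - I2 for each published reference row."""
    return {
        label: InfoDecomposition(i_joint=i, i1=i1, i2=i2).syn
        for label, i, i1, i2, _ in REFERENCE_DECOMPOSITIONS
    }


def _seed_stream(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def null_synergy_pvalues(
    seed: int = 0,
    n_runs: int = 40,
    n_per_group: int = 150,
    n_snps: int = 10,
    n_perm: int = 200,
) -> np.ndarray:
    """Pooled permutation p-values from synergy screens under the global null."""
    seeds = _seed_stream(seed, n_runs)
    out: list[float] = []
    for i, s in enumerate(seeds):
        cfg = SimConfig(
            n_cases=n_per_group,
            n_controls=n_per_group,
            panel=(("IIS", n_snps),),
            missing_rate=0.0,
            seed=s,
        )
        study, ann, _ = simulate_study(cfg)
        records = screen_pairs(
            study, ann, n_perm=n_perm, seed=s + 1, early_stop=False
        )
        out.extend(r.p_perm for r in records)
    return np.asarray(out)


def mdr_null_rejection_rate(
    seed: int = 0,
    n_runs: int = 40,
    n_per_group: int = 300,
    n_snps: int = 20,
    n_perm: int = 200,
    alpha: float = 0.05,
) -> float:
    """Fraction of null studies where MDR's permutation test rejects at alpha."""
    seeds = _seed_stream(seed + 1_000, n_runs)
    rejections = 0
    for s in seeds:
        cfg = SimConfig(
            n_cases=n_per_group,
            n_controls=n_per_group,
            panel=(("IIS", n_snps),),
            missing_rate=0.0,
            seed=s,
        )
        study, _, _ = simulate_study(cfg)
        models = run_mdr(study, k=2, n_perm=n_perm, seed=s + 1, min_cvc=0)
        rejections += models[0].p_perm <= alpha
    return rejections / n_runs


def planted_pair_recovery(
    seed: int = 0,
    n_runs: int = 25,
    n_per_group: int = 1000,
    cvc_min: int = 8,
) -> tuple[float, float]:
    """Recovery of a planted pure-epistasis pair on a 30-SNP panel.

    Returns (fraction of runs where the planted pair is top-ranked by
    synergy, fraction where it is MDR's top model with CVC >= cvc_min).
    """
    seeds = _seed_stream(seed + 2_000, n_runs)
    syn_hits = mdr_hits = 0
    for s in seeds:
        cfg = SimConfig(
            n_cases=n_per_group,
            n_controls=n_per_group,
            panel=(("IIS", 10), ("pro_antioxidant", 10), ("DNA_repair", 10)),
            effects=(
                PenetranceEffect(
                    loci=(0, 1), table=xor_penetrance(0.3, 0.7), mafs=(0.5, 0.5)
                ),
            ),
            missing_rate=0.0,
            seed=s,
        )
        study, ann, truth = simulate_study(cfg)
        planted = truth.planted_pairs()[0]
        records = screen_pairs(study, ann, n_perm=0, seed=0)
        best = max(records, key=lambda r: r.syn)
        syn_hits += (best.snp1, best.snp2) == planted
        models = run_mdr(study, k=2, n_perm=0, seed=s + 1)
        top = models[0]
        mdr_hits += tuple(sorted(top.loci)) == planted and top.cvc >= cvc_min
    return syn_hits / n_runs, mdr_hits / n_runs


def cox_hazard_ratio_recovery(
    seed: int = 0,
    n_runs: int = 100,
    n_cases: int = 700,
    true_hr: float = 0.7,
) -> tuple[float, float]:
    """Coverage and mean estimate of a planted carrier hazard ratio.

    Mimics a female nonagenarian stratum of ~700 subjects: exponential
    survival with the carriers of one SNP's minor allele at hazard ratio
    ``true_hr``. Returns (CI coverage fraction, mean HR estimate).
    """
    seeds = _seed_stream(seed + 3_000, n_runs)
    covered = 0
    estimates: list[float] = []
    for s in seeds:
        cfg = SimConfig(
            n_cases=n_cases,
            n_controls=40,
            panel=(("IIS", 4),),
            survival_effects=(
                SurvivalEffect(
                    loci=(0,), conditions=(frozenset({1, 2}),), hazard_ratio=true_hr
                ),
            ),
            female_frac_cases=1.0,
            censor_window=(24.0, 120.0),
            missing_rate=0.0,
            seed=s,
        )
        study, _, truth = simulate_study(cfg)
        cases = study.subset_subjects(study.case_mask)
        comb = survival_combination(truth.survival[0])
        match, _ = comb.evaluate(cases)
        hr, (lo, hi) = cox_hr(cases.survival_months, cases.event, match.astype(int))
        estimates.append(hr)
        covered += lo <= true_hr <= hi
    return covered / n_runs, float(np.mean(estimates))
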