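"""Multifactor dimensionality reduction (MDR) for k-locus epistasis models.

MDR pools the 3^k multilocus genotype cells of a k-SNP model into high- and
low-risk classes by comparing each cell's case:control ratio with the
overall ratio T, turning the model into a single binary classifier that is
scored by balanced accuracy. The search is exhaustive over k-subsets inside
a seeded, stratified 10-fold cross-validation: each fold's winner is the
subset with the best training balanced accuracy, cross-validation
consistency (CVC) counts how many folds agree, and significance comes from
full phenotype-permutation reruns of the entire search, comparing the null
distribution of the best model's mean testing balanced accuracy with the
observed value.

Missing genotypes are imputed globally with the per-SNP modal genotype
before any analysis (ties broken toward the lower code).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree

from .core_data import (
    ANY_GENOTYPE,
    CARRIER_MAJOR,
    CARRIER_MINOR,
    MISSING,
    GenotypeCombination,
    GenotypeStudy,
)
from .infotheory import entropy, information_gain, synergy

logger = logging.getLogger(__name__)

HIGH, LOW, EMPTY = "high_risk", "low_risk", "empty"


# ------------------------------------------------------------------ imputation


def impute_missing(study: GenotypeStudy) -> GenotypeStudy:
    """Replace every missing call with its SNP's modal genotype (whole sample).

    Deterministic: ties between modes resolve to the lower genotype code.
    Per-SNP imputation counts are logged.
    """
    g = study.genotypes.copy()
    for j in range(g.shape[1]):
        col = g[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValueError(f"SNP {study.snp_ids[j]!r} has no observed genotypes")
        counts = np.bincount(obs, minlength=3)
        mode = int(np.argmax(counts))  # argmax takes the lowest code on ties
        col[miss] = mode
        logger.info(
            "imputed %d missing calls at %s with genotype %d",
            int(miss.sum()),
            study.snp_ids[j],
            mode,
        )
    return GenotypeStudy(
        subject_ids=list(study.subject_ids),
        phenotype=study.phenotype.copy(),
        sex=study.sex.copy(),
        genotypes=g,
        snp_ids=list(study.snp_ids),
        survival_months=None
        if study.survival_months is None
        else study.survival_months.copy(),
        event=None if study.event is None else study.event.copy(),
    )


# ------------------------------------------------------------- cell labeling


def _cell_codes(genotypes: np.ndarray, loci_idx: tuple[int, ...]) -> np.ndarray:
    code = np.zeros(genotypes.shape[0], dtype=np.int64)
    for i in loci_idx:
        code = code * 3 + genotypes[:, i]
    return code


def _label_arrays(
    case_counts: np.ndarray, ctrl_counts: np.ndarray, n_case: int, n_ctrl: int
) -> np.ndarray:
    """Per-cell labels: 1 = high risk, 0 = low risk, -1 = empty.

    A non-empty cell is high-risk iff cases/controls >= T = n_case/n_ctrl
    (cells with zero controls but some cases are high-risk); ratio exactly
    at T counts as high-risk.
    """
    tot = case_counts + ctrl_counts
    high = case_counts * n_ctrl >= ctrl_counts * n_case
    labels = np.where(high, 1, 0)
    labels[tot == 0] = -1
    return labels


def label_cells(
    study: GenotypeStudy, loci: tuple[str, ...]
) -> tuple[dict[tuple[int, ...], str], float]:
    """Label every 3^k genotype cell of a k-locus model on the full study.

    Returns the cell -> {high_risk, low_risk, empty} map and the overall
    case:control ratio threshold T.
    """
    study.require_both_groups()
    k = len(loci)
    idx = tuple(study.snp_index(s) for s in loci)
    g = study.genotypes[:, idx]
    if np.any(g == MISSING):
        raise ValueError("label_cells requires an imputed (missing-free) study")
    codes = _cell_codes(study.genotypes, idx)
    yb = study.case_mask
    n_cells = 3**k
    case_counts = np.bincount(codes[yb], minlength=n_cells).astype(float)
    ctrl_counts = np.bincount(codes[~yb], minlength=n_cells).astype(float)
    n_case, n_ctrl = int(yb.sum()), int((~yb).sum())
    labels = _label_arrays(case_counts, ctrl_counts, n_case, n_ctrl)
    name = {1: HIGH, 0: LOW, -1: EMPTY}
    cell_map = {
        cell: name[labels[i]]
        for i, cell in enumerate(product((0, 1, 2), repeat=k))
    }
    return cell_map, n_case / n_ctrl


def balanced_accuracy(
    cell_labels: dict[tuple[int, ...], str],
    study: GenotypeStudy,
    loci: tuple[str, ...],
) -> float:
    """(sensitivity + specificity) / 2 of the high/low-risk classifier.

    Subjects falling in cells labelled ``empty`` (unseen during labelling)
    are excluded from the evaluation.
    """
    idx = tuple(study.snp_index(s) for s in loci)
    yb = study.case_mask
    tp = fn = tn = fp = 0
    for i in range(study.n_subjects):
        cell = tuple(int(v) for v in study.genotypes[i, idx])
        lab = cell_labels.get(cell, EMPTY)
        if lab == EMPTY:
            continue
        if yb[i]:
            tp += lab == HIGH
            fn += lab == LOW
        else:
            tn += lab == LOW
            fp += lab == HIGH
    if tp + fn + tn + fp == 0:
        raise ValueError("no evaluable subjects (all cells empty/unseen)")
    sens = tp / (tp + fn) if tp + fn else 0.5
    spec = tn / (tn + fp) if tn + fp else 0.5
    return (sens + spec) / 2.0


# -------------------------------------------------------------------- models


@dataclass
class MdrModel:
    """One k-locus MDR model with its CV and permutation statistics."""

    loci: tuple[str, ...]
    cell_labels: dict[tuple[int, ...], str]
    threshold_T: float
    train_ba: float
    test_ba: float
    cvc: int
    p_perm: float = float("nan")
    high_risk_combination: GenotypeCombination | None = None
    odds_ratio: float = float("nan")
    or_ci: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def k(self) -> int:
        return len(self.loci)


def distill_combination(
    loci: tuple[str, ...], cell_labels: dict[tuple[int, ...], str]
) -> GenotypeCombination:
    """Compact carrier condition from a model's high-risk cells.

    When the high-risk region factors into per-locus genotype sets — each an
    exact genotype, a minor-allele carrier set {1,2}, a major-allele carrier
    set {0,1}, or any genotype — the combination is emitted in compact
    per-locus form; otherwise the explicit cell list is kept.
    """
    high_cells = frozenset(c for c, lab in cell_labels.items() if lab == HIGH)
    if not high_cells:
        raise ValueError("model has no high-risk cells")
    per_locus = [frozenset(cell[d] for cell in high_cells) for d in range(len(loci))]
    rectangular = set(product(*[sorted(s) for s in per_locus])) == set(high_cells)
    compact_ok = rectangular and all(
        len(s) == 1 or s in (CARRIER_MINOR, CARRIER_MAJOR, ANY_GENOTYPE)
        for s in per_locus
    )
    if compact_ok:
        comb = GenotypeCombination(
            loci=tuple(zip(loci, per_locus)), cells=None
        )
    else:
        comb = GenotypeCombination(
            loci=tuple((s, ANY_GENOTYPE) for s in loci), cells=high_cells
        )
    return GenotypeCombination(loci=comb.loci, label=comb.default_label(), cells=comb.cells)


def combination_odds_ratio(
    study: GenotypeStudy, combination: GenotypeCombination
) -> tuple[float, tuple[float, float]]:
    """Carrier-vs-phenotype odds ratio with a Woolf log-scale 95% CI.

    OR is the cross-product ratio of the carrier/noncarrier x case/control
    2x2 table (identical to the univariate logistic estimate). A Haldane
    0.5 continuity correction is applied, and logged, when any cell is
    empty. Subjects undecidable at the combination loci are excluded.
    """
    match, decidable = combination.evaluate(study)
    if not decidable.any():
        raise ValueError("combination undecidable for every subject")
    yb = study.case_mask
    m, y = match[decidable], yb[decidable]
    a = float(np.sum(m & y))  # carrier cases
    b = float(np.sum(m & ~y))  # carrier controls
    c = float(np.sum(~m & y))
    d = float(np.sum(~m & ~y))
    if min(a, b, c, d) == 0:
        logger.info(
            "zero cell in carrier table for %s; Haldane 0.5 correction applied",
            combination.label or combination.default_label(),
        )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(or_) - 1.959963984540054 * se))
    hi = float(np.exp(np.log(or_) + 1.959963984540054 * se))
    return float(or_), (lo, hi)


# ------------------------------------------------------------ search engine


def _stratified_folds(yb: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Seeded fold assignment preserving the case:control ratio per fold."""
    folds = np.empty(len(yb), dtype=np.int64)
    for group in (np.where(yb)[0], np.where(~yb)[0]):
        perm = rng.permutation(group)
        folds[perm] = np.arange(len(perm)) % n_folds
    return folds


class _MdrSearch:
    """Vectorized exhaustive k-subset search under a fixed fold split.

    Precomputes per-fold flattened cell-code offsets once; a full search
    under any phenotype vector (observed or permuted) then costs a few
    bincounts per fold, which keeps 1000-permutation runs desk-tractable.
    """

    def __init__(
        self,
        genotypes: np.ndarray,
        subsets: list[tuple[int, ...]],
        folds: np.ndarray,
        n_folds: int,
    ) -> None:
        self.subsets = subsets
        self.n_folds = n_folds
        self.k = len(subsets[0])
        self.cells = 3**self.k
        p = len(subsets)
        n = genotypes.shape[0]
        codes = np.empty((n, p), dtype=np.int16)
        for col, sub in enumerate(subsets):
            codes[:, col] = _cell_codes(genotypes, sub).astype(np.int16)
        self.codes = codes
        base = (self.cells * np.arange(p, dtype=np.int64))[None, :]
        self.train_idx = [np.where(folds != f)[0] for f in range(n_folds)]
        self.test_idx = [np.where(folds == f)[0] for f in range(n_folds)]
        self.train_off = [
            (codes[idx].astype(np.int64) + base).ravel() for idx in self.train_idx
        ]
        self.tot_train = [
            np.bincount(off, minlength=self.cells * p).reshape(p, self.cells)
            for off in self.train_off
        ]

    def _fold_counts(self, yb: np.ndarray, f: int) -> tuple[np.ndarray, np.ndarray]:
        p = len(self.subsets)
        w = np.repeat(yb[self.train_idx[f]].astype(float), p)
        case = np.bincount(
            self.train_off[f], weights=w, minlength=self.cells * p
        ).reshape(p, self.cells)
        return case, self.tot_train[f] - case

    def _test_ba(
        self, yb: np.ndarray, f: int, col: int, high: np.ndarray, seen: np.ndarray
    ) -> float:
        codes = self.codes[self.test_idx[f], col]
        y = yb[self.test_idx[f]]
        case = np.bincount(codes[y], minlength=self.cells).astype(float)
        ctrl = np.bincount(codes[~y], minlength=self.cells).astype(float)
        tp = float(case[seen & high].sum())
        fn = float(case[seen & ~high].sum())
        tn = float(ctrl[seen & ~high].sum())
        fp = float(ctrl[seen & high].sum())
        sens = tp / (tp + fn) if tp + fn else 0.5
        spec = tn / (tn + fp) if tn + fp else 0.5
        return (sens + spec) / 2.0

    def search(self, yb: np.ndarray) -> dict:
        """Full CV search under phenotype ``yb``; returns winners and stats."""
        p = len(self.subsets)
        fold_winner = np.empty(self.n_folds, dtype=np.int64)
        winner_train_ba = np.empty(self.n_folds)
        fold_high: list[np.ndarray] = []
        fold_seen: list[np.ndarray] = []
        fold_case_ctrl: list[tuple[np.ndarray, np.ndarray]] = []
        for f in range(self.n_folds):
            case, ctrl = self._fold_counts(yb, f)
            n_case = float(yb[self.train_idx[f]].sum())
            n_ctrl = float(len(self.train_idx[f]) - n_case)
            if n_case == 0 or n_ctrl == 0:
                raise ValueError("a training fold lost one phenotype class")
            nonempty = (case + ctrl) > 0
            high = (case * n_ctrl >= ctrl * n_case) & nonempty
            tp = (case * high).sum(axis=1)
            tn = (ctrl * (nonempty & ~high)).sum(axis=1)
            ba = (tp / n_case + tn / n_ctrl) / 2.0
            w = int(np.argmax(ba))  # first index wins ties (stable pair order)
            fold_winner[f] = w
            winner_train_ba[f] = ba[w]
            fold_high.append(high)
            fold_seen.append(nonempty)
            fold_case_ctrl.append((case, ctrl))

        candidates = sorted(set(int(w) for w in fold_winner))
        stats = []
        for col in candidates:
            cvc = int(np.sum(fold_winner == col))
            test_scores = [
                self._test_ba(yb, f, col, fold_high[f][col], fold_seen[f][col])
                for f in range(self.n_folds)
            ]
            train_scores = []
            for f in range(self.n_folds):
                case, ctrl = fold_case_ctrl[f]
                n_case = float(yb[self.train_idx[f]].sum())
                n_ctrl = float(len(self.train_idx[f]) - n_case)
                high = fold_high[f][col]
                seen = fold_seen[f][col]
                tp = float(case[col][seen & high].sum())
                tn = float(ctrl[col][seen & ~high].sum())
                train_scores.append((tp / n_case + tn / n_ctrl) / 2.0)
            stats.append(
                {
                    "col": col,
                    "cvc": cvc,
                    "mean_test_ba": float(np.mean(test_scores)),
                    "mean_train_ba": float(np.mean(train_scores)),
                }
            )
        stats.sort(key=lambda s: (-s["cvc"], -s["mean_test_ba"], s["col"]))
        return {"fold_winner": fold_winner, "ranked": stats}


def run_mdr(
    study: GenotypeStudy,
    k: int = 2,
    n_folds: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    candidate_loci: list[str] | None = None,
    max_snps_for_triples: int = 150,
    min_cvc: int = 2,
    with_or: bool = True,
) -> list[MdrModel]:
    """Exhaustive k-locus MDR with 10-fold CV and permutation significance.

    Returns models ranked by CVC (ties broken by mean testing balanced
    accuracy), filtered to CVC >= ``min_cvc`` and full-data training
    balanced accuracy > 0.5. The permutation p-value (computed for the
    top-ranked model only; ``n_perm = 0`` skips it) compares the observed
    mean testing balanced accuracy with its distribution under full
    search reruns on shuffled phenotypes.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    study.require_both_groups()
    if np.any(study.genotypes == MISSING):
        logger.info("study contains missing genotypes; applying modal imputation")
        study = impute_missing(study)
    snp_pool = candidate_loci if candidate_loci is not None else study.snp_ids
    idx_pool = [study.snp_index(s) for s in snp_pool]
    if k == 3 and candidate_loci is None and len(idx_pool) > max_snps_for_triples:
        raise ValueError(
            f"exhaustive 3-locus search over {len(idx_pool)} SNPs is not "
            f"desk-tractable; pass candidate_loci or a panel of at most "
            f"{max_snps_for_triples} SNPs"
        )
    subsets = list(combinations(idx_pool, k))
    if not subsets:
        raise ValueError("candidate pool smaller than k")
    if 3**k > study.n_subjects:
        logger.warning(
            "3^%d cells exceed %d subjects; contingency tables will be sparse",
            k,
            study.n_subjects,
        )

    yb = study.case_mask
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(yb, n_folds, rng)
    engine = _MdrSearch(study.genotypes, subsets, folds, n_folds)
    result = engine.search(yb)

    models: list[MdrModel] = []
    for rank, stat in enumerate(result["ranked"]):
        loci = tuple(study.snp_ids[i] for i in subsets[stat["col"]])
        cell_map, threshold = label_cells(study, loci)
        full_train_ba = balanced_accuracy(cell_map, study, loci)
        model = MdrModel(
            loci=loci,
            cell_labels=cell_map,
            threshold_T=threshold,
            train_ba=full_train_ba,
            test_ba=stat["mean_test_ba"],
            cvc=stat["cvc"],
        )
        try:
            model.high_risk_combination = distill_combination(loci, cell_map)
            if with_or:
                model.odds_ratio, model.or_ci = combination_odds_ratio(
                    study, model.high_risk_combination
                )
        except ValueError as exc:
            logger.warning("no carrier combination for %s: %s", loci, exc)
        models.append(model)

    if n_perm and models:
        observed = result["ranked"][0]["mean_test_ba"]
        b = 0
        for _ in range(n_perm):
            y_perm = rng.permutation(yb)
            null = engine.search(y_perm)
            if null["ranked"][0]["mean_test_ba"] >= observed - 1e-12:
                b += 1
        models[0].p_perm = (b + 1) / (n_perm + 1)

    reported = [m for m in models if m.cvc >= min_cvc and m.train_ba > 0.5]
    if not reported and models:
        logger.info(
            "no model meets cvc >= %d and train BA > 0.5; returning best anyway",
            min_cvc,
        )
        reported = models[:1]
    return reported


def models_to_table(models: list[MdrModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "loci": ["/".join(m.loci) for m in models],
            "high_risk_combination": [
                m.high_risk_combination.label if m.high_risk_combination else ""
                for m in models
            ],
            "odds_ratio": [m.odds_ratio for m in models],
            "or_ci_low": [m.or_ci[0] for m in models],
            "or_ci_high": [m.or_ci[1] for m in models],
            "p_perm": [m.p_perm for m in models],
            "cvc": [m.cvc for m in models],
            "train_ba": [m.train_ba for m in models],
            "test_ba": [m.test_ba for m in models],
        }
    )


# ------------------------------------------------------------ entropy graph


@dataclass
class EntropyGraph:
    """Per-SNP and per-pair information as percentages of phenotype entropy."""

    loci: tuple[str, ...]
    main_effect_pct: dict[str, float]
    pairwise_ig_pct: dict[tuple[str, str], float]
    linkage_matrix: np.ndarray

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def render(node) -> str:
            if node.is_leaf():
                return self.loci[node.id]
            left, right = render(node.left), render(node.right)
            return f"({left}:{node.dist:.6g},{right}:{node.dist:.6g})"

        return render(tree) + ";"

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp1": [a for a, _ in self.pairwise_ig_pct],
                "snp2": [b for _, b in self.pairwise_ig_pct],
                "ig_pct": list(self.pairwise_ig_pct.values()),
            }
        )


def entropy_graph(study: GenotypeStudy, loci: tuple[str, ...]) -> EntropyGraph:
    """Entropy-based interaction graph statistics for a set of loci.

    Main effects are 100 * I(SNP; phenotype) / H(phenotype); connections are
    100 * Syn / H(phenotype), negative values indicating redundancy. The
    dendrogram groups loci by average linkage on the distance
    max|syn| - |syn|: strongly interacting pairs join first whether the
    interaction is synergistic or redundant (the usual MDR dendrogram
    convention, where redundant markers also cluster tightly).
    """
    if len(loci) < 2:
        raise ValueError("entropy graph needs at least 2 loci")
    yb = study.case_mask
    h_y = entropy(np.bincount(yb.astype(int), minlength=2))
    main = {
        s: 100.0 * information_gain(study.column(s), study.phenotype) / h_y
        for s in loci
    }
    pair_pct: dict[tuple[str, str], float] = {}
    syn_vals: dict[tuple[str, str], float] = {}
    for a, b in combinations(loci, 2):
        d = synergy(study.column(a), study.column(b), study.phenotype, min_complete=2)
        pair_pct[(a, b)] = 100.0 * d.syn / h_y
        syn_vals[(a, b)] = d.syn
    max_mag = max(abs(s) for s in syn_vals.values())
    m = len(loci)
    dist = np.zeros((m, m))
    for (a, b), s in syn_vals.items():
        i, j = loci.index(a), loci.index(b)
        dist[i, j] = dist[j, i] = max_mag - abs(s)
    condensed = dist[np.triu_indices(m, k=1)]
    lm = linkage(condensed, method="average")
    return EntropyGraph(
        loci=tuple(loci),
        main_effect_pct=main,
        pairwise_ig_pct=pair_pct,
        linkage_matrix=lm,
    )
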