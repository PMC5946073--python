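from itertools import product

import numpy as np
import pytest

from episyn.core_data import CARRIER_MINOR, MISSING, GenotypeCombination, GenotypeStudy
from episyn.mdr import (
    EMPTY,
    HIGH,
    LOW,
    balanced_accuracy,
    combination_odds_ratio,
    distill_combination,
    entropy_graph,
    impute_missing,
    label_cells,
    run_mdr,
)
from episyn.synthetic_data import (
    PenetranceEffect,
    SimConfig,
    simulate_study,
    xor_penetrance,
)


def _study(g, phenotype, **kw):
    g = np.asarray(g, dtype=np.int8)
    n = g.shape[0]
    return GenotypeStudy(
        subject_ids=[f"s{i}" for i in range(n)],
        phenotype=np.array(phenotype, dtype=object),
        sex=np.array(["unknown"] * n, dtype=object),
        genotypes=g,
        snp_ids=[f"rs{j}" for j in range(g.shape[1])],
        **kw,
    )


class TestImputeMissing:
    def test_mode_fills_missing(self):
        s = _study(
            [[0], [0], [1], [MISSING]], ["case", "case", "control", "control"]
        )
        out = impute_missing(s)
        assert out.genotypes[3, 0] == 0

    def test_tie_breaks_to_lower_code(self):
        s = _study(
            [[0], [0], [2], [2], [MISSING]],
            ["case", "case", "control", "control", "case"],
        )
        assert impute_missing(s).genotypes[4, 0] == 0

    def test_fully_observed_study_unchanged(self, tiny_study):
        filled = impute_missing(tiny_study)
        out = impute_missing(filled)
        assert np.array_equal(out.genotypes, filled.genotypes)


class TestLabelCells:
    def test_case_only_cell_is_high_risk(self):
        g = [[0, 0]] * 4 + [[2, 2]] * 4
        phen = ["case"] * 4 + ["control"] * 4
        labels, T = label_cells(_study(g, phen), ("rs0", "rs1"))
        assert labels[(0, 0)] == HIGH
        assert labels[(2, 2)] == LOW
        assert labels[(1, 1)] == EMPTY
        assert T == 1.0

    def test_ratio_equal_to_threshold_is_high_risk(self):
        # balanced study; one cell with 10 cases and 10 controls: ratio == T
        g = [[0, 0]] * 20 + [[1, 1]] * 10
        phen = ["case"] * 10 + ["control"] * 10 + ["case"] * 5 + ["control"] * 5
        labels, _ = label_cells(_study(g, phen), ("rs0", "rs1"))
        assert labels[(0, 0)] == HIGH
        assert labels[(1, 1)] == HIGH

    def test_hand_built_table_matches_manual_labels(self):
        # cases per cell / controls per cell chosen by hand; T = 12/12 = 1
        cells = {
            (0, 0): (3, 1),  # high
            (0, 1): (1, 3),  # low
            (1, 0): (2, 2),  # high (ratio == T)
            (1, 1): (0, 4),  # low
            (2, 0): (4, 0),  # high (no controls)
            (2, 2): (2, 2),  # high
        }
        rows, phen = [], []
        for (a, b), (nc, nk) in cells.items():
            rows += [[a, b]] * (nc + nk)
            phen += ["case"] * nc + ["control"] * nk
        labels, _ = label_cells(_study(rows, phen), ("rs0", "rs1"))
        assert labels[(0, 0)] == HIGH
        assert labels[(0, 1)] == LOW
        assert labels[(1, 0)] == HIGH
        assert labels[(1, 1)] == LOW
        assert labels[(2, 0)] == HIGH
        assert labels[(2, 2)] == HIGH
        assert labels[(2, 1)] == EMPTY

    def test_subject_order_invariance_and_count_conservation(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(60, 2))
        phen = ["case"] * 30 + ["control"] * 30
        s1 = _study(g, phen)
        labels1, _ = label_cells(s1, ("rs0", "rs1"))
        perm = rng.permutation(60)
        s2 = _study(g[perm], [phen[i] for i in perm])
        labels2, _ = label_cells(s2, ("rs0", "rs1"))
        assert labels1 == labels2


class TestBalancedAccuracy:
    def test_perfect_separation_scores_one(self):
        g = [[0, 0]] * 5 + [[2, 2]] * 5
        phen = ["case"] * 5 + ["control"] * 5
        s = _study(g, phen)
        labels, _ = label_cells(s, ("rs0", "rs1"))
        assert balanced_accuracy(labels, s, ("rs0", "rs1")) == 1.0

    def test_all_high_risk_scores_half(self):
        g = [[0, 0]] * 10
        phen = ["case"] * 5 + ["control"] * 5
        s = _study(g, phen)
        labels = {c: HIGH for c in product((0, 1, 2), repeat=2)}
        assert balanced_accuracy(labels, s, ("rs0", "rs1")) == 0.5

    def test_random_phenotype_self_evaluation_near_half(self):
        # training-resubstitution BA on a null phenotype: 0.5 + small optimism
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = rng.integers(0, 3, size=(400, 2))
            phen = np.where(rng.random(400) < 0.5, "case", "control")
            s = _study(g, list(phen))
            labels, _ = label_cells(s, ("rs0", "rs1"))
            vals.append(balanced_accuracy(labels, s, ("rs0", "rs1")))
        mean = float(np.mean(vals))
        assert 0.5 <= mean < 0.57

    def test_ratio_labeling_maximizes_training_ba(self):
        # brute force over all 2^9 labelings of a 3x3 table: the case:control
        # ratio rule attains the maximal training balanced accuracy
        rng = np.random.default_rng(3)
        for _ in range(5):
            g = rng.integers(0, 3, size=(80, 2))
            phen = ["case"] * 40 + ["control"] * 40
            s = _study(g, phen)
            labels, _ = label_cells(s, ("rs0", "rs1"))
            observed_cells = [c for c, l in labels.items() if l != EMPTY]
            best = balanced_accuracy(labels, s, ("rs0", "rs1"))
            for bits in product((HIGH, LOW), repeat=len(observed_cells)):
                trial = dict(zip(observed_cells, bits))
                ba = balanced_accuracy(trial, s, ("rs0", "rs1"))
                assert ba <= best + 1e-12


class TestRunMdr:
    def test_planted_pair_recovered_with_high_cvc(self, planted_study):
        study, ann, truth = planted_study
        models = run_mdr(study, k=2, n_perm=0, seed=1)
        top = models[0]
        assert tuple(sorted(top.loci)) == truth.planted_pairs()[0]
        assert top.cvc >= 8
        assert top.train_ba > 0.5

    def test_degenerate_candidate_list_returns_that_model(self, planted_study):
        study, _, _ = planted_study
        loci = (study.snp_ids[2], study.snp_ids[5])
        models = run_mdr(study, k=2, n_perm=0, seed=0, candidate_loci=list(loci))
        assert len(models) == 1
        assert models[0].loci == loci
        assert models[0].cvc == 10  # single candidate wins every fold

    def test_same_seed_is_bit_reproducible(self, planted_study):
        study, _, _ = planted_study
        m1 = run_mdr(study, k=2, n_perm=100, seed=9)
        m2 = run_mdr(study, k=2, n_perm=100, seed=9)
        assert [m.loci for m in m1] == [m.loci for m in m2]
        assert m1[0].p_perm == m2[0].p_perm
        assert m1[0].test_ba == m2[0].test_ba

    def test_k_outside_range_rejected(self, planted_study):
        study, _, _ = planted_study
        with pytest.raises(ValueError):
            run_mdr(study, k=4)

    def test_three_locus_search_gated_on_panel_size(self, planted_study):
        study, _, _ = planted_study
        with pytest.raises(ValueError, match="candidate_loci"):
            run_mdr(study, k=3, max_snps_for_triples=10)

    def test_three_locus_on_candidates(self, planted_study):
        study, _, truth = planted_study
        pair = truth.planted_pairs()[0]
        cands = list(pair) + [study.snp_ids[10], study.snp_ids[11]]
        models = run_mdr(study, k=3, n_perm=0, seed=2, candidate_loci=cands)
        assert models and set(pair) <= set(models[0].loci)


class TestPermutationCalibration:
    def test_null_rejection_rate_near_alpha(self):
        # type-I error of the MDR permutation test at alpha = 0.05
        rejections = 0
        n_runs = 15
        for seed in range(n_runs):
            cfg = SimConfig(
                n_cases=100,
                n_controls=100,
                panel=(("IIS", 8),),
                missing_rate=0.0,
                seed=1000 + seed,
            )
            study, _, _ = simulate_study(cfg)
            models = run_mdr(study, k=2, n_perm=100, seed=seed, min_cvc=0)
            rejections += models[0].p_perm <= 0.05
        # binomial(15, 0.05): P(X >= 5) < 0.001
        assert rejections <= 4


class TestCombinationOddsRatio:
    def test_closed_form_table(self):
        # carriers: 30 cases / 10 controls; noncarriers: 10 / 30 -> OR = 9
        g = (
            [[2]] * 30 + [[0]] * 10  # cases
            + [[2]] * 10 + [[0]] * 30  # controls
        )
        phen = ["case"] * 40 + ["control"] * 40
        s = _study(g, phen)
        comb = GenotypeCombination(loci=(("rs0", frozenset({2})),), label="hom")
        or_, (lo, hi) = combination_odds_ratio(s, comb)
        assert or_ == pytest.approx(9.0)
        se = np.sqrt(1 / 30 + 1 / 10 + 1 / 10 + 1 / 30)
        assert lo == pytest.approx(9.0 * np.exp(-1.959963984540054 * se))
        assert hi == pytest.approx(9.0 * np.exp(1.959963984540054 * se))

    def test_independent_carrier_status_gives_unit_or(self):
        g = ([[2]] * 20 + [[0]] * 20) * 2
        phen = ["case"] * 40 + ["control"] * 40
        s = _study(g, phen)
        comb = GenotypeCombination(loci=(("rs0", frozenset({2})),))
        or_, _ = combination_odds_ratio(s, comb)
        assert or_ == pytest.approx(1.0)

    def test_protective_or_coverage(self):
        # planted carrier OR 0.6: the Woolf CI covers it in >= 93/100 seeds
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 2000
            carrier = rng.random(n) < 0.4
            p_case = np.where(carrier, 0.6 * 0.5 / (0.6 * 0.5 + 0.5), 0.5)
            case = rng.random(n) < p_case
            g = np.where(carrier, 2, 0).reshape(-1, 1)
            s = _study(g, ["case" if c else "control" for c in case])
            comb = GenotypeCombination(loci=(("rs0", frozenset({2})),))
            _, (lo, hi) = combination_odds_ratio(s, comb)
            covered += lo <= 0.6 <= hi
        assert covered >= 93


class TestDistillation:
    def test_rectangular_high_risk_region_is_compact(self):
        labels = {c: LOW for c in product((0, 1, 2), repeat=2)}
        for a in (2,):
            for b in (1, 2):
                labels[(a, b)] = HIGH
        comb = distill_combination(("rs1", "rs2"), labels)
        assert comb.cells is None
        assert dict(comb.loci) == {
            "rs1": frozenset({2}),
            "rs2": CARRIER_MINOR,
        }

    def test_checkerboard_region_falls_back_to_cells(self):
        labels = {
            c: (HIGH if sum(c) % 2 else LOW)
            for c in product((0, 1, 2), repeat=2)
        }
        comb = distill_combination(("rs1", "rs2"), labels)
        assert comb.cells is not None
        assert all(sum(c) % 2 for c in comb.cells)


class TestEntropyGraph:
    def test_duplicate_snps_show_redundancy_and_join_first(self):
        rng = np.random.default_rng(6)
        g0 = rng.integers(0, 3, size=300)
        phen = np.where(
            rng.random(300) < np.where(g0 == 2, 0.7, 0.4), "case", "control"
        )
        g = np.column_stack([g0, g0, rng.integers(0, 3, size=300)])
        s = _study(g, list(phen))
        eg = entropy_graph(s, ("rs0", "rs1", "rs2"))
        assert eg.pairwise_ig_pct[("rs0", "rs1")] < 0
        # the duplicate pair joins first: smallest distance in the linkage
        first_join = set(eg.linkage_matrix[0, :2].astype(int))
        assert first_join == {0, 1}
        newick = eg.to_newick()
        assert newick.count("rs") == 3 and newick.endswith(";")

    def test_deterministic_single_snp_explains_all_entropy(self):
        g0 = np.array([0] * 50 + [2] * 50)
        phen = ["case"] * 50 + ["control"] * 50
        g = np.column_stack([g0, np.tile([0, 1], 50)])
        s = _study(g, phen)
        eg = entropy_graph(s, ("rs0", "rs1"))
        assert eg.main_effect_pct["rs0"] == pytest.approx(100.0)
        assert eg.main_effect_pct["rs1"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_pair_has_largest_connection(self, planted_study):
        study, _, truth = planted_study
        pair = truth.planted_pairs()[0]
        loci = tuple(pair) + (study.snp_ids[12], study.snp_ids[13])
        eg = entropy_graph(study, loci)
        best = max(eg.pairwise_ig_pct, key=eg.pairwise_ig_pct.get)
        assert set(best) == set(pair)
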