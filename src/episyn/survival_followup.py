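"""Sex-stratified survival of carriers vs noncarriers in the oldest-old group.

Candidate genotype combinations from the case-control stages are followed
up in the long-lived (case) cohort only: subjects are classified as
carriers or noncarriers, and the two groups are compared by Kaplan-Meier
curves, the Mantel-Cox log-rank test, and a Cox proportional-hazards
hazard ratio for the carrier indicator. Time is months from recruitment;
follow-up is right-censored.

The Cox fit maximises the partial likelihood by Newton-Raphson with
Breslow tie handling by default (months-resolution times produce heavy
ties); Efron weighting is available by flag. Kaplan-Meier estimation and
the log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .core_data import MISSING, GenotypeCombination, GenotypeStudy
from .synergy_screen import benjamini_yekutieli

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054


@dataclass
class SurvivalResult:
    """Carrier-vs-noncarrier survival contrast for one combination/stratum."""

    combination: GenotypeCombination
    stratum: str  # male | female | all
    n: int
    n_carriers: int
    logrank_chi2: float
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]
    km_curves: dict[str, pd.DataFrame]  # group -> (time, at_risk, survival)
    significant: bool = False
    fdr_q: float = float("nan")


def classify_carriers(
    study: GenotypeStudy, combination: GenotypeCombination
) -> tuple[np.ndarray, np.ndarray]:
    """Carrier status over case-group subjects.

    Returns ``(carrier, included)``: boolean vectors over the **case**
    subjects, where ``included`` drops subjects with a missing genotype at
    any combination locus (the count is logged). Raises when the contrast
    is degenerate (all carriers or all noncarriers).
    """
    cases = study.subset_subjects(study.case_mask)
    match, decidable = combination.evaluate(cases)
    n_excluded = int((~decidable).sum())
    if n_excluded:
        logger.info(
            "%d case subjects undecidable at loci %s; excluded",
            n_excluded,
            "/".join(combination.snp_ids),
        )
    carrier = match[decidable]
    if carrier.all() or not carrier.any():
        raise ValueError(
            f"combination {combination.label or combination.default_label()!r} "
            "yields no carrier/noncarrier contrast"
        )
    return match, decidable


def _clean_times(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float).astype(int)
    if np.any(t < 0):
        raise ValueError("negative survival time")
    zero = t == 0
    if zero.any():
        logger.info("%d zero follow-up times offset to 0.5 months", int(zero.sum()))
        t = np.where(zero, 0.5, t)
    return t, e


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate as a (time, at_risk, survival) table."""
    t, e = _clean_times(times, events)
    if t.size == 0:
        raise ValueError("no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=float),
            "survival": surv.to_numpy(dtype=float),
        }
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group Mantel-Cox log-rank test: (chi-square, 1-df p-value)."""
    ta, ea = _clean_times(times_a, events_a)
    tb, eb = _clean_times(times_b, events_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_hr(
    times,
    events,
    carrier,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[float, tuple[float, float]]:
    """Cox proportional-hazards HR for a single binary covariate.

    Newton-Raphson on the partial log-likelihood with Breslow (default) or
    Efron tie handling; Wald 95% CI on the log scale. Raises on
    non-convergence or a monotone likelihood (complete separation of event
    times between groups).
    """
    t, e = _clean_times(times, events)
    x = np.asarray(carrier, dtype=float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("carrier indicator must be binary")
    if e.sum() == 0:
        raise ValueError("no events")
    event_times = np.unique(t[e == 1])
    # risk-set composition at each event time: n0/n1 at risk, d events, s carrier events
    n1_risk = np.array([np.sum((t >= u) & (x == 1)) for u in event_times], float)
    n0_risk = np.array([np.sum((t >= u) & (x == 0)) for u in event_times], float)
    d = np.array([np.sum((t == u) & (e == 1)) for u in event_times], float)
    s = np.array([np.sum((t == u) & (e == 1) & (x == 1)) for u in event_times], float)
    d1 = s  # carrier events per time (for Efron)

    if np.all(s == d) or np.all(s == 0):
        raise ValueError(
            "monotone partial likelihood: all events in one carrier group "
            "(complete separation); HR is not estimable"
        )

    beta = 0.0
    for _ in range(max_iter):
        eb = np.exp(beta)
        if ties == "breslow":
            s0 = n0_risk + n1_risk * eb
            s1 = n1_risk * eb
            mu = s1 / s0
            score = float(np.sum(s - d * mu))
            info = float(np.sum(d * mu * (1.0 - mu)))
        elif ties == "efron":
            score = 0.0
            info = 0.0
            for j in range(len(event_times)):
                dj = int(d[j])
                for r in range(dj):
                    frac = r / dj
                    s0 = (n0_risk[j] - frac * (dj - d1[j])) + (
                        n1_risk[j] - frac * d1[j]
                    ) * eb
                    s1 = (n1_risk[j] - frac * d1[j]) * eb
                    mu = s1 / s0
                    score += (s[j] / dj) - mu
                    info += mu * (1.0 - mu)
        else:
            raise ValueError(f"unknown tie handling {ties!r}")
        if info <= 0:
            raise ValueError("non-positive information; likelihood is flat")
        step = score / info
        beta += step
        if abs(step) < tol:
            break
    else:
        raise ValueError(f"Cox fit did not converge in {max_iter} iterations")
    se = 1.0 / np.sqrt(info)
    hr = float(np.exp(beta))
    return hr, (float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se)))


def survival_screen(
    study: GenotypeStudy,
    combinations: list[GenotypeCombination],
    strata: tuple[str, ...] = ("male", "female"),
    alpha: float = 0.05,
    by_correct: bool = False,
) -> list[SurvivalResult]:
    """Survival contrast for each combination x sex stratum among cases.

    Significance is flagged at ``alpha`` on the log-rank p-value with no
    multiplicity correction by default (an explicit warning is logged when
    more than one test is run); ``by_correct`` adds Benjamini-Yekutieli
    adjusted q-values across all tests performed.
    """
    if study.survival_months is None:
        raise ValueError("study carries no survival follow-up columns")
    results: list[SurvivalResult] = []
    for comb in combinations:
        for stratum in strata:
            cases = study.subset_subjects(study.case_mask)
            if stratum != "all":
                in_stratum = cases.sex == stratum
                if not in_stratum.any():
                    logger.warning("stratum %r has no subjects; skipped", stratum)
                    continue
                cases = cases.subset_subjects(in_stratum)
            sub = GenotypeStudy(
                subject_ids=list(cases.subject_ids),
                phenotype=cases.phenotype,
                sex=cases.sex,
                genotypes=cases.genotypes,
                snp_ids=list(cases.snp_ids),
                survival_months=cases.survival_months,
                event=cases.event,
            )
            match, decidable = comb.evaluate(sub)
            has_fu = ~np.isnan(sub.survival_months)
            use = decidable & has_fu
            carrier = match[use]
            t = sub.survival_months[use]
            e = sub.event[use]
            if carrier.all() or not carrier.any():
                logger.warning(
                    "no carrier contrast for %s in stratum %s; skipped",
                    comb.label or comb.default_label(),
                    stratum,
                )
                continue
            chi2, p = logrank_test(t[carrier], e[carrier], t[~carrier], e[~carrier])
            try:
                hr, ci = cox_hr(t, e, carrier)
            except ValueError as exc:
                logger.warning("Cox fit failed (%s); HR reported as NaN", exc)
                hr, ci = float("nan"), (float("nan"), float("nan"))
            km = {
                "carrier": kaplan_meier(t[carrier], e[carrier]),
                "noncarrier": kaplan_meier(t[~carrier], e[~carrier]),
            }
            results.append(
                SurvivalResult(
                    combination=comb,
                    stratum=stratum,
                    n=int(use.sum()),
                    n_carriers=int(carrier.sum()),
                    logrank_chi2=chi2,
                    logrank_p=p,
                    hr=hr,
                    hr_ci=ci,
                    km_curves=km,
                    significant=p < alpha,
                )
            )
    if len(results) > 1 and not by_correct:
        logger.warning(
            "%d survival tests run without multiplicity correction "
            "(pass by_correct=True for Benjamini-Yekutieli q-values)",
            len(results),
        )
    if by_correct and results:
        qs = benjamini_yekutieli([r.logrank_p for r in results])
        for r, q in zip(results, qs):
            r.fdr_q = float(q)
    return results


def results_to_table(results: list[SurvivalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "combination": [
                r.combination.label or r.combination.default_label() for r in results
            ],
            "stratum": [r.stratum for r in results],
            "n": [r.n for r in results],
            "n_carriers": [r.n_carriers for r in results],
            "logrank_chi2": [r.logrank_chi2 for r in results],
            "logrank_p": [r.logrank_p for r in results],
            "hr": [r.hr for r in results],
            "hr_ci_low": [r.hr_ci[0] for r in results],
            "hr_ci_high": [r.hr_ci[1] for r in results],
            "significant": [r.significant for r in results],
        }
    )


def km_curves_table(results: list[SurvivalResult]) -> pd.DataFrame:
    """Tidy (combination, stratum, group, time, at_risk, survival) KM export."""
    frames = []
    for r in results:
        for group, df in r.km_curves.items():
            d = df.copy()
            d.insert(0, "group", group)
            d.insert(0, "stratum", r.stratum)
            d.insert(
                0,
                "combination",
                r.combination.label or r.combination.default_label(),
            )
            frames.append(d)
    return (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["combination", "stratum", "group", "time", "at_risk", "survival"]
        )
    )
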