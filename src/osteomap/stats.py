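"""Cohort statistics: 2x2 tables, Woolf odds-ratio intervals, exact and
rank tests, and exploratory logistic regression.

The subtype–symptom associations are summarized as unadjusted odds ratios
from 2x2 tables that collapse the four-class subtype into "target class vs
others" (e.g. SOM-IIB vs others for brain edema, SOM-I vs others for
exophthalmos). Confidence intervals use the Woolf (logit) method:

    CI = exp( ln(ad/bc) +/- z * sqrt(1/a + 1/b + 1/c + 1/d) )

with z = 1.959964 for 95%. When any cell is zero the Haldane–Anscombe +0.5
correction is applied to all four cells and flagged. All comparisons here are
exploratory: no multiplicity adjustment is applied, matching the
complete-case, effect-size-oriented analysis plan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

Z_95 = 1.959964

#: |coefficient| beyond which a logistic term is flagged as quasi-separated
SEPARATION_COEF_THRESHOLD = 15.0
LOGIT_MAX_ITER = 100


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cells a/b/c/d: exposed&outcome+, exposed&outcome-, unexposed&outcome+,
    unexposed&outcome-. Exposure = membership in the target subtype group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class OddsRatioResult:
    or_point: float
    ci_low: float
    ci_high: float
    correction_applied: bool
    alpha: float = 0.05


def contingency_from_cohort(
    subtypes: Sequence[str],
    flags: Sequence[Optional[float]],
    target: str,
) -> ContingencyTable2x2:
    """Collapse subtypes into target-vs-others and tally against a 0/1 flag.

    Cases with a missing flag are dropped (complete-case) with a logged count.
    """
    if len(subtypes) != len(flags):
        raise ValueError(
            f"length mismatch: {len(subtypes)} subtypes vs {len(flags)} flags")
    if len(subtypes) == 0:
        raise ValueError("empty cohort")
    a = b = c = d = 0
    n_missing = 0
    for st, fl in zip(subtypes, flags):
        if fl is None or (isinstance(fl, float) and math.isnan(fl)):
            n_missing += 1
            continue
        exposed = st == target
        positive = bool(int(fl))
        if exposed and positive:
            a += 1
        elif exposed:
            b += 1
        elif positive:
            c += 1
        else:
            d += 1
    if n_missing:
        logger.info("contingency_from_cohort: %d cases dropped for missing flag",
                    n_missing)
    return ContingencyTable2x2(a, b, c, d)


def odds_ratio_woolf(t: ContingencyTable2x2, alpha: float = 0.05) -> OddsRatioResult:
    """Odds ratio ad/bc with the Woolf (logit) confidence interval."""
    if t.total == 0:
        raise ValueError("all-zero contingency table")
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
        logger.info("Haldane–Anscombe +0.5 correction applied to %s", t)
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2) if alpha != 0.05 else Z_95
    lo = math.exp(math.log(or_point) - z * se)
    hi = math.exp(math.log(or_point) + z * se)
    return OddsRatioResult(or_point=or_point, ci_low=lo, ci_high=hi,
                           correction_applied=corrected, alpha=alpha)


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities of all
    tables with the same margins whose point probability is <= observed).

    A zero margin makes every table certain; p = 1.0 by convention, logged.
    """
    margins = (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)
    if 0 in margins:
        logger.info("fisher_exact_2x2: degenerate margin in %s; p = 1.0", t)
        return 1.0
    _, p = sps.fisher_exact(t.as_array(), alternative="two-sided")
    return float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (mid-rank ties, standard tie correction) and the
    chi-square p with (k-1) degrees of freedom."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if flat.size < 3:
        raise ValueError("need total n >= 3")
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def log1_volume(v: float) -> float:
    """log(volume + 1): right-skew-taming transform that keeps 0 defined."""
    if v < 0:
        raise ValueError(f"volume must be >= 0, got {v}")
    return math.log1p(v)


@dataclass(frozen=True)
class DescriptiveSummary:
    mean: float
    sd: float
    median: float
    iqr: tuple[float, float]
    n: int
    sd_degenerate: bool = False


def describe(values: Sequence[float]) -> DescriptiveSummary:
    """Mean, sample SD (n-1), median, and [25th, 75th] percentile IQR."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("describe needs a non-empty input")
    degenerate = arr.size == 1
    sd = 0.0 if degenerate else float(np.std(arr, ddof=1))
    q25, q75 = np.percentile(arr, [25, 75])
    return DescriptiveSummary(
        mean=float(np.mean(arr)), sd=sd, median=float(np.median(arr)),
        iqr=(float(q25), float(q75)), n=int(arr.size), sd_degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# exploratory logistic regression


@dataclass(frozen=True)
class LogisticTerm:
    name: str
    coef: float
    se: float
    aor: float
    ci_low: float
    ci_high: float
    p: float
    separation_flag: bool


@dataclass(frozen=True)
class LogisticFit:
    terms: tuple[LogisticTerm, ...]
    converged: bool
    n: int

    def term(self, name: str) -> LogisticTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _safe_exp(x: float) -> float:
    """exp that saturates to inf instead of overflowing (separated fits)."""
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf


def logistic_fit(outcome: Sequence[int], design: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald intervals and
    per-term sparse-data / quasi-separation flags.

    ``design`` holds the covariates (an intercept column is added). Terms
    whose fitted |coefficient| exceeds ``SEPARATION_COEF_THRESHOLD``, or —
    for binary covariates — whose 2x2 margin against the outcome has an empty
    cell, are flagged as unstable rather than suppressed.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome is constant; logistic model is undefined")
    X = design.astype(float).copy()
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # find an offending column by dropping one at a time
        for col in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=col).to_numpy()) == rank:
                raise ValueError(f"design is rank deficient; column {col!r} is redundant")
        raise ValueError("design is rank deficient")
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    try:
        res = model.fit(disp=0, maxiter=LOGIT_MAX_ITER, method="newton")
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception:
        res = model.fit(disp=0, maxiter=LOGIT_MAX_ITER, method="bfgs")
        converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        logger.warning("logistic fit did not converge after %d iterations",
                       LOGIT_MAX_ITER)
    terms = []
    for name in Xc.columns:
        coef = float(res.params[name])
        se = float(res.bse[name])
        flag = abs(coef) > SEPARATION_COEF_THRESHOLD
        col = Xc[name]
        if name != "const" and set(np.unique(col)) <= {0.0, 1.0}:
            # empty cell in the covariate x outcome margin => sparse data
            tab = pd.crosstab(col, y)
            if tab.shape != (2, 2) or (tab.to_numpy() == 0).any():
                flag = True
        terms.append(LogisticTerm(
            name=str(name), coef=coef, se=se, aor=_safe_exp(coef),
            ci_low=_safe_exp(coef - Z_95 * se), ci_high=_safe_exp(coef + Z_95 * se),
            p=float(res.pvalues[name]), separation_flag=flag,
        ))
    return LogisticFit(terms=tuple(terms), converged=converged, n=int(y.size))


def woolf_coverage(
    true_or: float,
    n_exposed: int,
    n_unexposed: int,
    p_unexposed: float,
    n_replicates: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Monte-Carlo coverage of the Woolf interval at a known true odds ratio.

    Each replicate draws binomial outcome counts for the exposed group (whose
    event probability is set so the exposed/unexposed odds ratio equals
    ``true_or``) and the unexposed group, builds the 2x2 table, and checks
    whether the interval covers ``true_or``. Returns the covered fraction.
    """
    odds_u = p_unexposed / (1 - p_unexposed)
    odds_e = true_or * odds_u
    p_exposed = odds_e / (1 + odds_e)
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_replicates):
        a = int(rng.binomial(n_exposed, p_exposed))
        c = int(rng.binomial(n_unexposed, p_unexposed))
        t = ContingencyTable2x2(a, n_exposed - a, c, n_unexposed - c)
        res = odds_ratio_woolf(t, alpha=alpha)
        if res.ci_low <= true_or <= res.ci_high:
            covered += 1
    return covered / n_replicates


# ---------------------------------------------------------------------------
# predefined subtype-symptom association pairs

#: (symptom column, target subtype) analysed univariably and multivariably
PREDEFINED_PAIRS = [
    ("edema", "SOM-IIB"),
    ("seizure", "SOM-IIB"),
    ("icp", "SOM-IIB"),
    ("exophthalmos", "SOM-I"),
]


def univariable_or_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Woolf ORs for the predefined subtype-symptom pairs on a cohort table
    with columns subtype + symptom flags. Exploratory: no multiplicity
    adjustment."""
    rows = []
    for symptom, target in PREDEFINED_PAIRS:
        if symptom not in cohort.columns:
            logger.warning("symptom %r absent from cohort table; pair skipped", symptom)
            continue
        flags = cohort[symptom]
        if flags.isna().all():
            logger.warning("symptom %r all-missing; pair skipped", symptom)
            continue
        table = contingency_from_cohort(cohort["subtype"].tolist(),
                                        flags.tolist(), target)
        res = odds_ratio_woolf(table)
        p = fisher_exact_2x2(table)
        rows.append({
            "symptom": symptom, "target": target,
            "a": table.a, "b": table.b, "c": table.c, "d": table.d,
            "odds_ratio": res.or_point, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "fisher_p": p,
            "haldane_correction": res.correction_applied,
        })
    return pd.DataFrame(rows)
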