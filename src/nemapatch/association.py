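"""Grouped-binomial analysis of deviance, exact 2×k tests, rate correlation.

The colonization analyses compare, across the levels of a single factor
(substrate class, bait type, accessibility treatment), the fraction of
sampling units colonized by a target taxon. With grouped binomial data and a
single categorical factor, the one-probability-per-level model *is* the
saturated model, so the likelihood-ratio (analysis-of-deviance) statistic
has the closed form

    G = 2 * sum_l [ k_l ln(k_l/n_l) + (n_l-k_l) ln(1-k_l/n_l) ]
      - 2 * [ K ln(K/N) + (N-K) ln(1-K/N) ],

identical to the deviance difference of a logistic regression with dummy
coding for the factor, with p from the chi-square upper tail on k-1 degrees
of freedom. Terms with k = 0 or k = n contribute 0·ln 0 = 0.

An exact conditional test for 2×k tables (the k bait types × two colonizer
classes) enumerates all tables with the observed margins under the
multivariate hypergeometric null and sums the probabilities of tables no
more probable than the observed one (the probability-ordering two-sided
rule); a seeded Monte-Carlo fallback handles tables whose enumeration would
exceed a configurable budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, xlogy

from .incidence import EmptyInputError
from .records import (
    BaitRecord,
    BaitType,
    CollectionRecord,
    ExclosureRecord,
    ExclosureTreatment,
    SubstrateCategory,
    TREATMENT_ORDER,
    normalize_species_name,
)

__all__ = [
    "DevianceTable",
    "RateCorrelationResult",
    "binomial_lrt",
    "substrate_association",
    "bait_type_analysis",
    "bait_type_fisher",
    "fisher_exact_2xk",
    "rate_correlation",
    "accessibility_analysis",
]


@dataclass(frozen=True)
class DevianceTable:
    """One-factor grouped-binomial likelihood-ratio (analysis of deviance)."""

    factor_name: str
    levels: tuple[str, ...]
    successes: tuple[int, ...]
    trials: tuple[int, ...]
    null_deviance: float
    residual_deviance: float
    lrt_stat: float
    df: int
    p_value: float

    def rates(self) -> np.ndarray:
        return np.asarray(self.successes, float) / np.asarray(self.trials, float)

    def summary(self) -> str:
        lines = [
            f"Analysis of deviance: factor {self.factor_name!r}",
            "=" * 58,
            f"{'level':<24}{'colonized':>10}{'trials':>8}{'rate':>8}",
        ]
        for lev, k, n in zip(self.levels, self.successes, self.trials):
            lines.append(f"{lev:<24}{k:>10d}{n:>8d}{k / n:>8.3f}")
        lines += [
            "-" * 58,
            f"LRT chi-square = {self.lrt_stat:.4f}  df = {self.df}  "
            f"p = {self.p_value:.4g}",
            "(raw p-value; no multiple-testing correction applied)",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class RateCorrelationResult:
    """Cross-taxon per-level colonization-rate regression (OLS of y on x)."""

    group_labels: tuple[str, ...]
    x_rates: tuple[float, ...]
    y_rates: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def binomial_lrt(
    successes: Sequence[int],
    trials: Sequence[int],
    levels: Sequence[str] | None = None,
    factor_name: str = "factor",
) -> DevianceTable:
    """Likelihood-ratio test of equal binomial rates across factor levels.

    Null model: one shared success probability (pooled MLE). Alternative:
    one probability per level (the saturated one-factor model). Levels with
    zero trials are dropped with a warning and reduce df.
    """
    k = np.asarray(successes, dtype=float)
    n = np.asarray(trials, dtype=float)
    if k.shape != n.shape or k.ndim != 1:
        raise ValueError("successes and trials must be 1-D and equal length")
    if np.any(k < 0) or np.any(n < k):
        raise ValueError("need 0 <= successes <= trials per level")
    if levels is None:
        levels = [f"level_{i + 1}" for i in range(len(k))]
    levels = [str(l) for l in levels]
    keep = n > 0
    if not np.all(keep):
        dropped = [l for l, good in zip(levels, keep) if not good]
        warnings.warn(
            f"dropping level(s) with zero trials: {', '.join(dropped)}",
            stacklevel=2,
        )
        k, n = k[keep], n[keep]
        levels = [l for l, good in zip(levels, keep) if good]
    if len(k) < 2:
        raise ValueError("need at least 2 levels with trials")
    if n.sum() < 1:
        raise ValueError("need at least one trial in total")
    ll_alt = float(np.sum(xlogy(k, k / n) + xlogy(n - k, 1.0 - k / n)))
    K, N = k.sum(), n.sum()
    ll_null = float(xlogy(K, K / N) + xlogy(N - K, 1.0 - K / N))
    lrt = max(2.0 * (ll_alt - ll_null), 0.0)
    df = len(k) - 1
    p = float(stats.chi2.sf(lrt, df)) if lrt > 0 else 1.0
    return DevianceTable(
        factor_name=factor_name,
        levels=tuple(levels),
        successes=tuple(int(v) for v in k),
        trials=tuple(int(v) for v in n),
        null_deviance=lrt,
        residual_deviance=0.0,
        lrt_stat=lrt,
        df=df,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# Exact 2×k test
# ---------------------------------------------------------------------------

def _log_choose(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def _enumerate_logprobs(cols: np.ndarray, r1: int):
    """Log-probabilities of every first row consistent with the margins."""
    k = len(cols)
    log_denom = float(_log_choose(cols.sum(), r1))
    suffix = np.concatenate([np.cumsum(cols[::-1])[::-1][1:], [0]])
    out: list[tuple[tuple[int, ...], float]] = []

    def rec(j: int, remaining: int, logp: float, row: tuple[int, ...]):
        if j == k - 1:
            if 0 <= remaining <= cols[j]:
                out.append(
                    (row + (remaining,),
                     logp + float(_log_choose(cols[j], remaining)))
                )
            return
        lo = max(0, remaining - int(suffix[j]))
        hi = min(int(cols[j]), remaining)
        for a in range(lo, hi + 1):
            rec(j + 1, remaining - a,
                logp + float(_log_choose(cols[j], a)), row + (a,))

    rec(0, r1, -log_denom, ())
    return out


def _count_tables_upper_bound(cols: np.ndarray, r1: int) -> float:
    bound = 1.0
    for c in cols:
        bound *= min(int(c), r1) + 1
    return bound


def fisher_exact_2xk(
    table,
    *,
    max_tables: float = 500_000,
    n_mc: int = 200_000,
    seed: int | None = None,
) -> float:
    """Exact conditional two-sided p for a 2×k contingency table.

    Enumerates all tables with the observed margins; the p-value is the
    total null probability of tables whose probability does not exceed the
    observed table's (with a small relative tolerance for float ties). When
    the number of candidate tables exceeds ``max_tables``, falls back to
    ``n_mc`` seeded multivariate-hypergeometric draws with an add-one
    estimate (count+1)/(n_mc+1).
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.ndim != 2 or tab.shape[0] != 2 or tab.shape[1] < 2:
        raise ValueError("table must be 2 x k with k >= 2")
    if np.any(tab < 0):
        raise ValueError("table entries must be nonnegative integers")
    col_keep = tab.sum(axis=0) > 0
    if not np.all(col_keep):
        warnings.warn("dropping zero-total column(s)", stacklevel=2)
        tab = tab[:, col_keep]
    if tab.shape[1] < 2 or np.any(tab.sum(axis=1) == 0):
        # No free variation left: only one table is possible.
        return 1.0
    cols = tab.sum(axis=0)
    r1 = int(tab.sum(axis=1)[0])
    logp_obs = float(
        np.sum(_log_choose(cols, tab[0])) - _log_choose(cols.sum(), r1)
    )
    tol = 1e-9
    if _count_tables_upper_bound(cols, r1) <= max_tables:
        entries = _enumerate_logprobs(cols, r1)
        logs = np.array([lp for _, lp in entries])
        p = float(np.exp(logs[logs <= logp_obs + tol]).sum())
        return min(p, 1.0)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(cols, r1, size=int(n_mc))
    logs = (
        np.sum(_log_choose(cols[None, :], draws), axis=1)
        - float(_log_choose(cols.sum(), r1))
    )
    count = int(np.sum(logs <= logp_obs + tol))
    return (count + 1) / (int(n_mc) + 1)


def _enumerated_table_probs(cols: np.ndarray, r1: int) -> np.ndarray:
    """All conditional table probabilities for the given margins (testing aid)."""
    return np.exp([lp for _, lp in _enumerate_logprobs(np.asarray(cols), int(r1))])


# ---------------------------------------------------------------------------
# Record-level analyses
# ---------------------------------------------------------------------------

def _target_predicate_collection(target: str):
    if target == "any":
        return lambda rec: bool(rec.species_present)
    name = normalize_species_name(target)
    return lambda rec: name in rec.species_present


def substrate_association(
    records: Iterable[CollectionRecord],
    target: str = "any",
    classification: str = "coarse",
) -> DevianceTable:
    """Test association of a species (or any species) with substrate class.

    ``classification='coarse'`` contrasts fruit vs. other;
    ``'fine'`` uses the full substrate category.
    """
    recs = list(records)
    if not recs:
        raise EmptyInputError("no collection records")
    pred = _target_predicate_collection(target)
    if classification == "coarse":
        def level(rec):
            return (
                "fruit" if rec.substrate_category == SubstrateCategory.FRUIT
                else "other"
            )
    elif classification == "fine":
        def level(rec):
            return rec.substrate_category.value
    else:
        raise ValueError("classification must be 'coarse' or 'fine'")
    groups: dict[str, list[bool]] = {}
    for rec in recs:
        groups.setdefault(level(rec), []).append(pred(rec))
    if len(groups) < 2:
        raise ValueError(
            "all samples share one substrate class; no contrast to test"
        )
    levels = sorted(groups)
    successes = [sum(groups[l]) for l in levels]
    trials = [len(groups[l]) for l in levels]
    return binomial_lrt(successes, trials, levels,
                        factor_name=f"substrate ({classification})")


def _bait_outcome(target: str):
    if target == "any_nematode":
        return lambda rec: rec.nematodes_present
    if target == "any_caenorhabditis":
        return lambda rec: rec.caenorhabditis_present
    name = normalize_species_name(target)
    return lambda rec: name in rec.species_present


def bait_type_analysis(
    bait_records: Iterable[BaitRecord],
    target: str = "any_nematode",
) -> DevianceTable:
    """Analysis of deviance of colonization rate across the six bait types.

    Only recovered baits enter the analysis (lost baits have no outcome).
    ``target`` is ``'any_nematode'``, ``'any_caenorhabditis'``, or a species
    name.
    """
    recovered = [r for r in bait_records if r.recovered]
    if not recovered:
        raise EmptyInputError("no recovered baits")
    outcome = _bait_outcome(target)
    levels = [bt.value for bt in BaitType]
    successes, trials = [], []
    for bt in BaitType:
        grp = [r for r in recovered if r.bait_type == bt]
        trials.append(len(grp))
        successes.append(sum(outcome(r) for r in grp))
    return binomial_lrt(successes, trials, levels, factor_name="bait_type")


def bait_type_fisher(table, **kwargs) -> float:
    """Exact test that two colonizer classes share one bait-type distribution.

    ``table`` is 2×k: counts of baits per type in each class (e.g. row 1 =
    baits with Caenorhabditis, row 2 = baits colonized only by
    non-Caenorhabditis nematodes). Delegates to :func:`fisher_exact_2xk`.
    """
    return fisher_exact_2xk(table, **kwargs)


def rate_correlation(
    bait_records: Iterable[BaitRecord],
) -> RateCorrelationResult:
    """Regress Caenorhabditis on non-Caenorhabditis colonization rates.

    Per bait type (recovered baits only): y = fraction of baits with
    Caenorhabditis; x = fraction colonized *only* by non-Caenorhabditis
    nematodes (baits containing both are excluded from x, mirroring the
    "only" wording). Unweighted OLS of y on x across types; the p-value is
    the two-sided slope t-test with k-2 df.
    """
    recovered = [r for r in bait_records if r.recovered]
    labels, xs, ys = [], [], []
    for bt in BaitType:
        grp = [r for r in recovered if r.bait_type == bt]
        if not grp:
            continue
        n = len(grp)
        labels.append(bt.value)
        ys.append(sum(r.caenorhabditis_present for r in grp) / n)
        xs.append(
            sum(r.nematodes_present and not r.caenorhabditis_present
                for r in grp) / n
        )
    if len(labels) < 3:
        raise ValueError("need >= 3 bait types with recovered baits")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in non-Caenorhabditis rates")
    fit = stats.linregress(x, y)
    return RateCorrelationResult(
        group_labels=tuple(labels),
        x_rates=tuple(float(v) for v in x),
        y_rates=tuple(float(v) for v in y),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
    )


def accessibility_analysis(
    exclosure_records: Iterable[ExclosureRecord],
    target: str = "any_nematode",
) -> tuple[DevianceTable, pd.DataFrame]:
    """Analysis of deviance across the six accessibility treatments.

    Returns the deviance table plus a species × treatment incidence table
    (counts of recovered baits on which each species occurred), which makes
    qualitative accessibility limits visible — e.g. a taxon absent from all
    treatments less accessible than a given mesh size.
    """
    recovered = [r for r in exclosure_records if r.recovered]
    if not recovered:
        raise EmptyInputError("no recovered exclosure baits")
    outcome = _bait_outcome(target)
    levels = [t.value for t in TREATMENT_ORDER]
    successes, trials = [], []
    for tr in TREATMENT_ORDER:
        grp = [r for r in recovered if r.treatment == tr]
        trials.append(len(grp))
        successes.append(sum(outcome(r) for r in grp))
    dev = binomial_lrt(successes, trials, levels, factor_name="accessibility")
    species = sorted({s for r in recovered for s in r.species_present})
    counts = pd.DataFrame(
        0, index=pd.Index(species, name="species"), columns=levels, dtype=int
    )
    for r in recovered:
        for s in r.species_present:
            counts.loc[s, r.treatment.value] += 1
    return dev, counts
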