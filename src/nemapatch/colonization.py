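"""Zero-class Poisson colonization model and species co-occurrence tests.

If a species reaches habitat patches by a Poisson colonization process with
mean λ events per patch, the number of colonization events K on a patch is
Poisson(λ) and the fraction of *unoccupied* patches estimates exp(-λ). A
presence/absence survey therefore identifies λ through its zero class:

    λ_hat = -ln(1 - p_occ),    p_occ = n_occupied / n_patches.

From λ_hat follow the class probabilities P(K=0), P(K=1), P(K>=2) and the
quantity of ecological interest, the fraction of *occupied* patches founded
more than once, P(K>=2)/P(K>=1). The model assumes homogeneous λ across
patches; spatial heterogeneity (patchiness) inflates the zero class and
biases λ_hat downward, which the simulation utilities quantify.

The co-occurrence test asks whether two species land on the same patches
more or less often than independent colonization predicts: expected joint
count n·(a/n)·(b/n) and an exact conditional (Fisher) test on the 2×2
presence table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .association import fisher_exact_2xk
from .records import normalize_species_name

__all__ = [
    "SaturationError",
    "ColonizationEstimate",
    "CooccurrenceResult",
    "fit_zero_class",
    "cooccurrence_test",
    "cooccurrence_from_counts",
    "ZeroClassPoissonModel",
    "ZeroClassPoissonResults",
]


class SaturationError(ValueError):
    """All patches occupied: the zero-class estimate of λ is unbounded."""


@dataclass(frozen=True)
class ColonizationEstimate:
    """Zero-class Poisson fit of colonization number per patch."""

    n_patches: int
    n_occupied: int
    p_occ: float
    lambda_hat: float
    p_zero: float
    p_one: float
    p_two_plus: float
    frac_multiple_occupied: float
    ci_lambda_low: float
    ci_lambda_high: float
    conf_level: float = 0.95


@dataclass(frozen=True)
class CooccurrenceResult:
    """Pairwise species co-occurrence against the independence null."""

    n: int
    count_a: int
    count_b: int
    count_both: int
    expected_both: float
    fisher_p: float
    odds_ratio: float


def fit_zero_class(
    n_patches: int, n_occupied: int, conf_level: float = 0.95
) -> ColonizationEstimate:
    """Fit the zero-class Poisson colonization model to occupancy counts.

    The λ confidence interval transforms an exact Clopper–Pearson binomial
    interval on the occupancy fraction through λ = -ln(1 - p), which is
    monotone, so coverage is inherited exactly.
    """
    n = int(n_patches)
    k = int(n_occupied)
    if n < 1:
        raise ValueError("n_patches must be >= 1")
    if k < 0 or k > n:
        raise ValueError("need 0 <= n_occupied <= n_patches")
    if k == n:
        raise SaturationError(
            "all patches occupied: lambda is not identified from the zero class"
        )
    p_occ = k / n
    lam = -math.log1p(-p_occ)
    p_zero = math.exp(-lam)  # equals 1 - p_occ by construction
    p_one = lam * p_zero
    p_two_plus = 1.0 - p_zero - p_one
    frac_multiple = p_two_plus / p_occ if p_occ > 0 else 0.0
    alpha = 1.0 - conf_level
    p_low = float(stats.beta.ppf(alpha / 2, k, n - k + 1)) if k > 0 else 0.0
    p_high = float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return ColonizationEstimate(
        n_patches=n,
        n_occupied=k,
        p_occ=p_occ,
        lambda_hat=lam,
        p_zero=p_zero,
        p_one=p_one,
        p_two_plus=p_two_plus,
        frac_multiple_occupied=frac_multiple,
        ci_lambda_low=-math.log1p(-p_low),
        ci_lambda_high=-math.log1p(-p_high),
        conf_level=conf_level,
    )


def cooccurrence_from_counts(
    n: int, count_a: int, count_b: int, count_both: int
) -> CooccurrenceResult:
    """Co-occurrence test from a pair's marginal and joint presence counts."""
    n = int(n)
    if n < 1:
        raise ValueError("need n >= 1 samples")
    if count_both > min(count_a, count_b):
        raise ValueError("joint count exceeds a marginal count")
    if min(count_a, count_b, count_both) < 0 or max(count_a, count_b) > n:
        raise ValueError("counts must lie in 0..n")
    a_only = count_a - count_both
    b_only = count_b - count_both
    neither = n - count_a - count_b + count_both
    if neither < 0:
        raise ValueError("counts inconsistent with n")
    expected = n * (count_a / n) * (count_b / n)
    table = np.array([[count_both, a_only], [b_only, neither]])
    import warnings

    with warnings.catch_warnings():
        # a species absent from every (or present in every) sample leaves a
        # degenerate margin; the exact test correctly returns p = 1
        warnings.simplefilter("ignore", UserWarning)
        p = fisher_exact_2xk(table)
    if a_only * b_only > 0:
        odds = (count_both * neither) / (a_only * b_only)
    else:
        odds = math.inf if count_both * neither > 0 else math.nan
    return CooccurrenceResult(
        n=n,
        count_a=int(count_a),
        count_b=int(count_b),
        count_both=int(count_both),
        expected_both=float(expected),
        fisher_p=float(p),
        odds_ratio=float(odds),
    )


def cooccurrence_test(
    records: Iterable, species_a: str, species_b: str
) -> CooccurrenceResult:
    """Test independence of two species' presence across sampled patches."""
    a = normalize_species_name(species_a)
    b = normalize_species_name(species_b)
    if a == b:
        raise ValueError("species_a and species_b must differ")
    recs = list(records)
    if not recs:
        raise ValueError("need at least one record")
    vocab = {s for r in recs for s in r.species_present}
    for name in (a, b):
        if name not in vocab:
            raise ValueError(f"species {name!r} never observed in these records")
    count_a = sum(a in r.species_present for r in recs)
    count_b = sum(b in r.species_present for r in recs)
    count_both = sum(
        a in r.species_present and b in r.species_present for r in recs
    )
    return cooccurrence_from_counts(len(recs), count_a, count_b, count_both)


class ZeroClassPoissonModel:
    """Zero-class Poisson colonization model for one species.

    Construct from occupancy counts, or from collection records via
    :meth:`from_records`; :meth:`fit` returns the fitted results object.
    """

    def __init__(self, n_patches: int, n_occupied: int):
        self.n_patches = int(n_patches)
        self.n_occupied = int(n_occupied)

    @classmethod
    def from_records(cls, records: Iterable, species: str) -> "ZeroClassPoissonModel":
        name = normalize_species_name(species)
        recs = list(records)
        if not recs:
            raise ValueError("need at least one record")
        occupied = sum(name in r.species_present for r in recs)
        return cls(len(recs), occupied)

    def fit(self, conf_level: float = 0.95) -> "ZeroClassPoissonResults":
        return ZeroClassPoissonResults(
            self, fit_zero_class(self.n_patches, self.n_occupied, conf_level)
        )


class ZeroClassPoissonResults:
    def __init__(self, model: ZeroClassPoissonModel, estimate: ColonizationEstimate):
        self.model = model
        self.estimate = estimate

    def expected_occupancy(self) -> float:
        """Occupancy fraction implied by the fitted λ (round-trip identity)."""
        return 1.0 - math.exp(-self.estimate.lambda_hat)

    def summary(self) -> str:
        e = self.estimate
        pct = 100.0 * e.conf_level
        return "\n".join(
            [
                "Zero-class Poisson colonization model",
                "=" * 48,
                f"patches sampled           {e.n_patches:>10d}",
                f"patches occupied          {e.n_occupied:>10d}"
                f"  ({100 * e.p_occ:.0f}%)",
                f"lambda_hat                {e.lambda_hat:>10.2f}"
                f"  colonizations/patch",
                f"{pct:.0f}% CI (Clopper-Pearson)  "
                f"[{e.ci_lambda_low:.3f}, {e.ci_lambda_high:.3f}]",
                f"P(K=0)                    {e.p_zero:>10.2f}",
                f"P(K=1)                    {e.p_one:>10.2f}",
                f"P(K>=2)                   {e.p_two_plus:>10.2f}",
                "fraction of occupied patches with multiple colonizations: "
                f"{e.frac_multiple_occupied:.2f}",
            ]
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ZeroClassPoissonResults lambda={self.estimate.lambda_hat:.3f}>"
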