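"""Pedigree-based Y-STR mutation-rate estimation.

Haplotypes of paternally related males separated by a known number of
meioses are compared locus by locus.  For indistinguishable multi-copy loci
only the sorted allele vector is observable, so the step count is settled
by parsimony: copies are matched by the assignment minimising the total
number of repeat steps.  Compound and complex loci are compared per variable
motif, which exposes parallel isoallele mutations that leave the summed
allele call unchanged.

Each non-zero per-motif, per-copy difference is one *mutation event* of its
step size.  Because a multi-step difference may hide several smaller
mutations, the event count brackets the true mutation number:

* lower bound — one mutation per event;
* upper bound — events of size one or two count as a single mutation, an
  event of size ``s >= 3`` may represent up to ``s`` one-step mutations.

The midpoint of the bracket is the numerator of the per-locus mutation rate
``mpg = differences / meioses`` (mutations per generation).  Exact 95%
binomial (Clopper-Pearson) intervals accompany per-locus rates; the
panel-wide aggregate is additionally reported with a normal-approximation
interval.  Rates are classified as slow (< 1e-3), moderate [1e-3, 5e-3),
fast [5e-3, 1e-2) and rapid (>= 1e-2, the RM Y-STR threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import stats

RATE_CLASSES = (("slow", 1e-3), ("moderate", 5e-3), ("fast", 1e-2))


def classify_rate(rate: float, differences: float | None = None) -> str:
    """Mutability class from the unrounded rate; zero differences are
    reported separately as non-mutating."""
    if differences is not None and differences == 0:
        return "non_mutating"
    for name, upper in RATE_CLASSES:
        if rate < upper:
            return name
    return "rapid"


# ---------------------------------------------------------------------------
# pairwise comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusComparison:
    """Step events between two calls of one locus."""

    locus: str
    events: tuple[int, ...]       # step size of each mutation event

    @property
    def steps_min(self) -> int:
        return len(self.events)

    @property
    def steps_max(self) -> int:
        return sum(1 if s <= 2 else s for s in self.events)

    @property
    def steps_mid(self) -> float:
        return (self.steps_min + self.steps_max) / 2.0

    @property
    def total_steps(self) -> int:
        return sum(self.events)


@dataclass
class PairComparison:
    pair: tuple[str, str]
    meioses: int
    loci: dict[str, LocusComparison] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)   # no_data in either sample


def optimal_assignment_steps(vectors_a, vectors_b) -> tuple[int, tuple[int, ...]]:
    """Parsimony matching of multi-copy allele vectors.

    ``vectors_*`` are per-copy tuples of variable-block counts.  Returns the
    minimal total step count over all copy-to-copy assignments and the step
    events (per-block absolute differences) of that assignment; ties prefer
    fewer events, then lexicographic order, for determinism.
    """
    if len(vectors_a) != len(vectors_b):
        raise ValueError("copy_count mismatch between profiles")
    best = None
    for perm in permutations(range(len(vectors_b))):
        events = []
        for i, j in enumerate(perm):
            for x, y in zip(vectors_a[i], vectors_b[j]):
                d = abs(x - y)
                if d:
                    events.append(d)
        key = (sum(events), len(events), tuple(sorted(events)), perm)
        if best is None or key < best:
            best = key
    return best[0], best[2]


def compare_pair(profile_a, profile_b, loci, pair_id=None,
                 meioses: int = 1) -> PairComparison:
    """Per-locus step events between two related samples' profiles.

    Loci with ``no_data`` in either sample are skipped and excluded from
    that locus's meiosis denominator.  Multi-copy loci are matched by
    parsimony over their sorted call vectors; per-motif comparison detects
    parallel mutations hidden from length-based typing.
    """
    pair_id = pair_id or (profile_a.sample, profile_b.sample)
    cmp = PairComparison(pair_id, meioses)
    for lc in loci:
        ca = profile_a.calls.get(lc.name)
        cb = profile_b.calls.get(lc.name)
        if ca is None or cb is None or not ca.called or not cb.called:
            cmp.skipped.append(lc.name)
            continue
        va, vb = ca.variable_vectors(), cb.variable_vectors()
        _, events = optimal_assignment_steps(va, vb)
        cmp.loci[lc.name] = LocusComparison(lc.name, events)
    return cmp


# ---------------------------------------------------------------------------
# rate estimation
# ---------------------------------------------------------------------------

def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval for k events in n trials."""
    if n < 1:
        raise ValueError("meioses must be >= 1")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class MutationRateEstimate:
    locus: str
    differences: float           # bracket midpoint (rate numerator)
    differences_min: int
    differences_max: int
    meioses: int
    rate: float                  # mpg
    ci_low: float
    ci_high: float
    rate_class: str


def mutation_rate(differences: float, meioses: int, locus: str = "",
                  differences_min: int | None = None,
                  differences_max: int | None = None) -> MutationRateEstimate:
    """Point rate ``differences / meioses`` with an exact 95% CI.

    The rate uses the (possibly fractional) bracket midpoint; the
    Clopper-Pearson interval needs an integer event count, so the midpoint
    is rounded half-up for the interval only.
    """
    if meioses < 1:
        raise ValueError("meioses must be >= 1")
    if differences < 0:
        raise ValueError("differences must be >= 0")
    rate = differences / meioses
    k = math.floor(differences + 0.5)
    lo, hi = clopper_pearson(min(k, meioses), meioses)
    return MutationRateEstimate(
        locus, differences,
        differences if differences_min is None else differences_min,
        differences if differences_max is None else differences_max,
        meioses, rate, lo, hi, classify_rate(rate, differences))


def normal_rate_ci(differences: float, meioses: int, conf: float = 0.95):
    """Wald (normal-approximation) interval on an aggregate rate."""
    p = differences / meioses
    z = stats.norm.ppf(0.5 + conf / 2)
    half = z * math.sqrt(p * (1 - p) / meioses)
    return max(p - half, 0.0), min(p + half, 1.0)


def step_ratio(events_by_size) -> tuple[int, int, int]:
    """One-:two-:multi-step percentage ratio (rounded to whole percent)."""
    one = events_by_size.get(1, 0)
    two = events_by_size.get(2, 0)
    multi = sum(n for s, n in events_by_size.items() if s >= 3)
    total = one + two + multi
    if total == 0:
        return 0, 0, 0
    return tuple(int(round(100.0 * x / total)) for x in (one, two, multi))


@dataclass
class PanelRateSummary:
    total_differences: float
    total_differences_min: int
    total_differences_max: int
    total_meioses: int
    rate: float
    ci_normal: tuple[float, float]
    ci_exact: tuple[float, float]
    mutating_rate: float          # zero-difference loci excluded
    mutating_meioses: int
    n_mutating: int
    n_non_mutating: int
    events_by_size: dict[int, int]
    step_ratio_pct: tuple[int, int, int]


def aggregate_rates(comparisons, loci) -> tuple[dict[str, MutationRateEstimate], PanelRateSummary]:
    """Per-locus and panel-wide rates from a set of pair comparisons.

    Per locus, midpoint numerators and covered meioses are summed over
    pairs; a pair contributes its meioses to a locus only when the locus is
    typed in both members.  The panel rate divides the summed numerators by
    the summed locus-meioses; a mutating-only average excludes loci without
    observed differences.
    """
    names = [lc.name for lc in loci]
    num = {n: 0.0 for n in names}
    num_min = {n: 0 for n in names}
    num_max = {n: 0 for n in names}
    den = {n: 0 for n in names}
    events_by_size: dict[int, int] = {}
    for cmp in comparisons:
        for name in names:
            lcmp = cmp.loci.get(name)
            if lcmp is None:
                continue
            den[name] += cmp.meioses
            num[name] += lcmp.steps_mid
            num_min[name] += lcmp.steps_min
            num_max[name] += lcmp.steps_max
            for s in lcmp.events:
                events_by_size[s] = events_by_size.get(s, 0) + 1
    per_locus = {}
    for name in names:
        if den[name] == 0:
            continue
        per_locus[name] = mutation_rate(num[name], den[name], name,
                                        num_min[name], num_max[name])
    tot_mid = sum(num[n] for n in per_locus)
    tot_m = sum(den[n] for n in per_locus)
    mut = [n for n in per_locus if num[n] > 0]
    mut_m = sum(den[n] for n in mut)
    k = math.floor(tot_mid + 0.5)
    summary = PanelRateSummary(
        total_differences=tot_mid,
        total_differences_min=sum(num_min[n] for n in per_locus),
        total_differences_max=sum(num_max[n] for n in per_locus),
        total_meioses=tot_m,
        rate=tot_mid / tot_m if tot_m else 0.0,
        ci_normal=normal_rate_ci(tot_mid, tot_m) if tot_m else (0.0, 0.0),
        ci_exact=clopper_pearson(min(k, tot_m), tot_m) if tot_m else (0.0, 0.0),
        mutating_rate=tot_mid / mut_m if mut_m else 0.0,
        mutating_meioses=mut_m,
        n_mutating=len(mut),
        n_non_mutating=len(per_locus) - len(mut),
        events_by_size=events_by_size,
        step_ratio_pct=step_ratio(events_by_size),
    )
    return per_locus, summary


# ---------------------------------------------------------------------------
# literature comparison and individualization
# ---------------------------------------------------------------------------

def compare_rate_to_reference(differences: float, meioses: int, ref_rate: float,
                              alpha: float = 0.05):
    """Chi-square goodness-of-fit of an observed rate against a published one.

    Observed (events, non-events) in ``meioses`` trials versus expected
    counts under ``ref_rate``.  Returns ``(statistic, p_value, significant)``.
    """
    if not 0.0 < ref_rate < 1.0:
        raise ValueError("ref_rate must lie in (0, 1)")
    k = math.floor(differences + 0.5)
    expected = np.array([meioses * ref_rate, meioses * (1.0 - ref_rate)])
    if (expected <= 0).any():
        raise ValueError("expected count of zero; reference rate degenerate")
    observed = np.array([k, meioses - k], dtype=float)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p, p < alpha


def expected_mutations_per_generation(rates) -> float:
    """Panel-level expected number of mutations in one meiosis."""
    return float(np.sum(rates))


def distinguish_probability(rates, generations: int, n_loci: int | None = None) -> float:
    """Probability that two relatives separated by ``generations`` meioses
    differ at one or more loci: ``1 - prod (1 - r_i)^g``.

    ``rates`` may be a scalar (uniform rate over ``n_loci`` loci) or a
    sequence of per-locus rates.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if np.ndim(rates) == 0:
        if n_loci is None:
            raise ValueError("n_loci required with a uniform rate")
        r = np.full(n_loci, float(rates))
    else:
        r = np.asarray(rates, dtype=float)
    if ((r < 0) | (r > 1)).any():
        raise ValueError("rates must lie in [0, 1]")
    return float(1.0 - np.prod((1.0 - r) ** generations))


def total_difference_pmf(rates, generations: int) -> np.ndarray:
    """Exact PMF of the total difference count over independent loci.

    Per locus the number of observed differences over ``g`` meioses is
    Binomial(g, r); the panel total is their convolution (Poisson-binomial
    when g = 1).
    """
    pmf = np.array([1.0])
    for r in np.atleast_1d(np.asarray(rates, dtype=float)):
        loc = stats.binom.pmf(np.arange(generations + 1), generations, r)
        pmf = np.convolve(pmf, loc)
    return pmf


def max_allowed_differences(rates, generations: int, quantile: float = 0.95) -> int:
    """Smallest k with P(total differences <= k) >= quantile.

    The kinship-verification threshold: more than k differences between two
    putative relatives is evidence against the claimed relationship.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    cdf = np.cumsum(total_difference_pmf(rates, generations))
    return int(np.searchsorted(cdf, quantile - 1e-12))


def write_rate_table(per_locus, summary: PanelRateSummary, path) -> None:
    """Per-locus rate TSV: step-size tallies, bracket, meioses, mpg, CI."""
    with open(path, "w") as fh:
        fh.write("locus\tdifferences\trange\tm\tmpg_x1000\tci95_x1000\tclass\n")
        for name, est in sorted(per_locus.items()):
            rng = (f"{est.differences_min}-{est.differences_max}"
                   if est.differences_min != est.differences_max else "")
            fh.write(f"{name}\t{est.differences:g}\t{rng}\t{est.meioses}\t"
                     f"{est.rate * 1e3:.2f}\t"
                     f"{est.ci_low * 1e3:.2f}-{est.ci_high * 1e3:.2f}\t{est.rate_class}\n")
        fh.write(f"Total\t{summary.total_differences:g}\t"
                 f"{summary.total_differences_min}-{summary.total_differences_max}\t"
                 f"{summary.total_meioses}\t{summary.rate * 1e3:.2f}\t"
                 f"{summary.ci_normal[0] * 1e3:.2f}-{summary.ci_normal[1] * 1e3:.2f}\t\n")
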