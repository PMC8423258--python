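"""Population summaries over unrelated samples.

Per-locus allele frequencies, ranges and discrimination capacity
(``DC = 1 - sum p_i^2`` over allele frequencies — zero for a monomorphic
locus), haplotype uniqueness across samples, haplogroup-tree coverage
bookkeeping for the SNP side of a panel, and molecular-factor summaries
relating mutation rates to repeat size, motif length and repeat type.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class DiversityStat:
    locus: str
    frequencies: dict            # allele (or sorted allele vector) -> frequency
    n_samples: int
    dc: float                    # discrimination capacity
    allele_range: tuple[int, int]
    mean_allele: float


def _allele_key(call):
    """Categorical allele identity: the sorted per-copy block-count vectors.

    Multi-copy loci contribute their whole sorted vector as one 'allele',
    the convention length-based kits use for e.g. two-copy dinucleotides.
    """
    return call.variable_vectors()


def diversity(profiles, locus_name: str, unbiased: bool = False) -> DiversityStat | None:
    """Allele frequency table, range and discrimination capacity for one locus.

    ``unbiased`` applies the n/(n-1) small-sample correction to DC.
    Returns None (with nothing to summarise) when no profile calls the locus.
    """
    keys = []
    totals = []
    for p in profiles:
        call = p.calls.get(locus_name)
        if call is None or not call.called:
            continue
        keys.append(_allele_key(call))
        totals.extend(call.allele_calls)
    n = len(keys)
    if n == 0:
        return None
    counts = Counter(keys)
    freqs = {k: c / n for k, c in counts.items()}
    dc = 1.0 - sum(f * f for f in freqs.values())
    if unbiased and n > 1:
        dc *= n / (n - 1)
    return DiversityStat(
        locus_name, freqs, n, dc,
        (int(min(totals)), int(max(totals))), float(np.mean(totals)))


def haplotype_uniqueness(profiles):
    """Pairwise distinguishability over shared called loci.

    Returns ``(n_identical_pairs, distance_distribution)`` where the
    distribution counts pairs by their number of differing loci.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    n_identical = 0
    dist: Counter = Counter()
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            a, b = profiles[i], profiles[j]
            shared = [
                name for name, ca in a.calls.items()
                if ca.called and (cb := b.calls.get(name)) is not None and cb.called
            ]
            d = sum(
                1 for name in shared
                if a.calls[name].variable_vectors() != b.calls[name].variable_vectors()
            )
            dist[d] += 1
            if shared and d == 0:
                n_identical += 1
    return n_identical, dict(dist)


@dataclass
class CoverageReport:
    covered: int
    total: int
    percent: int                           # round(100 * covered / total)
    per_main: dict[str, tuple[int, int, int]]  # letter -> (covered, total, n_snps)
    uncovered: list[str] = field(default_factory=list)


def haplogroup_coverage(panel_snps, reference_nodes) -> CoverageReport:
    """How much of a reference haplogroup tree the panel's SNPs cover.

    A node is covered when at least one panel SNP defines it.  Percentages
    are pure integer arithmetic: round(100 * covered / total).
    """
    reference_nodes = sorted(set(reference_nodes))
    by_label: Counter = Counter(s.haplogroup for s in panel_snps
                                if s.haplogroup != "unknown")
    covered = [n for n in reference_nodes if by_label.get(n, 0) > 0]
    per_main: dict[str, list[int]] = {}
    for n in reference_nodes:
        entry = per_main.setdefault(n[0], [0, 0, 0])
        entry[1] += 1
        if by_label.get(n, 0):
            entry[0] += 1
            entry[2] += by_label[n]
    total = len(reference_nodes)
    pct = int(round(100.0 * len(covered) / total)) if total else 0
    return CoverageReport(
        len(covered), total, pct,
        {k: tuple(v) for k, v in sorted(per_main.items())},
        [n for n in reference_nodes if not by_label.get(n, 0)])


@dataclass
class FactorSummary:
    correlation: float | None     # rate vs mean allele size
    p_value: float | None
    method: str
    by_unit_len: dict[int, float]
    by_repeat_type: dict[str, float]
    degenerate: bool = False


def factor_summary(rate_estimates, loci, mean_allele_sizes, method: str = "spearman",
                   ) -> FactorSummary:
    """Molecular factors of mutability: rate vs average allele size
    correlation and group means by motif unit length and repeat type."""
    by_name = {lc.name: lc for lc in loci}
    names = [n for n in rate_estimates if n in by_name and n in mean_allele_sizes]
    if len(names) < 3:
        raise ValueError("need rates and allele sizes for at least 3 loci")
    rates = np.array([rate_estimates[n].rate if hasattr(rate_estimates[n], "rate")
                      else float(rate_estimates[n]) for n in names])
    sizes = np.array([float(mean_allele_sizes[n]) for n in names])
    degenerate = np.allclose(rates, rates[0]) or np.allclose(sizes, sizes[0])
    if degenerate:
        corr = p = None
    else:
        if method == "spearman":
            corr, p = stats.spearmanr(rates, sizes)
        elif method == "pearson":
            corr, p = stats.pearsonr(rates, sizes)
        else:
            raise ValueError(f"unknown method {method!r}")
        corr, p = float(corr), float(p)
    by_unit: dict[int, list[float]] = {}
    by_type: dict[str, list[float]] = {}
    for n, r in zip(names, rates):
        lc = by_name[n]
        by_unit.setdefault(lc.min_unit_len, []).append(r)
        by_type.setdefault(lc.repeat_type, []).append(r)
    return FactorSummary(
        corr, p, method,
        {k: float(np.mean(v)) for k, v in sorted(by_unit.items())},
        {k: float(np.mean(v)) for k, v in sorted(by_type.items())},
        degenerate)
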