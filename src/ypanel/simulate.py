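"""Synthetic haploid amplicon data with known truth.

The generator emulates the assay this package analyses: paired-end amplicon
sequencing of Y-STR and Y-SNP targets on the male-specific Y chromosome.
It produces

* pedigrees — chains of father-to-son transmissions in which each locus copy
  mutates with its per-meiosis rate, step sizes drawn from a one-step-
  dominated distribution and reflected at the allele range boundaries;
* paired FASTQ reads per sample — for every STR locus copy the amplicon
  ``anchor5 + prefix + repeats + suffix + anchor3`` at negative-binomial
  depth, a stutter ladder (repeat-loss products at n-1 and n-2, strongest
  for dinucleotide motifs), per-base substitution error and an optional
  per-length depth decay emulating template degradation; SNP amplicons carry
  the ancestral or derived base according to a planted haplogroup path;
* a no-chrY (female) mode that emits only off-target reads, and
* a machine-readable truth record (:class:`SimTruth`) for verification.

Defaults mirror the assay being modelled: 2x300 bp reads, ~150 reads per
Y-STR locus and ~717 per Y-SNP, mutation rates of a few per thousand
meioses with an 83:11:6 one/two/multi-step mix.  Quantitative stutter ratios
are engineering choices (no published values exist for this chemistry) and
are exposed in :class:`SimulationConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .panel import (
    DNA, ANCHOR_LEN, MotifBlock, SnpDef, StrLocusDef,
    revcomp, snp_amplicon_context,
)

# genotype of one sample: locus name -> per-copy tuples of variable-block counts
Genotype = dict[str, tuple[tuple[int, ...], ...]]

DEFAULT_STUTTER = {2: 0.30, 3: 0.12, 4: 0.10, 5: 0.05, 6: 0.05}


@dataclass
class SimulationConfig:
    """All knobs of the generator; every random draw flows from ``seed``."""

    seed: int = 0
    depth_mean: float = 150.0          # mean reads per STR locus copy
    snp_depth_mean: float = 717.0      # mean reads per SNP amplicon
    depth_dispersion: float = 4.0      # negative-binomial size k (var = mu + mu^2/k)
    error_rate: float = 0.005          # per-base substitution probability
    stutter_ratio: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_STUTTER))
    stutter_decay: float = 0.3         # n-2 ratio relative to n-1
    stutter_gain: float = 0.0          # optional repeat-gain (n+1) component
    mutation_rate: float = 5e-3        # per-copy, per-meiosis STR mutation rate
    mutation_rate_per_locus: dict[str, float] = field(default_factory=dict)
    p_one_step: float = 0.83
    p_two_step: float = 0.11           # remaining mass: geometric tail from 3 up
    tail_decay: float = 0.5
    read_length: int = 300
    degradation: float = 1.0           # depth multiplier per 100 bp of amplicon
    base_quality: int = 35             # constant Phred score (Phred+33)
    offtarget_reads: int = 100         # junk read pairs per sample

    def __post_init__(self):
        rates = [self.error_rate, self.mutation_rate, self.stutter_decay,
                 self.stutter_gain, *self.stutter_ratio.values(),
                 *self.mutation_rate_per_locus.values()]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.stutter_ratio.get(2, 0.0) < self.stutter_ratio.get(4, 0.0):
            raise ValueError("dinucleotide stutter must be >= tetranucleotide stutter")
        if self.read_length < ANCHOR_LEN + 1:
            raise ValueError(f"read_length must exceed the {ANCHOR_LEN} bp anchor")

    def rate_for(self, locus: str) -> float:
        return self.mutation_rate_per_locus.get(locus, self.mutation_rate)


@dataclass
class PlantedMutation:
    meiosis: int
    locus: str
    copy_index: int
    block_index: int      # index among the locus's variable blocks
    step: int
    direction: int        # +1 / -1 after boundary reflection


@dataclass
class SimTruth:
    """Everything the simulator planted, for downstream verification."""

    founder: Genotype
    mutations: list[PlantedMutation] = field(default_factory=list)
    sample_genotypes: dict[str, Genotype] = field(default_factory=dict)
    haplogroup_path: dict[str, str] = field(default_factory=dict)
    planted_depths: dict[str, int] = field(default_factory=dict)  # "locus" -> total reads

    def to_json(self, path) -> None:
        doc = {
            "founder": {k: [list(c) for c in v] for k, v in self.founder.items()},
            "mutations": [asdict(m) for m in self.mutations],
            "sample_genotypes": {
                s: {k: [list(c) for c in v] for k, v in g.items()}
                for s, g in self.sample_genotypes.items()
            },
            "haplogroup_path": self.haplogroup_path,
            "planted_depths": self.planted_depths,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def _draw_step(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    u = rng.random()
    if u < cfg.p_one_step:
        return 1
    if u < cfg.p_one_step + cfg.p_two_step:
        return 2
    # geometric tail over 3, 4, ...
    return 3 + rng.geometric(1.0 - cfg.tail_decay) - 1


def founder_genotype(loci) -> Genotype:
    return {lc.name: tuple(lc.ref_variable_counts() for _ in range(lc.copy_count))
            for lc in loci}


def simulate_pedigree(config: SimulationConfig, n_meioses: int, loci,
                      founder: Genotype | None = None,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[list[Genotype], SimTruth]:
    """Simulate a chain of ``n_meioses`` father-to-son transmissions.

    Per meiosis, each copy of each locus mutates with its configured rate
    (locus-level probability rate x copies).  A mutation changes one variable
    block by the drawn step size, direction +/- with equal probability,
    reflected (and clamped) at the block's allele range boundary.  Returns
    the ``n_meioses + 1`` genotypes along the chain and the planted truth.
    """
    rng = rng or np.random.default_rng(config.seed)
    loci = list(loci)
    if founder is None:
        founder = founder_genotype(loci)
    for lc in loci:
        for copy in founder[lc.name]:
            for b, c in zip(lc.variable_blocks, copy):
                if not b.min_count <= c <= b.max_count:
                    raise ValueError(f"{lc.name}: founder count {c} outside block range")
    truth = SimTruth(founder={k: tuple(v) for k, v in founder.items()})
    chain = [dict(founder)]
    current = {k: [list(c) for c in v] for k, v in founder.items()}
    for meiosis in range(1, n_meioses + 1):
        for lc in loci:
            rate = config.rate_for(lc.name)
            for ci in range(lc.copy_count):
                if rng.random() >= rate:
                    continue
                vb = lc.variable_blocks
                counts = current[lc.name][ci]
                weights = np.asarray(counts, dtype=float)
                if weights.sum() <= 0:
                    weights = np.ones(len(vb))
                bi = int(rng.choice(len(vb), p=weights / weights.sum()))
                step = _draw_step(rng, config)
                direction = 1 if rng.random() < 0.5 else -1
                block = vb[bi]
                new = counts[bi] + direction * step
                if not block.min_count <= new <= block.max_count:
                    direction = -direction  # reflect at the boundary
                    new = counts[bi] + direction * step
                new = min(max(new, block.min_count), block.max_count)
                step_eff = abs(new - counts[bi])
                if step_eff == 0:
                    continue
                counts[bi] = new
                truth.mutations.append(PlantedMutation(
                    meiosis, lc.name, ci, bi, step_eff, direction))
        chain.append({k: tuple(tuple(c) for c in v) for k, v in current.items()})
    genotypes = [chain[0], *chain[1:]]
    for i, g in enumerate(genotypes):
        truth.sample_genotypes[f"gen{i}"] = g
    return genotypes, truth


def apply_mutations(founder: Genotype, mutations, loci_by_name, upto_meiosis: int) -> Genotype:
    """Re-derive a genotype from the founder and the planted mutation list."""
    state = {k: [list(c) for c in v] for k, v in founder.items()}
    for m in sorted(mutations, key=lambda m: m.meiosis):
        if m.meiosis > upto_meiosis:
            break
        state[m.locus][m.copy_index][m.block_index] += m.direction * m.step
    return {k: tuple(tuple(c) for c in v) for k, v in state.items()}


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadPair:
    name: str
    r1: str
    r2: str


def _nb_depth(rng, mean: float, k: float) -> int:
    """Negative-binomial depth draw; dispersion 0 means deterministic depth."""
    if mean <= 0:
        return 0
    if k <= 0:
        return int(round(mean))
    p = k / (k + mean)
    return int(rng.negative_binomial(k, p))


def _with_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    lut = {b: [o for o in b"ACGT" if o != b] for b in b"ACGT"}
    for i in hits:
        arr[i] = rng.choice(lut[arr[i]])
    return arr.tobytes().decode()


def _emit(rng, cfg, amplicon: str, count: int, tag: str, out: list[ReadPair]) -> None:
    rl = cfg.read_length
    for i in range(count):
        r1 = _with_errors(rng, amplicon[:rl], cfg.error_rate)
        r2 = _with_errors(rng, revcomp(amplicon)[:rl], cfg.error_rate)
        out.append(ReadPair(f"{tag}:{i}", r1, r2))


def _stutter_products(block_counts: tuple[int, ...], blocks: tuple[MotifBlock, ...]):
    """Yield (counts, which-block, offset) for n-1 / n-2 / n+1 products."""
    for bi, b in enumerate(blocks):
        for off in (-1, -2, +1):
            n = block_counts[bi] + off
            if n >= 1 and n <= b.max_count + 1:
                counts = list(block_counts)
                counts[bi] = n
                yield tuple(counts), b, off


def simulate_reads(genotype: Genotype, loci, snps, config: SimulationConfig,
                   sample: str = "s", derived_labels: frozenset | set = frozenset(),
                   female: bool = False,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[list[ReadPair], SimTruth]:
    """Emit paired-end reads for one sample plus the planted truth.

    ``derived_labels`` is the set of haplogroup labels on the sample's true
    path; SNPs defining those labels carry the derived base.  In female mode
    no chrY amplicons are emitted, only off-target noise reads.
    """
    rng = rng or np.random.default_rng(config.seed)
    reads: list[ReadPair] = []
    truth = SimTruth(founder={k: tuple(v) for k, v in genotype.items()})
    truth.sample_genotypes[sample] = genotype
    truth.haplogroup_path[sample] = ",".join(sorted(derived_labels))

    if not female:
        for lc in loci:
            for ci in range(lc.copy_count):
                counts = genotype[lc.name][ci]
                amplicon = lc.amplicon(counts)
                mean = config.depth_mean * config.degradation ** (len(amplicon) / 100.0)
                depth = _nb_depth(rng, mean, config.depth_dispersion)
                truth.planted_depths[f"{lc.name}:{ci}"] = depth
                _emit(rng, config, amplicon, depth, f"{sample}:{lc.name}:{ci}", reads)
                vb = lc.variable_blocks
                for st_counts, block, off in _stutter_products(counts, vb):
                    base = config.stutter_ratio.get(block.unit_len, 0.05)
                    ratio = {-1: base, -2: base * config.stutter_decay,
                             +1: base * config.stutter_gain}[off]
                    if ratio <= 0 or depth == 0:
                        continue
                    n_st = int(rng.binomial(depth, min(ratio, 1.0)))
                    if n_st:
                        _emit(rng, config, lc.amplicon(st_counts), n_st,
                              f"{sample}:{lc.name}:{ci}:st{off:+d}", reads)
        for snp in snps:
            left, right = snp_amplicon_context(snp)
            state = snp.derived if snp.haplogroup in derived_labels else snp.ancestral
            amplicon = left + state + right
            depth = _nb_depth(rng, config.snp_depth_mean, config.depth_dispersion)
            truth.planted_depths[f"snp:{snp.name}"] = depth
            _emit(rng, config, amplicon, depth, f"{sample}:{snp.name}", reads)

    for i in range(config.offtarget_reads):
        junk = "".join(DNA[b] for b in rng.integers(0, 4, size=config.read_length))
        reads.append(ReadPair(f"{sample}:offtarget:{i}",
                              junk, revcomp(junk)))
    return reads, truth


def write_fastq(reads, r1_path, r2_path, base_quality: int = 35) -> None:
    """Write the two mates as plain Phred+33 FASTQ (byte-deterministic)."""
    q = chr(base_quality + 33)
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for rp in reads:
            f1.write(f"@{rp.name}/1\n{rp.r1}\n+\n{q * len(rp.r1)}\n")
            f2.write(f"@{rp.name}/2\n{rp.r2}\n+\n{q * len(rp.r2)}\n")


def simulate_cohort(n_samples: int, loci, snps, tree, config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    diversify_meioses: int = 5, diversify_rate: float = 0.05):
    """A cohort of unrelated males with reads and per-sample truth.

    Each sample's genotype is diversified from the panel reference by a
    short private pedigree (``diversify_meioses`` transmissions at
    ``diversify_rate``), and its haplogroup is a uniformly drawn tree node;
    SNPs on the root path carry the derived base.  Returns a list of dicts
    with keys ``sample``, ``genotype``, ``terminal``, ``derived_labels``
    and ``reads``.
    """
    rng = rng or np.random.default_rng(config.seed)
    div_cfg = SimulationConfig(seed=config.seed, mutation_rate=diversify_rate,
                               p_one_step=config.p_one_step,
                               p_two_step=config.p_two_step)
    nodes = sorted(tree.nodes)
    cohort = []
    for i in range(n_samples):
        chain, _ = simulate_pedigree(div_cfg, diversify_meioses, loci, rng=rng)
        genotype = chain[-1]
        terminal = nodes[int(rng.integers(len(nodes)))]
        derived = frozenset(tree.path(terminal))
        sample = f"sim{i:03d}"
        reads, truth = simulate_reads(genotype, loci, snps, config, sample=sample,
                                      derived_labels=derived, rng=rng)
        cohort.append({
            "sample": sample, "genotype": genotype, "terminal": terminal,
            "derived_labels": derived, "reads": reads, "truth": truth,
        })
    return cohort


# ---------------------------------------------------------------------------
# random panel / positions generators (synthetic study designs)
# ---------------------------------------------------------------------------

_COMPOUND_PAIRS = [("AAAGG", "AAGGG"), ("GT", "GTCT"), ("TAGA", "CAGA"), ("TCTA", "TCTG")]
_SIMPLE_MOTIFS = ["AC", "GT", "TG", "AAT", "TCT", "AGAT", "TATC", "CTTT",
                  "AAAGG", "TTTTA", "GGAGAA"]


def _random_dna(rng, n: int, avoid: str | None = None) -> str:
    while True:
        s = "".join(DNA[b] for b in rng.integers(0, 4, size=n))
        if avoid is None or avoid not in s:
            return s


def _distinct_anchor(rng, used: list[str]) -> str:
    from .panel import hamming
    while True:
        a = _random_dna(rng, ANCHOR_LEN)
        if all(hamming(a, u) > 3 for u in used) and all(
                hamming(revcomp(a), u) > 3 for u in used):
            used.append(a)
            return a


def random_panel(n_loci: int, rng: np.random.Generator,
                 multi_copy_fraction: float = 0.2) -> list[StrLocusDef]:
    """Generate a synthetic panel mixing motif lengths, repeat types and
    copy numbers in roughly the proportions of a real chrY multiplex."""
    loci = []
    used: list[str] = []
    pos = 2_700_000
    for i in range(n_loci):
        kind = rng.random()
        if kind < 0.6:  # simple
            motif = _SIMPLE_MOTIFS[int(rng.integers(len(_SIMPLE_MOTIFS)))]
            ref = int(rng.integers(8, 20))
            blocks = (MotifBlock(motif, True, ref, min_count=3, max_count=40),)
        elif kind < 0.8:  # compound
            m1, m2 = _COMPOUND_PAIRS[int(rng.integers(len(_COMPOUND_PAIRS)))]
            blocks = (
                MotifBlock(m1, True, int(rng.integers(5, 15)), min_count=3, max_count=30),
                MotifBlock(m2, True, int(rng.integers(4, 12)), min_count=3, max_count=30),
            )
        else:  # complex: variable - interruption - variable
            motif = _SIMPLE_MOTIFS[int(rng.integers(len(_SIMPLE_MOTIFS)))]
            gap = _random_dna(rng, int(rng.integers(3, 9)), avoid=motif)
            blocks = (
                MotifBlock(motif, True, int(rng.integers(6, 14)), min_count=3, max_count=30),
                MotifBlock(gap, False, 1, interruption=True),
                MotifBlock(motif, True, int(rng.integers(4, 10)), min_count=3, max_count=30),
            )
        copy_count = 1
        if rng.random() < multi_copy_fraction:
            copy_count = 2 if rng.random() < 0.8 else 4
        first_motif, last_motif = blocks[0].motif, blocks[-1].motif
        prefix = _random_dna(rng, int(rng.integers(8, 20)), avoid=first_motif)
        while prefix.endswith(first_motif[0]):
            prefix = prefix[:-1] + _random_dna(rng, 1)
            continue
        suffix = _random_dna(rng, int(rng.integers(8, 20)), avoid=last_motif)
        while suffix.startswith(last_motif):
            suffix = _random_dna(rng, 1) + suffix[1:]
        length = sum(b.unit_len * b.ref_count for b in blocks)
        loci.append(StrLocusDef(
            name=f"SYS{i + 1:03d}" + ("-" + "ab"[:copy_count] if copy_count == 2
                                      else "-abcd" if copy_count == 4 else ""),
            copy_count=copy_count,
            chr_start=pos, chr_end=pos + length + 100,
            anchor5=_distinct_anchor(rng, used),
            anchor3=_distinct_anchor(rng, used),
            prefix_ref=prefix, suffix_ref=suffix,
            blocks=blocks,
        ))
        pos += 10_000
    return loci


def random_positions(tree_labels, rng: np.random.Generator,
                     snps_per_label: int = 1) -> list[SnpDef]:
    """One or more synthetic SNP definitions per haplogroup label."""
    snps = []
    pos = 6_000_000
    for lab in sorted(tree_labels):
        for j in range(snps_per_label):
            anc, der = rng.choice(list(DNA), size=2, replace=False)
            snps.append(SnpDef(
                names=(f"{lab}-M{pos % 100000}",), position=pos,
                ancestral=str(anc), derived=str(der), haplogroup=lab,
            ))
            pos += 1_517
    return snps
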