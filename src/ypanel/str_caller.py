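"""Sequence-based Y-STR genotyping.

The calling strategy works directly on amplicon reads, without alignment:

1. :func:`tabulate_sequences` — assign each read to a locus by its 15-bp
   anchor sequences (tolerating a configurable number of mismatches), trim
   the anchors and count unique sequences per locus, separately for the two
   read ends and strands.
2. :func:`decompose` — split a sequence into prefix / repeat / suffix
   against the locus structure (greedy left-to-right, variable blocks
   maximal, exact flank lengths preferred within a tolerance).  The allele
   call is the summed repeat count of the variable blocks, so isoalleles
   with equal total length but different internal structure stay distinct.
3. :func:`filter_stutter` — discard replication-slippage artifacts sitting
   one or two repeats below a better-supported sequence.
4. :func:`call_locus` — walk candidates in depth order (the top
   ``4 x copy_count`` are examined), validate by decomposition, and emit
   ``copy_count`` calls or ``no_data``.
5. :func:`paired_end_consensus` — reconcile the two single-end calls: when
   they disagree, the end whose repeat starts closer to its anchor wins
   (sequencing error grows per cycle), with depth as the tie-break.

Multi-copy loci with indistinguishable copies are reported as sorted allele
vectors (shortest first), the convention under which parsimony-based
mutation counting operates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .panel import ANCHOR_LEN, StrLocusDef, hamming, revcomp

DEFAULT_STUTTER_THRESHOLDS = {2: 0.50, 3: 0.15, 4: 0.15, 5: 0.10, 6: 0.10}
FLANK_TOL = 3


# ---------------------------------------------------------------------------
# read tabulation
# ---------------------------------------------------------------------------

@dataclass
class SequenceCount:
    """One unique anchor-trimmed sequence at one locus."""

    locus: str
    sequence: str
    forward: int = 0
    reverse: int = 0

    @property
    def total(self) -> int:
        return self.forward + self.reverse


def _iter_reads(source):
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        from Bio import SeqIO
        for rec in SeqIO.parse(str(source), "fastq"):
            yield str(rec.seq)
    else:
        for item in source:
            yield item if isinstance(item, str) else item[0]


def _find_anchor(seq: str, anchor: str, max_mm: int, from_end: bool) -> int:
    """Best anchor position (exact match first, then mismatch scan); -1 if absent."""
    idx = seq.rfind(anchor) if from_end else seq.find(anchor)
    if idx >= 0:
        return idx
    if max_mm > 0:
        rng = range(len(seq) - ANCHOR_LEN, -1, -1) if from_end else \
            range(0, len(seq) - ANCHOR_LEN + 1)
        for j in rng:
            if hamming(seq[j:j + ANCHOR_LEN], anchor) <= max_mm:
                return j
    return -1


class _Assigner:
    def __init__(self, loci, max_mm: int):
        self.loci = list(loci)
        self.max_mm = max_mm
        self.exact = {}
        for lc in self.loci:
            self.exact.setdefault(lc.anchor5, []).append((lc, "+"))
            self.exact.setdefault(revcomp(lc.anchor3), []).append((lc, "-"))

    def locus_for(self, read: str):
        head = read[:ANCHOR_LEN]
        if head in self.exact:
            return self.exact[head][0]
        if self.max_mm > 0:
            for lc in self.loci:
                if hamming(head, lc.anchor5) <= self.max_mm:
                    return lc, "+"
                if hamming(head, revcomp(lc.anchor3)) <= self.max_mm:
                    return lc, "-"
        return None

    def trim(self, read: str, lc: StrLocusDef, orient: str):
        """Canonical between-anchor sequence, or None if the far anchor is absent."""
        canonical = read if orient == "+" else revcomp(read)
        if orient == "+":
            j = _find_anchor(canonical, lc.anchor3, self.max_mm, from_end=True)
            if j < ANCHOR_LEN:
                return None
            return canonical[ANCHOR_LEN:j]
        j = _find_anchor(canonical, lc.anchor5, self.max_mm, from_end=False)
        if j < 0 or j + ANCHOR_LEN > len(canonical) - ANCHOR_LEN:
            return None
        return canonical[j + ANCHOR_LEN:len(canonical) - ANCHOR_LEN]


def tabulate_sequences(r1, r2, loci, min_anchor_match: int = 1):
    """Count unique anchor-trimmed sequences per locus and read end.

    ``r1``/``r2`` are FASTQ paths or iterables of read sequences (``r2`` may
    be None).  A read is assigned to a locus iff its first 15 bp match the
    5' anchor (forward strand) or the reverse-complemented 3' anchor
    (reverse strand) within ``min_anchor_match`` mismatches, and the far
    anchor is found in the read.  Returns ``(tables, unassigned)`` where
    ``tables[end][locus_name]`` is a list of :class:`SequenceCount` sorted
    by descending depth and ``unassigned[end]`` counts leftover reads.
    """
    assigner = _Assigner(loci, min_anchor_match)
    tables: dict[str, dict[str, list[SequenceCount]]] = {}
    unassigned: dict[str, int] = {}
    for end, source in (("R1", r1), ("R2", r2)):
        if source is None:
            continue
        counts: dict[tuple[str, str], SequenceCount] = {}
        missed = 0
        for read in _iter_reads(source):
            hit = assigner.locus_for(read)
            if hit is None:
                missed += 1
                continue
            lc, orient = hit
            between = assigner.trim(read, lc, orient)
            if between is None:
                missed += 1
                continue
            sc = counts.setdefault((lc.name, between), SequenceCount(lc.name, between))
            if orient == "+":
                sc.forward += 1
            else:
                sc.reverse += 1
        table: dict[str, list[SequenceCount]] = {}
        for sc in counts.values():
            table.setdefault(sc.locus, []).append(sc)
        for lst in table.values():
            lst.sort(key=lambda s: (-s.total, s.sequence))
        tables[end] = table
        unassigned[end] = missed
    return tables, unassigned


def write_sequence_counts(table, path) -> None:
    """Per-end TSV: locus, sequence, forward, reverse, total."""
    with open(path, "w") as fh:
        fh.write("locus\tsequence\tforward\treverse\ttotal\n")
        for locus in sorted(table):
            for sc in table[locus]:
                fh.write(f"{sc.locus}\t{sc.sequence}\t{sc.forward}\t{sc.reverse}\t{sc.total}\n")


# ---------------------------------------------------------------------------
# repeat decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatDecomposition:
    """prefix | repeat blocks | suffix split of one anchor-trimmed sequence."""

    prefix: str
    blocks: tuple[tuple[str, int], ...]   # (motif, count) for every block
    suffix: str
    variable_counts: tuple[int, ...]      # counts of the variable blocks only
    variants: tuple[str, ...]             # flank differences vs the reference

    @property
    def allele_call(self) -> int:
        return sum(self.variable_counts)

    def expand(self) -> str:
        return self.prefix + "".join(m * c for m, c in self.blocks) + self.suffix

    def block_string(self) -> str:
        return "".join(f"{m}[{c}]" for m, c in self.blocks)

    def __str__(self) -> str:
        return f"{self.prefix}|{self.block_string()}|{self.suffix}"


@dataclass(frozen=True)
class DecompositionFailure:
    reason: str   # flank_too_short | flank_too_long | block_missing
    detail: str = ""


def _parse_blocks(seq: str, i: int, blocks, bi: int, acc: list, out: list) -> None:
    if bi == len(blocks):
        out.append((tuple(acc), i))
        return
    b = blocks[bi]
    if not b.variable:
        exp = b.expand()
        if seq.startswith(exp, i):
            _parse_blocks(seq, i + len(exp), blocks, bi + 1, acc, out)
        return
    u = b.unit_len
    cmax = 0
    while cmax < b.max_count and seq.startswith(b.motif, i + cmax * u):
        cmax += 1
    for c in range(cmax, b.min_count - 1, -1):
        acc.append(c)
        _parse_blocks(seq, i + c * u, blocks, bi + 1, acc, out)
        acc.pop()


def _flank_mismatch_frac(obs: str, ref: str, align: str) -> float:
    """Mismatch fraction over the flank overlap (right-aligned for the
    prefix, left-aligned for the suffix, i.e. anchored at the repeat)."""
    n = min(len(obs), len(ref))
    if n == 0:
        return 0.0
    o = obs[-n:] if align == "right" else obs[:n]
    r = ref[-n:] if align == "right" else ref[:n]
    return hamming(o, r) / n


def _flank_variants(tag: str, obs: str, ref: str) -> list[str]:
    if obs == ref:
        return []
    if len(obs) == len(ref):
        return [f"{tag}:{i + 1}{r}>{o}" for i, (r, o) in enumerate(zip(ref, obs)) if r != o]
    return [f"{tag}:len{len(obs) - len(ref):+d}"]


def decompose(locus: StrLocusDef, sequence: str, flank_tol: int = FLANK_TOL):
    """Decompose an anchor-trimmed sequence into prefix/repeat/suffix.

    Blocks are matched left to right in configured order with variable
    blocks maximal; among admissible parses the one with flank lengths
    closest to the reference wins (then the longer leading repeat, for
    determinism).  Fails when the flanks deviate from the reference lengths
    by more than ``flank_tol`` bp or a required block is absent — the
    signature of off-target homology or heavily erred reads.
    """
    lp, ls = len(locus.prefix_ref), len(locus.suffix_ref)
    best = None
    for dp in sorted(range(-flank_tol, flank_tol + 1), key=lambda d: (abs(d), d)):
        plen = lp + dp
        if plen < 0 or plen > len(sequence):
            continue
        parses: list = []
        _parse_blocks(sequence, plen, locus.blocks, 0, [], parses)
        for counts, end in parses:
            sdev = (len(sequence) - end) - ls
            if abs(sdev) > flank_tol:
                continue
            # repeat chars masquerading as flank: demand flank identity over
            # the overlap (isoallele substitutions pass, junk does not)
            if (_flank_mismatch_frac(sequence[:plen], locus.prefix_ref, "right") > 0.5
                    or _flank_mismatch_frac(sequence[end:], locus.suffix_ref, "left") > 0.5):
                continue
            key = (abs(dp) + abs(sdev), abs(dp), tuple(-c for c in counts))
            if best is None or key < best[0]:
                best = (key, plen, counts, end)
    if best is None:
        # classify the failure: look for the block structure anywhere in the
        # sequence and report which flank is out of tolerance
        closest = None
        for plen in range(len(sequence) + 1):
            parses: list = []
            _parse_blocks(sequence, plen, locus.blocks, 0, [], parses)
            for _, end in parses:
                pdev = plen - lp
                sdev = (len(sequence) - end) - ls
                key = abs(pdev) + abs(sdev)
                if closest is None or key < closest[0]:
                    closest = (key, pdev, sdev)
        if closest is None:
            return DecompositionFailure("block_missing",
                                        f"{locus.name}: repeat structure not found")
        _, pdev, sdev = closest
        dev = pdev if abs(pdev) >= abs(sdev) else sdev
        reason = "flank_too_long" if dev > 0 else "flank_too_short"
        return DecompositionFailure(reason,
                                    f"{locus.name}: flank deviates {dev:+d} bp")
    _, plen, counts, end = best
    prefix, suffix = sequence[:plen], sequence[end:]
    it = iter(counts)
    blk = tuple(
        (b.motif, next(it)) if b.variable else (b.motif, b.ref_count)
        for b in locus.blocks
    )
    variants = (*_flank_variants("prefix", prefix, locus.prefix_ref),
                *_flank_variants("suffix", suffix, locus.suffix_ref))
    return RepeatDecomposition(prefix, blk, suffix, tuple(counts), tuple(variants))


# ---------------------------------------------------------------------------
# stutter filtering and allele calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    sequence: str
    reads: int
    decomposition: RepeatDecomposition

    @property
    def allele_call(self) -> int:
        return self.decomposition.allele_call


def filter_stutter(candidates, locus: StrLocusDef, thresholds=None):
    """Split decomposed candidates into genuine calls and stutter artifacts.

    A candidate one (or two) repeats below a better-supported candidate is
    flagged as stutter when its depth falls below ``threshold x parent
    depth`` (the n-2 threshold is halved); thresholds are keyed by the
    locus's shortest variable motif, dinucleotides being the most
    slippage-prone.  The top-depth candidate is never flagged.  After
    flagging, only the ``copy_count`` best-supported survivors are retained
    (the rest are returned with the flagged ones).
    """
    thresholds = thresholds or DEFAULT_STUTTER_THRESHOLDS
    unit = locus.min_unit_len
    base = thresholds.get(unit, 0.10)
    ordered = sorted(candidates, key=lambda c: (-c.reads, c.sequence))
    genuine: list[Candidate] = []
    flagged: list[Candidate] = []
    for i, c in enumerate(ordered):
        is_stutter = False
        if i > 0:
            for p in ordered:
                if p.reads <= c.reads:
                    break
                delta = p.allele_call - c.allele_call
                if delta in (1, 2):
                    thr = base if delta == 1 else base / 2.0
                    if c.reads < thr * p.reads:
                        is_stutter = True
                        break
        (flagged if is_stutter else genuine).append(c)
    retained = genuine[:locus.copy_count]
    flagged.extend(genuine[locus.copy_count:])
    return retained, flagged


@dataclass(frozen=True)
class CallRecord:
    allele_call: int
    decomposition: RepeatDecomposition
    reads: int


@dataclass(frozen=True)
class AlleleCall:
    locus: str
    status: str                      # "called" | "no_data"
    calls: tuple[CallRecord, ...] = ()
    source: str = "R1"               # R1 | R2 | consensus

    @property
    def called(self) -> bool:
        return self.status == "called"

    @property
    def allele_calls(self) -> tuple[int, ...]:
        return tuple(cr.allele_call for cr in self.calls)

    def variable_vectors(self) -> tuple[tuple[int, ...], ...]:
        """Per-copy variable-block count vectors (parsimony comparison unit)."""
        return tuple(cr.decomposition.variable_counts for cr in self.calls)

    @property
    def supporting_reads(self) -> int:
        return sum(cr.reads for cr in self.calls)


def no_data(locus: str, source: str = "R1") -> AlleleCall:
    return AlleleCall(locus, "no_data", (), source)


def _apportion(counts: list[int], total: int) -> list[int]:
    """Distribute ``total`` copies over survivors, depth-proportionally
    (highest-averages), each survivor keeping at least one copy."""
    mult = [1] * len(counts)
    for _ in range(total - len(counts)):
        quot = [c / (m + 1) for c, m in zip(counts, mult)]
        mult[quot.index(max(quot))] += 1
    return mult


def call_locus(seq_counts, locus: StrLocusDef, min_reads: int = 10,
               stutter_thresholds=None, flank_tol: int = FLANK_TOL,
               source: str = "R1") -> AlleleCall:
    """Call one locus from one read end's sequence counts.

    Candidates are examined in descending depth; only the top
    ``4 x copy_count`` are validated by decomposition.  If none validates,
    or fewer than ``min_reads`` reads cover the locus, the result is
    ``no_data`` (a value, not an error).  Indistinguishable multi-copy loci
    report their calls sorted ascending; when fewer distinct sequences
    survive than the locus has copies, the copies are apportioned to the
    survivors in proportion to depth.
    """
    seq_counts = list(seq_counts)
    total = sum(sc.total for sc in seq_counts)
    if total < min_reads:
        return no_data(locus.name, source)
    ordered = sorted(seq_counts, key=lambda s: (-s.total, s.sequence))
    budget = 4 * locus.copy_count
    valid: list[Candidate] = []
    for sc in ordered[:budget]:
        dec = decompose(locus, sc.sequence, flank_tol)
        if isinstance(dec, RepeatDecomposition):
            valid.append(Candidate(sc.sequence, sc.total, dec))
    if not valid:
        return no_data(locus.name, source)
    genuine, _ = filter_stutter(valid, locus, stutter_thresholds)
    mult = _apportion([c.reads for c in genuine], locus.copy_count)
    records = []
    for c, m in zip(genuine, mult):
        records.extend([CallRecord(c.allele_call, c.decomposition, c.reads)] * m)
    records.sort(key=lambda r: (r.allele_call, r.decomposition.variable_counts))
    return AlleleCall(locus.name, "called", tuple(records), source)


# ---------------------------------------------------------------------------
# paired-end consensus and profile assembly
# ---------------------------------------------------------------------------

def _calls_equal(a: AlleleCall, b: AlleleCall) -> bool:
    return a.variable_vectors() == b.variable_vectors()


def paired_end_consensus(call_r1: AlleleCall, call_r2: AlleleCall,
                         str_offset_r1: int | None = None,
                         str_offset_r2: int | None = None) -> AlleleCall:
    """Reconcile the two single-end calls for one locus.

    Equal calls agree trivially; when they differ, the end whose repeat
    region starts fewer bases from its own starting anchor is trusted
    (per-cycle error accumulation), with higher depth breaking offset ties
    and R1 breaking exact ties.  A single-ended ``no_data`` defers to the
    other end; offsets default to the observed prefix length (R1) and
    suffix length (R2) of the top call.
    """
    if not call_r1.called and not call_r2.called:
        return no_data(call_r1.locus, "consensus")
    if not call_r1.called:
        return call_r2
    if not call_r2.called:
        return call_r1
    if _calls_equal(call_r1, call_r2):
        best = call_r1 if call_r1.supporting_reads >= call_r2.supporting_reads else call_r2
        return AlleleCall(best.locus, "called", best.calls, "consensus")
    if str_offset_r1 is None:
        str_offset_r1 = len(call_r1.calls[0].decomposition.prefix)
    if str_offset_r2 is None:
        str_offset_r2 = len(call_r2.calls[0].decomposition.suffix)
    if str_offset_r1 != str_offset_r2:
        return call_r1 if str_offset_r1 < str_offset_r2 else call_r2
    if call_r1.supporting_reads != call_r2.supporting_reads:
        return call_r1 if call_r1.supporting_reads > call_r2.supporting_reads else call_r2
    return call_r1


@dataclass
class HaplotypeProfile:
    """A sample's full Y-STR haplotype (one entry per panel locus)."""

    sample: str
    calls: dict[str, AlleleCall] = field(default_factory=dict)

    @property
    def n_called(self) -> int:
        return sum(1 for c in self.calls.values() if c.called)

    @property
    def n_no_data(self) -> int:
        return len(self.calls) - self.n_called


def assemble_profile(sample: str, per_locus_calls: dict, loci) -> HaplotypeProfile:
    calls = {}
    for lc in loci:
        calls[lc.name] = per_locus_calls.get(lc.name) or no_data(lc.name, "consensus")
    return HaplotypeProfile(sample, calls)


def call_sample(r1, r2, loci, min_reads: int = 10, min_anchor_match: int = 1,
                stutter_thresholds=None, sample: str = "sample") -> HaplotypeProfile:
    """End-to-end convenience: FASTQ pair -> per-end calls -> consensus profile."""
    tables, _ = tabulate_sequences(r1, r2, loci, min_anchor_match)
    per_locus = {}
    for lc in loci:
        c1 = call_locus(tables.get("R1", {}).get(lc.name, []), lc, min_reads,
                        stutter_thresholds, source="R1")
        c2 = call_locus(tables.get("R2", {}).get(lc.name, []), lc, min_reads,
                        stutter_thresholds, source="R2")
        per_locus[lc.name] = paired_end_consensus(c1, c2)
    return assemble_profile(sample, per_locus, loci)


# ---------------------------------------------------------------------------
# profile I/O
# ---------------------------------------------------------------------------

_BLOCK_RE = re.compile(r"([ACGT]+)\[(\d+)\]")


def write_profile_csv(profile: HaplotypeProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus,status,calls,decomposition,variants\n")
        for locus, call in profile.calls.items():
            if not call.called:
                fh.write(f"{locus},no_data,,,\n")
                continue
            alleles = ";".join(str(a) for a in call.allele_calls)
            decs = ";".join(str(cr.decomposition) for cr in call.calls)
            var = ";".join("/".join(cr.decomposition.variants) for cr in call.calls)
            fh.write(f"{locus},called,{alleles},{decs},{var}\n")


def read_profile_csv(path, loci, sample: str = "sample") -> HaplotypeProfile:
    by_name = {lc.name: lc for lc in loci}
    calls: dict[str, AlleleCall] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            fields = line.rstrip("\n").split(",")
            locus, status = fields[0], fields[1]
            lc = by_name.get(locus)
            if lc is None:
                continue
            if status != "called":
                calls[locus] = no_data(locus, "consensus")
                continue
            records = []
            for dec_str in fields[3].split(";"):
                pre, blocks_str, suf = dec_str.split("|")
                parsed = _BLOCK_RE.findall(blocks_str)
                blk = tuple((m, int(c)) for m, c in parsed)
                var_counts = tuple(
                    c for (m, c), b in zip(blk, lc.blocks) if b.variable)
                dec = RepeatDecomposition(pre, blk, suf, var_counts, ())
                records.append(CallRecord(dec.allele_call, dec, 0))
            calls[locus] = AlleleCall(locus, "called", tuple(records), "consensus")
    return assemble_profile(sample, calls, loci)
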