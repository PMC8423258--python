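"""Threshold-based Y-SNP calling and haplogroup assignment.

Y-SNPs are bi-allelic; the derived state marks membership of a phylogenetic
branch.  Calling is deliberately simple and conservative: per SNP, count
quality-passing bases over anchored amplicon reads, then accept a call only
with at least ``min_reads`` coverage (default 10) and a ``min_fraction``
majority (default 90%) for the majority base — the thresholds under which
deep subhaplogroup assignment is reliable on haploid data.

The terminal haplogroup is the deepest tree node supported by a derived
call whose root path is not contradicted (a node is contradicted when its
ancestral calls outnumber its derived calls); SNPs with an unknown
phylogenetic position are reported but never steer the assignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .panel import ANCHOR_LEN, HaplogroupTree, ROOT, SnpDef, hamming, revcomp, snp_amplicon_context


@dataclass(frozen=True)
class SnpCall:
    name: str
    state: str              # ancestral | derived | no_call
    depth: int = 0          # quality-passing bases at the SNP position
    majority_fraction: float = 0.0
    haplogroup: str = "unknown"


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def _iter_fastq(source):
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        from Bio import SeqIO
        for rec in SeqIO.parse(str(source), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            yield str(rec.seq), quals
    else:
        yield from source


def pileup_snps(r1, r2, snps, min_base_quality: int = 20,
                min_anchor_match: int = 1, flank: int = 30):
    """Per-SNP base counts from anchored amplicon reads.

    Each SNP's amplicon context is the deterministic synthetic flanking
    sequence around its coordinate (see
    :func:`ypanel.panel.snp_amplicon_context`); the first 15 bp anchor the
    read in either orientation.  Bases with quality below ``min_base_quality``
    (default Q20) are excluded; reads not covering the SNP offset count as
    uncovered.  Returns ``{snp_name: Counter(base -> count)}``.
    """
    snps = list(snps)
    meta = {}
    exact: dict[str, tuple[SnpDef, str]] = {}
    for snp in snps:
        left, right = snp_amplicon_context(snp, flank)
        amp_len = len(left) + 1 + len(right)
        meta[snp.name] = (left[:ANCHOR_LEN], len(left), amp_len)
        exact[left[:ANCHOR_LEN]] = (snp, "+")
        # reverse-orientation reads start with the reverse complement of the
        # amplicon's 3' end
        tail = (left + "N" + right)[-ANCHOR_LEN:]
        if "N" not in tail:
            exact[revcomp(tail)] = (snp, "-")

    def assign(read: str):
        head = read[:ANCHOR_LEN]
        if head in exact:
            return exact[head]
        if min_anchor_match > 0:
            for key, hit in exact.items():
                if hamming(head, key) <= min_anchor_match:
                    return hit
        return None

    counts: dict[str, Counter] = {snp.name: Counter() for snp in snps}
    for source in (r1, r2):
        if source is None:
            continue
        for seq, quals in _iter_fastq(source):
            hit = assign(seq)
            if hit is None:
                continue
            snp, orient = hit
            _, offset, amp_len = meta[snp.name]
            if orient == "+":
                idx = offset
            else:
                # read starts at the amplicon's far end
                idx = (amp_len - 1 - offset)
            if idx >= len(seq):
                continue  # SNP position not covered by this read
            if quals[idx] < min_base_quality:
                continue
            base = seq[idx] if orient == "+" else revcomp(seq[idx])
            counts[snp.name][base] += 1
    return counts


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_snp(base_counts: Counter, snp: SnpDef, min_reads: int = 10,
             min_fraction: float = 0.90) -> SnpCall:
    """Call one SNP from its quality-passing base counts.

    ``no_call`` when coverage is below ``min_reads``, the majority fraction
    is below ``min_fraction``, or the majority base is neither the ancestral
    nor the derived allele.
    """
    depth = sum(base_counts.values())
    if depth == 0:
        return SnpCall(snp.name, "no_call", 0, 0.0, snp.haplogroup)
    base, n = max(base_counts.items(), key=lambda kv: (kv[1], kv[0]))
    frac = n / depth
    if depth < min_reads or frac < min_fraction:
        return SnpCall(snp.name, "no_call", depth, frac, snp.haplogroup)
    if base == snp.derived:
        state = "derived"
    elif base == snp.ancestral:
        state = "ancestral"
    else:
        state = "no_call"
    return SnpCall(snp.name, state, depth, frac, snp.haplogroup)


def call_snps(pileup: dict, snps, min_reads: int = 10,
              min_fraction: float = 0.90) -> list[SnpCall]:
    return [call_snp(pileup.get(s.name, Counter()), s, min_reads, min_fraction)
            for s in snps]


# ---------------------------------------------------------------------------
# haplogroup assignment
# ---------------------------------------------------------------------------

@dataclass
class HaplogroupAssignment:
    terminal: str                     # haplogroup label, or ROOT when unresolved
    depth: int = 0
    resolved: bool = False
    supporting: list[str] = field(default_factory=list)   # derived SNPs on the path
    conflicting: list[str] = field(default_factory=list)  # ancestral calls on the path


def assign_haplogroup(snp_calls, tree: HaplogroupTree, snp_defs=None) -> HaplogroupAssignment:
    """Deepest-subhaplogroup assignment on the tree.

    The terminal node is the deepest node with at least one derived call
    whose root path contains no contradicted node (ancestral calls
    outnumbering derived calls there).  Ties prefer more supporting derived
    SNPs along the path, then the lexicographically smaller label.  SNPs
    whose haplogroup is unknown or absent from the tree never influence the
    result.  All-ancestral data yields an unresolved root-level assignment.
    """
    derived_at: dict[str, list[str]] = {}
    ancestral_at: dict[str, list[str]] = {}
    for call in snp_calls:
        label = call.haplogroup
        if label == "unknown" or label not in tree.nodes:
            continue
        if call.state == "derived":
            derived_at.setdefault(label, []).append(call.name)
        elif call.state == "ancestral":
            ancestral_at.setdefault(label, []).append(call.name)

    def contradicted(node: str) -> bool:
        return len(ancestral_at.get(node, ())) > len(derived_at.get(node, ()))

    best: tuple | None = None
    for node in derived_at:
        path = tree.path(node)
        if any(contradicted(n) for n in path):
            continue
        support = [s for n in path for s in derived_at.get(n, ())]
        key = (tree.depth(node), len(support))
        if best is None or key > best[0] or (key == best[0] and node < best[1]):
            best = (key, node, support,
                    [s for n in path for s in ancestral_at.get(n, ())])
    if best is None:
        return HaplogroupAssignment(ROOT, 0, False)
    _, node, support, conflicts = best
    return HaplogroupAssignment(node, tree.depth(node), True, support, conflicts)


def branch_depth_delta(assignment_a, assignment_b, tree: HaplogroupTree) -> int:
    """Signed branch-depth difference depth(a) - depth(b) on the same tree.

    Accepts assignments or plain labels; raises ``KeyError`` naming any
    label absent from the tree.
    """
    labels = []
    for a in (assignment_a, assignment_b):
        label = a.terminal if isinstance(a, HaplogroupAssignment) else a
        if label != ROOT and label not in tree.nodes:
            raise KeyError(f"label {label!r} not in haplogroup tree")
        labels.append(label)
    return tree.depth(labels[0]) - tree.depth(labels[1])


def write_snp_calls(calls, snps, path) -> None:
    """Per-sample TSV: name, position, state, depth, fraction, haplogroup."""
    pos = {s.name: s.position for s in snps}
    with open(path, "w") as fh:
        fh.write("name\tposition\tstate\tdepth\tfraction\thaplogroup\n")
        for c in calls:
            fh.write(f"{c.name}\t{pos.get(c.name, '')}\t{c.state}\t"
                     f"{c.depth}\t{c.majority_fraction:.3f}\t{c.haplogroup}\n")
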