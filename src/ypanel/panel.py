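"""Panel data model and file I/O.

A targeted chrY amplicon panel is described by three plain-text tables:

* a **panel config** (TSV) with one row per Y-STR locus: 15-bp anchor
  sequences, reference flanking sequences (prefix/suffix) and the repeat
  structure written as ``+``-joined blocks — ``MOTIF[min-max:ref]`` for a
  variable repeat, ``MOTIF[k]`` for a fixed repeat stretch and ``N[k]:SEQ``
  for a fixed interruption of ``k`` bp;
* a **positions file** (TSV) mapping hg19 chrY coordinates to Y-SNP names,
  ancestral->derived bases and haplogroup labels;
* a **pair table** (CSV) of sample pairs with the number of meioses
  separating them.

Haplogroup labels follow the alternating letter/number lineage convention
(``R`` -> ``R1`` -> ``R1a`` -> ...); :class:`HaplogroupTree` derives the
phylogeny from those names, with an implicit root ``Y`` above the main
haplogroups A-T.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DNA = "ACGT"
ANCHOR_LEN = 15
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming: unequal lengths")
    return sum(x != y for x, y in zip(a, b))


class PanelError(ValueError):
    """Invalid panel definition (names the offending locus/line)."""


# ---------------------------------------------------------------------------
# Y-STR locus model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifBlock:
    """One block of a Y-STR repeat structure.

    A block is either a repeat stretch (``motif`` repeated ``ref_count``
    times in the reference, variable blocks between ``min_count`` and
    ``max_count``) or a fixed interruption (``variable=False``,
    ``ref_count=1`` and ``motif`` holding the full interruption sequence).
    Only variable blocks contribute to the allele call.
    """

    motif: str
    variable: bool
    ref_count: int
    min_count: int = 1
    max_count: int = 60
    interruption: bool = False

    @property
    def unit_len(self) -> int:
        return len(self.motif)

    def expand(self, count: int | None = None) -> str:
        return self.motif * (self.ref_count if count is None else count)

    def validate(self, where: str) -> None:
        if not self.motif or any(c not in DNA for c in self.motif):
            raise PanelError(f"{where}: motif {self.motif!r} is not plain ACGT")
        if self.ref_count < 1:
            raise PanelError(f"{where}: ref_count must be >= 1")
        if self.variable:
            if self.interruption:
                raise PanelError(f"{where}: interruption cannot be variable")
            if not 2 <= self.unit_len <= 6:
                raise PanelError(
                    f"{where}: variable motif unit length {self.unit_len} outside 2-6"
                )
            # repeat-inclusion rule: a variable stretch needs >=3 homogeneous
            # repetitions in the reference
            if self.ref_count < 3:
                raise PanelError(f"{where}: variable block needs ref_count >= 3")
            if not self.min_count <= self.ref_count <= self.max_count:
                raise PanelError(f"{where}: ref_count outside [min,max]")


_COPY_LABELS = "abcd"


@dataclass(frozen=True)
class StrLocusDef:
    """Full structural description of one Y-STR locus."""

    name: str
    copy_count: int
    chr_start: int
    chr_end: int
    anchor5: str
    anchor3: str
    prefix_ref: str
    suffix_ref: str
    blocks: tuple[MotifBlock, ...]
    distinguishable_copies: bool = False

    def __post_init__(self):
        if self.copy_count not in (1, 2, 4):
            raise PanelError(f"{self.name}: copy_count {self.copy_count} not in {{1,2,4}}")
        for which, a in (("anchor5", self.anchor5), ("anchor3", self.anchor3)):
            if len(a) != ANCHOR_LEN or any(c not in DNA for c in a):
                raise PanelError(f"{self.name}: {which} must be exactly {ANCHOR_LEN} bp ACGT")
        for fl in (self.prefix_ref, self.suffix_ref):
            if any(c not in DNA for c in fl):
                raise PanelError(f"{self.name}: flank contains non-ACGT base")
        if not 1 <= self.chr_start <= self.chr_end:
            raise PanelError(f"{self.name}: bad 1-based interval {self.chr_start}-{self.chr_end}")
        if not self.blocks:
            raise PanelError(f"{self.name}: no repeat blocks")
        for b in self.blocks:
            b.validate(self.name)

    @property
    def copy_labels(self) -> tuple[str, ...]:
        return tuple(_COPY_LABELS[: self.copy_count])

    @property
    def variable_blocks(self) -> tuple[MotifBlock, ...]:
        return tuple(b for b in self.blocks if b.variable)

    @property
    def repeat_type(self) -> str:
        """simple / compound / complex, per the usual STR nomenclature."""
        if any(b.interruption for b in self.blocks):
            return "complex"
        return "simple" if len(self.blocks) == 1 else "compound"

    @property
    def min_unit_len(self) -> int:
        """Shortest variable motif; dinucleotides dominate the stutter ladder."""
        vb = self.variable_blocks
        return min((b.unit_len for b in vb), default=self.blocks[0].unit_len)

    def ref_variable_counts(self) -> tuple[int, ...]:
        return tuple(b.ref_count for b in self.variable_blocks)

    def reference_repeat(self, variable_counts: tuple[int, ...] | None = None) -> str:
        """Repeat region sequence for the given variable-block counts."""
        counts = iter(variable_counts or self.ref_variable_counts())
        parts = []
        for b in self.blocks:
            parts.append(b.expand(next(counts) if b.variable else None))
        return "".join(parts)

    def amplicon(self, variable_counts: tuple[int, ...] | None = None) -> str:
        return (
            self.anchor5 + self.prefix_ref
            + self.reference_repeat(variable_counts)
            + self.suffix_ref + self.anchor3
        )

    def structure_string(self) -> str:
        toks = []
        for b in self.blocks:
            if b.interruption:
                toks.append(f"N[{len(b.motif)}]:{b.motif}")
            elif b.variable:
                toks.append(f"{b.motif}[{b.min_count}-{b.max_count}:{b.ref_count}]")
            else:
                toks.append(f"{b.motif}[{b.ref_count}]")
        return "+".join(toks)


_VAR_RE = re.compile(r"^([ACGT]+)\[(\d+)-(\d+):(\d+)\]$")
_FIX_RE = re.compile(r"^([ACGT]+)\[(\d+)\]$")
_INT_RE = re.compile(r"^N\[(\d+)\]:([ACGT]+)$")


def parse_structure(text: str, where: str = "?") -> tuple[MotifBlock, ...]:
    blocks = []
    for tok in text.split("+"):
        tok = tok.strip()
        if m := _INT_RE.match(tok):
            k, seq = int(m.group(1)), m.group(2)
            if len(seq) != k:
                raise PanelError(f"{where}: interruption N[{k}] has {len(seq)} bp sequence")
            blocks.append(MotifBlock(seq, variable=False, ref_count=1, interruption=True))
        elif m := _VAR_RE.match(tok):
            motif, lo, hi, ref = m.group(1), int(m.group(2)), int(m.group(3)), int(m.group(4))
            blocks.append(MotifBlock(motif, True, ref, min_count=lo, max_count=hi))
        elif m := _FIX_RE.match(tok):
            blocks.append(MotifBlock(m.group(1), False, int(m.group(2))))
        else:
            raise PanelError(f"{where}: unparseable structure token {tok!r}")
    return tuple(blocks)


_CONFIG_COLS = [
    "name", "copy_count", "chr_start", "chr_end", "anchor5", "anchor3",
    "prefix_ref", "suffix_ref", "structure", "flags",
]


def read_panel_config(path) -> list[StrLocusDef]:
    """Read the TSV panel config; validates every locus, rejects duplicates."""
    loci: list[StrLocusDef] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise PanelError(f"line {lineno}: expected >=9 tab-separated fields")
            flags = fields[9].split(",") if len(fields) > 9 and fields[9] else []
            try:
                locus = StrLocusDef(
                    name=fields[0],
                    copy_count=int(fields[1]),
                    chr_start=int(fields[2]),
                    chr_end=int(fields[3]),
                    anchor5=fields[4],
                    anchor3=fields[5],
                    prefix_ref=fields[6],
                    suffix_ref=fields[7],
                    blocks=parse_structure(fields[8], fields[0]),
                    distinguishable_copies="distinguishable" in flags,
                )
            except (PanelError, ValueError) as exc:
                raise PanelError(f"line {lineno} ({fields[0]}): {exc}") from exc
            if locus.name in seen:
                raise PanelError(f"line {lineno}: duplicate locus name {locus.name}")
            seen.add(locus.name)
            loci.append(locus)
    return loci


def write_panel_config(loci, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CONFIG_COLS) + "\n")
        for lc in loci:
            flags = "distinguishable" if lc.distinguishable_copies else ""
            fh.write("\t".join(map(str, [
                lc.name, lc.copy_count, lc.chr_start, lc.chr_end,
                lc.anchor5, lc.anchor3, lc.prefix_ref, lc.suffix_ref,
                lc.structure_string(), flags,
            ])) + "\n")


# ---------------------------------------------------------------------------
# Y-SNP model and positions-file filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpDef:
    """One bi-allelic Y-SNP; the first name is canonical, the rest aliases."""

    names: tuple[str, ...]
    position: int
    ancestral: str
    derived: str
    haplogroup: str = "unknown"
    private: bool = False

    def __post_init__(self):
        if self.ancestral == self.derived:
            raise PanelError(f"{self.name}: ancestral == derived")
        for b in (self.ancestral, self.derived):
            if len(b) != 1 or b not in DNA:
                raise PanelError(f"{self.name}: allele {b!r} is not a single ACGT base")

    @property
    def name(self) -> str:
        return self.names[0]


_MUT_RE = re.compile(r"^([A-Z-]+)\s*(?:->|→)\s*([A-Z-]+)$")


def _classify_row(mutation: str, flags: set[str]) -> str | None:
    """Rejection reason for one positions-file row, or None if it passes."""
    if "primer_region" in flags:
        return "primer_region"
    if "," in mutation or "/" in mutation:
        return "poly_allelic"
    m = _MUT_RE.match(mutation.strip())
    if m is None:
        return "unknown mutation"
    anc, der = m.groups()
    if len(anc) != 1 or len(der) != 1 or "-" in (anc, der):
        return "indel"
    if anc not in DNA or der not in DNA:
        return "unknown mutation"
    if anc == der:
        return "equal mutation"
    return None


def filter_snp_records(records: list[dict]) -> tuple[list[SnpDef], Counter]:
    """Apply the positions-file exclusion rules.

    Excludes SNPs flagged as lying in amplicon primer regions, with equal or
    unknown mutations (e.g. ``T->N``), indels and poly-allelic records, and
    counts exclusions by reason.  Rows sharing a position with identical
    alleles are merged (alias names onto one SNP); conflicting records at one
    position are rejected as poly-allelic.  The filter is idempotent.
    """
    report: Counter = Counter()
    by_pos: dict[int, list[dict]] = {}
    order: list[int] = []
    for rec in records:
        reason = _classify_row(rec["mutation"], set(rec.get("flags", ())))
        if reason is not None:
            report[reason] += 1
            continue
        pos = int(rec["position"])
        if pos not in by_pos:
            order.append(pos)
        by_pos.setdefault(pos, []).append(rec)
    snps = []
    for pos in order:
        group = by_pos[pos]
        alleles = {_MUT_RE.match(r["mutation"].strip()).groups() for r in group}
        if len(alleles) > 1:  # conflicting records at one coordinate
            report["poly_allelic"] += len(group)
            continue
        anc, der = alleles.pop()
        names: list[str] = []
        for r in group:
            names.extend(n for n in (r["name"], *r.get("aliases", ())) if n not in names)
        hgs = [r.get("haplogroup") or "unknown" for r in group]
        snps.append(SnpDef(
            names=tuple(names), position=pos, ancestral=anc, derived=der,
            haplogroup=next((h for h in hgs if h != "unknown"), "unknown"),
            private=any("private" in set(r.get("flags", ())) for r in group),
        ))
    return snps, report


def read_positions_file(path, strict: bool = False) -> tuple[list[SnpDef], Counter]:
    """Read the Y-SNP positions TSV and apply the exclusion filters.

    Columns: name, aliases (comma-joined), position, mutation ("A->G"),
    haplogroup, flags (comma-joined; recognised: primer_region, private).
    Malformed rows are counted under ``malformed`` unless ``strict``.
    """
    records = []
    malformed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                if strict:
                    raise PanelError(f"line {lineno}: expected >=4 fields")
                malformed += 1
                continue
            try:
                records.append({
                    "name": fields[0],
                    "aliases": [a for a in fields[1].split(",") if a],
                    "position": int(fields[2]),
                    "mutation": fields[3],
                    "haplogroup": fields[4] if len(fields) > 4 and fields[4] else "unknown",
                    "flags": [f for f in (fields[5].split(",") if len(fields) > 5 else []) if f],
                })
            except ValueError:
                if strict:
                    raise PanelError(f"line {lineno}: bad position field")
                malformed += 1
    snps, report = filter_snp_records(records)
    if malformed:
        report["malformed"] = malformed
    return snps, report


def write_positions_file(snps, path) -> None:
    with open(path, "w") as fh:
        fh.write("name\taliases\tposition\tmutation\thaplogroup\tflags\n")
        for s in snps:
            flags = "private" if s.private else ""
            fh.write(
                f"{s.name}\t{','.join(s.names[1:])}\t{s.position}\t"
                f"{s.ancestral}->{s.derived}\t{s.haplogroup}\t{flags}\n"
            )


# ---------------------------------------------------------------------------
# Haplogroup tree
# ---------------------------------------------------------------------------

ROOT = "Y"
_LABEL_RE = re.compile(r"^[A-T](\d+|[a-z]+)*$")
_SEG_RE = re.compile(r"^[A-T]|\d+|[a-z]+")


def lineage_segments(label: str) -> list[str]:
    """Split a lineage label into its alternating letter/number segments."""
    if not _LABEL_RE.match(label):
        raise PanelError(f"invalid haplogroup label {label!r}")
    segs, i = [], 0
    while i < len(label):
        m = _SEG_RE.match(label[i:])
        segs.append(m.group(0))
        i += len(m.group(0))
    return segs


def lineage_prefixes(label: str) -> list[str]:
    """All proper prefixes of a label at segment boundaries, shortest first."""
    segs = lineage_segments(label)
    return ["".join(segs[:k]) for k in range(1, len(segs))]


@dataclass
class HaplogroupTree:
    """Rooted tree of haplogroup labels.

    The implicit root ``Y`` sits above the main haplogroups (A-T), which have
    depth 1; every other node's depth is its parent's depth + 1.
    """

    parent: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self._depth: dict[str, int] = {ROOT: 0}
        # resolve depths iteratively (parents may appear in any order)
        pending = dict(self.parent)
        while pending:
            progressed = False
            for node, par in list(pending.items()):
                if par in self._depth:
                    self._depth[node] = self._depth[par] + 1
                    del pending[node]
                    progressed = True
            if not progressed:
                raise PanelError(f"haplogroup tree has a cycle or orphan: {sorted(pending)}")

    @property
    def nodes(self) -> set[str]:
        return set(self.parent)

    def depth(self, label: str) -> int:
        return self._depth[label]

    def path(self, label: str) -> list[str]:
        """Nodes from the main haplogroup down to ``label`` (root Y excluded)."""
        out = []
        while label != ROOT:
            out.append(label)
            label = self.parent[label]
        return out[::-1]

    def is_ancestor_or_self(self, anc: str, label: str) -> bool:
        return anc == ROOT or anc in self.path(label)

    @classmethod
    def from_parent_table(cls, parent: dict[str, str]) -> "HaplogroupTree":
        return cls(dict(parent))

    @classmethod
    def from_labels(cls, labels, include_prefix_closure: bool = False) -> "HaplogroupTree":
        """Derive the tree from lineage names.

        A node's parent is its longest proper-prefix label present in the set;
        main-haplogroup letters hang off the implicit root.  A label whose
        main letter is absent from the set cannot be placed and is an error.
        """
        labels = set(labels)
        if include_prefix_closure:
            for lab in list(labels):
                labels.update(lineage_prefixes(lab))
        parent = {}
        for lab in sorted(labels):
            prefixes = lineage_prefixes(lab)
            present = [p for p in prefixes if p in labels]
            if present:
                parent[lab] = present[-1]
            elif not prefixes:  # main-haplogroup letter
                parent[lab] = ROOT
            else:
                raise PanelError(
                    f"label {lab!r} has no resolvable parent (main haplogroup "
                    f"{prefixes[0]!r} missing from the set)"
                )
        return cls(parent)


def build_tree(snp_defs=None, labels=None, parent_table=None,
               include_prefix_closure: bool = False) -> HaplogroupTree:
    """Build the haplogroup tree from SNP definitions, labels or an explicit
    parent table (which overrides name-derived parentage)."""
    if parent_table is not None:
        return HaplogroupTree.from_parent_table(parent_table)
    if labels is None:
        labels = {s.haplogroup for s in snp_defs if s.haplogroup != "unknown"}
    return HaplogroupTree.from_labels(labels, include_prefix_closure)


# ---------------------------------------------------------------------------
# Pair table / synthetic SNP amplicon context
# ---------------------------------------------------------------------------

def read_pair_table(path) -> pd.DataFrame:
    """CSV of sample_a, sample_b, meioses (optional: relationship)."""
    df = pd.read_csv(path)
    required = {"sample_a", "sample_b", "meioses"}
    if not required <= set(df.columns):
        raise PanelError(f"pair table must have columns {sorted(required)}")
    if (df["meioses"] < 1).any():
        bad = df[df["meioses"] < 1].index[0]
        raise PanelError(f"pair table row {bad}: meioses must be >= 1")
    return df


def snp_amplicon_context(snp: SnpDef, flank: int = 30) -> tuple[str, str]:
    """Deterministic synthetic flanking context for one SNP amplicon.

    The positions file carries no sequence, so both the simulator and the
    pileup derive the same surrogate reference context from the SNP's hg19
    position (a seeded draw standing in for the genome sequence).  The first
    15 bp of the left context double as the amplicon's anchor.
    """
    rng = np.random.default_rng((snp.position * 2654435761) % (2**31 - 1))
    bases = rng.integers(0, 4, size=2 * flank)
    seq = "".join(DNA[b] for b in bases)
    return seq[:flank], seq[flank:]
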