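"""Shared fixtures: a small hand-built panel, a haplogroup tree and helpers."""

import numpy as np
import pytest
from hypothesis import settings

from ypanel.panel import HaplogroupTree, MotifBlock, SnpDef, StrLocusDef, build_tree
from ypanel.str_caller import (AlleleCall, CallRecord, HaplotypeProfile,
                               RepeatDecomposition)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_locus(name, blocks, copy_count=1, prefix="TTCAGGT", suffix="CTTCAGG",
               anchor5="GATTACAGATTACAG", anchor3="CTGACCTGACCTGAC"):
    return StrLocusDef(
        name=name, copy_count=copy_count, chr_start=1_000_000,
        chr_end=1_000_400, anchor5=anchor5, anchor3=anchor3,
        prefix_ref=prefix, suffix_ref=suffix, blocks=tuple(blocks))


@pytest.fixture(scope="session")
def compound_locus():
    """DYS463-style double variable repeat (AAAGG[n]AAGGG[n])."""
    return make_locus(
        "CMP1",
        [MotifBlock("AAAGG", True, 7, min_count=3, max_count=30),
         MotifBlock("AAGGG", True, 15, min_count=3, max_count=30)],
        anchor5="ACGTTGCAACGGTTA", anchor3="TTGGCCAATTGGCAC")


@pytest.fixture(scope="session")
def di_locus():
    """Single-copy dinucleotide, the most stutter-prone class."""
    return make_locus(
        "DIN1", [MotifBlock("AC", True, 19, min_count=3, max_count=40)],
        prefix="TTGGTTCTT", suffix="GTTCAGGTT",
        anchor5="CCAATTGGACGTACA", anchor3="GGTTAACCGGTTAAC")


@pytest.fixture(scope="session")
def ycaii_locus():
    """Two-copy indistinguishable dinucleotide (YCAII-ab style)."""
    return make_locus(
        "MCD1-ab", [MotifBlock("CA", True, 21, min_count=3, max_count=40)],
        copy_count=2, prefix="TGGATTCGT", suffix="TGTTGGATG",
        anchor5="TTACGGATCCATGCA", anchor3="CAGGTTACGATCCGT")


@pytest.fixture(scope="session")
def tetra_locus():
    return make_locus(
        "TET1", [MotifBlock("AGAT", True, 11, min_count=3, max_count=30)],
        prefix="CCTTGGAACT", suffix="CTTGCCAGTT",
        anchor5="GGCATCATTGACCAT", anchor3="ACCTGGTCAGTTACA")


@pytest.fixture(scope="session")
def complex_locus():
    """Interrupted repeat (DYS19 style: TATC[n] N4 TATC[n])."""
    return make_locus(
        "CPX1",
        [MotifBlock("TATC", True, 11, min_count=3, max_count=30),
         MotifBlock("GGTT", False, 1, interruption=True),
         MotifBlock("TATC", True, 3, min_count=3, max_count=30)],
        prefix="GATTGCCAT", suffix="GGAACCTGA",
        anchor5="TACCATGGATTCACG", anchor3="CGTTAGGCATCCATG")


@pytest.fixture(scope="session")
def small_panel(compound_locus, di_locus, ycaii_locus, tetra_locus, complex_locus):
    return [compound_locus, di_locus, ycaii_locus, tetra_locus, complex_locus]


@pytest.fixture(scope="session")
def tree_labels():
    return {"R", "R1", "R1a", "R1a1", "R1a1a", "R1b", "J", "J1", "J2",
            "J2a", "E", "E1", "E1b", "I", "I1", "I2"}


@pytest.fixture(scope="session")
def tree(tree_labels):
    return build_tree(labels=tree_labels)


@pytest.fixture(scope="session")
def snp_set(tree_labels):
    """One synthetic SNP per haplogroup label, deterministic alleles."""
    rng = np.random.default_rng(7)
    from ypanel.simulate import random_positions
    return random_positions(tree_labels, rng)


def profile_from_genotype(genotype, loci, name="sample"):
    """True-genotype profile, bypassing read simulation (calls sorted)."""
    calls = {}
    for lc in loci:
        recs = []
        for vec in sorted(genotype[lc.name]):
            dec = RepeatDecomposition(
                lc.prefix_ref,
                tuple((b.motif, c) for b, c in _pair_blocks(lc, vec)),
                lc.suffix_ref, tuple(vec), ())
            recs.append(CallRecord(sum(vec), dec, 1))
        calls[lc.name] = AlleleCall(lc.name, "called", tuple(recs), "consensus")
    return HaplotypeProfile(name, calls)


def _pair_blocks(locus, variable_counts):
    it = iter(variable_counts)
    for b in locus.blocks:
        yield b, (next(it) if b.variable else b.ref_count)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
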