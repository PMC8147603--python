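"""Repeat-structure typing of the honey bee COI-COII intergenic region.

The region between the tRNA-leu and COII genes carries a variable cassette
of non-coding tandem elements.  Its composition separates the major
maternal lineages of *Apis mellifera*: a single Q and no P-type element
marks the Southeast-European C-lineage, while A- and M-lineage bees carry
one P-type element (the long variant P0 in the African A-lineage, the
shortened P in the West/North-European M-lineage) followed by one to three
Q copies.

This module detects the elements by semi-global alignment of consensus
sequences against each sample, concatenates the hits into a structure
string such as ``"P0QQ"``, maps the string to a lineage call, and offers
the classic DraI in-silico digest alongside exact haplotype collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from Bio import Align, SeqIO

from .io_formats import MtSequence

__all__ = [
    "ElementLibrary",
    "ElementHit",
    "RepeatAnnotation",
    "StructureLabel",
    "Haplotype",
    "HaplotypeSet",
    "default_library",
    "detect_elements",
    "classify_structure",
    "assign_lineage",
    "type_sequence",
    "in_silico_dra1",
    "call_haplotypes",
    "exact_haplotype_groups",
]

#: element names eligible for detection (flanks are generator scaffolding)
DETECTABLE = ("P0", "P", "Q")

LINEAGES = ("A", "C", "M")


@dataclass(frozen=True)
class ElementLibrary:
    """Named consensus sequences for the repeat elements and flanks.

    ``elements`` must contain P, P0 and Q; ``flanks`` the tRNA-leu and COII
    stubs used by the sequence generator.  Defaults ship with the package
    and can be overridden from any FASTA via :meth:`from_fasta`.
    """

    elements: dict
    flanks: dict

    def __post_init__(self):
        for name, seq in {**self.elements, **self.flanks}.items():
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"element {name!r} is empty or not plain DNA")
        missing = set(DETECTABLE) - set(self.elements)
        if missing:
            raise ValueError(f"element library missing {sorted(missing)}")

    @classmethod
    def from_fasta(cls, path) -> "ElementLibrary":
        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate element name {rec.id!r}")
            seqs[rec.id] = str(rec.seq).upper()
        elements = {k: v for k, v in seqs.items() if k in DETECTABLE}
        flanks = {k: v for k, v in seqs.items() if k not in DETECTABLE}
        return cls(elements=elements, flanks=flanks)

    @property
    def min_element_length(self) -> int:
        return min(len(s) for s in self.elements.values())


def default_library() -> ElementLibrary:
    """The packaged consensus library (synthetic, user-overridable)."""
    ref = resources.files("beemito.data").joinpath("elements.fasta")
    with resources.as_file(ref) as path:
        return ElementLibrary.from_fasta(path)


@dataclass(frozen=True)
class ElementHit:
    """One detected element: 0-based half-open span on the input sequence."""

    name: str
    start: int
    end: int
    identity: float


@dataclass
class RepeatAnnotation:
    """Ordered, non-overlapping element hits for one sample."""

    sample_id: str
    hits: list

    def __post_init__(self):
        self.hits = sorted(self.hits, key=lambda h: h.start)
        for a, b in zip(self.hits, self.hits[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.sample_id}: overlapping hits {a} / {b}")
        for h in self.hits:
            if not 0.0 <= h.identity <= 1.0:
                raise ValueError(f"identity out of [0,1]: {h}")


@dataclass(frozen=True)
class StructureLabel:
    """Structure string over {P, P0, Q} and the lineage it implies."""

    structure: str
    lineage: str


def _make_aligner() -> Align.PairwiseAligner:
    # semi-global: consensus (query) fully aligned, free end gaps on the target
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aligner.end_deletion_score = 0  # unaligned target flanks cost nothing
    return aligner


def _best_placement(aligner, target: str, query: str):
    """Best semi-global placement of query within target.

    Returns (score, start, end, identity) with identity = matches /
    alignment columns over the query-spanning region, or None if the
    target is shorter than the query.
    """
    if len(target) < len(query) or not target:
        return None
    aln = aligner.align(target, query)[0]
    trow, qrow = str(aln[0]), str(aln[1])
    i0, i1 = 0, len(qrow)
    while i0 < i1 and qrow[i0] == "-":
        i0 += 1
    while i1 > i0 and qrow[i1 - 1] == "-":
        i1 -= 1
    cols = i1 - i0
    if cols == 0:
        return None
    matches = sum(1 for a, b in zip(trow[i0:i1], qrow[i0:i1]) if a == b and a != "-")
    start = sum(1 for c in trow[:i0] if c != "-")
    end = start + sum(1 for c in trow[i0:i1] if c != "-")
    return aln.score, start, end, matches / cols


def detect_elements(
    seq: str,
    lib: Optional[ElementLibrary] = None,
    min_identity: float = 0.8,
) -> RepeatAnnotation:
    """Greedy detection of P/P0/Q elements in one ungapped sequence.

    Each consensus is aligned semi-globally into every still-unclaimed
    interval; the best-scoring hit at or above ``min_identity`` is accepted,
    its span masked, and the search repeats until nothing qualifies.  P and
    P0 compete for the same locus, so the higher-identity variant wins by
    construction.  A sequence shorter than every consensus yields an empty
    annotation.
    """
    if not 0.5 < min_identity <= 1.0:
        raise ValueError("min_identity must be in (0.5, 1]")
    lib = lib or default_library()
    seq = seq.replace("-", "").upper()
    aligner = _make_aligner()

    free: list = [(0, len(seq))]  # unclaimed half-open intervals
    accepted: list = []
    while True:
        best = None
        for lo, hi in free:
            segment = seq[lo:hi]
            for name in DETECTABLE:
                placed = _best_placement(aligner, segment, lib.elements[name])
                if placed is None:
                    continue
                score, s, e, ident = placed
                if ident < min_identity:
                    continue
                cand = (score, ident, -(lo + s), name, lo + s, lo + e, lo, hi)
                if best is None or cand > best:
                    best = cand
        if best is None:
            break
        _, ident, _, name, s, e, lo, hi = best
        accepted.append(ElementHit(name, s, e, ident))
        free.remove((lo, hi))
        if s - lo >= 1:
            free.append((lo, s))
        if hi - e >= 1:
            free.append((e, hi))
    return RepeatAnnotation(sample_id="", hits=accepted)


def classify_structure(ann: RepeatAnnotation) -> str:
    """Concatenate detected element names in genomic order (e.g. ``"P0QQ"``)."""
    return "".join(h.name for h in ann.hits)


def assign_lineage(structure: str) -> str:
    """Map a structure string to its evolutionary lineage.

    ``Q`` → C; ``P0`` + 1..3 ``Q`` → A; ``P`` + 1..3 ``Q`` → M; anything
    else (including out-of-grammar strings passed through verbatim by
    :func:`classify_structure`) → ``"unknown"``.
    """
    if structure == "Q":
        return "C"
    for prefix, lineage in (("P0", "A"), ("P", "M")):
        if structure.startswith(prefix):
            tail = structure[len(prefix):]
            if tail and len(tail) <= 3 and set(tail) == {"Q"}:
                return lineage
    return "unknown"


def type_sequence(
    seq: MtSequence,
    lib: Optional[ElementLibrary] = None,
    min_identity: float = 0.8,
) -> tuple[RepeatAnnotation, StructureLabel]:
    """Detect elements and return annotation plus structure/lineage label."""
    ann = detect_elements(seq.ungapped, lib, min_identity)
    ann.sample_id = seq.sample_id
    structure = classify_structure(ann)
    return ann, StructureLabel(structure, assign_lineage(structure))


DRA1_SITE = "TTTAAA"
#: DraI cleaves TTT^AAA: offset of the cut within the recognition site
DRA1_CUT_OFFSET = 3


def in_silico_dra1(seq: str) -> list[int]:
    """Fragment lengths from an in-silico DraI digest (site TTT^AAA).

    Sites are consumed left to right; a site overlapping a previous cut no
    longer exists.  Fragment lengths always sum to the input length.
    """
    seq = seq.upper()
    cuts = []
    pos = 0
    while True:
        hit = seq.find(DRA1_SITE, pos)
        if hit < 0:
            break
        cuts.append(hit + DRA1_CUT_OFFSET)
        pos = hit + DRA1_CUT_OFFSET
    bounds = [0] + cuts + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


@dataclass(frozen=True)
class Haplotype:
    hap_id: str
    sequence: str
    count: int
    members: tuple


@dataclass
class HaplotypeSet:
    """Unique mitotypes with counts; ids H1..Hk by decreasing abundance."""

    haplotypes: list
    by_sample: dict = field(repr=False)

    @property
    def n_samples(self) -> int:
        return sum(h.count for h in self.haplotypes)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    def __getitem__(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.hap_id == hap_id:
                return h
        raise KeyError(hap_id)


def exact_haplotype_groups(seqs: Iterable[MtSequence]) -> dict:
    """Group samples by exact ungapped sequence identity.

    Unlike :func:`call_haplotypes` this accepts unaligned sequences of
    differing lengths (different lengths are simply different
    haplotypes), which is all the kin-deduplication filter needs.
    Returns sample_id -> group label ("G1".. by decreasing count).
    """
    groups: dict = {}
    first_seen: dict = {}
    for i, s in enumerate(seqs):
        key = s.ungapped.upper()
        groups.setdefault(key, []).append(s.sample_id)
        first_seen.setdefault(key, i)
    ordered = sorted(groups, key=lambda k: (-len(groups[k]), first_seen[k]))
    return {
        sid: f"G{i + 1}"
        for i, key in enumerate(ordered)
        for sid in groups[key]
    }


def call_haplotypes(seqs: Iterable[MtSequence]) -> HaplotypeSet:
    """Collapse sequences into unique mitotypes by exact identity.

    Comparison is case-insensitive and position-wise, so input must be
    aligned (or unaligned but identical-length); a length mismatch raises
    with instructions to align first.  Ids ``H1..Hk`` are assigned by
    decreasing count, ties broken by first appearance in the input.
    """
    seqs = list(seqs)
    if not seqs:
        return HaplotypeSet(haplotypes=[], by_sample={})
    lengths = {len(s.seq) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(
            "sequences differ in length; align them (e.g. with MAFFT) before "
            "haplotype collapsing"
        )
    groups: dict = {}
    first_seen: dict = {}
    for i, s in enumerate(seqs):
        key = s.seq.upper()
        groups.setdefault(key, []).append(s.sample_id)
        first_seen.setdefault(key, i)
    ordered = sorted(groups, key=lambda k: (-len(groups[k]), first_seen[k]))
    haplotypes = [
        Haplotype(f"H{i + 1}", key, len(groups[key]), tuple(groups[key]))
        for i, key in enumerate(ordered)
    ]
    by_sample = {sid: h.hap_id for h in haplotypes for sid in h.members}
    return HaplotypeSet(haplotypes=haplotypes, by_sample=by_sample)
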