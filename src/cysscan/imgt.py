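"""IMGT position model of immunoglobulin variable domains.

The IMGT unique numbering assigns every residue of an Ig V domain to a fixed
position in 1..128, so that structurally equivalent residues of different
domains (V_H, V_L, V_HH) share a number regardless of loop-length variation.
The scaffold alternates framework regions (FR1-FR4), which carry the nine
beta-strands of the Ig sandwich, with the hypervariable CDR loops.  The two
beta-sheets partition the strands as {A, B, D, E} and {C, C', C'', F, G};
the canonical intradomain disulfide joins Cys23 (strand B) to Cys104
(strand F) across the sheets.

This module holds the region / strand / sheet tables, classifies position
pairs by their sheet topology, and numbers arbitrary V-domain sequences by
template-based global alignment with IMGT CDR gapping rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "RegionDef",
    "StrandDef",
    "PairTopology",
    "ImgtNumberedSequence",
    "NumberingError",
    "REGIONS",
    "STRANDS",
    "SHEETS",
    "CANONICAL_PAIR",
    "VH_TEMPLATE",
    "region_of",
    "strand_of",
    "classify_pair",
    "number_sequence",
    "make_null_variant",
]

CANONICAL_PAIR = frozenset({23, 104})

#: Conserved anchor positions every usable numbering template must occupy:
#: 1st-CYS 23, CONSERVED-TRP 41, 2nd-CYS 104 and J-TRP/PHE 118.
ANCHOR_POSITIONS = (23, 41, 104, 118)


@dataclass(frozen=True)
class RegionDef:
    """An FR or CDR delimitation: an inclusive IMGT position interval."""

    name: str
    start: int
    end: int

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(range(self.start, self.end + 1))

    @property
    def is_cdr(self) -> bool:
        return self.name.startswith("CDR")


#: Standard IMGT delimitations for V domains.
REGIONS: tuple[RegionDef, ...] = (
    RegionDef("FR1", 1, 26),
    RegionDef("CDR1", 27, 38),
    RegionDef("FR2", 39, 55),
    RegionDef("CDR2", 56, 65),
    RegionDef("FR3", 66, 104),
    RegionDef("CDR3", 105, 117),
    RegionDef("FR4", 118, 128),
)


@dataclass(frozen=True)
class StrandDef:
    """A beta-strand: its ordered IMGT positions and which sheet it lies in."""

    name: str
    positions: tuple[int, ...]
    sheet: str  # "ABED" or "CC'C''FG"

    def __contains__(self, position: int) -> bool:
        return position in self.positions

    @property
    def size(self) -> int:
        return len(self.positions)


def _span(a: int, b: int) -> tuple[int, ...]:
    return tuple(range(a, b + 1))


#: The nine beta-strands of the Ig fold over framework positions.  Positions
#: 10 and 73 are universal gaps of the scheme and belong to no strand.
STRANDS: dict[str, StrandDef] = {
    s.name: s
    for s in (
        StrandDef("A", _span(1, 9) + _span(11, 15), "ABED"),
        StrandDef("B", _span(16, 26), "ABED"),
        StrandDef("C", _span(39, 46), "CC'C''FG"),
        StrandDef("C'", _span(47, 55), "CC'C''FG"),
        StrandDef("C''", _span(66, 72) + (74,), "CC'C''FG"),
        StrandDef("D", _span(75, 84), "ABED"),
        StrandDef("E", _span(85, 96), "ABED"),
        StrandDef("F", _span(97, 104), "CC'C''FG"),
        StrandDef("G", _span(118, 128), "CC'C''FG"),
    )
}

SHEETS: dict[str, tuple[str, ...]] = {
    "ABED": ("A", "B", "D", "E"),
    "CC'C''FG": ("C", "C'", "C''", "F", "G"),
}

_POSITION_TO_STRAND: dict[int, str] = {
    p: s.name for s in STRANDS.values() for p in s.positions
}


def region_of(position: int) -> str:
    """Name of the FR/CDR region containing an IMGT position."""
    if not 1 <= position <= 128:
        raise ValueError(f"IMGT position out of range 1-128: {position}")
    for region in REGIONS:
        if position in region:
            return region.name
    raise AssertionError("unreachable: regions cover 1-128")


def strand_of(position: int) -> str | None:
    """Beta-strand containing an IMGT position, or None for loop/gap positions."""
    if not 1 <= position <= 128:
        raise ValueError(f"IMGT position out of range 1-128: {position}")
    return _POSITION_TO_STRAND.get(position)


@dataclass(frozen=True)
class PairTopology:
    """Sheet topology of a position pair (order-free)."""

    p1: int
    p2: int
    strands: tuple[str | None, str | None]
    category: str  # canonical | intra_sheet | inter_sheet | same_strand | loop_involved

    @property
    def positions(self) -> frozenset[int]:
        return frozenset({self.p1, self.p2})


def classify_pair(p1: int, p2: int) -> PairTopology:
    """Classify a Cys position pair by strand/sheet topology.

    ``canonical`` is reserved for {23, 104}; ``intra_sheet`` / ``inter_sheet``
    require both positions on (distinct) strands of the same / different
    sheets; a pair within one strand is ``same_strand`` and a pair touching
    any non-strand position is ``loop_involved``.
    """
    if p1 == p2:
        raise ValueError("a Cys pair needs two distinct positions")
    for p in (p1, p2):
        if not 1 <= p <= 128:
            raise ValueError(f"IMGT position out of range 1-128: {p}")
    lo, hi = sorted((p1, p2))
    s1, s2 = strand_of(lo), strand_of(hi)
    if {lo, hi} == set(CANONICAL_PAIR):
        category = "canonical"
    elif s1 is None or s2 is None:
        category = "loop_involved"
    elif s1 == s2:
        category = "same_strand"
    elif STRANDS[s1].sheet == STRANDS[s2].sheet:
        category = "intra_sheet"
    else:
        category = "inter_sheet"
    return PairTopology(lo, hi, (s1, s2), category)


class NumberingError(ValueError):
    """A sequence could not be mapped onto the IMGT scheme.

    Carries an explicit record rather than permitting a silent partial
    mapping; consumers that tolerate failures (e.g. the repertoire census)
    catch this and account for the read.
    """

    def __init__(self, message: str, sequence: str = ""):
        super().__init__(message)
        self.record = {"reason": message, "sequence": sequence}


@dataclass(frozen=True)
class ImgtNumberedSequence:
    """A V-domain sequence mapped onto IMGT positions 1..128.

    ``mapping`` is position -> one-letter residue for occupied positions;
    absent positions (IMGT gaps, short loops, truncations) are simply
    missing keys.  ``provenance`` records how the mapping was obtained.
    """

    chain_type: str  # VH | VHH | VL
    raw: str
    mapping: dict[int, str]
    provenance: str = "unspecified"

    def __post_init__(self):
        if self.chain_type not in ("VH", "VHH", "VL"):
            raise ValueError(f"unknown chain type: {self.chain_type}")
        bad = [p for p in self.mapping if not 1 <= p <= 128]
        if bad:
            raise ValueError(f"mapping outside 1-128: {sorted(bad)}")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.mapping))

    def residue(self, position: int) -> str | None:
        return self.mapping.get(position)

    def to_sequence(self) -> str:
        """Render the occupied positions, in order, as a plain sequence."""
        return "".join(self.mapping[p] for p in self.positions)

    @property
    def has_canonical_pair(self) -> bool:
        """True when Cys occupies both positions 23 and 104."""
        return self.mapping.get(23) == "C" and self.mapping.get(104) == "C"

    def cys_positions(self) -> tuple[int, ...]:
        return tuple(p for p in self.positions if self.mapping[p] == "C")

    def substitute(self, replacements: dict[int, str], provenance: str | None = None
                   ) -> "ImgtNumberedSequence":
        """Return a copy with residues replaced at the given occupied positions."""
        missing = [p for p in replacements if p not in self.mapping]
        if missing:
            raise ValueError(f"cannot substitute unoccupied positions: {missing}")
        mapping = dict(self.mapping)
        mapping.update(replacements)
        new = replace(self, mapping=mapping,
                      provenance=provenance or self.provenance)
        # raw must stay consistent with the mapping render
        object.__setattr__(new, "raw", new.to_sequence())
        return new

    def to_table(self) -> pd.DataFrame:
        """Tab-friendly view: imgt_position, residue, region, strand."""
        rows = [
            {
                "imgt_position": p,
                "residue": self.mapping[p],
                "region": region_of(p),
                "strand": strand_of(p) or "",
            }
            for p in self.positions
        ]
        return pd.DataFrame(rows, columns=["imgt_position", "residue", "region", "strand"])


def _build_numbered(chain_type: str, mapping: dict[int, str], provenance: str
                    ) -> ImgtNumberedSequence:
    raw = "".join(mapping[p] for p in sorted(mapping))
    return ImgtNumberedSequence(chain_type, raw, dict(mapping), provenance)


# ---------------------------------------------------------------------------
# Built-in synthetic VH numbering template
# ---------------------------------------------------------------------------

def _make_vh_template() -> ImgtNumberedSequence:
    """Synthetic IMGT-complete VH-like template.

    Occupies every position 1..128 except the universal gaps 10 and 73, with
    the conserved anchors in place (Cys23, Trp41, Cys104, Trp118).  The FR
    segments follow a human VH3-family consensus flavour; the CDRs are
    filler at full IMGT capacity so that any shorter loop can be gapped
    against them.  Synthetic: not any individual germline gene.
    """
    segments = {
        # FR1, positions 1-26 with gap at 10
        tuple(list(range(1, 10)) + list(range(11, 27))): "EVQLVESGGGLVQPGGSLRLSCAAS",
        # CDR1 at capacity, 27-38
        tuple(range(27, 39)): "GFTFSSYSSSYA",
        # FR2, 39-55 (W41)
        tuple(range(39, 56)): "MSWVRQAPGKGLEWVSA",
        # CDR2 at capacity, 56-65
        tuple(range(56, 66)): "AISGSGGSTY",
        # FR3, 66-104 with gap at 73 (C104)
        tuple(list(range(66, 73)) + list(range(74, 105))): "YADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYYC",
        # CDR3 at capacity, 105-117
        tuple(range(105, 118)): "ARDGGYSSGWYDY",
        # FR4, 118-128 (W118)
        tuple(range(118, 129)): "WGQGTLVTVSS",
    }
    mapping: dict[int, str] = {}
    for positions, seq in segments.items():
        assert len(positions) == len(seq), (positions, seq)
        mapping.update(zip(positions, seq))
    return _build_numbered("VH", mapping, "built-in synthetic VH template")


VH_TEMPLATE: ImgtNumberedSequence = _make_vh_template()

_CDR_REGIONS = tuple(r for r in REGIONS if r.is_cdr)


def cdr_fill_positions(region: RegionDef, length: int) -> tuple[int, ...]:
    """IMGT positions occupied by a CDR of the given length.

    The scheme fills a loop from both ends toward the middle, putting the
    gaps at the loop apex: the first ceil(L/2) slots from the start and the
    last floor(L/2) slots from the end are occupied.
    """
    capacity = region.end - region.start + 1
    if not 0 <= length <= capacity:
        raise NumberingError(
            f"{region.name} length {length} exceeds capacity {capacity}")
    n_left = (length + 1) // 2
    n_right = length - n_left
    left = tuple(range(region.start, region.start + n_left))
    right = tuple(range(region.end - n_right + 1, region.end + 1))
    return left + right


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # cheap end gaps so N/C-terminal truncations do not distort the core
    aligner.open_end_gap_score = -2.0
    aligner.extend_end_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def number_sequence(seq: str, chain_type: str = "VH",
                    template: ImgtNumberedSequence | None = None,
                    ) -> ImgtNumberedSequence:
    """Number a V-domain amino-acid sequence against a numbered template.

    Global alignment (BLOSUM62, affine gaps) to the template transfers IMGT
    positions onto the query's framework residues; each CDR is then
    re-numbered wholesale from its observed length by the IMGT loop-gapping
    rule, so loop-length differences never depend on alignment detail.
    Insertions relative to the template inside an FR are refused — the
    scheme has no slots for them.

    Raises :class:`NumberingError` with an explicit record when the sequence
    cannot be anchored; never returns a silent partial mapping.
    """
    template = template or VH_TEMPLATE
    seq = str(seq).upper().replace("*", "")
    if not 90 <= len(seq) <= 140:
        raise NumberingError(
            f"sequence length {len(seq)} outside the V-domain range 90-140", seq)
    missing_anchors = [p for p in ANCHOR_POSITIONS if p not in template.mapping]
    if missing_anchors:
        raise ValueError(f"template lacks anchor positions {missing_anchors}")

    tseq = template.to_sequence()
    tpositions = template.positions  # template index -> IMGT position
    try:
        alignment = _ALIGNER.align(tseq, seq)[0]
    except Exception as exc:  # non-alphabet residues etc.
        raise NumberingError(f"alignment failed: {exc}", seq) from None

    # Transfer positions for residue-to-residue columns.
    mapping: dict[int, str] = {}
    query_position: dict[int, int] = {}  # query index -> IMGT position
    for (tstart, tend), (qstart, qend) in zip(*alignment.aligned):
        for ti, qi in zip(range(tstart, tend), range(qstart, qend)):
            pos = tpositions[ti]
            mapping[pos] = seq[qi]
            query_position[qi] = pos

    if 23 not in mapping or 104 not in mapping:
        raise NumberingError(
            "no anchor alignment: positions 23/104 could not be assigned", seq)

    # Re-number each CDR from its observed length: all query residues lying
    # between the last residue numbered before the loop and the first one
    # numbered after it belong to the loop.
    for region in _CDR_REGIONS:
        before = [qi for qi, p in query_position.items() if p < region.start]
        after = [qi for qi, p in query_position.items() if p > region.end]
        start_qi = max(before) + 1 if before else 0
        end_qi = min(after) - 1 if after else len(seq) - 1
        loop = seq[start_qi:end_qi + 1]
        for p in region.positions:
            mapping.pop(p, None)
        for qi in range(start_qi, end_qi + 1):
            query_position.pop(qi, None)
        slots = cdr_fill_positions(region, len(loop))
        for offset, (slot, residue) in enumerate(zip(slots, loop)):
            mapping[slot] = residue
            query_position[start_qi + offset] = slot

    # Any query residue still unassigned is an FR insertion: refuse.
    unassigned = [qi for qi in range(len(seq)) if qi not in query_position]
    if unassigned:
        raise NumberingError(
            f"framework insertion(s) at query index(es) {unassigned}: "
            "the scheme has no slots for FR insertions", seq)

    numbered = ImgtNumberedSequence(
        chain_type, seq, mapping,
        provenance=f"aligned to template ({template.provenance})")
    assert numbered.to_sequence() == seq
    return numbered


def make_null_variant(ns: ImgtNumberedSequence) -> ImgtNumberedSequence:
    """Cys23Ala/Cys104Ala derivative abolishing the canonical disulfide.

    Refuses inputs that do not carry the canonical pair — "nulling" a domain
    whose 23/104 are not both Cys would silently change other residues'
    meaning.
    """
    if not ns.has_canonical_pair:
        raise ValueError(
            "canonical pair absent: positions 23/104 are not both Cys")
    return ns.substitute({23: "A", 104: "A"},
                         provenance=ns.provenance + " | C23A/C104A null")
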