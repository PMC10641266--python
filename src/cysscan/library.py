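"""Cys-pair scan library design and diversity accounting.

A scan library over a strand pair (X, Y) contains every mutant carrying one
Cys substitution in X and one in Y; its theoretical diversity is therefore
|X| x |Y|, and one Kunkel mutagenesis reaction is run per pair.  The study
configuration comprises 17 strand-pair libraries (7 putatively intra-sheet,
10 inter-sheet) over the nine framework beta-strands.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .imgt import STRANDS, ImgtNumberedSequence, StrandDef, classify_pair

__all__ = [
    "StrandPairLibrary",
    "LibrarySizeRecord",
    "MutagenicOligo",
    "DesignManifest",
    "CodingSequence",
    "STUDY_LIBRARIES",
    "KNOWN_PAIRS",
    "theoretical_diversity",
    "enumerate_pairs",
    "build_manifest",
    "design_oligos",
    "apply_oligos",
    "expected_copies",
]

#: Previously characterised linkages: the canonical pair plus the two known
#: stabilizing noncanonical linkages.  Libraries containing them (B-F, C-C',
#: C'-D) served as panning test libraries and were excluded from the pooled
#: selections; the pairs stay in enumeration but are flaggable.
KNOWN_PAIRS: tuple[frozenset[int], ...] = (
    frozenset({23, 104}),   # canonical, B-F
    frozenset({40, 55}),    # C-C'
    frozenset({54, 78}),    # C'-D
)

#: Study configuration: (strand1, strand2, functional library size).
#: Functional size = colony-forming units x fraction correctly mutagenized.
STUDY_LIBRARIES: tuple[tuple[str, str, float], ...] = (
    # inter-beta-sheet libraries
    ("A", "F", 5.1e3),
    ("A", "G", 4.5e3),
    ("B", "C", 6.3e3),
    ("B", "F", 1.9e4),
    ("C", "D", 1.8e4),
    ("C", "E", 8.3e3),
    ("C'", "D", 3.2e3),
    ("C'", "E", 9.5e3),
    ("C''", "D", 3.9e3),
    ("E", "F", 8.5e3),
    # intra-beta-sheet libraries
    ("A", "B", 1.9e4),
    ("B", "E", 1.8e4),
    ("C", "C'", 1.9e4),
    ("C", "F", 4.6e3),
    ("C'", "C''", 6.4e3),
    ("D", "E", 1.6e4),
    ("F", "G", 8.3e3),
)


@dataclass(frozen=True)
class LibrarySizeRecord:
    """Observed functional library size: cfu scaled by the correct fraction."""

    cfu: float
    fraction_correct: float

    def __post_init__(self):
        if not 0.0 <= self.fraction_correct <= 1.0:
            raise ValueError("fraction_correct must lie in [0, 1]")
        if self.cfu < 0:
            raise ValueError("cfu must be nonnegative")

    @property
    def functional_size(self) -> float:
        return self.cfu * self.fraction_correct


def _resolve(strand: str | StrandDef) -> StrandDef:
    if isinstance(strand, StrandDef):
        return strand
    try:
        return STRANDS[strand]
    except KeyError:
        raise ValueError(f"unknown strand name: {strand!r}") from None


def theoretical_diversity(sx: str | StrandDef, sy: str | StrandDef) -> int:
    """Number of Cys pair combinations between two distinct strands."""
    sx, sy = _resolve(sx), _resolve(sy)
    if sx.name == sy.name:
        raise ValueError("same-strand scanning is not part of the design")
    return sx.size * sy.size


def enumerate_pairs(sx: str | StrandDef, sy: str | StrandDef
                    ) -> list[tuple[int, int]]:
    """All position pairs of a strand-pair library, lexicographically ordered.

    Cartesian product of the strands' IMGT position sets, (x, y) with x from
    the first strand; its length equals :func:`theoretical_diversity`.
    """
    sx, sy = _resolve(sx), _resolve(sy)
    if sx.name == sy.name:
        raise ValueError("same-strand scanning is not part of the design")
    return list(itertools.product(sx.positions, sy.positions))


@dataclass(frozen=True)
class StrandPairLibrary:
    """One scan library: a strand pair with its enumerated Cys positions."""

    strands: tuple[StrandDef, StrandDef]
    library_size: float | None = None  # observed functional size, if known

    @property
    def name(self) -> str:
        return f"{self.strands[0].name}-{self.strands[1].name}"

    @property
    def category(self) -> str:
        """intra or inter, from the sheet membership of the two strands."""
        return "intra" if self.strands[0].sheet == self.strands[1].sheet else "inter"

    @property
    def theoretical_diversity(self) -> int:
        return theoretical_diversity(*self.strands)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return enumerate_pairs(*self.strands)

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(self.strands[0].positions) | frozenset(self.strands[1].positions)

    def contains_known_pair(self) -> bool:
        pair_sets = {frozenset(p) for p in self.pairs}
        return any(k in pair_sets for k in KNOWN_PAIRS)

    def expected_copies(self) -> float | None:
        if self.library_size is None:
            return None
        return expected_copies(self.library_size, self.theoretical_diversity)


@dataclass(frozen=True)
class DesignManifest:
    """The full library slate with per-library diversity accounting."""

    libraries: tuple[StrandPairLibrary, ...]

    def __len__(self) -> int:
        return len(self.libraries)

    def by_name(self, name: str) -> StrandPairLibrary:
        for lib in self.libraries:
            if lib.name == name:
                return lib
        raise KeyError(name)

    @property
    def total_reactions(self) -> int:
        """One mutagenesis reaction per enumerated pair, summed over libraries."""
        return sum(lib.theoretical_diversity for lib in self.libraries)

    def count_by_category(self) -> dict[str, int]:
        out = {"intra": 0, "inter": 0}
        for lib in self.libraries:
            out[lib.category] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lib in self.libraries:
            rows.append({
                "library": lib.name,
                "strand_1": lib.strands[0].name,
                "strand_2": lib.strands[1].name,
                "positions_1": ",".join(map(str, lib.strands[0].positions)),
                "positions_2": ",".join(map(str, lib.strands[1].positions)),
                "category": lib.category,
                "theoretical_diversity": lib.theoretical_diversity,
                "library_size": lib.library_size,
                "expected_copies_per_pair": lib.expected_copies(),
            })
        return pd.DataFrame(rows)


def build_manifest(config: list[tuple] | None = None) -> DesignManifest:
    """Build a manifest from (strand1, strand2[, library_size]) entries.

    With no argument, the 17-library study configuration is used.  Category
    (intra/inter) is assigned from the sheet partition, never configured.
    """
    if config is None:
        config = list(STUDY_LIBRARIES)
    libraries = []
    for entry in config:
        s1, s2, *rest = entry
        size = rest[0] if rest else None
        libraries.append(StrandPairLibrary((_resolve(s1), _resolve(s2)), size))
    return DesignManifest(tuple(libraries))


def expected_copies(functional_size: float, diversity: int) -> float:
    """Expected copies of each pair given the functional library size."""
    if diversity <= 0:
        raise ValueError("diversity must be positive")
    return functional_size / diversity


# ---------------------------------------------------------------------------
# Kunkel mutagenic oligonucleotide design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingSequence:
    """A numbered V-domain protein with its in-frame coding DNA."""

    protein: ImgtNumberedSequence
    dna: str

    def __post_init__(self):
        dna = self.dna.upper()
        object.__setattr__(self, "dna", dna)
        if len(dna) != 3 * len(self.protein.raw):
            raise ValueError("coding DNA length must be 3x the protein length")
        translated = str(Seq(dna).translate())
        if translated != self.protein.raw:
            raise ValueError("coding DNA does not translate to the protein")

    def codon_start(self, imgt_position: int) -> int:
        """Offset of the codon for an IMGT position on the coding strand."""
        positions = self.protein.positions
        try:
            index = positions.index(imgt_position)
        except ValueError:
            raise ValueError(
                f"IMGT position {imgt_position} is a gap in this template"
            ) from None
        return 3 * index

    def codon(self, imgt_position: int) -> str:
        start = self.codon_start(imgt_position)
        return self.dna[start:start + 3]


@dataclass(frozen=True)
class MutagenicOligo:
    """One Kunkel mutagenic oligo.

    ``dna`` is the oligo as synthesised: complementary to the displayed
    (coding) strand, as the chemistry anneals oligos to dU-ssDNA of the
    phage strand.  ``start``/``end`` delimit the replaced coding-strand
    window (half-open) so the design can be applied in silico.
    """

    targets: tuple[int, ...]      # one or two IMGT positions
    replacement_codon: str
    flank_length: int
    start: int
    end: int
    dna: str

    @property
    def coding_patch(self) -> str:
        """The coding-strand sequence this oligo writes."""
        return str(Seq(self.dna).reverse_complement())


def design_oligos(parent: CodingSequence, pair: tuple[int, int],
                  flank_length: int = 15, codon: str = "TGC",
                  contiguity_threshold: int = 60) -> list[MutagenicOligo]:
    """Design the mutagenic oligo(s) introducing a Cys pair into a parent.

    One oligo spans both targets when their codons start within
    ``contiguity_threshold`` nucleotides on the coding sequence (contiguous
    strands in primary sequence); otherwise two oligos are made, one per
    strand.  Flanks of ``flank_length`` nt of parent-matching sequence sit
    on each side for annealing.
    """
    if flank_length <= 0:
        raise ValueError("flank_length must be positive (oligos must anneal)")
    if len(set(pair)) != 2:
        raise ValueError("pair must name two distinct IMGT positions")
    codon = codon.upper()
    if str(Seq(codon).translate()) != "C":
        raise ValueError(f"replacement codon {codon} does not encode Cys")

    starts = sorted(parent.codon_start(p) for p in pair)  # raises inside gaps
    order = sorted(pair, key=parent.codon_start)
    dna = parent.dna

    def make(targets: tuple[int, ...], lo: int, hi: int) -> MutagenicOligo:
        start = max(0, lo - flank_length)
        end = min(len(dna), hi + flank_length)
        patch = list(dna[start:end])
        for p in targets:
            offset = parent.codon_start(p) - start
            patch[offset:offset + 3] = codon
        coding_patch = "".join(patch)
        return MutagenicOligo(
            targets=targets, replacement_codon=codon, flank_length=flank_length,
            start=start, end=end,
            dna=str(Seq(coding_patch).reverse_complement()))

    if starts[1] - starts[0] <= contiguity_threshold:
        return [make(tuple(order), starts[0], starts[1] + 3)]
    return [make((order[0],), starts[0], starts[0] + 3),
            make((order[1],), starts[1], starts[1] + 3)]


def apply_oligos(parent: CodingSequence, oligos: list[MutagenicOligo]
                 ) -> CodingSequence:
    """Apply mutagenic oligos in silico, returning the mutant coding sequence."""
    dna = parent.dna
    for oligo in sorted(oligos, key=lambda o: o.start, reverse=True):
        if dna[oligo.start:oligo.end] is None:
            raise ValueError("oligo window outside the parent")
        patch = oligo.coding_patch
        if len(patch) != oligo.end - oligo.start:
            raise ValueError("oligo patch length mismatch")
        dna = dna[:oligo.start] + patch + dna[oligo.end:]
    protein = str(Seq(dna).translate())
    targets = {p for o in oligos for p in o.targets}
    mapping = dict(zip(parent.protein.positions, protein))
    mutant = ImgtNumberedSequence(
        parent.protein.chain_type, protein, mapping,
        provenance=parent.protein.provenance + f" | mutagenized {sorted(targets)}")
    return CodingSequence(mutant, dna)
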