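"""Repertoire-wide noncanonical cysteine census.

Counts noncanonical Cys (any Cys outside the canonical 23/104 pair) across
an IMGT-numbered V_H repertoire: per-region frequencies, per-read Cys-count
histograms (whole-domain and FR-only), the subset of reads bearing >= 4
framework Cys residues (the canonical two included in the count), the
strand-pair co-occurrence of noncanonical FR Cys pairs within that subset,
and hit counts for query (e.g. engineered) pairs.

Positions 23 and 104 are disregarded in every noncanonical statistic.
Repertoire reads whose library preparation primer-forces the strand-A
N-terminus and strand-G C-terminus cannot report Cys there; a configurable
mask (on by default) suppresses those positions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .imgt import (CANONICAL_PAIR, ImgtNumberedSequence, NumberingError,
                   REGIONS, number_sequence, region_of, strand_of)

__all__ = [
    "RepertoireRead",
    "CysCensus",
    "DEFAULT_PRIMER_MASK",
    "census",
    "cooccurrence",
    "find_pairs",
]

#: Positions suppressed by default because amplification primers force the
#: template sequence there (strand-A N terminus, strand-G C terminus).
DEFAULT_PRIMER_MASK: frozenset[int] = frozenset({1, 2, 3, 126, 127, 128})

FR_NAMES = ("FR1", "FR2", "FR3", "FR4")
CDR_NAMES = ("CDR1", "CDR2", "CDR3")
REGION_NAMES = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


@dataclass(frozen=True)
class RepertoireRead:
    id: str
    numbered: ImgtNumberedSequence
    productive: bool = True


def _strand_bin(position: int) -> str:
    """Strand name, or 'FR-other' for framework positions off any strand."""
    return strand_of(position) or "FR-other"


@dataclass
class CysCensus:
    """Noncanonical Cys statistics over a numbered repertoire."""

    n_input: int
    n_counted: int                 # units entering the census (reads or unique)
    n_failed: int                  # reads that could not be numbered
    per_unique: bool
    mask: frozenset[int]
    region_frequency: dict[str, float]      # fraction of units with >=1 noncanonical Cys in region
    cys_count_hist_all: "pd.Series"         # whole-domain Cys count (23/104 excluded)
    cys_count_hist_fr: "pd.Series"          # FR-only noncanonical Cys count
    subset_4plus_ids: tuple[str, ...]       # units with >=4 FR Cys incl. 23/104
    _subset_noncanonical_fr: dict[str, tuple[int, ...]] = field(repr=False, default_factory=dict)

    @property
    def subset_4plus_count(self) -> int:
        return len(self.subset_4plus_ids)

    @property
    def subset_4plus_frequency(self) -> float:
        return self.subset_4plus_count / self.n_counted

    def to_frame(self) -> pd.DataFrame:
        rows = [{"region": r, "frequency": self.region_frequency[r]}
                for r in REGION_NAMES]
        return pd.DataFrame(rows)


def _noncanonical_cys(ns: ImgtNumberedSequence, mask: frozenset[int]
                      ) -> tuple[int, ...]:
    return tuple(p for p in ns.cys_positions()
                 if p not in CANONICAL_PAIR and p not in mask)


def _fr_cys_total(ns: ImgtNumberedSequence, mask: frozenset[int]) -> int:
    """All framework Cys including the canonical pair, mask applied."""
    return sum(1 for p in ns.cys_positions()
               if region_of(p).startswith("FR") and p not in mask)


def census(reads, per_unique: bool = True,
           mask: frozenset[int] | None = DEFAULT_PRIMER_MASK,
           chain_type: str = "VH", template=None) -> CysCensus:
    """Run the Cys census over a repertoire.

    ``reads`` may be (id, sequence-string) tuples, RepertoireRead objects,
    or ImgtNumberedSequence objects.  Raw strings are numbered here, with
    reads failing numbering counted and excluded.  By default statistics are
    per unique amino-acid sequence; set ``per_unique=False`` to weight by
    read.  ``mask=None`` disables the primer-forced position mask.
    """
    mask = frozenset() if mask is None else frozenset(mask)
    numbered: list[tuple[str, ImgtNumberedSequence]] = []
    n_failed = 0
    n_input = 0
    cache: dict[str, ImgtNumberedSequence | None] = {}
    for i, read in enumerate(reads):
        n_input += 1
        if isinstance(read, RepertoireRead):
            numbered.append((read.id, read.numbered))
            continue
        if isinstance(read, ImgtNumberedSequence):
            numbered.append((f"read{i}", read))
            continue
        read_id, seq = read
        if seq not in cache:
            try:
                cache[seq] = number_sequence(seq, chain_type, template)
            except NumberingError:
                cache[seq] = None
        ns = cache[seq]
        if ns is None:
            n_failed += 1
        else:
            numbered.append((read_id, ns))
    if not numbered:
        raise ValueError("no numberable reads")

    if per_unique:
        seen: dict[str, tuple[str, ImgtNumberedSequence]] = {}
        for read_id, ns in numbered:
            seen.setdefault(ns.to_sequence(), (read_id, ns))
        units = list(seen.values())
    else:
        units = numbered

    region_hits = {r: 0 for r in REGION_NAMES}
    hist_all: Counter[int] = Counter()
    hist_fr: Counter[int] = Counter()
    subset_ids: list[str] = []
    subset_noncan: dict[str, tuple[int, ...]] = {}
    for unit_id, ns in units:
        noncan = _noncanonical_cys(ns, mask)
        regions_present = {region_of(p) for p in noncan}
        for r in regions_present:
            region_hits[r] += 1
        hist_all[len(noncan)] += 1
        fr_noncan = tuple(p for p in noncan if region_of(p).startswith("FR"))
        hist_fr[len(fr_noncan)] += 1
        if _fr_cys_total(ns, mask) >= 4:
            subset_ids.append(unit_id)
            subset_noncan[unit_id] = fr_noncan

    n = len(units)
    return CysCensus(
        n_input=n_input, n_counted=n, n_failed=n_failed,
        per_unique=per_unique, mask=mask,
        region_frequency={r: region_hits[r] / n for r in REGION_NAMES},
        cys_count_hist_all=pd.Series(hist_all).sort_index(),
        cys_count_hist_fr=pd.Series(hist_fr).sort_index(),
        subset_4plus_ids=tuple(subset_ids),
        _subset_noncanonical_fr=subset_noncan,
    )


def cooccurrence(cns: CysCensus) -> pd.DataFrame:
    """Strand-pair co-occurrence of noncanonical FR Cys in the >=4-Cys subset.

    Every unordered pair of noncanonical FR Cys positions in each subset
    unit contributes weight 1 to the cell keyed by the (sorted) strand bins
    of its two members; positions off any strand bin as 'FR-other'.  The
    returned long-format table (bin_1, bin_2, weight) is Circos-compatible;
    an empty subset gives an empty table.
    """
    weights: Counter[tuple[str, str]] = Counter()
    for positions in cns._subset_noncanonical_fr.values():
        ps = sorted(positions)
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                key = tuple(sorted((_strand_bin(ps[i]), _strand_bin(ps[j]))))
                weights[key] += 1
    rows = [{"bin_1": k[0], "bin_2": k[1], "weight": w}
            for k, w in sorted(weights.items())]
    return pd.DataFrame(rows, columns=["bin_1", "bin_2", "weight"])


def find_pairs(cns_or_reads, query_pairs, **census_kwargs) -> dict[tuple[int, int], int]:
    """Count census units carrying Cys at both positions of each query pair.

    Takes reads in the same forms :func:`census` accepts (per-unit Cys
    positions are needed, so a finished :class:`CysCensus` alone does not
    suffice).  The canonical positions may appear in queries; the count is
    a plain both-positions-Cys scan with the census mask applied.
    """
    mask = census_kwargs.pop("mask", DEFAULT_PRIMER_MASK)
    mask = frozenset() if mask is None else frozenset(mask)
    per_unique = census_kwargs.pop("per_unique", True)
    chain_type = census_kwargs.pop("chain_type", "VH")
    template = census_kwargs.pop("template", None)
    if census_kwargs:
        raise TypeError(f"unexpected arguments: {sorted(census_kwargs)}")

    units: list[ImgtNumberedSequence] = []
    cache: dict[str, ImgtNumberedSequence | None] = {}
    for i, read in enumerate(cns_or_reads):
        if isinstance(read, RepertoireRead):
            units.append(read.numbered)
        elif isinstance(read, ImgtNumberedSequence):
            units.append(read)
        else:
            _, seq = read
            if seq not in cache:
                try:
                    cache[seq] = number_sequence(seq, chain_type, template)
                except NumberingError:
                    cache[seq] = None
            if cache[seq] is not None:
                units.append(cache[seq])
    if per_unique:
        units = list({ns.to_sequence(): ns for ns in units}.values())

    out: dict[tuple[int, int], int] = {}
    for pair in query_pairs:
        p1, p2 = pair
        count = 0
        if p1 not in mask and p2 not in mask:
            for ns in units:
                if ns.mapping.get(p1) == "C" and ns.mapping.get(p2) == "C":
                    count += 1
        out[(p1, p2)] = count
    return out
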