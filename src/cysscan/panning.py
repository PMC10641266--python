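"""Phage panning quantitation: titers, enrichment trajectories, candidates.

Selections are tracked as per-pair clone counts across rounds; enrichment is
read out as per-round frequencies, fold change versus the first round, and
final-round rank.  Candidate calling applies a configurable rule (the study
reports "enrichment" without a numeric criterion; the default here is a
final-round frequency of at least 0.05 that did not fall over the last two
rounds, and the rule used is echoed in the output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imgt import PairTopology, classify_pair

__all__ = [
    "TiterInputs",
    "PanningRound",
    "EnrichmentTable",
    "titer_from_absorbance",
    "enrichment_trajectory",
    "select_enriched",
]

Pair = tuple[int, int]


@dataclass(frozen=True)
class TiterInputs:
    """Spectrophotometric phage titer inputs."""

    a269: float
    a320: float
    genome_bases: int

    def __post_init__(self):
        if self.a320 < 0 or self.a269 < self.a320:
            raise ValueError("need A269 >= A320 >= 0")
        if self.genome_bases <= 0:
            raise ValueError("genome_bases must be positive")


def titer_from_absorbance(t: TiterInputs) -> float:
    """Virions/ml from absorbance: (A269 - A320) x 10^16 / genome bases."""
    return (t.a269 - t.a320) * 1e16 / t.genome_bases


@dataclass(frozen=True)
class PanningRound:
    """Per-pair clone counts for one selection round."""

    round_index: int
    counts: dict[Pair, int]
    condition: str = "ambient"  # ambient | heat50 (30 min at 50 C pre-incubation)

    def __post_init__(self):
        if self.condition not in ("ambient", "heat50"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be nonnegative")
        if sum(self.counts.values()) == 0:
            raise ValueError(f"round {self.round_index} is empty")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[Pair, float]:
        total = self.total
        return {pair: c / total for pair, c in self.counts.items()}


@dataclass
class EnrichmentTable:
    """Per-pair frequencies by round, fold change vs round 1, final rank.

    Fold change is flagged undefined (NaN) when the round-1 frequency is
    zero rather than pseudocounted.  Ranks are a permutation of 1..n_pairs
    over final-round frequency, ties broken stably by pair position order.
    """

    table: pd.DataFrame
    rounds: tuple[int, ...]

    @property
    def pairs(self) -> list[Pair]:
        return list(self.table.index)

    def frequency(self, pair: Pair, round_index: int) -> float:
        return float(self.table.loc[[pair], f"freq_r{round_index}"].iloc[0])


def enrichment_trajectory(rounds: list[PanningRound]) -> EnrichmentTable:
    """Build the enrichment table from at least two selection rounds.

    All rounds must share a pair universe (a pair may have zero count in a
    round, but the set of tracked pairs is the union).  Deterministic and
    invariant to uniform rescaling of the counts within any round.
    """
    if len(rounds) < 2:
        raise ValueError("need at least two panning rounds")
    indices = [r.round_index for r in rounds]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate round indices")
    ordered = sorted(rounds, key=lambda r: r.round_index)
    pairs = sorted({p for r in ordered for p in r.counts})

    data: dict[str, list[float]] = {}
    for r in ordered:
        freqs = r.frequencies
        data[f"freq_r{r.round_index}"] = [freqs.get(p, 0.0) for p in pairs]
    table = pd.DataFrame(data, index=pd.Index(pairs, tupleize_cols=False))

    first, last = ordered[0], ordered[-1]
    f0 = table[f"freq_r{first.round_index}"].to_numpy()
    fN = table[f"freq_r{last.round_index}"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(f0 > 0, fN / np.where(f0 > 0, f0, 1.0), np.nan)
    table["fold_change"] = fold
    table["fold_change_defined"] = f0 > 0
    # stable sort on descending final frequency; index order breaks ties
    order = np.argsort(-fN, kind="stable")
    rank = np.empty(len(pairs), dtype=int)
    rank[order] = np.arange(1, len(pairs) + 1)
    table["final_rank"] = rank
    return EnrichmentTable(table, tuple(r.round_index for r in ordered))


def select_enriched(table: EnrichmentTable,
                    min_final_freq: float = 0.05,
                    require_monotone: bool = True
                    ) -> pd.DataFrame:
    """Call candidate pairs from an enrichment table.

    A pair is a candidate when its final-round frequency is at least
    ``min_final_freq`` and, when ``require_monotone``, its frequency did not
    decrease over the last two rounds.  Candidates are annotated with their
    strand/sheet topology.  Loosening ``min_final_freq`` never removes a
    candidate.
    """
    if not len(table.table):
        raise ValueError("empty enrichment table")
    last = table.rounds[-1]
    fN = table.table[f"freq_r{last}"]
    keep = fN >= min_final_freq
    if require_monotone and len(table.rounds) >= 2:
        prev = table.rounds[-2]
        keep &= fN >= table.table[f"freq_r{prev}"]
    out = table.table.loc[keep].copy()
    topologies = [classify_pair(*pair) for pair in out.index]
    out["strand_1"] = [t.strands[0] or "" for t in topologies]
    out["strand_2"] = [t.strands[1] or "" for t in topologies]
    out["category"] = [t.category for t in topologies]
    out["rule"] = (f"final_freq>={min_final_freq}"
                   + (";nondecreasing_last2" if require_monotone else ""))
    return out.sort_values("final_rank")
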