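"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Everything is generated from a seed (full determinism: same configuration
and seed give identical output) and every generator's output feeds its
consuming stage directly: clone pools into the QC classifier, count
trajectories into the enrichment analysis, repertoires into the census,
melt curves into the Boltzmann/DSF fits, and coordinate sets into the
geometry screen.  Default compositions echo the study conditions (70%
correct / 14% single-Cys / 16% unmodified clone pools; four panning
rounds).  The selection model is deliberately minimal — round-to-round
multinomial resampling with probabilities proportional to frequency x
fitness — and claims no phage biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biophys import MeltCurve, boltzmann
from .imgt import (STRANDS, VH_TEMPLATE, ImgtNumberedSequence,
                   make_null_variant, region_of)
from .library import StrandPairLibrary
from .panning import PanningRound
from .structure import CoordinateModel

__all__ = [
    "DEFAULT_CLONE_FRACTIONS",
    "gen_library_clones",
    "gen_panning",
    "gen_repertoire",
    "gen_melt",
    "gen_coords",
    "null_parent",
]

#: Study-average clone composition: correct pair / single Cys / unmodified.
DEFAULT_CLONE_FRACTIONS: tuple[float, float, float] = (0.70, 0.14, 0.16)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def null_parent(template: ImgtNumberedSequence | None = None) -> ImgtNumberedSequence:
    """The canonical-null scan parent (C23A/C104A of the template)."""
    return make_null_variant(template or VH_TEMPLATE)


def gen_library_clones(parent: ImgtNumberedSequence,
                       library: StrandPairLibrary,
                       fractions: tuple[float, float, float] = DEFAULT_CLONE_FRACTIONS,
                       n: int = 500,
                       seed: int | np.random.Generator = 0,
                       ) -> list[tuple[str, str]]:
    """Simulate a sequenced clone pool of one scan library.

    ``fractions`` gives (correct_pair, single_cys, unmodified); any
    remainder becomes off-target clones carrying one random non-Cys,
    non-parental substitution.  Correct-pair clones draw uniformly from the
    library's enumerated pairs; single-Cys clones draw one position
    uniformly from the library's position grid.  Returns (id, sequence)
    records ready for FASTA output or :func:`cysscan.cloneqc.classify_pool`.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or np.any(fr < 0) or fr.sum() > 1 + 1e-9:
        raise ValueError("fractions must be 3 nonnegative values summing to <= 1")
    rng = _rng(seed)
    probs = np.append(fr, max(0.0, 1.0 - fr.sum()))
    labels = rng.choice(4, size=n, p=probs / probs.sum())
    pairs = library.pairs
    positions = sorted(library.positions)
    # off-target substitutions go at occupied non-library, non-anchor positions
    other_positions = [p for p in parent.positions
                       if p not in library.positions and p not in (23, 104)]
    records: list[tuple[str, str]] = []
    for i, label in enumerate(labels):
        if label == 0:  # correct pair
            p1, p2 = pairs[rng.integers(len(pairs))]
            clone = parent.substitute({p1: "C", p2: "C"})
        elif label == 1:  # single Cys
            p = positions[rng.integers(len(positions))]
            clone = parent.substitute({p: "C"})
        elif label == 2:  # unmodified
            clone = parent
        else:  # off-target: one random non-Cys missense
            p = other_positions[rng.integers(len(other_positions))]
            current = parent.mapping[p]
            choices = [a for a in AMINO_ACIDS if a not in (current, "C")]
            clone = parent.substitute({p: choices[rng.integers(len(choices))]})
        records.append((f"clone_{i:05d}", clone.to_sequence()))
    return records


def gen_panning(initial_frequencies: dict, fitness: dict,
                rounds: int = 4, depth: int = 10_000,
                seed: int | np.random.Generator = 0,
                condition: str = "heat50") -> list[PanningRound]:
    """Simulate a panning count trajectory under frequency x fitness selection.

    Round 1 counts are multinomial draws from the initial frequencies; each
    subsequent round draws ``depth`` clones with probabilities proportional
    to the previous round's observed frequencies times per-pair fitness.
    """
    if rounds < 1:
        raise ValueError("need at least one round")
    if depth < 100:
        raise ValueError("depth must be at least 100")
    pairs = sorted(initial_frequencies)
    f = np.array([fitness.get(p, 0.0) for p in pairs], dtype=float)
    if np.any(f < 0):
        raise ValueError("fitness values must be nonnegative")
    if f.sum() == 0:
        raise ValueError("all-zero fitness: nothing can be selected")
    freq = np.array([initial_frequencies[p] for p in pairs], dtype=float)
    if np.any(freq < 0) or freq.sum() <= 0:
        raise ValueError("initial frequencies must be nonnegative, not all zero")
    freq = freq / freq.sum()
    rng = _rng(seed)

    out: list[PanningRound] = []
    for r in range(1, rounds + 1):
        if r > 1:
            weights = freq * f
            if weights.sum() == 0:
                raise ValueError("selection extinguished every pair")
            freq = weights / weights.sum()
        counts = rng.multinomial(depth, freq)
        out.append(PanningRound(round_index=r, condition=condition,
                                counts={p: int(c) for p, c in zip(pairs, counts)}))
        freq = counts / counts.sum()
    return out


def gen_repertoire(template: ImgtNumberedSequence | None = None,
                   n: int = 10_000,
                   cys_rate: float | dict[int, float] = 0.0,
                   doped_pairs: dict[tuple[int, int], float] | None = None,
                   seed: int | np.random.Generator = 0,
                   ) -> list[tuple[str, str]]:
    """Simulate an IMGT-numberable V_H repertoire with controllable Cys content.

    Every read derives from the template and keeps the canonical Cys23/104.
    ``cys_rate`` is a per-position Cys substitution probability applied to
    framework positions (a scalar for all, or a per-position mapping);
    ``doped_pairs`` maps position pairs to the fraction of reads carrying
    Cys at both positions (rates must sum to <= 1).  Returns (id, sequence)
    records.
    """
    template = template or VH_TEMPLATE
    if not template.has_canonical_pair:
        raise ValueError("repertoire template must carry the canonical pair")
    doped_pairs = doped_pairs or {}
    dope_items = sorted(doped_pairs.items())
    dope_rates = np.array([r for _, r in dope_items], dtype=float)
    if np.any(dope_rates < 0) or dope_rates.sum() > 1:
        raise ValueError("dope rates must be nonnegative and sum to <= 1")
    # per-position substitution probabilities over framework positions only
    fr_positions = [p for p in template.positions
                    if p not in (23, 104) and region_of(p).startswith("FR")]
    if isinstance(cys_rate, dict):
        rates = {p: float(cys_rate.get(p, 0.0)) for p in fr_positions}
    else:
        rates = {p: float(cys_rate) for p in fr_positions}
    if any(not 0 <= r <= 1 for r in rates.values()):
        raise ValueError("cys_rate values must lie in [0, 1]")

    rng = _rng(seed)
    probs = np.append(dope_rates, max(0.0, 1.0 - dope_rates.sum()))
    assignment = rng.choice(len(dope_items) + 1, size=n, p=probs / probs.sum())
    rate_positions = [p for p, r in rates.items() if r > 0]
    rate_values = np.array([rates[p] for p in rate_positions])

    records: list[tuple[str, str]] = []
    for i in range(n):
        subs: dict[int, str] = {}
        if rate_positions:
            hits = rng.random(len(rate_positions)) < rate_values
            for p in np.asarray(rate_positions)[hits]:
                subs[int(p)] = "C"
        a = assignment[i]
        if a < len(dope_items):
            (p1, p2), _ = dope_items[a]
            subs[p1] = "C"
            subs[p2] = "C"
        read = template.substitute(subs) if subs else template
        records.append((f"read_{i:06d}", read.to_sequence()))
    return records


def gen_melt(tm: float = 65.0, slope: float = 2.5,
             lower: float = 0.0, upper: float = 100.0,
             noise_sd: float = 0.0,
             grid: np.ndarray | None = None,
             seed: int | np.random.Generator = 0,
             kind: str = "CD") -> MeltCurve:
    """Generate a Boltzmann melt curve with Gaussian noise.

    The default grid is the study's CD protocol: 25 to 106 degrees C in
    0.5-degree steps.  ``noise_sd`` is in signal units (e.g. 2 for 2% of a
    0-100 range).
    """
    if grid is None:
        grid = np.arange(25.0, 106.0 + 0.25, 0.5)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 10 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be an ascending 1-D array of >= 10 points")
    if slope <= 0:
        raise ValueError("slope must be positive")
    rng = _rng(seed)
    y = boltzmann(grid, tm, slope, lower, upper)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(grid))
    return MeltCurve(grid, y, kind=kind)


def gen_coords(spec: dict[int, tuple[float, float, float]] | None = None,
               lattice: bool = False,
               strand_spacing: float = 4.8,
               residue_spacing: float = 3.4,
               sheet_gap: float = 10.0,
               seed: int | np.random.Generator = 0,
               jitter: float = 0.0) -> CoordinateModel:
    """Build a synthetic coordinate model.

    Explicit mode: ``spec`` maps IMGT positions to Calpha coordinates
    (duplicates are rejected by construction of the dict; passing the same
    position twice is impossible, so conflicts must be resolved upstream).
    Lattice mode: an idealised two-sheet geometry placing each strand as a
    straight row (``residue_spacing`` apart along the strand,
    ``strand_spacing`` between strands in a sheet, the sheets ``sheet_gap``
    apart), optionally jittered.  A toy for closed-loop screen tests, not a
    model of the Ig fold's twist.
    """
    rng = _rng(seed)
    if spec is not None and lattice:
        raise ValueError("give either an explicit spec or lattice=True, not both")
    if spec is not None:
        ca = {int(p): np.asarray(xyz, dtype=float) for p, xyz in spec.items()}
        if len(ca) != len(spec):
            raise ValueError("duplicate position placement in spec")
        return CoordinateModel(ca=ca, source="synthetic (explicit spec)")
    if not lattice:
        raise ValueError("no spec given and lattice mode off")

    sheet_y = {"ABED": 0.0, "CC'C''FG": float(sheet_gap)}
    order = {"ABED": ["A", "B", "D", "E"], "CC'C''FG": ["C", "C'", "C''", "F", "G"]}
    ca: dict[int, np.ndarray] = {}
    for sheet, names in order.items():
        for k, name in enumerate(names):
            strand = STRANDS[name]
            for j, p in enumerate(strand.positions):
                xyz = np.array([k * strand_spacing, sheet_y[sheet],
                                j * residue_spacing])
                if jitter > 0:
                    xyz = xyz + rng.normal(0.0, jitter, size=3)
                ca[p] = xyz
    return CoordinateModel(ca=ca, source="synthetic (two-sheet lattice)")
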