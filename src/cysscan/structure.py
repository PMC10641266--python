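"""Geometric plausibility screening of Cys pairs on coordinate models.

Disulfide formation imposes tight spatial constraints: the Calpha atoms of
the two half-cystines typically sit 4-7 Angstrom apart with a chi-ss
dihedral near 90 degrees.  This module evaluates candidate pairs on
coordinate models whose residues are keyed by IMGT position, flagging each
pair as plausible (Calpha distance inside a closed window, default
[4.0, 7.0] A) or not.  The dihedral criterion has no stated tolerance and
is off by default; an optional Cbeta-based proxy (+-30 degrees) is provided
as a clearly heuristic check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imgt import number_sequence, NumberingError

__all__ = [
    "CoordinateModel",
    "ScreenParams",
    "GeometryReport",
    "ca_distance",
    "screen_pair",
    "rank_all_pairs",
    "model_from_pdb",
]


@dataclass
class CoordinateModel:
    """Calpha (and optional Cbeta) coordinates keyed by IMGT position."""

    ca: dict[int, np.ndarray]
    cb: dict[int, np.ndarray] = field(default_factory=dict)
    source: str = "synthetic"

    def __post_init__(self):
        for table in (self.ca, self.cb):
            for p, xyz in list(table.items()):
                if not 1 <= p <= 128:
                    raise ValueError(f"IMGT position out of range: {p}")
                arr = np.asarray(xyz, dtype=float)
                if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                    raise ValueError(f"bad coordinate for position {p}: {xyz}")
                table[p] = arr

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.ca))

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "CoordinateModel":
        """Apply a rigid motion (useful for invariance checks)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return CoordinateModel(
            ca={p: R @ xyz + t for p, xyz in self.ca.items()},
            cb={p: R @ xyz + t for p, xyz in self.cb.items()},
            source=self.source + " (transformed)")


@dataclass(frozen=True)
class ScreenParams:
    """Geometry screen parameters.

    ca_window: closed Calpha-Calpha distance interval in Angstrom.
    check_dihedral: enable the heuristic Cbeta-proxy dihedral check.
    dihedral_target / dihedral_tolerance: degrees.
    """

    ca_window: tuple[float, float] = (4.0, 7.0)
    check_dihedral: bool = False
    dihedral_target: float = 90.0
    dihedral_tolerance: float = 30.0

    def __post_init__(self):
        lo, hi = self.ca_window
        if not (0 < lo < hi):
            raise ValueError("ca_window must satisfy 0 < lower < upper")


@dataclass(frozen=True)
class GeometryReport:
    pair: tuple[int, int]
    ca_distance: float
    plausible: bool
    notes: str = ""
    dihedral: float | None = None


def ca_distance(model: CoordinateModel, p1: int, p2: int) -> float:
    """Euclidean Calpha-Calpha distance in Angstrom (symmetric in p1, p2)."""
    for p in (p1, p2):
        if p not in model.ca:
            raise KeyError(f"position {p} missing from the coordinate model")
    return float(np.linalg.norm(model.ca[p1] - model.ca[p2]))


def _cb_dihedral(model: CoordinateModel, p1: int, p2: int) -> float | None:
    """Heuristic chi-ss proxy: dihedral Cb1-Ca1-Ca2-Cb2 in degrees.

    A stand-in for the S-S dihedral (no sulfur atoms exist before
    mutagenesis); requires Cbeta coordinates for both positions.
    """
    if p1 not in model.cb or p2 not in model.cb:
        return None
    b1 = model.ca[p1] - model.cb[p1]
    axis = model.ca[p2] - model.ca[p1]
    b3 = model.cb[p2] - model.ca[p2]
    n1 = np.cross(b1, axis)
    n2 = np.cross(axis, b3)
    m1 = np.cross(n1, axis / np.linalg.norm(axis))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(abs(np.degrees(np.arctan2(y, x))))


def screen_pair(model: CoordinateModel, pair: tuple[int, int],
                params: ScreenParams | None = None) -> GeometryReport:
    """Evaluate one pair: plausible iff Calpha distance lies in the window.

    The window is closed at both ends.  When the dihedral option is on and
    Cbeta coordinates exist, the proxy dihedral must additionally fall
    within tolerance of the target.
    """
    params = params or ScreenParams()
    p1, p2 = pair
    d = ca_distance(model, p1, p2)
    lo, hi = params.ca_window
    plausible = lo <= d <= hi
    notes = []
    dihedral = None
    if params.check_dihedral:
        dihedral = _cb_dihedral(model, p1, p2)
        if dihedral is None:
            notes.append("dihedral not evaluable (missing Cbeta)")
        else:
            ok = abs(dihedral - params.dihedral_target) <= params.dihedral_tolerance
            plausible = plausible and ok
            notes.append(f"dihedral proxy {dihedral:.1f} deg ({'ok' if ok else 'off-target'})")
    return GeometryReport((p1, p2), d, plausible, "; ".join(notes), dihedral)


def rank_all_pairs(model: CoordinateModel, manifest,
                   params: ScreenParams | None = None
                   ) -> tuple[list[GeometryReport], list[tuple[int, int]]]:
    """Screen every manifest pair; rank evaluable pairs, list the rest.

    Returns (reports sorted by |distance - window midpoint|, pairs with a
    missing position).  ``manifest`` may be a DesignManifest or any iterable
    of position pairs.
    """
    params = params or ScreenParams()
    libraries = getattr(manifest, "libraries", None)
    if libraries is not None:
        pairs = sorted({tuple(p) for lib in libraries for p in lib.pairs})
    else:
        pairs = sorted({tuple(p) for p in manifest})
    mid = sum(params.ca_window) / 2.0
    reports, missing = [], []
    for pair in pairs:
        try:
            reports.append(screen_pair(model, pair, params))
        except KeyError:
            missing.append(pair)
    reports.sort(key=lambda r: (abs(r.ca_distance - mid), r.pair))
    return reports, missing


def reports_to_frame(reports: list[GeometryReport]) -> pd.DataFrame:
    return pd.DataFrame([
        {"p1": r.pair[0], "p2": r.pair[1], "ca_distance": r.ca_distance,
         "plausible": r.plausible, "dihedral": r.dihedral, "notes": r.notes}
        for r in reports])


def model_from_pdb(path, chain: str | None = None,
                   chain_type: str = "VH", template=None) -> CoordinateModel:
    """Build a coordinate model from a PDB file.

    The selected chain's sequence is numbered onto the IMGT scheme (author
    numbering is never assumed to be IMGT); Calpha/Cbeta coordinates are
    then keyed by IMGT position.  First model; altlocs resolved by highest
    occupancy.  Residues whose position cannot be numbered are dropped.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile
    from biotite.sequence import ProteinSequence

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if chain is not None:
        atoms = atoms[atoms.chain_id == chain]
    if atoms.array_length() == 0:
        raise ValueError(f"no amino-acid atoms for chain {chain!r}")

    res_ids, seq3 = struc.get_residues(atoms)
    letters = []
    for name in seq3:
        try:
            letters.append(ProteinSequence.convert_letter_3to1(name))
        except KeyError:
            letters.append("X")
    seq = "".join(letters)
    numbered = number_sequence(seq, chain_type, template)
    # residue order == occupied-position order
    index_to_pos = dict(enumerate(numbered.positions))

    ca: dict[int, np.ndarray] = {}
    cb: dict[int, np.ndarray] = {}
    for i, res_id in enumerate(res_ids):
        pos = index_to_pos.get(i)
        if pos is None:
            continue
        res_atoms = atoms[atoms.res_id == res_id]
        for name, table in (("CA", ca), ("CB", cb)):
            sel = res_atoms[res_atoms.atom_name == name]
            if sel.array_length():
                table[pos] = np.asarray(sel.coord[0], dtype=float)
    return CoordinateModel(ca=ca, cb=cb, source=str(path))
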