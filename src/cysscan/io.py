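"""File I/O: FASTA sequences, tab-separated tables, melt-curve CSVs, PDB out."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .biophys import MeltCurve
from .structure import CoordinateModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_melt_csv",
    "write_melt_csv",
    "read_round_tsv",
    "write_pdb",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) records."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_melt_csv(path, kind: str = "CD") -> MeltCurve:
    """Two-column CSV (temperature, signal), header optional."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError("melt CSV needs two columns: temperature, signal")
    # tolerate headerless files read with a data row as header
    try:
        float(df.columns[0])
    except (TypeError, ValueError):
        pass
    else:
        df = pd.read_csv(path, comment="#", header=None)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    return MeltCurve(t, y, kind=kind)


def write_melt_csv(curve: MeltCurve, path) -> None:
    pd.DataFrame({"temperature": curve.temperature,
                  "signal": curve.signal}).to_csv(path, index=False)


def read_round_tsv(path) -> dict[tuple[int, int], int]:
    """Per-round pair counts: columns pair_p1, pair_p2, count."""
    df = pd.read_csv(path, sep="\t")
    required = {"pair_p1", "pair_p2", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"round table needs columns {sorted(required)}")
    return {(int(r.pair_p1), int(r.pair_p2)): int(r.count)
            for r in df.itertuples()}


def write_pdb(model: CoordinateModel, path) -> None:
    """Write a coordinate model as a minimal CA-trace PDB (poly-Ala/Cys-free)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    positions = model.positions
    atoms = struc.AtomArray(len(positions))
    atoms.coord = np.stack([model.ca[p] for p in positions])
    atoms.chain_id[:] = "A"
    atoms.res_id[:] = list(positions)
    atoms.res_name[:] = "ALA"
    atoms.atom_name[:] = "CA"
    atoms.element[:] = "C"
    atoms.hetero[:] = False
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))
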