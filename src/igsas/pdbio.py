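"""Coordinate I/O: PDB fixed-column records and a plain bead-table dialect.

PDB files carry one CA pseudo-atom per bead, coordinates in Angstrom
(converted from the internal nm), the scattering length in the occupancy
column and the rigid-region tag as an integer in the B-factor column.
The bead table is whitespace-separated with columns

    index chain resnum resname region x y z      (x, y, z in nm)

and round-trips region tags and coordinates exactly.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .models import REGIONS, BeadModel

_AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
_AA_1TO3 = {v: k for k, v in _AA_3TO1.items()}

_REGION_INDEX = {r: i for i, r in enumerate(REGIONS)}


def _is_pdb(path) -> bool:
    return str(path).lower().endswith((".pdb", ".ent"))


def write_model(model: BeadModel, path) -> None:
    """Write a bead model to PDB (by extension) or to the bead-table dialect."""
    path = Path(path)
    if _is_pdb(path):
        _write_pdb(model, path)
    else:
        _write_table(model, path)


def read_model(path) -> BeadModel:
    """Read a bead model written by :func:`write_model`.

    Unparseable records raise with the offending line number; extra PDB
    columns beyond those used here are ignored.
    """
    path = Path(path)
    model = _read_pdb(path) if _is_pdb(path) else _read_table(path)
    model.validate()
    return model


# -- PDB dialect -----------------------------------------------------------

def _write_pdb(model: BeadModel, path: Path) -> None:
    st = gemmi.Structure()
    st.name = "igsas bead model"
    md = gemmi.Model("1")
    for chain_id in pd.unique(model.chain):
        ch = gemmi.Chain(str(chain_id))
        for i in np.flatnonzero(model.chain == chain_id):
            res = gemmi.Residue()
            res.name = _AA_1TO3.get(model.resname[i], str(model.resname[i]))[:3]
            res.seqid = gemmi.SeqId(int(model.resnum[i]), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            x, y, z = model.positions[i] * 10.0  # nm -> Angstrom
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = float(model.f[i])
            atom.b_iso = float(_REGION_INDEX[model.region[i]])
            res.add_atom(atom)
            ch.add_residue(res)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


def _read_pdb(path: Path) -> BeadModel:
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from None
    pos, resnum, chain, resname, region, f = [], [], [], [], [], []
    for md in st:
        for ch in md:
            for res in ch:
                for atom in res:
                    pos.append([atom.pos.x / 10.0, atom.pos.y / 10.0,
                                atom.pos.z / 10.0])
                    resnum.append(res.seqid.num)
                    chain.append(ch.name)
                    resname.append(_AA_3TO1.get(res.name, res.name))
                    ridx = int(round(atom.b_iso))
                    if not 0 <= ridx < len(REGIONS):
                        raise ValueError(
                            f"{path}: atom {atom.serial} carries no region tag "
                            f"(B-factor {atom.b_iso})")
                    region.append(REGIONS[ridx])
                    f.append(atom.occ)
        break  # first model only
    if not pos:
        raise ValueError(f"{path}: no atom records found")
    return BeadModel(np.array(pos), np.array(resnum), np.array(chain, dtype=object),
                     np.array(resname, dtype=object), np.array(region, dtype=object),
                     np.array(f))


# -- bead-table dialect ----------------------------------------------------

_TABLE_COLUMNS = ["index", "chain", "resnum", "resname", "region", "x", "y", "z"]


def _write_table(model: BeadModel, path: Path) -> None:
    df = pd.DataFrame({
        "index": np.arange(model.n_sites),
        "chain": model.chain,
        "resnum": model.resnum,
        "resname": model.resname,
        "region": model.region,
        "x": model.positions[:, 0],
        "y": model.positions[:, 1],
        "z": model.positions[:, 2],
    })
    with open(path, "w") as fh:
        fh.write("# " + " ".join(_TABLE_COLUMNS) + "\n")
        df.to_csv(fh, sep=" ", header=False, index=False, float_format="%.6f")


def _read_table(path: Path) -> BeadModel:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns, got {len(parts)}")
            try:
                rows.append((int(parts[0]), parts[1], int(parts[2]), parts[3],
                             parts[4], float(parts[5]), float(parts[6]),
                             float(parts[7])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if rows[-1][4] not in REGIONS:
                raise ValueError(f"{path}:{lineno}: unknown region {parts[4]!r}")
    if not rows:
        raise ValueError(f"{path}: empty bead table")
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    pos = df[["x", "y", "z"]].to_numpy()
    return BeadModel(pos, df["resnum"].to_numpy(),
                     df["chain"].to_numpy(dtype=object),
                     df["resname"].to_numpy(dtype=object),
                     df["region"].to_numpy(dtype=object))
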