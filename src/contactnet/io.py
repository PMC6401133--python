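"""Readers and writers for the standard formats the pipeline touches.

Structures come in as PDB files (read with gemmi); alignments as A3M or
aligned FASTA; coevolution scores as the flat whitespace matrix dialect
emitted by CCMpred-style tools; predictions go out as CASP RR records or
dense matrices.  Residues are 0-based in memory and 1-based in every file
written or read, after renumbering file residues sequentially.
"""

from __future__ import annotations

import io as _io
import os

import gemmi
import numpy as np
from Bio import SeqIO

from .core import ContactMap, ProteinRecord, ResidueCoords, CONTACT

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "C", "PYL": "K",
}


# ---------------------------------------------------------------------------
# sequences and alignments
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(path, records: list[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_alignment(path) -> list[str]:
    """Read an A3M or aligned-FASTA alignment into equal-width rows.

    A3M lowercase letters mark insertions relative to the first (target)
    sequence and are dropped; '.' gap characters are likewise removed, and
    '-' is kept as the gap symbol.
    """
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(c for c in str(rec.seq) if not (c.islower() or c == "."))
        rows.append(seq.upper().replace(".", "-"))
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    width = len(rows[0])
    for k, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"{path}: row {k} has width {len(row)}, expected {width}"
            )
    return rows


def write_alignment(path, rows: list[str], ids: list[str] | None = None) -> None:
    ids = ids or [f"seq{k}" for k in range(len(rows))]
    with open(path, "w") as fh:
        for name, row in zip(ids, rows):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def read_pdb_coords(path, chain: str | None = None) -> tuple[ProteinRecord, ResidueCoords]:
    """Extract sequence and contact/side-chain coordinates from a PDB file.

    Uses the first model; selects ``chain`` by name or else the first chain
    containing amino-acid residues; for alternate locations keeps the
    highest-occupancy conformer.  The contact atom is C-beta, or C-alpha for
    glycine and for residues lacking a C-beta; the side-chain center of mass
    is mass-weighted over non-backbone atoms.  Residues with neither C-beta
    nor C-alpha are flagged unresolved.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    sel = None
    for ch in model:
        has_aa = any(r.name in _THREE_TO_ONE for r in ch)
        if chain is None and has_aa:
            sel = ch
            break
        if chain is not None and ch.name == chain:
            sel = ch
            break
    if sel is None:
        raise ValueError(f"{path}: chain {chain!r} not found")

    seq, cb_xyz, com_xyz, resolved = [], [], [], []
    for res in sel:
        if res.name not in _THREE_TO_ONE and not res.is_amino_acid():
            continue
        seq.append(_THREE_TO_ONE.get(res.name, "X"))
        atoms: dict[str, gemmi.Atom] = {}
        for atom in res:
            prev = atoms.get(atom.name)
            if prev is None or atom.occ > prev.occ:
                atoms[atom.name] = atom
        ca = atoms.get("CA")
        cb = atoms.get("CB")
        anchor = cb if (cb is not None and res.name != "GLY") else ca
        if anchor is None:
            cb_xyz.append((np.nan,) * 3)
            com_xyz.append((np.nan,) * 3)
            resolved.append(False)
            continue
        cb_xyz.append(tuple(anchor.pos))
        side = [a for name, a in atoms.items() if name not in BACKBONE_ATOMS
                and a.element != gemmi.Element("H")]
        if side:
            w = np.array([a.element.weight for a in side])
            pts = np.array([tuple(a.pos) for a in side])
            com_xyz.append(tuple((w[:, None] * pts).sum(0) / w.sum()))
        else:
            com_xyz.append(tuple(ca.pos) if ca is not None else tuple(anchor.pos))
        resolved.append(True)
    if not seq:
        raise ValueError(f"{path}: chain {sel.name!r} has no amino-acid residues")
    record = ProteinRecord(id=f"{os.path.basename(str(path))}:{sel.name}",
                           sequence="".join(seq))
    coords = ResidueCoords(
        contact_xyz=np.array(cb_xyz, dtype=float),
        sidechain_com=np.array(com_xyz, dtype=float),
        resolved=np.array(resolved, dtype=bool),
    )
    return record, coords


def write_minimal_pdb(path, record: ProteinRecord, ca_xyz: np.ndarray,
                      cb_xyz: np.ndarray, resolved: np.ndarray | None = None,
                      chain: str = "A") -> None:
    """Write CA/CB ATOM records (1-based sequential numbering).

    Enough structure for the package's own PDB reader: every resolved
    residue gets a CA record and, unless it is glycine, a CB record.
    Unresolved residues are simply absent from the file, as in real PDB
    entries.
    """
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items() if k not in
                    {"MSE", "SEC", "PYL"}}
    ca_xyz = np.asarray(ca_xyz, dtype=float)
    cb_xyz = np.asarray(cb_xyz, dtype=float)
    if resolved is None:
        resolved = np.ones(len(record.sequence), dtype=bool)
    serial = 1
    with open(path, "w") as fh:
        for i, aa in enumerate(record.sequence):
            if not resolved[i]:
                continue
            res3 = one_to_three.get(aa, "UNK")
            x, y, z = ca_xyz[i]
            fh.write(
                f"ATOM  {serial:>5d}  CA  {res3} {chain}{i + 1:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
            serial += 1
            if aa != "G":
                x, y, z = cb_xyz[i]
                fh.write(
                    f"ATOM  {serial:>5d}  CB  {res3} {chain}{i + 1:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def read_flat_matrix(path, expected_length: int | None = None) -> np.ndarray:
    """Read an L x L whitespace-separated float matrix (CCMpred dialect)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric token at row {lineno}") from exc
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    width = len(rows[0])
    for k, row in enumerate(rows, start=1):
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged row {k} (got {len(row)} columns, expected {width})"
            )
    mat = np.array(rows, dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, not square")
    if expected_length is not None and mat.shape[0] != expected_length:
        raise ValueError(
            f"{path}: matrix size {mat.shape[0]} does not match sequence "
            f"length {expected_length}"
        )
    return mat


def write_flat_matrix(path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.17g")


def read_pssm(path) -> np.ndarray:
    """Read a PSI-BLAST ASCII PSSM into an L x 20 probability profile.

    Parses the 20 percentage columns (weighted observed frequencies) and
    renormalises each row; rows that are all zero fall back to uniform.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if len(toks) >= 42 and toks[0].isdigit():
                rows.append([float(t) for t in toks[22:42]])
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    prof = np.array(rows, dtype=float)
    sums = prof.sum(axis=1, keepdims=True)
    uniform = np.full(20, 1.0 / 20)
    prof = np.where(sums > 0, prof / np.where(sums == 0, 1, sums), uniform)
    return prof


# ---------------------------------------------------------------------------
# CASP RR contact records
# ---------------------------------------------------------------------------

def write_rr(path, pred: np.ndarray, sequence: str | None = None,
             cutoff: float = 0.0) -> None:
    """Write 'i j 0 8 p' records (1-based, upper triangle, P descending)."""
    p = np.asarray(pred, dtype=float)
    L = p.shape[0]
    entries = [
        (i, j, p[i, j])
        for i in range(L) for j in range(i + 1, L)
        if p[i, j] > cutoff
    ]
    entries.sort(key=lambda t: (-t[2], t[0], t[1]))
    with open(path, "w") as fh:
        if sequence:
            fh.write(sequence + "\n")
        for i, j, prob in entries:
            fh.write(f"{i + 1} {j + 1} 0 8 {prob:.6f}\n")


def read_rr(path, length: int) -> np.ndarray:
    """Read CASP RR records into a symmetric probability map."""
    pred = np.zeros((length, length), dtype=float)
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if len(toks) < 5 or not toks[0].isdigit():
                continue
            i, j = int(toks[0]) - 1, int(toks[1]) - 1
            if not (0 <= i < length and 0 <= j < length):
                raise ValueError(f"{path}: residue index out of range: {line!r}")
            prob = float(toks[4])
            pred[i, j] = pred[j, i] = prob
    return pred


def write_contact_map(path, cmap: ContactMap) -> None:
    np.savetxt(path, cmap.states, fmt="%d")


def read_contact_map(path, threshold: float = 8.0) -> ContactMap:
    return ContactMap(states=np.loadtxt(path, dtype=np.int8), threshold=threshold)


# ---------------------------------------------------------------------------
# feature tensor cache
# ---------------------------------------------------------------------------

def save_features(path, target_id: str, tensor: np.ndarray) -> None:
    """Store an L x L x C feature tensor in an HDF5 container, keyed by id."""
    import h5py

    with h5py.File(path, "a") as h5:
        if target_id in h5:
            del h5[target_id]
        h5.create_dataset(target_id, data=tensor, compression="gzip")


def load_features(path, target_id: str) -> np.ndarray:
    import h5py

    with h5py.File(path, "r") as h5:
        if target_id not in h5:
            raise KeyError(f"{target_id} not present in {path}")
        return h5[target_id][()]
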