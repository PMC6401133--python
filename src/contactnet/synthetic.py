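"""Synthetic folds, alignments, and coevolution matrices.

The generator fabricates the whole input ecosystem the prediction stack
expects, at desk scale and with no downloads: toy folds built from ideal
secondary-structure segments packed into a bundle (so their contact maps
show the clustered stripe patterns real folds produce between packed
helices and strands), multiple sequence alignments whose column covariation
tracks the fold's contacts, coevolution score matrices derived from that
covariation, and per-residue secondary-structure / accessibility tracks.

Geometry is idealised, not physical: helices rise 1.5 A per residue at 100
degrees per turn, strands extend 3.3 A per residue, consecutive segments
are antiparallel and spaced by a packing distance, and every residue gets a
pseudo-C-beta offset outward from the bundle axis (glycines, inserted at
random, exercise the C-alpha fallback).  Everything is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (AMINO_ACIDS, CONTACT, ContactMap, ProteinRecord,
                   ResidueCoords, extract_native_contacts, separation_mask)
from .features import (Alignment, PairPotentialTable, assemble_features,
                       compute_mutual_information, compute_profile)

HELIX_RISE = 1.5       # A per residue along the axis
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # A, C-alpha distance from the axis
STRAND_RISE = 3.3      # A per residue
CB_OFFSET = 1.5        # A, pseudo C-beta displacement from C-alpha
DEFAULT_PACKING = 9.0  # A between neighbouring segment axes
LOOP_LENGTH = 4
GLYCINE_RATE = 0.08

SS_CODES = {"H": 0, "E": 1, "C": 2}


@dataclass
class SyntheticTarget:
    """One toy target: fold, labels, alignment, and auxiliary tracks."""

    record: ProteinRecord
    coords: ResidueCoords
    ca_xyz: np.ndarray
    contact_map: ContactMap
    alignment: Alignment
    coevolution: np.ndarray
    ss_labels: np.ndarray          # (L,) ints, 0=H 1=E 2=C
    ss3: np.ndarray                # (L, 3) noisy state probabilities
    accessibility: np.ndarray      # (L,) in [0, 1]

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def length(self) -> int:
        return self.record.length


def _segment_coords(kind: str, n: int, origin: np.ndarray,
                    direction: int) -> tuple[np.ndarray, np.ndarray]:
    """Ideal C-alpha and pseudo-C-beta traces of one segment along +/-z.

    The pseudo-C-beta points radially away from the segment's own axis
    (for strands, alternately +/-x across the pleat), which is what lets
    packed neighbours form contacts on their facing sides.
    """
    t = np.arange(n, dtype=float)
    if kind == "H":
        ang = np.deg2rad(HELIX_TWIST) * t
        x = origin[0] + HELIX_RADIUS * np.cos(ang)
        y = origin[1] + HELIX_RADIUS * np.sin(ang)
        z = origin[2] + direction * HELIX_RISE * t
        ca = np.stack([x, y, z], axis=1)
        radial = ca - np.stack([np.full(n, origin[0]),
                                np.full(n, origin[1]), z], axis=1)
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    else:  # strand: gentle pleat in y, side chains alternating in +/-x
        x = np.full(n, origin[0])
        y = origin[1] + 0.5 * (-1.0) ** t
        z = origin[2] + direction * STRAND_RISE * t
        ca = np.stack([x, y, z], axis=1)
        radial = np.zeros((n, 3))
        radial[:, 0] = (-1.0) ** t
    cb = ca + CB_OFFSET * radial
    return ca, cb


def generate_toy_fold(n_helices: int, n_strands: int,
                      packing: float = DEFAULT_PACKING, seed: int = 0,
                      segment_length: tuple[int, int] = (12, 16),
                      loop_length: int = LOOP_LENGTH) -> dict:
    """Build a packed bundle of ideal segments; returns coords + ss labels.

    Segments alternate direction (antiparallel bundle) and sit on parallel
    axes ``packing`` A apart, which produces the stripe-shaped clusters of
    medium/long contacts between sequential neighbours.  ``packing`` <= 0
    or a single segment yields an extended arrangement with no medium/long
    contacts.  Deterministic given ``seed``.
    """
    n_segments = n_helices + n_strands
    if n_segments < 1:
        raise ValueError("need at least one segment")
    if packing != 0 and abs(packing) < 4.0:
        raise ValueError(f"packing {packing} A would clash segment axes")
    rng = np.random.default_rng(seed)
    kinds = list("H" * n_helices + "E" * n_strands)
    rng.shuffle(kinds)
    spacing = packing if packing > 0 else 30.0  # unpacked: far apart
    ca_parts, cb_parts, ss_parts = [], [], []
    prev_end = None
    lengths = [int(rng.integers(segment_length[0], segment_length[1] + 1))
               for _ in kinds]
    span = max(
        (l - 1) * (HELIX_RISE if k == "H" else STRAND_RISE)
        for k, l in zip(kinds, lengths)
    )
    for s, (kind, seg_len) in enumerate(zip(kinds, lengths)):
        direction = 1 if s % 2 == 0 else -1
        rise = HELIX_RISE if kind == "H" else STRAND_RISE
        own_span = (seg_len - 1) * rise
        # centre every segment on the shared z midpoint so neighbours overlap
        z0 = (span - direction * own_span) / 2.0
        origin = np.array([s * spacing, 0.0, z0])
        seg_ca, seg_cb = _segment_coords(kind, seg_len, origin, direction)
        if prev_end is not None:
            loop = np.linspace(prev_end, seg_ca[0], loop_length + 2)[1:-1]
            loop[:, 1] += 6.0  # bow the loop out of the contact zone
            ca_parts.append(loop)
            cb_parts.append(loop + np.array([0.0, CB_OFFSET, 0.0]))
            ss_parts.extend("C" * loop_length)
        ca_parts.append(seg_ca)
        cb_parts.append(seg_cb)
        ss_parts.extend(kind * seg_len)
        prev_end = seg_ca[-1]
    ca = np.vstack(ca_parts)
    cb = np.vstack(cb_parts)
    ss = np.array([SS_CODES[c] for c in ss_parts], dtype=np.int64)
    return {"ca": ca, "cb": cb, "ss_labels": ss}


def random_sequence(length: int, rng: np.random.Generator,
                    glycine_rate: float = GLYCINE_RATE) -> str:
    letters = [a for a in AMINO_ACIDS if a != "G"]
    seq = [letters[int(rng.integers(len(letters)))] for _ in range(length)]
    for i in range(length):
        if rng.random() < glycine_rate:
            seq[i] = "G"
    return "".join(seq)


def generate_covarying_msa(target: ProteinRecord, contacts,
                           depth: int = 300, mutation_rate: float = 0.35,
                           covariation_strength: float = 0.8,
                           gap_rate: float = 0.02,
                           seed: int = 0) -> Alignment:
    """MSA whose columns at contacting pairs mutate jointly.

    Each contact pair carries a random letter bijection; with probability
    ``covariation_strength`` a homolog draws a random letter for column i
    and the mapped letter for column j, creating mutual information above
    background.  Non-contact columns mutate independently at
    ``mutation_rate``; a few gaps are sprinkled outside the target row.
    """
    if depth < 2:
        raise ValueError("alignment depth must be >= 2")
    for name, rate in (("mutation_rate", mutation_rate),
                       ("covariation_strength", covariation_strength),
                       ("gap_rate", gap_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    L = target.length
    pairs = sorted({(min(i, j), max(i, j)) for (i, j) in contacts})
    perms = {pair: rng.permutation(20) for pair in pairs}
    rows = [target.sequence]
    aa = AMINO_ACIDS
    for _ in range(depth - 1):
        row = list(target.sequence)
        mutate = rng.random(L) < mutation_rate
        for i in np.nonzero(mutate)[0]:
            row[i] = aa[int(rng.integers(20))]
        for pair in pairs:
            if rng.random() < covariation_strength:
                a = int(rng.integers(20))
                row[pair[0]] = aa[a]
                row[pair[1]] = aa[int(perms[pair][a])]
        gaps = rng.random(L) < gap_rate
        for i in np.nonzero(gaps)[0]:
            row[i] = "-"
        rows.append("".join(row))
    return Alignment(rows=rows)


def fabricate_coevolution(mi: np.ndarray, noise: float = 0.05,
                          seed: int = 0) -> np.ndarray:
    """Toy coevolution score matrix: normalised MI plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    top = mi.max()
    coev = mi / top if top > 0 else mi.copy()
    coev = coev + noise * rng.standard_normal(coev.shape)
    coev = (coev + coev.T) / 2.0
    np.fill_diagonal(coev, 0.0)
    return coev


def generate_target(target_id: str, n_helices: int = 2, n_strands: int = 1,
                    packing: float = DEFAULT_PACKING, msa_depth: int = 300,
                    mutation_rate: float = 0.35,
                    covariation_strength: float = 0.8,
                    seed: int = 0) -> SyntheticTarget:
    """Full synthetic target: fold, labels, MSA, coevolution, 1D tracks."""
    rng = np.random.default_rng(seed)
    fold = generate_toy_fold(n_helices, n_strands, packing=packing,
                             seed=int(rng.integers(2 ** 31)))
    L = len(fold["ca"])
    record = ProteinRecord(id=target_id, sequence=random_sequence(L, rng))
    is_gly = np.array([a == "G" for a in record.sequence])
    contact_atom = np.where(is_gly[:, None], fold["ca"], fold["cb"])
    coords = ResidueCoords(contact_xyz=contact_atom,
                           sidechain_com=fold["cb"].copy(),
                           resolved=np.ones(L, dtype=bool))
    cmap = extract_native_contacts(coords)
    nonlocal_contacts = cmap.regime_pairs(("short", "medium", "long"))
    aln = generate_covarying_msa(
        record, nonlocal_contacts, depth=msa_depth,
        mutation_rate=mutation_rate,
        covariation_strength=covariation_strength,
        seed=int(rng.integers(2 ** 31)),
    )
    mi = compute_mutual_information(aln)
    coev = fabricate_coevolution(mi, seed=int(rng.integers(2 ** 31)))
    # noisy 3-state probabilities around the true labels
    ss = fold["ss_labels"]
    ss3 = np.full((L, 3), 0.1)
    ss3[np.arange(L), ss] = 0.8
    ss3 = ss3 + 0.05 * rng.random((L, 3))
    ss3 /= ss3.sum(axis=1, keepdims=True)
    # accessibility: radial distance from the fold centroid, squashed to [0,1]
    d = np.linalg.norm(fold["ca"] - fold["ca"].mean(axis=0), axis=1)
    acc = (d - d.min()) / (d.max() - d.min() + 1e-9)
    return SyntheticTarget(record=record, coords=coords, ca_xyz=fold["ca"],
                           contact_map=cmap, alignment=aln, coevolution=coev,
                           ss_labels=ss, ss3=ss3, accessibility=acc)


def featurize_target(target: SyntheticTarget,
                     potential: PairPotentialTable) -> np.ndarray:
    """Assemble the 51-channel tensor for one synthetic target."""
    profile = compute_profile(target.alignment)
    mi = compute_mutual_information(target.alignment)
    return assemble_features(target.record, profile, target.ss3,
                             target.accessibility, target.coevolution, mi,
                             potential)


@dataclass
class SyntheticDataset:
    """Train/validation split of synthetic targets plus its manifest."""

    train: list
    validation: list
    manifest: dict = field(default_factory=dict)


def generate_dataset(n_targets: int, length_range: tuple[int, int] = (40, 80),
                     validation_fraction: float = 0.2, seed: int = 0,
                     msa_depth: int = 300,
                     covariation_strength: float = 0.8) -> SyntheticDataset:
    """Generate ``n_targets`` toy targets and split them train/validation.

    Segment counts are drawn so that target lengths fall inside
    ``length_range``; ids are unique and the split is disjoint.
    """
    if n_targets < 2:
        raise ValueError("need at least 2 targets to split")
    n_val = max(1, int(round(validation_fraction * n_targets)))
    if n_val >= n_targets:
        raise ValueError("validation fraction leaves no training targets")
    rng = np.random.default_rng(seed)
    targets = []
    for k in range(n_targets):
        for _ in range(20):  # redraw until the length lands in range
            n_helices = int(rng.integers(1, 3))
            n_strands = int(rng.integers(1, 3))
            t = generate_target(
                f"toy{k:04d}", n_helices=n_helices, n_strands=n_strands,
                msa_depth=msa_depth,
                covariation_strength=covariation_strength,
                seed=int(rng.integers(2 ** 31)),
            )
            if length_range[0] <= t.length <= length_range[1]:
                break
        else:
            raise RuntimeError("could not generate a target in the length range")
        targets.append(t)
    order = rng.permutation(n_targets)
    val_ids = {targets[i].id for i in order[:n_val]}
    train = [t for t in targets if t.id not in val_ids]
    val = [t for t in targets if t.id in val_ids]
    manifest = {
        "n_targets": n_targets,
        "length_range": list(length_range),
        "seed": seed,
        "msa_depth": msa_depth,
        "covariation_strength": covariation_strength,
        "train_ids": [t.id for t in train],
        "validation_ids": [t.id for t in val],
    }
    return SyntheticDataset(train=train, validation=val, manifest=manifest)


def write_target_files(target: SyntheticTarget, outdir) -> dict:
    """Write FASTA / aligned FASTA / PDB / flat coevolution matrix files.

    Exercises the package's real readers; returns the path map.
    """
    import os

    from . import io as cio

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, f"{target.id}.fasta"),
        "alignment": os.path.join(outdir, f"{target.id}.aln.fasta"),
        "pdb": os.path.join(outdir, f"{target.id}.pdb"),
        "coevolution": os.path.join(outdir, f"{target.id}.coev.mat"),
    }
    cio.write_fasta(paths["fasta"], [target.record])
    cio.write_alignment(paths["alignment"], target.alignment.rows)
    cio.write_minimal_pdb(paths["pdb"], target.record, target.ca_xyz,
                          target.coords.contact_xyz,
                          resolved=target.coords.resolved)
    cio.write_flat_matrix(paths["coevolution"], target.coevolution)
    return paths
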