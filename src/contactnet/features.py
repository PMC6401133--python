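"""Assembly of the 51-channel per-pair feature tensor.

Each residue pair (i, j) of a length-L target is described by 51 channels:

======  =====================================================================
0-19    sequence profile row of residue i (20 amino-acid frequencies)
20-39   sequence profile row of residue j
40-42   3-state secondary-structure probabilities of residue i (H, E, C)
43-45   3-state secondary-structure probabilities of residue j
46      relative solvent accessibility of residue i, in [0, 1]
47      relative solvent accessibility of residue j
48      coevolution coupling score (symmetrised, zero diagonal)
49      mutual information between alignment columns i and j
50      statistical contact pair potential U(seq[i], seq[j])
======  =====================================================================

The 1D tracks (profile, secondary structure, accessibility) are turned into
2D features by concatenating the values of the two residues of a pair, so
``T[i, j, 0:20] == T[j, i, 20:40]`` and likewise for the other 1D blocks;
the three genuinely 2D channels are symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AMINO_ACIDS, AA_INDEX, CONTACT, ContactMap, ProteinRecord

N_CHANNELS = 51
GAP = "-"

#: channel-block boundaries, see module docstring
PROFILE_I = slice(0, 20)
PROFILE_J = slice(20, 40)
SS_I = slice(40, 43)
SS_J = slice(43, 46)
ACC_I = 46
ACC_J = 47
COEV = 48
MUTUAL_INFO = 49
PAIR_POTENTIAL = 50


@dataclass
class Alignment:
    """Multiple sequence alignment over the 20 amino acids plus gap.

    The first row is the ungapped target sequence; all rows share its width.
    """

    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        width = len(self.rows[0])
        if width == 0:
            raise ValueError("zero-width alignment")
        for k, row in enumerate(self.rows):
            if len(row) != width:
                raise ValueError(f"row {k} width {len(row)} != target width {width}")
        if GAP in self.rows[0]:
            raise ValueError("first alignment row (the target) must be ungapped")

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def encoded(self) -> np.ndarray:
        """Integer encoding, 0..19 amino acids, 20 for gap/unknown."""
        enc = np.full((self.depth, self.width), 20, dtype=np.int8)
        for r, row in enumerate(self.rows):
            for c, letter in enumerate(row):
                enc[r, c] = AA_INDEX.get(letter, 20)
        return enc


def compute_profile(aln: Alignment, pseudocount: float = 1.0) -> np.ndarray:
    """Per-column amino-acid frequency profile, L x 20, rows summing to 1.

    Gaps are excluded from the normalisation; ``pseudocount`` extra
    observations are spread uniformly over the 20 letters.  All-gap columns
    with zero pseudocount fall back to the uniform row.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    enc = aln.encoded()
    L = aln.width
    counts = np.zeros((L, 20), dtype=float)
    for a in range(20):
        counts[:, a] = (enc == a).sum(axis=0)
    counts += pseudocount / 20.0
    totals = counts.sum(axis=1, keepdims=True)
    uniform = np.full(20, 1.0 / 20)
    with np.errstate(invalid="ignore"):
        prof = np.where(totals > 0, counts / np.where(totals == 0, 1, totals), uniform)
    return prof


def compute_mutual_information(aln: Alignment, pseudocount: float = 0.0) -> np.ndarray:
    """Mutual information between alignment columns, natural log, L x L.

    MI(i, j) = sum_{a,b} f_ij(a,b) ln[ f_ij(a,b) / (f_i(a) f_j(b)) ] over the
    20-letter alphabet, computed from rows where both columns are ungapped.
    Marginals are taken from the (optionally pseudocount-smoothed) joint
    distribution, which keeps MI non-negative.  The diagonal is zero; no
    average-product correction is applied.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    enc = aln.encoded()
    L = aln.width
    mi = np.zeros((L, L), dtype=float)
    # one-hot encode once: (N, L, 21) is wasteful; use per-pair bincount
    valid = enc < 20
    for i in range(L):
        for j in range(i + 1, L):
            both = valid[:, i] & valid[:, j]
            if both.sum() == 0:
                continue
            pair_codes = enc[both, i].astype(np.int32) * 20 + enc[both, j]
            joint = np.bincount(pair_codes, minlength=400).astype(float)
            joint += pseudocount / 400.0
            joint /= joint.sum()
            joint = joint.reshape(20, 20)
            fi = joint.sum(axis=1)
            fj = joint.sum(axis=0)
            nz = joint > 0
            denom = np.outer(fi, fj)
            val = float((joint[nz] * np.log(joint[nz] / denom[nz])).sum())
            mi[i, j] = mi[j, i] = max(val, 0.0)
    return mi


def load_coevolution_matrix(path, sequence_length: int | None = None) -> np.ndarray:
    """Read a CCMpred-style flat score matrix, symmetrise, zero the diagonal."""
    from .io import read_flat_matrix

    mat = read_flat_matrix(path, expected_length=sequence_length)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    return mat


@dataclass
class PairPotentialTable:
    """Symmetric 20 x 20 table of contact pseudo-energies (log-odds)."""

    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.shape != (20, 20):
            raise ValueError("pair potential table must be 20 x 20")
        if not np.allclose(t, t.T):
            raise ValueError("pair potential table must be symmetric")
        if not np.isfinite(t).all():
            raise ValueError("pair potential table must be finite")
        self.table = t

    def lookup(self, a: str, b: str) -> float:
        """U for a residue pair; letters outside the alphabet get the mean."""
        ia, ib = AA_INDEX.get(a), AA_INDEX.get(b)
        if ia is None or ib is None:
            return float(self.table.mean())
        return float(self.table[ia, ib])

    def pair_matrix(self, sequence: str) -> np.ndarray:
        L = len(sequence)
        out = np.empty((L, L), dtype=float)
        for i, a in enumerate(sequence):
            for j, b in enumerate(sequence):
                out[i, j] = self.lookup(a, b)
        return out


def derive_pair_potential(
    structures: list[tuple[str, ContactMap]], smoothing: float = 1.0
) -> PairPotentialTable:
    """Knowledge-based contact potential from a corpus of structures.

    U(a, b) = -ln[ P_obs(a, b | contact) / P_exp(a, b) ], where the observed
    distribution counts amino-acid pairs over the corpus contacts (additively
    smoothed) and the expected distribution is the product of the corpus
    amino-acid composition.  Favourable (over-represented) contact pairs get
    negative energies.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    obs = np.zeros((20, 20), dtype=float)
    comp = np.zeros(20, dtype=float)
    n_contacts = 0
    for seq, cmap in structures:
        if cmap.length != len(seq):
            raise ValueError("sequence / contact-map length mismatch")
        for a in seq:
            ia = AA_INDEX.get(a)
            if ia is not None:
                comp[ia] += 1
        for (i, j) in cmap.contact_pairs():
            ia, ib = AA_INDEX.get(seq[i]), AA_INDEX.get(seq[j])
            if ia is None or ib is None:
                continue
            obs[ia, ib] += 1
            obs[ib, ia] += 1
            n_contacts += 1
    if n_contacts == 0:
        raise ValueError("corpus contains no contacts")
    obs += smoothing
    p_obs = obs / obs.sum()
    if comp.sum() == 0:
        raise ValueError("corpus contains no standard residues")
    freq = (comp + smoothing) / (comp + smoothing).sum()
    p_exp = np.outer(freq, freq)
    table = -np.log(p_obs / p_exp)
    table = (table + table.T) / 2.0
    return PairPotentialTable(table=table)


def _check_length(name: str, arr: np.ndarray, L: int, ndim_shape: tuple) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape != ndim_shape:
        raise ValueError(
            f"feature {name!r} has shape {arr.shape}, expected {ndim_shape} "
            f"for a length-{L} target"
        )
    return arr


def assemble_features(
    target: ProteinRecord,
    profile: np.ndarray,
    ss3: np.ndarray,
    accessibility: np.ndarray,
    coevolution: np.ndarray,
    mutual_information: np.ndarray,
    pair_potential: PairPotentialTable | np.ndarray,
) -> np.ndarray:
    """Build the L x L x 51 feature tensor for one target.

    ``pair_potential`` may be a table (looked up against the target
    sequence) or a precomputed L x L matrix.
    """
    L = target.length
    profile = _check_length("profile", profile, L, (L, 20))
    ss3 = _check_length("ss3", ss3, L, (L, 3))
    accessibility = _check_length("accessibility", np.ravel(accessibility), L, (L,))
    coevolution = _check_length("coevolution", coevolution, L, (L, L))
    mutual_information = _check_length(
        "mutual_information", mutual_information, L, (L, L)
    )
    if isinstance(pair_potential, PairPotentialTable):
        pot = pair_potential.pair_matrix(target.sequence)
    else:
        pot = _check_length("pair_potential", pair_potential, L, (L, L))

    T = np.zeros((L, L, N_CHANNELS), dtype=float)
    T[:, :, PROFILE_I] = profile[:, None, :]
    T[:, :, PROFILE_J] = profile[None, :, :]
    T[:, :, SS_I] = ss3[:, None, :]
    T[:, :, SS_J] = ss3[None, :, :]
    T[:, :, ACC_I] = accessibility[:, None]
    T[:, :, ACC_J] = accessibility[None, :]
    T[:, :, COEV] = coevolution
    T[:, :, MUTUAL_INFO] = mutual_information
    T[:, :, PAIR_POTENTIAL] = pot
    return T
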