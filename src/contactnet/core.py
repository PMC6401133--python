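"""Core domain types: protein records, residue coordinates, contact maps,
and sequence-separation regimes.

A *contact* between residues i and j is defined on the native structure: the
Euclidean distance between their contact atoms (C-beta, or C-alpha for
glycine and for residues whose C-beta is absent from the file) is strictly
below a threshold, 8 A by default.  Sequence separation ``|i - j|`` places a
pair in one of four regimes: local [1, 5], short [6, 11], medium [12, 23],
long [24, inf).  Medium and long range pairs are the ones that matter for
fold-level modelling and are the default evaluation focus throughout the
package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: ternary contact-map state codes
NON_CONTACT = 0
CONTACT = 1
IGNORED = 2

DEFAULT_CONTACT_THRESHOLD = 8.0  # Angstrom, strict '<'


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence over the 20-letter alphabet plus X."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise ValueError(f"{self.id}: invalid residue letters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ResidueCoords:
    """Per-residue coordinates used for contact extraction and restraints.

    ``contact_xyz``
        (L, 3) coordinate of the contact atom: C-beta, falling back to
        C-alpha for glycine and for residues lacking a C-beta.
    ``sidechain_com``
        (L, 3) side-chain center of mass (mass-weighted over non-backbone
        atoms; C-alpha for glycine / side-chain-less residues).
    ``resolved``
        (L,) boolean mask; unresolved residues carry NaN coordinates and are
        never silently zero-filled.
    """

    contact_xyz: np.ndarray
    sidechain_com: np.ndarray
    resolved: np.ndarray

    def __post_init__(self) -> None:
        self.contact_xyz = np.asarray(self.contact_xyz, dtype=float)
        self.sidechain_com = np.asarray(self.sidechain_com, dtype=float)
        self.resolved = np.asarray(self.resolved, dtype=bool)
        L = len(self.resolved)
        if self.contact_xyz.shape != (L, 3) or self.sidechain_com.shape != (L, 3):
            raise ValueError("coordinate arrays must be (L, 3)")
        if L == 0:
            raise ValueError("empty coordinate set")
        if np.isnan(self.contact_xyz[self.resolved]).any():
            raise ValueError("resolved residues must have finite contact coordinates")

    def __len__(self) -> int:
        return len(self.resolved)


@dataclass
class ContactMap:
    """Symmetric L x L ternary matrix over {non-contact, contact, ignored}.

    The diagonal is never ``contact``; any pair involving an unresolved
    residue is ``ignored``.
    """

    states: np.ndarray
    threshold: float = DEFAULT_CONTACT_THRESHOLD

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=np.int8)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("contact map must be square")
        if not np.isin(s, (NON_CONTACT, CONTACT, IGNORED)).all():
            raise ValueError("contact map states must be in {0, 1, 2}")
        if (s != s.T).any():
            raise ValueError("contact map must be symmetric")
        if (np.diag(s) == CONTACT).any():
            raise ValueError("diagonal pairs cannot be contacts")
        self.states = s

    @property
    def length(self) -> int:
        return self.states.shape[0]

    def contact_pairs(self, min_separation: int = 0) -> set[tuple[int, int]]:
        """Upper-triangle (i, j) pairs in the ``contact`` state."""
        ii, jj = np.nonzero(np.triu(self.states == CONTACT, k=1))
        return {(int(i), int(j)) for i, j in zip(ii, jj) if j - i >= min_separation}

    def regime_pairs(self, regimes: "RegimeSpec") -> set[tuple[int, int]]:
        """Contact pairs whose separation falls in any of ``regimes``."""
        names = _regime_names(regimes)
        return {
            (i, j)
            for (i, j) in self.contact_pairs()
            if classify_range(i, j).name.lower() in names
        }


class RangeRegime(enum.Enum):
    """Sequence-separation regime; bounds are inclusive on both ends."""

    LOCAL = (1, 5)
    SHORT = (6, 11)
    MEDIUM = (12, 23)
    LONG = (24, None)

    @property
    def bounds(self) -> tuple[int, int | None]:
        return self.value


RegimeSpec = "str | RangeRegime | tuple"

#: regimes used for fold-level evaluation throughout the package
MEDIUM_LONG = ("medium", "long")
NON_LOCAL = ("short", "medium", "long")


def _regime_names(regimes) -> frozenset[str]:
    if isinstance(regimes, (str, RangeRegime)):
        regimes = (regimes,)
    names = set()
    for r in regimes:
        name = r.name if isinstance(r, RangeRegime) else str(r)
        name = name.lower()
        if name.upper() not in RangeRegime.__members__:
            raise ValueError(f"unknown regime {r!r}")
        names.add(name)
    return frozenset(names)


def classify_range(i: int, j: int) -> RangeRegime:
    """Regime of the pair (i, j), determined solely by ``|i - j|``."""
    if i == j:
        raise ValueError("classify_range requires i != j")
    sep = abs(i - j)
    if sep <= 5:
        return RangeRegime.LOCAL
    if sep <= 11:
        return RangeRegime.SHORT
    if sep <= 23:
        return RangeRegime.MEDIUM
    return RangeRegime.LONG


def separation_mask(L: int, regimes) -> np.ndarray:
    """Boolean (L, L) mask of pairs whose separation lies in ``regimes``."""
    names = _regime_names(regimes)
    sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    mask = np.zeros((L, L), dtype=bool)
    for name in names:
        lo, hi = RangeRegime[name.upper()].bounds
        m = sep >= lo if hi is None else (sep >= lo) & (sep <= hi)
        mask |= m
    return mask


def extract_native_contacts(
    coords: ResidueCoords,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    sequence_length: int | None = None,
) -> ContactMap:
    """Build the ternary native contact map from residue coordinates.

    A pair (i, j) is ``contact`` iff both residues are resolved and their
    contact atoms lie strictly closer than ``threshold`` (in A); pairs
    involving an unresolved residue are ``ignored``; everything else,
    including the diagonal, is ``non-contact``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    L = len(coords)
    if sequence_length is not None and sequence_length != L:
        raise ValueError(
            f"coordinate count {L} does not match sequence length {sequence_length}"
        )
    xyz = np.where(coords.resolved[:, None], coords.contact_xyz, 0.0)
    dist = squareform(pdist(xyz))
    states = np.where(dist < threshold, CONTACT, NON_CONTACT).astype(np.int8)
    np.fill_diagonal(states, NON_CONTACT)
    missing = ~coords.resolved
    states[missing, :] = IGNORED
    states[:, missing] = IGNORED
    return ContactMap(states=states, threshold=threshold)


def validate_prediction_map(pred: np.ndarray) -> np.ndarray:
    """Check a contact-probability map is square, symmetric and in [0, 1]."""
    p = np.asarray(pred, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("prediction map must be square")
    if not np.allclose(p, p.T, atol=1e-8):
        raise ValueError("prediction map must be symmetric")
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")
    return p


def positive_predictions(
    pred: np.ndarray, cutoff: float = 0.5
) -> set[tuple[int, int]]:
    """Upper-triangle pairs predicted in contact, i.e. with P strictly > cutoff."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    p = validate_prediction_map(pred)
    ii, jj = np.nonzero(np.triu(p > cutoff, k=1))
    return {(int(i), int(j)) for i, j in zip(ii, jj)}
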