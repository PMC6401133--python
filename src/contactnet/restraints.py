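"""Conversion of confident contact predictions into modelling restraints.

Every positive prediction (P strictly above the cutoff, 0.5 by default)
becomes one distance restraint: an 8.0 A upper bound between the
side-chain centers of mass of the two residues, carrying the prediction
probability as its confidence.  Predicted contacts can be merged with
template-derived contacts as a tagged union before conversion; template
pairs keep their own origin tag so downstream modelling can leave
template restraints unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import positive_predictions, validate_prediction_map

RESTRAINT_BOUND = 8.0  # Angstrom, side-chain center-of-mass upper bound
ANCHOR = "sidechain_com"


@dataclass(frozen=True)
class Restraint:
    """Upper distance bound between the side-chain COMs of residues i < j."""

    i: int
    j: int
    bound: float = RESTRAINT_BOUND
    anchor: str = ANCHOR
    probability: float = 1.0
    source: str = "predicted"

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError("restraint requires i < j")
        if self.bound <= 0:
            raise ValueError("bound must be positive")
        if not 0.0 < self.probability <= 1.0:
            raise ValueError("probability must lie in (0, 1]")


def contacts_to_restraints(pred: np.ndarray, cutoff: float = 0.5,
                           bound: float = RESTRAINT_BOUND,
                           sources: dict | None = None) -> list[Restraint]:
    """One restraint per positive prediction, sorted by descending P.

    ``sources`` optionally maps (i, j) pairs to an origin tag (e.g.
    'template' from :func:`combine_contact_sources`).
    """
    p = validate_prediction_map(pred)
    pairs = positive_predictions(p, cutoff)
    sources = sources or {}
    restraints = [
        Restraint(i=i, j=j, bound=bound, probability=float(p[i, j]),
                  source=sources.get((i, j), "predicted"))
        for (i, j) in pairs
    ]
    restraints.sort(key=lambda r: (-r.probability, r.i, r.j))
    return restraints


def combine_contact_sources(template_contacts, pred: np.ndarray,
                            mode: str = "union",
                            template_floor: float = 0.5):
    """Merge template-derived contacts with predicted probabilities.

    Union mode (the default and only mode): predicted probabilities are
    retained; template pairs absent from (or below the floor in) the
    prediction are injected at ``template_floor`` so that they survive the
    positive-prediction cutoff.  Returns (combined map, source tags), the
    tags marking pairs of template origin so their restraints can be kept
    unchanged downstream.
    """
    if mode != "union":
        raise ValueError(f"unknown combination mode {mode!r}")
    p = validate_prediction_map(pred).copy()
    L = p.shape[0]
    tags: dict[tuple[int, int], str] = {}
    for (i, j) in template_contacts:
        i, j = int(i), int(j)
        if i > j:
            i, j = j, i
        if not (0 <= i < L and 0 <= j < L):
            raise ValueError(
                f"template contact {(i, j)} outside a length-{L} target"
            )
        tags[(i, j)] = "template"
        val = max(p[i, j], template_floor)
        p[i, j] = p[j, i] = val
    return p, tags


def write_restraints_tsv(path, restraints: list[Restraint]) -> None:
    """TSV restraint file: i, j (1-based), bound_A, anchor, P, source.

    The header spells out the atom-selection semantics so generic
    modelling engines can consume the file.
    """
    with open(path, "w") as fh:
        fh.write("# upper distance bounds between side-chain centers of mass\n")
        fh.write("# (glycine: C-alpha); residue numbering is 1-based\n")
        fh.write("i\tj\tbound_A\tanchor\tP\tsource\n")
        for r in restraints:
            fh.write(f"{r.i + 1}\t{r.j + 1}\t{r.bound:.1f}\t{r.anchor}\t"
                     f"{r.probability:.6f}\t{r.source}\n")


def read_restraints_tsv(path) -> list[Restraint]:
    restraints = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("i\t"):
                continue
            toks = line.split()
            if len(toks) != 6:
                raise ValueError(f"{path}: malformed restraint line {line!r}")
            restraints.append(Restraint(
                i=int(toks[0]) - 1, j=int(toks[1]) - 1, bound=float(toks[2]),
                anchor=toks[3], probability=float(toks[4]), source=toks[5],
            ))
    return restraints
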