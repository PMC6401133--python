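"""CASP-style evaluation of contact predictions.

The headline metric is top-L/k precision: rank the eligible residue pairs
(upper triangle, requested separation regimes, not ``ignored`` in the
native map) by predicted probability, take the ceil(L/k) best (k = 1, 2, 5,
10), and report the fraction that are native contacts.  Targets without any
native contact in the requested regimes score zero, mirroring the CASP
convention of always grading the top predictions.  Two secondary views:
precision within probability bins of the positive predictions (P > 0.5),
and the contact prediction depth D — the number of confident medium/long
predictions (P > 0.8) divided by L.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .core import (CONTACT, IGNORED, ContactMap, MEDIUM_LONG,
                   separation_mask, validate_prediction_map)

DEFAULT_KS = (1, 2, 5, 10)
DEFAULT_BIN_EDGES = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
CONFIDENT_CUTOFF = 0.8


def _eligible_pairs(L: int, regimes, native: ContactMap | None):
    """Upper-triangle pairs in the regimes, minus native-ignored pairs."""
    mask = np.triu(separation_mask(L, regimes), k=1)
    if native is not None:
        mask &= native.states != IGNORED
    return np.nonzero(mask)


def ranked_pairs(pred: np.ndarray, native: ContactMap | None = None,
                 regimes=MEDIUM_LONG) -> list[tuple[int, int]]:
    """Eligible pairs ranked by P descending, ties by ascending (i, j)."""
    p = validate_prediction_map(pred)
    ii, jj = _eligible_pairs(p.shape[0], regimes, native)
    order = np.lexsort((jj, ii, -p[ii, jj]))
    return [(int(ii[k]), int(jj[k])) for k in order]


def top_k_precision(pred: np.ndarray, native: ContactMap, k: int = 5,
                    regimes=MEDIUM_LONG) -> float:
    """Precision of the top ceil(L/k) predictions in the given regimes.

    If fewer eligible pairs exist than ceil(L/k), all are taken and the
    denominator is the number taken.  A target with zero native contacts in
    the regimes scores 0.0.
    """
    p = validate_prediction_map(pred)
    if p.shape != native.states.shape:
        raise ValueError("prediction / native shape mismatch")
    if k < 1:
        raise ValueError("k must be >= 1")
    L = native.length
    ranked = ranked_pairs(p, native, regimes)
    n_native = sum(
        1 for (i, j) in ranked if native.states[i, j] == CONTACT
    )
    if n_native == 0:
        return 0.0
    take = min(math.ceil(L / k), len(ranked))
    if take == 0:
        return 0.0
    chosen = ranked[:take]
    tp = sum(1 for (i, j) in chosen if native.states[i, j] == CONTACT)
    return tp / take


def precision_by_probability_bin(pred: np.ndarray, native: ContactMap,
                                 bin_edges=DEFAULT_BIN_EDGES,
                                 regimes=("short", "medium", "long")):
    """Counts and precision of positive predictions, binned by probability.

    Positives are pairs with P > the lowest edge (0.5 by default), among
    resolved (non-ignored) pairs in the regimes.  Bins are [lo, hi), with
    the last bin closed at 1.  Empty bins report precision None rather
    than 0.
    """
    edges = list(bin_edges)
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly ascending")
    if edges[0] < 0.5 or edges[-1] > 1.0 or edges[0] <= 0:
        raise ValueError("bin edges must lie within [0.5, 1]")
    p = validate_prediction_map(pred)
    if p.shape != native.states.shape:
        raise ValueError("prediction / native shape mismatch")
    ii, jj = _eligible_pairs(native.length, regimes, native)
    probs = p[ii, jj]
    correct = native.states[ii, jj] == CONTACT
    out = []
    for lo, hi in zip(edges, edges[1:]):
        sel = (probs > lo) if lo == edges[0] else (probs >= lo)
        sel &= (probs <= hi) if hi == edges[-1] else (probs < hi)
        n = int(sel.sum())
        out.append({
            "lo": lo,
            "hi": hi,
            "count": n,
            "precision": float(correct[sel].mean()) if n else None,
        })
    return out


def prediction_depth(pred: np.ndarray, native: ContactMap | None = None,
                     length: int | None = None,
                     cutoff: float = CONFIDENT_CUTOFF,
                     regimes=MEDIUM_LONG) -> float:
    """Contact prediction depth D = |confident predictions| / L.

    Confident means P strictly above ``cutoff`` (default 0.8) among
    eligible pairs in the regimes (default medium/long).
    """
    p = validate_prediction_map(pred)
    L = length if length is not None else p.shape[0]
    if L < 1:
        raise ValueError("length must be >= 1")
    ii, jj = _eligible_pairs(p.shape[0], regimes, native)
    return float((p[ii, jj] > cutoff).sum()) / L


@dataclass
class EvalReport:
    """Per-target evaluation: top-L/k precisions, bin precisions, depth."""

    target_id: str
    length: int
    precisions: dict = field(default_factory=dict)  # (k, regime-name) -> float
    bins: list = field(default_factory=list)
    depth: float = 0.0

    def to_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "length": self.length,
            "precisions": {f"top_L{k}_{name}": v
                           for (k, name), v in self.precisions.items()},
            "bins": self.bins,
            "depth": self.depth,
        }


REGIME_SETS = {
    "short": ("short",),
    "medium": ("medium",),
    "long": ("long",),
    "medium_long": ("medium", "long"),
    "non_local": ("short", "medium", "long"),
}


def evaluate_target(target_id: str, pred: np.ndarray, native: ContactMap,
                    ks=DEFAULT_KS, regime_sets=None) -> EvalReport:
    """Full CASP-style report for one target."""
    regime_sets = regime_sets or REGIME_SETS
    report = EvalReport(target_id=target_id, length=native.length)
    for name, regimes in regime_sets.items():
        for k in ks:
            report.precisions[(k, name)] = top_k_precision(
                pred, native, k=k, regimes=regimes
            )
    report.bins = precision_by_probability_bin(pred, native)
    report.depth = prediction_depth(pred, native)
    return report


def write_report_tsv(path, reports: list[EvalReport]) -> None:
    import pandas as pd

    rows = []
    for r in reports:
        row = {"target_id": r.target_id, "length": r.length, "depth": r.depth}
        for (k, name), v in r.precisions.items():
            row[f"top_L{k}_{name}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_aggregate_json(path, reports: list[EvalReport]) -> None:
    keys = reports[0].precisions.keys() if reports else []
    agg = {}
    for key in keys:
        vals = [r.precisions[key] for r in reports]
        agg[f"top_L{key[0]}_{key[1]}"] = {
            "mean": float(np.mean(vals)),
            "median": float(np.median(vals)),
        }
    agg["depth"] = {
        "mean": float(np.mean([r.depth for r in reports])) if reports else 0.0,
        "median": float(np.median([r.depth for r in reports])) if reports else 0.0,
    }
    with open(path, "w") as fh:
        json.dump(agg, fh, indent=2)
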