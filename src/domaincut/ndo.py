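"""Normalized Domain Overlap (NDO) scoring of domain predictions.

A prediction and a reference annotation each give every residue a domain
label (or none, for linkers). Because the ordinal labels are arbitrary
bookkeeping, the predicted labels are first realigned to the reference by
stable-marriage (Gale–Shapley) matching, with preferences given by the
residue-overlap between each label pair — so a prediction that is correct up
to a relabelling is not penalized. The score then compares per-residue label
agreement over the l residues labelled on both sides, truncated below at 0
to give values in [0, 100].

Two normalizations are provided and must be chosen explicitly downstream:

- ``balanced``: 100 · (2M − l) / l, where M is the number of agreeing
  residues — mismatches actively penalize, so truncation at 0 is meaningful;
- ``fraction``: 100 · M / l, the plain agreement fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .domains import DomainAnnotation, label_residues

logger = logging.getLogger(__name__)

__all__ = ["NdoResult", "overlap_matrix", "stable_marriage_match", "ndo_score"]

VARIANTS = ("balanced", "fraction")


@dataclass
class NdoResult:
    """Outcome of an NDO comparison.

    score is the truncated value in [0, 100]; raw the pre-truncation value;
    matching maps reference labels to the predicted labels they were paired
    with; l counts residues labelled on both sides, M those whose matched
    labels agree.
    """

    score: float
    raw: float
    matching: dict[int, int]
    l: int
    M: int
    variant: str


def overlap_matrix(ref_labels: np.ndarray, pred_labels: np.ndarray):
    """Residue-overlap counts between reference and predicted labels.

    Returns (ref_label_ids, pred_label_ids, matrix) where matrix[a, b] is the
    number of residues carrying ref label ref_label_ids[a] and pred label
    pred_label_ids[b]. Residues unlabeled (0) on either side are excluded.
    """
    ref_labels = np.asarray(ref_labels)
    pred_labels = np.asarray(pred_labels)
    if ref_labels.shape != pred_labels.shape:
        raise ValueError("label vectors differ in length")
    both = (ref_labels > 0) & (pred_labels > 0)
    r, p = ref_labels[both], pred_labels[both]
    ref_ids = np.unique(r)
    pred_ids = np.unique(p)
    matrix = np.zeros((len(ref_ids), len(pred_ids)), dtype=np.int64)
    ri = np.searchsorted(ref_ids, r)
    pi = np.searchsorted(pred_ids, p)
    np.add.at(matrix, (ri, pi), 1)
    return ref_ids, pred_ids, matrix


def stable_marriage_match(matrix: np.ndarray) -> dict[int, int]:
    """Stable matching of row labels to column labels by overlap size.

    Gale–Shapley with rows (reference labels) proposing; each side ranks the
    other by descending overlap, ties broken toward the lower index. Unequal
    side sizes are padded with zero-overlap dummies whose pairings are
    dropped. Returns {row index: column index}. The result is stable: no
    (row, column) pair strictly prefer each other (under the tie-broken
    order) to their assigned partners.
    """
    matrix = np.asarray(matrix)
    n_rows, n_cols = matrix.shape if matrix.ndim == 2 else (0, 0)
    if n_rows == 0 or n_cols == 0:
        return {}
    n = max(n_rows, n_cols)
    padded = np.zeros((n, n), dtype=float)
    padded[:n_rows, :n_cols] = matrix

    # preference lists: descending overlap, ties toward lower index
    row_pref = [sorted(range(n), key=lambda c: (-padded[r, c], c)) for r in range(n)]
    # col_rank[c][r] = position of row r in column c's preference order
    col_rank = np.empty((n, n), dtype=np.int64)
    for c in range(n):
        order = sorted(range(n), key=lambda r: (-padded[r, c], r))
        for pos, r in enumerate(order):
            col_rank[c, r] = pos

    next_proposal = [0] * n
    col_partner = [-1] * n
    free = list(range(n - 1, -1, -1))
    while free:
        r = free.pop()
        c = row_pref[r][next_proposal[r]]
        next_proposal[r] += 1
        cur = col_partner[c]
        if cur == -1:
            col_partner[c] = r
        elif col_rank[c, r] < col_rank[c, cur]:
            col_partner[c] = r
            free.append(cur)
        else:
            free.append(r)
    return {r: c for c, r in enumerate(col_partner) if r < n_rows and c < n_cols}


def ndo_score(
    ref: DomainAnnotation, pred: DomainAnnotation, variant: str = "balanced"
) -> NdoResult:
    """NDO score of a prediction against a reference annotation.

    Residues unlabeled in either annotation (linkers) are ignored: l counts
    residues labelled on both sides, and M those whose reference label maps
    (through the stable matching) to the predicted label. The raw score is
    100·(2M − l)/l (``balanced``) or 100·M/l (``fraction``); the returned
    score truncates negatives to 0. l = 0 gives score 0 with a warning.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown NDO variant {variant!r}")
    if ref.length != pred.length:
        raise ValueError(f"length mismatch: reference {ref.length}, prediction {pred.length}")
    ref_lab = label_residues(ref)
    pred_lab = label_residues(pred)
    ref_ids, pred_ids, matrix = overlap_matrix(ref_lab, pred_lab)
    idx_match = stable_marriage_match(matrix)
    matching = {int(ref_ids[r]): int(pred_ids[c]) for r, c in idx_match.items()}

    both = (ref_lab > 0) & (pred_lab > 0)
    l = int(both.sum())
    if l == 0:
        logger.warning("no residues labelled in both annotations; NDO undefined, scoring 0")
        return NdoResult(0.0, 0.0, matching, 0, 0, variant)
    mapped = np.array([matching.get(int(a), -1) for a in ref_lab])
    M = int((both & (mapped == pred_lab)).sum())
    if variant == "balanced":
        raw = 100.0 * (2 * M - l) / l
    else:
        raw = 100.0 * M / l
    return NdoResult(max(0.0, raw), raw, matching, l, M, variant)
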