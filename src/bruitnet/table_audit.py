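"""Audit of the published results table via confusion-matrix reconstruction.

The published evaluation pooled a test set of 111 recordings (85 normal,
26 abnormal) and printed accuracy / precision / recall / F1 to four decimals.
Those printed values are inputs here: for each row we exhaustively search for
the integer confusion matrices consistent with the printed accuracy,
precision, and recall, and check whether the implied F1 agrees with the
printed one.  One row ("contrastive") is internally inconsistent — no integer
matrix reproduces its printed triple — and the audit reports that rather than
resolving it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .evaluate import ConfusionMatrix, compute_metrics, reconstruct_confusion

__all__ = ["PrintedRow", "PRINTED_ROWS", "N_POS", "N_NEG", "audit_row", "audit_all"]

N_POS = 26
N_NEG = 85


@dataclass(frozen=True)
class PrintedRow:
    method: str
    accuracy: float
    precision: float
    recall: float
    f1: float


#: the published per-method metrics (test set: 85 normal, 26 abnormal)
PRINTED_ROWS: tuple[PrintedRow, ...] = (
    PrintedRow("scratch", 0.8649, 0.7391, 0.6538, 0.6939),
    PrintedRow("panns", 0.8919, 0.8182, 0.6923, 0.7500),
    PrintedRow("contrastive", 0.9279, 0.8462, 0.8077, 0.8400),
    PrintedRow("human_evaluator_1", 0.7117, 0.4400, 0.8461, 0.5789),
    PrintedRow("human_evaluator_2", 0.7837, 0.5294, 0.6923, 0.5999),
)


@dataclass
class AuditResult:
    row: PrintedRow
    matrices: list[ConfusionMatrix]
    consistent: bool          # at least one integer matrix matches acc/prec/rec
    unique: bool
    f1_implied: float | None  # F1 of the unique matrix, if any
    f1_matches: bool | None   # implied F1 renders as the printed F1


def audit_row(row: PrintedRow, n_pos: int = N_POS, n_neg: int = N_NEG) -> AuditResult:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            matrices = reconstruct_confusion(row.accuracy, row.precision, row.recall, n_pos, n_neg)
    except ValueError:
        return AuditResult(row, [], False, False, None, None)
    if len(matrices) != 1:
        return AuditResult(row, matrices, True, False, None, None)
    cm = matrices[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f1 = compute_metrics(cm).f1
    from .evaluate import _matches_printed

    return AuditResult(row, matrices, True, True, f1, _matches_printed(f1, row.f1))


def audit_all() -> dict[str, AuditResult]:
    return {row.method: audit_row(row) for row in PRINTED_ROWS}
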