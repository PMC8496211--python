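"""Benchmark arithmetic: precision / recall / false-positive rate, and
cell-by-cell disagreement between two ortholog call sets.

Precision and recall follow the usual confusion-count definitions for
single-copy gene identification:

    precision = TP / (TP + FP)        recall = TP / (TP + FN)

No true-negative count exists in this setting (there is no finite universe
of "genes correctly not called"), so the false-positive rate reported here is
``FP / (TP + FP) = 1 - precision``, the share of calls that are wrong.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .errors import FormatError, InputError

Cell = tuple[str, str]  # (gene/profile, proteome)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class Metrics:
    """Full-precision metrics plus their conventional 2-decimal renderings.

    A metric whose denominator is zero is ``None`` (never silently 0/0).
    """

    precision: float | None
    recall: float | None
    false_positive_rate: float | None

    def rounded(self) -> dict[str, float | None]:
        return {
            name: None if v is None else round(v, 2)
            for name, v in (
                ("precision", self.precision),
                ("recall", self.recall),
                ("false_positive_rate", self.false_positive_rate),
            )
        }


@dataclass(frozen=True)
class CallSetComparison:
    n_genes: int
    n_proteomes: int
    n_differing: int

    @property
    def n_cells(self) -> int:
        return self.n_genes * self.n_proteomes

    @property
    def pct_differing(self) -> float:
        pct = (Decimal(100) * Decimal(self.n_differing) / Decimal(self.n_cells)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
        return float(pct)


def evaluation_metrics(c: ConfusionCounts) -> Metrics:
    """Precision, recall and false-positive rate from confusion counts."""
    pos = c.TP + c.FP
    true = c.TP + c.FN
    if pos == 0 and true == 0:
        warnings.warn("TP+FP and TP+FN are both zero; all metrics undefined",
                      stacklevel=2)
        return Metrics(None, None, None)
    precision = c.TP / pos if pos else None
    recall = c.TP / true if true else None
    fpr = c.FP / pos if pos else None
    return Metrics(precision=precision, recall=recall, false_positive_rate=fpr)


def confusion_from_calls(
    calls: dict, truth: dict, positive_status: str = "single_copy"
) -> ConfusionCounts:
    """Tally TP/FP/FN of ``positive_status`` calls against a truth table.

    Both arguments map a key (gene, or (gene, proteome)) to a status string.
    Keys present in only one mapping raise, so partial grids are caught.
    """
    missing = set(truth) ^ set(calls)
    if missing:
        raise InputError(f"calls and truth cover different cells: {sorted(missing)[:5]} ...")
    tp = fp = fn = 0
    for key, truth_status in truth.items():
        called = calls[key] == positive_status
        actual = truth_status == positive_status
        tp += called and actual
        fp += called and not actual
        fn += actual and not called
    return ConfusionCounts(TP=tp, FP=fp, FN=fn)


def compare_callsets(a: dict, b: dict, equal=None) -> CallSetComparison:
    """Count grid cells on which two call sets disagree.

    ``a`` and ``b`` map (gene, proteome) cells to statuses and must cover the
    same grid.  ``equal(x, y)`` is the cell-equality predicate (default:
    status equality), so callers can plug in orthogroup-membership notions of
    agreement.  Symmetric in its arguments under the default predicate.
    """
    if set(a) != set(b):
        missing = sorted(set(a) ^ set(b))
        raise InputError(f"call sets cover different cells, e.g. {missing[:5]}")
    if equal is None:
        equal = lambda x, y: x == y
    genes = sorted({g for g, _ in a})
    proteomes = sorted({p for _, p in a})
    if len(a) != len(genes) * len(proteomes):
        raise InputError(
            f"call set is not a full grid: {len(a)} cells for "
            f"{len(genes)} genes x {len(proteomes)} proteomes"
        )
    n_diff = sum(0 if equal(a[cell], b[cell]) else 1 for cell in a)
    return CallSetComparison(
        n_genes=len(genes), n_proteomes=len(proteomes), n_differing=n_diff
    )


# ---------------------------------------------------------------------------
# TSV ingestion


def read_calls_long_summary(path: str | Path) -> dict[Cell, str]:
    """Load (gene, proteome) -> status from a pipeline ``long_summary.txt``."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"call-set file not found: {path}")
    calls: dict[Cell, str] = {}
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:3] != ["proteome", "hmm", "status"]:
            raise FormatError(f"{path}: not a long_summary table")
        for row in reader:
            if not row:
                continue
            proteome, hmm, status = row[0], row[1], row[2]
            cell = (hmm, proteome)
            if cell in calls and calls[cell] != status:
                raise FormatError(f"{path}: conflicting statuses for {cell}")
            calls[cell] = status
    return calls


def read_truth_tsv(path: str | Path) -> dict:
    """Load a truth table: ``gene<TAB>status`` or ``gene<TAB>proteome<TAB>status``.

    Two-column rows key by gene alone; three-column rows key by
    (gene, proteome).  ``#`` comments and a recognisable header are skipped.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"truth file not found: {path}")
    truth: dict = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[-1] in ("status", "expected_status"):
                continue
            if len(fields) == 2:
                truth[fields[0]] = fields[1]
            elif len(fields) >= 3:
                truth[(fields[0], fields[1])] = fields[2]
            else:
                raise FormatError(f"{path}:{lineno}: expected 2 or 3 tab-separated columns")
    if not truth:
        raise InputError(f"{path}: empty truth table")
    return truth
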