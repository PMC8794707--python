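"""Disease expression restrictions from differential-expression tables.

The pipeline contract starts at the statistics level: a table of
transcript-level log2 fold changes and multiplicity-adjusted p-values
(typically a GEO2R / limma export), already mapped to UniProtKB
accessions.  Records passing ``adj_p < alpha`` and ``|logFC| > lfc_min``
(both strict) are collapsed to one up/down restriction per protein;
proteins whose transcripts disagree in direction are discarded and
reported.  The resulting restrictions constrain the disease-state
simulations downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence, Union

import math

import pandas as pd

from .errors import UnmappedTranscriptError
from .knowledge_base import ProteinRef

__all__ = [
    "DifferentialExpressionRecord",
    "ExpressionRestriction",
    "filter_de_records",
    "collapse_to_protein_restrictions",
    "CollapseResult",
    "derive_restrictions",
    "read_de_table",
    "write_restrictions",
]


@dataclass(frozen=True)
class DifferentialExpressionRecord:
    """One transcript-level differential-expression result."""

    transcript_id: str
    protein: ProteinRef | None
    logFC: float
    adj_p: float

    def __post_init__(self):
        if not (0.0 <= self.adj_p <= 1.0):
            raise ValueError(f"adj_p must be in [0,1], got {self.adj_p}")
        if not math.isfinite(self.logFC):
            raise ValueError("logFC must be finite")


@dataclass(frozen=True)
class ExpressionRestriction:
    """A protein-level up/down constraint: +1 up in disease, -1 down."""

    protein: ProteinRef
    sign: int

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValueError(f"restriction sign must be +1/-1, got {self.sign}")


def filter_de_records(
    records: Sequence[DifferentialExpressionRecord],
    alpha: float = 0.01,
    lfc_min: float = 2.0,
) -> list[DifferentialExpressionRecord]:
    """Keep records with ``adj_p < alpha`` and ``|logFC| > lfc_min``.

    Both comparisons are strict; input order is preserved.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    if lfc_min < 0:
        raise ValueError("lfc_min must be >= 0")
    return [
        r for r in records if r.adj_p < alpha and abs(r.logFC) > lfc_min
    ]


class CollapseResult(NamedTuple):
    restrictions: list[ExpressionRestriction]
    discarded_proteins: list[str]
    dropped_unsigned: int


def collapse_to_protein_restrictions(
    records: Sequence[DifferentialExpressionRecord],
) -> CollapseResult:
    """Collapse transcript records to one signed restriction per protein.

    Proteins whose records all share a single logFC direction yield one
    restriction with that sign; proteins observed in both directions are
    discarded and reported.  ``logFC == 0`` records carry no direction and
    are ignored for sign determination (counted in ``dropped_unsigned``).
    Records without a protein mapping raise
    :class:`UnmappedTranscriptError` listing the transcripts.
    """
    unmapped = [r.transcript_id for r in records if r.protein is None]
    if unmapped:
        raise UnmappedTranscriptError(unmapped)

    signs: dict[str, set[int]] = {}
    refs: dict[str, ProteinRef] = {}
    dropped_unsigned = 0
    for r in records:
        acc = r.protein.accession
        refs.setdefault(acc, r.protein)
        if r.logFC == 0:
            dropped_unsigned += 1
            continue
        signs.setdefault(acc, set()).add(1 if r.logFC > 0 else -1)

    restrictions, discarded = [], []
    for acc, ss in signs.items():
        if len(ss) == 1:
            restrictions.append(ExpressionRestriction(refs[acc], next(iter(ss))))
        else:
            discarded.append(acc)
    return CollapseResult(restrictions, discarded, dropped_unsigned)


def derive_restrictions(
    records: Sequence[DifferentialExpressionRecord],
    alpha: float = 0.01,
    lfc_min: float = 2.0,
) -> list[ExpressionRestriction]:
    """Filter then collapse: the full restriction-derivation step."""
    return collapse_to_protein_restrictions(
        filter_de_records(records, alpha=alpha, lfc_min=lfc_min)
    ).restrictions


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_de_table(
    source: Union[str, Path],
    drop_unmapped: bool = True,
) -> tuple[list[DifferentialExpressionRecord], int]:
    """Read a TSV with header (transcript_id, protein_accession, logFC, adj_p).

    Rows whose ``protein_accession`` is empty/NA are dropped when
    ``drop_unmapped`` (the count is returned alongside the records),
    otherwise kept with ``protein=None``.
    """
    df = pd.read_csv(source, sep="\t", dtype={"transcript_id": str})
    records: list[DifferentialExpressionRecord] = []
    n_unmapped = 0
    for row in df.itertuples(index=False):
        acc = getattr(row, "protein_accession")
        mapped = isinstance(acc, str) and acc.strip() != ""
        if not mapped:
            n_unmapped += 1
            if drop_unmapped:
                continue
        records.append(
            DifferentialExpressionRecord(
                transcript_id=str(row.transcript_id),
                protein=ProteinRef(acc) if mapped else None,
                logFC=float(row.logFC),
                adj_p=float(row.adj_p),
            )
        )
    return records, n_unmapped


def write_restrictions(
    restrictions: Iterable[ExpressionRestriction], path: Union[str, Path]
) -> None:
    """Write restrictions as TSV (protein_accession, sign)."""
    lines = ["protein_accession\tsign"]
    lines += [f"{r.protein.accession}\t{r.sign:+d}" for r in restrictions]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
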