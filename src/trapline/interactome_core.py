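"""Filtering cascade and pseudocounted PSM enrichment for bait interactomes.

The cascade removes single-peptide identifications and proteins that look
like bead/background binders in a negative-control sample (more than
``max_control_unique`` unique peptides there).  Survivors get a trap/reference
PSM ratio where a missing or zero reference count is replaced by 1 so the
ratio stays finite, and are prioritized on the joint (ratio, MS score)
evidence.  Two baits analysed with identical settings can be contrasted
accession by accession.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .errors import ValidationError
from .tables_io import IdentificationTable, ProteinRecord

logger = logging.getLogger(__name__)

SINGLE_PEPTIDE = "single_peptide"
CONTROL_BACKGROUND = "control_background"

AggregationMethod = Literal["sum", "mean_rounded"]
Strategy = Literal["ratio_first", "score_first"]


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-protein trap-vs-reference enrichment with filter provenance."""

    accession: str
    gene_symbol: str
    psm_trap: int
    psm_ref: int | None
    ratio: float
    ms_score: float
    filter_flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def flagged(self) -> bool:
        return bool(self.filter_flags)


@dataclass(frozen=True)
class DifferentialRow:
    """One protein's enrichment contrasted between two baits."""

    accession: str
    gene_symbol: str
    ratio_wt: float | None
    ratio_mut: float | None
    present_wt: bool
    present_mut: bool

    def __post_init__(self) -> None:
        if self.present_wt != (self.ratio_wt is not None):
            raise ValidationError(
                f"{self.accession}: present_wt inconsistent with ratio_wt"
            )
        if self.present_mut != (self.ratio_mut is not None):
            raise ValidationError(
                f"{self.accession}: present_mut inconsistent with ratio_mut"
            )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def drop_single_peptide(table: IdentificationTable) -> IdentificationTable:
    """Remove proteins identified with a single unique peptide.

    Idempotent; record order of the survivors is preserved.
    """
    kept = [r for r in table if r.unique_peptides > 1]
    removed = len(table) - len(kept)
    if removed:
        logger.info(
            "%s: removed %d single-peptide identification(s)", table.sample_id, removed
        )
    return table.replace_records(kept)


def subtract_background(
    table: IdentificationTable,
    control: IdentificationTable,
    max_control_unique: int = 2,
) -> IdentificationTable:
    """Remove proteins that the negative control identifies with more than
    ``max_control_unique`` unique peptides.

    Proteins absent from the control, or present with at most
    ``max_control_unique`` unique peptides there, are retained.
    """
    if len(control) == 0:
        logger.warning(
            "%s: control table %s is empty; background subtraction is a no-op",
            table.sample_id,
            control.sample_id,
        )
        return table.replace_records(list(table))
    kept = []
    for record in table:
        in_control = control.get(record.accession)
        if in_control is not None and in_control.unique_peptides > max_control_unique:
            continue
        kept.append(record)
    removed = len(table) - len(kept)
    if removed:
        logger.info(
            "%s: removed %d background protein(s) via control %s",
            table.sample_id,
            removed,
            control.sample_id,
        )
    return table.replace_records(kept)


def filter_flags(
    table: IdentificationTable,
    control: IdentificationTable | None = None,
    max_control_unique: int = 2,
) -> dict[str, frozenset[str]]:
    """Audit-mode counterpart of the two filters: per-accession flag sets.

    An empty set means the protein survives the cascade; flags are
    ``single_peptide`` and ``control_background``.
    """
    flags: dict[str, frozenset[str]] = {}
    for record in table:
        labels = set()
        if record.unique_peptides <= 1:
            labels.add(SINGLE_PEPTIDE)
        if control is not None and len(control) > 0:
            in_control = control.get(record.accession)
            if (
                in_control is not None
                and in_control.unique_peptides > max_control_unique
            ):
                labels.add(CONTROL_BACKGROUND)
        flags[record.accession] = frozenset(labels)
    return flags


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------


def aggregate_replicates(
    tables: Sequence[IdentificationTable],
    method: AggregationMethod = "sum",
) -> IdentificationTable:
    """Combine per-replicate tables of one (bait, condition) into a single table.

    ``psms`` and ``unique_peptides`` are combined by ``method`` (sum by
    default; ``mean_rounded`` takes the rounded mean over the tables in which
    the protein appears); ``ms_score`` by maximum.  Accessions missing from a
    replicate count as zero under ``sum``.
    """
    if not tables:
        raise ValidationError("aggregate_replicates needs at least one table")
    if method not in ("sum", "mean_rounded"):
        raise ValidationError(f"unknown aggregation method {method!r}")
    baits = {t.bait for t in tables}
    conditions = {t.condition for t in tables}
    if len(baits) > 1 or len(conditions) > 1:
        raise ValidationError(
            f"cannot aggregate across baits {sorted(baits)} / "
            f"conditions {sorted(conditions)}"
        )
    if len(tables) == 1:
        table = tables[0]
        return table.replace_records(list(table))

    order: list[str] = []
    by_acc: dict[str, list[ProteinRecord]] = {}
    for table in tables:
        for record in table:
            if record.accession not in by_acc:
                by_acc[record.accession] = []
                order.append(record.accession)
            by_acc[record.accession].append(record)

    def combine(values: list[int]) -> int:
        if method == "sum":
            return int(sum(values))
        return int(round(sum(values) / len(values)))

    records = []
    for accession in order:
        group = by_acc[accession]
        symbol = next((r.gene_symbol for r in group if r.gene_symbol), "")
        psms = combine([r.psms for r in group])
        unique = combine([r.unique_peptides for r in group])
        if psms >= 1:
            unique = max(unique, 1)
        records.append(
            ProteinRecord(
                accession=accession,
                gene_symbol=symbol,
                unique_peptides=unique,
                psms=psms,
                ms_score=max(r.ms_score for r in group),
            )
        )
    first = tables[0]
    logger.info(
        "aggregated %d replicate table(s) of (%s, %s) by %s: %d proteins",
        len(tables), first.bait, first.condition, method, len(records),
    )
    return IdentificationTable.from_records(
        records,
        sample_id=f"{first.bait}_{first.condition}_pooled",
        bait=first.bait,
        condition=first.condition,
        replicate=1,
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def enrichment_ratio(psm_trap: int, psm_ref: int | None) -> float:
    """Trap/reference PSM ratio with the +1-when-absent pseudocount.

    A missing or zero reference count is replaced by 1 so detection without a
    reference counterpart still yields a finite, meaningful ratio.  A zero
    trap count against a present reference gives 0.
    """
    if psm_trap is None and psm_ref is None:
        raise ValidationError("enrichment_ratio: both counts absent")
    if psm_trap is None or psm_trap < 0:
        raise ValidationError(f"psm_trap must be >= 0, got {psm_trap!r}")
    denominator = psm_ref if (psm_ref is not None and psm_ref > 0) else 1
    return psm_trap / denominator


def build_enrichment(
    trap: IdentificationTable,
    ref: IdentificationTable,
    *,
    control: IdentificationTable | None = None,
    max_control_unique: int = 2,
    flag_mode: bool = False,
) -> tuple[list[EnrichmentRecord], list[str]]:
    """Per-protein enrichment records for every protein detected in ``trap``.

    Returns ``(records, reference_only)`` where ``reference_only`` lists
    accessions detected in the reference sample but not under trapping (they
    are never given a ratio).  With ``flag_mode`` the two filters annotate
    rather than remove: flagged records are kept, carrying their
    ``filter_flags``; otherwise both input tables are expected to be filtered
    already and all flags are empty.
    """
    flags = (
        filter_flags(trap, control, max_control_unique)
        if flag_mode
        else {r.accession: frozenset() for r in trap}
    )
    records = []
    for record in trap:
        ref_record = ref.get(record.accession)
        psm_ref = ref_record.psms if ref_record is not None else None
        records.append(
            EnrichmentRecord(
                accession=record.accession,
                gene_symbol=record.gene_symbol,
                psm_trap=record.psms,
                psm_ref=psm_ref,
                ratio=enrichment_ratio(record.psms, psm_ref),
                ms_score=record.ms_score,
                filter_flags=flags[record.accession],
            )
        )
    reference_only = [r.accession for r in ref if r.accession not in trap]
    return records, reference_only


def prioritize(
    records: Iterable[EnrichmentRecord],
    min_ratio: float = 2.0,
    min_score: float = 0.0,
    strategy: Strategy = "ratio_first",
) -> list[EnrichmentRecord]:
    """Rank unflagged records passing both thresholds.

    ``ratio_first`` sorts by (ratio desc, ms_score desc), ``score_first`` by
    (ms_score desc, ratio desc); ties break lexicographically by accession.
    Flagged records never appear in the output.
    """
    if strategy not in ("ratio_first", "score_first"):
        raise ValidationError(f"unknown strategy {strategy!r}")
    survivors = [
        r
        for r in records
        if not r.flagged and r.ratio >= min_ratio and r.ms_score >= min_score
    ]
    if strategy == "ratio_first":
        key = lambda r: (-r.ratio, -r.ms_score, r.accession)
    else:
        key = lambda r: (-r.ms_score, -r.ratio, r.accession)
    return sorted(survivors, key=key)


def compare_baits(
    wt: Iterable[EnrichmentRecord],
    mut: Iterable[EnrichmentRecord],
) -> list[DifferentialRow]:
    """Outer join of two baits' enrichment records on accession.

    A protein detected under only one bait is reported with the other ratio
    absent.  Rows are ordered by accession.
    """
    wt_by_acc = {r.accession: r for r in wt}
    mut_by_acc = {r.accession: r for r in mut}
    rows = []
    for accession in sorted(set(wt_by_acc) | set(mut_by_acc)):
        w = wt_by_acc.get(accession)
        m = mut_by_acc.get(accession)
        symbol = (w.gene_symbol if w else "") or (m.gene_symbol if m else "")
        rows.append(
            DifferentialRow(
                accession=accession,
                gene_symbol=symbol,
                ratio_wt=w.ratio if w else None,
                ratio_mut=m.ratio if m else None,
                present_wt=w is not None,
                present_mut=m is not None,
            )
        )
    return rows
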