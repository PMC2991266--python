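"""Build and filter the concatenated cognate-pair alignment.

Cognate HK–RR pairs are recognized by genome-ordinal gene identifiers that
differ by exactly one (adjacent genes, typically the same operon).  The
paired rows are concatenated, gappy columns are removed, and near-identical
rows are collapsed so that no two retained rows exceed the identity bound.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Optional

from .alignment import (
    GAP,
    HK,
    RR,
    AlignmentFormatError,
    ColumnMap,
    ColumnMapEntry,
    ColumnOrigin,
    PairedAlignment,
    PairedRow,
    SequenceRecord,
)

logger = logging.getLogger(__name__)

CognatePair = tuple[SequenceRecord, SequenceRecord]


def pair_cognates(
    hks: list[SequenceRecord], rrs: list[SequenceRecord]
) -> list[CognatePair]:
    """Return every (HK, RR) pair whose gene indices differ by exactly one.

    Ambiguous adjacencies (an HK adjacent to two RRs or vice versa) are all
    retained; they are logged and can be inspected with
    :func:`ambiguous_pairings`.
    """
    for h in hks:
        if h.protein_class != HK:
            raise AlignmentFormatError(f"{h.record_id} is not an HK record")
    for r in rrs:
        if r.protein_class != RR:
            raise AlignmentFormatError(f"{r.record_id} is not an RR record")
    by_index: dict[int, list[SequenceRecord]] = {}
    for r in rrs:
        by_index.setdefault(r.gene_index, []).append(r)
    pairs: list[CognatePair] = []
    for h in hks:
        for idx in (h.gene_index - 1, h.gene_index + 1):
            for r in by_index.get(idx, []):
                pairs.append((h, r))
    for rid, count in ambiguous_pairings(pairs).items():
        logger.info("ambiguous adjacency: %s participates in %d pairs", rid, count)
    return pairs


def ambiguous_pairings(pairs: list[CognatePair]) -> dict[str, int]:
    """Record ids (HK or RR) that participate in more than one cognate pair."""
    counts: Counter[str] = Counter()
    for h, r in pairs:
        counts[h.record_id] += 1
        counts[r.record_id] += 1
    return {rid: n for rid, n in counts.items() if n > 1}


def concatenate_pairs(
    pairs: list[CognatePair],
    hk_width: Optional[int] = None,
    rr_width: Optional[int] = None,
) -> PairedAlignment:
    """Concatenate each cognate pair into one row; HK columns precede RR columns.

    For an empty pair list the widths must be given so the (empty) alignment
    still has well-defined column provenance.
    """
    if pairs:
        hk_w = len(pairs[0][0].aligned_seq)
        rr_w = len(pairs[0][1].aligned_seq)
        for h, r in pairs:
            if len(h.aligned_seq) != hk_w:
                raise AlignmentFormatError(
                    f"HK {h.record_id} has aligned length {len(h.aligned_seq)}, expected {hk_w}"
                )
            if len(r.aligned_seq) != rr_w:
                raise AlignmentFormatError(
                    f"RR {r.record_id} has aligned length {len(r.aligned_seq)}, expected {rr_w}"
                )
    else:
        if hk_width is None or rr_width is None:
            raise ValueError("empty pair list requires explicit hk_width and rr_width")
        hk_w, rr_w = hk_width, rr_width
    meta = [ColumnOrigin(HK, c) for c in range(1, hk_w + 1)] + [
        ColumnOrigin(RR, c) for c in range(1, rr_w + 1)
    ]
    rows = [
        PairedRow(h.record_id, r.record_id, h.aligned_seq + r.aligned_seq)
        for h, r in pairs
    ]
    return PairedAlignment(rows, meta)


def filter_gappy_columns(
    aln: PairedAlignment,
    max_gap_frac: float = 0.10,
    reference_row_id: Optional[str] = None,
) -> tuple[PairedAlignment, ColumnMap]:
    """Drop columns whose gap fraction is strictly greater than ``max_gap_frac``.

    A column with exactly the threshold fraction of gaps (e.g. 1 gap in 10
    rows at the default 10%) is kept.  Surviving columns are renumbered
    1..m; the returned :class:`ColumnMap` records the old->new mapping and,
    if ``reference_row_id`` is given, 1-based residue numbers in that row's
    ungapped HK and RR sequences.
    """
    if not 0.0 <= max_gap_frac <= 1.0:
        raise ValueError(f"max_gap_frac must be in [0, 1], got {max_gap_frac}")
    if aln.n_rows == 0:
        raise AlignmentFormatError("cannot gap-filter an alignment with zero rows")
    keep = [
        c
        for c in range(1, aln.n_cols + 1)
        if aln.column(c).count(GAP) / aln.n_rows <= max_gap_frac
    ]
    filtered = aln.subset_columns(keep)

    ref_residue: dict[int, Optional[int]] = {}
    if reference_row_id is not None:
        ref_row = aln.row_by_reference(reference_row_id)
        counters = {HK: 0, RR: 0}
        for c in range(1, aln.n_cols + 1):
            protein = aln.column_meta[c - 1].source_protein
            if ref_row.seq[c - 1] != GAP:
                counters[protein] += 1
                ref_residue[c] = counters[protein]
            else:
                ref_residue[c] = None
    entries = [
        ColumnMapEntry(
            filtered_col=new,
            source_protein=aln.column_meta[old - 1].source_protein,
            source_col=aln.column_meta[old - 1].source_col,
            original_col=old,
            reference_residue=ref_residue.get(old),
        )
        for new, old in enumerate(keep, start=1)
    ]
    logger.info(
        "gap filter: kept %d of %d columns (max gap fraction %.3f)",
        len(keep),
        aln.n_cols,
        max_gap_frac,
    )
    return filtered, ColumnMap(entries, reference_row_id=reference_row_id)


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Fraction of identical positions between two aligned rows.

    Positions where both rows are gaps are excluded from the denominator; a
    gap aligned to a residue counts as a mismatch.  Raises ``ValueError``
    when no positions are compared.
    """
    if len(row_a) != len(row_b):
        raise ValueError(f"length mismatch: {len(row_a)} vs {len(row_b)}")
    matches = compared = 0
    for a, b in zip(row_a, row_b):
        if a == GAP and b == GAP:
            continue
        compared += 1
        if a == b:
            matches += 1
    if compared == 0:
        raise ValueError("identity undefined: all positions are double gaps")
    return matches / compared


def filter_redundant_rows(
    aln: PairedAlignment,
    max_identity: float = 0.90,
    return_dropped: bool = False,
):
    """Greedy redundancy filter: scan rows in input order, keep a row unless it
    is *strictly more than* ``max_identity`` identical to an already-kept row.

    Two rows at exactly the bound (e.g. 90%) are both retained.  Deterministic
    given input order (first-seen row wins).
    """
    kept: list[PairedRow] = []
    dropped: list[PairedRow] = []
    for row in aln.rows:
        if any(pairwise_identity(row.seq, k.seq) > max_identity for k in kept):
            dropped.append(row)
        else:
            kept.append(row)
    logger.info(
        "redundancy filter: kept %d of %d rows (max identity %.2f)",
        len(kept),
        aln.n_rows,
        max_identity,
    )
    out = PairedAlignment(kept, list(aln.column_meta))
    return (out, dropped) if return_dropped else out
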