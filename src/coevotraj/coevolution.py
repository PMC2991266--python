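"""Mutual-information covariation analysis of the concatenated alignment.

For columns *i*, *j* the plug-in mutual information is

    MI(i,j) = sum_xy p(x,y) ln[ p(x,y) / (p(x) p(y)) ]

with frequencies taken from raw counts over the rows and the 21-symbol
alphabet (20 amino acids + gap).  Because some columns carry globally
elevated scores against *every* partner, raw MI is corrected by each
column's average score:

    MI(i,j)_adj = MI(i,j)_raw / ((MI(i)_avg + MI(j)_avg) / 2)

where MI(i)_avg is the mean of MI(i,k) over all other columns k.  Pairs
above an adjusted-score threshold (default 3.5) that span the HK/RR
interface are reported as coevolving, and their residue graph is analyzed
for connected clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .alignment import GAP_CODE, HK, RR, ColumnMap, PairedAlignment

N_SYMBOLS = 21


def _column_codes(aln: PairedAlignment) -> np.ndarray:
    if aln.n_rows == 0:
        raise ValueError("mutual information undefined for an empty alignment")
    return aln.to_codes()


def _mi_from_codes(x: np.ndarray, y: np.ndarray, log_base: Optional[float]) -> float:
    """Plug-in MI (in nats unless ``log_base`` is given) from two code vectors."""
    n = x.shape[0]
    joint = np.bincount(x.astype(np.intp) * N_SYMBOLS + y, minlength=N_SYMBOLS**2)
    joint = joint.reshape(N_SYMBOLS, N_SYMBOLS).astype(float)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    pj = joint[nz] / n
    outer = np.outer(px, py)[nz] / (n * n)
    mi = float(np.sum(pj * np.log(pj / outer)))
    mi = max(mi, 0.0)  # clip -0.0 / rounding dust
    if log_base is not None:
        mi /= math.log(log_base)
    return mi


def _pair_codes(
    x: np.ndarray, y: np.ndarray, gap_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    if gap_mode == "symbol":
        return x, y
    if gap_mode == "pairwise_delete":
        keep = (x != GAP_CODE) & (y != GAP_CODE)
        if not keep.any():
            raise ValueError("no ungapped row pairs left after pairwise deletion")
        return x[keep], y[keep]
    raise ValueError(f"unknown gap_mode {gap_mode!r}")


def raw_mi(
    aln: PairedAlignment,
    i: int,
    j: int,
    gap_mode: str = "symbol",
    log_base: Optional[float] = None,
) -> float:
    """Plug-in mutual information between 1-based columns ``i`` and ``j``.

    ``gap_mode="symbol"`` (default) treats the gap as a 21st symbol so every
    column pair sees the same row set; ``"pairwise_delete"`` drops rows
    gapped in either column.  ``raw_mi(aln, i, i)`` equals the column's
    entropy.  Natural log (nats) unless ``log_base`` is given.
    """
    codes = _column_codes(aln)
    aln._check_col(i)
    aln._check_col(j)
    x, y = _pair_codes(codes[:, i - 1], codes[:, j - 1], gap_mode)
    return _mi_from_codes(x, y, log_base)


@dataclass
class MIResult:
    """Raw MI matrix, per-column averages, and the column-adjusted matrix.

    ``raw`` holds MI(i,j) for i != j and the column entropy on the diagonal;
    ``adjusted`` has a zero diagonal.  All matrices are symmetric.
    """

    raw: np.ndarray
    col_avg: np.ndarray
    adjusted: np.ndarray
    m: int
    log_base: Optional[float] = None

    def __post_init__(self) -> None:
        assert self.raw.shape == (self.m, self.m)
        assert self.adjusted.shape == (self.m, self.m)
        assert self.col_avg.shape == (self.m,)


def mi_matrix(
    aln: PairedAlignment,
    gap_mode: str = "symbol",
    log_base: Optional[float] = None,
    avg_include_self: bool = False,
) -> MIResult:
    """Compute raw MI for all column pairs and the column-average adjustment.

    ``col_avg(i)`` is the mean of raw MI(i,k) over k != i; with
    ``avg_include_self`` the self-pair (the column entropy) is included in
    the average.  ``adjusted(i,j) = raw(i,j) / ((col_avg(i)+col_avg(j))/2)``,
    defined as 0 where the denominator is 0 (which forces raw = 0 too).
    """
    m = aln.n_cols
    if m < 2:
        raise ValueError(f"need at least 2 columns, got {m}")
    codes = _column_codes(aln)
    raw = np.zeros((m, m))
    for i in range(m):
        x = codes[:, i]
        xi, yi = _pair_codes(x, x, gap_mode)
        raw[i, i] = _mi_from_codes(xi, yi, log_base)  # column entropy
        for j in range(i + 1, m):
            xp, yp = _pair_codes(x, codes[:, j], gap_mode)
            raw[i, j] = raw[j, i] = _mi_from_codes(xp, yp, log_base)
    off_sum = raw.sum(axis=1) - np.diag(raw)
    if avg_include_self:
        col_avg = (off_sum + np.diag(raw)) / m
    else:
        col_avg = off_sum / (m - 1)
    denom = (col_avg[:, None] + col_avg[None, :]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        adjusted = np.where(denom > 0, raw / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(adjusted, 0.0)
    return MIResult(raw=raw, col_avg=col_avg, adjusted=adjusted, m=m, log_base=log_base)


@dataclass(frozen=True)
class CoevolvingPair:
    col_i: int  # 1-based filtered column, col_i < col_j
    col_j: int
    raw_mi: float
    adjusted_mi: float
    residue_i: Optional[tuple[str, int]] = None  # (protein, reference residue)
    residue_j: Optional[tuple[str, int]] = None


@dataclass
class CoevolvingPairSet:
    """Column pairs above the adjusted-MI threshold, with their residue graph."""

    pairs: list[CoevolvingPair]
    threshold: float
    hk_residues: set = field(default_factory=set)
    rr_residues: set = field(default_factory=set)
    graph: nx.Graph = field(default_factory=nx.Graph)


def _node_label(protein: str, col: int, residue: Optional[tuple[str, int]]) -> tuple:
    if residue is not None:
        return residue
    return (protein, col)


def find_coevolving_pairs(
    mi: MIResult,
    colmap: Optional[ColumnMap] = None,
    threshold: float = 3.5,
    inter_protein_only: bool = True,
) -> CoevolvingPairSet:
    """All column pairs with adjusted MI >= ``threshold``.

    By default only inter-protein (HK column x RR column) pairs are
    reported, since the interface is where cognate specificity coevolves;
    this requires a :class:`ColumnMap`.  Pairs are ordered by descending
    adjusted score, then by (i, j).  When the map carries reference
    numbering, pairs are translated to (protein, residue) labels.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if inter_protein_only and colmap is None:
        raise ValueError("inter_protein_only requires a ColumnMap")
    found: list[CoevolvingPair] = []
    for i in range(mi.m):
        for j in range(i + 1, mi.m):
            if mi.adjusted[i, j] < threshold:
                continue
            res_i = res_j = None
            if colmap is not None:
                ei, ej = colmap.entry(i + 1), colmap.entry(j + 1)
                if inter_protein_only and ei.source_protein == ej.source_protein:
                    continue
                if ei.reference_residue is not None:
                    res_i = (ei.source_protein, ei.reference_residue)
                if ej.reference_residue is not None:
                    res_j = (ej.source_protein, ej.reference_residue)
            found.append(
                CoevolvingPair(i + 1, j + 1, mi.raw[i, j], mi.adjusted[i, j], res_i, res_j)
            )
    found.sort(key=lambda p: (-p.adjusted_mi, p.col_i, p.col_j))

    pairset = CoevolvingPairSet(pairs=found, threshold=threshold)
    for p in found:
        prot_i = colmap.source_protein(p.col_i) if colmap is not None else "?"
        prot_j = colmap.source_protein(p.col_j) if colmap is not None else "?"
        ni = _node_label(prot_i, p.col_i, p.residue_i)
        nj = _node_label(prot_j, p.col_j, p.residue_j)
        pairset.graph.add_edge(ni, nj, adjusted_mi=p.adjusted_mi)
        for node, prot in ((ni, prot_i), (nj, prot_j)):
            if prot == HK:
                pairset.hk_residues.add(node[1])
            elif prot == RR:
                pairset.rr_residues.add(node[1])
    return pairset


def coevolution_graph_components(pairset: CoevolvingPairSet) -> list[set]:
    """Connected components of the coevolving-residue graph, largest first."""
    comps = [set(c) for c in nx.connected_components(pairset.graph)]
    comps.sort(key=lambda c: (-len(c), sorted(c)))
    return comps


def column_score_distribution(
    mi: MIResult, i: int, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, bin_edges) of raw MI(i, .) against all other columns.

    Diagnoses why a per-column average correction is needed: columns with
    broad, long-tailed score distributions inflate every pairing they enter.
    """
    if not 1 <= i <= mi.m:
        raise IndexError(f"column {i} out of range 1..{mi.m}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    scores = np.delete(mi.raw[i - 1], i - 1)
    return np.histogram(scores, bins=n_bins)


def write_pair_table(pairset: CoevolvingPairSet, path) -> None:
    """TSV of coevolving pairs: columns, residue labels, raw and adjusted MI."""
    with open(path, "w") as fh:
        fh.write("col_i\tcol_j\tresidue_i\tresidue_j\traw_mi\tadjusted_mi\n")
        for p in pairset.pairs:
            ri = "" if p.residue_i is None else f"{p.residue_i[0]}:{p.residue_i[1]}"
            rj = "" if p.residue_j is None else f"{p.residue_j[0]}:{p.residue_j[1]}"
            fh.write(
                f"{p.col_i}\t{p.col_j}\t{ri}\t{rj}\t{p.raw_mi:.6f}\t{p.adjusted_mi:.6f}\n"
            )


def shuffle_null_max_adjusted(
    aln: PairedAlignment, n_shuffles: int, seed: int, **mi_kwargs
) -> np.ndarray:
    """Max adjusted MI under independent per-column row shuffles (diagnostic only).

    Not part of the default pipeline: the reported analysis uses a fixed
    adjusted-score threshold rather than shuffle p-values.
    """
    from .alignment import PairedRow

    rng = np.random.default_rng(seed)
    codes = aln.to_codes()
    maxima = np.empty(n_shuffles)
    from .alignment import ALPHABET

    for s in range(n_shuffles):
        shuffled = codes.copy()
        for c in range(shuffled.shape[1]):
            rng.shuffle(shuffled[:, c])
        rows = [
            PairedRow(r.hk_record_id, r.rr_record_id, "".join(ALPHABET[k] for k in shuffled[t]))
            for t, r in enumerate(aln.rows)
        ]
        res = mi_matrix(PairedAlignment(rows, list(aln.column_meta)), **mi_kwargs)
        off = res.adjusted[~np.eye(res.m, dtype=bool)]
        maxima[s] = off.max()
    return maxima
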