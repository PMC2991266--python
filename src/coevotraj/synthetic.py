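"""Synthetic fixtures with planted ground truth for every pipeline stage.

Three generators, each a pure function of its spec + seed:

* paired alignments with planted covarying inter-protein column pairs,
  optional gappy columns and near-duplicate rows — benchmarks the MI
  pipeline (rows are i.i.d., no phylogeny: this isolates the estimator
  from tree-induced correlation, which the redundancy filter only
  approximates on real data);
* kinase x regulator intensity panels whose structure follows a weighted
  specificity-unit hierarchy — benchmarks clustering + split concordance;
* binary interaction matrices from a unit-matching rule, with ground-truth
  insulated-path existence — benchmarks the path search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .alignment import (
    ALPHABET,
    GAP,
    HK,
    RR,
    ColumnOrigin,
    PairedAlignment,
    PairedRow,
    SequenceRecord,
)
from .schemes import SchemeUnit, SpecificityScheme, all_variants, ompr_regulator_scheme
from .trajectory import InteractionMatrix


# ---------------------------------------------------------------------------
# Paired alignments with planted covariation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentSimSpec:
    """Simulation spec for a concatenated cognate-pair alignment.

    ``planted_pairs`` lists (hk_col, rr_col, coupling) with 1-based columns
    inside each protein; coupling 1.0 means the RR symbol is a fixed
    bijection of the HK symbol in every row, 0.0 means independence.
    ``n_redundant`` near-duplicate rows at ``redundancy_identity`` are
    appended after the i.i.d. rows.
    """

    n_rows: int = 500
    hk_width: int = 50
    rr_width: int = 50
    planted_pairs: tuple[tuple[int, int, float], ...] = ()
    alphabet_size: int = 20
    gap_rate: float = 0.0
    n_redundant: int = 0
    redundancy_identity: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.alphabet_size <= 20:
            raise ValueError("alphabet_size must be in 1..20")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")
        seen_hk, seen_rr = set(), set()
        for hk_col, rr_col, coupling in self.planted_pairs:
            if not 1 <= hk_col <= self.hk_width:
                raise ValueError(f"planted HK column {hk_col} outside 1..{self.hk_width}")
            if not 1 <= rr_col <= self.rr_width:
                raise ValueError(f"planted RR column {rr_col} outside 1..{self.rr_width}")
            if not 0.0 <= coupling <= 1.0:
                raise ValueError(f"coupling must be in [0, 1], got {coupling}")
            if hk_col in seen_hk or rr_col in seen_rr:
                raise ValueError("planted columns collide across pairs")
            seen_hk.add(hk_col)
            seen_rr.add(rr_col)


@dataclass
class AlignmentGroundTruth:
    """Planted pairs as 1-based concatenated columns, plus duplicate row ids."""

    planted_concat_pairs: list[tuple[int, int]]
    couplings: list[float]
    duplicate_ids: list[tuple[str, str]]
    hk_width: int
    rr_width: int


def generate_paired_alignment(
    spec: AlignmentSimSpec,
) -> tuple[PairedAlignment, AlignmentGroundTruth]:
    rng = np.random.default_rng(spec.seed)
    w = spec.hk_width + spec.rr_width
    codes = rng.integers(0, spec.alphabet_size, size=(spec.n_rows, w))

    planted_concat = []
    couplings = []
    for hk_col, rr_col, coupling in spec.planted_pairs:
        i = hk_col - 1
        j = spec.hk_width + rr_col - 1
        bijection = rng.permutation(spec.alphabet_size)
        coupled = rng.random(spec.n_rows) < coupling
        codes[coupled, j] = bijection[codes[coupled, i]]
        planted_concat.append((hk_col, spec.hk_width + rr_col))
        couplings.append(coupling)

    chars = np.array(list(ALPHABET[: spec.alphabet_size]))
    sym = chars[codes]
    if spec.gap_rate > 0:
        sym[rng.random(sym.shape) < spec.gap_rate] = GAP

    rows = [
        PairedRow(f"hk{t:05d}", f"rr{t:05d}", "".join(sym[t]))
        for t in range(spec.n_rows)
    ]

    duplicate_ids = []
    mut_rate = 1.0 - spec.redundancy_identity
    for d in range(spec.n_redundant):
        src = int(rng.integers(0, spec.n_rows))
        seq = list(rows[src].seq)
        for pos in range(w):
            if rng.random() < mut_rate:
                choices = [c for c in ALPHABET[: spec.alphabet_size] if c != seq[pos]]
                seq[pos] = choices[int(rng.integers(0, len(choices)))]
        hk_id, rr_id = f"hkdup{d:03d}", f"rrdup{d:03d}"
        rows.append(PairedRow(hk_id, rr_id, "".join(seq)))
        duplicate_ids.append((hk_id, rr_id))

    meta = [ColumnOrigin(HK, c) for c in range(1, spec.hk_width + 1)] + [
        ColumnOrigin(RR, c) for c in range(1, spec.rr_width + 1)
    ]
    truth = AlignmentGroundTruth(
        planted_concat_pairs=planted_concat,
        couplings=couplings,
        duplicate_ids=duplicate_ids,
        hk_width=spec.hk_width,
        rr_width=spec.rr_width,
    )
    return PairedAlignment(rows, meta), truth


def paired_alignment_to_records(
    aln: PairedAlignment,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split a paired alignment back into HK and RR record sets with adjacent
    gene indices — exercises the assembly pairing path on generated data.

    Pairs are spaced three indices apart (HK at 3t, its cognate RR at 3t+1)
    so that no HK is adjacent to the previous pair's RR.
    """
    hk_w = sum(1 for m in aln.column_meta if m.source_protein == HK)
    hks, rrs = [], []
    for t, row in enumerate(aln.rows):
        hks.append(SequenceRecord(row.hk_record_id, 3 * t, HK, row.seq[:hk_w]))
        rrs.append(SequenceRecord(row.rr_record_id, 3 * t + 1, RR, row.seq[hk_w:]))
    return hks, rrs


# ---------------------------------------------------------------------------
# Profile panels with a weighted unit hierarchy
# ---------------------------------------------------------------------------

def _mirrored_kinase_scheme(regulator: SpecificityScheme, protein: str = "K") -> SpecificityScheme:
    """A kinase scheme with one unit per regulator unit (positional mirror)."""
    return SpecificityScheme(
        protein,
        tuple(
            SchemeUnit(u.label, u.positions, u.start_allele, u.target_allele)
            for u in regulator.units
        ),
    )


@dataclass(frozen=True)
class PanelSimSpec:
    """Simulation spec for a kinase x regulator intensity panel.

    ``weights`` are per *regulator* unit (in unit order).  Intensity of
    kinase k against regulator r is

        max(0, base - sum_u weight_u * mismatch_u(k, r) + N(0, sigma))

    where regulator unit u mismatches when its allele differs from the
    kinase's preferred allele: kinase unit u's state for u < k_kinase,
    otherwise the start allele.  Defaults model the trajectory-scanning
    panel: four regulator units with strictly ordered weights 8 > 4 > 2 > 1
    (loop strongest), base 20 so intensities stay positive before noise,
    and noise sigma 0.25 — a quarter of the smallest weight, i.e. small
    relative to every weight gap.
    """

    regulator_scheme: SpecificityScheme = field(default_factory=ompr_regulator_scheme)
    kinase_scheme: Optional[SpecificityScheme] = None
    # per-unit in scheme order (pos1, pos2, pos3, loop): the loop dominates
    weights: tuple[float, ...] = (4.0, 2.0, 1.0, 8.0)
    base: float = 20.0
    noise_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.weights) != self.regulator_scheme.k:
            raise ValueError(
                f"{len(self.weights)} weights for {self.regulator_scheme.k} regulator units"
            )
        if any(w <= 0 for w in self.weights):
            raise ValueError("unit weights must be strictly positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def resolved_kinase_scheme(self) -> SpecificityScheme:
        if self.kinase_scheme is not None:
            return self.kinase_scheme
        return _mirrored_kinase_scheme(self.regulator_scheme)


def generate_profile_panel(
    spec: PanelSimSpec,
) -> tuple[pd.DataFrame, Optional[list[str]]]:
    """Raw intensity panel over all kinase and regulator variants, plus the
    ground-truth unit order (weight descending), or None when weights tie."""
    rng = np.random.default_rng(spec.seed)
    kscheme = spec.resolved_kinase_scheme()
    rscheme = spec.regulator_scheme
    kin = all_variants(kscheme)
    reg = all_variants(rscheme)
    w = np.asarray(spec.weights, dtype=float)

    values = np.empty((len(kin), len(reg)))
    for a, kv in enumerate(kin):
        pref = np.array(
            [kv.vector[u] if u < kscheme.k else False for u in range(rscheme.k)]
        )
        for b, rv in enumerate(reg):
            mismatch = np.array(rv.vector) != pref
            values[a, b] = spec.base - float(w[mismatch].sum())
    values = values + rng.normal(0.0, spec.noise_sigma, size=values.shape)
    values = np.maximum(values, 0.0)

    raw = pd.DataFrame(
        values, index=[v.name for v in kin], columns=[v.name for v in reg]
    )
    if len(set(spec.weights)) < len(spec.weights):
        truth = None
    else:
        order = sorted(range(rscheme.k), key=lambda u: -spec.weights[u])
        truth = [rscheme.units[u].label for u in order]
    return raw, truth


# ---------------------------------------------------------------------------
# Interaction matrices with known insulated paths
# ---------------------------------------------------------------------------

MatchRule = Union[str, Callable[[tuple[bool, ...], tuple[bool, ...]], bool]]


def _matched_units(kvec: tuple[bool, ...], rvec: tuple[bool, ...]) -> int:
    return sum(a == b for a, b in zip(kvec, rvec))


def generate_interaction_matrix(
    kinase_scheme: SpecificityScheme,
    regulator_scheme: SpecificityScheme,
    rule: MatchRule = "matched_units",
    min_match: Optional[int] = None,
    seed: int = 0,
) -> tuple[InteractionMatrix, dict]:
    """Binary interaction matrix over all variants of both schemes.

    The built-in ``"matched_units"`` rule calls transfer when at least
    ``min_match`` of the positionally aligned units (over the shorter
    scheme) agree; default ``min_match`` is one fewer than that count, which
    leaves insulated paths open, while requiring *all* units to match
    closes them (any first flip of a matched unit breaks transfer).  A
    callable rule receives the two allele vectors.  Ground truth records
    insulated-path existence computed by exhaustive breadth-first search
    over the monotone state graph.  Deterministic (``seed`` is reserved for
    stochastic rules).
    """
    matchable = min(kinase_scheme.k, regulator_scheme.k)
    if min_match is None:
        min_match = matchable - 1
    if callable(rule):
        call_fn = rule
    elif rule == "matched_units":
        call_fn = lambda kv, rv: _matched_units(kv, rv) >= min_match
    else:
        raise ValueError(f"unknown rule {rule!r}")

    kin = all_variants(kinase_scheme)
    reg = all_variants(regulator_scheme)
    calls = pd.DataFrame(
        [[bool(call_fn(kv.vector, rv.vector)) for rv in reg] for kv in kin],
        index=[v.name for v in kin],
        columns=[v.name for v in reg],
    )
    intensity = calls.astype(float)
    mat = InteractionMatrix(intensity=intensity, calls=calls)

    truth = {
        "path_exists": _monotone_path_exists(call_fn, kinase_scheme.k, regulator_scheme.k),
        "rule": rule if isinstance(rule, str) else "custom",
        "min_match": min_match if not callable(rule) else None,
    }
    return mat, truth


def _monotone_path_exists(call_fn, k_kin: int, k_reg: int) -> bool:
    """BFS over (kvec, rvec) states, flipping one unit start->target per move."""
    start = ((False,) * k_kin, (False,) * k_reg)
    goal = ((True,) * k_kin, (True,) * k_reg)
    if not call_fn(*start) or not call_fn(*goal):
        return False
    frontier = [start]
    seen = {start}
    while frontier:
        nxt = []
        for kv, rv in frontier:
            if (kv, rv) == goal:
                return True
            for i in range(k_kin):
                if not kv[i]:
                    cand = (kv[:i] + (True,) + kv[i + 1 :], rv)
                    if cand not in seen and call_fn(*cand):
                        seen.add(cand)
                        nxt.append(cand)
            for i in range(k_reg):
                if not rv[i]:
                    cand = (kv, rv[:i] + (True,) + rv[i + 1 :])
                    if cand not in seen and call_fn(*cand):
                        seen.add(cand)
                        nxt.append(cand)
        frontier = nxt
    return False
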