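"""Mutational-trajectory combinatorics over specificity residues.

Covers the trajectory-scanning bookkeeping: enumerating and naming every
intermediate between two alleles, sizing the kinase x regulator assay
panel, scoring codon-level substitution costs, detecting context-dependent
(epistatic) unit effects, and searching an interaction matrix for
*insulated paths* — ordered series of single mutations that convert one
cognate pair into another while every intermediate pair still
phosphotransfers and no intermediate regulator is captured by a third-party
kinase (cross-talk).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Callable, Optional, Sequence

import networkx as nx
import pandas as pd
from Bio.Data import CodonTable

from .schemes import SchemeError, SpecificityScheme, Variant, enumerate_variants


# ---------------------------------------------------------------------------
# Panel enumeration
# ---------------------------------------------------------------------------

def enumerate_panel(
    kinase_scheme: SpecificityScheme,
    regulator_scheme: SpecificityScheme,
    extra_kinases: Sequence[str] = (),
    extra_regulators: Sequence[str] = (),
) -> list[tuple[str, str]]:
    """Cartesian product of (kinase intermediates + extras) x (regulator
    intermediates + extras).

    Intermediates are all variants at depths 1..k.  Extras are plain names
    (wild types, cross-talk controls).  With the 3-unit kinase scheme, its 7
    intermediates plus 3 wild-type kinases against the 4-unit regulator
    scheme's 15 intermediates plus 3 wild-type regulators give the full
    180-pair panel.
    """
    kin = [v.qualified_name for v in enumerate_variants(kinase_scheme, range(1, kinase_scheme.k + 1))]
    reg = [v.qualified_name for v in enumerate_variants(regulator_scheme, range(1, regulator_scheme.k + 1))]
    kin += list(extra_kinases)
    reg += list(extra_regulators)
    return list(itertools.product(kin, reg))


# ---------------------------------------------------------------------------
# Codon-level substitution cost
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _codons_by_aa(table_name: str) -> dict[str, tuple[str, ...]]:
    table = CodonTable.unambiguous_dna_by_name[table_name]
    out: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        out.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in out.items()}


def min_codon_distance(aa_from: str, aa_to: str, table_name: str = "Standard") -> int:
    """Minimum nucleotide substitutions between codons of two amino acids.

    Minimized over all codon pairs of the (default standard) genetic code;
    stop codons are excluded.  Converting each of the three EnvZ specificity
    residues to its RstB counterpart (T->V, L->Y, A->R) costs two
    substitutions, so single-nucleotide intermediates exist that the
    residue-level trajectory scan does not enumerate.
    """
    codons = _codons_by_aa(table_name)
    for aa in (aa_from, aa_to):
        if aa not in codons:
            raise ValueError(f"unknown amino acid {aa!r}")
    return min(
        sum(a != b for a, b in zip(c1, c2))
        for c1 in codons[aa_from]
        for c2 in codons[aa_to]
    )


def unit_codon_cost(start_allele: str, target_allele: str, table_name: str = "Standard") -> int:
    """Codon cost of flipping a (possibly multi-residue) unit: sum of per-residue minima."""
    return sum(
        min_codon_distance(a, b, table_name) for a, b in zip(start_allele, target_allele)
    )


# ---------------------------------------------------------------------------
# Interaction matrices
# ---------------------------------------------------------------------------

class MissingVariantError(KeyError):
    pass


@dataclass
class InteractionMatrix:
    """Kinase-variant x regulator-variant phosphotransfer intensities.

    Binary transfer *calls* are derived from intensities by a declared
    threshold, by default a fraction of each kinase's profile maximum
    (band-intensity panels are only comparable within a kinase's profile).
    An explicit call matrix may be supplied instead.
    """

    intensity: pd.DataFrame  # rows: kinases, cols: regulators, floats >= 0
    calls: Optional[pd.DataFrame] = None
    call_threshold_frac: float = 0.10

    def __post_init__(self) -> None:
        if (self.intensity.values < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.calls is None:
            rowmax = self.intensity.max(axis=1)
            cutoff = rowmax * self.call_threshold_frac
            self.calls = self.intensity.gt(cutoff, axis=0) & (self.intensity > 0)

    def intensity_of(self, kinase: str, regulator: str) -> float:
        self._check(kinase, regulator)
        return float(self.intensity.at[kinase, regulator])

    def call(self, kinase: str, regulator: str) -> bool:
        self._check(kinase, regulator)
        return bool(self.calls.at[kinase, regulator])

    def substrates(self, kinase: str) -> frozenset[str]:
        if kinase not in self.calls.index:
            raise MissingVariantError(f"kinase {kinase!r} absent from interaction matrix")
        row = self.calls.loc[kinase]
        return frozenset(row.index[row])

    def kinases_of(self, regulator: str) -> frozenset[str]:
        if regulator not in self.calls.columns:
            raise MissingVariantError(f"regulator {regulator!r} absent from interaction matrix")
        col = self.calls[regulator]
        return frozenset(col.index[col])

    def _check(self, kinase: str, regulator: str) -> None:
        if kinase not in self.intensity.index:
            raise MissingVariantError(f"kinase {kinase!r} absent from interaction matrix")
        if regulator not in self.intensity.columns:
            raise MissingVariantError(f"regulator {regulator!r} absent from interaction matrix")

    def to_tsv(self, path: str | Path, calls_path: str | Path | None = None) -> None:
        self.intensity.to_csv(path, sep="\t")
        if calls_path is not None:
            self.calls.astype(int).to_csv(calls_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        calls_path: str | Path | None = None,
        call_threshold_frac: float = 0.10,
    ) -> "InteractionMatrix":
        intensity = pd.read_csv(path, sep="\t", index_col=0)
        calls = None
        if calls_path is not None:
            calls = pd.read_csv(calls_path, sep="\t", index_col=0).astype(bool)
        return cls(intensity, calls, call_threshold_frac)


# ---------------------------------------------------------------------------
# Insulated-path search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryStep:
    protein: str  # 'kinase' or 'regulator'
    unit_label: str
    kinase_name: str  # state after the step
    regulator_name: str


@dataclass
class TrajectoryPath:
    """One mutational path: states visited and the single-unit step at each move."""

    states: list[tuple[Variant, Variant]]  # (kinase, regulator), start..end
    steps: list[TrajectoryStep]

    def __len__(self) -> int:
        return len(self.steps)

    def state_names(self) -> list[tuple[str, str]]:
        return [(k.name, r.name) for k, r in self.states]


def _state_ok(
    mat: InteractionMatrix,
    kin: Variant,
    reg: Variant,
    transfer_threshold: Optional[float],
    crosstalk_forbidden: Optional[str],
) -> bool:
    if transfer_threshold is None:
        ok = mat.call(kin.name, reg.name)
    else:
        ok = mat.intensity_of(kin.name, reg.name) >= transfer_threshold
    if not ok:
        return False
    if crosstalk_forbidden is not None and mat.call(crosstalk_forbidden, reg.name):
        return False
    return True


def find_insulated_paths(
    mat: InteractionMatrix,
    kinase_scheme: SpecificityScheme,
    regulator_scheme: SpecificityScheme,
    start: Optional[tuple[Variant, Variant]] = None,
    end: Optional[tuple[Variant, Variant]] = None,
    transfer_threshold: Optional[float] = None,
    crosstalk_forbidden: Optional[str] = None,
    allow_reversion: bool = False,
    alternating: bool = False,
) -> list[TrajectoryPath]:
    """All insulated mutational paths from ``start`` to ``end``.

    States are (kinase variant, regulator variant); edges flip exactly one
    unit in exactly one protein.  A path is insulated when every visited
    state (including endpoints) retains phosphotransfer — intensity >=
    ``transfer_threshold``, or the matrix's binary call when the threshold
    is None — and, if ``crosstalk_forbidden`` names a third-party kinase, no
    visited regulator is one of its substrates.

    By default units only flip start -> target (no reversions), so every
    path has exactly k_kinase + k_regulator steps; ``allow_reversion``
    permits back-flips (simple paths only).  ``alternating`` restricts to
    paths that alternate kinase and regulator mutations.  Paths are returned
    shortest first, ties broken by their step sequence.
    """
    if start is None:
        start = (
            Variant(kinase_scheme, (False,) * kinase_scheme.k),
            Variant(regulator_scheme, (False,) * regulator_scheme.k),
        )
    if end is None:
        end = (
            Variant(kinase_scheme, (True,) * kinase_scheme.k),
            Variant(regulator_scheme, (True,) * regulator_scheme.k),
        )

    def neighbors(state):
        kin, reg = state
        for i in range(kinase_scheme.k):
            if allow_reversion or not kin.vector[i]:
                yield (kin.flip(i), reg), ("kinase", kinase_scheme.units[i].label)
        for i in range(regulator_scheme.k):
            if allow_reversion or not reg.vector[i]:
                yield (kin, reg.flip(i)), ("regulator", regulator_scheme.units[i].label)

    def key(state):
        return (state[0].vector, state[1].vector)

    g = nx.DiGraph()
    valid: dict = {}
    for kvec in itertools.product([False, True], repeat=kinase_scheme.k):
        for rvec in itertools.product([False, True], repeat=regulator_scheme.k):
            st = (Variant(kinase_scheme, kvec), Variant(regulator_scheme, rvec))
            if _state_ok(mat, *st, transfer_threshold, crosstalk_forbidden):
                valid[key(st)] = st
    for st in valid.values():
        for nxt, move in neighbors(st):
            if key(nxt) in valid:
                g.add_edge(key(st), key(nxt), move=move)
    if key(start) not in valid or key(end) not in valid:
        return []

    paths: list[TrajectoryPath] = []
    if key(start) == key(end):
        node_paths = [[key(start)]]
    elif g.has_node(key(start)) and g.has_node(key(end)):
        node_paths = nx.all_simple_paths(g, key(start), key(end))
    else:
        node_paths = []
    for node_path in node_paths:
        states = [valid[k] for k in node_path]
        steps = []
        for a, b in zip(node_path, node_path[1:]):
            protein, label = g.edges[a, b]["move"]
            kin, reg = valid[b]
            steps.append(TrajectoryStep(protein, label, kin.name, reg.name))
        if alternating and any(
            s1.protein == s2.protein for s1, s2 in zip(steps, steps[1:])
        ):
            continue
        paths.append(TrajectoryPath(states, steps))
    paths.sort(key=lambda p: (len(p), [(s.protein, s.unit_label) for s in p.steps]))
    return paths


# ---------------------------------------------------------------------------
# Context dependence (epistasis) of unit effects
# ---------------------------------------------------------------------------

def context_dependence_table(
    mat: InteractionMatrix,
    scheme: SpecificityScheme,
    axis: str = "kinase",
) -> pd.DataFrame:
    """Effect of flipping each unit, in every background of the other units.

    For ``axis="kinase"`` the effect is the change in the kinase's substrate
    set (regulators called as transferred-to); for ``axis="regulator"`` it is
    the change in the set of kinases that phosphorylate the regulator.  A
    unit is flagged epistatic when its (added, removed) effect differs
    across backgrounds — e.g. a substitution that is silent in the wild type
    but switches specificity in a mutant background.  The table has
    k * 2^(k-1) rows.
    """
    if axis not in ("kinase", "regulator"):
        raise ValueError("axis must be 'kinase' or 'regulator'")
    partners = mat.substrates if axis == "kinase" else mat.kinases_of
    records = []
    epistatic: dict[str, bool] = {}
    for ui, unit in enumerate(scheme.units):
        others = [i for i in range(scheme.k) if i != ui]
        effects = set()
        for background in itertools.product([False, True], repeat=len(others)):
            vec = [False] * scheme.k
            for pos, flag in zip(others, background):
                vec[pos] = flag
            vec[ui] = False
            v_start = Variant(scheme, tuple(vec))
            vec[ui] = True
            v_target = Variant(scheme, tuple(vec))
            before = partners(v_start.name)
            after = partners(v_target.name)
            effect = (after - before, before - after)
            effects.add(effect)
            records.append(
                {
                    "unit": unit.label,
                    "background": "".join(
                        scheme.units[pos].label + ("*" if flag else "")
                        for pos, flag in zip(others, background)
                    ),
                    "variant_start": v_start.name,
                    "variant_target": v_target.name,
                    "added": ",".join(sorted(effect[0])),
                    "removed": ",".join(sorted(effect[1])),
                }
            )
        epistatic[unit.label] = len(effects) > 1
    df = pd.DataFrame.from_records(records)
    df["epistatic"] = df["unit"].map(epistatic)
    return df
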