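"""Specificity-residue schemes and mutational variants.

A scheme lists the *mutable units* separating two alleles of a protein's
specificity residues.  A unit is usually a single residue (EnvZ T250 -> V)
but may span several residues mutated atomically, like the response
regulator's beta5-alpha5 loop (PFN -> TTP).  A variant assigns each unit
either its start or its target allele; its name concatenates the per-unit
residue strings in unit order, so wild-type EnvZ is "TLA" and the fully
converted kinase is "VYR".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml


class SchemeError(ValueError):
    pass


@dataclass(frozen=True)
class SchemeUnit:
    """One mutable unit: label, residue positions, start and target alleles."""

    label: str
    positions: tuple[int, ...]
    start_allele: str
    target_allele: str

    def __post_init__(self) -> None:
        if len(self.start_allele) != len(self.positions) or len(
            self.target_allele
        ) != len(self.positions):
            raise SchemeError(
                f"unit {self.label!r}: allele length must match its "
                f"{len(self.positions)} position(s)"
            )
        if self.start_allele == self.target_allele:
            raise SchemeError(f"unit {self.label!r}: start and target alleles are equal")

    @property
    def width(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SpecificityScheme:
    """Ordered mutable units for one protein context (e.g. 'EnvZ')."""

    protein: str
    units: tuple[SchemeUnit, ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for u in self.units:
            overlap = seen & set(u.positions)
            if overlap:
                raise SchemeError(f"positions {sorted(overlap)} appear in two units")
            seen |= set(u.positions)

    @property
    def k(self) -> int:
        return len(self.units)

    @property
    def start_name(self) -> str:
        return "".join(u.start_allele for u in self.units)

    @property
    def target_name(self) -> str:
        return "".join(u.target_allele for u in self.units)

    def unit_labels(self) -> list[str]:
        return [u.label for u in self.units]

    def parse_name(self, name: str) -> tuple[bool, ...]:
        """Invert variant naming: return the per-unit (is target?) vector."""
        vector = []
        pos = 0
        for u in self.units:
            chunk = name[pos : pos + u.width]
            pos += u.width
            if chunk == u.start_allele:
                vector.append(False)
            elif chunk == u.target_allele:
                vector.append(True)
            else:
                raise SchemeError(
                    f"{name!r}: chunk {chunk!r} matches neither allele of unit {u.label!r}"
                )
        if pos != len(name):
            raise SchemeError(f"{name!r} has trailing characters beyond the scheme's units")
        return tuple(vector)


@dataclass(frozen=True)
class Variant:
    """One assignment of start/target alleles across a scheme's units."""

    scheme: SpecificityScheme
    vector: tuple[bool, ...]  # True = target allele

    def __post_init__(self) -> None:
        if len(self.vector) != self.scheme.k:
            raise SchemeError(
                f"vector length {len(self.vector)} != unit count {self.scheme.k}"
            )

    @property
    def depth(self) -> int:
        """Number of units carrying the target allele (Hamming distance from start)."""
        return sum(self.vector)

    @property
    def name(self) -> str:
        return "".join(
            u.target_allele if flipped else u.start_allele
            for u, flipped in zip(self.scheme.units, self.vector)
        )

    @property
    def qualified_name(self) -> str:
        return f"{self.scheme.protein}({self.name})"

    def flip(self, unit_index: int) -> "Variant":
        vec = list(self.vector)
        vec[unit_index] = not vec[unit_index]
        return Variant(self.scheme, tuple(vec))


def name_variant(variant: Variant, scheme: SpecificityScheme | None = None) -> str:
    """Concatenated per-unit residue string, e.g. 'VLA' or 'EVATTP'."""
    if scheme is not None and scheme is not variant.scheme and scheme != variant.scheme:
        raise SchemeError("variant does not belong to the given scheme")
    return variant.name


def enumerate_variants(
    scheme: SpecificityScheme, depths: Iterable[int]
) -> list[Variant]:
    """All variants whose depth lies in ``depths``.

    Deterministic order: depth ascending, then lexicographic over the tuple
    of flipped unit indices; the count at depth d is C(k, d).
    """
    k = scheme.k
    depth_set = sorted(set(depths))
    for d in depth_set:
        if not 0 <= d <= k:
            raise SchemeError(f"depth {d} outside 0..{k}")
    out = []
    for d in depth_set:
        for combo in itertools.combinations(range(k), d):
            vec = tuple(i in combo for i in range(k))
            out.append(Variant(scheme, vec))
    return out


def all_variants(scheme: SpecificityScheme) -> list[Variant]:
    return enumerate_variants(scheme, range(scheme.k + 1))


# ---------------------------------------------------------------------------
# Built-in schemes for the EnvZ/OmpR <-> RstB/RstA conversion
# ---------------------------------------------------------------------------

def envz_kinase_scheme(protein: str = "EnvZ") -> SpecificityScheme:
    """Three kinase specificity residues: T250->V, L254->Y, A255->R.

    The same three substitutions convert EnvZ specificity toward RstB and
    (reversed) RstB toward EnvZ.
    """
    return SpecificityScheme(
        protein,
        (
            SchemeUnit("pos1", (250,), "T", "V"),
            SchemeUnit("pos2", (254,), "L", "Y"),
            SchemeUnit("pos3", (255,), "A", "R"),
        ),
    )


def ompr_regulator_scheme(protein: str = "OmpR") -> SpecificityScheme:
    """Four regulator units: three alpha-helix-1 residues (R->E, L->V, R->A)
    and the beta5-alpha5 loop mutated atomically (PFN -> TTP).

    Positions are ordinal (the analysis never dereferences them against a
    structure); the loop counts as one unit of width three.
    """
    return SpecificityScheme(
        protein,
        (
            SchemeUnit("pos1", (1,), "R", "E"),
            SchemeUnit("pos2", (2,), "L", "V"),
            SchemeUnit("pos3", (3,), "R", "A"),
            SchemeUnit("loop", (4, 5, 6), "PFN", "TTP"),
        ),
    )


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------

def scheme_to_dict(scheme: SpecificityScheme) -> dict:
    return {
        "protein": scheme.protein,
        "units": [
            {
                "label": u.label,
                "positions": list(u.positions),
                "start": u.start_allele,
                "target": u.target_allele,
            }
            for u in scheme.units
        ],
    }


def scheme_from_dict(d: dict) -> SpecificityScheme:
    try:
        units = tuple(
            SchemeUnit(u["label"], tuple(u["positions"]), u["start"], u["target"])
            for u in d["units"]
        )
        return SpecificityScheme(d["protein"], units)
    except KeyError as exc:
        raise SchemeError(f"scheme config missing key {exc}") from exc


def load_schemes(path: str | Path) -> dict[str, SpecificityScheme]:
    """Load a YAML file with a top-level ``schemes:`` list, keyed by protein."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["schemes"] if isinstance(doc, dict) and "schemes" in doc else [doc]
    schemes = [scheme_from_dict(e) for e in entries]
    return {s.protein: s for s in schemes}


def dump_schemes(schemes: Sequence[SpecificityScheme], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"schemes": [scheme_to_dict(s) for s in schemes]}, fh, sort_keys=False)
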