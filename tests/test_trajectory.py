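"""Variant combinatorics, codon costs, epistasis tables, and insulated paths."""

import itertools
import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevotraj.schemes import (
    SchemeError,
    SchemeUnit,
    SpecificityScheme,
    Variant,
    all_variants,
    enumerate_variants,
    envz_kinase_scheme,
    load_schemes,
    name_variant,
    ompr_regulator_scheme,
    dump_schemes,
)
from coevotraj.trajectory import (
    InteractionMatrix,
    MissingVariantError,
    context_dependence_table,
    enumerate_panel,
    find_insulated_paths,
    min_codon_distance,
    unit_codon_cost,
)

# ---------------------------------------------------------------------------
# Independent genetic-code oracle (NCBI standard table, hard-coded layout)
# ---------------------------------------------------------------------------

_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_BASES = "TCAG"
CODON_TABLE_ORACLE = {
    b1 + b2 + b3: _AAS[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}


def oracle_codon_distance(a, b):
    ca = [c for c, aa in CODON_TABLE_ORACLE.items() if aa == a]
    cb = [c for c, aa in CODON_TABLE_ORACLE.items() if aa == b]
    return min(sum(x != y for x, y in zip(c1, c2)) for c1 in ca for c2 in cb)


AMINO_ACIDS = sorted(set(_AAS) - {"*"})


class TestEnumeration:
    def test_regulator_intermediates_count_by_depth(self, regulator_scheme):
        variants = enumerate_variants(regulator_scheme, [1, 2, 3, 4])
        assert len(variants) == 15
        by_depth = [sum(v.depth == d for v in variants) for d in (1, 2, 3, 4)]
        assert by_depth == [4, 6, 4, 1]

    def test_kinase_single_and_double_mutants_both_contexts(self, kinase_scheme):
        from coevotraj.schemes import envz_kinase_scheme

        envz = enumerate_variants(kinase_scheme, [1, 2])
        rstb = enumerate_variants(envz_kinase_scheme("RstB"), [1, 2])
        assert len(envz) == 6
        assert len(envz) + len(rstb) == 12

    def test_depth_zero_is_wild_type(self, kinase_scheme):
        (wt,) = enumerate_variants(kinase_scheme, [0])
        assert wt.depth == 0 and wt.name == "TLA"

    def test_counts_follow_binomials_for_all_k_up_to_six(self):
        for k in range(1, 7):
            scheme = SpecificityScheme(
                "P",
                tuple(SchemeUnit(f"u{i}", (i + 1,), "A", "G") for i in range(k)),
            )
            for d in range(k + 1):
                assert len(enumerate_variants(scheme, [d])) == math.comb(k, d)

    def test_order_is_depth_then_lexicographic(self, kinase_scheme):
        names = [v.name for v in enumerate_variants(kinase_scheme, [1, 2])]
        assert names == ["VLA", "TYA", "TLR", "VYA", "VLR", "TYR"]

    def test_out_of_range_depth_rejected(self, kinase_scheme):
        with pytest.raises(SchemeError):
            enumerate_variants(kinase_scheme, [4])


class TestNaming:
    def test_kinase_names(self, kinase_scheme):
        assert Variant(kinase_scheme, (False,) * 3).name == "TLA"
        assert Variant(kinase_scheme, (True,) * 3).name == "VYR"
        assert name_variant(Variant(kinase_scheme, (True, False, False))) == "VLA"

    def test_regulator_loop_contributes_three_residues(self, regulator_scheme):
        assert Variant(regulator_scheme, (False,) * 4).name == "RLRPFN"
        assert Variant(regulator_scheme, (True,) * 4).name == "EVATTP"

    def test_names_injective_over_variant_set(self, regulator_scheme):
        names = [v.name for v in all_variants(regulator_scheme)]
        assert len(names) == len(set(names)) == 16

    def test_parse_inverts_naming(self, regulator_scheme):
        for v in all_variants(regulator_scheme):
            assert regulator_scheme.parse_name(v.name) == v.vector
        with pytest.raises(SchemeError):
            regulator_scheme.parse_name("XLRPFN")

    def test_allele_length_mismatch_rejected(self):
        with pytest.raises(SchemeError):
            SchemeUnit("loop", (1, 2, 3), "PF", "TTP")


class TestPanel:
    def test_full_trajectory_panel_is_180_pairs(self, kinase_scheme, regulator_scheme):
        pairs = enumerate_panel(
            kinase_scheme,
            regulator_scheme,
            extra_kinases=["EnvZ(wt)", "RstB(wt)", "CpxA"],
            extra_regulators=["OmpR(wt)", "RstA(wt)", "CpxR"],
        )
        assert len(pairs) == 180

    def test_minimal_panel(self, one_unit_schemes):
        kin, reg = one_unit_schemes
        assert len(enumerate_panel(kin, reg)) == 1

    @given(k=st.integers(1, 4), kp=st.integers(1, 4), ek=st.integers(0, 3), er=st.integers(0, 3))
    @settings(deadline=None, max_examples=25)
    def test_product_rule(self, k, kp, ek, er):
        kin = SpecificityScheme("K", tuple(SchemeUnit(f"u{i}", (i + 1,), "A", "G") for i in range(k)))
        reg = SpecificityScheme("R", tuple(SchemeUnit(f"u{i}", (i + 1,), "C", "D") for i in range(kp)))
        pairs = enumerate_panel(kin, reg, ["x"] * ek, ["y"] * er)
        assert len(pairs) == (2**k - 1 + ek) * (2**kp - 1 + er)


class TestCodonDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("A", "A", 0), ("T", "V", 2), ("L", "Y", 2), ("A", "R", 2), ("M", "I", 1)],
    )
    def test_examples_match_oracle(self, a, b, expected):
        assert min_codon_distance(a, b) == expected == oracle_codon_distance(a, b)

    def test_agrees_with_oracle_for_all_amino_acid_pairs(self):
        for a, b in itertools.product(AMINO_ACIDS, repeat=2):
            assert min_codon_distance(a, b) == oracle_codon_distance(a, b)

    def test_symmetric_and_bounded(self):
        d = {(a, b): min_codon_distance(a, b) for a in AMINO_ACIDS for b in AMINO_ACIDS}
        for a, b in d:
            assert d[a, b] == d[b, a]
            assert 0 <= d[a, b] <= 3
            assert (d[a, b] == 0) == (a == b)

    def test_not_a_metric_min_over_codon_pairs_breaks_triangle(self):
        # the two legs may use different codons of the middle amino acid:
        # C->G via TGT~GGT and G->E via GGA~GAA, but C->E needs 3 changes
        assert min_codon_distance("C", "G") == 1
        assert min_codon_distance("G", "E") == 1
        assert min_codon_distance("C", "E") == 3

    def test_unknown_amino_acid_rejected(self):
        with pytest.raises(ValueError):
            min_codon_distance("B", "A")

    def test_multi_residue_unit_cost_is_sum_of_minima(self):
        assert unit_codon_cost("TLA", "VYR") == 6
        assert unit_codon_cost("PFN", "TTP") == sum(
            oracle_codon_distance(x, y) for x, y in zip("PFN", "TTP")
        )


# ---------------------------------------------------------------------------
# Insulated-path search
# ---------------------------------------------------------------------------

def _call_matrix(kin, reg, calls):
    """InteractionMatrix from {(kname, rname): bool}; intensity mirrors calls."""
    knames = [v.name for v in all_variants(kin)]
    rnames = [v.name for v in all_variants(reg)]
    df = pd.DataFrame(
        [[bool(calls[(k, r)]) for r in rnames] for k in knames],
        index=knames,
        columns=rnames,
    )
    return InteractionMatrix(df.astype(float), df)


def oracle_insulated_paths(kin, reg, state_ok):
    """Exhaustive recursive enumeration of monotone single-flip paths whose
    every visited state satisfies ``state_ok``; independent of the library."""
    start = ((False,) * kin.k, (False,) * reg.k)
    goal = ((True,) * kin.k, (True,) * reg.k)
    out = []

    def extend(path):
        state = path[-1]
        if state == goal:
            out.append(list(path))
            return
        kv, rv = state
        for i in range(kin.k):
            if not kv[i]:
                nxt = (kv[:i] + (True,) + kv[i + 1 :], rv)
                if state_ok(nxt):
                    extend(path + [nxt])
        for i in range(reg.k):
            if not rv[i]:
                nxt = (kv, rv[:i] + (True,) + rv[i + 1 :])
                if state_ok(nxt):
                    extend(path + [nxt])

    if state_ok(start):
        extend([start])
    return out


class TestInsulatedPaths:
    def test_single_shortest_path_in_four_state_toy(self, one_unit_schemes):
        kin, reg = one_unit_schemes
        calls = {("A", "C"): 1, ("A", "D"): 1, ("G", "C"): 0, ("G", "D"): 1}
        mat = _call_matrix(kin, reg, calls)
        paths = find_insulated_paths(mat, kin, reg)
        assert len(paths) == 1
        assert paths[0].state_names() == [("A", "C"), ("A", "D"), ("G", "D")]
        assert [(s.protein, s.unit_label) for s in paths[0].steps] == [
            ("regulator", "u1"),
            ("kinase", "u1"),
        ]

    def test_strict_matching_has_no_path(self, one_unit_schemes):
        kin, reg = one_unit_schemes
        calls = {("A", "C"): 1, ("A", "D"): 0, ("G", "C"): 0, ("G", "D"): 1}
        assert find_insulated_paths(_call_matrix(kin, reg, calls), kin, reg) == []

    def test_crosstalk_constraint_blocks_mandatory_state(self, one_unit_schemes):
        kin, reg = one_unit_schemes
        calls = {("A", "C"): 1, ("A", "D"): 1, ("G", "C"): 0, ("G", "D"): 1}
        mat = _call_matrix(kin, reg, calls)
        # third-party kinase phosphorylates regulator D, the only corridor
        mat.intensity.loc["CpxA"] = [0.0, 1.0]
        mat.calls.loc["CpxA"] = [False, True]
        assert find_insulated_paths(mat, kin, reg, crosstalk_forbidden="CpxA") == []

    def test_missing_variant_is_named_in_error(self, one_unit_schemes):
        kin, reg = one_unit_schemes
        df = pd.DataFrame([[1.0]], index=["A"], columns=["C"])
        mat = InteractionMatrix(df)
        with pytest.raises(MissingVariantError, match="absent"):
            find_insulated_paths(mat, kin, reg)

    def test_agrees_with_exhaustive_oracle_on_random_two_unit_matrices(
        self, two_unit_schemes
    ):
        import numpy as np

        kin, reg = two_unit_schemes
        rng = np.random.default_rng(11)
        kvars = all_variants(kin)
        rvars = all_variants(reg)
        vec_of = {v.name: v.vector for v in kvars} | {v.name: v.vector for v in rvars}
        for trial in range(40):
            bits = rng.random((4, 4)) < 0.7
            calls = {
                (kv.name, rv.name): bits[a, b]
                for a, kv in enumerate(kvars)
                for b, rv in enumerate(rvars)
            }
            mat = _call_matrix(kin, reg, calls)
            got = [
                [(vec_of[k], vec_of[r]) for k, r in p.state_names()]
                for p in find_insulated_paths(mat, kin, reg)
            ]
            expected = oracle_insulated_paths(
                kin, reg, lambda st: calls[(_name(kin, st[0]), _name(reg, st[1]))]
            )
            assert sorted(got) == sorted(expected)

    def test_every_path_flips_each_unit_exactly_once(self, two_unit_schemes):
        kin, reg = two_unit_schemes
        calls = {
            (k.name, r.name): True for k in all_variants(kin) for r in all_variants(reg)
        }
        paths = find_insulated_paths(_call_matrix(kin, reg, calls), kin, reg)
        assert all(len(p) == kin.k + reg.k for p in paths)
        # all-permissive matrix: one path per interleaving of 4 distinct flips
        assert len(paths) == math.factorial(4)

    def test_alternating_flag_restricts_interleavings(self, two_unit_schemes):
        kin, reg = two_unit_schemes
        calls = {
            (k.name, r.name): True for k in all_variants(kin) for r in all_variants(reg)
        }
        mat = _call_matrix(kin, reg, calls)
        alt = find_insulated_paths(mat, kin, reg, alternating=True)
        assert all(
            s1.protein != s2.protein
            for p in alt
            for s1, s2 in zip(p.steps, p.steps[1:])
        )
        assert 0 < len(alt) < math.factorial(4)

    def test_intensity_threshold_route(self, one_unit_schemes):
        kin, reg = one_unit_schemes
        df = pd.DataFrame(
            [[100.0, 40.0], [0.0, 90.0]], index=["A", "G"], columns=["C", "D"]
        )
        mat = InteractionMatrix(df)
        assert len(find_insulated_paths(mat, kin, reg, transfer_threshold=30.0)) == 1
        assert find_insulated_paths(mat, kin, reg, transfer_threshold=50.0) == []


def _name(scheme, vector):
    return Variant(scheme, vector).name


class TestContextDependence:
    def test_no_epistasis_when_flip_never_changes_substrates(self, two_unit_schemes):
        kin, reg = two_unit_schemes
        # substrates depend only on unit 2 of the kinase
        calls = {
            (k.name, r.name): k.vector[1]
            for k in all_variants(kin)
            for r in all_variants(reg)
        }
        table = context_dependence_table(_call_matrix(kin, reg, calls), kin)
        u1 = table[table.unit == "u1"]
        assert not u1.epistatic.any()
        assert (u1.added == "").all() and (u1.removed == "").all()

    def test_background_dependent_flip_is_flagged(self, two_unit_schemes):
        kin, reg = two_unit_schemes
        # unit 1 adds substrate 'FI' only when unit 2 is already target
        calls = {
            (k.name, r.name): (r.name == "EH")
            or (k.vector[0] and k.vector[1] and r.name == "FI")
            for k in all_variants(kin)
            for r in all_variants(reg)
        }
        table = context_dependence_table(_call_matrix(kin, reg, calls), kin)
        assert table[table.unit == "u1"].epistatic.all()

    def test_row_count_is_k_times_two_to_k_minus_one(self, regulator_scheme):
        calls = {
            (k, r.name): True
            for k in ["K0"]
            for r in all_variants(regulator_scheme)
        }
        df = pd.DataFrame(
            [[True] * 16], index=["K0"], columns=[v.name for v in all_variants(regulator_scheme)]
        )
        mat = InteractionMatrix(df.astype(float), df)
        table = context_dependence_table(mat, regulator_scheme, axis="regulator")
        assert len(table) == 4 * 2**3


def test_scheme_yaml_round_trip(tmp_path, kinase_scheme, regulator_scheme):
    path = tmp_path / "schemes.yaml"
    dump_schemes([kinase_scheme, regulator_scheme], path)
    loaded = load_schemes(path)
    assert loaded["EnvZ"] == kinase_scheme
    assert loaded["OmpR"] == regulator_scheme
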