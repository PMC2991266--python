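import pytest

from coevotraj.alignment import HK, RR, ColumnOrigin, PairedAlignment, PairedRow
from coevotraj.schemes import SchemeUnit, SpecificityScheme


def make_paired(seqs, n_hk_cols, ids=None):
    """Build a PairedAlignment from row strings; first ``n_hk_cols`` columns are HK."""
    if not seqs:
        raise ValueError("need at least one row to infer width")
    width = len(seqs[0])
    meta = [ColumnOrigin(HK, c + 1) for c in range(n_hk_cols)] + [
        ColumnOrigin(RR, c + 1) for c in range(width - n_hk_cols)
    ]
    ids = ids or [(f"hk{i}", f"rr{i}") for i in range(len(seqs))]
    rows = [PairedRow(h, r, s) for (h, r), s in zip(ids, seqs)]
    return PairedAlignment(rows, meta)


@pytest.fixture
def worked_three_column():
    """Three columns [A,A,G,G], [C,C,D,D], [E,F,E,F]: the first two are
    perfectly correlated (MI = ln 2), the third is independent of both."""
    return make_paired(["ACE", "ACF", "GDE", "GDF"], n_hk_cols=1)


@pytest.fixture
def kinase_scheme():
    from coevotraj.schemes import envz_kinase_scheme

    return envz_kinase_scheme()


@pytest.fixture
def regulator_scheme():
    from coevotraj.schemes import ompr_regulator_scheme

    return ompr_regulator_scheme()


@pytest.fixture
def one_unit_schemes():
    """Minimal 1-unit kinase (A->G) and regulator (C->D) schemes."""
    kin = SpecificityScheme("K", (SchemeUnit("u1", (1,), "A", "G"),))
    reg = SpecificityScheme("R", (SchemeUnit("u1", (1,), "C", "D"),))
    return kin, reg


@pytest.fixture
def two_unit_schemes():
    """2-unit schemes with distinct alleles so variant names are unambiguous."""
    kin = SpecificityScheme(
        "K", (SchemeUnit("u1", (1,), "A", "G"), SchemeUnit("u2", (2,), "C", "D"))
    )
    reg = SpecificityScheme(
        "R", (SchemeUnit("u1", (1,), "E", "F"), SchemeUnit("u2", (2,), "H", "I"))
    )
    return kin, reg
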