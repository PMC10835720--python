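import pytest

import copigkit as ck


@pytest.fixture(scope="session")
def oi():
    """CIE 1964 10-degree observer / D65 weighting set on the 380-770 nm grid."""
    return ck.cie1964_d65()


@pytest.fixture(scope="session")
def cielab_table():
    return ck.reference.cielab_reference()


@pytest.fixture(scope="session")
def itc_table():
    return ck.reference.itc_reference()


@pytest.fixture(scope="session")
def mmpbsa_rows():
    return ck.reference.mmpbsa_reference()


@pytest.fixture(scope="session")
def colors(cielab_table):
    """CIEColor objects from the published rounded solution means."""
    out = {}
    for label, row in cielab_table.iterrows():
        out[label] = ck.CIEColor(
            row.L_star, row.a_star, row.b_star, row.C_ab, row.h_ab, label=label
        )
    return out
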