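import pandas as pd
import pytest
from hypothesis import settings

from biogeopath.model import AbundanceProfile

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def sulfur_profile():
    """Family abundances for the worked sulfur/nitrogen formula examples."""
    return AbundanceProfile(
        "s1",
        {
            "K00392": 4.0,
            "K00380": 2.0,
            "K00381": 6.0,
            "K00362": 1.0,
            "K00363": 3.0,
            "K03385": 2.0,
            "K15876": 4.0,
            "phsA": 6.0,
            "phsC": 3.0,
        },
    )


@pytest.fixture
def tblout_file(tmp_path):
    """A small hand-crafted hmmsearch --tblout file (HMMER3 column layout)."""
    lines = [
        "#                                               --- full sequence ---- --- best 1 domain ---- --- domain number estimation ----",
        "# target name Acc query name Acc   E-value  score  bias   E-value  score  bias   exp reg clu  ov env dom rep inc description of target",
        "g1 - K00392 - 1e-50 210.3 0.1 1e-49 209.0 0.1 1.0 1 0 0 1 1 1 1 sulfite reductase",
        "g2 - K00380 - 2e-20 90.5 0.0 3e-20 88.1 0.0 1.0 1 0 0 1 1 1 1 -",
        "g2 - K00381 - 1e-30 140.0 0.0 1e-30 139.0 0.0 1.0 1 0 0 1 1 1 1 -",
    ]
    path = tmp_path / "hits.tblout"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def ko_list_file(tmp_path):
    path = tmp_path / "ko_list"
    rows = [
        "knum\tthreshold\tscore_type\tprofile_type\tF-measure\tdefinition",
        "K00392\t150.00\tfull\tall\t0.99\tsulfite reductase (ferredoxin)",
        "K00380\t100.00\tdomain\tall\t0.95\tsulfite reductase flavoprotein",
        "K00381\t120.50\tfull\tall\t0.97\tsulfite reductase hemoprotein",
        "K99999\t-\t-\tall\t-\tuncharacterized",
    ]
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def pathway_table():
    return pd.DataFrame(
        {"A": [2.0, 0.0, 1.0], "B": [3.0, 0.0, 1.0], "C": [5.0, 0.0, 2.0]},
        index=["p1", "p2", "p3"],
    )
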