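"""Small packaged chemical fixture: four structural families.

Twenty molecules from four well-separated chemical families — the kind
of family structure that structure-based clustering of screen hits is
expected to recover: ethanolamine surfactants, triazine herbicides,
steroid hormones, and pyrazole scaffolds.  Used by tests and demos; the
SMILES are standard public structures.
"""

from __future__ import annotations

import pandas as pd

#: family -> {chemical_id: SMILES}
FAMILY_SMILES: dict[str, dict[str, str]] = {
    "ethanolamine": {
        "ethanolamine": "NCCO",
        "diethanolamine": "OCCNCCO",
        "triethanolamine": "OCCN(CCO)CCO",
        "N-methyldiethanolamine": "CN(CCO)CCO",
        "N-ethyldiethanolamine": "CCN(CCO)CCO",
    },
    "triazine": {
        "atrazine": "CCNc1nc(Cl)nc(NC(C)C)n1",
        "simazine": "CCNc1nc(Cl)nc(NCC)n1",
        "propazine": "CC(C)Nc1nc(Cl)nc(NC(C)C)n1",
        "ametryn": "CCNc1nc(SC)nc(NC(C)C)n1",
        "prometon": "COc1nc(NC(C)C)nc(NC(C)C)n1",
    },
    "steroid": {
        "estradiol": "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",
        "estrone": "CC12CCC3c4ccc(O)cc4CCC3C1CCC2=O",
        "testosterone": "CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O",
        "progesterone": "CC(=O)C1CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C",
        "ethinylestradiol": "CC12CCC3c4ccc(O)cc4CCC3C1CCC2(O)C#C",
    },
    "pyrazole": {
        "pyrazole": "c1cc[nH]n1",
        "3-methylpyrazole": "Cc1cc[nH]n1",
        "edaravone": "CC1=NN(c2ccccc2)C(=O)C1",
        "antipyrine": "CC1=CC(=O)N(c2ccccc2)N1C",
        "1,3-dimethylpyrazole": "Cc1ccn(C)n1",
    },
}


def fixture_table() -> pd.DataFrame:
    """Chemical annotation table for the fixture, with family labels."""
    rows = [
        (cid, cid, None, smi, family)
        for family, members in FAMILY_SMILES.items()
        for cid, smi in members.items()
    ]
    return pd.DataFrame(
        rows, columns=["chemical_id", "name", "casrn", "smiles", "family"]
    )
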