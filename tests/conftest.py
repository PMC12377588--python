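import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from idrbench import PlddtProfile

settings.register_profile("repro", derandomize=True, database=None)
settings.load_profile("repro")


@pytest.fixture
def dip_profile():
    """50 confident residues, a 20-residue low-confidence dip, 50 confident."""
    return PlddtProfile("P1", np.array([90.0] * 50 + [40.0] * 20 + [90.0] * 50))


@pytest.fixture
def toy_variants():
    """Ten region-assigned variants: 4 pathogenic, 6 putatively benign."""
    rows = []
    regions = ["disordered", "intermediate", "ordered", "ordered"]
    for i, region in enumerate(regions):
        rows.append(("P1", "GENE1", i + 1, "A", "V", "clinvar_pathogenic", region))
    for i, region in enumerate(
        ["disordered", "disordered", "intermediate", "ordered", "ordered", "ordered"]
    ):
        rows.append(("P2", "GENE2", i + 1, "L", "P", "gnomad_benign", region))
    return pd.DataFrame(
        rows,
        columns=["protein_id", "gene", "position", "ref_aa", "alt_aa",
                 "class_label", "region"],
    )


def write_tsv(path, df):
    df.to_csv(path, sep="\t", index=False)
    return path
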