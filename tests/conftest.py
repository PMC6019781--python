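import numpy as np
import pandas as pd
import pytest

from chloroedit.ppr_code import CodeTable, MotifSpec, PPRArray

AA_POOL = list("ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture
def toy_table():
    """The two-entry table used by the lookup examples."""
    return CodeTable(
        entries={
            ("T", "D"): np.array([1.2, -0.5, -1.0, -0.8]),
            ("S", "N"): np.array([-0.2, 0.1, -0.9, 1.1]),
        }
    )


@pytest.fixture
def six_motif_array():
    combos = [("T", "N"), ("S", "N"), ("N", "S"), ("T", "D"), ("N", "D"), ("S", "S")]
    motifs = [MotifSpec(i + 1, "P1", a, b) for i, (a, b) in enumerate(combos)]
    return PPRArray("FACTOR_A", motifs)


def random_table(rng, n_entries=15):
    entries = {}
    while len(entries) < n_entries:
        key = (rng.choice(AA_POOL), rng.choice(AA_POOL))
        entries[key] = rng.normal(0, 1, size=4)
    return CodeTable(entries=entries)


def random_array(rng, table, n_motifs, protein_id="RND"):
    keys = list(table.entries)
    motifs = []
    for i in range(n_motifs):
        aa5, aa_last = keys[rng.integers(len(keys))]
        motifs.append(MotifSpec(i + 1, "P1", aa5, aa_last))
    return PPRArray(protein_id, motifs)


def pileup_row(sample_id, seq_id, position, strand, ref_base, nA=0, nC=0, nG=0, nT=0):
    return {
        "sample_id": sample_id,
        "seq_id": seq_id,
        "position": position,
        "strand": strand,
        "ref_base": ref_base,
        "nA": nA,
        "nC": nC,
        "nG": nG,
        "nT": nT,
    }


def pileup_frame(rows):
    return pd.DataFrame(rows)
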