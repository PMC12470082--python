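import numpy as np
import pytest

import cpgphylo as cp


def random_records(rng, n, min_len=20, max_len=120, alphabet="ACGTN"):
    out = []
    for i in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(list(alphabet), size=L))
        out.append(cp.SequenceRecord(id=f"s{i}", seq=seq))
    return out


def random_msa(rng, n_rows=6, n_cols=60, gap_frac=0.05, cpg_boost=0.3):
    """Random alignment with some CpG-rich columns and occasional gaps."""
    rows = []
    base_cols = rng.choice(list("ACGT"), size=n_cols)
    for r in range(n_rows):
        row = []
        for c in range(n_cols):
            x = base_cols[c]
            if rng.random() < 0.15:
                x = rng.choice(list("ACGT"))
            if rng.random() < gap_frac:
                x = "-"
            row.append(x)
        # sprinkle CpG dinucleotides at even columns
        for k in range(0, n_cols - 1, 2):
            if rng.random() < cpg_boost:
                row[k], row[k + 1] = "C", "G"
        if all(x == "-" for x in row):
            row[0] = "A"
        rows.append("".join(row))
    return cp.Msa(ids=[f"t{r}" for r in range(n_rows)], rows=rows)


@pytest.fixture(scope="session")
def study_dataset():
    """Full-size study-like simulation (12 taxa, 5000 concatenated bases)."""
    return cp.generate_study_like_dataset(cp.ErosionParams(seed=1))


@pytest.fixture(scope="session")
def study_table(study_dataset):
    msa = study_dataset.msa
    return cp.classify_positions(cp.tile_dinucleotides(msa), msa)
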