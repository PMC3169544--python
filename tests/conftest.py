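import numpy as np
import pandas as pd
import pytest

from hybridhallmarks.seqio import (
    AFLPMatrix,
    AlignedLocus,
    Inheritance,
    PopulationMap,
    SequenceRecord,
    Sex,
)


def make_locus(seqs, name="toy", inheritance=Inheritance.Z_LINKED, pops=None, sexes=None,
               samples=None):
    """Build an AlignedLocus from a list of sequence strings."""
    n = len(seqs)
    pops = pops or ["pop1"] * n
    sexes = sexes or [Sex.FEMALE] * n
    samples = samples or [f"s{i}" for i in range(n)]
    seen: dict[str, int] = {}
    records = []
    for i in range(n):
        allele = seen.get(samples[i], 0)
        seen[samples[i]] = allele + 1
        records.append(
            SequenceRecord(
                sequence_id=f"{samples[i]}|{pops[i]}|{sexes[i].value}|{allele}",
                sample_id=samples[i],
                population=pops[i],
                sex=sexes[i],
                seq=seqs[i],
            )
        )
    return AlignedLocus(name, inheritance, records)


def make_aflp(array, samples=None, markers=None):
    array = np.asarray(array, dtype=float)
    samples = samples or [f"i{r}" for r in range(array.shape[0])]
    markers = markers or [f"m{c}" for c in range(array.shape[1])]
    return AFLPMatrix(pd.DataFrame(array, index=samples, columns=markers))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def two_pop_map():
    return PopulationMap.from_pairs(
        {f"a{i}": ("popA", "U") for i in range(10)} | {f"b{i}": ("popB", "U") for i in range(10)}
    )
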