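import numpy as np
import pandas as pd
import pytest

from mtpopgen.seqio import Alignment, PopulationMap, collapse_haplotypes


def make_dataset(seqs, pops=None, counts=None, coords=None, ids=None):
    """Build (Alignment, PopulationMap, HaplotypeDataset) from raw sequences."""
    n = len(seqs)
    ids = ids or [f"s{i + 1}" for i in range(n)]
    pops = pops or ["P1"] * n
    counts = counts or [1] * n
    coords = coords or {}
    uniq = list(dict.fromkeys(pops))
    latlon = {p: coords.get(p, (float(uniq.index(p)), 0.0)) for p in uniq}
    aln = Alignment(list(zip(ids, seqs)))
    pm = PopulationMap(
        pd.DataFrame(
            {
                "sequence_id": ids,
                "count": counts,
                "population": pops,
                "latitude": [latlon[p][0] for p in pops],
                "longitude": [latlon[p][1] for p in pops],
            }
        )
    )
    return aln, pm, collapse_haplotypes(aln, pm)


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_alignment(rng, n, L, alphabet="ACGT"):
    return ["".join(rng.choice(list(alphabet), size=L)) for _ in range(n)]


def similar_sequences(rng, n, L, divergence=0.05):
    """Sequences derived from one ancestor by sparse random substitutions:
    realistic intraspecific divergence, safe for log-based distances."""
    base = rng.choice(list("ACGT"), size=L)
    out = []
    for _ in range(n):
        s = base.copy()
        k = rng.binomial(L, divergence)
        for j in rng.choice(L, size=k, replace=False):
            s[j] = rng.choice([b for b in "ACGT" if b != s[j]])
        out.append("".join(s))
    return out
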