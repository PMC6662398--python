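"""Shared helper: build an all-male multi-type collection for rarefaction tests."""

import numpy as np

from arcticum.nomenclature import parse_inversion_name
from arcticum.records import Genotype, GenotypeState, LarvaRecord, Sex


def build_multitype_collection(frequencies: dict[str, float], n: int, seed: int):
    """All-male collection with multinomially drawn per-type counts.

    Returns the records and the realised type frequencies (the analytic
    rarefaction expectation must be evaluated at the realised, not nominal,
    frequencies because subsampling is within the fixed collection).
    """
    rng = np.random.default_rng(seed)
    types = list(frequencies)
    counts = rng.multinomial(n, [frequencies[t] for t in types])
    records = []
    i = 0
    for t, c in zip(types, counts):
        inv = parse_inversion_name(t)
        for _ in range(c):
            records.append(
                LarvaRecord(
                    f"m{i}", "s", None, Sex.M, True,
                    [Genotype(inv, GenotypeState.ST_I)],
                )
            )
            i += 1
    realised = [c / n for c in counts]
    return records, realised
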