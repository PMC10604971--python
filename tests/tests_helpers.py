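"""Small constructors shared across test modules."""

import numpy as np

from conftest import make_genotypes


def hap_from_freqs(freqs, n=100, seed=0):
    """GenotypeData whose SNPs have exactly the requested alt frequencies."""
    rng = np.random.default_rng(seed)
    m = len(freqs)
    haps = np.zeros((n, m, 2), dtype=np.int8)
    for j, f in enumerate(freqs):
        count = int(round(f * 2 * n))
        flat = np.zeros(2 * n, dtype=np.int8)
        flat[:count] = 1
        rng.shuffle(flat)
        haps[:, j, :] = flat.reshape(n, 2)
    return make_genotypes(haps)
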