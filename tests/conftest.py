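import numpy as np
import pytest

from bacsat import PlantSpec, generate_genome


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(rng, s: str, d: float) -> str:
    out = list(s)
    for i in range(len(out)):
        if rng.random() < d:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def embed_array(left: str, units, right: str) -> str:
    """Splice an array between background flanks with crisp boundaries:
    the flanking bases must not continue the array's periodicity, or the
    true maximal periodic extent would exceed the planted coordinates."""
    def different(base):
        return "A" if base != "A" else "C"

    if left and left[-1] == units[0][-1]:
        left = left[:-1] + different(units[0][-1])
    if right and right[0] == units[-1][0]:
        right = different(units[-1][0]) + right[1:]
    return left + "".join(units) + right


@pytest.fixture(scope="session")
def small_planted():
    """One modest synthetic genome with exact planted arrays, shared by
    several test modules."""
    spec = PlantSpec(
        n_arrays=6, genome_length_nt=120_000, seed=3, copy_range=(4, 12)
    )
    return generate_genome(spec)
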