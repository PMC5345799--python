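import numpy as np
import pytest

from dedomains import DomainMap, Genome, Interval


@pytest.fixture
def small_genome() -> Genome:
    return Genome.from_dict({"chr2L": 1_000_000, "chr2R": 500_000})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_regular_map(
    length: int, chrom: str = "chrA", d_width: int = 80_000, e_width: int = 100_000
) -> DomainMap:
    """Alternating D/E map tiling a chromosome, starting with D."""
    ivs, pos, lab = [], 0, "D"
    while pos < length:
        width = d_width if lab == "D" else e_width
        end = min(pos + width, length)
        ivs.append(Interval(chrom, pos, end, lab))
        pos = end
        lab = "E" if lab == "D" else "D"
    return DomainMap(ivs)
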