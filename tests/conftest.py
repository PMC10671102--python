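import numpy as np
import pytest

from mitopop import synthetic_reference, parse_haplotype_string, example_tree
from mitopop.refmodel import ReferenceGenome, TRANSITIONS

# Published example haplotypes (rCRS-relative, EMPOP-style notation)
H2A1N = "146C 263G 309.xC 315.1C 750G 951A 4659A 8860G 15326G 16354T"
U8A1A1A = (
    "73G 263G 282C 309.1C 315.1C 750G 1438G 1811G 2706G 3738T 4129G 4769G "
    "5240G 6392C 6455T 7028T 7055G 8860G 9365T 9698C 10733T 11150A 11467G "
    "11719A 12135A 12308G 12372A 13145A 14766T 15326G 16209C 16342C"
)
U5B1B1A = (
    "73G 150T 263G 309.xC 315.1C 750G 1438G 2706G 3197C 4769G 5656G 7028T "
    "7385G 7768G 8860G 9477A 10927C 11467G 11719A 12308G 12372A 12618A "
    "13617C 14182C 14766T 15326G 16144C 16189C 16270T"
)


@pytest.fixture(scope="session")
def reference():
    return synthetic_reference()


@pytest.fixture(scope="session")
def mini_tree():
    return example_tree()


@pytest.fixture
def h2a1n():
    return parse_haplotype_string(H2A1N, sample_id="h2a1n")


@pytest.fixture
def u5b1b1a():
    return parse_haplotype_string(U5B1B1A, sample_id="u5b1b1a")


@pytest.fixture
def u8a1a1a():
    return parse_haplotype_string(U8A1A1A, sample_id="u8a1a1a")


@pytest.fixture(scope="session")
def adapted_reference(reference):
    """Synthetic reference adjusted so the published example substitutions
    are genuine differences (the real rCRS is not shipped): wherever a
    printed variant letter coincides with the synthetic base, the reference
    base is flipped to its transition partner."""
    bases = list(reference.bases)
    for text in (H2A1N, U5B1B1A, U8A1A1A):
        h = parse_haplotype_string(text)
        for pos, sym in h.substitutions.items():
            if bases[pos - 1] == sym:
                bases[pos - 1] = TRANSITIONS[sym]
    return ReferenceGenome(name="synthetic-mtref-adapted", bases="".join(bases))
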