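import pytest

from wingbind.synthdata import SynthSpec

# Printed operator probes: the 36-nt wild-type site-A oligo and its 35-nt
# mutant in which the second TTAA box is destroyed.
PROBE_A_PRIME = "GGAAACAGTATTAATAAAGTGTTAATCCTATTACCC"
PROBE_A_PRIME_MUT = "GGAAACAGTATTAATAAAGTGCCGTTCCTATTACC"

SITE_A_20MER = "AGTATTAATAAAGTGTTAAT"


@pytest.fixture
def spec() -> SynthSpec:
    """Default study-condition spec with its default noise levels."""
    return SynthSpec(seed=1)


@pytest.fixture
def spec0() -> SynthSpec:
    """Noiseless spec for exact round-trip checks."""
    return SynthSpec(seed=1).noiseless()
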