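import numpy as np
import pytest

from zfnscreen.sites import TargetSpec, revcomp

# Composite target of the adenylate kinase 2 (ak2) exon-1 site:
# 18 nt left half-site, 5 bp spacer, 12 nt right half-site.
AK2_LEFT = "CGATACCGTCTCCGGTAT"
AK2_SPACER = "ACGGA"
AK2_RIGHT = "AAGGCATACGGG"


@pytest.fixture(scope="session")
def ak2_spec() -> TargetSpec:
    return TargetSpec("ak2", AK2_LEFT, (5, 5), AK2_RIGHT)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def brute_force_matches(genome: dict[str, str], query: str, k: int):
    """Independent O(G*L) Hamming oracle over both strands.

    Pure-python character comparison; N mismatches everything.
    """
    query = query.upper()
    rc = revcomp(query)
    L = len(query)
    out = []
    for contig in sorted(genome):
        seq = genome[contig].upper()
        for start in range(len(seq) - L + 1):
            win = seq[start:start + L]
            for strand, q in (("+", query), ("-", rc)):
                mm = sum(1 for a, b in zip(win, q)
                         if a != b or a == "N" or b == "N")
                if mm <= k:
                    out.append((contig, start, strand, mm))
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return out
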