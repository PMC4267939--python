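import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from codonsel.codon_core import CodonCounts, identify_major_codons
from codonsel.polymorphism import HaplotypeAlignment


@pytest.fixture(scope="session")
def majors_study():
    """A major-codon table shaped like the study's (GC-ending majors),
    built from pooled counts biased toward the C-ending codon of each
    family."""
    from codonsel.codon_core import AA_TO_CODONS

    counts = {}
    for aa, codons in AA_TO_CODONS.items():
        if len(codons) < 2:
            continue
        gc = [c for c in codons if c[2] in "GC"]
        top = min(gc) if gc else min(codons)
        for c in codons:
            counts[c] = counts.get(c, 0) + (300 if c == top else 50)
    return identify_major_codons(CodonCounts("pooled", counts))


@pytest.fixture
def toy_alignment():
    """Four haplotypes, one outgroup; contains one synonymous (Lys AAA/AAG)
    and one nonsynonymous (Asn/Lys) polymorphism."""
    #            Lys  Phe  Asn/Lys
    seqs = [
        "AAA" "TTC" "AAC",
        "AAG" "TTC" "AAC",
        "AAG" "TTC" "AAC",
        "AAG" "TTC" "AAA",
    ]
    return HaplotypeAlignment(
        gene_id="toy",
        sequences=seqs,
        arrangement="AR",
        outgroup="AAA" "TTC" "AAC",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
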