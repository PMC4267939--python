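"""Genetic-code tables, codon counting, and major-codon identification.

The standard nuclear genetic code partitions the 61 sense codons into 20
amino-acid families.  Within a family, the most frequently used synonymous
codon is the *major* codon and all others are *minor*.  Heterogeneity of
synonymous-codon usage within a family is measured with a G-test against
the equal-usage expectation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASES = "TCAG"

#: codon -> one-letter amino acid for the 61 sense codons ("*" = stop).
_CODE_STRING = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)

CODON_TABLE: dict[str, str] = {
    "".join(c): aa
    for c, aa in zip(itertools.product(BASES, repeat=3), _CODE_STRING)
    if aa != "*"
}
STOP_CODONS: frozenset[str] = frozenset(
    "".join(c)
    for c, aa in zip(itertools.product(BASES, repeat=3), _CODE_STRING)
    if aa == "*"
)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TABLE))

#: amino acid -> sorted tuple of synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TABLE.items():
    AA_TO_CODONS.setdefault(_aa, ())
AA_TO_CODONS = {
    aa: tuple(sorted(c for c, a in CODON_TABLE.items() if a == aa))
    for aa in AA_TO_CODONS
}

#: amino acid -> degeneracy class (number of synonymous codons: 1,2,3,4,6)
DEGENERACY: dict[str, int] = {aa: len(cods) for aa, cods in AA_TO_CODONS.items()}

ONEFOLD_AAS = frozenset(aa for aa, k in DEGENERACY.items() if k == 1)  # M, W


class GeneticCode:
    """The standard nuclear genetic code.

    Exposes the codon->amino-acid map for the 61 sense codons, the stop-codon
    set and per-amino-acid degeneracy classes.  A single shared instance
    (:data:`STANDARD_CODE`) is used throughout the package.
    """

    def __init__(self) -> None:
        self.codon_to_aa = dict(CODON_TABLE)
        self.stop_codons = set(STOP_CODONS)
        self.aa_to_codons = dict(AA_TO_CODONS)
        self.degeneracy = dict(DEGENERACY)
        assert len(self.codon_to_aa) == 61 and len(self.stop_codons) == 3

    def translate(self, codon: str) -> str | None:
        """Amino acid for ``codon``; ``'*'`` for stops; None if ambiguous."""
        codon = codon.upper().replace("U", "T")
        if codon in self.stop_codons:
            return "*"
        return self.codon_to_aa.get(codon)

    def is_synonymous(self, codon_a: str, codon_b: str) -> bool:
        aa_a, aa_b = self.translate(codon_a), self.translate(codon_b)
        if aa_a is None or aa_b is None or "*" in (aa_a, aa_b):
            return False
        return aa_a == aa_b


STANDARD_CODE = GeneticCode()


@dataclass
class CodonCounts:
    """Non-negative integer counts per sense codon for one gene (or pooled)."""

    gene_id: str = "pooled"
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(SENSE_CODONS)
        if bad & STOP_CODONS:
            raise ValueError(f"counts contain stop codons: {sorted(bad & STOP_CODONS)}")
        if bad:
            raise ValueError(f"unknown codons in counts: {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative codon counts")

    @classmethod
    def from_sequence(cls, seq: str, gene_id: str = "gene") -> "CodonCounts":
        """Tally in-frame codons of a CDS; codons with N/-, or stops, are skipped."""
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3:
            raise ValueError("sequence length not divisible by 3")
        counts: dict[str, int] = {}
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in CODON_TABLE:
                counts[codon] = counts.get(codon, 0) + 1
        return cls(gene_id=gene_id, counts=counts)

    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = dict(self.counts)
        for c, v in other.counts.items():
            merged[c] = merged.get(c, 0) + v
        return CodonCounts(gene_id="pooled", counts=merged)

    def aa_counts(self, aa: str) -> dict[str, int]:
        return {c: self.counts.get(c, 0) for c in AA_TO_CODONS[aa]}


@dataclass
class MajorCodonRow:
    amino_acid: str
    codon: str
    count: int
    fraction: float
    is_major: bool
    tie: bool
    G: float


class MajorCodonTable:
    """Per-amino-acid synonymous codon usage, major codon and heterogeneity G.

    Only amino acids with >= 2 synonymous codons carry a major/minor
    assignment; Met and Trp are excluded by construction.
    """

    def __init__(self, rows: list[MajorCodonRow], unobserved: set[str]):
        self.rows = rows
        self.unobserved = unobserved  # amino acids with zero observations
        self._major: dict[str, str] = {
            r.amino_acid: r.codon for r in rows if r.is_major
        }

    def major_for(self, aa: str) -> str | None:
        return self._major.get(aa)

    def has_major(self, aa: str) -> bool:
        return aa in self._major

    def is_major(self, codon: str) -> bool:
        aa = CODON_TABLE.get(codon)
        return aa is not None and self._major.get(aa) == codon

    def is_minor(self, codon: str) -> bool:
        aa = CODON_TABLE.get(codon)
        return (
            aa is not None and aa in self._major and self._major[aa] != codon
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "amino_acid": r.amino_acid,
                    "codon": r.codon,
                    "count": r.count,
                    "fraction": r.fraction,
                    "is_major": r.is_major,
                    "tie": r.tie,
                    "G": r.G,
                }
                for r in self.rows
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MajorCodonTable":
        df = pd.read_csv(path, sep="\t")
        rows = [
            MajorCodonRow(
                amino_acid=t.amino_acid,
                codon=t.codon,
                count=int(t.count),
                fraction=float(t.fraction),
                is_major=bool(t.is_major),
                tie=bool(t.tie),
                G=float(t.G),
            )
            for t in df.itertuples()
        ]
        return cls(rows, unobserved=set())


def g_test_heterogeneity(counts) -> tuple[float, int, float]:
    """G-test of synonymous-codon usage against equal usage within one family.

    G = 2 * sum O*ln(O/E) with E = total/k and the convention 0*ln(0) = 0;
    df = k - 1; p from the chi-square distribution.
    """
    counts = np.asarray(list(counts), dtype=float)
    k = counts.size
    if k < 2:
        raise ValueError("G-test requires >= 2 synonymous codons")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    total = counts.sum()
    if total < 1:
        raise ValueError("total count must be >= 1")
    expected = total / k
    obs = counts[counts > 0]
    G = 2.0 * float(np.sum(obs * np.log(obs / expected)))
    df = k - 1
    p = float(stats.chi2.sf(G, df))
    return G, df, p


def identify_major_codons(
    pooled: CodonCounts, code: GeneticCode = STANDARD_CODE
) -> MajorCodonTable:
    """Identify the major (most used) synonymous codon per amino acid.

    Ties are resolved to the lexicographically smallest codon and flagged.
    Amino acids with zero observations are reported in
    ``MajorCodonTable.unobserved`` rather than silently dropped.
    """
    if pooled.total() == 0:
        raise ValueError("empty codon counts")
    rows: list[MajorCodonRow] = []
    unobserved: set[str] = set()
    for aa, codons in sorted(code.aa_to_codons.items()):
        if len(codons) < 2:
            continue
        counts = [pooled.counts.get(c, 0) for c in codons]
        total = sum(counts)
        if total == 0:
            unobserved.add(aa)
            continue
        G, _, _ = g_test_heterogeneity(counts)
        top = max(counts)
        winners = [c for c, v in zip(codons, counts) if v == top]
        major = min(winners)  # lexicographic tie-break
        tie = len(winners) > 1
        for c, v in zip(codons, counts):
            rows.append(
                MajorCodonRow(
                    amino_acid=aa,
                    codon=c,
                    count=v,
                    fraction=v / total,
                    is_major=(c == major),
                    tie=tie and v == top,
                    G=G,
                )
            )
    return MajorCodonTable(rows, unobserved)


@dataclass
class CompositionRecord:
    """Base composition of a sequence set; GC3 only when frame-aware."""

    frac_a: float
    frac_t: float
    frac_c: float
    frac_g: float
    pct_gc: float
    gc3: float | None = None


def nucleotide_composition(sequences, frame_aware: bool = False) -> CompositionRecord:
    """Base fractions and %GC over one or more sequences; N and gaps excluded.

    With ``frame_aware`` each sequence must be an in-frame CDS (length
    divisible by 3) and GC3 — the fraction of third codon positions that are
    G or C — is also computed.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    sequences = [s.upper().replace("U", "T") for s in sequences]
    if not sequences or all(len(s) == 0 for s in sequences):
        raise ValueError("empty input")
    tallies = {b: 0 for b in "ACGT"}
    third = {b: 0 for b in "ACGT"}
    for s in sequences:
        if frame_aware and len(s) % 3:
            raise ValueError("frame-aware composition requires length divisible by 3")
        for i, b in enumerate(s):
            if b in tallies:
                tallies[b] += 1
                if frame_aware and i % 3 == 2:
                    third[b] += 1
    total = sum(tallies.values())
    if total == 0:
        raise ValueError("no unambiguous bases")
    gc3 = None
    if frame_aware:
        t3 = sum(third.values())
        gc3 = (third["G"] + third["C"]) / t3 if t3 else None
    return CompositionRecord(
        frac_a=tallies["A"] / total,
        frac_t=tallies["T"] / total,
        frac_c=tallies["C"] / total,
        frac_g=tallies["G"] / total,
        pct_gc=100.0 * (tallies["G"] + tallies["C"]) / total,
        gc3=gc3,
    )
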