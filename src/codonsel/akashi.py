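"""Akashi's translational-accuracy test.

Selection for translational accuracy predicts that major codons are enriched
at evolutionarily conserved amino-acid positions, where misincorporation is
most costly.  For each amino acid a 2x2 table is built from the counts of
major/minor codons at conserved/variable sites; the association is an odds
ratio (psi = ad/bc) and amino-acid strata are pooled with the
Mantel–Haenszel estimator, which tolerates sparse strata.

Conservation is classified at the amino-acid level per codon column:
conserved = ingroup monomorphic and equal to the outgroup amino acid;
variable = ingroup amino-acid polymorphic; monomorphic-but-divergent columns
are excluded.  A nucleotide-level mode is available behind a flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .codon_core import CODON_TABLE, ONEFOLD_AAS, MajorCodonTable
from .polymorphism import HaplotypeAlignment

_UNAMBIG = set("ACGT")


@dataclass
class ContingencyStratum:
    """One amino acid's 2x2 table: (a, c | b, d) = (major, minor) x (conserved, variable)."""

    amino_acid: str
    a: float  # major codons at conserved sites
    b: float  # major codons at variable sites
    c: float  # minor codons at conserved sites
    d: float  # minor codons at variable sites

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell counts")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d


def classify_codon_sites(
    aln: HaplotypeAlignment, level: str = "amino_acid"
) -> list[str]:
    """Label each codon column ``conserved`` / ``variable`` / ``excluded``.

    Requires the alignment's outgroup.  With ``level='nucleotide'`` a column
    is conserved only when all three codon positions are monomorphic and
    identical to the outgroup.
    """
    if aln.outgroup is None:
        raise ValueError("Akashi site classification requires an outgroup")
    labels = []
    for ci in range(aln.length // 3):
        codons = [aln.codon(i, ci) for i in range(aln.n)]
        called = [c for c in codons if c in CODON_TABLE]
        og_codon = aln.outgroup[3 * ci : 3 * ci + 3]
        if len(called) < 2 or og_codon not in CODON_TABLE:
            labels.append("excluded")
            continue
        if level == "nucleotide":
            states = set(called)
            if len(states) > 1:
                labels.append("variable")
            elif next(iter(states)) == og_codon:
                labels.append("conserved")
            else:
                labels.append("excluded")
            continue
        aas = {CODON_TABLE[c] for c in called}
        if len(aas) > 1:
            labels.append("variable")
        elif next(iter(aas)) == CODON_TABLE[og_codon]:
            labels.append("conserved")
        else:
            labels.append("excluded")
    return labels


def build_contingency(
    aln: HaplotypeAlignment,
    site_classes: list[str],
    majors: MajorCodonTable,
    per_haplotype: bool = True,
) -> list[ContingencyStratum]:
    """Tally major/minor codons into per-amino-acid strata.

    By default every haplotype's codon at a classified column is counted
    (sample size weights the strata); with ``per_haplotype=False`` each
    column contributes its majority codon once.
    """
    cells: dict[str, list[float]] = {}
    for ci, label in enumerate(site_classes):
        if label == "excluded":
            continue
        codons = [aln.codon(i, ci) for i in range(aln.n)]
        called = [c for c in codons if c in CODON_TABLE]
        if not per_haplotype:
            called = [Counter(called).most_common(1)[0][0]]
        for codon in called:
            aa = CODON_TABLE[codon]
            if aa in ONEFOLD_AAS or not majors.has_major(aa):
                continue
            cell = cells.setdefault(aa, [0.0, 0.0, 0.0, 0.0])
            is_major = majors.is_major(codon)
            if label == "conserved":
                cell[0 if is_major else 2] += 1
            else:
                cell[1 if is_major else 3] += 1
    return [
        ContingencyStratum(aa, a=v[0], b=v[1], c=v[2], d=v[3])
        for aa, v in sorted(cells.items())
    ]


def psi(stratum: ContingencyStratum, haldane: bool = False) -> float:
    """Odds ratio psi = ad/bc; NaN when bc = 0 unless the Haldane–Anscombe
    +0.5 correction is enabled."""
    a, b, c, d = stratum.a, stratum.b, stratum.c, stratum.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        return float("nan")
    return (a * d) / (b * c)


def mh_combine(strata: list[ContingencyStratum]) -> float:
    """Mantel–Haenszel pooled odds ratio: sum(ad/n) / sum(bc/n).

    Strata with zero total are skipped; NaN when the denominator vanishes.
    """
    num = 0.0
    den = 0.0
    for s in strata:
        if s.total == 0:
            continue
        num += s.a * s.d / s.total
        den += s.b * s.c / s.total
    if den == 0.0:
        return float("nan")
    return num / den


def akashi_table(
    alignments: list[HaplotypeAlignment],
    majors: MajorCodonTable,
    level: str = "amino_acid",
    per_haplotype: bool = True,
) -> pd.DataFrame:
    """Per-gene psi_MH plus long-format strata for a set of alignments."""
    rows = []
    for aln in alignments:
        strata = build_contingency(
            aln, classify_codon_sites(aln, level=level), majors,
            per_haplotype=per_haplotype,
        )
        pooled = mh_combine(strata)
        for s in strata:
            rows.append(
                dict(
                    gene_id=aln.gene_id,
                    amino_acid=s.amino_acid,
                    a=s.a, b=s.b, c=s.c, d=s.d,
                    psi=psi(s),
                    psi_mh=pooled,
                )
            )
    return pd.DataFrame(rows)
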