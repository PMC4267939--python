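"""Site counting, diversity statistics, mutation classification and the SFS.

Synonymous and nonsynonymous site numbers follow the Nei–Gojobori counting:
each codon position contributes (number of synonymous single-base changes)/3
synonymous sites, mutations to stop codons counting as nonsynonymous, so the
two totals sum to exactly 3 per codon.

Polymorphic sites are polarized with a single outgroup sequence (ancestral =
the outgroup allele when it matches one of the two segregating alleles) and
classified as synonymous/nonsynonymous, preferred/unpreferred (minor->major /
major->minor codon changes), transition/transversion, and by GC->AT mutation
direction.  The site frequency spectrum counts sites by the number of
haplotypes carrying the focal (major- or minor-codon) state, with monomorphic
eligible sites entering the terminal classes.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_core import (
    CODON_TABLE,
    ONEFOLD_AAS,
    STANDARD_CODE,
    GeneticCode,
    MajorCodonTable,
)

_VALID = set("ACGTN-")
_UNAMBIG = set("ACGT")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_GC = set("GC")


@dataclass
class HaplotypeAlignment:
    """In-frame CDS alignment of n ingroup haplotypes plus optional outgroup."""

    gene_id: str
    sequences: list[str]
    haplotype_ids: list[str] = field(default_factory=list)
    arrangement: str = "NA"
    outgroup: str | None = None
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("alignment needs n >= 2 ingroup haplotypes")
        L = len(self.sequences[0])
        if L % 3:
            raise ValueError("alignment length not divisible by 3")
        seqs = [s.upper().replace("U", "T") for s in self.sequences]
        for s in seqs:
            if len(s) != L:
                raise ValueError("sequences have unequal lengths")
            if set(s) - _VALID:
                raise ValueError(f"invalid characters: {sorted(set(s) - _VALID)}")
        self.sequences = seqs
        if self.outgroup is not None:
            og = self.outgroup.upper().replace("U", "T")
            if len(og) != L:
                raise ValueError("outgroup length differs from alignment")
            self.outgroup = og
        if not self.haplotype_ids:
            self.haplotype_ids = [f"hap{i}" for i in range(len(seqs))]

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def codon(self, seq_index: int, codon_index: int) -> str:
        s = self.sequences[seq_index]
        return s[3 * codon_index : 3 * codon_index + 3]

    def column(self, pos: int) -> list[str]:
        return [s[pos] for s in self.sequences]


def count_sites(
    seq: str, code: GeneticCode = STANDARD_CODE
) -> tuple[float, float]:
    """Nei–Gojobori fractional synonymous / nonsynonymous site counts.

    ``seq`` may be a single codon or a full in-frame CDS; codons containing
    N or gaps are skipped, as are stop codons (with a warning for internal
    premature stops handled by the caller).
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError("length not divisible by 3")
    syn = 0.0
    nonsyn = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        s, n = _codon_sites(codon, code)
        syn += s
        nonsyn += n
    return syn, nonsyn


def _codon_sites(codon: str, code: GeneticCode = STANDARD_CODE) -> tuple[float, float]:
    if codon not in CODON_TABLE:
        return 0.0, 0.0  # ambiguous or stop codon: skipped
    aa = CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        s_changes = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TABLE.get(mutant) == aa:  # stops drop out (nonsynonymous)
                s_changes += 1
        syn += s_changes / 3.0
    return syn, 3.0 - syn


def _pairwise_syn_diffs(
    aln: HaplotypeAlignment, i: int, j: int, code: GeneticCode = STANDARD_CODE
) -> tuple[float, float]:
    """(synonymous differences, mean synonymous sites) for one sequence pair.

    Codons with ambiguity in either sequence are skipped; a differing
    position is synonymous when the one-step change preserves the amino acid
    in both codon contexts.
    """
    a, b = aln.sequences[i], aln.sequences[j]
    diffs = 0.0
    sites_a = 0.0
    sites_b = 0.0
    for c0 in range(0, aln.length, 3):
        ca, cb = a[c0 : c0 + 3], b[c0 : c0 + 3]
        if ca not in CODON_TABLE or cb not in CODON_TABLE:
            continue
        sa, _ = _codon_sites(ca, code)
        sb, _ = _codon_sites(cb, code)
        sites_a += sa
        sites_b += sb
        for pos in range(3):
            if ca[pos] == cb[pos]:
                continue
            mut_a = ca[:pos] + cb[pos] + ca[pos + 1 :]
            mut_b = cb[:pos] + ca[pos] + cb[pos + 1 :]
            if (
                CODON_TABLE.get(mut_a) == CODON_TABLE[ca]
                and CODON_TABLE.get(mut_b) == CODON_TABLE[cb]
            ):
                diffs += 1.0
    return diffs, 0.5 * (sites_a + sites_b)


def pi_synonymous(aln: HaplotypeAlignment) -> float:
    """Nucleotide diversity at synonymous sites (mean pairwise differences
    per synonymous site over all haplotype pairs).

    The mean over all n(n-1)/2 pairs is the unbiased (n/(n-1)-corrected)
    estimator of heterozygosity.  Returns NaN when no synonymous sites are
    callable.
    """
    n = aln.n
    tot = 0.0
    denom = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            d, s = _pairwise_syn_diffs(aln, i, j)
            tot += d
            denom += s
            pairs += 1
    if denom == 0:
        return float("nan")
    return tot / (denom / pairs) / pairs


def watterson_theta(S: int, n: int, sites: float) -> float:
    """Watterson's per-site theta: S / (a_n * sites), a_n = sum_{i<n} 1/i."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if sites <= 0:
        raise ValueError("sites must be positive")
    a_n = sum(1.0 / i for i in range(1, n))
    return S / (a_n * sites)


def tajimas_d(
    S: int | None = None,
    pi_total: float | None = None,
    n: int | None = None,
    aln: HaplotypeAlignment | None = None,
) -> float:
    """Tajima's D from (S, mean pairwise differences, n), or from an alignment.

    ``pi_total`` is the mean number of pairwise differences (a count, not per
    site).  Returns NaN when S = 0.
    """
    if aln is not None:
        n = aln.n
        S = 0
        tot = 0.0
        npairs = n * (n - 1) // 2
        for pos in range(aln.length):
            col = [c for c in aln.column(pos) if c in _UNAMBIG]
            if len(col) < 2:
                continue
            cnt = Counter(col)
            if len(cnt) > 1:
                S += 1
            # pairwise differences at this column among called haplotypes,
            # rescaled to the full pair count
            m = len(col)
            same = sum(v * (v - 1) // 2 for v in cnt.values())
            dpairs = m * (m - 1) // 2 - same
            if m >= 2:
                tot += dpairs * npairs / (m * (m - 1) // 2)
        pi_total = tot / npairs
    if S is None or pi_total is None or n is None:
        raise ValueError("provide (S, pi_total, n) or aln")
    if S == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_total - S / a1) / math.sqrt(var)


@dataclass
class SiteClass:
    """Classification of one biallelic polymorphic site."""

    column: int
    codon_index: int
    codon_pos: int
    alleles: tuple[str, str]
    derived_count: int | None  # None when unpolarized
    synonymous: bool | None
    preference: str  # preferred|unpreferred|unpolarized|not-applicable
    transition: bool | None
    direction: str  # GC->AT | AT->GC | GC-conservative
    amino_acid: str | None = None
    excluded: str | None = None  # reason code when the site is unusable


def _codon_context(
    aln: HaplotypeAlignment, pos: int
) -> tuple[int, int, dict[str, str]] | None:
    """Map each segregating allele at ``pos`` to its codon, requiring the two
    flanking positions of the codon to be monomorphic among called haplotypes.
    Returns (codon_index, within-codon position, allele->codon) or None."""
    ci, cp = divmod(pos, 3)
    flank_pos = [3 * ci + k for k in range(3) if k != cp]
    flanks = []
    for fp in flank_pos:
        col = {c for c in aln.column(fp) if c in _UNAMBIG}
        if len(col) != 1:
            return None
        flanks.append(col.pop())
    alleles = {c for c in aln.column(pos) if c in _UNAMBIG}
    mapping = {}
    for al in alleles:
        codon = ["", "", ""]
        codon[cp] = al
        for fp, fb in zip(flank_pos, flanks):
            codon[fp - 3 * ci] = fb
        mapping[al] = "".join(codon)
    return ci, cp, mapping


def classify_mutation(
    aln: HaplotypeAlignment,
    pos: int,
    majors: MajorCodonTable | None = None,
) -> SiteClass:
    """Classify the biallelic site at alignment column ``pos``.

    Polarization uses the outgroup allele when it matches one segregating
    allele.  Preferred/unpreferred is assigned only to synonymous, polarized
    sites where one codon is the major and the other a minor codon.
    """
    col = [c for c in aln.column(pos) if c in _UNAMBIG]
    counts = Counter(col)
    ci, cp = divmod(pos, 3)
    base = dict(
        column=pos, codon_index=ci, codon_pos=cp, alleles=("N", "N"),
        derived_count=None, synonymous=None, preference="not-applicable",
        transition=None, direction="GC-conservative",
    )
    if len(counts) != 2:
        reason = "monomorphic" if len(counts) < 2 else "multiallelic"
        return SiteClass(**base, excluded=reason)
    ctx = _codon_context(aln, pos)
    if ctx is None:
        return SiteClass(**base, excluded="complex_codon")
    ci, cp, allele_codon = ctx
    (a1, n1), (a2, n2) = counts.most_common(2)
    base["alleles"] = (a1, a2)
    c1, c2 = allele_codon[a1], allele_codon[a2]
    if c1 not in CODON_TABLE or c2 not in CODON_TABLE:
        return SiteClass(**base, excluded="stop_codon")
    synonymous = CODON_TABLE[c1] == CODON_TABLE[c2]
    base["synonymous"] = synonymous
    base["amino_acid"] = CODON_TABLE[c1] if synonymous else None
    base["transition"] = (a1, a2) in _TRANSITIONS

    anc = None
    if aln.outgroup is not None:
        og = aln.outgroup[pos]
        if og in (a1, a2):
            anc = og
    if anc is None:
        base["preference"] = "unpolarized"
        return SiteClass(**base)
    der = a2 if anc == a1 else a1
    base["derived_count"] = counts[der]
    if anc in _GC and der not in _GC:
        base["direction"] = "GC->AT"
    elif anc not in _GC and der in _GC:
        base["direction"] = "AT->GC"
    anc_codon, der_codon = allele_codon[anc], allele_codon[der]
    if synonymous and majors is not None:
        if majors.is_major(der_codon) and majors.is_minor(anc_codon):
            base["preference"] = "preferred"
        elif majors.is_minor(der_codon) and majors.is_major(anc_codon):
            base["preference"] = "unpreferred"
    return SiteClass(**base)


def scan_alignment(
    aln: HaplotypeAlignment, majors: MajorCodonTable | None = None
) -> list[SiteClass]:
    """Classify every alignment column; monomorphic columns are skipped."""
    out = []
    for pos in range(aln.length):
        col = {c for c in aln.column(pos) if c in _UNAMBIG}
        if len(col) < 2:
            continue
        out.append(classify_mutation(aln, pos, majors))
    return out


def diversity_stats(aln: HaplotypeAlignment) -> dict:
    """Per-gene summary: NG site counts, S, pi_S, Watterson theta, Tajima's D."""
    syn_sites = np.mean([count_sites(s)[0] for s in aln.sequences])
    nonsyn_sites = np.mean([count_sites(s)[1] for s in aln.sequences])
    classes = scan_alignment(aln)
    usable = [c for c in classes if c.excluded is None]
    S_syn = sum(1 for c in usable if c.synonymous)
    S_non = sum(1 for c in usable if c.synonymous is False)
    pis = pi_synonymous(aln)
    theta_syn = watterson_theta(S_syn, aln.n, syn_sites) if syn_sites else float("nan")
    theta_non = (
        watterson_theta(S_non, aln.n, nonsyn_sites) if nonsyn_sites else float("nan")
    )
    return dict(
        gene_id=aln.gene_id,
        arrangement=aln.arrangement,
        n=aln.n,
        syn_sites=float(syn_sites),
        nonsyn_sites=float(nonsyn_sites),
        S_syn=S_syn,
        S_nonsyn=S_non,
        pi_syn=pis,
        theta_w_syn=theta_syn,
        theta_w_nonsyn=theta_non,
        tajimas_d=tajimas_d(aln=aln),
    )


def per_aa_rates(
    alignments: list[HaplotypeAlignment],
    majors: MajorCodonTable | None = None,
    transitions_only: bool = False,
) -> pd.DataFrame:
    """Per-amino-acid synonymous/nonsynonymous Watterson theta, pooled over genes.

    Synonymous (nonsynonymous) segregating sites and Nei–Gojobori site
    denominators are partitioned by the amino acid of the ancestral codon
    when polarized, else of the majority-allele codon.  Met, Trp and stop
    codons are excluded.  With ``transitions_only`` the numerators count only
    third-codon-position transitions.
    """
    n = alignments[0].n
    if any(a.n != n for a in alignments):
        raise ValueError("alignments have differing sample sizes")
    syn_sites: Counter = Counter()
    non_sites: Counter = Counter()
    S_syn: Counter = Counter()
    S_non: Counter = Counter()
    for aln in alignments:
        for ci in range(aln.length // 3):
            per_hap = [aln.codon(i, ci) for i in range(aln.n)]
            valid = [c for c in per_hap if c in CODON_TABLE]
            if not valid:
                continue
            ref = Counter(valid).most_common(1)[0][0]
            aa = CODON_TABLE[ref]
            if aa in ONEFOLD_AAS:
                continue
            s, ns = _codon_sites(ref)
            syn_sites[aa] += s
            non_sites[aa] += ns
        for site in scan_alignment(aln, majors):
            if site.excluded is not None or site.synonymous is None:
                continue
            if transitions_only and not (site.transition and site.codon_pos == 2):
                continue
            codons = _site_codons(aln, site)
            if codons is None:
                continue
            aa_anc = CODON_TABLE.get(codons[0])
            if aa_anc is None or aa_anc in ONEFOLD_AAS:
                continue
            if site.synonymous:
                S_syn[aa_anc] += 1
            else:
                S_non[aa_anc] += 1
    rows = []
    for aa in sorted(syn_sites):
        rows.append(
            dict(
                amino_acid=aa,
                syn_sites=syn_sites[aa],
                nonsyn_sites=non_sites[aa],
                S_syn=S_syn[aa],
                S_nonsyn=S_non[aa],
                theta_syn=(
                    watterson_theta(S_syn[aa], n, syn_sites[aa])
                    if syn_sites[aa] > 0
                    else float("nan")
                ),
                theta_nonsyn=(
                    watterson_theta(S_non[aa], n, non_sites[aa])
                    if non_sites[aa] > 0
                    else float("nan")
                ),
            )
        )
    return pd.DataFrame(rows)


def _site_codons(aln: HaplotypeAlignment, site: SiteClass) -> tuple[str, str] | None:
    """(ancestral-or-majority codon, other codon) for a classified site."""
    ctx = _codon_context(aln, site.column)
    if ctx is None:
        return None
    _, _, mapping = ctx
    a1, a2 = site.alleles
    if site.derived_count is not None:
        col = [c for c in aln.column(site.column) if c in _UNAMBIG]
        counts = Counter(col)
        der = a1 if counts[a1] == site.derived_count else a2
        anc = a2 if der == a1 else a1
        return mapping[anc], mapping[der]
    return mapping[a1], mapping[a2]


def directional_theta(
    alignments: list[HaplotypeAlignment],
    transitions_only: bool = True,
    third_position_only: bool = True,
) -> dict:
    """Polarized mutation-rate contrast: theta(GC->AT) vs theta(AT->GC).

    Numerators are polarized segregating sites in each direction; the
    denominators are the counts of (third-codon-position) sites whose
    ancestral base is G/C, resp. A/T.  Unpolarized sites are excluded.
    """
    n = alignments[0].n
    S_dir = Counter()
    sites_gc = 0
    sites_at = 0
    for aln in alignments:
        og = aln.outgroup
        for pos in range(aln.length):
            if third_position_only and pos % 3 != 2:
                continue
            col = [c for c in aln.column(pos) if c in _UNAMBIG]
            if len(col) < 2:
                continue
            counts = Counter(col)
            if len(counts) == 1:
                anc = next(iter(counts))
                if og is not None and og[pos] in _UNAMBIG and og[pos] != anc:
                    continue  # apparent fixed difference: ancestral state unclear
            else:
                if len(counts) != 2:
                    continue
                if og is None or og[pos] not in counts:
                    continue
                anc = og[pos]
                der = next(a for a in counts if a != anc)
                if transitions_only and (anc, der) not in _TRANSITIONS:
                    # still counts toward the ancestral-site denominator
                    pass
                else:
                    if anc in _GC and der not in _GC:
                        S_dir["GC->AT"] += 1
                    elif anc not in _GC and der in _GC:
                        S_dir["AT->GC"] += 1
            if anc in _GC:
                sites_gc += 1
            else:
                sites_at += 1
    th_gc_at = (
        watterson_theta(S_dir["GC->AT"], n, sites_gc) if sites_gc else float("nan")
    )
    th_at_gc = (
        watterson_theta(S_dir["AT->GC"], n, sites_at) if sites_at else float("nan")
    )
    ratio = th_gc_at / th_at_gc if th_at_gc and not math.isnan(th_at_gc) else float("nan")
    return dict(
        S_gc_to_at=S_dir["GC->AT"],
        S_at_to_gc=S_dir["AT->GC"],
        sites_gc=sites_gc,
        sites_at=sites_at,
        theta_gc_to_at=th_gc_at,
        theta_at_to_gc=th_at_gc,
        ratio=ratio,
    )


@dataclass
class SFSpectrum:
    """Counts c_0..c_n of sites by number of haplotypes with the focal state."""

    n: int
    counts: np.ndarray
    focal: str = "major"
    excluded: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n + 1,):
            raise ValueError("counts must have length n+1")
        if np.any(self.counts < 0):
            raise ValueError("negative SFS counts")

    @property
    def total_sites(self) -> float:
        return float(self.counts.sum())

    def mirrored(self) -> "SFSpectrum":
        return SFSpectrum(
            n=self.n,
            counts=self.counts[::-1].copy(),
            focal="minor" if self.focal == "major" else "major",
            excluded=dict(self.excluded),
        )

    def project(self, m: int, rng=None) -> "SFSpectrum":
        """Hypergeometric projection of the spectrum down to sample size m."""
        if m > self.n:
            raise ValueError("cannot project upward")
        from scipy.stats import hypergeom

        out = np.zeros(m + 1)
        for i, c in enumerate(self.counts):
            if c == 0:
                continue
            j = np.arange(m + 1)
            out += c * hypergeom.pmf(j, self.n, i, m)
        return SFSpectrum(n=m, counts=out, focal=self.focal, excluded=dict(self.excluded))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"i": np.arange(self.n + 1), "count": self.counts}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, focal: str = "major") -> "SFSpectrum":
        df = pd.read_csv(path, sep="\t")
        return cls(n=len(df) - 1, counts=df["count"].to_numpy(), focal=focal)


def build_sfs(
    alignments: list[HaplotypeAlignment],
    majors: MajorCodonTable,
    focal: str = "major",
) -> SFSpectrum:
    """Site frequency spectrum of major/minor codon states, pooled over genes.

    A codon column enters the spectrum when its amino acid has a defined
    major codon and the column is either monomorphic (class 0 or n) or
    segregates exactly one major and one minor codon differing at a single
    nucleotide position.  Columns with missing data, more than two codon
    states, minor/minor segregation or amino-acid change are excluded, with
    per-reason counts recorded.
    """
    if focal not in ("major", "minor"):
        raise ValueError("focal must be 'major' or 'minor'")
    n = alignments[0].n
    if any(a.n != n for a in alignments):
        raise ValueError(
            "alignments have differing sample sizes; project spectra to a "
            "common n first"
        )
    counts = np.zeros(n + 1)
    excluded: Counter = Counter()
    for aln in alignments:
        for ci in range(aln.length // 3):
            per_hap = [aln.codon(i, ci) for i in range(aln.n)]
            if any(c not in CODON_TABLE for c in per_hap):
                excluded["missing_or_stop"] += 1
                continue
            states = Counter(per_hap)
            if len(states) == 1:
                codon = next(iter(states))
                aa = CODON_TABLE[codon]
                if not majors.has_major(aa):
                    excluded["no_major_defined"] += 1
                    continue
                is_focal_state = majors.is_major(codon) == (focal == "major")
                counts[n if is_focal_state else 0] += 1
                continue
            if len(states) > 2:
                excluded["multiallelic"] += 1
                continue
            (c1, n1), (c2, n2) = states.most_common(2)
            if CODON_TABLE[c1] != CODON_TABLE[c2]:
                excluded["nonsynonymous"] += 1
                continue
            if sum(x != y for x, y in zip(c1, c2)) != 1:
                excluded["multi_step"] += 1
                continue
            pair = {c1, c2}
            majority = [c for c in pair if majors.is_major(c)]
            minority = [c for c in pair if majors.is_minor(c)]
            if len(majority) != 1 or len(minority) != 1:
                excluded["minor_minor"] += 1
                continue
            focal_codon = majority[0] if focal == "major" else minority[0]
            counts[states[focal_codon]] += 1
    return SFSpectrum(n=n, counts=counts, focal=focal, excluded=dict(excluded))
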