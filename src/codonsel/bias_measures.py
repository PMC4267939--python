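"""Gene-level codon-usage-bias statistics: ENC, Fop, CAI.

ENC (effective number of codons) is nondirectional and ranges from 20 (a
single codon used per amino acid) to 61 (uniform synonymous usage).  Fop is
the fraction of codons that are the major codon of their amino acid, among
codons of amino acids that have a major codon.  CAI is the geometric mean of
relative-adaptiveness weights taken from a reference codon-usage set.

An amino-acid-composition randomization test is also provided: it resamples
each codon uniformly among its synonymous alternatives (preserving the
amino-acid sequence, destroying any codon preference) and asks how often the
randomized gene is at least as biased (ENC at least as low) as the observed
gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .codon_core import (
    AA_TO_CODONS,
    DEGENERACY,
    ONEFOLD_AAS,
    CodonCounts,
    MajorCodonTable,
)

# degeneracy class -> number of amino acids in that class (standard code)
_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass
class BiasScores:
    gene_id: str
    enc: float
    fop: float
    cai: float
    comp_p: float | None = None
    comp_flag: bool | None = None


def _family_homozygosity(counts: dict[str, int]) -> tuple[float, int] | None:
    """Codon homozygosity F-hat = (n*sum p^2 - 1)/(n - 1) for one family."""
    n = sum(counts.values())
    if n < 2:
        return None
    p = np.array([v / n for v in counts.values()])
    f = (n * float(np.sum(p * p)) - 1.0) / (n - 1.0)
    return f, n


def enc(gene: CodonCounts) -> float:
    """Wright's effective number of codons, capped to [20, 61].

    Per-family homozygosities are averaged within each degeneracy class
    (2, 3, 4, 6).  A missing threefold class is imputed as the mean of the
    two- and fourfold class averages; a wholly missing 2/4/6 class drops its
    term and the result is rescaled so uniform usage still maps to 61.
    """
    fbar: dict[int, float] = {}
    for k in (2, 3, 4, 6):
        fs = []
        for aa, codons in AA_TO_CODONS.items():
            if DEGENERACY[aa] != k:
                continue
            res = _family_homozygosity(gene.aa_counts(aa))
            if res is not None and res[0] > 1e-12:
                fs.append(res[0])
        if fs:
            fbar[k] = float(np.mean(fs))
    if not fbar:
        raise ValueError("ENC undefined: no amino acid with >= 2 observed codons")
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = 0.5 * (fbar[2] + fbar[4])
    partial = sum(_CLASS_SIZES[k] / fbar[k] for k in fbar)
    max_partial = sum(_CLASS_SIZES[k] * k for k in fbar)
    if max_partial == 0:
        raise ValueError("ENC undefined")
    # rescale so uniform usage over the available classes still gives 61
    value = 2.0 + partial * (61.0 - 2.0) / max_partial
    return float(min(61.0, max(20.0, value)))


def fop(gene: CodonCounts, majors: MajorCodonTable) -> float:
    """Frequency of optimal codons; NaN when no eligible codon is present."""
    major = 0
    eligible = 0
    for codon, v in gene.counts.items():
        aa = _aa_of(codon)
        if not majors.has_major(aa):
            continue
        eligible += v
        if majors.major_for(aa) == codon:
            major += v
    if eligible == 0:
        return float("nan")
    return major / eligible


def _aa_of(codon: str) -> str:
    from .codon_core import CODON_TABLE

    return CODON_TABLE[codon]


def cai_weights(reference: CodonCounts, floor: float = 0.01) -> dict[str, float]:
    """Relative adaptiveness w_c = f_c / max f within each amino acid family.

    Codons unobserved in the reference get the floored weight.
    """
    if reference.total() == 0:
        raise ValueError("empty reference counts")
    weights: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        if len(codons) < 2:
            continue
        counts = {c: reference.counts.get(c, 0) for c in codons}
        top = max(counts.values())
        for c, v in counts.items():
            weights[c] = max(v / top, floor) if top > 0 else 1.0
    return weights


def cai(gene: CodonCounts, reference: CodonCounts, floor: float = 0.01) -> float:
    """Codon adaptation index: geometric mean of weights over the gene's codons.

    Met, Trp (and stops, which never appear in counts) are excluded.
    """
    w = cai_weights(reference, floor=floor)
    log_sum = 0.0
    n = 0
    for codon, v in gene.counts.items():
        if _aa_of(codon) in ONEFOLD_AAS:
            continue
        log_sum += v * math.log(w[codon])
        n += v
    if n == 0:
        return float("nan")
    return math.exp(log_sum / n)


def reference_from_top_fop(
    genes: list[CodonCounts], majors: MajorCodonTable, quantile: float = 0.9
) -> CodonCounts:
    """Default CAI reference: pooled counts of the top-decile Fop genes."""
    scored = [(fop(g, majors), g) for g in genes]
    scored = [(s, g) for s, g in scored if not math.isnan(s)]
    if not scored:
        raise ValueError("no genes with defined Fop")
    cutoff = float(np.quantile([s for s, _ in scored], quantile))
    pooled = CodonCounts(gene_id="reference")
    for s, g in scored:
        if s >= cutoff:
            pooled = pooled + g
    return pooled


def aa_composition_randomization(
    gene: CodonCounts,
    replicates: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Randomization test for the effect of amino-acid composition on ENC.

    Each replicate redistributes the gene's codons uniformly among the
    synonymous codons of their amino acid.  Returns ``(p, flagged)`` where
    ``p`` is the fraction of replicates at least as biased as observed
    (ENC_replicate <= ENC_observed) and ``flagged`` is True when p > alpha,
    i.e. the observed bias is explainable by amino-acid composition alone and
    the gene should be excluded from selection-on-codon-usage analyses.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    try:
        observed = enc(gene)
    except ValueError:
        # only onefold amino acids: every replicate is identical to the
        # observed gene, so composition fully explains the (absent) bias
        return 1.0, True
    aa_totals = {
        aa: sum(gene.aa_counts(aa).values())
        for aa in AA_TO_CODONS
        if sum(gene.aa_counts(aa).values()) > 0
    }
    hits = 0
    for _ in range(replicates):
        rep_counts: dict[str, int] = {}
        for aa, n_aa in aa_totals.items():
            codons = AA_TO_CODONS[aa]
            k = len(codons)
            if k == 1:
                rep_counts[codons[0]] = n_aa
                continue
            draw = rng.multinomial(n_aa, np.full(k, 1.0 / k))
            for c, v in zip(codons, draw):
                if v:
                    rep_counts[c] = int(v)
        try:
            rep_enc = enc(CodonCounts(gene_id="rep", counts=rep_counts))
        except ValueError:
            rep_enc = observed  # degenerate gene: replicate identical to observed
        if rep_enc <= observed + 1e-12:
            hits += 1
    p = hits / replicates
    return p, p > alpha
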