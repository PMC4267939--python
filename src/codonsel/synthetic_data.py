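"""Synthetic haplotype datasets with the statistical structure the analysis
assumes: GC-ending favoured codons against an AT-biased mutation process,
weak selection on synonymous sites, an optional one-step population
expansion, five chromosome-arrangement labels, and a close outgroup.

Sites are unlinked.  For each synonymous codon column the count of
haplotypes carrying the favoured (GC-ending) codon is drawn from the model's
expected sample SFS at size n+1; the extra lineage plays the outgroup, so
polarization against the outgroup has the correct joint distribution, and
additional outgroup-lineage substitutions are applied at the configured
divergence.  The generator's defaults follow the study design: 47 haplotypes
over five arrangements, theta ~ 0.005/site, mutational bias kappa toward
AT-ending codons of ~2.2, selection gamma ~ 0.8 on preferred codons, and a
recent one-step expansion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_core import AA_TO_CODONS, CODON_TABLE, ONEFOLD_AAS
from .polymorphism import HaplotypeAlignment
from .sfs_selection import SelectionParams, expected_sfs

# favoured (GC-ending) codon and its one-step AT-ending partner per amino acid
PREFERRED_PAIR: dict[str, tuple[str, str]] = {}
for _aa, _codons in AA_TO_CODONS.items():
    if len(_codons) < 2:
        continue
    gc_ending = [c for c in _codons if c[2] in "GC"]
    at_ending = [c for c in _codons if c[2] in "AT"]
    pref = min(gc_ending) if gc_ending else min(_codons)
    partners = [c for c in at_ending if sum(a != b for a, b in zip(c, pref)) == 1]
    if not partners:
        partners = [c for c in _codons if c != pref and sum(a != b for a, b in zip(c, pref)) == 1]
    PREFERRED_PAIR[_aa] = (pref, min(partners))


@dataclass
class SimConfig:
    """Study-shaped simulation settings (defaults follow the study design)."""

    n_genes: int = 100
    codons_per_gene: int = 300
    arrangements: tuple = ("AR", "ST", "PP", "TL", "CH")
    n_haplotypes: tuple = (15, 8, 9, 8, 7)
    params: SelectionParams = field(
        default_factory=lambda: SelectionParams(
            theta01=0.005, theta10=0.005 * 2.23, gamma=0.788, g=3.70, tau=0.026
        )
    )
    gamma_by_class: tuple | None = None  # per-gene-class gamma overrides
    theta_nonsyn_factor: float = 0.15
    #: translational-accuracy selection: fraction by which gamma is reduced
    #: at amino-acid-variable columns (0 = none; >0 makes major codons
    #: preferentially retained at conserved positions, as Akashi's test
    #: detects)
    accuracy_selection: float = 0.5
    outgroup_divergence: float = 0.03
    #: per-haplotype rate of replacing a codon with a uniform synonymous
    #: alternative.  Non-zero values scatter usage over all codons of a
    #: family (useful for exercising multi-state exclusion paths) but inject
    #: spurious singleton polymorphism, so the default keeps sites strictly
    #: two-state as the SFS model assumes.
    background_codon_noise: float = 0.0
    chrom_length: int = 20_000_000
    breakpoints: tuple = (2_496_966, 17_725_256)
    rho_mean: float = 0.052
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.codons_per_gene < 1:
            raise ValueError("sizes must be >= 1")
        if not 0.0 <= self.outgroup_divergence <= 0.2:
            raise ValueError("outgroup divergence must be in [0, 0.2]")
        if len(self.arrangements) != len(self.n_haplotypes):
            raise ValueError("arrangement labels and sample sizes differ in length")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def n_total(self) -> int:
        return int(sum(self.n_haplotypes))


def simulate_sfs(
    params: SelectionParams,
    n: int,
    n_sites: int | None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "sample",
) -> np.ndarray:
    """Draw an SFS of ``n_sites`` unlinked sites from the model.

    ``mode='expected'`` returns real-valued expected counts instead of a
    multinomial draw.
    """
    p = expected_sfs(params, n)
    if mode == "expected":
        if n_sites is None:
            return p.copy()
        return p * n_sites
    if n_sites is None or n_sites < 1:
        raise ValueError("n_sites must be >= 1 in sample mode")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.multinomial(int(n_sites), p).astype(float)


_AA_POOL = sorted(set(AA_TO_CODONS) - ONEFOLD_AAS)


def _site_params(base: SelectionParams, gamma: float) -> SelectionParams:
    return SelectionParams(
        theta01=base.theta01, theta10=base.theta10, gamma=gamma,
        g=base.g, tau=base.tau,
    )


def simulate_alignment(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[HaplotypeAlignment]:
    """Generate per-gene haplotype alignments (all arrangements pooled; ids
    are ``{arrangement}|strain{i}`` so arrangement subsets can be split off).

    Each gene belongs to a selection class (``gamma_by_class``); within a
    gene every synonymous column draws the favoured-codon count from the
    expected SFS at n+1, the extra lineage serving as the outgroup.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_total
    hap_ids = []
    for arr, n_arr in zip(cfg.arrangements, cfg.n_haplotypes):
        hap_ids += [f"{arr}|strain{len(hap_ids) + j}" for j in range(n_arr)]
    gammas = cfg.gamma_by_class or (cfg.params.gamma,)
    # cache expected SFS per distinct gamma (site draws are iid given class)
    sfs_cache = {
        gm: expected_sfs(_site_params(cfg.params, gm), n + 1) for gm in gammas
    }
    # at amino-acid-variable columns synonymous selection is weakened by the
    # accuracy factor (selection for translational accuracy acts mostly at
    # conserved positions)
    sfs_cache_var = {
        gm: expected_sfs(
            _site_params(cfg.params, gm * (1.0 - cfg.accuracy_selection)), n + 1
        )
        for gm in gammas
    }
    if cfg.theta_nonsyn_factor > 0:
        neutral_nonsyn = expected_sfs(
            SelectionParams(
                theta01=cfg.params.theta01 * cfg.theta_nonsyn_factor,
                theta10=cfg.params.theta10 * cfg.theta_nonsyn_factor,
                gamma=0.0, g=cfg.params.g, tau=cfg.params.tau,
            ),
            n + 1,
        )
    else:
        neutral_nonsyn = np.zeros(n + 2)
        neutral_nonsyn[0] = 1.0
    alignments = []
    for gi in range(cfg.n_genes):
        gamma = gammas[gi % len(gammas)]
        p_site = sfs_cache[gamma]
        p_site_var = sfs_cache_var[gamma]
        aas = rng.choice(_AA_POOL, size=cfg.codons_per_gene)
        hap_codons = np.empty((n, cfg.codons_per_gene), dtype="U3")
        out_codons = np.empty(cfg.codons_per_gene, dtype="U3")
        k_draw = rng.choice(p_site.size, size=cfg.codons_per_gene, p=p_site)
        k_non = rng.choice(
            neutral_nonsyn.size, size=cfg.codons_per_gene, p=neutral_nonsyn
        )
        for ci, aa in enumerate(aas):
            pref, unpref = PREFERRED_PAIR[aa]
            kn = k_non[ci]  # derived-amino-acid lineages among n+1
            aa_variable = 0 < kn <= n
            if aa_variable:
                k_tot = int(rng.choice(p_site_var.size, p=p_site_var))
            else:
                k_tot = k_draw[ci]  # favoured-state lineages among n+1
            lineages = np.zeros(n + 1, dtype=bool)
            lineages[rng.choice(n + 1, size=k_tot, replace=False)] = True
            ingroup = lineages[:n]
            out_is_pref = bool(lineages[n])
            if rng.random() < cfg.outgroup_divergence:
                out_is_pref = not out_is_pref
            codons = np.where(ingroup, pref, unpref)
            # sparse background usage of other synonymous codons
            if cfg.background_codon_noise > 0:
                mask = rng.random(n) < cfg.background_codon_noise
                if mask.any():
                    others = AA_TO_CODONS[aa]
                    codons[mask] = rng.choice(others, size=int(mask.sum()))
            # occasional amino-acid polymorphism (derived aa on kn lineages);
            # the derived amino acid's synonymous state is drawn at the same
            # favoured-codon frequency as the column, so amino-acid
            # polymorphism itself carries no major/minor signal
            if aa_variable:
                alt_aa = rng.choice(_AA_POOL)
                if alt_aa != aa:
                    alt_pair = PREFERRED_PAIR[alt_aa]
                    alt = alt_pair[0] if rng.random() < k_tot / (n + 1) else alt_pair[1]
                    idx = rng.choice(n, size=min(kn, n), replace=False)
                    codons[idx] = alt
            hap_codons[:, ci] = codons
            out_codons[ci] = pref if out_is_pref else unpref
        seqs = ["".join(hap_codons[i]) for i in range(n)]
        start = gi * (cfg.chrom_length // max(cfg.n_genes, 1))
        aln = HaplotypeAlignment(
            gene_id=f"gene{gi:04d}",
            sequences=seqs,
            haplotype_ids=list(hap_ids),
            arrangement="TO",
            outgroup="".join(out_codons),
            start=start,
            end=start + 3 * cfg.codons_per_gene,
        )
        alignments.append(aln)
    return alignments


def split_by_arrangement(aln: HaplotypeAlignment) -> dict[str, HaplotypeAlignment]:
    """Subset an alignment into per-arrangement alignments using the
    ``{arrangement}|{strain}`` id convention."""
    groups: dict[str, list[int]] = {}
    for i, hid in enumerate(aln.haplotype_ids):
        arr = hid.split("|", 1)[0]
        groups.setdefault(arr, []).append(i)
    out = {}
    for arr, idx in groups.items():
        if len(idx) < 2:
            continue
        out[arr] = HaplotypeAlignment(
            gene_id=aln.gene_id,
            sequences=[aln.sequences[i] for i in idx],
            haplotype_ids=[aln.haplotype_ids[i] for i in idx],
            arrangement=arr,
            outgroup=aln.outgroup,
            start=aln.start,
            end=aln.end,
        )
    return out


def simulate_annotations(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Sorted, non-overlapping gene intervals with long-tailed per-gene rho.

    rho is lognormal with mean ``cfg.rho_mean`` (the chromosome-wide average
    scaled recombination rate); region labels follow the outermost inversion
    breakpoints.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    pitch = cfg.chrom_length // max(cfg.n_genes, 1)
    glen = 3 * cfg.codons_per_gene
    rows = []
    sigma = 1.0
    mu = np.log(cfg.rho_mean) - sigma**2 / 2.0
    first, last = cfg.breakpoints[0], cfg.breakpoints[-1]
    for gi in range(cfg.n_genes):
        start = gi * pitch + int(rng.integers(0, max(pitch - glen, 1)))
        end = start + glen
        mid = (start + end) // 2
        region = "proximal" if mid < first else ("inverted" if mid <= last else "distal")
        rows.append(
            dict(
                gene_id=f"gene{gi:04d}",
                start=start,
                end=end,
                rho=float(rng.lognormal(mu, sigma)),
                region=region,
            )
        )
    return pd.DataFrame(rows)


def write_dataset(cfg: SimConfig, outdir: str | Path) -> Path:
    """Write FASTA alignments, GFF3/BED gene models, rho TSV and a manifest."""
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    alignments = simulate_alignment(cfg, rng)
    ann = simulate_annotations(cfg)
    coords = {r.gene_id: (r.start, r.end) for r in ann.itertuples()}
    for aln in alignments:
        aln.start, aln.end = coords[aln.gene_id]
        with open(outdir / "alignments" / f"{aln.gene_id}.fasta", "w") as fh:
            for hid, seq in zip(aln.haplotype_ids, aln.sequences):
                fh.write(f">{hid}\n{seq}\n")
            fh.write(f">outgroup|sister_species\n{aln.outgroup}\n")
    ann.drop(columns=["region"]).to_csv(outdir / "rho.tsv", sep="\t", index=False)
    with open(outdir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for r in ann.itertuples():
            fh.write(
                f"chr3\tcodonsel_sim\tCDS\t{r.start + 1}\t{r.end}\t.\t+\t0\t"
                f"ID={r.gene_id}\n"
            )
    ann[["gene_id", "start", "end"]].assign(chrom="chr3")[
        ["chrom", "start", "end", "gene_id"]
    ].to_csv(outdir / "genes.bed", sep="\t", index=False, header=False)
    manifest = asdict(cfg)
    manifest["params"] = asdict(cfg.params)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
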