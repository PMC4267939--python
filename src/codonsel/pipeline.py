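"""Orchestration: QC filters, chromosome-region assignment, covariate
binning, and the report tables that summarise a full analysis run.

Region labels follow the inversion-breakpoint geometry of the third
chromosome: proximal = before the first breakpoint interval, inverted =
within the span of the outermost breakpoints, distal = after the last.
Genes are assigned by their midpoint; genes overlapping a breakpoint
interval are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .akashi import akashi_table
from .bias_measures import (
    BiasScores,
    aa_composition_randomization,
    cai,
    enc,
    fop,
    reference_from_top_fop,
)
from .codon_core import (
    CodonCounts,
    identify_major_codons,
    nucleotide_composition,
)
from .io import read_alignment_dir, read_rho_table
from .polymorphism import (
    build_sfs,
    directional_theta,
    diversity_stats,
    per_aa_rates,
)
from .sfs_selection import fit_model, lrt
from .synthetic_data import split_by_arrangement

# QC thresholds follow the study defaults: SNP quality >= 30, per-site
# coverage >= 2, heterozygous calls dropped (isochromosomal strains), gene
# coverage above the 99% quantile excluded.
DEFAULT_QC = dict(
    min_quality=30.0,
    min_coverage=2,
    drop_heterozygous=True,
    coverage_quantile=0.99,
    composition_alpha=0.05,
)


def qc_filter(records: pd.DataFrame, thresholds: dict | None = None):
    """Filter a site-level record table on quality/coverage/genotype.

    ``records`` needs the columns a given filter uses: ``quality``,
    ``coverage``, ``genotype`` (value ``"het"`` marks heterozygous calls) and
    ``gene_id`` plus per-gene mean ``gene_coverage`` for the outlier rule.
    Returns (kept records, exclusion log with one row per dropped record).
    """
    th = dict(DEFAULT_QC)
    th.update(thresholds or {})
    df = records.copy()
    reasons = pd.Series([None] * len(df), index=df.index, dtype=object)
    if th.get("min_quality") is not None:
        if "quality" not in df.columns:
            raise ValueError("quality filter enabled but no 'quality' column")
        bad = df["quality"] < th["min_quality"]
        reasons[bad & reasons.isna()] = "low_quality"
    if th.get("min_coverage") is not None:
        if "coverage" not in df.columns:
            raise ValueError("coverage filter enabled but no 'coverage' column")
        bad = df["coverage"] < th["min_coverage"]
        reasons[bad & reasons.isna()] = "low_coverage"
    if th.get("drop_heterozygous"):
        if "genotype" not in df.columns:
            raise ValueError("heterozygote filter enabled but no 'genotype' column")
        bad = df["genotype"] == "het"
        reasons[bad & reasons.isna()] = "heterozygous"
    if th.get("coverage_quantile") is not None and "gene_coverage" in df.columns:
        per_gene = df.groupby("gene_id")["gene_coverage"].mean()
        cutoff = per_gene.quantile(th["coverage_quantile"])
        bad = df["gene_id"].map(per_gene) > cutoff
        reasons[bad & reasons.isna()] = "gene_coverage_outlier"
    dropped = reasons.notna()
    log = df[dropped].assign(reason=reasons[dropped])
    return df[~dropped], log


@dataclass
class RegionConfig:
    """Breakpoint intervals on the reference coordinate system."""

    breakpoints: list[tuple[str, int, int]] = field(
        default_factory=lambda: [
            ("first", 2_496_966, 2_502_362),
            ("last", 17_722_064, 17_725_256),
        ]
    )
    chrom_length: int = 20_000_000

    def __post_init__(self) -> None:
        bps = sorted(self.breakpoints, key=lambda b: b[1])
        for _, s, e in bps:
            if not (0 <= s <= e <= self.chrom_length):
                raise ValueError("breakpoint outside chromosome bounds")
        self.breakpoints = bps

    @property
    def inverted_span(self) -> tuple[int, int]:
        return self.breakpoints[0][1], self.breakpoints[-1][2]


def assign_region(start: int, end: int, cfg: RegionConfig) -> str:
    """proximal/inverted/distal by gene midpoint against the outer breakpoints."""
    if not (0 <= start <= end <= cfg.chrom_length):
        raise ValueError("gene coordinates outside chromosome bounds")
    mid = (start + end) / 2.0
    lo, hi = cfg.inverted_span
    if mid < lo:
        return "proximal"
    if mid <= hi:
        return "inverted"
    return "distal"


def overlaps_breakpoint(start: int, end: int, cfg: RegionConfig) -> bool:
    return any(start < be and end > bs for _, bs, be in cfg.breakpoints)


def bin_genes(values, scheme: str = "quartiles", width: float = 0.05) -> np.ndarray:
    """Quantile-bin a per-gene covariate.

    ``quartiles`` gives 4 equal-size bins; ``percentile`` gives bins of the
    given width (0.05 -> 20 classes).  Quantiles are type-7 (linear
    interpolation); boundary ties go to the lower bin.
    """
    v = np.asarray(values, dtype=float)
    k = 4 if scheme == "quartiles" else int(round(1.0 / width))
    if v.size < k:
        raise ValueError("fewer genes than bins")
    if np.unique(v).size == 1:
        raise ValueError("degenerate quantiles: all values identical")
    edges = np.quantile(v, np.linspace(0, 1, k + 1), method="linear")
    return np.clip(np.searchsorted(edges[1:-1], v, side="left"), 0, k - 1)


def per_gene_rho(
    gene_start: int, gene_end: int, segments: pd.DataFrame
) -> float:
    """Length-weighted mean of rho segments overlapping the gene span.

    ``segments`` has columns start, end, rho.
    """
    s = segments[(segments.end > gene_start) & (segments.start < gene_end)]
    if s.empty:
        return float("nan")
    w = np.minimum(s.end, gene_end) - np.maximum(s.start, gene_start)
    return float(np.average(s.rho, weights=w))


def run_report(
    data_dir: str | Path,
    out_dir: str | Path,
    seed: int = 1,
    region_cfg: RegionConfig | None = None,
    comp_replicates: int = 200,
    fit_models: bool = True,
    fit_starts: int = 6,
) -> dict[str, pd.DataFrame]:
    """Run the full analysis over a dataset directory and write report TSVs.

    Expects ``alignments/*.fasta`` (with outgroup records) and ``rho.tsv``.
    Emits: major-codon table (usage + G), per-gene bias scores with
    composition-test flags, nucleotide composition, per-gene/arrangement
    diversity, per-amino-acid polymorphism rates, directional theta,
    per-gene Akashi psi, region summaries (rho, pi_S, rho/pi_S, Fop), and —
    when ``fit_models`` — L0/L1/NS fits with LRTs for major- and minor-codon
    spectra.
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    alignments = read_alignment_dir(data_dir / "alignments")
    if not alignments:
        raise FileNotFoundError(f"no alignments under {data_dir}")
    rho = read_rho_table(data_dir / "rho.tsv") if (data_dir / "rho.tsv").exists() else None
    tables: dict[str, pd.DataFrame] = {}

    counts = {a.gene_id: CodonCounts.from_sequence(a.sequences[0], a.gene_id) for a in alignments}
    pooled = CodonCounts(gene_id="pooled")
    for c in counts.values():
        pooled = pooled + c
    majors = identify_major_codons(pooled)
    tables["major_codons"] = majors.to_frame()

    reference = reference_from_top_fop(list(counts.values()), majors)
    bias_rows = []
    for gid, c in counts.items():
        p, flag = aa_composition_randomization(
            c, replicates=comp_replicates, rng=rng
        )
        bias_rows.append(
            dict(gene_id=gid, enc=enc(c), fop=fop(c, majors),
                 cai=cai(c, reference), comp_p=p, comp_flag=flag)
        )
    bias = pd.DataFrame(bias_rows)
    tables["bias_scores"] = bias
    kept_ids = set(bias.loc[~bias.comp_flag, "gene_id"])
    kept = [a for a in alignments if a.gene_id in kept_ids]

    comp = nucleotide_composition([a.sequences[0] for a in kept], frame_aware=True)
    tables["composition"] = pd.DataFrame(
        [dict(region="coding", frac_a=comp.frac_a, frac_t=comp.frac_t,
              frac_c=comp.frac_c, frac_g=comp.frac_g, pct_gc=comp.pct_gc,
              gc3=comp.gc3)]
    )

    div_rows = [diversity_stats(a) for a in kept]
    for a in kept:
        for arr, sub in split_by_arrangement(a).items():
            if arr == "outgroup":
                continue
            div_rows.append(diversity_stats(sub))
    tables["diversity"] = pd.DataFrame(div_rows)

    tables["per_aa_rates"] = per_aa_rates(kept, majors)
    tables["directional_theta"] = pd.DataFrame([directional_theta(kept)])
    tables["akashi"] = akashi_table(kept, majors)

    if rho is not None:
        cfg = region_cfg or RegionConfig()
        gene_meta = rho.set_index("gene_id")
        region_rows = []
        total_div = tables["diversity"].query("arrangement == 'TO'").set_index("gene_id")
        for gid in kept_ids:
            if gid not in gene_meta.index or gid not in total_div.index:
                continue
            start, end = int(gene_meta.loc[gid, "start"]), int(gene_meta.loc[gid, "end"])
            region_rows.append(
                dict(gene_id=gid, region=assign_region(start, end, cfg),
                     rho=float(gene_meta.loc[gid, "rho"]),
                     pi_syn=float(total_div.loc[gid, "pi_syn"]),
                     fop=float(bias.set_index("gene_id").loc[gid, "fop"]))
            )
        rg = pd.DataFrame(region_rows)
        if not rg.empty:
            summary = rg.groupby("region").agg(
                n_genes=("gene_id", "size"), rho=("rho", "mean"),
                pi_syn=("pi_syn", "mean"), fop=("fop", "mean"),
            ).reset_index()
            summary["rho_over_pi"] = np.where(
                summary.pi_syn > 0, summary.rho / summary.pi_syn, np.nan
            )
            tables["regions"] = summary
            tables["gene_regions"] = rg

    if fit_models:
        fit_rows = []
        for focal in ("major", "minor"):
            sfs = build_sfs(kept, majors, focal=focal)
            fits = {}
            for model in ("L0", "NS", "L1"):
                fits[model] = fit_model(
                    sfs, model=model, n_starts=fit_starts,
                    seed=int(rng.integers(2**31 - 1)),
                )
            chi_l0, p_l0 = lrt(fits["L1"], fits["L0"], df=2)
            chi_ns, p_ns = lrt(fits["L1"], fits["NS"], df=1)
            for model, f in fits.items():
                fit_rows.append(
                    dict(focal=focal, model=model, loglik=f.loglik,
                         theta01=f.params.theta01, theta10=f.params.theta10,
                         kappa=f.params.kappa, gamma=f.params.gamma,
                         g=f.params.g, tau=f.params.tau,
                         chi2_vs_L0=chi_l0 if model == "L1" else np.nan,
                         chi2_vs_NS=chi_ns if model == "L1" else np.nan,
                         p_vs_L0=p_l0 if model == "L1" else np.nan,
                         p_vs_NS=p_ns if model == "L1" else np.nan)
                )
        tables["model_fits"] = pd.DataFrame(fit_rows)

    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    return tables


def association_stats(x, y) -> dict:
    """Standard association summaries used in report tables (thin wrappers)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    rs, rs_p = stats.spearmanr(x, y)
    lin = stats.linregress(x, y)
    return dict(
        spearman_r=float(rs), spearman_p=float(rs_p),
        slope=float(lin.slope), r_squared=float(lin.rvalue**2),
        lin_p=float(lin.pvalue),
    )
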