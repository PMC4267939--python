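"""File-format ingest/egress: FASTA alignments, annotation tables, VCF.

Per-gene haplotype alignments are plain FASTA with one record per strain;
a record whose id starts with ``outgroup|`` supplies the single outgroup
sequence.  Annotations are TSV/BED/GFF3; a minimal VCF ingest path converts
called variants plus reference CDS features into per-gene alignments.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .polymorphism import HaplotypeAlignment

OUTGROUP_PREFIX = "outgroup|"


def read_alignment_fasta(
    path: str | Path, gene_id: str | None = None, arrangement: str = "TO"
) -> HaplotypeAlignment:
    """Read one per-gene alignment; the ``outgroup|`` record is split off."""
    path = Path(path)
    seqs, ids = [], []
    outgroup = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id.startswith(OUTGROUP_PREFIX):
            outgroup = str(rec.seq)
        else:
            ids.append(rec.id)
            seqs.append(str(rec.seq))
    if not seqs:
        raise ValueError(f"no ingroup records in {path}")
    return HaplotypeAlignment(
        gene_id=gene_id or path.stem,
        sequences=seqs,
        haplotype_ids=ids,
        arrangement=arrangement,
        outgroup=outgroup,
    )


def read_alignment_dir(path: str | Path) -> list[HaplotypeAlignment]:
    return [read_alignment_fasta(p) for p in sorted(Path(path).glob("*.fasta"))]


def write_alignment_fasta(aln: HaplotypeAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for hid, seq in zip(aln.haplotype_ids, aln.sequences):
            fh.write(f">{hid}\n{seq}\n")
        if aln.outgroup is not None:
            fh.write(f">{OUTGROUP_PREFIX}reference\n{aln.outgroup}\n")


def read_rho_table(path: str | Path) -> pd.DataFrame:
    """Per-gene recombination annotations: gene_id, start, end, rho."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "rho"}
    if not required <= set(df.columns):
        raise ValueError(f"rho table must have columns {sorted(required)}")
    if (df["rho"] < 0).any():
        raise ValueError("negative rho values")
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id"], usecols=range(4),
    )
    return df


def read_gff3_cds(path: str | Path) -> pd.DataFrame:
    """CDS features of a GFF3 file as a 0-based half-open interval table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                dict(
                    chrom=f[0],
                    start=int(f[3]) - 1,  # GFF is 1-based inclusive
                    end=int(f[4]),
                    strand=f[6],
                    gene_id=attrs.get("ID") or attrs.get("Parent", "NA"),
                )
            )
    return pd.DataFrame(rows)


def vcf_to_alignments(
    vcf_path: str | Path,
    gff_path: str | Path,
    reference_fasta: str | Path,
    min_qual: float = 30.0,
    min_coverage: int = 2,
    drop_heterozygous: bool = True,
) -> tuple[list[HaplotypeAlignment], pd.DataFrame]:
    """Build per-gene haplotype alignments from a VCF of haploid calls.

    Variants failing the quality/coverage thresholds, or called heterozygous
    in a supposedly isochromosomal strain, set the sample's base to N at that
    site.  Returns the alignments and an exclusion log.
    """
    import cyvcf2

    cds = read_gff3_cds(gff_path)
    ref = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(reference_fasta), "fasta")}
    vcf = cyvcf2.VCF(str(vcf_path))
    samples = list(vcf.samples)
    gene_seqs = {
        r.gene_id: {s: list(ref[r.chrom][r.start : r.end]) for s in samples}
        for r in cds.itertuples()
    }
    log = []
    for var in vcf:
        hits = cds[(cds.chrom == var.CHROM) & (cds.start <= var.POS - 1) & (cds.end > var.POS - 1)]
        if hits.empty or not var.ALT:
            continue
        qual_ok = var.QUAL is None or var.QUAL >= min_qual
        depths = var.format("DP")
        gts = var.gt_types  # cyvcf2: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        for r in hits.itertuples():
            offset = var.POS - 1 - r.start
            for si, s in enumerate(samples):
                reason = None
                if not qual_ok:
                    reason = "low_quality"
                elif depths is not None and depths[si][0] < min_coverage:
                    reason = "low_coverage"
                elif drop_heterozygous and gts[si] == 1:
                    reason = "heterozygous"
                if reason:
                    gene_seqs[r.gene_id][s][offset] = "N"
                    log.append(dict(gene_id=r.gene_id, pos=var.POS, sample=s, reason=reason))
                elif gts[si] == 3:
                    gene_seqs[r.gene_id][s][offset] = var.ALT[0]
    alignments = []
    for r in cds.itertuples():
        seqs = ["".join(gene_seqs[r.gene_id][s]) for s in samples]
        if r.strand == "-":
            comp = str.maketrans("ACGTN-", "TGCAN-")
            seqs = [s.translate(comp)[::-1] for s in seqs]
        alignments.append(
            HaplotypeAlignment(
                gene_id=r.gene_id, sequences=seqs, haplotype_ids=list(samples),
                start=r.start, end=r.end,
            )
        )
    return alignments, pd.DataFrame(log)
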