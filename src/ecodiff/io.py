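"""File formats and coordinate conventions.

Internally everything is 0-based half-open (BED-like); VCF positions
and GFF3 intervals are 1-based inclusive and converted at this
boundary.  VCF handling goes through pysam; trees through dendropy.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import pysam

from ecodiff.genotyping import MISSING, GenotypeMatrix
from ecodiff.intervals import Region

# --- coordinate converters (tested as inverse pairs) -----------------------


def to_zero_half_open(start1: int, end1: int) -> tuple[int, int]:
    """GFF3/1-based-inclusive interval -> BED/0-based half-open."""
    return start1 - 1, end1


def to_one_inclusive(start0: int, end0: int) -> tuple[int, int]:
    """BED/0-based half-open interval -> GFF3/1-based inclusive."""
    return start0 + 1, end0


# --- VCF --------------------------------------------------------------------


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a biallelic VCFv4.2 with GT fields ("./." for missing)."""
    path = str(path)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lengths = matrix.sites.groupby("chrom")["pos"].max()
    for chrom in matrix.sites["chrom"].unique():
        header.contigs.add(chrom, length=int(lengths[chrom]) + 1)
    for s in matrix.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        chroms = matrix.sites["chrom"].to_numpy()
        pos = matrix.sites["pos"].to_numpy()
        ref = matrix.sites["ref"].to_numpy()
        alt = matrix.sites["alt"].to_numpy()
        for i in range(matrix.n_sites):
            rec = vcf.new_record(
                contig=str(chroms[i]),
                start=int(pos[i]) - 1,
                stop=int(pos[i]),
                alleles=(str(ref[i]), str(alt[i])),
            )
            for j, s in enumerate(matrix.samples):
                d = matrix.dosage[i, j]
                if d == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    # dosage counts REF alleles
                    rec.samples[s]["GT"] = {2: (0, 0), 1: (0, 1), 0: (1, 1)}[int(d)]
            vcf.write(rec)


def read_vcf(path: str | Path, populations: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a biallelic VCF into a genotype matrix.

    ``populations`` maps sample -> {pop1, pop2, other}; unlisted samples
    get "other".  Multiallelic records are rejected.
    """
    rows, dosages = [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for line_no, rec in enumerate(vcf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"record {line_no} ({rec.chrom}:{rec.pos}) is not biallelic")
            rows.append((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
            row = np.full(len(samples), MISSING, dtype=np.int8)
            for j, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or any(x is None for x in gt):
                    continue
                row[j] = sum(1 for x in gt if x == 0)
            dosages.append(row)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    pops = np.array([(populations or {}).get(s, "other") for s in samples], dtype=object)
    return GenotypeMatrix(
        sites=sites, samples=samples, populations=pops,
        dosage=np.vstack(dosages) if dosages else np.empty((0, len(samples)), np.int8),
    )


# --- population / frequency / phenotype tables ------------------------------


def write_populations_tsv(samples: list[str], populations, path: str | Path) -> None:
    pd.DataFrame({"sample": samples, "population": populations}).to_csv(
        path, sep="\t", index=False
    )


def read_populations_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["population"]))


def write_frequencies_tsv(freqs, path: str | Path) -> None:
    freqs.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- GFF3 / BED -------------------------------------------------------------


def write_gff3(genes: pd.DataFrame, path: str | Path, source: str = "ecodiff") -> None:
    """Write a gene track (internal 0-based half-open) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples():
            start1, end1 = to_one_inclusive(int(r.start), int(r.end))
            strand = getattr(r, "strand", "+")
            fh.write(
                f"{r.chrom}\t{source}\tgene\t{start1}\t{end1}\t.\t{strand}\t.\tID={r.gene_id}\n"
            )


def read_gff3(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Read gene features from GFF3 into the internal half-open convention."""
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{line_no}: malformed GFF3 record")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = parts
            if ftype != feature:
                continue
            gene_id = None
            for field in attrs.split(";"):
                if field.startswith("ID="):
                    gene_id = field[3:]
            start0, end0 = to_zero_half_open(int(start1), int(end1))
            rows.append((chrom, start0, end0, strand, gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])


def write_bed(regions: list[Region], path: str | Path) -> None:
    """Write regions as BED (0-based half-open), name = joined sources."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            name = "+".join(sorted(r.source)) or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


def read_bed(path: str | Path) -> list[Region]:
    regions = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: malformed BED record")
            source = frozenset(parts[3].strip().split("+")) if len(parts) > 3 and parts[3].strip() != "." else frozenset()
            regions.append(
                Region(chrom=parts[0], start=int(parts[1]), end=int(parts[2]), source=source)
            )
    return regions


# --- newick -----------------------------------------------------------------


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_phylip_distances(dm, path: str | Path) -> None:
    """Distance matrix in PHYLIP square format."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for i, label in enumerate(dm.labels):
            vals = " ".join(f"{v:.6f}" for v in dm.values[i])
            fh.write(f"{label:<10s} {vals}\n")
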