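"""Readers and writers for the formats the pipeline touches.

VCF is read with cyvcf2, GFF3 with gffutils, FASTA with pyfaidx; tab-separated
tables (motifs, ancestral alleles, genetic map, scores) with pandas.  Output
tables carry a commented header line naming columns; coordinates in files
follow each format's native convention and are converted to the internal
0-based half-open convention at this boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    DNA,
    ConfigurationError,
    FormatError,
    GeneModel,
    HaplotypePanel,
    IntervalTrack,
    MotifSet,
    Transcript,
    Variant,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF

def read_vcf_panel(
    path: str | Path,
    pop_assignment: dict[str, str],
    genetic_map: "GeneticMap | None" = None,
    ancestral: dict[tuple[str, int], str] | None = None,
) -> tuple[dict[str, HaplotypePanel], list[Variant]]:
    """Read phased biallelic SNPs into per-population haplotype panels.

    Unphased, multi-allelic or non-SNP records are skipped and counted.
    Every sample in the VCF must appear in ``pop_assignment``.

    Returns (panels keyed by population, variant list); panels carry one
    column per retained variant in file order.
    """
    vcf = VCF(str(path))
    samples = vcf.samples
    missing = [s for s in samples if s not in pop_assignment]
    if missing:
        raise ConfigurationError(f"samples absent from population map: {missing}")
    pops = sorted(set(pop_assignment[s] for s in samples))
    # haplotype row indices per population, in sample order
    hap_rows = {p: [] for p in pops}
    for j, s in enumerate(samples):
        hap_rows[pop_assignment[s]].extend([2 * j, 2 * j + 1])

    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    chroms: list[str] = []
    positions: list[int] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        gts = rec.genotype.array()
        if gts.shape[1] < 3 or not np.all(gts[:, 2]):
            n_skipped += 1  # unphased record
            continue
        alleles = gts[:, :2]
        if np.any(alleles < 0):
            n_skipped += 1  # missing genotype
            continue
        hap = alleles.reshape(-1).astype(np.int8)
        anc = None
        if ancestral is not None:
            anc = ancestral.get((rec.CHROM, rec.POS))
            if anc is not None and anc not in (rec.REF, rec.ALT[0]):
                anc = None
        v = Variant(
            chrom=rec.CHROM,
            pos=rec.POS,
            ref=rec.REF,
            alt=rec.ALT[0],
            ancestral=anc,
            vid=rec.ID if rec.ID not in (None, ".") else None,
        )
        for p in pops:
            rows = hap_rows[p]
            v.counts[p] = (len(rows), int(hap[rows].sum()))
        variants.append(v)
        columns.append(hap)
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
    if n_skipped:
        logger.info("read_vcf_panel: skipped %d records (multi-allelic/indel/unphased)", n_skipped)
    if not variants:
        raise FormatError(f"no usable phased biallelic SNPs in {path}")
    uniq_chroms = set(chroms)
    if len(uniq_chroms) > 1:
        raise FormatError("panels spanning multiple chromosomes are not supported")
    chrom = chroms[0]
    pos = np.asarray(positions, dtype=np.int64)
    H = np.stack(columns, axis=1)
    gpos = genetic_map.interpolate(chrom, pos) if genetic_map is not None else pos / 1e6
    panels = {
        p: HaplotypePanel(
            population=p,
            haplotypes=H[hap_rows[p], :],
            positions=pos,
            genetic_pos=gpos,
            chrom=chrom,
        )
        for p in pops
    }
    read_vcf_panel.last_skip_count = n_skipped  # type: ignore[attr-defined]
    return panels, variants


def write_vcf(
    path: str | Path,
    variants: list[Variant],
    haplotypes: np.ndarray,
    sample_names: list[str],
    chrom_length: int | None = None,
) -> None:
    """Write phased GT records; haplotypes is (2*n_samples, n_variants) 0/1."""
    n_hap, n_var = haplotypes.shape
    if n_hap != 2 * len(sample_names):
        raise ValueError("haplotype rows must be 2 x samples")
    if n_var != len(variants):
        raise ValueError("haplotype columns must match variants")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if variants and chrom_length:
            fh.write(f"##contig=<ID={variants[0].chrom},length={chrom_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        for j, v in enumerate(variants):
            col = haplotypes[:, j]
            gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}" for i in range(len(sample_names)))
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Gene models

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 or BED12 (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".bed", ".bed12"}:
        return _read_bed12(path)
    return _read_gff3(path)


def _read_gff3(path: Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts = []
        cds: list[tuple[int, int]] | None = None
        for t in db.children(g, featuretype=("mRNA", "transcript")):
            exons = []
            for e in db.children(t, featuretype="exon"):
                if e.start - 1 < t.start - 1 or e.end > t.end:
                    raise FormatError(
                        f"exon {e.id} outside transcript span of {t.id}"
                    )
                exons.append((e.start - 1, e.end))  # GFF3 1-based closed -> 0-based half-open
            if not exons:
                continue
            transcripts.append(Transcript(tid=t.id, exons=exons))
            t_cds = sorted((c.start - 1, c.end) for c in db.children(t, featuretype="CDS"))
            if t_cds and (cds is None or sum(e - s for s, e in t_cds) > sum(e - s for s, e in cds)):
                cds = t_cds
        if transcripts:
            genes.append(
                GeneModel(gid=g.id, chrom=g.seqid, strand=g.strand, transcripts=transcripts, cds=cds)
            )
    return genes


def _read_bed12(path: Path) -> list[GeneModel]:
    """BED12 transcripts; gene grouping by the name field's 'gene|tx' prefix."""
    by_gene: dict[tuple[str, str, str], list[Transcript]] = {}
    cds_by_gene: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError("BED12 requires 12 columns")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            gid = name.split("|")[0]
            key = (gid, chrom, strand)
            by_gene.setdefault(key, []).append(Transcript(tid=name, exons=exons))
            if thick_e > thick_s:
                cds = [
                    (max(s, thick_s), min(e, thick_e))
                    for s, e in exons
                    if min(e, thick_e) > max(s, thick_s)
                ]
                old = cds_by_gene.get(key)
                if old is None or sum(e - s for s, e in cds) > sum(e - s for s, e in old):
                    cds_by_gene[key] = cds
    return [
        GeneModel(
            gid=gid, chrom=chrom, strand=strand, transcripts=txs, cds=cds_by_gene.get((gid, chrom, strand))
        )
        for (gid, chrom, strand), txs in by_gene.items()
    ]


def write_gff3(path: str | Path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chrom}\t.\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gid}\n"
            )
            for t in g.transcripts:
                ts, te = t.span
                fh.write(
                    f"{g.chrom}\t.\tmRNA\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t"
                    f"ID={t.tid};Parent={g.gid}\n"
                )
                for i, (es, ee) in enumerate(t.exons):
                    fh.write(
                        f"{g.chrom}\t.\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                        f"ID={t.tid}.exon{i};Parent={t.tid}\n"
                    )
                if g.cds and set(t.exons) >= set(g.cds):
                    phase = 0
                    cds_order = g.cds if g.strand == "+" else list(reversed(g.cds))
                    for i, (cs, ce) in enumerate(cds_order):
                        fh.write(
                            f"{g.chrom}\t.\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t{phase}\t"
                            f"ID={t.tid}.cds{i};Parent={t.tid}\n"
                        )
                        phase = (3 - ((ce - cs) - phase) % 3) % 3
    # one CDS chain per gene keeps codon arithmetic unambiguous


# ---------------------------------------------------------------------------
# Motifs and small tables

def read_motifs(path: str | Path, element_type: str | None = None) -> dict[str, MotifSet]:
    """Read hexamer motifs from a TSV with columns (hexamer, element_type).

    Rows with invalid length or non-ACGT characters are rejected and reported
    with their row numbers; the returned sets are deduplicated.
    """
    rows = pd.read_csv(path, sep="\t", comment="#", header=None, names=["hexamer", "element_type"], dtype=str)
    if rows.empty:
        raise ConfigurationError(f"empty motif file {path}")
    bad_rows = []
    by_type: dict[str, set[str]] = {}
    for i, (hexamer, etype) in enumerate(zip(rows["hexamer"], rows["element_type"]), start=1):
        hexamer = str(hexamer).strip().upper()
        if len(hexamer) != 6 or set(hexamer) - DNA:
            bad_rows.append(i)
            continue
        by_type.setdefault(str(etype).strip(), set()).add(hexamer)
    if bad_rows:
        logger.warning("read_motifs: rejected rows %s (bad hexamer)", bad_rows)
    read_motifs.rejected_rows = bad_rows  # type: ignore[attr-defined]
    out = {t: MotifSet(element_type=t, hexamers=frozenset(h)) for t, h in by_type.items()}
    if element_type is not None:
        return {element_type: out[element_type]}
    return out


def read_ancestral(path: str | Path) -> dict[tuple[str, int], str]:
    """TSV with columns (chrom, pos[1-based], ancestral_allele)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "pos", "ancestral"], dtype={"chrom": str})
    out = {}
    for chrom, pos, aa in df.itertuples(index=False):
        aa = str(aa).strip().upper()
        if aa in DNA:
            out[(str(chrom), int(pos))] = aa
    return out


def read_bvalue_track(path: str | Path) -> IntervalTrack:
    """BED (chrom, start, end, value) -> IntervalTrack."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "value"], dtype={"chrom": str})
    grouped = {
        chrom: (g["start"].to_numpy(), g["end"].to_numpy(), g["value"].to_numpy())
        for chrom, g in df.groupby("chrom")
    }
    return IntervalTrack(grouped)


def lookup_track(track: IntervalTrack, chrom: str, pos: int) -> float | None:
    """Value of the unique interval covering 1-based ``pos``, else None."""
    return track.lookup(chrom, pos)


class GeneticMap:
    """Physical->genetic position map (linear interpolation, cM)."""

    def __init__(self, table: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._table = {
            c: (np.asarray(p, dtype=np.int64), np.asarray(cm, dtype=float))
            for c, (p, cm) in table.items()
        }
        for c, (p, cm) in self._table.items():
            if np.any(np.diff(p) <= 0) or np.any(np.diff(cm) < 0):
                raise FormatError(f"genetic map not monotone on {c}")

    def interpolate(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        if chrom not in self._table:
            # fallback: uniform 1 cM/Mb
            return np.asarray(pos, dtype=float) / 1e6
        p, cm = self._table[chrom]
        return np.interp(np.asarray(pos, dtype=float), p.astype(float), cm)


def read_genetic_map(path: str | Path) -> GeneticMap:
    """TSV with columns (chrom, pos[1-based bp], cM)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "pos", "cM"], dtype={"chrom": str})
    return GeneticMap(
        {c: (g["pos"].to_numpy(), g["cM"].to_numpy()) for c, g in df.groupby("chrom")}
    )


def write_table(path: str | Path, df: pd.DataFrame, comment: str | None = None) -> None:
    """Tab-separated output with a commented header line."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("# " + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_table(path: str | Path, columns: list[str] | None = None) -> pd.DataFrame:
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("# ") and "\t" in line:
                header = line[2:].rstrip("\n").split("\t")
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if columns is not None:
        df.columns = columns
    elif header is not None and len(header) == df.shape[1]:
        df.columns = header
    return df
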