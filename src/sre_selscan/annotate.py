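"""Annotate SNPs against splicing-regulatory hexamer motifs.

A SNP is an SRE SNP when (a) at least one of its alleles places a hexamer of
some element type within the 11-base sequence context centred on the SNP, and
(b) the exon-skip geometry for that element type holds: exonic elements
(ESE/ESS) require the SNP to lie inside a skipped exon, intronic elements
(ISE) require it to lie in an intron directly flanking a skipped exon.

Motif matching is performed on the transcribed strand of the host gene:
contexts of minus-strand genes are reverse-complemented before windowing,
because the motifs are defined on pre-mRNA.  SNPs outside any gene are
matched on the reference strand (their geometry gate fails regardless).

The allele that creates the motif is the *inducing* allele; the other is the
*disrupting* allele.  If both alleles match motifs the direction is recorded
as ambiguous and the SNP is excluded from disrupt/induce contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .types import FormatError, GeneModel, MotifSet, Variant

_COMPL = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPL)[::-1]


class ContextUnavailable(Exception):
    """Variant too close to a contig edge for an 11-base context."""


def _fetch(fasta, chrom: str, start0: int, end0: int) -> str:
    """Sequence slice [start0, end0) from a pyfaidx.Fasta or a dict of str."""
    start0 = max(start0, 0)
    return str(fasta[chrom][start0:end0]).upper()


def extract_context(fasta, chrom: str, pos: int) -> str:
    """11-base reference context centred on the 1-based position ``pos``.

    Raises ContextUnavailable within 5 bases of a contig edge.
    """
    x = pos - 1
    if x < 5:
        raise ContextUnavailable(f"{chrom}:{pos} within 5 bp of contig start")
    ctx = _fetch(fasta, chrom, x - 5, x + 6)
    if len(ctx) != 11:
        raise ContextUnavailable(f"{chrom}:{pos} within 5 bp of contig end")
    return ctx


def hexamer_windows(context11: str, allele: str) -> list[str]:
    """The six 6-mers containing the SNP: the window starts with the SNP in
    the last position and shifts until the SNP is in the first position."""
    if len(context11) != 11:
        raise ValueError("context must be 11 bases")
    s = context11[:5] + allele + context11[6:]
    return [s[i : i + 6] for i in range(6)]


def allelic_motif_match(
    context11: str, ref: str, alt: str, motifset: MotifSet
) -> tuple[set[str], set[str]]:
    """Exact-match hexamers of ``motifset`` among each allele's six windows."""
    if context11[5] != ref:
        raise FormatError(
            f"reference allele {ref!r} does not match context centre {context11[5]!r}"
        )
    ref_hits = {w for w in hexamer_windows(context11, ref) if w in motifset}
    alt_hits = {w for w in hexamer_windows(context11, alt) if w in motifset}
    return ref_hits, alt_hits


# ---------------------------------------------------------------------------
# Gene geometry


def find_host_gene(genes: list[GeneModel], chrom: str, pos0: int) -> GeneModel | None:
    for g in genes:
        s, e = g.span
        if g.chrom == chrom and s <= pos0 < e:
            return g
    return None


def junction_distance(gene: GeneModel, pos0: int) -> int | None:
    """bp to the nearest exon/intron boundary of the host gene; 0 for the
    first base on either side of a junction."""
    feats = gene._merged_exons() + gene.introns()
    for s, e in feats:
        if s <= pos0 < e:
            return int(min(pos0 - s, e - 1 - pos0))
    return None


@dataclass
class SkipContext:
    context_ok: bool
    skipped_exon_id: str | None
    junction_distance: int | None
    reason: str = ""


def exon_skip_context(
    chrom: str,
    pos0: int,
    genes: list[GeneModel],
    element_type: str,
    max_intron_distance: int | None = None,
) -> SkipContext:
    """Exon-skip geometry gate for one element type.

    ESE/ESS: the SNP must lie inside a skipped exon.  ISE: the SNP must lie
    in an intron immediately flanking (either side of) a skipped exon; by
    default anywhere within that intron, optionally capped at
    ``max_intron_distance`` bp from the shared junction.
    """
    gene = find_host_gene(genes, chrom, pos0)
    if gene is None:
        return SkipContext(False, None, None, reason="intergenic")
    jd = junction_distance(gene, pos0)
    skipped = gene.skipped_exons()
    if element_type in ("ESE", "ESS"):
        for ex in skipped:
            if ex[0] <= pos0 < ex[1]:
                return SkipContext(True, f"{gene.gid}:{ex[0]}-{ex[1]}", jd)
        return SkipContext(False, None, jd, reason="not in a skipped exon")
    if element_type == "ISE":
        for s, e in gene.introns():
            if not s <= pos0 < e:
                continue
            for ex in skipped:
                if e == ex[0] or s == ex[1]:
                    if max_intron_distance is not None:
                        d = ex[0] - 1 - pos0 if e == ex[0] else pos0 - ex[1]
                        d = abs(d)
                        if d > max_intron_distance:
                            continue
                    return SkipContext(True, f"{gene.gid}:{ex[0]}-{ex[1]}", jd)
        return SkipContext(False, None, jd, reason="not flanking a skipped exon")
    raise ValueError(f"unknown element type {element_type!r}")


# ---------------------------------------------------------------------------
# Functional class


def _splice_dinucleotide_hit(gene: GeneModel, fasta, pos0: int) -> bool:
    """True when the SNP falls on a canonical GT/AG splice dinucleotide of
    the host gene (strand-aware)."""
    for s, e in gene.introns():
        if not (s <= pos0 < s + 2 or e - 2 <= pos0 < e):
            continue
        donor = _fetch(fasta, gene.chrom, s, s + 2)
        acceptor = _fetch(fasta, gene.chrom, e - 2, e)
        if gene.strand == "+":
            canonical = donor == "GT" and acceptor == "AG"
        else:
            # transcribed GT..AG reads AC at the genomic end, CT at the start
            canonical = acceptor == "AC" and donor == "CT"
        if canonical:
            return True
    return False


def functional_class(variant: Variant, genes: list[GeneModel], fasta) -> str:
    """SNP class: intronic, synonymous, non-synonymous, LOF or other.

    LOF covers stop-gain and canonical splice-dinucleotide disruption.
    Codon comparison assumes the annotated CDS chain starts in frame 0 at its
    transcription 5' end; genes with no CDS yield "other".
    """
    gene = find_host_gene(genes, variant.chrom, variant.pos0)
    if gene is None:
        return "other"
    pos0 = variant.pos0
    if _splice_dinucleotide_hit(gene, fasta, pos0):
        return "LOF"
    for s, e in gene.introns():
        if s <= pos0 < e:
            return "intronic"
    if not gene.cds:
        return "other"
    cds = sorted(gene.cds)
    in_cds = any(s <= pos0 < e for s, e in cds)
    if not in_cds:
        return "other"
    # genomic CDS offset, then orient to the transcribed strand
    off = 0
    for s, e in cds:
        if s <= pos0 < e:
            off += pos0 - s
            break
        off += e - s
    total = sum(e - s for s, e in cds)
    if gene.strand == "-":
        off = total - 1 - off
    cds_seq = "".join(_fetch(fasta, gene.chrom, s, e) for s, e in cds)
    ref_allele, alt_allele = variant.ref, variant.alt
    if gene.strand == "-":
        cds_seq = _revcomp(cds_seq)
        ref_allele, alt_allele = _revcomp(ref_allele), _revcomp(alt_allele)
    if cds_seq[off] != ref_allele:
        return "other"  # reference/CDS disagreement; refuse to classify
    ci = 3 * (off // 3)
    codon_ref = cds_seq[ci : ci + 3]
    if len(codon_ref) < 3:
        return "other"
    codon_alt = codon_ref[: off - ci] + alt_allele + codon_ref[off - ci + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    if aa_alt == "*" and aa_ref != "*":
        return "LOF"
    return "synonymous" if aa_ref == aa_alt else "non-synonymous"


# ---------------------------------------------------------------------------
# Full annotation


def annotate_all(
    variants: list[Variant],
    genes: list[GeneModel],
    motifs: dict[str, MotifSet],
    fasta,
    max_intron_distance: int | None = None,
) -> pd.DataFrame:
    """One annotation row per variant.

    is_sre = (some allele matches a motif of element type T) AND (the
    exon-skip geometry for T holds).  Column ``element_types`` lists every
    matched type (geometry-passing ones marked by is_sre); direction columns
    are "ambiguous" when both alleles match motifs.
    """
    rows = []
    for v in variants:
        rec = {
            "vid": v.vid, "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
            "alt": v.alt, "ancestral": v.ancestral or "",
            "func_class": functional_class(v, genes, fasta),
            "is_sre": False, "element_types": "", "inducing_allele": "",
            "disrupting_allele": "", "context_ok": False,
            "skipped_exon_id": "", "junction_distance": np.nan, "reason": "",
        }
        try:
            ctx = extract_context(fasta, v.chrom, v.pos)
        except ContextUnavailable:
            rec["reason"] = "context-unavailable"
            rows.append(rec)
            continue
        gene = find_host_gene(genes, v.chrom, v.pos0)
        ref_m, alt_m = v.ref, v.alt
        if gene is not None and gene.strand == "-":
            ctx_m = _revcomp(ctx)
            ref_m, alt_m = _revcomp(v.ref), _revcomp(v.alt)
        else:
            ctx_m = ctx
        ref_hits_all: set[str] = set()
        alt_hits_all: set[str] = set()
        matched_types: list[str] = []
        passing_types: list[str] = []
        skipped_id, jd = None, None
        for etype, ms in sorted(motifs.items()):
            rh, ah = allelic_motif_match(ctx_m, ref_m, alt_m, ms)
            if not rh and not ah:
                continue
            matched_types.append(etype)
            ref_hits_all |= rh
            alt_hits_all |= ah
            sc = exon_skip_context(v.chrom, v.pos0, genes, etype, max_intron_distance)
            if sc.junction_distance is not None:
                jd = sc.junction_distance
            if sc.context_ok:
                passing_types.append(etype)
                skipped_id = sc.skipped_exon_id
        if jd is None and gene is not None:
            jd = junction_distance(gene, v.pos0)
        rec["junction_distance"] = np.nan if jd is None else jd
        rec["element_types"] = ",".join(matched_types)
        rec["context_ok"] = bool(passing_types)
        rec["is_sre"] = bool(passing_types)
        if skipped_id:
            rec["skipped_exon_id"] = skipped_id
        if matched_types:
            if ref_hits_all and alt_hits_all:
                rec["inducing_allele"] = "ambiguous"
                rec["disrupting_allele"] = "ambiguous"
            elif ref_hits_all:
                rec["inducing_allele"], rec["disrupting_allele"] = v.ref, v.alt
            else:
                rec["inducing_allele"], rec["disrupting_allele"] = v.alt, v.ref
        if not rec["is_sre"] and matched_types:
            rec["reason"] = "geometry"
        rows.append(rec)
    return pd.DataFrame(rows)
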