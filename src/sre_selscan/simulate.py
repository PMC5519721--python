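"""Synthetic study data with known truth.

The generator emulates the statistical structure the analysis assumes:

* population allele-frequency divergence under the Balding–Nichols model,
  whose parameter ``c`` equals the expected Weir–Cockerham F_ST;
* phased haplotype panels with local linkage disequilibrium induced by
  template copying, and optional planted selective sweeps (extended
  haplotype homozygosity around a favoured core allele);
* gene models with skipped internal exons and canonical GT/AG introns;
* SNPs planted inside or outside splicing-regulatory hexamer motifs with a
  known inducing/disrupting allele, functional class, and exon-skip context.

Every draw is governed by a single seed; the emitted fixture is a set of
plain-text files (VCF, GFF3, FASTA, TSV, BED) that the io module reads back.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .types import (
    ConfigurationError,
    GeneModel,
    HaplotypePanel,
    MotifSet,
    Transcript,
    Variant,
)
from . import io as sio

BASES = np.array(list("ACGT"))


class GenerationError(RuntimeError):
    """Planting could not satisfy its constraints."""


# ---------------------------------------------------------------------------
# Allele frequencies and haplotype panels


def simulate_frequencies(
    n_snps: int, c: float, rng: np.random.Generator, n_populations: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Balding–Nichols divergence: ancestral p0 ~ U(0.05, 0.95), each
    population frequency ~ Beta(p0(1-c)/c, (1-p0)(1-c)/c).

    Returns (p0 of shape (n_snps,), freqs of shape (n_populations, n_snps)).
    """
    if not 0 < c < 1:
        raise ConfigurationError(f"divergence parameter c={c} outside (0, 1)")
    p0 = rng.uniform(0.05, 0.95, size=n_snps)
    a = p0 * (1 - c) / c
    b = (1 - p0) * (1 - c) / c
    freqs = np.stack([rng.beta(a, b) for _ in range(n_populations)])
    return p0, freqs


def simulate_panel(
    freqs: np.ndarray,
    n_hap: int,
    rng: np.random.Generator,
    positions: np.ndarray | None = None,
    genetic_pos: np.ndarray | None = None,
    population: str = "P1",
    ld: bool = True,
    ld_ar: float = 0.9,
    chrom: str = "1",
) -> HaplotypePanel:
    """Draw a haplotype panel with per-site ALT frequency ``freqs``.

    Haplotypes are mutually independent, so each site's allele count is an
    exact Binomial(n_hap, freq) draw.  With ``ld=True`` local LD along the
    chromosome is induced by a Gaussian-copula AR(1) latent process per
    haplotype (adjacent-site latent correlation ``ld_ar``): the allele at
    site j is 1 iff the latent value falls below the freq-quantile, which
    preserves the Bernoulli(freq) marginal exactly while correlating nearby
    sites.
    """
    if n_hap < 4:
        raise ConfigurationError("need at least 4 haplotypes")
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ConfigurationError("frequencies must lie in [0, 1]")
    m = len(freqs)
    if not ld:
        H = (rng.random((n_hap, m)) < freqs[None, :]).astype(np.int8)
    else:
        from scipy.special import ndtri

        eps = rng.standard_normal((n_hap, m))
        z = np.empty((n_hap, m))
        z[:, 0] = eps[:, 0]
        s = np.sqrt(1 - ld_ar**2)
        for j in range(1, m):  # stationary AR(1), unit marginal variance
            z[:, j] = ld_ar * z[:, j - 1] + s * eps[:, j]
        thresh = ndtri(np.clip(freqs, 1e-12, 1 - 1e-12))
        H = (z < thresh[None, :]).astype(np.int8)
        H[:, freqs <= 0] = 0
        H[:, freqs >= 1] = 1
    if positions is None:
        positions = np.arange(1, m + 1, dtype=np.int64) * 500
    if genetic_pos is None:
        genetic_pos = np.asarray(positions, dtype=float) / 1e6  # 1 cM/Mb
    return HaplotypePanel(
        population=population,
        haplotypes=H,
        positions=positions,
        genetic_pos=genetic_pos,
        chrom=chrom,
    )


def simulate_panels(
    n_snps: int,
    c: float,
    n_hap: int,
    seed: int | np.random.Generator,
    n_populations: int = 2,
    spacing_bp: int = 500,
    ld: bool = True,
    **panel_kwargs,
) -> tuple[dict[str, HaplotypePanel], np.ndarray, np.ndarray]:
    """Convenience: Balding–Nichols frequencies + one panel per population.

    Returns (panels keyed 'P1'..'Pk', ancestral frequencies p0, per-pop freqs).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p0, freqs = simulate_frequencies(n_snps, c, rng, n_populations)
    positions = np.arange(1, n_snps + 1, dtype=np.int64) * spacing_bp
    panels = {}
    for k in range(n_populations):
        name = f"P{k + 1}"
        panels[name] = simulate_panel(
            freqs[k], n_hap, rng, positions=positions, population=name, ld=ld, **panel_kwargs
        )
    return panels, p0, freqs


def plant_sweep(
    panel: HaplotypePanel,
    core_index: int,
    favored_allele: int,
    carrier_fraction: float,
    rng: np.random.Generator,
    window_sites: int = 100,
) -> HaplotypePanel:
    """Plant a selective-sweep signature at a core site.

    A fraction ``carrier_fraction`` of the haplotypes carrying
    ``favored_allele`` at ``core_index`` are replaced by copies of one
    template carrier haplotype over a +/- ``window_sites`` window, producing
    elevated extended haplotype homozygosity on the favoured background.
    Returns a new panel; the input is untouched.
    """
    if not 0 <= carrier_fraction <= 1:
        raise ConfigurationError("carrier_fraction must lie in [0, 1]")
    H = panel.haplotypes.copy()
    carriers = np.flatnonzero(H[:, core_index] == favored_allele)
    if len(carriers) == 0:
        raise ConfigurationError("favored allele absent at core site")
    if carrier_fraction > 0:
        n_copy = int(round(carrier_fraction * len(carriers)))
        template = carriers[0]
        chosen = rng.choice(carriers, size=n_copy, replace=False) if n_copy else []
        lo = max(0, core_index - window_sites)
        hi = min(H.shape[1], core_index + window_sites + 1)
        H[chosen, lo:hi] = H[template, lo:hi]
    return HaplotypePanel(
        population=panel.population,
        haplotypes=H,
        positions=panel.positions,
        genetic_pos=panel.genetic_pos,
        chrom=panel.chrom,
    )


# ---------------------------------------------------------------------------
# Motif sets


def random_motif_sets(
    rng: np.random.Generator, n_per_type: int = 50
) -> dict[str, MotifSet]:
    """Disjoint random hexamer sets for ESE, ESS and ISE."""
    n_total = 3 * n_per_type
    chosen: set[str] = set()
    while len(chosen) < n_total:
        h = "".join(rng.choice(BASES, size=6))
        chosen.add(h)
    hexamers = sorted(chosen)
    rng.shuffle(hexamers)
    out = {}
    for i, etype in enumerate(("ESE", "ESS", "ISE")):
        out[etype] = MotifSet(
            element_type=etype,
            hexamers=frozenset(hexamers[i * n_per_type : (i + 1) * n_per_type]),
        )
    return out


def _windows6(context11: str, allele: str) -> list[str]:
    s = context11[:5] + allele + context11[6:]
    return [s[i : i + 6] for i in range(6)]


def _matches(context11: str, allele: str, motifs: dict[str, MotifSet]) -> set[str]:
    """Element types whose motif set contains any 6-mer window of the allele."""
    wins = _windows6(context11, allele)
    return {t for t, ms in motifs.items() if any(w in ms for w in wins)}


# ---------------------------------------------------------------------------
# Genes, motifs, planted SNPs


@dataclass
class SweepSpec:
    population: str = "P1"
    carrier_fraction: float = 0.8
    window_sites: int = 100
    core_index: int | None = None  # None: site nearest the panel middle


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixture."""

    n_populations: int = 2
    n_hap: int = 100            # haplotypes per population (50 diploids)
    n_snps: int = 1000
    divergence_c: float = 0.15  # expected F_ST under Balding-Nichols
    sweeps: list[SweepSpec] = field(default_factory=list)
    # gene models
    n_genes: int = 20
    exons_per_gene: int = 5
    skip_probability: float = 0.6
    exon_len_range: tuple[int, int] = (180, 240)   # rounded to codon multiples
    intron_len_range: tuple[int, int] = (240, 600)
    intergenic_len_range: tuple[int, int] = (300, 800)
    # motif planting
    sre_fraction: float = 0.2
    element_weights: tuple[float, float, float] = (0.5, 0.25, 0.25)  # ISE, ESE, ESS
    disrupt_induce_ratio: float = 1.0  # derived-disrupts : derived-induces
    decoy_fraction: float = 0.05       # motif match with failing exon-skip geometry
    n_motifs_per_type: int = 50
    # haplotype structure
    ld: bool = True
    ld_ar: float = 0.9  # adjacent-site latent AR(1) correlation
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Fixture:
    """Everything the generator knows about one synthetic study."""

    config: SimulationConfig
    sequence: str
    genes: list[GeneModel]
    motifs: dict[str, MotifSet]
    variants: list[Variant]
    truth: "list[dict]"
    panels: dict[str, HaplotypePanel]
    chrom: str = "1"

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame(self.truth)


def _layout_genes(cfg: SimulationConfig, rng: np.random.Generator):
    """Place genes on a fresh random contig; return (genes, seq array)."""
    pieces = []
    genes: list[GeneModel] = []
    cursor = 0
    chunks: list[tuple[int, int]] = []  # gene spans
    exon_lists: list[list[tuple[int, int]]] = []
    for gi in range(cfg.n_genes):
        cursor += rng.integers(*cfg.intergenic_len_range)
        exons = []
        pos = cursor
        for ei in range(cfg.exons_per_gene):
            elen = int(rng.integers(*cfg.exon_len_range))
            elen -= elen % 3  # codon-aligned exon lengths
            exons.append((pos, pos + elen))
            pos += elen
            if ei < cfg.exons_per_gene - 1:
                pos += int(rng.integers(*cfg.intron_len_range))
        exon_lists.append(exons)
        chunks.append((cursor, pos))
        cursor = pos
    total_len = cursor + int(rng.integers(*cfg.intergenic_len_range))
    seq = rng.choice(BASES, size=total_len)
    # exactly round(skip_probability * n_genes) genes carry a skip event,
    # so fixture capacity for exonic plants does not fluctuate across seeds
    n_skip_genes = int(round(cfg.skip_probability * cfg.n_genes))
    skip_genes = set(rng.choice(cfg.n_genes, size=n_skip_genes, replace=False))
    for gi, exons in enumerate(exon_lists):
        full = Transcript(tid=f"g{gi}.t1", exons=list(exons))
        transcripts = [full]
        if gi in skip_genes and len(exons) >= 3:
            skip_i = int(rng.integers(1, len(exons) - 1))
            alt_exons = [e for j, e in enumerate(exons) if j != skip_i]
            transcripts.append(Transcript(tid=f"g{gi}.t2", exons=alt_exons))
        gene = GeneModel(
            gid=f"g{gi}", chrom="1", strand="+", transcripts=transcripts, cds=list(exons)
        )
        genes.append(gene)
        # canonical splice dinucleotides GT..AG in every union intron
        for s, e in gene.introns():
            seq[s : s + 2] = list("GT")
            seq[e - 2 : e] = list("AG")
    return genes, seq


def _codon_class(seq: np.ndarray, gene: GeneModel, pos0: int, ref: str, alt: str) -> str:
    """Functional class by codon arithmetic (plus strand, exon-aligned CDS)."""
    for s, e in gene.introns():
        if s <= pos0 < s + 2 or e - 2 <= pos0 < e:
            return "LOF"  # splice dinucleotide (generator guarantees GT/AG)
        if s <= pos0 < e:
            return "intronic"
    for s, e in gene.cds or []:
        if s <= pos0 < e:
            off = pos0 - s
            cs = s + 3 * (off // 3)
            codon_ref = "".join(seq[cs : cs + 3])
            codon_alt = list(codon_ref)
            codon_alt[pos0 - cs] = alt
            codon_alt = "".join(codon_alt)
            aa_ref = str(Seq(codon_ref).translate())
            aa_alt = str(Seq(codon_alt).translate())
            if aa_alt == "*" and aa_ref != "*":
                return "LOF"
            return "synonymous" if aa_ref == aa_alt else "non-synonymous"
    return "other"


def generate_genes_and_motifs(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[str, list[GeneModel], dict[str, MotifSet], list[Variant], list[dict]]:
    """Build the reference contig, gene models, motif sets and planted SNPs.

    Returns (sequence, genes, motifs, variants, truth rows).  SRE SNPs are
    planted so that exactly one allele's 11-base context contains a motif
    hexamer of the intended element type and the other allele's context
    matches no motif of any type; non-SRE SNPs match no motif with either
    allele.  The truth rows record the planted annotation.
    """
    genes, seq = _layout_genes(cfg, rng)
    motifs = random_motif_sets(rng, cfg.n_motifs_per_type)

    skipped: list[tuple[GeneModel, tuple[int, int]]] = []
    for g in genes:
        for ex in sorted(g.skipped_exons()):
            skipped.append((g, ex))
    n_sre = int(round(cfg.sre_fraction * cfg.n_snps))
    if n_sre > 0 and not skipped:
        raise GenerationError("no skipped exons available for SRE planting")

    w = np.asarray(cfg.element_weights, dtype=float)
    w = w / w.sum()
    n_ise = int(round(n_sre * w[0]))
    n_ese = int(round(n_sre * w[1]))
    n_ess = n_sre - n_ise - n_ese
    n_decoy = int(round(cfg.decoy_fraction * cfg.n_snps))
    n_plain = cfg.n_snps - n_sre - n_decoy

    used: list[int] = []
    used_arr = np.empty(0, dtype=np.int64)

    def far_enough(p: int, min_sep: int) -> bool:
        if len(used) == 0:
            return True
        i = np.searchsorted(used_arr[: len(used)], p)
        for j in (i - 1, i):
            if 0 <= j < len(used) and abs(used[j] - p) < min_sep:
                return False
        return True

    def register(p: int) -> None:
        nonlocal used_arr
        import bisect

        bisect.insort(used, p)
        used_arr = np.asarray(used, dtype=np.int64)

    def intron_flanks(g: GeneModel, ex: tuple[int, int]) -> list[tuple[int, int]]:
        out = []
        for s, e in g.introns():
            if e == ex[0] or s == ex[1]:
                out.append((s, e))
        return out

    p_derived_disrupts = cfg.disrupt_induce_ratio / (1.0 + cfg.disrupt_induce_ratio)

    def plant_sre(etype: str, region: tuple[int, int], gene: GeneModel,
                  skipped_id: str, want_context: bool) -> dict | None:
        """Embed one motif-bearing SNP inside region; returns a truth row."""
        lo, hi = region[0] + 8, region[1] - 8
        if hi <= lo:
            return None
        ms = sorted(motifs[etype].hexamers)
        for _ in range(200):
            x = int(rng.integers(lo, hi))
            if not far_enough(x, 12):
                continue
            motif = ms[int(rng.integers(len(ms)))]
            k = int(rng.integers(6))  # SNP index within the motif
            start = x - k
            if start < 0 or start + 6 > len(seq):
                continue
            old = seq[start : start + 6].copy()
            seq[start : start + 6] = list(motif)
            inducing = motif[k]
            others = [b for b in "ACGT" if b != inducing]
            rng.shuffle(others)
            ctx = "".join(seq[x - 5 : x + 6])
            ok = False
            for disrupting in others:
                if _matches(ctx, inducing, motifs) == {etype} and not _matches(
                    ctx, disrupting, motifs
                ):
                    ok = True
                    break
            if not ok:
                seq[start : start + 6] = old
                continue
            derived_disrupts = rng.random() < p_derived_disrupts
            # ancestral allele is always the reference allele in the fixture
            if derived_disrupts:
                ref, alt = inducing, disrupting
            else:
                ref, alt = disrupting, inducing
            seq[x] = ref
            register(x)
            func = _codon_class(seq, gene, x, ref, alt)
            return {
                "pos0": x,
                "ref": ref,
                "alt": alt,
                "ancestral": ref,
                "is_sre": bool(want_context),
                "element_type": etype,
                "inducing_allele": inducing,
                "disrupting_allele": disrupting,
                "func_class": func,
                "skipped_exon_id": skipped_id if want_context else "",
                "gene_id": gene.gid,
                "motif_match": True,
            }
        return None  # region exhausted; caller retries elsewhere

    truth: list[dict] = []

    def skipped_region(etype: str):
        g, ex = skipped[int(rng.integers(len(skipped)))]
        ex_id = f"{g.gid}:{ex[0]}-{ex[1]}"
        if etype == "ISE":
            flanks = intron_flanks(g, ex)
            region = flanks[int(rng.integers(len(flanks)))]
        else:
            region = ex
        return g, region, ex_id

    for etype, n in (("ISE", n_ise), ("ESE", n_ese), ("ESS", n_ess)):
        planted = 0
        attempts = 0
        while planted < n:
            attempts += 1
            if attempts > 200 * max(n, 1):
                raise GenerationError(f"ran out of space planting {etype} SNPs")
            g, region, ex_id = skipped_region(etype)
            row = plant_sre(etype, region, g, ex_id, want_context=True)
            if row is not None:
                truth.append(row)
                planted += 1

    # decoys: real motif match, failing exon-skip geometry
    planted = 0
    attempts = 0
    while planted < n_decoy:
        attempts += 1
        if attempts > 50 * max(n_decoy, 1):
            raise GenerationError("ran out of space planting decoy SNPs")
        g = genes[int(rng.integers(len(genes)))]
        g_skipped = g.skipped_exons()
        etype = ("ISE", "ESE", "ESS")[int(rng.integers(3))]
        if etype == "ISE":
            # an intron NOT flanking any skipped exon
            regions = [
                iv
                for iv in g.introns()
                if not any(iv[1] == ex[0] or iv[0] == ex[1] for ex in g_skipped)
            ]
        else:
            regions = [ex for ex in g.exons if ex not in g_skipped]
        if not regions:
            continue
        region = regions[int(rng.integers(len(regions)))]
        row = plant_sre(etype, region, g, "", want_context=False)
        if row is not None:
            truth.append(row)
            planted += 1

    # plain non-SRE SNPs: neither allele matches any motif
    genic_spans = [g.span for g in genes]
    planted = 0
    attempts = 0
    while planted < n_plain:
        attempts += 1
        if attempts > 1000 * max(n_plain, 1):
            raise GenerationError("could not plant a motif-free SNP after 1000 attempts")
        if rng.random() < 0.8:
            g = genes[int(rng.integers(len(genes)))]
            lo, hi = g.span
        else:
            g = None
            lo, hi = 6, len(seq) - 6
        x = int(rng.integers(lo + 6, hi - 6))
        if not far_enough(x, 6):
            continue
        ref = str(seq[x])
        alts = [b for b in "ACGT" if b != ref]
        alt = alts[int(rng.integers(3))]
        ctx = "".join(seq[x - 5 : x + 6])
        if _matches(ctx, ref, motifs) or _matches(ctx, alt, motifs):
            continue
        host = g
        if host is None:
            for gg in genes:
                s, e = gg.span
                if s <= x < e:
                    host = gg
                    break
        func = _codon_class(seq, host, x, ref, alt) if host is not None else "other"
        register(x)
        truth.append(
            {
                "pos0": x,
                "ref": ref,
                "alt": alt,
                "ancestral": ref,
                "is_sre": False,
                "element_type": "",
                "inducing_allele": "",
                "disrupting_allele": "",
                "func_class": func,
                "skipped_exon_id": "",
                "gene_id": host.gid if host is not None else "",
                "motif_match": False,
            }
        )
        planted += 1

    truth.sort(key=lambda r: r["pos0"])
    variants = [
        Variant(
            chrom="1",
            pos=r["pos0"] + 1,
            ref=r["ref"],
            alt=r["alt"],
            ancestral=r["ancestral"],
            func_class=r["func_class"],
        )
        for r in truth
    ]
    for r, v in zip(truth, variants):
        r["vid"] = v.vid
    return "".join(seq), genes, motifs, variants, truth


def simulate_fixture(cfg: SimulationConfig) -> Fixture:
    """Full synthetic study: contig + genes + planted SNPs + panels (+ sweeps)."""
    rng = np.random.default_rng(cfg.seed)
    sequence, genes, motifs, variants, truth = generate_genes_and_motifs(cfg, rng)
    n = len(variants)
    positions = np.array([v.pos for v in variants], dtype=np.int64)
    gpos = positions / 1e6
    _, freqs = simulate_frequencies(n, cfg.divergence_c, rng, cfg.n_populations)
    panels: dict[str, HaplotypePanel] = {}
    for k in range(cfg.n_populations):
        name = f"P{k + 1}"
        panels[name] = simulate_panel(
            freqs[k],
            cfg.n_hap,
            rng,
            positions=positions,
            genetic_pos=gpos,
            population=name,
            ld=cfg.ld,
            ld_ar=cfg.ld_ar,
        )
    for r in truth:
        r["swept"] = False
    for spec in cfg.sweeps:
        panel = panels[spec.population]
        core = spec.core_index if spec.core_index is not None else n // 2
        counts = panel.alt_count()
        favored = 1 if 0 < counts[core] < panel.n_hap else 0
        panels[spec.population] = plant_sweep(
            panel, core, favored, spec.carrier_fraction, rng, spec.window_sites
        )
        truth[core]["swept"] = True
    for v, r in zip(variants, truth):
        for name, panel in panels.items():
            j = int(np.searchsorted(positions, v.pos))
            v.counts[name] = (panel.n_hap, int(panel.haplotypes[:, j].sum()))
    return Fixture(
        config=cfg,
        sequence=sequence,
        genes=genes,
        motifs=motifs,
        variants=variants,
        truth=truth,
        panels=panels,
    )


# ---------------------------------------------------------------------------
# Fixture emission


def write_fixture(fix: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Emit VCF, GFF3, FASTA(+fai), motif/ancestral/map TSVs, B-value BED,
    truth TSV and a manifest with the seed and config hash."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in {
        "vcf": "panel.vcf", "gff3": "genes.gff3", "fasta": "ref.fa",
        "motifs": "motifs.tsv", "ancestral": "ancestral.tsv",
        "genetic_map": "genetic_map.tsv", "bvalues": "bvalues.bed",
        "truth": "truth.tsv", "manifest": "manifest.json",
    }.items()}

    cfg = fix.config
    n_hap_total = sum(p.n_hap for p in fix.panels.values())
    H = np.vstack([fix.panels[p].haplotypes for p in sorted(fix.panels)])
    sample_names = []
    pop_of_sample = {}
    for pname in sorted(fix.panels):
        for i in range(fix.panels[pname].n_hap // 2):
            s = f"{pname}_s{i}"
            sample_names.append(s)
            pop_of_sample[s] = pname
    sio.write_vcf(paths["vcf"], fix.variants, H, sample_names, chrom_length=len(fix.sequence))
    sio.write_gff3(paths["gff3"], fix.genes)

    with open(paths["fasta"], "w") as fh:
        fh.write(">1\n")
        for i in range(0, len(fix.sequence), 70):
            fh.write(fix.sequence[i : i + 70] + "\n")
    import pyfaidx

    pyfaidx.Faidx(str(paths["fasta"]))  # writes ref.fa.fai

    with open(paths["motifs"], "w") as fh:
        for etype in sorted(fix.motifs):
            for h in sorted(fix.motifs[etype].hexamers):
                fh.write(f"{h}\t{etype}\n")

    with open(paths["ancestral"], "w") as fh:
        for v in fix.variants:
            if v.ancestral is not None:
                fh.write(f"{v.chrom}\t{v.pos}\t{v.ancestral}\n")

    L = len(fix.sequence)
    with open(paths["genetic_map"], "w") as fh:  # uniform 1 cM/Mb
        fh.write(f"1\t1\t{1/1e6:.8f}\n")
        fh.write(f"1\t{L}\t{L/1e6:.8f}\n")

    rng = np.random.default_rng(cfg.seed + 101)
    with open(paths["bvalues"], "w") as fh:
        step = 2000
        for s in range(0, L, step):
            b = int(rng.choice(np.arange(100, 1001, 100)))
            fh.write(f"1\t{s}\t{min(s + step, L)}\t{b}\n")

    tf = fix.truth_frame()
    tf["pos"] = tf["pos0"] + 1
    cols = ["vid", "pos", "ref", "alt", "ancestral", "is_sre", "element_type",
            "inducing_allele", "disrupting_allele", "func_class",
            "skipped_exon_id", "gene_id", "motif_match", "swept"]
    sio.write_table(paths["truth"], tf[cols], comment="planted truth; pos is 1-based")

    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_variants": len(fix.variants),
        "populations": {s: pop_of_sample[s] for s in sample_names},
        "panel_note": (
            "independent haplotypes with Gaussian-copula AR(1) local LD "
            f"(adjacent-site latent correlation {cfg.ld_ar}); per-site "
            "allele counts are exact Binomial(n_hap, freq) draws"
        ),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# Focused generators for the statistical models


def confounded_strata(
    rng: np.random.Generator,
    n_strata: int = 5,
    n_per_stratum: int = 20000,
    stratum_or: float = 1.2,
    sre_fraction: tuple[float, float] = (0.1, 0.5),
    base_rate: tuple[float, float] = (0.05, 0.30),
) -> list[tuple[int, int, int, int]]:
    """2x2 counts (a, b, c, d) per background-selection stratum in which the
    within-stratum odds ratio is ``stratum_or`` everywhere, while both SRE
    membership and the high-F_ST rate rise across strata.  Pooling the strata
    therefore inflates the crude odds ratio above the common one (Simpson-type
    confounding by B-value).

    Cells: a = SRE & high-F_ST, b = SRE & not, c = non-SRE & high, d = non-SRE & not.
    """
    tables = []
    f_sre = np.linspace(*sre_fraction, n_strata)
    q0 = np.linspace(*base_rate, n_strata)
    for s in range(n_strata):
        n_sre = int(round(n_per_stratum * f_sre[s]))
        n_non = n_per_stratum - n_sre
        odds1 = stratum_or * q0[s] / (1 - q0[s])
        q1 = odds1 / (1 + odds1)
        a = int(rng.binomial(n_sre, q1))
        c = int(rng.binomial(n_non, q0[s]))
        tables.append((a, n_sre - a, c, n_non - c))
    return tables


def simulate_logistic_overlap(
    n: int,
    beta0: float,
    beta: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary SRE-overlap outcomes from the logistic model on features
    Delta = (DAF, F_ST, B-value/1000, LD extent/100), drawn on realistic
    scales.  Returns (Delta matrix n x 4, overlap 0/1 vector)."""
    D = rng.uniform(0, 1, size=n)
    F = rng.beta(0.5, 3.0, size=n)
    B = rng.uniform(0.1, 1.0, size=n)
    Lx = rng.gamma(2.0, 0.4, size=n)
    Delta = np.column_stack([D, F, B, Lx])
    eta = beta0 + Delta @ np.asarray(beta, dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(np.int8)
    return Delta, y


def simulate_two_vc_trait(
    n: int,
    m_sre: int,
    m_non: int,
    var_sre: float,
    var_non: float,
    var_e: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dosage matrices for SRE and non-SRE SNPs and a quantitative trait with
    the given variance components (per-SNP effects on standardized dosages).

    Returns (dosage_sre n x m_sre, dosage_non n x m_non, y)."""
    def dosages(m):
        p = rng.uniform(0.05, 0.95, size=m)
        return rng.binomial(2, p[None, :], size=(n, m)).astype(np.float64), p

    G_sre, p1 = dosages(m_sre)
    G_non, p2 = dosages(m_non)

    def genetic_value(G, p, var):
        Z = (G - 2 * p) / np.sqrt(2 * p * (1 - p))
        u = rng.normal(0.0, np.sqrt(var / G.shape[1]), size=G.shape[1])
        return Z @ u

    y = (
        genetic_value(G_sre, p1, var_sre)
        + genetic_value(G_non, p2, var_non)
        + rng.normal(0.0, np.sqrt(var_e), size=n)
    )
    return G_sre, G_non, y
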