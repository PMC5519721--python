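#!/usr/bin/env python
"""Annotate every fixture SNP against the hexamer motif sets with the
exon-skip geometry gate, and check the calls against the planted truth.

Reads results/fixture/, writes results/annotation.tsv.
"""

import argparse
import json
from pathlib import Path

import pyfaidx

from sre_selscan import annotate, io as sio


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixture-dir", type=Path, default=Path("results/fixture"))
    ap.add_argument("--out", type=Path, default=Path("results/annotation.tsv"))
    args = ap.parse_args()
    d = args.fixture_dir

    man = json.loads((d / "manifest.json").read_text())
    anc = sio.read_ancestral(d / "ancestral.tsv")
    _, variants = sio.read_vcf_panel(d / "panel.vcf", man["populations"], ancestral=anc)
    genes = sio.read_gene_models(d / "genes.gff3")
    motifs = sio.read_motifs(d / "motifs.tsv")
    fasta = pyfaidx.Fasta(str(d / "ref.fa"))

    ann = annotate.annotate_all(variants, genes, motifs, fasta)
    sio.write_table(args.out, ann, comment="SRE annotation; pos is 1-based")

    truth = sio.read_table(d / "truth.tsv")
    m = truth.merge(ann, on="vid", suffixes=("_t", "_a"))
    tp = int((m["is_sre_t"] & m["is_sre_a"]).sum())
    fp = int((~m["is_sre_t"] & m["is_sre_a"]).sum())
    fn = int((m["is_sre_t"] & ~m["is_sre_a"]).sum())
    print(f"annotated {len(ann)} SNPs: {int(ann['is_sre'].sum())} SRE calls")
    print(f"vs planted truth: sensitivity {tp / (tp + fn):.3f}, "
          f"false positives {fp}")
    print(f"functional-class agreement: "
          f"{(m['func_class_t'] == m['func_class_a']).mean():.3f}")
    print("wrote", args.out)


if __name__ == "__main__":
    main()
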