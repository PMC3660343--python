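#!/usr/bin/env python
"""Anchor marker sequences to the physical map through the BES set.

Aligns every marker against the BES FASTA with the built-in seed-and-extend
aligner, applies the acceptance thresholds (>=150 bp SSR / >=100 bp SNP,
identity > 95%), resolves clones to contigs or singleton BACs, and compares
the accepted anchors with the generator's embedding truth.  Also mines
candidate contig-anchored SSR loci from contigs > 1 Mb.
"""

import argparse
from pathlib import Path

import pandas as pd

from carpmap.anchoring import select_candidate_loci
from carpmap.dataio import PipelineConfig, read_fasta, read_physical_map
from carpmap.pipeline import run_anchoring

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", type=Path, default=ROOT / "scratch" / "dataset")
    args = ap.parse_args()

    cfg = PipelineConfig()
    marker_seqs = read_fasta(args.dataset / "markers.fasta")
    bes = read_fasta(args.dataset / "bes.fasta")
    pm = read_physical_map(args.dataset / "physical_map.tsv")
    res = run_anchoring(marker_seqs, bes, pm, cfg)

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    anchors = pd.DataFrame(
        [
            {"marker_id": a.marker_id, "bes_id": a.bes_id, "clone_id": a.clone_id,
             "target_kind": a.target_kind, "target_id": a.target_id,
             "accepted": a.accepted, "reason": a.reject_reason}
            for a in res.anchors
        ]
    )
    anchors.to_csv(out / "03_anchors.tsv", sep="\t", index=False)

    truth = pd.read_csv(args.dataset / "truth" / "marker_anchors.tsv", sep="\t")
    got = {(a.marker_id, a.target_id) for a in res.anchors if a.accepted}
    want = set(zip(truth.marker_id, truth.target_id))
    recall = len(got & want) / len(want)
    precision = len(got & want) / len(got) if got else 0.0

    loci = select_candidate_loci(pm, bes, cfg)
    loci.to_csv(out / "03_candidate_ssr_loci.tsv", sep="\t", index=False)

    n_acc = int(anchors.accepted.sum())
    print(f"{n_acc} accepted anchors for {anchors.marker_id.nunique()} markers "
          f"({(anchors.target_kind == 'contig').sum()} contig, "
          f"{(anchors.target_kind == 'single_bac').sum()} single-BAC)")
    print(f"recovery vs embedding truth: recall {recall:.3f}, precision {precision:.3f}")
    print(f"{len(loci)} candidate SSR loci from contigs > 1 Mb "
          f"({loci.contig_id.nunique() if len(loci) else 0} contigs)")


if __name__ == "__main__":
    main()
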