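"""Assign peaks to target genes and test auxin-induction enrichment.

Runs the proximal (TSS−1100 .. TTS+900) and distal (TSS−10 kb ..
TTS+3 kb) assignment rules, summarizes clade co-occupancy of target
genes, counts peaks within 10 kb of induced versus random genes (Welch
t-test), and tests TSS-proximal enrichment of induced genes with
Fisher's exact test.
"""

import argparse
from pathlib import Path

import numpy as np

from arfcaliper import io as aio
from arfcaliper import overlap as ov
from arfcaliper import targets


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    tf_meta = [(f"A{i}", "A") for i in range(1, 5)] + [
        (f"B{i}", "B") for i in range(1, 5)]
    peaksets = [aio.read_narrowpeak(args.simdir / f"{tf}.narrowPeak", tf, clade)
                for tf, clade in tf_meta]
    genes = aio.read_gene_table(args.simdir / "genes.bed")
    de = aio.read_expression_table(args.simdir / "expression.tsv")

    prox = targets.assign_proximal_targets(peaksets, genes)
    dist = targets.assign_distal_targets(peaksets, genes)
    prox.links.to_csv(out / "proximal_targets.tsv", sep="\t", index=False)
    dist.links.to_csv(out / "distal_targets.tsv", sep="\t", index=False)
    print(f"proximal rule: {len(prox.links)} links, "
          f"{prox.links.gene_id.nunique()} unique target genes")
    print(f"distal rule:   {len(dist.links)} links, "
          f"{dist.links.gene_id.nunique()} unique target genes")

    cons_a, _ = ov.consensus_peaks([p for p in peaksets if p.clade == "A"])
    cons_b, _ = ov.consensus_peaks([p for p in peaksets if p.clade == "B"])
    rc = ov.classify_regions(cons_a, cons_b)
    for name, ta in [("proximal", prox), ("distal", dist)]:
        summary = targets.co_occupancy_summary(ta, rc)
        summary.round(4).to_csv(out / f"co_occupancy_{name}.tsv", sep="\t")
        print(f"{name} co-occupancy: "
              f"{100 * summary.loc['both', 'fraction']:.1f}% of target genes "
              f"bound by both clades "
              f"({100 * summary.loc['both_via_shared_peak', 'fraction']:.1f}% "
              f"via a shared region)")

    strong_up = set(de.loc[de["class"] == "strong_up", "gene"])
    induced = [g for g in genes if g.gene_id in strong_up]
    rng = np.random.default_rng(args.seed + 90)
    others = [g for g in genes if g.gene_id not in strong_up]
    random_genes = [others[i] for i in
                    rng.choice(len(others), size=len(induced), replace=False)]
    counts, tests = targets.peaks_within_distance(
        {"induced": induced, "random": random_genes}, peaksets, d=10_000)
    counts.to_csv(out / "peaks_within_10kb.tsv", sep="\t", index=False)
    t_row = tests.iloc[0]
    print(f"peaks within 10 kb: induced mean {t_row.mean_a:.2f} vs random "
          f"{t_row.mean_b:.2f} (Welch t={t_row.t:.2f}, p={t_row.p:.3g})")

    odds, p, table = targets.tss_proximal_enrichment(induced, genes, peaksets,
                                                     d=1000)
    print(f"TSS-proximal enrichment of induced genes: OR={odds:.2f}, "
          f"p={p:.3g}, table={table.tolist()}")


if __name__ == "__main__":
    main()
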