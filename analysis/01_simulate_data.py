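"""Build the synthetic study dataset every later stage consumes.

Simulates a 2 Mb maize-composition genome, plants three core-motif
grammars (clade-A-like DR7, ER11, and clade-B-like IR2 elements),
derives 4 clade A + 4 clade B peak families with controlled co-binding,
gene models, an auxin-response DE table biased toward TSS-proximal
clade-A binding, tissue open-chromatin sets, and a Tn5 integration
track. Everything is written as standard flat files under
results/sim/ so downstream stages exercise the package's readers.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from arfcaliper import io as aio
from arfcaliper import simulate
from arfcaliper.core import SignalTrack

GENOME_BP = 2_000_000
GC = 0.47


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    s = args.seed

    genome = simulate.simulate_genome(GENOME_BP, GC, seed=s)
    plan = [
        simulate.PlantSpec("DR", 7, 700),   # DR5-like direct repeats
        simulate.PlantSpec("ER", 11, 500),  # everted repeats (ER7 in 6-mer naming)
        simulate.PlantSpec("IR", 2, 700),   # inverted repeats
    ]
    genome, truth = simulate.plant_motif_architecture(genome, plan, seed=s + 1)
    aio.write_fasta(genome, out / "genome.fa")
    truth.elements.to_csv(out / "planted_elements.tsv", sep="\t", index=False)

    # clade A binds DR/ER elements; clade B mainly IR elements plus a
    # shared subset of the DR pool, which supplies cross-clade sharing
    el = truth.elements
    dr = el[el.orientation_class == "DR"]
    t_a = simulate.TruthTable(
        el[el.orientation_class.isin(["DR", "ER"])].reset_index(drop=True))
    t_b = simulate.TruthTable(
        pd.concat([el[el.orientation_class == "IR"], dr.head(250)])
        .sort_values("start").reset_index(drop=True))
    ps_a, truth_a = simulate.simulate_peak_families(
        t_a, genome, 4, 0, within_clade_share=0.8, cross_clade_share=0.0,
        signal_beta=3.0, noise_sd=0.25, seed=s + 2)
    ps_b, truth_b = simulate.simulate_peak_families(
        t_b, genome, 0, 4, within_clade_share=0.75, cross_clade_share=0.0,
        signal_beta=3.0, noise_sd=0.25, seed=s + 3)
    for ps in ps_a + ps_b:
        aio.write_narrowpeak(ps, out / f"{ps.tf_id}.narrowPeak")
    n_a = sum(len(p) for p in ps_a)
    n_b = sum(len(p) for p in ps_b)
    print(f"peak families: {n_a} clade A peaks, {n_b} clade B peaks across 8 TFs")

    genes = simulate.simulate_gene_annotation(GENOME_BP, 1200, 900, seed=s + 4)
    aio.write_gene_table(genes, out / "genes.bed")

    de = simulate.simulate_expression_response(
        genes, ps_a, prox_effect=6.0, n_up=150, n_down=100, seed=s + 5)
    de.to_csv(out / "expression.tsv", sep="\t", index=False)
    print(f"expression table: {(de.log2fc > 1).sum()} strongly induced genes")

    oc_sets, planted_specific = simulate.simulate_open_chromatin(
        GENOME_BP, ["ear", "tassel", "leaf"], n_common=250,
        n_specific_per_tissue=60, region_width=400, seed=s + 6)
    for tissue, regions in oc_sets.items():
        aio.write_bed(regions, out / f"oc_{tissue}.bed")
    for tissue, regions in planted_specific.items():
        aio.write_bed(regions, out / f"oc_{tissue}_specific_truth.bed")

    # Tn5 integration track: flat 1x background with hot cores only in
    # the ear-specific regions, so the genome stays mostly quiescent and
    # the 25-fold density rule has something real to find
    rng = np.random.default_rng(s + 7)
    dense = np.ones(GENOME_BP)
    for iv in planted_specific["ear"]:
        core = (iv.start + iv.end) // 2
        dense[core - 100 : core + 100] = rng.uniform(40, 90)
    change = np.flatnonzero(np.diff(dense)) + 1
    bounds = np.concatenate([[0], change, [GENOME_BP]])
    track = SignalTrack({"chr1": (bounds[:-1], bounds[1:], dense[bounds[:-1]])})
    aio.write_bedgraph(track, out / "tn5_integration.bedGraph")

    print(f"wrote synthetic study dataset to {out}/")


if __name__ == "__main__":
    main()
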