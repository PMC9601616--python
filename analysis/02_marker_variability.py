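"""Per-marker variability statistics on the generated study.

Reads the per-marker FASTA + metadata written by 01_simulate_dataset.py and
tabulates, for each single marker: aligned length, SNP and indel site counts,
their percentages of the aligned length, and mean intra-/interspecific K2P
divergence — the usual single-barcode variability summary.

Run from the repository root:
    python analysis/02_marker_variability.py --data results/data --out results
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import barcodegap as bg
from barcodegap.distances import write_variability_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=str, default="results/data")
    ap.add_argument("--out", type=str, default="results")
    args = ap.parse_args()

    data = Path(args.data)
    species = bg.SpeciesLabelMap.from_tsv(data / "metadata.tsv")
    stats = []
    for fasta in sorted(data.glob("*.fasta")):
        aln = bg.read_alignment_fasta(fasta, fasta.stem, species)
        mat = bg.distance_matrix(aln, "k2p")
        part = bg.partition_by_species(mat, species)
        stats.append(bg.variability_stats(aln, mat, part))

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    write_variability_table(stats, out / "variability.tsv")

    header = (f"{'marker':8s} {'bp':>5s} {'SNPs':>5s} {'%SNP':>6s} "
              f"{'indels':>6s} {'%var':>6s} {'intra':>9s} {'inter':>9s}")
    print(header)
    for s in stats:
        print(f"{s.marker:8s} {s.length_bp:5d} {s.n_snps:5d} {s.pct_snp:6.2f} "
              f"{s.n_indels:6d} {s.pct_variable:6.2f} "
              f"{s.mean_intra:9.5f} {s.mean_inter:9.4f}")
    most = max(stats, key=lambda s: s.mean_inter)
    least = min(stats, key=lambda s: s.mean_inter)
    print(f"\nmost variable marker: {most.marker} "
          f"(mean inter {100 * most.mean_inter:.2f}%); most conserved: "
          f"{least.marker} ({100 * least.mean_inter:.2f}%)")
    print(f"table written to {out / 'variability.tsv'}")


if __name__ == "__main__":
    main()
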