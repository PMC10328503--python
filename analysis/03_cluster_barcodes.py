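"""Error-correct the raw barcode counts by greedy Levenshtein clustering.

Sequencing errors scatter each true barcode into low-count neighbors; the
abundance-greedy clusterer (radius 2, merge ratio 5) folds that error
cloud back onto its centroid, then drops centroids that are not 15 bp.
Compares the corrected set against the simulator's true array barcodes.

Run after 02:  python analysis/03_cluster_barcodes.py
"""

from pathlib import Path

import pandas as pd

from tardis_barseq import ClusterParams, cluster_barcodes

PROC = Path("results/analysis/process")
SIM = Path("results/analysis/sim")
OUT = Path("results/analysis/cluster")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    raw = pd.read_csv(PROC / "raw_counts.tsv", sep="\t")
    counts = dict(zip(raw["barcode"], raw["count"]))
    result = cluster_barcodes(counts, ClusterParams(radius=2, merge_ratio=5.0,
                                                    required_length=15))
    mass_in = sum(counts.values())
    print(f"clustering: {len(counts)} raw -> {len(result.centroids)} centroids, "
          f"{len(result.dropped)} dropped for length; mass {mass_in} -> "
          f"{result.total} (conserved: {mass_in == result.total})")

    truth = set(pd.read_csv(SIM / "array_sidecar.tsv", sep="\t")["barcode"])
    centroids = set(result.centroids)
    print(f"vs truth: {len(centroids & truth)} true centroids recovered, "
          f"{len(centroids - truth)} spurious, {len(truth - centroids)} missed")

    with open(OUT / "corrected_counts.tsv", "w") as fh:
        fh.write("barcode\tcount\n")
        for b in sorted(result.centroids, key=lambda b: (-result.centroids[b], b)):
            fh.write(f"{b}\t{result.centroids[b]}\n")
    with open(OUT / "cluster_map.tsv", "w") as fh:
        fh.write("member\tcentroid\tcount\n")
        for m in sorted(result.assignments):
            fh.write(f"{m}\t{result.assignments[m]}\t{counts[m]}\n")
    print(f"wrote {OUT}/corrected_counts.tsv and cluster_map.tsv")


if __name__ == "__main__":
    main()
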