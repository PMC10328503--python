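"""Simulate the full generative cascade and write every stage snapshot.

Builds a barcode library from the degenerate 15-mer template, amplifies it
through 10 cycles of heterogeneous-efficiency PCR (the jackpotting stage),
founds an extrachromosomal array (zero-truncated Poisson copy numbers),
draws F1 integrants, and emits UMI-tagged 87 bp reads as FASTQ with a
ground-truth sidecar.  Outputs go to results/analysis/sim/.

Run:  python analysis/01_simulate_dataset.py [seed]
"""

import sys
from pathlib import Path

from tardis_barseq import (
    AmpliconLayout,
    BarcodeTemplate,
    draw_integrants,
    enumerate_space,
    form_array,
    generate_reads,
    sample_library,
    simulate_pcr,
    stage_rngs,
)

OUT = Path("results/analysis/sim")


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rngs = stage_rngs(seed, 5)
    template = BarcodeTemplate()
    print(f"template {template.pattern}: {len(template.free_positions)} free "
          f"positions, space {enumerate_space(template):,}")

    library = sample_library(template, 200_000, rngs[0])
    print(f"library: {library.n_unique:,} unique barcodes from 200,000 molecules")

    mix = simulate_pcr(library, cycles=10, efficiency_beta=(8.0, 2.0), seed=rngs[1])
    print(f"injection mix after 10 PCR cycles: total {mix.total:.3g} molecules")

    array = form_array(mix, m=1319, copy_lambda=3.0, jackpot_prob=0.05,
                       jackpot_factor_log_sd=1.0, seed=rngs[2])
    print(f"array: {array.n_unique} founders, mean copy number "
          f"{array.total / array.n_unique:.2f}")

    integrants = draw_integrants(array, 50_000, seed=rngs[3])
    print(f"integrants: {integrants.total:.0f} draws, {integrants.n_unique} unique")

    layout = AmpliconLayout(error_rate=0.001, duplicate_rate=0.5,
                            quality_model=(36.0, 3.0, 0.02))
    n = generate_reads(array, layout, depth=30_000, fastq_path=OUT / "array.fastq",
                       sidecar_path=OUT / "array_sidecar.tsv", seed=rngs[4])
    print(f"sequencing: wrote {n} reads (30,000 molecules, ~0.5 duplicates each)")

    for pool, name in ((library, "library"), (mix, "injection_mix"),
                       (array, "array"), (integrants, "integrants")):
        pool.to_tsv(OUT / f"pool_{name}.tsv")
    print(f"stage snapshots in {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
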