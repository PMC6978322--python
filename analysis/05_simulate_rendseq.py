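#!/usr/bin/env python
"""Generate the synthetic genome and end-enriched count tracks.

Builds a block-structured annotation (operon-like runs of 2-5
same-strand genes, each run closed by an intrinsic terminator), plants
a 3' sense end-count spike at every terminator and a 5' antisense spike
at a fraction of them, over i.i.d. Poisson background.  Writes the four
bedGraph tracks, BED6 terminators, GFF3 genes, FASTA sequence to
scratch/ and the truth table to results/.
"""

import sys
from pathlib import Path

from termcycle import io
from termcycle.simulate import (
    RendSimConfig,
    simulate_rendseq,
    synthetic_genome_annotation,
    synthetic_genome_sequence,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
root = Path(__file__).resolve().parents[1]
outdir = root / "scratch" / "rendseq"

genes, terms, G = synthetic_genome_annotation(n_blocks=60, seed=SEED)
cfg = RendSimConfig(
    genome_length=G,
    genes=list(genes[["start", "end", "strand"]].itertuples(index=False)),
    terminators=[tuple(x) for x in
                 terms[["position", "strand"]].itertuples(index=False)],
    background_rate=0.2,
    fraction_terminators_with_antisense=0.2,
    seed=SEED,
)
tracks, truth = simulate_rendseq(cfg)

io.write_end_tracks(tracks, outdir)
io.write_bed6(terms, outdir / "terminators.bed")
io.write_gff3(genes, outdir / "genes.gff3")
seq = synthetic_genome_sequence(
    G,
    planted_motifs=[
        # the antisense start site sits on the strand opposite the terminator
        (int(row["antisense_position"]),
         "-" if row["strand"] == "+" else "+",
         "GTATAAT")
        for _, row in truth[truth["has_antisense"]].iterrows()
    ],
    seed=SEED,
)
io.write_fasta(seq, outdir / "genome.fasta")
io.write_table(truth, root / "results" / "rendseq_truth.tsv", {"seed": SEED})

n_as = int(truth["has_antisense"].sum())
print(f"synthetic genome: {G} bp, {len(genes)} genes, {len(terms)} terminators")
print(f"  antisense 5' peaks planted at {n_as}/{len(terms)} terminators "
      f"(config fraction {cfg.fraction_terminators_with_antisense})")
print(f"  background: Poisson({cfg.background_rate}) per nt per track")
print(f"  tracks/annotation -> {outdir}")
print(f"  truth table -> {root / 'results' / 'rendseq_truth.tsv'}")
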