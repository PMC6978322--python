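#!/usr/bin/env python
"""Terminator-centric antisense-initiation analysis of the end tracks.

Filters terminators to those flanked by same-orientation genes, scores
sense termination (Delta_S) and nearby antisense initiation (Delta_AS,
z > 12) per terminator, builds the terminator-relative distance
profile, runs the 100-replicate constrained random-location control,
and measures the information content of the sequence around antisense
start sites.  Writes all tables to results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from termcycle import io
from termcycle.rendseq import (
    Z_THRESHOLD,
    control_replicates,
    distance_profile,
    filter_terminators,
    terminator_peak_table,
    tss_information_content,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
root = Path(__file__).resolve().parents[1]
d = root / "scratch" / "rendseq"
results = root / "results"

genes = io.read_gff3(d / "genes.gff3")
terms = io.read_bed6(d / "terminators.bed")
seq = io.read_fasta(d / "genome.fasta")
tracks = io.read_end_tracks(
    d / "five_plus.bedgraph", d / "five_minus.bedgraph",
    d / "three_plus.bedgraph", d / "three_minus.bedgraph",
    genome_length=len(seq),
)

term_set = filter_terminators(terms, genes)
n_eligible = int(term_set["eligible"].sum())
print(f"{n_eligible}/{len(term_set)} terminators flanked by same-orientation genes")

peaks = terminator_peak_table(tracks, term_set)
io.write_table(peaks, results / "terminator_peaks.tsv", {"seed": SEED})
strong = peaks[peaks["antisense_peak_z"] > Z_THRESHOLD]
print(f"{len(strong)}/{len(peaks)} eligible terminators show a strong "
      f"(z > {Z_THRESHOLD:.0f}) antisense 5' peak within 500 nt")
if len(strong):
    print(f"  their Delta_S: {strong['Delta_S'].mean():.2f} +/- "
          f"{strong['Delta_S'].std():.2f} log2 units; "
          f"Delta_AS: {strong['Delta_AS'].mean():.2f} +/- "
          f"{strong['Delta_AS'].std():.2f}")

profile = distance_profile(tracks, term_set)
io.write_table(profile, results / "distance_profile.tsv", {"seed": SEED})
center = profile.loc[profile["distance"] == 0].iloc[0]
print(f"terminator-proximal antisense fraction: {center['fraction']:.3f} "
      f"+/- {center['sem']:.3f}")

controls = control_replicates(
    tracks, genes, terms, n_locations=n_eligible, n_replicates=100, seed=SEED
)
io.write_table(controls, results / "control_replicates.tsv", {"seed": SEED})
p_emp = float(np.mean(controls["fraction"] >= center["fraction"]))
print(f"100 constrained random-location replicates: max central fraction "
      f"{controls['fraction'].max():.3f}; empirical p = {p_emp:.2f}"
      + (" (< 0.01)" if p_emp < 0.01 else ""))

strong_peaks = strong[["antisense_peak_position", "strand"]].rename(
    columns={"antisense_peak_position": "position"}
)
# the antisense TSS lies on the strand opposite its terminator
strong_peaks["strand"] = strong_peaks["strand"].map({"+": "-", "-": "+"})
if len(strong_peaks) >= 2:
    info, pwm = tss_information_content(seq, strong_peaks)
    out = pd.DataFrame({"offset": np.arange(-3, 4), "information_bits": info})
    io.write_table(out, results / "tss_information.tsv", {"seed": SEED})
    io.write_table(pwm, results / "tss_pwm.tsv", {"seed": SEED})
    print("TSS window information content (bits, -3..+3): "
          + " ".join(f"{v:.2f}" for v in info))
print(f"  tables -> {results}")
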