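"""Readers and writers for the plain-text formats used by the pipeline.

Traces travel as delimited text (columns ``trace_id, time_s, I_dna,
I_rnap, I_probe``), end-count tracks as bedGraph (wig also accepted on
read), terminators as BED6, gene annotations as GFF3 and genome
sequence as FASTA.  Genomic coordinates are 0-based half-open in
memory; 1-based formats are converted at the boundary.  Every table
written here carries a comment header with the configuration hash so
outputs can be traced back to the run that made them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calibration import IntensityTrace
from .rendseq import EndTracks

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "write_traces",
    "read_traces",
    "write_ground_truth",
    "write_bedgraph",
    "read_bedgraph",
    "read_wig",
    "read_end_tracks",
    "write_end_tracks",
    "write_bed6",
    "read_bed6",
    "write_gff3",
    "read_gff3",
    "write_fasta",
    "read_fasta",
    "load_config",
]

TRACE_COLUMNS = ["trace_id", "time_s", "I_dna", "I_rnap", "I_probe"]


def config_hash(params: object) -> str:
    """Short stable hash of a parameter mapping/dataclass repr."""
    text = json.dumps(params, sort_keys=True, default=repr)
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a TSV with ``# key=value`` comment headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# single-molecule traces
# ---------------------------------------------------------------------------


def write_traces(
    traces: list[IntensityTrace], path: str | Path, meta: dict | None = None
) -> None:
    frames = []
    for i, tr in enumerate(traces):
        tid = tr.trace_id or f"mol{i:04d}"
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": tid,
                    "time_s": tr.time,
                    "I_dna": tr.I_dna,
                    "I_rnap": tr.I_rnap,
                    "I_probe": tr.I_probe,
                    "rnap_present": (
                        tr.rnap_present.astype(int)
                        if tr.rnap_present is not None
                        else 1
                    ),
                    "probe_present": (
                        tr.probe_present.astype(int)
                        if tr.probe_present is not None
                        else 0
                    ),
                }
            )
        )
    write_table(pd.concat(frames, ignore_index=True), path, meta)


def read_traces(path: str | Path) -> list[IntensityTrace]:
    """Parse a trace table back into per-molecule records.

    Malformed rows (missing columns, non-numeric fields) and
    non-monotone time within a trace raise ``ValueError`` naming the
    offending trace and line.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in TRACE_COLUMNS[1:]:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]
            raise ValueError(f"{path}: non-numeric {col} at lines {lines}")
        df[col] = pd.to_numeric(df[col])
    traces = []
    for tid, grp in df.groupby("trace_id", sort=False):
        t = grp["time_s"].to_numpy()
        if t.size > 1 and not np.all(np.diff(t) > 0):
            bad_i = int(np.nonzero(np.diff(t) <= 0)[0][0])
            line = int(grp.index[bad_i + 1]) + 2
            raise ValueError(
                f"{path}: trace {tid}: non-monotone time at line {line}"
            )
        traces.append(
            IntensityTrace(
                time=t,
                I_dna=grp["I_dna"].to_numpy(),
                I_rnap=grp["I_rnap"].to_numpy(),
                I_probe=grp["I_probe"].to_numpy(),
                rnap_present=(
                    grp["rnap_present"].to_numpy().astype(bool)
                    if "rnap_present" in grp
                    else None
                ),
                probe_present=(
                    grp["probe_present"].to_numpy().astype(bool)
                    if "probe_present" in grp
                    else None
                ),
                trace_id=str(tid),
            )
        )
    return traces


def write_ground_truth(truths, path: str | Path, meta: dict | None = None) -> None:
    """Per-molecule truth sidecar (rates, event times, behavior flags)."""
    rows = []
    for i, gt in enumerate(truths):
        rows.append(
            {
                "trace_id": f"mol{i:04d}",
                "lam": gt.lam,
                "r": gt.r,
                "t_start": gt.t_start,
                "t_T": gt.t_T,
                "retained": int(gt.retained),
                "antisense": int(gt.antisense),
                "sense_reinit": int(gt.sense_reinit),
                "dissociation_time": gt.dissociation_time,
                "bleach_time": gt.bleach_time,
                "secondary_start": gt.secondary_start,
                "secondary_end": gt.secondary_end,
            }
        )
    write_table(pd.DataFrame(rows), path, meta)


# ---------------------------------------------------------------------------
# genomic tracks and annotations
# ---------------------------------------------------------------------------


def write_bedgraph(
    track: np.ndarray, path: str | Path, chrom: str = "synthetic"
) -> None:
    """Run-length-encoded bedGraph (0-based half-open intervals)."""
    track = np.asarray(track)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    change = np.nonzero(np.diff(track))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [track.size]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            v = track[s]
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path: str | Path, genome_length: int) -> np.ndarray:
    """Read a bedGraph file into a dense count vector."""
    track = np.zeros(genome_length, dtype=np.int64)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 bedGraph fields")
            start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            if value < 0:
                raise ValueError(f"{path}:{ln}: negative count {value}")
            if end > genome_length:
                raise ValueError(f"{path}:{ln}: interval beyond genome length")
            track[start:end] = np.int64(value)
    return track


def read_wig(path: str | Path, genome_length: int) -> np.ndarray:
    """Read fixedStep/variableStep wig (1-based) into a 0-based vector."""
    track = np.zeros(genome_length, dtype=np.int64)
    mode = None
    pos = 0
    step = 1
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                mode = "fixed"
                pos = int(fields["start"]) - 1  # 1-based -> 0-based
                step = int(fields.get("step", 1))
                continue
            if line.startswith("variableStep"):
                mode = "variable"
                continue
            if mode == "fixed":
                v = float(line)
                if v < 0:
                    raise ValueError(f"{path}:{ln}: negative count")
                track[pos] = np.int64(v)
                pos += step
            elif mode == "variable":
                p_str, v_str = line.split()[:2]
                v = float(v_str)
                if v < 0:
                    raise ValueError(f"{path}:{ln}: negative count")
                track[int(p_str) - 1] = np.int64(v)
            else:
                raise ValueError(f"{path}:{ln}: data before step declaration")
    return track


def _read_track(path: str | Path, genome_length: int) -> np.ndarray:
    text = Path(path).read_text().lstrip()
    if text.startswith(("fixedStep", "variableStep")) or "Step" in text.split("\n")[0]:
        return read_wig(path, genome_length)
    return read_bedgraph(path, genome_length)


def read_end_tracks(
    five_plus: str | Path,
    five_minus: str | Path,
    three_plus: str | Path,
    three_minus: str | Path,
    genome_length: int,
) -> EndTracks:
    """Assemble the four strand-specific end tracks from disk."""
    return EndTracks(
        five_plus=_read_track(five_plus, genome_length),
        five_minus=_read_track(five_minus, genome_length),
        three_plus=_read_track(three_plus, genome_length),
        three_minus=_read_track(three_minus, genome_length),
        genome_length=genome_length,
        convention="0-based",
    )


def write_end_tracks(
    tracks: EndTracks, outdir: str | Path, chrom: str = "synthetic"
) -> dict[str, Path]:
    outdir = Path(outdir)
    paths = {}
    for name in ("five_plus", "five_minus", "three_plus", "three_minus"):
        p = outdir / f"{name}.bedgraph"
        write_bedgraph(getattr(tracks, name), p, chrom)
        paths[name] = p
    return paths


def write_bed6(
    terminators: pd.DataFrame, path: str | Path, chrom: str = "synthetic"
) -> None:
    """Terminators as BED6: single-nt intervals at the 3'-end position."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, row in terminators.iterrows():
            name = row.get("name", f"term{i:03d}")
            fh.write(
                f"{chrom}\t{int(row['position'])}\t{int(row['position']) + 1}"
                f"\t{name}\t0\t{row['strand']}\n"
            )


def read_bed6(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 BED fields")
            rows.append(
                {"name": parts[3], "position": int(parts[1]), "strand": parts[5]}
            )
    return pd.DataFrame(rows)


def write_gff3(
    genes: pd.DataFrame, path: str | Path, chrom: str = "synthetic"
) -> None:
    """Genes as GFF3 (converts half-open 0-based to 1-based inclusive)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, row in genes.iterrows():
            gid = row.get("gene_id", f"gene{i:04d}")
            fh.write(
                f"{chrom}\ttermcycle\tgene\t{int(row['start']) + 1}"
                f"\t{int(row['end'])}\t.\t{row['strand']}\t.\tID={gid}\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Gene features from GFF3 as a (start, end, strand) table, 0-based."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene", order_by="start"):
        rows.append(
            {
                "gene_id": feat.id,
                "start": feat.start - 1,  # GFF is 1-based inclusive
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    return pd.DataFrame(rows)


def write_fasta(sequence: str, path: str | Path, name: str = "synthetic") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_fasta(path: str | Path) -> str:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {"run", "traces", "rendseq"}
_KNOWN_RUN_KEYS = {"seed", "outdir", "log_level", "n_molecules", "t_censor"}


def load_config(path: str | Path) -> dict[str, dict[str, str]]:
    """Parse a ``[section]`` / ``key=value`` run configuration.

    Section names and the keys of ``[run]`` are validated here; keys of
    the ``[traces]`` and ``[rendseq]`` sections are validated against
    the simulator config fields by the pipeline.  Unknown sections or
    run keys raise ``ValueError``.
    """
    sections: dict[str, dict[str, str]] = {}
    current = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                if current not in _KNOWN_SECTIONS:
                    raise ValueError(f"{path}:{ln}: unknown section [{current}]")
                sections[current] = {}
                continue
            if "=" not in line or current is None:
                raise ValueError(f"{path}:{ln}: expected key=value inside a section")
            key, value = (s.strip() for s in line.split("=", 1))
            if current == "run" and key not in _KNOWN_RUN_KEYS:
                raise ValueError(f"{path}:{ln}: unknown run key {key!r}")
            sections[current][key] = value
    return sections
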