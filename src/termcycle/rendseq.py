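"""Terminator-centric statistics on end-enriched sequencing tracks.

End-enriched RNA sequencing (Rend-seq) maps transcript 5' and 3' ends
genome-wide on both strands.  Intrinsic termination shows up as a spike
of 3' ends on the sense strand at the terminator; antisense secondary
initiation predicts a nearby spike of 5' ends on the opposite strand.
This module quantifies both:

* ``Delta_S = log2(k_max)`` where ``k_max`` is the peak 3' sense count
  in a 10 nt region around the terminator;
* ``Delta_AS = log2(k_max2)`` where ``k_max2`` is the peak 5' antisense
  count within +/-500 nt;
* peaks are scored by a z-score against the local flank (z > 12 selects
  strong peaks);
* a distance profile gives the fraction of terminators with a strong
  antisense peak in 200-nt windows at increasing distances, compared
  against a constrained random-location negative control;
* the information content of the sequence around antisense peaks
  measures promoter-like sequence bias at the start site.

Coordinates are 0-based half-open throughout; converters in
:mod:`termcycle.io` handle 1-based wig input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EndTracks",
    "filter_terminators",
    "compute_delta_S",
    "compute_delta_AS",
    "peak_zscore",
    "zscore_track",
    "terminator_peak_table",
    "distance_profile",
    "sample_control_locations",
    "control_replicates",
    "tss_information_content",
    "Z_THRESHOLD",
]

#: z-score above which a 5' antisense peak counts as strong
Z_THRESHOLD = 12.0


@dataclass
class EndTracks:
    """Strand-specific 5'/3' end-count vectors over one genome."""

    five_plus: np.ndarray
    five_minus: np.ndarray
    three_plus: np.ndarray
    three_minus: np.ndarray
    genome_length: int
    convention: str = "0-based"

    def __post_init__(self) -> None:
        for name in ("five_plus", "five_minus", "three_plus", "three_minus"):
            v = np.asarray(getattr(self, name))
            if v.size != self.genome_length:
                raise ValueError(f"{name} length {v.size} != genome {self.genome_length}")
            if np.any(v < 0):
                raise ValueError(f"{name} contains negative counts")
            setattr(self, name, v.astype(np.int64))

    def five(self, strand: str) -> np.ndarray:
        return self.five_plus if strand == "+" else self.five_minus

    def three(self, strand: str) -> np.ndarray:
        return self.three_plus if strand == "+" else self.three_minus


def _opposite(strand: str) -> str:
    return "-" if strand == "+" else "+"


def filter_terminators(
    terminators: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Flag terminators whose flanking genes share their orientation.

    5' peak shadows near convergent gene ends can mimic antisense
    initiation, so the analysis keeps only terminators for which the
    nearest gene on each side is annotated in the same orientation as
    the terminator itself.

    Parameters
    ----------
    terminators:
        Columns ``position`` and ``strand`` (plus any carried through).
    genes:
        Columns ``start``, ``end`` (0-based half-open) and ``strand``.

    Returns
    -------
    DataFrame
        The terminator table with an added boolean ``eligible`` column;
        terminators lacking a gene on either side are ineligible.
    """
    g = genes.sort_values("start").reset_index(drop=True)
    starts = g["start"].to_numpy()
    ends = g["end"].to_numpy()
    strands = g["strand"].to_numpy()
    out = terminators.copy().reset_index(drop=True)
    eligible = []
    for pos, strand in zip(out["position"], out["strand"]):
        left = np.nonzero(ends <= pos)[0]
        right = np.nonzero(starts >= pos)[0]
        if left.size == 0 or right.size == 0:
            eligible.append(False)
            continue
        left_strand = strands[left[np.argmax(ends[left])]]
        right_strand = strands[right[np.argmin(starts[right])]]
        eligible.append(left_strand == strand and right_strand == strand)
    out["eligible"] = eligible
    return out


def compute_delta_S(
    tracks: EndTracks, position: int, strand: str, window: int = 10
) -> tuple[int, float, int]:
    """Sense-termination magnitude at one terminator.

    ``k_max`` is the largest 3' end count on the terminator strand in a
    centered window of +/-(window//2) nt (inclusive) and
    ``Delta_S = log2(k_max)``.  Ties resolve to the leftmost genomic
    coordinate; ``k_max = 0`` yields ``Delta_S = nan`` (the terminator
    is then excluded from peak-height scatters downstream).

    Returns (k_max, Delta_S, peak_position).
    """
    half = window // 2
    lo = max(position - half, 0)
    hi = min(position + half + 1, tracks.genome_length)
    if lo >= hi:
        raise ValueError("window outside genome")
    seg = tracks.three(strand)[lo:hi]
    k_max = int(seg.max())
    peak_pos = lo + int(np.argmax(seg))
    delta = math.log2(k_max) if k_max >= 1 else math.nan
    return k_max, delta, peak_pos


def compute_delta_AS(
    tracks: EndTracks, position: int, strand: str, halfwidth: int = 500
) -> tuple[int, float, int, float]:
    """Antisense-initiation magnitude near one terminator.

    ``k_max2`` is the largest 5' end count on the strand opposite the
    terminator within +/-halfwidth nt (inclusive) and
    ``Delta_AS = log2(k_max2)``.  The returned distance is signed in
    the terminator's reading direction (positive = downstream of the
    terminator).

    Returns (k_max2, Delta_AS, peak_position, distance).
    """
    lo = max(position - halfwidth, 0)
    hi = min(position + halfwidth + 1, tracks.genome_length)
    if lo >= hi:
        raise ValueError("window outside genome")
    seg = tracks.five(_opposite(strand))[lo:hi]
    k_max2 = int(seg.max())
    peak_pos = lo + int(np.argmax(seg))
    if k_max2 < 1:
        return 0, math.nan, -1, math.nan
    dist = float(peak_pos - position if strand == "+" else position - peak_pos)
    return k_max2, math.log2(k_max2), peak_pos, dist


def peak_zscore(
    track: np.ndarray,
    position: int,
    flank: int = 50,
    exclusion: int = 2,
) -> float:
    """z-score of one position against its local flank.

    The flank comprises positions within ``flank`` nt on each side,
    excluding the center +/-``exclusion`` nt (so a multi-nt peak does
    not inflate its own background).  The flank SD is floored at the
    Poisson SD of the flank mean, sqrt(max(mean, 1)), which keeps flat
    tracks at z = 0 instead of dividing by zero.
    """
    track = np.asarray(track)
    n = track.size
    lo = max(position - flank, 0)
    hi = min(position + flank + 1, n)
    idx = np.arange(lo, hi)
    keep = np.abs(idx - position) > exclusion
    flank_vals = track[idx[keep]]
    if flank_vals.size == 0:
        raise ValueError("empty flank window")
    mean = float(flank_vals.mean())
    sd = float(flank_vals.std())
    sd = max(sd, math.sqrt(max(mean, 1.0)))
    return (float(track[position]) - mean) / sd


def zscore_track(
    track: np.ndarray, flank: int = 50, exclusion: int = 2
) -> np.ndarray:
    """Vectorized :func:`peak_zscore` over every genome position.

    Uses cumulative sums for the windowed flank mean/SD; windows are
    truncated at the genome edges, matching the per-position function.
    """
    x = np.asarray(track, dtype=float)
    n = x.size
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    pos = np.arange(n)

    def win_sums(h):
        lo = np.clip(pos - h, 0, n)
        hi = np.clip(pos + h + 1, 0, n)
        return c1[hi] - c1[lo], c2[hi] - c2[lo], (hi - lo).astype(float)

    s1_out, s2_out, n_out = win_sums(flank)
    s1_in, s2_in, n_in = win_sums(exclusion)
    s1, s2, cnt = s1_out - s1_in, s2_out - s2_in, n_out - n_in
    mean = s1 / cnt
    var = np.maximum(s2 / cnt - mean * mean, 0.0)
    sd = np.maximum(np.sqrt(var), np.sqrt(np.maximum(mean, 1.0)))
    return (x - mean) / sd


def terminator_peak_table(
    tracks: EndTracks,
    terminators: pd.DataFrame,
    window: int = 10,
    halfwidth: int = 500,
    flank: int = 50,
    exclusion: int = 2,
) -> pd.DataFrame:
    """Per-terminator Delta_S / Delta_AS summary.

    Operates on the eligible subset when an ``eligible`` column is
    present.  The antisense peak z-score is evaluated on the opposite
    strand 5' track at the ``k_max2`` position.
    """
    rows = []
    terms = terminators
    if "eligible" in terms.columns:
        terms = terms[terms["eligible"]]
    for _, t in terms.iterrows():
        pos, strand = int(t["position"]), t["strand"]
        k_max, d_s, s_pos = compute_delta_S(tracks, pos, strand, window)
        k_max2, d_as, as_pos, dist = compute_delta_AS(tracks, pos, strand, halfwidth)
        z = (
            peak_zscore(tracks.five(_opposite(strand)), as_pos, flank, exclusion)
            if as_pos >= 0
            else math.nan
        )
        rows.append(
            {
                "position": pos,
                "strand": strand,
                "k_max": k_max,
                "Delta_S": d_s,
                "sense_peak_position": s_pos,
                "k_max2": k_max2,
                "Delta_AS": d_as,
                "antisense_peak_position": as_pos,
                "antisense_peak_z": z,
                "antisense_distance": dist,
            }
        )
    return pd.DataFrame(rows)


def _window_has_peak(z: np.ndarray, lo: int, hi: int, threshold: float) -> bool:
    return bool(np.any(z[lo:hi] > threshold))


def distance_profile(
    tracks: EndTracks,
    locations: pd.DataFrame,
    bin_width: int = 200,
    max_distance: int = 2000,
    z_threshold: float = Z_THRESHOLD,
    flank: int = 50,
    exclusion: int = 2,
) -> pd.DataFrame:
    """Fraction of locations with a strong antisense peak vs distance.

    For each signed distance d (multiples of ``bin_width`` from
    -max_distance to +max_distance, oriented along each location's
    strand), a ``bin_width``-wide window centered d nt from the
    location is searched for any opposite-strand 5' position with
    z-score above ``z_threshold``.  Locations whose window would leave
    the genome are dropped from that bin's denominator.

    Returns a DataFrame with columns distance, fraction, sem, n.
    """
    locs = locations
    if "eligible" in locs.columns:
        locs = locs[locs["eligible"]]
    if len(locs) == 0:
        raise ValueError("no eligible locations")
    z_by_strand = {
        "+": zscore_track(tracks.five_plus, flank, exclusion),
        "-": zscore_track(tracks.five_minus, flank, exclusion),
    }
    G = tracks.genome_length
    half = bin_width // 2
    centers = np.arange(-max_distance, max_distance + 1, bin_width)
    rows = []
    for d in centers:
        hits = 0
        n = 0
        for pos, strand in zip(locs["position"], locs["strand"]):
            genomic_d = d if strand == "+" else -d
            c = int(pos) + int(genomic_d)
            lo, hi = c - half, c + half
            if lo < 0 or hi > G:
                continue
            n += 1
            if _window_has_peak(z_by_strand[_opposite(strand)], lo, hi, z_threshold):
                hits += 1
        if n == 0:
            rows.append({"distance": int(d), "fraction": math.nan, "sem": math.nan, "n": 0})
        else:
            p = hits / n
            rows.append(
                {
                    "distance": int(d),
                    "fraction": p,
                    "sem": math.sqrt(p * (1 - p) / n),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def sample_control_locations(
    genes: pd.DataFrame,
    terminators: pd.DataFrame,
    n: int,
    min_terminator_distance: int = 700,
    min_run: int = 3,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Random terminator-free control locations under the stated constraints.

    Eligible positions lie on the sense strand of genomic regions with
    at least ``min_run`` consecutive same-orientation genes and are
    more than ``min_terminator_distance`` nt from every annotated
    terminator.  ``n`` positions are drawn uniformly without
    replacement.

    Raises
    ------
    ValueError
        If the eligible pool is smaller than ``n`` (pool size included
        in the message).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = genes.sort_values("start").reset_index(drop=True)
    strands = g["strand"].to_numpy()
    spans: list[tuple[int, int, str]] = []
    i = 0
    while i < len(g):
        j = i
        while j + 1 < len(g) and strands[j + 1] == strands[i]:
            j += 1
        if j - i + 1 >= min_run:
            spans.append((int(g["start"].iloc[i]), int(g["end"].iloc[j]), strands[i]))
        i = j + 1
    if not spans:
        raise ValueError("eligible pool is empty (0 positions): no qualifying gene runs")
    term_pos = np.asarray(terminators["position"], dtype=np.int64)
    pools = []
    pool_strands = []
    for start, end, strand in spans:
        cand = np.arange(start, end, dtype=np.int64)
        if term_pos.size:
            dist = np.min(np.abs(cand[:, None] - term_pos[None, :]), axis=1)
            cand = cand[dist > min_terminator_distance]
        pools.append(cand)
        pool_strands.append(np.full(cand.size, strand))
    positions = np.concatenate(pools)
    pos_strands = np.concatenate(pool_strands)
    if positions.size < n:
        raise ValueError(
            f"eligible pool has {positions.size} positions; {n} requested"
        )
    pick = rng.choice(positions.size, size=n, replace=False)
    return pd.DataFrame(
        {"position": positions[pick], "strand": pos_strands[pick]}
    ).sort_values("position").reset_index(drop=True)


def control_replicates(
    tracks: EndTracks,
    genes: pd.DataFrame,
    terminators: pd.DataFrame,
    n_locations: int,
    n_replicates: int = 100,
    bin_width: int = 200,
    z_threshold: float = Z_THRESHOLD,
    seed: int = 0,
    **constraint_kwargs,
) -> pd.DataFrame:
    """Run the constrained random-location control ``n_replicates`` times.

    Each replicate samples ``n_locations`` control positions and
    records the fraction with a strong antisense peak in the central
    ``bin_width`` window (distance 0), i.e. the quantity compared
    against the terminator-proximal fraction.
    """
    rng = np.random.default_rng(seed)
    fracs = []
    for rep in range(n_replicates):
        locs = sample_control_locations(
            genes, terminators, n_locations, seed=rng, **constraint_kwargs
        )
        prof = distance_profile(
            tracks,
            locs,
            bin_width=bin_width,
            max_distance=0,
            z_threshold=z_threshold,
        )
        fracs.append(float(prof.loc[prof["distance"] == 0, "fraction"].iloc[0]))
    return pd.DataFrame({"replicate": np.arange(n_replicates), "fraction": fracs})


_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def tss_information_content(
    sequence: str,
    peaks: pd.DataFrame,
    halfwidth: int = 3,
    small_sample_correction: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-position information content around start-site peaks.

    Windows of +/-``halfwidth`` nt centered on each peak are extracted
    (reverse-complemented for '-' strand peaks) and the information
    content per position computed against a uniform background:
    ``info = 2 - H`` bits with ``H`` the Shannon entropy of the
    observed base frequencies, minus the standard small-sample
    correction 3 / (2 ln2 n) when enabled.

    Parameters
    ----------
    sequence:
        Forward-strand genome sequence.
    peaks:
        Columns ``position`` and ``strand``; at least two peaks whose
        windows lie inside the genome.

    Returns
    -------
    info : ndarray of shape (2*halfwidth + 1,)
    pwm : DataFrame of base frequencies, one row per window offset.
    """
    w = 2 * halfwidth + 1
    windows = []
    for pos, strand in zip(peaks["position"], peaks["strand"]):
        lo = int(pos) - halfwidth
        hi = int(pos) + halfwidth + 1
        if lo < 0 or hi > len(sequence):
            raise ValueError(f"window around {pos} outside genome")
        s = sequence[lo:hi].upper()
        if strand == "-":
            s = s.translate(_COMP)[::-1]
        windows.append(s)
    n = len(windows)
    if n < 2:
        raise ValueError("need at least two peak sequences")
    counts = np.zeros((w, 4))
    for s in windows:
        for i, b in enumerate(s):
            counts[i, _BASES.index(b)] += 1
    freq = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    H = -plogp.sum(axis=1)
    info = 2.0 - H
    if small_sample_correction:
        info = info - 3.0 / (2.0 * math.log(2) * n)
    pwm = pd.DataFrame(freq, columns=list(_BASES))
    pwm.insert(0, "offset", np.arange(-halfwidth, halfwidth + 1))
    return info, pwm
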