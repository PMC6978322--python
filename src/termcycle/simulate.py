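"""Synthetic single-molecule traces and end-enriched count tracks.

The generators in this module emit data with the same statistical
structure the downstream analysis assumes, together with a ground-truth
channel, so that every stage of the pipeline can be exercised with known
answers:

* :func:`simulate_trace` -- a three-channel TIRF intensity record for
  one DNA spot: exponential intensity decay during elongation (with
  molecule-to-molecule rate heterogeneity), post-termination
  slide/stick switching as a bounded random walk, optional antisense or
  sense secondary initiation, photobleaching, and acquisition
  censoring.
* :func:`simulate_bounded_walk` -- a reflected 1D Brownian walk, the
  model for post-termination sliding.
* :func:`simulate_lifetimes` -- competing-exponential spot lifetimes
  with right censoring at the end of acquisition.
* :func:`simulate_rendseq` -- strand-specific 5'/3' end-count tracks
  over a synthetic genome with Poisson background, planted terminator
  3' peaks, and offset antisense 5' peaks.

All functions are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import IntensityTrace

__all__ = [
    "TraceSimConfig",
    "GroundTruth",
    "RendSimConfig",
    "simulate_trace",
    "simulate_cohort",
    "simulate_bounded_walk",
    "simulate_slide_stick",
    "simulate_lifetimes",
    "simulate_rendseq",
    "synthetic_genome_annotation",
    "synthetic_genome_sequence",
]

# frame states in the ground-truth path
PRE = "pre"
ELONGATING = "elongating"
SLIDING = "sliding"
STUCK = "stuck"
ANTISENSE = "antisense"
SENSE_REINIT = "sense_reinit"
DISSOCIATED = "dissociated"
BLEACHED = "bleached"


@dataclass
class TraceSimConfig:
    """Parameters of the single-trace generator.

    Geometry follows the experimental template: a 2.1 kbp transcription
    unit (z_T - z_P = 2100 bp) on a somewhat longer tethered DNA.
    Rates use seconds and basepairs throughout.  ``lambda_mean`` and
    ``lambda_cv`` parameterize the lognormal distribution of
    per-molecule intensity decay constants; the per-molecule elongation
    rate is lognormal with mean ``r_mean`` and CV ``r_cv``.
    """

    frame_interval: float = 2.0
    n_frames: int = 700
    I_P: float = 800.0
    I_mn: float = 100.0
    lambda_mean: float = 0.01  # 1/s
    lambda_cv: float = 0.3
    noise_sd: float = 20.0
    D_slide: float = 3.5e4  # bp^2/s, the sliding mode of the D histogram
    p_stick: float = 0.005  # per-frame slide -> stuck (sojourns of minutes)
    p_unstick: float = 0.005  # per-frame stuck -> slide
    p_initial_slide: float = 0.5  # state entered at termination
    template_length: float = 2500.0
    z_P: float = 200.0
    z_T: float = 2300.0
    p_retain: float = 0.87
    p_antisense: float = 0.25
    p_sense_reinit: float = 0.02
    k_PB: float = 1.0 / 3000.0  # 1/s photobleach rate
    k_RNAP: float = 1.0 / 1140.0  # 1/s post-termination dissociation rate
    tether_orientation: str = "up"
    seed: int = 0
    # elongation kinematics (needed to tie lambda to position)
    r_mean: float = 21.0  # bp/s
    r_cv: float = 0.2
    # plumbing not fixed by the experimental description
    t_start: float = 20.0  # s, elongation start after NTP introduction
    hybridization_lag: float = 10.0  # s, probe appearance after start
    probe_target: str = "sense"  # or "antisense"
    secondary_delay_mean: float = 60.0  # s of slide/stick before re-initiation
    antisense_start_sd: float = 30.0  # bp, antisense start scatter below z_T
    dna_intensity: float = 500.0
    probe_intensity: float = 600.0
    probe_background: float = 50.0
    gap_every: int = 0  # if >0, every gap_every-th interval is lengthened
    gap_extra: float = 2.0  # s added to lengthened intervals

    def validate(self) -> None:
        for name in (
            "p_stick",
            "p_unstick",
            "p_initial_slide",
            "p_retain",
            "p_antisense",
            "p_sense_reinit",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0 <= self.z_P < self.z_T <= self.template_length):
            raise ValueError("need 0 <= z_P < z_T <= template_length")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tether_orientation not in ("up", "down"):
            raise ValueError("tether_orientation must be 'up' or 'down'")
        if self.probe_target not in ("sense", "antisense"):
            raise ValueError("probe_target must be 'sense' or 'antisense'")
        for name in (
            "frame_interval", "I_P", "I_mn", "lambda_mean", "lambda_cv",
            "noise_sd", "D_slide", "template_length", "z_P", "z_T",
            "k_PB", "k_RNAP", "r_mean", "r_cv",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class GroundTruth:
    """Per-molecule truth channel emitted alongside each trace."""

    lam: float
    r: float
    t_start: float
    t_T: float
    retained: bool
    states: np.ndarray  # per-frame state labels
    z: np.ndarray  # per-frame true position, bp
    mean_rnap: np.ndarray  # noiseless RNAP-channel mean per frame
    dissociation_time: float  # inf if never
    bleach_time: float  # inf if never
    antisense: bool = False
    sense_reinit: bool = False
    secondary_start: float = math.nan
    secondary_end: float = math.nan


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _frame_times(config: TraceSimConfig) -> np.ndarray:
    dt = np.full(config.n_frames - 1, config.frame_interval)
    if config.gap_every > 0:
        dt[config.gap_every - 1 :: config.gap_every] += config.gap_extra
    return np.concatenate([[0.0], np.cumsum(dt)])


def _intensity_map(config: TraceSimConfig, lam: float, r: float, z: np.ndarray):
    """Noiseless RNAP intensity at contour position z (orientation-aware)."""
    decay_per_bp = lam / r
    if config.tether_orientation == "up":
        depth = np.asarray(z) - config.z_P
    else:
        depth = config.z_T - np.asarray(z)
    return config.I_P * np.exp(-decay_per_bp * depth) + config.I_mn


def simulate_trace(
    config: TraceSimConfig, rng: np.random.Generator | None = None
) -> tuple[IntensityTrace, GroundTruth]:
    """Generate one three-channel trace and its ground truth.

    The molecule waits promoter-bound until ``t_start``, elongates at
    its own constant rate until the terminator at ``z_T``, and is then
    either released (probability ``1 - p_retain``) or retained.  A
    retained molecule alternates between sliding (reflected Brownian
    steps of variance ``2 * D_slide * dt``) and stuck states, may start
    one secondary-initiation episode (antisense with probability
    ``p_antisense``, else sense with ``p_sense_reinit``), and loses its
    spot at the first of dissociation (rate ``k_RNAP`` past
    termination) and photobleaching (rate ``k_PB`` from t=0).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    t = _frame_times(config)
    n = t.size
    lam = _lognormal(rng, config.lambda_mean, config.lambda_cv)
    r = _lognormal(rng, config.r_mean, config.r_cv)
    t_T = config.t_start + (config.z_T - config.z_P) / r

    retained = bool(rng.random() < config.p_retain)
    bleach_time = (
        rng.exponential(1.0 / config.k_PB) if config.k_PB > 0 else math.inf
    )
    if retained:
        diss_time = t_T + (
            rng.exponential(1.0 / config.k_RNAP) if config.k_RNAP > 0 else math.inf
        )
    else:
        diss_time = t_T

    # secondary-initiation schedule, decided at termination
    antisense = retained and bool(rng.random() < config.p_antisense)
    sense_reinit = (
        retained and not antisense and bool(rng.random() < config.p_sense_reinit)
    )
    sec_start = math.nan
    sec_end = math.nan
    z_sec0 = math.nan
    if antisense or sense_reinit:
        sec_start = t_T + rng.exponential(config.secondary_delay_mean)
        if antisense:
            z_sec0 = min(
                config.z_T,
                config.z_T - abs(rng.normal(0.0, config.antisense_start_sd)),
            )
            z_sec0 = max(z_sec0, config.z_P + 1.0)
            sec_end = sec_start + (z_sec0 - config.z_P) / r
        else:
            z_sec0 = config.z_P
            sec_end = sec_start + (config.z_T - config.z_P) / r

    states = np.empty(n, dtype=object)
    z = np.empty(n)
    sliding = bool(rng.random() < config.p_initial_slide)
    z_cur = config.z_T
    prev_time = None
    gone_time = min(bleach_time, diss_time)
    for i, ti in enumerate(t):
        if ti >= gone_time:
            states[i] = BLEACHED if bleach_time <= diss_time else DISSOCIATED
            z[i] = math.nan
            continue
        if ti < config.t_start:
            states[i] = PRE
            z[i] = config.z_P
        elif ti < t_T:
            states[i] = ELONGATING
            z[i] = config.z_P + r * (ti - config.t_start)
        elif (antisense or sense_reinit) and sec_start <= ti < sec_end:
            states[i] = ANTISENSE if antisense else SENSE_REINIT
            if antisense:
                z[i] = z_sec0 - r * (ti - sec_start)
            else:
                z[i] = z_sec0 + r * (ti - sec_start)
            z_cur = z[i]
        else:
            # post-termination slide/stick random walk
            if prev_time is not None and states[i - 1] in (SLIDING, STUCK):
                if sliding and rng.random() < config.p_stick:
                    sliding = False
                elif not sliding and rng.random() < config.p_unstick:
                    sliding = True
            if sliding and config.D_slide > 0:
                dt_i = ti - prev_time if prev_time is not None else 0.0
                if dt_i > 0:
                    step = rng.normal(0.0, math.sqrt(2.0 * config.D_slide * dt_i))
                    z_cur = _reflect(z_cur + step, config.template_length)
            states[i] = SLIDING if sliding else STUCK
            z[i] = z_cur
        prev_time = ti

    visible = np.array([s not in (DISSOCIATED, BLEACHED) for s in states])
    mean_rnap = np.where(
        visible,
        _intensity_map(config, lam, r, np.where(np.isnan(z), config.z_P, z)),
        config.I_mn,
    )
    def _noise() -> np.ndarray:
        if config.noise_sd > 0:
            return rng.normal(0.0, config.noise_sd, n)
        return np.zeros(n)

    I_rnap = mean_rnap + _noise()
    I_dna = np.full(n, config.dna_intensity) + _noise()

    if config.probe_target == "sense":
        probe_on = (t >= config.t_start + config.hybridization_lag) & (t < t_T)
    else:
        if antisense and math.isfinite(sec_end):
            probe_on = t >= sec_end
        else:
            probe_on = np.zeros(n, dtype=bool)
    mean_probe = np.where(probe_on, config.probe_intensity, config.probe_background)
    I_probe = mean_probe + _noise()

    trace = IntensityTrace(
        time=t,
        I_dna=I_dna,
        I_rnap=I_rnap,
        I_probe=I_probe,
        rnap_present=visible,
        probe_present=probe_on,
    )
    truth = GroundTruth(
        lam=lam,
        r=r,
        t_start=config.t_start,
        t_T=t_T,
        retained=retained,
        states=states,
        z=z,
        mean_rnap=mean_rnap,
        dissociation_time=diss_time if retained else t_T,
        bleach_time=bleach_time,
        antisense=antisense,
        sense_reinit=sense_reinit,
        secondary_start=sec_start,
        secondary_end=sec_end,
    )
    return trace, truth


def simulate_cohort(
    config: TraceSimConfig, n_molecules: int, seed: int | None = None
) -> tuple[list[IntensityTrace], list[GroundTruth]]:
    """Generate ``n_molecules`` independent traces from one config."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    traces: list[IntensityTrace] = []
    truths: list[GroundTruth] = []
    for i in range(n_molecules):
        tr, gt = simulate_trace(config, rng=rng)
        tr.trace_id = f"mol{i:04d}"
        traces.append(tr)
        truths.append(gt)
    return traces, truths


def _reflect(x: float, L: float) -> float:
    """Fold a real coordinate into [0, L] by reflection at both walls."""
    if L <= 0:
        raise ValueError("L must be positive")
    y = x % (2.0 * L)
    return 2.0 * L - y if y > L else y


def simulate_bounded_walk(
    D: float,
    L: float,
    dt: float,
    n: int,
    seed: int | np.random.Generator = 0,
    z0: float | None = None,
) -> np.ndarray:
    """Reflected 1D Brownian walk on [0, L].

    Increments are Gaussian with variance ``2 * D * dt`` before
    reflection at the two boundaries.  Returns ``n`` positions, the
    first at ``z0`` (default L/2).
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    if dt <= 0 or L <= 0:
        raise ValueError("dt and L must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = np.empty(n)
    z[0] = L / 2.0 if z0 is None else float(z0)
    if D == 0:
        z[:] = z[0]
        return z
    steps = rng.normal(0.0, math.sqrt(2.0 * D * dt), n - 1)
    cur = z[0]
    for i, s in enumerate(steps):
        cur = _reflect(cur + s, L)
        z[i + 1] = cur
    return z


def simulate_slide_stick(
    D: float,
    n: int,
    dt: float = 1.0,
    p_switch: float = 0.002,
    L: float = math.inf,
    seed: int | np.random.Generator = 0,
    start_sliding: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Position trace of a molecule switching between sliding and stuck.

    While sliding, steps are Gaussian with variance ``2*D*dt``
    (reflected at 0 and L when ``L`` is finite); while stuck, the
    position is frozen.  The state toggles with probability
    ``p_switch`` per frame (mean sojourn ``dt/p_switch`` seconds).

    Returns (positions, sliding_flags).
    """
    if D < 0 or dt <= 0 or not (0 <= p_switch <= 1):
        raise ValueError("bad slide/stick parameters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = np.empty(n)
    sliding = np.empty(n, dtype=bool)
    z[0] = L / 2.0 if math.isfinite(L) else 0.0
    sliding[0] = bool(rng.random() < 0.5) if start_sliding is None else start_sliding
    sd = math.sqrt(2.0 * D * dt)
    for i in range(1, n):
        s = sliding[i - 1] != (rng.random() < p_switch)
        sliding[i] = s
        if s:
            step = rng.normal(0.0, sd)
            z[i] = _reflect(z[i - 1] + step, L) if math.isfinite(L) else z[i - 1] + step
        else:
            z[i] = z[i - 1]
    return z, sliding


def simulate_lifetimes(
    k_RNAP: float,
    k_PB: float,
    t_censor: float,
    n: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed spot lifetimes under competing dissociation/bleaching.

    The spot disappears at the first of dissociation (rate ``k_RNAP``)
    and photobleaching (rate ``k_PB``); acquisition ends at
    ``t_censor``, right-censoring longer-lived spots.

    Returns
    -------
    durations, censored : ndarray
        Observed durations (s) and boolean censoring flags.
    """
    if k_RNAP < 0 or k_PB < 0 or (k_RNAP == 0 and k_PB == 0):
        raise ValueError("rates must be >= 0 and not both zero")
    if t_censor <= 0:
        raise ValueError("t_censor must be positive (zero-length records rejected)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = k_RNAP + k_PB
    raw = rng.exponential(1.0 / k, n)
    censored = raw >= t_censor
    durations = np.where(censored, t_censor, raw)
    return durations, censored


# ---------------------------------------------------------------------------
# Rend-seq-like end-count tracks
# ---------------------------------------------------------------------------


@dataclass
class RendSimConfig:
    """Parameters of the end-enriched track generator.

    Emulates the expected sequencing signature of antisense secondary
    initiation: every terminator gets a spike in 3' sense end counts;
    a fraction additionally get a 5' antisense spike at a signed offset
    on the opposite strand.  Background counts are i.i.d. Poisson.
    Offsets are oriented (positive = downstream of the terminator in
    its own reading direction) and clipped to ``max_offset``.
    """

    genome_length: int = 200_000
    genes: list[tuple[int, int, str]] = field(default_factory=list)
    terminators: list[tuple[int, str]] = field(default_factory=list)
    background_rate: float = 0.2  # mean Poisson counts per nt
    term_peak_height: int = 64
    antisense_peak_height: int = 40
    antisense_offset_dist: tuple = ("normal", 0.0, 120.0)
    max_offset: int = 480
    fraction_terminators_with_antisense: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not (0.0 <= self.fraction_terminators_with_antisense <= 1.0):
            raise ValueError("fraction_terminators_with_antisense outside [0,1]")
        if self.term_peak_height < 0 or self.antisense_peak_height < 0:
            raise ValueError("peak heights must be >= 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for pos, strand in self.terminators:
            if not (0 <= pos < self.genome_length):
                raise ValueError(f"terminator at {pos} outside genome")
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")


def _sample_offsets(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "fixed":
        return np.full(n, int(dist[1]))
    if kind == "uniform":
        return rng.integers(int(dist[1]), int(dist[2]) + 1, n)
    if kind == "normal":
        return np.rint(rng.normal(float(dist[1]), float(dist[2]), n)).astype(int)
    raise ValueError(f"unknown offset distribution {kind!r}")


def simulate_rendseq(config: RendSimConfig):
    """Generate four strand-specific end-count tracks plus a truth table.

    Returns
    -------
    tracks : :class:`termcycle.rendseq.EndTracks`
    truth : pandas.DataFrame
        One row per terminator: position, strand, planted 3' height,
        whether an antisense 5' peak was planted, its oriented offset
        and genomic position.
    """
    from .rendseq import EndTracks  # local import to avoid a cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.genome_length
    shape = (G,)

    def background():
        if config.background_rate == 0:
            return np.zeros(shape, dtype=np.int64)
        return rng.poisson(config.background_rate, shape).astype(np.int64)

    five_plus = background()
    five_minus = background()
    three_plus = background()
    three_minus = background()

    terms = config.terminators
    n_term = len(terms)
    has_as = rng.random(n_term) < config.fraction_terminators_with_antisense
    offsets = _sample_offsets(config.antisense_offset_dist, n_term, rng)
    offsets = np.clip(offsets, -config.max_offset, config.max_offset)

    rows = []
    for (pos, strand), with_as, off in zip(terms, has_as, offsets):
        three = three_plus if strand == "+" else three_minus
        three[pos] += config.term_peak_height
        as_pos = -1
        if with_as:
            genomic_off = int(off) if strand == "+" else -int(off)
            as_pos = int(np.clip(pos + genomic_off, 0, G - 1))
            five = five_minus if strand == "+" else five_plus
            five[as_pos] += config.antisense_peak_height
        rows.append(
            {
                "position": pos,
                "strand": strand,
                "term_peak_height": config.term_peak_height,
                "has_antisense": bool(with_as),
                "antisense_offset": int(off) if with_as else pd.NA,
                "antisense_position": as_pos if with_as else pd.NA,
                "antisense_height": config.antisense_peak_height if with_as else 0,
            }
        )
    truth = pd.DataFrame(rows)
    tracks = EndTracks(
        five_plus=five_plus,
        five_minus=five_minus,
        three_plus=three_plus,
        three_minus=three_minus,
        genome_length=G,
        convention="0-based",
    )
    return tracks, truth


def synthetic_genome_annotation(
    n_blocks: int = 60,
    genes_per_block: tuple[int, int] = (2, 5),
    gene_length: int = 900,
    intra_gap: int = 100,
    term_offset: int = 30,
    spacer: int = 600,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Build a block-structured bacterial-like annotation.

    The genome is a series of operon-like blocks; each block carries
    2-5 consecutive same-strand genes followed by one intrinsic
    terminator ``term_offset`` nt past the last gene.  Block strands
    are random.  Returns (genes, terminators, genome_length) with genes
    as (start, end, strand) half-open 0-based intervals.
    """
    rng = np.random.default_rng(seed)
    genes = []
    terminators = []
    cursor = spacer
    for b in range(n_blocks):
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(genes_per_block[0], genes_per_block[1] + 1))
        block_genes = []
        for g in range(k):
            start = cursor
            end = start + gene_length
            block_genes.append((start, end, strand))
            cursor = end + intra_gap
        if strand == "+":
            tpos = block_genes[-1][1] + term_offset
        else:
            # terminator sits past the block's last gene in reading
            # direction; for '-' blocks that is before the first gene
            tpos = block_genes[0][0] - term_offset
        genes.extend(block_genes)
        terminators.append((tpos, strand))
        cursor += spacer
    genome_length = cursor + spacer
    genes_df = pd.DataFrame(genes, columns=["start", "end", "strand"])
    genes_df.insert(0, "gene_id", [f"gene{i:04d}" for i in range(len(genes_df))])
    term_df = pd.DataFrame(terminators, columns=["position", "strand"])
    term_df.insert(0, "name", [f"term{i:03d}" for i in range(len(term_df))])
    return genes_df, term_df, genome_length


def synthetic_genome_sequence(
    genome_length: int,
    planted_motifs: list[tuple[int, str, str]] | None = None,
    seed: int = 0,
) -> str:
    """Uniform-random genome sequence with optional planted motifs.

    ``planted_motifs`` is a list of (center, strand, motif); the motif
    is written centered at ``center`` on the given strand (reverse
    complemented into the forward sequence for '-').
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), genome_length)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if planted_motifs:
        for center, strand, motif in planted_motifs:
            if strand == "-":
                motif = "".join(comp[b] for b in reversed(motif))
            start = center - len(motif) // 2
            if start < 0 or start + len(motif) > genome_length:
                raise ValueError("planted motif outside genome")
            seq[start : start + len(motif)] = list(motif)
    return "".join(seq)
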