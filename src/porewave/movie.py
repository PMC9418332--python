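"""HS-AFM movie analysis: ring unbending, state assignment, kinetics.

Implements the movie-analysis procedures: each ring is computationally
unbent into a column of 16 angular sectors; sector heights are assigned
to the three conformational states (plus transient OPEN breakages) by
height thresholds relative to the pre-pore-I baseline (I->II threshold
0.8 nm = half the 1.6 nm step; pore threshold 2.7 nm = 1.6 + half the
2.2 nm step); and the state matrices feed counting and rate estimators
for breakage openings, initiation survival, clockwise propagation, and
per-subunit transition rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .expfit import (
    LifetimeFit,
    RateEstimate,
    fit_exponential_frame_quantized,
    fit_exponential_right_censored,
)
from .geometry import RingLayout, sector_pixel_map
from .states import CellState, StateMatrix
from .synthetic import TopographyMovie

THRESH_I_II = 0.8  # nm above pre-pore-I baseline
THRESH_PORE = 2.7  # nm above pre-pore-I baseline
D_OPEN = 4.0  # nm below baseline marking a visual ring discontinuity


@dataclass
class SubunitTraceMatrix:
    """frames x 16 sector-averaged heights (nm) for one unbent ring."""

    heights: np.ndarray
    ring_id: int
    frame_interval: float
    baseline_height: float  # estimated PRE_I top level (nm)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.shape[1] != 16:
            raise ValueError("heights must be a frames x 16 matrix")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("sector heights must be finite")


def unbend_ring(
    movie: TopographyMovie,
    center_nm,
    radius_nm: float,
    annulus_width: float = 4.0,
    ring_id: int = 0,
    baseline_frames: int = 1,
) -> SubunitTraceMatrix:
    """Unbend one ring into per-frame 16-sector mean heights.

    Pixels in the annulus ``radius +/- width/2`` are partitioned into 16
    sectors of 22.5 degrees (clockwise indexing shared with the renderer)
    and averaged per frame.  The pre-pore-I baseline is the median sector
    height over the first ``baseline_frames`` frames (the recording is
    assumed to start before the ring's transition).
    """
    rows, cols, sectors = sector_pixel_map(
        movie.frames.shape[1:], np.asarray(center_nm, dtype=float), radius_nm,
        annulus_width, movie.pixel_size,
    )
    pix = movie.frames[:, rows, cols].astype(float)  # (T, n_pix)
    counts = np.bincount(sectors, minlength=16)
    if np.any(counts == 0):
        raise ValueError("annulus too thin: some sectors contain no pixels")
    heights = np.stack(
        [np.bincount(sectors, weights=pix[f], minlength=16) / counts
         for f in range(pix.shape[0])]
    )
    baseline = float(np.median(heights[:baseline_frames]))
    return SubunitTraceMatrix(
        heights=heights, ring_id=ring_id, frame_interval=movie.frame_interval,
        baseline_height=baseline,
    )


def unbend_layout(movie: TopographyMovie, layout: RingLayout) -> list[SubunitTraceMatrix]:
    """Unbend every ring of a layout."""
    return [
        unbend_ring(movie, c, layout.ring_radius, layout.annulus_width, ring_id=i)
        for i, c in enumerate(layout.centers)
    ]


def assign_states(
    traces: SubunitTraceMatrix,
    thresh_i_ii: float = THRESH_I_II,
    thresh_pore: float = THRESH_PORE,
    d_open: float = D_OPEN,
    temporal_median: int | None = None,
) -> StateMatrix:
    """Threshold sector heights into OPEN / PRE_I / PRE_II / PORE.

    Heights are measured relative to the ring's pre-pore-I baseline:
    below ``-d_open`` -> OPEN, below ``thresh_i_ii`` -> PRE_I, in
    [thresh_i_ii, thresh_pore) -> PRE_II, at or above ``thresh_pore`` ->
    PORE.  ``temporal_median`` optionally median-filters each sector trace
    over that many frames first (off by default: sector averaging already
    suppresses pixel noise, and a temporal median would erase single-frame
    breakage openings).
    """
    if not math.isfinite(traces.baseline_height):
        raise ValueError("baseline height unavailable; estimate it before assignment")
    h = traces.heights
    if temporal_median:
        h = median_filter(h, size=(temporal_median, 1), mode="nearest")
    rel = h - traces.baseline_height
    states = np.full(rel.shape, CellState.PRE_I, dtype=np.int8)
    states[rel >= thresh_i_ii] = CellState.PRE_II
    states[rel >= thresh_pore] = CellState.PORE
    states[rel < -d_open] = CellState.OPEN
    return StateMatrix(
        states=states, frame_interval=traces.frame_interval, ring_id=traces.ring_id
    )


def _first_entry_frames(states: np.ndarray, level: int) -> np.ndarray:
    """Per-column first frame index with state >= level (NaN if never)."""
    hit = states >= level
    out = np.full(16, np.nan)
    any_hit = hit.any(axis=0)
    out[any_hit] = hit.argmax(axis=0)[any_hit]
    return out


def _count_open_runs(row: np.ndarray) -> int:
    """Number of breakages visible in one frame's OPEN sectors.

    One broken bond drops its two flanking sectors, so a circularly
    contiguous OPEN run of L >= 2 sectors shows L - 1 broken bonds;
    an isolated OPEN sector still counts as one discontinuity.
    """
    is_open = row == CellState.OPEN
    if is_open.all():
        return 15  # fully open ring: every bond boundary but one
    if not is_open.any():
        return 0
    starts = np.where(is_open & ~np.roll(is_open, 1))[0]
    total = 0
    for s in starts:
        length = 1
        while is_open[(s + length) % 16]:
            length += 1
        total += max(length - 1, 1)
    return total


def opening_rate(
    state_matrices: list[StateMatrix], window: float = 1.0
) -> RateEstimate:
    """Breakage opening rate from discontinuity counting.

    For each ring, frames before the transition begins (no sector at
    pre-pore-II or beyond yet) are scanned for visual discontinuities;
    each circularly contiguous run of OPEN sectors counts as one opening
    (openings never persist beyond a single frame).  A ring whose
    transition initiates within the recording contributes one further
    opening: the initiation occurs at a breakage site, so the nucleating
    opening is part of the same breakage process even though it is
    overtaken by the transition instead of re-closing.  The rate is total
    openings divided by total pre-transition ring observation time
    (``window`` is the averaging bin of the counting procedure; with
    homogeneous counting it cancels from the estimate).
    """
    n_open = 0
    total_time = 0.0
    for sm in state_matrices:
        first = _first_entry_frames(sm.states, CellState.PRE_II)
        f_stop = int(np.nanmin(first)) if np.any(~np.isnan(first)) else sm.n_frames
        for f in range(f_stop):
            n_open += _count_open_runs(sm.states[f])
        if f_stop < sm.n_frames:
            n_open += 1  # the nucleating breakage of the observed initiation
        total_time += f_stop * sm.frame_interval
    if total_time <= 0:
        raise ValueError("zero pre-transition observation time")
    rate = n_open / total_time
    se = math.sqrt(max(n_open, 1)) / total_time
    return RateEstimate(
        rate=rate, ci95=(rate - 1.96 * se, rate + 1.96 * se), n_events=n_open,
        method="discontinuity counting",
    )


def propagation_direction(states: StateMatrix) -> float:
    """Signed clockwise-propagation score in [-1, +1].

    Each circular neighbour pair (i, i+1 clockwise) in which both subunits
    transitioned contributes +1 when the clockwise neighbour entered
    pre-pore-II in a later frame (clockwise hand-over), -1 when earlier;
    same-frame ties are uninformative at the frame rate and are skipped.
    When every subunit transitioned (full-ring run) the single wave seam -
    the neighbour pair with the largest entry-frame gap - is excluded.
    +1 means purely clockwise propagation.
    """
    first = _first_entry_frames(states.states, CellState.PRE_II)
    idx = np.where(~np.isnan(first))[0]
    if idx.size < 2:
        raise ValueError("fewer than two transition events: direction undefined")
    pairs = [
        (i, (i + 1) % 16)
        for i in range(16)
        if not (np.isnan(first[i]) or np.isnan(first[(i + 1) % 16]))
    ]
    if idx.size == 16 and pairs:
        seam = max(pairs, key=lambda p: abs(first[p[1]] - first[p[0]]))
        pairs = [p for p in pairs if p != seam]
    scores = [
        float(np.sign(first[b] - first[a])) for a, b in pairs if first[a] != first[b]
    ]
    if not scores:
        raise ValueError("no informative neighbour pairs")
    return float(np.mean(scores))


def _wave_order(first_ii: np.ndarray) -> list[int]:
    """Clockwise order of the transitioned subunits, from the wave start.

    The run is the set of columns that ever reached pre-pore-II; the start
    is the earliest entry (ties broken by taking the subunit whose
    counter-clockwise neighbour did not transition, i.e. the run's
    clockwise-first element).
    """
    members = set(np.where(~np.isnan(first_ii))[0])
    if not members:
        return []
    starts = [i for i in members if (i - 1) % 16 not in members]
    if starts:
        start = min(starts, key=lambda i: first_ii[i])
    else:  # full ring: start at the global earliest entry
        start = int(np.nanargmin(first_ii))
    order = []
    i = start
    for _ in range(16):
        if i not in members:
            break
        order.append(i)
        i = (i + 1) % 16
    return order


def estimate_propagation_rates(
    state_matrices: list[StateMatrix],
    guard_s: float = 3.0,
) -> tuple[RateEstimate, RateEstimate]:
    """Per-subunit I->II and II->pore rates by interval-censored fitting.

    The I->II waiting time of subunit i is measured from subunit i-1's
    I->II entry (wave-relative, so the initiation delay does not enter);
    the II->pore dwell from the subunit's own II entry.  At 200 ms framing
    both waits are observed only as frame-index differences and are fitted
    with the frame-quantized exponential MLE.  Runs initiating within
    ``guard_s`` of the recording end are skipped (their waits are
    right-censored by the movie edge).
    """
    d12, d23 = [], []
    for sm in state_matrices:
        first_ii = _first_entry_frames(sm.states, CellState.PRE_II)
        first_pore = _first_entry_frames(sm.states, CellState.PORE)
        order = _wave_order(first_ii)
        if not order:
            continue
        guard_frames = sm.n_frames - int(guard_s / sm.frame_interval)
        if first_ii[order[0]] > guard_frames:
            continue
        for prev, cur in zip(order[:-1], order[1:]):
            d = first_ii[cur] - first_ii[prev]
            if d >= 0:
                d12.append(int(d))
        for i in order:
            if not np.isnan(first_pore[i]):
                d = first_pore[i] - first_ii[i]
                if d >= 0:
                    d23.append(int(d))
    dt = state_matrices[0].frame_interval
    k12 = fit_exponential_frame_quantized(d12, dt)
    k23 = fit_exponential_frame_quantized(d23, dt)
    return k12, k23


def arc_length_subunits(states: StateMatrix, at_frame: int = -1) -> int:
    """Longest circularly contiguous run of PORE sectors in one frame,
    i.e. the pore arc length in subunits (360 deg = 16, 270 deg = 12)."""
    row = states.states[at_frame] == CellState.PORE
    if row.all():
        return 16
    if not row.any():
        return 0
    # rotate so a non-pore sector is first, then take the longest run
    shift = int(np.argmin(row))
    r = np.roll(row, -shift)
    best = cur = 0
    for v in r:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return int(best)


def transition_time(states: StateMatrix) -> float | None:
    """Pre-pore to pore transition time of one assembly (s).

    First pre-pore-II entry to last pore entry, frame-midpoint convention;
    None when no pore formed.
    """
    first_ii = _first_entry_frames(states.states, CellState.PRE_II)
    first_pore = _first_entry_frames(states.states, CellState.PORE)
    if np.all(np.isnan(first_pore)) or np.all(np.isnan(first_ii)):
        return None
    return float((np.nanmax(first_pore) - np.nanmin(first_ii)) * states.frame_interval)


def survival_times(
    state_matrices: list[StateMatrix],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ring time of transition initiation, censored at the movie end.

    Returns ``(times, censored)`` where the time is the first pre-pore-II
    entry (frame midpoint) relative to acidification at t = 0.
    """
    times, censored = [], []
    for sm in state_matrices:
        first = _first_entry_frames(sm.states, CellState.PRE_II)
        if np.all(np.isnan(first)):
            times.append(sm.n_frames * sm.frame_interval)
            censored.append(True)
        else:
            times.append((np.nanmin(first) + 0.5) * sm.frame_interval)
            censored.append(False)
    return np.asarray(times), np.asarray(censored)


def initiation_survival_fit(state_matrices: list[StateMatrix]) -> LifetimeFit:
    """Exponential pre-pore survival lifetime from observed state matrices."""
    times, censored = survival_times(state_matrices)
    return fit_exponential_right_censored(times, censored)


def height_distribution(
    movie: TopographyMovie, layout: RingLayout, frame: int = 0, band_nm: float = 0.5
) -> tuple[np.ndarray, float, float]:
    """Per-assembly top height distribution for one frame.

    Each ring's annulus is averaged into 16 sector means (pixel noise
    averages out within a sector); the assembly's top height is the mean
    of the sector means within ``band_nm`` of the highest sector — the
    elevated arc for a pore assembly, the whole ring for a uniform one.
    Returns (per-ring heights, mean, std).
    """
    per_ring = []
    for c in layout.centers:
        rows, cols, sectors = sector_pixel_map(
            movie.frames.shape[1:], c, layout.ring_radius, layout.annulus_width,
            movie.pixel_size,
        )
        px = movie.frames[frame, rows, cols].astype(float)
        if px.size == 0:
            raise ValueError("empty ring mask")
        counts = np.bincount(sectors, minlength=16)
        means = np.bincount(sectors, weights=px, minlength=16) / np.maximum(counts, 1)
        means = means[counts > 0]
        top = means[means >= means.max() - band_nm]
        per_ring.append(float(top.mean()))
    per_ring = np.asarray(per_ring)
    return per_ring, float(per_ring.mean()), float(per_ring.std())


def detect_ring_centers(
    movie: TopographyMovie,
    radius_nm: float = 10.0,
    annulus_width: float = 4.0,
    n_frames_avg: int = 5,
    threshold: float = 0.5,
) -> np.ndarray:
    """Layout-free ring detection by annulus correlation.

    Correlates the time-averaged height image with a mean-zero annulus
    template and returns local maxima above ``threshold`` x the global
    maximum, separated by at least one ring diameter, as (row, col) nm
    coordinates.  Intended as a convenience for externally supplied
    movies; synthetic analyses use the generator's layout directly.
    """
    from scipy.ndimage import maximum_filter
    from scipy.signal import fftconvolve

    img = movie.frames[: max(n_frames_avg, 1)].mean(axis=0).astype(float)
    px = movie.pixel_size
    r = radius_nm / px
    w = annulus_width / px
    half = int(np.ceil(r + w))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    rad = np.hypot(yy, xx)
    template = ((rad >= r - w / 2) & (rad <= r + w / 2)).astype(float)
    template -= template.mean()
    corr = fftconvolve(img - img.mean(), template[::-1, ::-1], mode="same")
    sep = int(1.2 * r)  # suppression radius: just over one ring radius
    peaks = (corr == maximum_filter(corr, size=2 * sep + 1)) & (
        corr >= threshold * corr.max()
    )
    rows, cols = np.where(peaks)
    order = np.argsort(-corr[rows, cols])
    return np.column_stack([(rows[order] + 0.5) * px, (cols[order] + 0.5) * px])


@dataclass
class UnfurlingEstimate:
    strand_length_aa: float
    duration_ms: float
    speed_aa_per_ms: float


def unfurling_speed(
    dh_nm: float = 2.2,
    v_nm_per_s: float = 48.0,
    pitch_A_per_aa: float = 1.75,
    bilayer_A: float = 40.0,
) -> UnfurlingEstimate:
    """Speed of TMH unfurling into the transmembrane beta-strands.

    A ~40 A bilayer at 1.75 A/residue beta-strand pitch corresponds to a
    ~23 aa strand; the 2.2 nm II->pore rise at ~48 nm/s takes ~46 ms, so
    the strand threads at ~0.5 aa/ms.
    """
    for v in (dh_nm, v_nm_per_s, pitch_A_per_aa, bilayer_A):
        if not v > 0:
            raise ValueError("all inputs must be positive")
    strand = bilayer_A / pitch_A_per_aa
    duration_ms = dh_nm / v_nm_per_s * 1e3
    return UnfurlingEstimate(
        strand_length_aa=strand,
        duration_ms=duration_ms,
        speed_aa_per_ms=strand / duration_ms,
    )
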