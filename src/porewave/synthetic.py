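"""Synthetic HS-AFM topography movies and line-scan kymographs.

Renders kinetic-Monte-Carlo ring trajectories into height maps with the
statistical structure of the recordings: hexagonally packed 16-subunit
rings ~8.1 nm above a membrane baseline (0 nm), 200 ms frames, clockwise
two-wave state transitions with 1.6 nm and 2.2 nm steps, finite ramp
speeds (~47-48 nm/s, visible only at 2 ms line scanning), transient
breakages visible in exactly one imaging frame, and additive Gaussian
pixel noise.  Every rendering returns its ground truth, enabling
round-trip validation of the analysis procedures.

Not emulated: scanner feedback artifacts, drift, tip convolution (an
optional spherical-cap dilation is provided but off by default since no
tip radius is available), or inter-ring interactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import RingLayout, sector_pixel_map
from .kmc import RING_SIZE, EventKind, RingTrajectory
from .states import CellState, StateMatrix


@dataclass(frozen=True)
class HeightConventions:
    """Height and speed conventions of the three-state transition (nm, nm/s).

    ``h_preI`` pre-pore-I top height above the membrane; ``dh_I_II`` and
    ``dh_II_pore`` step heights of the two transitions (total rise 3.8 nm);
    ``v_I_II``/``v_II_pore`` ramp speeds; ``noise_sigma`` per-pixel additive
    Gaussian noise.
    """

    h_preI: float = 8.1
    dh_I_II: float = 1.6
    dh_II_pore: float = 2.2
    v_I_II: float = 47.3
    v_II_pore: float = 48.0
    noise_sigma: float = 0.3

    def __post_init__(self) -> None:
        for name in ("h_preI", "dh_I_II", "dh_II_pore", "v_I_II", "v_II_pore"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def level(self, state: int) -> float:
        """Absolute height of a sector in the given state (OPEN = membrane)."""
        return {
            CellState.OPEN: 0.0,
            CellState.PRE_I: self.h_preI,
            CellState.PRE_II: self.h_preI + self.dh_I_II,
            CellState.PORE: self.h_preI + self.dh_I_II + self.dh_II_pore,
        }[CellState(state)]

    def levels(self) -> np.ndarray:
        """Heights indexed by state code + 1 (OPEN, PRE_I, PRE_II, PORE)."""
        return np.array([self.level(s) for s in (-1, 0, 1, 2)])


@dataclass
class TopographyMovie:
    """Stack of 2-D height maps in nm above the membrane baseline (0 nm)."""

    frames: np.ndarray  # (T, H, W) float32
    pixel_size: float  # nm / pixel
    frame_interval: float  # s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("heights must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class Kymograph:
    """Repeated-line height profile vs time: (lines, position) in nm."""

    lines: np.ndarray  # (T, X) float32
    line_interval: float = 0.002  # s
    pixel_size: float = 1.0  # nm / pixel

    def __post_init__(self) -> None:
        self.lines = np.asarray(self.lines, dtype=np.float32)
        if self.lines.ndim != 2:
            raise ValueError("lines must be 2-D (time x position)")
        if not self.line_interval > 0:
            raise ValueError("line_interval must be positive")

    @property
    def n_lines(self) -> int:
        return self.lines.shape[0]


def trajectory_to_state_matrix(
    traj: RingTrajectory, n_frames: int, frame_interval: float
) -> StateMatrix:
    """Ground-truth per-sector states sampled at frame midpoints.

    Conformational states are sampled at ``(k + 1/2) * frame_interval``.
    Each transient BREAK_OPEN marks the two sectors flanking the broken
    bond OPEN in the single frame containing the opening (breakage dwells
    are sub-frame at the recording's frame rate).
    """
    t_mid = (np.arange(n_frames) + 0.5) * frame_interval
    t_ii = np.full(RING_SIZE, np.inf)
    t_pore = np.full(RING_SIZE, np.inf)
    for e in traj.events:
        if e.kind is EventKind.TO_II:
            t_ii[e.subunit] = e.time
        elif e.kind is EventKind.TO_PORE:
            t_pore[e.subunit] = e.time
    states = (
        (t_mid[:, None] >= t_ii[None, :]).astype(np.int8)
        + (t_mid[:, None] >= t_pore[None, :]).astype(np.int8)
    )
    for e in traj.events:
        if e.kind is EventKind.BREAK_OPEN:
            f = int(e.time / frame_interval)
            if 0 <= f < n_frames:
                for su in (e.subunit, (e.subunit + 1) % RING_SIZE):
                    if states[f, su] == CellState.PRE_I:
                        states[f, su] = CellState.OPEN
    return StateMatrix(states=states, frame_interval=frame_interval, ring_id=traj.ring_id)


def render_movie(
    layout: RingLayout,
    trajs: list[RingTrajectory],
    conv: HeightConventions | None = None,
    n_frames: int | None = None,
    frame_interval: float = 0.2,
    seed=None,
) -> tuple[TopographyMovie, list[StateMatrix]]:
    """Render one trajectory per layout ring into a topography movie.

    Each ring is an annulus split into 16 equal 22.5 degree sectors whose
    height is the level of the sector's state at the frame midpoint; the
    membrane is 0 nm; i.i.d. Gaussian noise is added per pixel.  Returns
    the movie together with the per-ring ground-truth state matrices.
    """
    conv = conv or HeightConventions()
    if len(trajs) != layout.n_rings:
        raise ValueError(
            f"{len(trajs)} trajectories for {layout.n_rings} rings in the layout"
        )
    if n_frames is None:
        n_frames = int(math.ceil(max(tr.t_end for tr in trajs) / frame_interval))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    level_by_code = conv.levels()  # index = state + 1
    truth = [trajectory_to_state_matrix(tr, n_frames, frame_interval) for tr in trajs]
    maps = [
        sector_pixel_map(
            layout.image_shape, c, layout.ring_radius, layout.annulus_width,
            layout.pixel_size, layout.sector_count,
        )
        for c in layout.centers
    ]
    frames = np.zeros((n_frames, *layout.image_shape), dtype=np.float32)
    for f in range(n_frames):
        img = frames[f]
        for (rows, cols, sectors), sm in zip(maps, truth):
            img[rows, cols] = level_by_code[sm.states[f, sectors] + 1]
    if conv.noise_sigma > 0:
        frames += rng.normal(0.0, conv.noise_sigma, size=frames.shape).astype(np.float32)
    movie = TopographyMovie(
        frames=frames, pixel_size=layout.pixel_size, frame_interval=frame_interval
    )
    return movie, truth


# ---------------------------------------------------------------------------
# kymographs (line-scanning mode, 2 ms lines)


@dataclass
class KymoGroundTruth:
    """Generator truth for one rendered subunit trace."""

    levels: tuple[float, float, float]  # PRE_I, PRE_II, PORE plateau heights
    step_heights: tuple[float, float]  # dh I->II, dh II->pore
    speeds: tuple[float, float]  # nm/s
    ramp1: tuple[float, float]  # (start, end) s of the I->II ramp
    ramp2: tuple[float, float]
    dwell_II: float  # flat pre-pore-II plateau duration (s)
    center_col: int


def render_kymograph(
    schedule: list[tuple[int, float]],
    conv: HeightConventions | None = None,
    duration: float | None = None,
    line_interval: float = 0.002,
    seed=None,
    n_cols: int = 15,
    plateau_halfwidth: int = 3,
    taper: int = 3,
) -> tuple[Kymograph, KymoGroundTruth]:
    """Render a single-subunit transition into a line-scan kymograph.

    ``schedule`` lists ``(state, ramp_start_s)`` chronologically, e.g.
    ``[(PRE_I, 0.0), (PRE_II, 0.15), (PORE, 0.26)]``; the height trace
    holds plateaus at the three state levels and connects them with linear
    ramps at the transition's speed (durations dh/v, ~34 ms and ~46 ms).
    A negative dwell (next ramp starting before the previous one ends)
    raises.  The subunit occupies a flat-topped lateral profile; Gaussian
    noise is added per pixel.
    """
    conv = conv or HeightConventions()
    if [s for s, _ in schedule] != sorted(s for s, _ in schedule):
        raise ValueError("schedule states must be chronological and non-decreasing")
    ramps = []  # (t_start, t_end, level_from, level_to, speed)
    prev_level = conv.level(schedule[0][0])
    prev_end = schedule[0][1]
    for state, t_start in schedule[1:]:
        level = conv.level(state)
        speed = conv.v_I_II if state == CellState.PRE_II else conv.v_II_pore
        if t_start < prev_end:
            raise ValueError(
                f"negative dwell: ramp to state {state} starts at {t_start:.4f}s "
                f"before the previous ramp ends at {prev_end:.4f}s"
            )
        t_end = t_start + (level - prev_level) / speed
        ramps.append((t_start, t_end, prev_level, level, speed))
        prev_level, prev_end = level, t_end
    if duration is None:
        duration = prev_end + 0.15
    t = np.arange(int(round(duration / line_interval))) * line_interval
    h = np.full(t.shape, conv.level(schedule[0][0]))
    for t_start, t_end, lo, hi, speed in ramps:
        h = np.where(t >= t_start, np.minimum(lo + speed * (t - t_start), hi), h)
    center = n_cols // 2
    profile = np.zeros(n_cols)
    for j in range(n_cols):
        d = abs(j - center)
        if d <= plateau_halfwidth:
            profile[j] = 1.0
        elif d <= plateau_halfwidth + taper:
            profile[j] = 1.0 - (d - plateau_halfwidth) / (taper + 1.0)
    lines = h[:, None] * profile[None, :]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if conv.noise_sigma > 0:
        lines = lines + rng.normal(0.0, conv.noise_sigma, size=lines.shape)
    levels = (conv.level(0), conv.level(1), conv.level(2))
    r1 = ramps[0][:2] if len(ramps) >= 1 else (np.nan, np.nan)
    r2 = ramps[1][:2] if len(ramps) >= 2 else (np.nan, np.nan)
    dwell = r2[0] - r1[1] if len(ramps) >= 2 else np.nan
    truth = KymoGroundTruth(
        levels=levels,
        step_heights=(conv.dh_I_II, conv.dh_II_pore),
        speeds=(conv.v_I_II, conv.v_II_pore),
        ramp1=tuple(float(x) for x in r1),
        ramp2=tuple(float(x) for x in r2),
        dwell_II=float(dwell),
        center_col=center,
    )
    kymo = Kymograph(
        lines=lines.astype(np.float32), line_interval=line_interval, pixel_size=1.0
    )
    return kymo, truth


def jittered_conventions(
    rng: np.random.Generator,
    conv: HeightConventions | None = None,
    dh1_sd: float = 0.4,
    dh2_sd: float = 0.2,
    v1_sd: float = 5.0,
    v2_sd: float = 7.0,
) -> HeightConventions:
    """Per-trace conventions with step heights and speeds drawn around the
    ensemble means at the observed spreads (1.6+/-0.4, 2.2+/-0.2 nm;
    47.3+/-5, 48+/-7 nm/s), truncated away from non-physical values."""
    conv = conv or HeightConventions()

    def draw(mean, sd, lo):
        for _ in range(100):
            x = rng.normal(mean, sd)
            if x > lo:
                return float(x)
        return float(mean)

    return replace(
        conv,
        dh_I_II=draw(conv.dh_I_II, dh1_sd, 0.5),
        dh_II_pore=draw(conv.dh_II_pore, dh2_sd, 0.5),
        v_I_II=draw(conv.v_I_II, v1_sd, 15.0),
        v_II_pore=draw(conv.v_II_pore, v2_sd, 15.0),
    )


def sample_kymo_ensemble(
    n_traces: int,
    seed=None,
    conv: HeightConventions | None = None,
    tau_II: float = 0.075,
    pre_dwell: tuple[float, float] = (0.12, 0.3),
    tail: float = 0.15,
    line_interval: float = 0.002,
    jitter: bool = True,
) -> list[tuple[Kymograph, KymoGroundTruth]]:
    """Ensemble of single-subunit transition kymographs.

    Pre-pore-II plateau dwells are exponential with mean ``tau_II``
    (default 75 ms, the measured lifetime); the initial pre-pore-I plateau
    is uniform over ``pre_dwell`` and the trace ends ``tail`` seconds after
    the pore plateau is reached.
    """
    conv = conv or HeightConventions()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_traces):
        rng = np.random.default_rng(child)
        c = jittered_conventions(rng, conv) if jitter else conv
        t1 = rng.uniform(*pre_dwell)
        dwell = rng.exponential(tau_II)
        t2 = t1 + c.dh_I_II / c.v_I_II + dwell
        duration = t2 + c.dh_II_pore / c.v_II_pore + tail
        out.append(
            render_kymograph(
                [(CellState.PRE_I, 0.0), (CellState.PRE_II, t1), (CellState.PORE, t2)],
                conv=c,
                duration=duration,
                line_interval=line_interval,
                seed=rng,
            )
        )
    return out
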