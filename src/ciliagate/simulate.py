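"""Stochastic simulator of a 1D ciliary membrane with a transition-zone barrier.

The model emulates the in vivo FRAP assay used to probe ARL-13 ciliary
compartmentalization in C. elegans phasmid neurons: two membrane pools — the
periciliary membrane (PCM) and the ciliary middle segment (MS) — separated by
a ~1 µm transition zone (TZ) that acts as a tunable diffusion barrier.
Molecules perform reflected Brownian motion within pools; a step attempting
to cross a TZ boundary succeeds with probability ``p_tz`` and is otherwise
reflected.  In intact-barrier mode molecules never occupy the TZ interval
(ARL-13 is excluded from the wild-type TZ membrane): a successful crossing
jumps across the interval.  In compromised mode (``tz_occupancy=True``,
modelling mks-5 class mutants) molecules may reside inside the TZ and the
boundaries act as semi-permeable walls.

Photobleaching is instantaneous per event and stochastic per molecule.
Optional IFT-like directed transport moves bound molecules ballistically.
A separate exact transition-kernel integrator (:func:`expected_trace`)
provides the noise-free expectation of the stochastic simulator and is used
as its correctness oracle.

Coordinates: 1D position in µm, origin at the proximal PCM boundary,
increasing toward the ciliary tip; anterograde = increasing coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimConfig",
    "IFTParams",
    "NoiseParams",
    "ROI",
    "AcquisitionSchedule",
    "IntensityTrace",
    "ApmsTruth",
    "INTRACILIARY_SCHEDULE",
    "COMPARTMENTAL_SCHEDULE",
    "default_rois",
    "simulate_membrane",
    "expected_trace",
    "simulate_kymograph",
    "generate_apms_dataset",
]


# --------------------------------------------------------------------------
# configuration dataclasses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IFTParams:
    """Directed (IFT-like) transport parameters.

    k_on / k_off are per-second binding/unbinding rates between the freely
    diffusing and train-bound states; v_ant / v_ret are anterograde and
    retrograde train speeds in µm/s; train_rate is the per-second injection
    rate of trains in kymograph simulations.
    """

    k_on: float = 0.0
    k_off: float = 0.0
    v_ant: float = 0.65
    v_ret: float = 0.0
    train_rate: float = 0.0


@dataclass(frozen=True)
class NoiseParams:
    """Imaging model: intensity = gain * count + background + N(0, sigma)."""

    gain: float = 1.0
    background: float = 0.0
    sigma: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Geometry, dynamics and imaging parameters of the membrane simulator.

    Lengths in µm.  The domain is [0, L_pcm + L_tz + L_ms + L_ds] with the
    PCM at the origin and the ciliary tip at the far end.  ``p_tz`` is the
    per-attempt probability that a diffusive step crossing a TZ boundary
    succeeds; ``p_msds`` optionally adds a second semi-permeable wall at the
    middle/distal-segment boundary.  ``dendrite_rate`` exchanges PCM
    molecules with an external (unbleached) reservoir; the default 0 encodes
    the sealed-dendrite behaviour observed in vivo (almost no recovery after
    bleaching both pools).
    """

    L_pcm: float = 2.0
    L_tz: float = 1.0
    L_ms: float = 3.0
    L_ds: float = 0.0
    D: float = 0.1
    p_tz: float = 0.01
    p_msds: float | None = None
    tz_occupancy: bool = False
    dendrite_rate: float = 0.0
    n_molecules: int = 1000
    dt: float = 0.25
    bleach_efficiency: float = 0.95
    ift: IFTParams | None = None
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    # -- derived geometry ---------------------------------------------------
    @property
    def tz_start(self) -> float:
        return self.L_pcm

    @property
    def tz_end(self) -> float:
        return self.L_pcm + self.L_tz

    @property
    def ms_end(self) -> float:
        return self.L_pcm + self.L_tz + self.L_ms

    @property
    def total_length(self) -> float:
        return self.L_pcm + self.L_tz + self.L_ms + self.L_ds

    @property
    def step_sd(self) -> float:
        return math.sqrt(2.0 * self.D * self.dt)

    def validate(self) -> None:
        if self.L_pcm <= 0 or self.L_ms <= 0:
            raise ValueError("L_pcm and L_ms must be > 0")
        if self.L_tz < 0 or self.L_ds < 0:
            raise ValueError("lengths must be >= 0")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        for name in ("p_tz", "bleach_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_msds is not None and not 0.0 <= self.p_msds <= 1.0:
            raise ValueError("p_msds must be in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.L_tz > 0 and self.step_sd > self.L_tz / 2.0 + 1e-12:
            raise ValueError(
                "unstable dt: sqrt(2*D*dt) = %.4g exceeds L_tz/2 = %.4g; "
                "reduce dt or D" % (self.step_sd, self.L_tz / 2.0)
            )
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.dendrite_rate < 0:
            raise ValueError("dendrite_rate must be >= 0")


@dataclass(frozen=True)
class ROI:
    """A 1D region of interest [start, end) in µm along the membrane."""

    name: str
    start: float
    end: float

    def validate(self, total_length: float) -> None:
        if not (0.0 <= self.start < self.end <= total_length + 1e-9):
            raise ValueError(
                f"ROI {self.name!r} [{self.start}, {self.end}] outside "
                f"domain [0, {total_length}]"
            )

    def contains(self, x: np.ndarray) -> np.ndarray:
        return (x >= self.start) & (x < self.end)


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Imaging timepoints relative to the bleach pulse at t = 0 s."""

    pre_bleach_times: tuple[float, ...]
    post_bleach_times: tuple[float, ...]
    name: str = "custom"

    def validate(self) -> None:
        times = self.times
        if len(self.pre_bleach_times) < 2:
            raise ValueError("need >= 2 pre-bleach timepoints")
        if any(t >= 0 for t in self.pre_bleach_times):
            raise ValueError("pre-bleach times must be < 0")
        if any(t < 0 for t in self.post_bleach_times):
            raise ValueError("post-bleach times must be >= 0")
        if not np.all(np.diff(times) > 0):
            raise ValueError("schedule times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(
            tuple(self.pre_bleach_times) + tuple(self.post_bleach_times), dtype=float
        )


#: Intraciliary FRAP preset: immediate post-bleach frame then 15..600 s.
INTRACILIARY_SCHEDULE = AcquisitionSchedule(
    pre_bleach_times=(-30.0, -15.0),
    post_bleach_times=(1.0, 15.0, 30.0, 60.0, 120.0, 180.0, 240.0, 360.0, 480.0, 600.0),
    name="intraciliary",
)

#: Compartmental (PCM / cilium / both) FRAP preset, out to 1200 s.
COMPARTMENTAL_SCHEDULE = AcquisitionSchedule(
    pre_bleach_times=(-30.0, -15.0),
    post_bleach_times=(
        1.0, 15.0, 30.0, 60.0, 120.0, 180.0, 240.0, 300.0, 600.0, 900.0, 1200.0,
    ),
    name="compartmental",
)


def default_rois(config: SimConfig) -> dict[str, ROI]:
    """Standard ROI layout: PCM, whole cilium (MS+DS), and MS 40/60 split."""
    return {
        "pcm": ROI("pcm", 0.0, config.tz_start),
        "cilium": ROI("cilium", config.tz_end, config.total_length),
        "ms_proximal": ROI(
            "ms_proximal", config.tz_end, config.tz_end + 0.4 * config.L_ms
        ),
        "ms_distal": ROI(
            "ms_distal", config.tz_end + 0.4 * config.L_ms, config.ms_end
        ),
    }


@dataclass
class IntensityTrace:
    """Per-timepoint ROI intensities from a simulated (or real) recording.

    ``raw`` is (n_times, n_rois) in arbitrary units; ``truth`` holds the
    underlying fluorescent-molecule counts when known.
    """

    times: np.ndarray
    roi_names: list[str]
    raw: np.ndarray
    background: float
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (self.times.size, len(self.roi_names)):
            raise ValueError("raw must have shape (n_times, n_rois)")
        if np.any(self.raw < 0):
            raise ValueError("raw intensities must be >= 0")

    def column(self, roi_name: str) -> np.ndarray:
        try:
            j = self.roi_names.index(roi_name)
        except ValueError:
            raise KeyError(f"ROI {roi_name!r} not in trace ({self.roi_names})")
        return self.raw[:, j]

    def truth_column(self, roi_name: str) -> np.ndarray:
        if self.truth is None:
            raise ValueError("trace carries no ground-truth counts")
        j = self.roi_names.index(roi_name)
        return self.truth[:, j]


# --------------------------------------------------------------------------
# Brownian stepping with semi-permeable walls
# --------------------------------------------------------------------------

def _initial_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform positions over the occupiable region."""
    n = config.n_molecules
    if config.tz_occupancy or config.L_tz == 0:
        return rng.uniform(0.0, config.total_length, n)
    # excluded-TZ mode: uniform over PCM union (MS+DS), weighted by length
    l_pcm = config.L_pcm
    l_cil = config.total_length - config.tz_end
    u = rng.uniform(0.0, l_pcm + l_cil, n)
    return np.where(u < l_pcm, u, config.tz_end + (u - l_pcm))


def _cross_wall(
    x: np.ndarray,
    prop: np.ndarray,
    wall: float,
    p_cross: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Resolve a semi-permeable wall (occupiable on both sides).

    A proposed step ending on the far side of ``wall`` succeeds with
    probability ``p_cross``, else the molecule is reflected about the wall.
    """
    from_left = x < wall
    crossing = (from_left & (prop >= wall)) | (~from_left & (prop < wall))
    if not np.any(crossing):
        return prop
    out = prop.copy()
    blocked = crossing & (rng.random(x.size) >= p_cross)
    out[blocked] = 2.0 * wall - prop[blocked]
    return out


def _step_positions(
    x: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    mobile: np.ndarray | None = None,
) -> np.ndarray:
    """One Brownian step with barrier and boundary rules applied."""
    prop = x + rng.normal(0.0, config.step_sd, x.size)
    a, b = config.tz_start, config.tz_end
    if config.L_tz > 0:
        if config.tz_occupancy:
            # two semi-permeable walls, resolved sequentially (double
            # crossings are rare under the dt stability constraint)
            prop = _cross_wall(x, prop, a, config.p_tz, rng)
            prop = _cross_wall(x, prop, b, config.p_tz, rng)
        else:
            out = prop.copy()
            u = rng.random(x.size)
            # PCM molecules attempting to enter the TZ interval: success
            # jumps across the excluded interval, failure reflects
            attempt = (x < a) & (prop >= a)
            passed = attempt & (u < config.p_tz)
            out[passed] = prop[passed] + (b - a)
            out[attempt & ~passed] = 2.0 * a - prop[attempt & ~passed]
            # ciliary molecules attempting to enter the TZ interval
            attempt = (x >= b) & (prop < b)
            passed = attempt & (u < config.p_tz)
            out[passed] = prop[passed] - (b - a)
            out[attempt & ~passed] = 2.0 * b - prop[attempt & ~passed]
            prop = out
    if config.p_msds is not None and config.L_ds > 0:
        prop = _cross_wall(x, prop, config.ms_end, config.p_msds, rng)
    # reflecting outer boundaries
    L = config.total_length
    prop = np.abs(prop)
    prop = np.where(prop > L, 2.0 * L - prop, prop)
    prop = np.clip(prop, 0.0, L)
    if mobile is not None:
        prop = np.where(mobile, prop, x)
    return prop


def _time_grid(config: SimConfig, t0: float, t1: float) -> np.ndarray:
    n_steps = int(round((t1 - t0) / config.dt))
    return t0 + config.dt * np.arange(n_steps + 1)


def _snap_indices(times: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Map event/sample times to the nearest step index on the dt grid."""
    return np.clip(
        np.round((np.asarray(times, dtype=float) - grid[0]) / (grid[1] - grid[0]))
        .astype(int),
        0,
        grid.size - 1,
    )


# --------------------------------------------------------------------------
# stochastic simulator
# --------------------------------------------------------------------------

def simulate_membrane(
    config: SimConfig,
    rois: list[ROI] | dict[str, ROI],
    schedule: AcquisitionSchedule,
    bleach_events: list[tuple[float, ROI]],
    seed: int | None = None,
) -> IntensityTrace:
    """Simulate the membrane and return ROI intensity readouts.

    ``bleach_events`` is a list of (time_s, roi) pairs; at each event every
    fluorescent molecule inside the ROI is bleached independently with
    probability ``config.bleach_efficiency``.  The readout at each scheduled
    time is gain * (fluorescent count in ROI) + background + N(0, sigma),
    floored at zero.  Total molecule count is conserved and the fluorescent
    count never increases (with ``dendrite_rate`` = 0).
    """
    config.validate()
    schedule.validate()
    if isinstance(rois, dict):
        rois = list(rois.values())
    for roi in rois:
        roi.validate(config.total_length)
    times = schedule.times
    t0, t1 = times[0], times[-1]
    for t_ev, roi in bleach_events:
        if not (t0 <= t_ev <= t1):
            raise ValueError(f"bleach event at {t_ev} s outside schedule span")
        roi.validate(config.total_length)

    rng = np.random.default_rng(config.seed if seed is None else seed)
    x = _initial_positions(config, rng)
    fluorescent = np.ones(x.size, dtype=bool)
    bound = np.zeros(x.size, dtype=bool)
    direction = np.ones(x.size)  # +1 anterograde, -1 retrograde (bound only)

    grid = _time_grid(config, t0, t1)
    sample_idx = _snap_indices(times, grid)
    events: dict[int, list[ROI]] = {}
    for t_ev, roi in bleach_events:
        events.setdefault(int(_snap_indices([t_ev], grid)[0]), []).append(roi)
    sample_map: dict[int, list[int]] = {}
    for i, si in enumerate(sample_idx):
        sample_map.setdefault(int(si), []).append(i)

    counts = np.zeros((times.size, len(rois)))
    raw = np.zeros_like(counts)
    ift = config.ift

    for step in range(grid.size):
        if step > 0:
            x = _step_positions(x, config, rng, mobile=~bound if bound.any() else None)
            if ift is not None and (ift.k_on > 0 or bound.any()):
                # bound molecules ride trains ballistically, crossing the
                # barrier freely (active transport across the TZ)
                v = np.where(direction > 0, ift.v_ant, -abs(ift.v_ret))
                x = np.where(bound, x + v * config.dt, x)
                at_end = bound & ((x >= config.total_length) | (x <= 0.0))
                x = np.clip(x, 0.0, config.total_length)
                bound &= ~at_end  # release at the ends of the track
                release = bound & (rng.random(x.size) < ift.k_off * config.dt)
                bound &= ~release
                bind = (
                    ~bound
                    & (rng.random(x.size) < ift.k_on * config.dt)
                    & (x >= config.tz_end)  # trains load within the cilium
                )
                direction = np.where(bind, 1.0, direction)
                bound |= bind
                if not config.tz_occupancy and config.L_tz > 0:
                    # freshly released cargo inside the excluded TZ interval
                    # is pushed to the nearest pool boundary
                    in_tz = ~bound & (x > config.tz_start) & (x < config.tz_end)
                    if np.any(in_tz):
                        mid = 0.5 * (config.tz_start + config.tz_end)
                        x[in_tz] = np.where(
                            x[in_tz] < mid, config.tz_start, config.tz_end
                        )
            if config.dendrite_rate > 0:
                # exchange PCM molecules with an external fluorescent pool
                swap = (x < config.tz_start) & (
                    rng.random(x.size) < config.dendrite_rate * config.dt
                )
                fluorescent |= swap
        if step in events:
            for roi in events[step]:
                hit = fluorescent & roi.contains(x)
                bleached = hit & (rng.random(x.size) < config.bleach_efficiency)
                fluorescent &= ~bleached
        if step in sample_map:
            for i in sample_map[step]:
                for j, roi in enumerate(rois):
                    counts[i, j] = np.count_nonzero(fluorescent & roi.contains(x))
                noise = (
                    rng.normal(0.0, config.noise.sigma, len(rois))
                    if config.noise.sigma > 0
                    else np.zeros(len(rois))
                )
                raw[i] = np.maximum(
                    config.noise.gain * counts[i] + config.noise.background + noise,
                    0.0,
                )

    return IntensityTrace(
        times=times,
        roi_names=[r.name for r in rois],
        raw=raw,
        background=config.noise.background,
        truth=counts,
    )


# --------------------------------------------------------------------------
# exact transition-kernel oracle
# --------------------------------------------------------------------------

def _make_bins(config: SimConfig, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Bin boundaries (lo, hi arrays) covering the occupiable region."""
    a, b, L = config.tz_start, config.tz_end, config.total_length
    if config.tz_occupancy or config.L_tz == 0:
        n = max(8, int(math.ceil(L / h)))
        edges = np.linspace(0.0, L, n + 1)
        # align bin edges with the TZ walls so the kernel sees sharp walls
        if config.L_tz > 0:
            edges = np.unique(np.concatenate([edges, [a, b]]))
        return edges[:-1], edges[1:]
    n1 = max(2, int(math.ceil(a / h)))
    n2 = max(2, int(math.ceil((L - b) / h)))
    e1 = np.linspace(0.0, a, n1 + 1)
    e2 = np.linspace(b, L, n2 + 1)
    return (
        np.concatenate([e1[:-1], e2[:-1]]),
        np.concatenate([e1[1:], e2[1:]]),
    )


def _bin_locator(config: SimConfig, lo: np.ndarray, hi: np.ndarray):
    """Return a vectorized position -> bin-index function."""
    a, b = config.tz_start, config.tz_end
    if config.tz_occupancy or config.L_tz == 0:
        edges = np.append(lo, hi[-1])

        def loc(pos: np.ndarray) -> np.ndarray:
            idx = np.searchsorted(edges, pos, side="right") - 1
            return np.clip(idx, 0, lo.size - 1)

    else:
        n1 = int(np.searchsorted(lo, a - 1e-12))
        e1 = np.append(lo[:n1], a)
        e2 = np.append(lo[n1:], hi[-1])
        mid = 0.5 * (a + b)

        def loc(pos: np.ndarray) -> np.ndarray:
            idx = np.empty(pos.size, dtype=int)
            left = pos < mid
            idx[left] = np.clip(
                np.searchsorted(e1, pos[left], side="right") - 1, 0, n1 - 1
            )
            idx[~left] = n1 + np.clip(
                np.searchsorted(e2, pos[~left], side="right") - 1,
                0,
                lo.size - n1 - 1,
            )
            return idx

    return loc


def _step_outcomes(
    xi: float, prop: np.ndarray, w: np.ndarray, config: SimConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a Gaussian proposal into (positions, weights) barrier outcomes.

    Implements exactly the rule of :func:`_step_positions` with the barrier
    Bernoulli trials expanded into weighted branches.
    """
    a, b = config.tz_start, config.tz_end
    branches: list[tuple[np.ndarray, np.ndarray]] = [(prop, w)]

    def split(branches, wall, p, start_left):
        out = []
        for pos, wt in branches:
            crossing = (pos >= wall) if start_left else (pos < wall)
            stay = ~crossing
            if stay.any():
                out.append((pos[stay], wt[stay]))
            if crossing.any():
                if p > 0:
                    out.append((pos[crossing], wt[crossing] * p))
                if p < 1:
                    out.append((2.0 * wall - pos[crossing], wt[crossing] * (1.0 - p)))
        return out

    if config.L_tz > 0:
        if config.tz_occupancy:
            branches = split(branches, a, config.p_tz, xi < a)
            branches = split(branches, b, config.p_tz, xi < b)
        else:
            if xi < a:
                crossing = prop >= a
                branches = [(prop[~crossing], w[~crossing])]
                if crossing.any():
                    if config.p_tz > 0:
                        branches.append(
                            (prop[crossing] + (b - a), w[crossing] * config.p_tz)
                        )
                    if config.p_tz < 1:
                        branches.append(
                            (2.0 * a - prop[crossing], w[crossing] * (1.0 - config.p_tz))
                        )
            else:
                crossing = prop < b
                branches = [(prop[~crossing], w[~crossing])]
                if crossing.any():
                    if config.p_tz > 0:
                        branches.append(
                            (prop[crossing] - (b - a), w[crossing] * config.p_tz)
                        )
                    if config.p_tz < 1:
                        branches.append(
                            (2.0 * b - prop[crossing], w[crossing] * (1.0 - config.p_tz))
                        )
    if config.p_msds is not None and config.L_ds > 0:
        # only mass that did not change sides via the TZ can meet this wall
        branches = split(branches, config.ms_end, config.p_msds, xi < config.ms_end)
    return branches


def _kernel_matrix(
    config: SimConfig, centers: np.ndarray, loc
) -> np.ndarray:
    """One-step transition matrix over bin centers by Gaussian quadrature."""
    sd = config.step_sd
    dz = np.linspace(-5.0 * sd, 5.0 * sd, 801)
    w = np.exp(-0.5 * (dz / sd) ** 2)
    w /= w.sum()
    L = config.total_length
    n = centers.size
    K = np.zeros((n, n))
    for i, xi in enumerate(centers):
        for pos, wt in _step_outcomes(xi, xi + dz, w, config):
            pos = np.abs(pos)
            pos = np.where(pos > L, 2.0 * L - pos, pos)
            pos = np.clip(pos, 0.0, L - 1e-12)
            np.add.at(K[i], loc(pos), wt)
    return K


def expected_trace(
    config: SimConfig,
    rois: list[ROI] | dict[str, ROI],
    schedule: AcquisitionSchedule,
    bleach_events: list[tuple[float, ROI]],
    bin_width: float | None = None,
) -> IntensityTrace:
    """Noise-free expectation of :func:`simulate_membrane`.

    Iterates the exact single-molecule transition kernel (position ×
    fluorescence discretized Markov chain built from the same step rule as
    the stochastic simulator).  Independent of any seed.  Only pure-diffusion
    configurations are supported; configs with IFT transport are rejected.
    """
    config.validate()
    schedule.validate()
    if config.ift is not None and (config.ift.k_on > 0 or config.ift.train_rate > 0):
        raise ValueError("expected_trace supports diffusion-only configurations")
    if isinstance(rois, dict):
        rois = list(rois.values())
    for roi in rois:
        roi.validate(config.total_length)

    max_bin = (
        config.step_sd / 2.0 if config.D > 0 else config.total_length / 64.0
    )
    h = max_bin if bin_width is None else bin_width
    if h > max_bin + 1e-12:
        raise ValueError(
            f"discretization bin {h} too coarse; need <= sqrt(2 D dt)/2 = "
            f"{max_bin:.4g}"
        )

    lo, hi = _make_bins(config, h)
    centers = 0.5 * (lo + hi)
    widths = hi - lo
    loc = _bin_locator(config, lo, hi)
    K = (
        _kernel_matrix(config, centers, loc)
        if config.D > 0
        else np.eye(centers.size)
    )

    # expected molecules per bin; fluorescence tracked as a second density
    total = config.n_molecules * widths / widths.sum()
    fluor = total.copy()

    times = schedule.times
    grid = _time_grid(config, times[0], times[-1])
    sample_idx = _snap_indices(times, grid)
    ev_idx: dict[int, list[ROI]] = {}
    for t_ev, roi in bleach_events:
        if not (times[0] <= t_ev <= times[-1]):
            raise ValueError(f"bleach event at {t_ev} s outside schedule span")
        roi.validate(config.total_length)
        ev_idx.setdefault(int(_snap_indices([t_ev], grid)[0]), []).append(roi)
    sample_map: dict[int, list[int]] = {}
    for i, si in enumerate(sample_idx):
        sample_map.setdefault(int(si), []).append(i)

    def overlap_frac(roi: ROI) -> np.ndarray:
        o = np.clip(np.minimum(hi, roi.end) - np.maximum(lo, roi.start), 0.0, None)
        return o / widths

    roi_frac = np.vstack([overlap_frac(r) for r in rois])
    counts = np.zeros((times.size, len(rois)))

    for step in range(grid.size):
        if step > 0 and config.D > 0:
            fluor = fluor @ K
            total = total @ K
        if step in ev_idx:
            for roi in ev_idx[step]:
                fluor = fluor * (1.0 - config.bleach_efficiency * overlap_frac(roi))
        if step in sample_map:
            for i in sample_map[step]:
                counts[i] = roi_frac @ fluor

    raw = np.maximum(config.noise.gain * counts + config.noise.background, 0.0)
    return IntensityTrace(
        times=times,
        roi_names=[r.name for r in rois],
        raw=raw,
        background=config.noise.background,
        truth=counts,
    )


# --------------------------------------------------------------------------
# kymograph simulation
# --------------------------------------------------------------------------

def simulate_kymograph(
    config: SimConfig,
    duration: float,
    pixel_size: float = 0.1,
    frame_interval: float = 1.0 / 3.0,
    n_anterograde: int | None = None,
    n_retrograde: int | None = None,
    particle_amplitude: float = 50.0,
    seed: int | None = None,
):
    """Simulate a time × position kymograph with IFT-like moving particles.

    Particles move ballistically (anterograde at ``ift.v_ant`` from the base,
    retrograde at ``ift.v_ret`` from the tip when enabled), rendered with a
    1-pixel-sd Gaussian point-spread function on top of the diffusing
    molecular background, camera background and Gaussian read noise.  The
    default frame interval of 1/3 s matches 3 frames-per-second video.
    ``n_anterograde``/``n_retrograde`` override the Poisson train process
    with an exact particle count.

    Returns ``(Kymograph, tracks)`` where ``tracks`` are the exact
    ground-truth trajectories (:class:`ciliagate.kymo.Track`).
    """
    from .kymo import Kymograph, Track  # local import to avoid a cycle

    config.validate()
    if config.ift is None:
        raise ValueError("simulate_kymograph requires config.ift to be set")
    if pixel_size <= 0 or frame_interval <= 0 or duration <= 0:
        raise ValueError("duration, pixel_size and frame_interval must be > 0")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    ift = config.ift
    L = config.total_length
    n_frames = int(math.floor(duration / frame_interval)) + 1
    n_px = int(math.ceil(L / pixel_size))
    frame_times = frame_interval * np.arange(n_frames)

    # particle birth times: (t0, x0, v_signed)
    births: list[tuple[float, float, float]] = []
    def spaced_times(n: int, hi: float) -> np.ndarray:
        # jittered even spacing: trains are discrete, so successive
        # particles stay separated by >= 0.4 * (hi / n) in birth time and
        # never overlap within the point-spread function
        spacing = hi / n
        jitter = rng.uniform(-0.3, 0.3, n)
        return (np.arange(n) + 0.5 + jitter) * spacing

    if n_anterograde is not None:
        if ift.v_ant <= 0:
            raise ValueError("n_anterograde requires ift.v_ant > 0")
        hi_t = max(duration - L / ift.v_ant, 1e-6)
        for t0 in spaced_times(n_anterograde, hi_t):
            births.append((float(t0), 0.0, ift.v_ant))
    elif ift.train_rate > 0 and ift.v_ant > 0:
        t = rng.exponential(1.0 / ift.train_rate)
        while t < duration:
            births.append((t, 0.0, ift.v_ant))
            t += rng.exponential(1.0 / ift.train_rate)
    if n_retrograde is not None:
        if ift.v_ret <= 0:
            raise ValueError("n_retrograde requires ift.v_ret > 0")
        hi_t = max(duration - L / ift.v_ret, 1e-6)
        for t0 in spaced_times(n_retrograde, hi_t):
            births.append((float(t0), L, -ift.v_ret))
    elif ift.v_ret > 0 and ift.train_rate > 0 and n_anterograde is None:
        t = rng.exponential(1.0 / ift.train_rate)
        while t < duration:
            births.append((t, L, -ift.v_ret))
            t += rng.exponential(1.0 / ift.train_rate)

    # the unbound, diffusing ARL-13 pool forms the fluctuating background
    x_bg = _initial_positions(config, rng)
    data = np.zeros((n_frames, n_px))
    px_centers = (np.arange(n_px) + 0.5) * pixel_size
    px_index = np.arange(n_px, dtype=float)
    track_points: list[list[tuple[int, float]]] = [[] for _ in births]

    n_sub = max(1, int(round(frame_interval / config.dt)))
    sub_cfg = replace(config, dt=frame_interval / n_sub)

    for f, t in enumerate(frame_times):
        if f > 0:
            for _ in range(n_sub):
                x_bg = _step_positions(x_bg, sub_cfg, rng)
        frame = np.full(n_px, config.noise.background, dtype=float)
        if config.noise.gain > 0:
            d = (px_centers[None, :] - x_bg[:, None]) / pixel_size
            frame += config.noise.gain * np.exp(-0.5 * d**2).sum(axis=0)
        for k, (t0, x0, v) in enumerate(births):
            pos = x0 + v * (t - t0)
            if t < t0 or pos < 0.0 or pos > L:
                continue
            pos_px = pos / pixel_size
            frame += particle_amplitude * np.exp(-0.5 * (px_index - pos_px) ** 2)
            track_points[k].append((f, pos_px))
        if config.noise.sigma > 0:
            frame = frame + rng.normal(0.0, config.noise.sigma, n_px)
        data[f] = np.maximum(frame, 0.0)

    tracks = [
        Track(points=pts, velocity=births[k][2], residual=0.0)
        for k, pts in enumerate(track_points)
        if len(pts) >= 2
    ]
    kym = Kymograph(data=data, frame_interval=frame_interval, pixel_size=pixel_size)
    return kym, tracks


# --------------------------------------------------------------------------
# synthetic AP-MS data
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ApmsTruth:
    """Ground truth for a synthetic AP-MS purification series.

    ``interactors`` maps symbol -> mean peptide count per bait experiment
    (Poisson rate); ``contaminants`` maps symbol -> probability of appearing
    in any single control run (contaminants also appear in bait runs with
    Poisson counts at ``contaminant_rate``).  ``silac_enrichment`` maps
    interactor symbol -> true log2 H/L enrichment; contaminants are centred
    at log2 ratio 0.
    """

    bait: str
    interactors: dict[str, float]
    contaminants: dict[str, float]
    silac_enrichment: dict[str, float]
    silac_noise_sd: float = 0.2
    contaminant_rate: float = 4.0
    bait_rate: float = 30.0
    n_experiments: int = 3
    n_control_runs: int = 8
    seed: int = 0

    def validate(self) -> None:
        if any(r < 0 for r in self.interactors.values()):
            raise ValueError("interactor rates must be >= 0")
        if any(not 0.0 <= p <= 1.0 for p in self.contaminants.values()):
            raise ValueError("contaminant probabilities must be in [0, 1]")
        if self.silac_noise_sd < 0 or self.contaminant_rate < 0:
            raise ValueError("rates and noise must be >= 0")
        if self.n_experiments < 1 or self.n_control_runs < 1:
            raise ValueError("need >= 1 experiment and control run")


def generate_apms_dataset(truth: ApmsTruth, seed: int | None = None):
    """Draw synthetic TAP and SILAC protein records from ``truth``.

    Interactors receive Poisson peptide counts per bait experiment, high
    identification probabilities and zero control-run occurrence;
    contaminants appear in control runs per their probability and carry
    near-zero SILAC log2 ratios.  Reproducible under the seed.
    """
    from .apms import SilacProteinRecord, TapProteinRecord  # avoid a cycle

    truth.validate()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    tap: list = []
    silac: list = []

    def tap_record(symbol, rate, ctrl_p, is_bait=False):
        counts = rng.poisson(rate, truth.n_experiments)
        in_ctrl = rng.random(truth.n_control_runs) < ctrl_p
        return TapProteinRecord(
            symbol=symbol,
            counts=tuple(int(c) for c in counts),
            peptide_probability=float(rng.uniform(0.9, 0.999)),
            protein_probability=float(rng.uniform(0.96, 0.999)),
            control_frequency=float(np.mean(in_ctrl)),
            is_bait=is_bait,
        )

    def silac_record(symbol, log2_true, rate):
        ratios = log2_true + rng.normal(0.0, truth.silac_noise_sd, truth.n_experiments)
        peptides = rng.poisson(rate, truth.n_experiments)
        return SilacProteinRecord(
            symbol=symbol,
            log2_ratios=tuple(float(r) for r in ratios),
            peptides_quantified=tuple(int(p) for p in peptides),
        )

    tap.append(tap_record(truth.bait, truth.bait_rate, 0.0, is_bait=True))
    silac.append(
        silac_record(
            truth.bait, truth.silac_enrichment.get(truth.bait, 3.0), truth.bait_rate
        )
    )
    for sym, rate in truth.interactors.items():
        tap.append(tap_record(sym, rate, 0.0))
        silac.append(silac_record(sym, truth.silac_enrichment.get(sym, 1.5), rate))
    for sym, ctrl_p in truth.contaminants.items():
        tap.append(tap_record(sym, truth.contaminant_rate, ctrl_p))
        silac.append(silac_record(sym, 0.0, truth.contaminant_rate))
    return tap, silac
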