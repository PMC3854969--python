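"""FRAP quantification: ratio statistic, one-phase association fitting,
barrier classification, and compartment signal/length measurements.

The recovery statistic is the background-subtracted ratio of the bleached
to the non-bleached ROI, normalised so the mean pre-bleach ratio is 1.0.
Because both ROIs suffer acquisition photobleaching equally, the ratio is
invariant to uniform attenuation — the design rationale of the statistic.
Post-bleach recovery is fitted with the one-phase association model

    F(t) = plateau - (plateau - f0) * exp(-k t),      t_1/2 = ln 2 / k,

the conventional FRAP saturation model; fits are gated on R² > 0.75.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import optimize, stats

from .simulate import IntensityTrace

__all__ = [
    "FRAPCurve",
    "RecoveryFit",
    "CompartmentQuant",
    "BarrierAssessment",
    "ClassifyThresholds",
    "ratio_curve",
    "subtract_baseline",
    "fit_recovery",
    "classify_exchange",
    "reciprocal_decline",
    "compartment_ratio",
    "compartment_length",
    "compare_groups",
    "one_phase_association",
]

R2_GATE = 0.75


@dataclass
class FRAPCurve:
    """A bleach-aligned, normalised bleached:non-bleached ratio series.

    Times are in seconds with the bleach at t = 0 (pre-bleach times are
    negative); values are dimensionless with mean pre-bleach value 1.0.
    """

    times: np.ndarray
    values: np.ndarray
    n_prebleach: int
    bleached_roi: str = ""
    reference_roi: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.n_prebleach >= 1:
            pre = self.values[: self.n_prebleach]
            if abs(float(pre.mean()) - 1.0) > 1e-9:
                raise ValueError(
                    "pre-bleach values must be normalised to mean 1.0 "
                    f"(got {pre.mean():.6g})"
                )

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.n_prebleach:]

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.n_prebleach:]


@dataclass(frozen=True)
class RecoveryFit:
    """One-phase association fit of a FRAP recovery."""

    k: float
    t_half: float
    f0: float
    plateau: float
    r_squared: float
    n_points: int
    converged: bool

    @property
    def passes_gate(self) -> bool:
        """High-goodness-of-fit gate: exactly R² > 0.75, no epsilon slack."""
        return self.r_squared > R2_GATE


def one_phase_association(
    t: np.ndarray, f0: float, plateau: float, k: float
) -> np.ndarray:
    """F(t) = plateau - (plateau - f0) exp(-k t)."""
    return plateau - (plateau - f0) * np.exp(-k * np.asarray(t, dtype=float))


# --------------------------------------------------------------------------
# ratio statistic
# --------------------------------------------------------------------------

def ratio_curve(
    trace: IntensityTrace,
    bleached: str,
    reference: str,
    bleach_time: float,
    background: float | np.ndarray | None = None,
    n_prebleach: int | None = None,
) -> FRAPCurve:
    """Bleached:non-bleached ratio curve, background-subtracted and
    normalised to the mean pre-bleach ratio.

    value(t) = [(I_bleached(t) - BG) / (I_reference(t) - BG)] / R_pre,
    with times shifted so that ``bleach_time`` maps to 0.
    """
    bg = trace.background if background is None else background
    ib = trace.column(bleached) - bg
    ir = trace.column(reference) - bg
    if np.any(ir <= 0):
        t_bad = trace.times[np.argmax(ir <= 0)]
        raise ValueError(
            f"non-positive background-subtracted reference intensity at "
            f"t = {t_bad} s"
        )
    times = trace.times - bleach_time
    pre = times < 0
    n_pre = int(np.count_nonzero(pre)) if n_prebleach is None else n_prebleach
    if n_pre < 2:
        raise ValueError("need >= 2 pre-bleach timepoints")
    ratio = ib / ir
    r_pre = float(ratio[:n_pre].mean())
    if r_pre <= 0:
        raise ValueError("mean pre-bleach ratio must be > 0")
    return FRAPCurve(
        times=times,
        values=ratio / r_pre,
        n_prebleach=n_pre,
        bleached_roi=bleached,
        reference_roi=reference,
    )


def pool_intensity_curve(
    trace: IntensityTrace,
    rois: list[str],
    bleach_time: float,
    background: float | None = None,
) -> FRAPCurve:
    """Summed background-subtracted pool intensity, normalised to the mean
    pre-bleach level.

    Used for the both-pools (PCM+cilium) bleach control, where no unbleached
    reference region exists and any recovery must come from outside the two
    pools: the readout is the total signal of the bleached pools themselves.
    """
    bg = trace.background if background is None else background
    sig = sum(trace.column(r) for r in rois) - bg * len(rois)
    times = trace.times - bleach_time
    pre = times < 0
    n_pre = int(np.count_nonzero(pre))
    if n_pre < 2:
        raise ValueError("need >= 2 pre-bleach timepoints")
    pre_mean = float(sig[:n_pre].mean())
    if pre_mean <= 0:
        raise ValueError("non-positive pre-bleach pool intensity")
    return FRAPCurve(
        times=times,
        values=sig / pre_mean,
        n_prebleach=n_pre,
        bleached_roi="+".join(rois),
        reference_roi="prebleach_total",
    )


def subtract_baseline(curve: FRAPCurve, baseline: FRAPCurve) -> FRAPCurve:
    """Remove the baseline's residual recovery from a FRAP curve.

    The baseline is typically the both-pools (PCM+cilium) bleach control;
    its excess over its own post-bleach floor (first post-bleach value) is
    subtracted from the curve's post-bleach values, and the pre-bleach
    normalisation is re-imposed.
    """
    if (
        baseline.post_times[0] > curve.post_times[0] + 1e-9
        or baseline.post_times[-1] < curve.post_times[-1] - 1e-9
    ):
        raise ValueError("baseline does not span the curve's post-bleach times")
    base_post = np.interp(curve.post_times, baseline.post_times, baseline.post_values)
    floor = baseline.post_values[0]
    excess = base_post - floor
    values = curve.values.copy()
    values[curve.n_prebleach:] = curve.post_values - excess
    pre_mean = float(values[: curve.n_prebleach].mean())
    return FRAPCurve(
        times=curve.times,
        values=values / pre_mean,
        n_prebleach=curve.n_prebleach,
        bleached_roi=curve.bleached_roi,
        reference_roi=curve.reference_roi,
    )


def simulate_compartment_frap(
    config, design: str, seed: int | None = None
) -> tuple[FRAPCurve, IntensityTrace]:
    """Simulate a bleach design and build its analysis curve.

    Designs: 'partial_ms' (40%-of-MS bleach, intraciliary schedule, ratio
    of the bleached MS region to the distal MS reference), 'pcm_only' /
    'cilium_only' (whole-pool bleach, compartmental schedule, ratio to the
    reciprocal pool), 'both' (PCM+cilium bleach; readout is the summed pool
    intensity, since no unbleached reference remains).
    """
    from .simulate import (
        COMPARTMENTAL_SCHEDULE,
        INTRACILIARY_SCHEDULE,
        default_rois,
        simulate_membrane,
    )

    from .simulate import ROI

    rois = default_rois(config)
    designs = {
        "partial_ms": (INTRACILIARY_SCHEDULE, ["ms_proximal"], "ms_distal"),
        "pcm_only": (COMPARTMENTAL_SCHEDULE, ["pcm"], "cilium"),
        "cilium_only": (COMPARTMENTAL_SCHEDULE, ["cilium"], "pcm"),
        "both": (COMPARTMENTAL_SCHEDULE, ["pcm", "cilium"], None),
    }
    if design not in designs:
        raise ValueError(f"unknown design {design!r} (choose from {sorted(designs)})")
    schedule, bleach_names, reference = designs[design]
    if design == "both":
        # the whole-cell quench covers every region with signal, including
        # any TZ-resident molecules in compromised-barrier mode
        bleach = [(0.0, ROI("everything", 0.0, config.total_length))]
    else:
        bleach = [(0.0, rois[n]) for n in bleach_names]
    trace = simulate_membrane(config, rois, schedule, bleach, seed=seed)
    if reference is None:
        curve = pool_intensity_curve(trace, bleach_names, 0.0)
    else:
        curve = ratio_curve(trace, bleach_names[0], reference, 0.0)
    return curve, trace


# --------------------------------------------------------------------------
# one-phase association fitting
# --------------------------------------------------------------------------

_K_BOUNDS = (1e-5, 10.0)


def fit_recovery(curve: FRAPCurve) -> RecoveryFit:
    """Least-squares one-phase association fit on post-bleach points.

    Initialisation: f0 = first post-bleach value, plateau = mean of the last
    two values, k from a log-linear regression of (plateau - F).  k is
    bounded to [1e-5, 10] 1/s.  Non-convergence is flagged, not raised;
    degenerate flat input converges with k at the lower bound and fails the
    R² gate.
    """
    t = curve.post_times
    y = curve.post_values
    if t.size < 4:
        raise ValueError(f"need >= 4 post-bleach points, got {t.size}")

    f0_init = float(y[0])
    plateau_init = float(y[-2:].mean())
    k_init = 0.01
    resid = plateau_init - y
    usable = resid > 1e-12
    if np.count_nonzero(usable) >= 2 and plateau_init > f0_init + 1e-12:
        slope = np.polyfit(t[usable], np.log(resid[usable]), 1)[0]
        if slope < 0:
            k_init = float(np.clip(-slope, *_K_BOUNDS))

    lo_y = min(0.0, float(y.min()))
    hi_y = float(y.max()) + 10.0
    p0 = [
        float(np.clip(f0_init, lo_y, hi_y)),
        float(np.clip(plateau_init, lo_y, hi_y)),
        k_init,
    ]
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                one_phase_association,
                t,
                y,
                p0=p0,
                bounds=([lo_y, lo_y, _K_BOUNDS[0]], [hi_y, hi_y, _K_BOUNDS[1]]),
                maxfev=20000,
                xtol=1e-12,
                ftol=1e-12,
            )
        f0, plateau, k = (float(v) for v in popt)
    except RuntimeError:
        converged = False
        f0, plateau, k = p0

    pred = one_phase_association(t, f0, plateau, k)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RecoveryFit(
        k=k,
        t_half=math.log(2.0) / k,
        f0=f0,
        plateau=plateau,
        r_squared=r2,
        n_points=int(t.size),
        converged=converged,
    )


# --------------------------------------------------------------------------
# barrier classification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifyThresholds:
    """Thresholds for the qualitative exchange classification.

    plateau_thresh: minimum single-pool recovery plateau (fraction of the
    pre-bleach ratio); fast_thresh: maximum single-pool t_1/2 in s;
    null_thresh: maximum recovery of the both-pools control above its
    post-bleach floor; decline_thresh: minimum fractional decline of the
    reciprocal (non-bleached) pool.
    """

    plateau_thresh: float = 0.8
    fast_thresh: float = 60.0
    null_thresh: float = 0.1
    decline_thresh: float = 0.05


@dataclass
class BarrierAssessment:
    """Outcome of the TZ-barrier FRAP classification."""

    status: str  # exchanging | restricted | indeterminate
    recovery_source: str  # reciprocal_pool | external | none
    fits: dict[str, RecoveryFit] = field(default_factory=dict)
    warning: str | None = None


def classify_exchange(
    fits: dict[str, RecoveryFit],
    reciprocal_decline: float = 0.0,
    thresholds: ClassifyThresholds | None = None,
) -> BarrierAssessment:
    """Classify ciliary/PCM exchange from compartment-bleach fits.

    ``fits`` maps bleach design -> fit, with keys among
    {'pcm_only', 'cilium_only', 'both'}.  Exchange requires both single-pool
    recoveries to be fast and near-complete while the both-pools control
    (the sealed-system null) shows essentially no recovery.
    """
    th = thresholds or ClassifyThresholds()
    if "both" not in fits:
        return BarrierAssessment(
            status="indeterminate",
            recovery_source="none",
            fits=dict(fits),
            warning="missing both-pools bleach control",
        )
    singles = {k: f for k, f in fits.items() if k in ("pcm_only", "cilium_only")}
    if not singles:
        raise ValueError("need at least one single-pool fit")

    both = fits["both"]
    both_recovery = both.plateau - both.f0
    if both_recovery > th.null_thresh:
        # recovery in the null control: signal arrives from outside the
        # two pools, so pool-exchange kinetics cannot be interpreted
        return BarrierAssessment(
            status="indeterminate",
            recovery_source="external",
            fits=dict(fits),
            warning="both-pools control recovered above the null threshold",
        )

    def passes(f: RecoveryFit) -> bool:
        return f.plateau >= th.plateau_thresh and f.t_half <= th.fast_thresh

    exchanging = (
        "pcm_only" in singles
        and "cilium_only" in singles
        and all(passes(f) for f in singles.values())
    )
    source = (
        "reciprocal_pool" if reciprocal_decline >= th.decline_thresh else "none"
    )
    return BarrierAssessment(
        status="exchanging" if exchanging else "restricted",
        recovery_source=source,
        fits=dict(fits),
    )


def reciprocal_decline(
    trace: IntensityTrace,
    reference: str,
    bleach_time: float,
    background: float | None = None,
) -> float:
    """Fractional drop of the non-bleached pool between bleach and the last
    timepoint (signal arriving in the bleached pool must leave this one)."""
    bg = trace.background if background is None else background
    sig = trace.column(reference) - bg
    post = trace.times >= bleach_time
    first = float(sig[post][0])
    last = float(sig[post][-1])
    if first <= 0:
        raise ValueError("non-positive reference signal at bleach time")
    return (first - last) / first


# --------------------------------------------------------------------------
# compartment quantification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentQuant:
    """Background-adjusted cilium vs cilium+PCM signal partition."""

    cilium_signal: float
    pcm_signal: float
    background: float
    ciliary_fraction: float


def compartment_ratio(
    cilium: float, pcm: float, background: float = 0.0
) -> CompartmentQuant:
    """Ciliary fraction = (cilium - bg) / ((cilium - bg) + (pcm - bg)),
    with each background-subtracted term clamped at zero."""
    if cilium < 0 or pcm < 0 or background < 0:
        raise ValueError("intensities must be >= 0")
    c = max(cilium - background, 0.0)
    p = max(pcm - background, 0.0)
    if c + p == 0:
        raise ValueError(
            "both compartments at or below background: fraction undefined"
        )
    return CompartmentQuant(
        cilium_signal=cilium,
        pcm_signal=pcm,
        background=background,
        ciliary_fraction=c / (c + p),
    )


def compartment_length(
    profile: np.ndarray,
    pixel_size: float,
    threshold_frac: float = 0.5,
    background: float = 0.0,
) -> float:
    """Compartment length from a 1D intensity profile.

    Length of the longest contiguous pixel run whose background-subtracted
    signal is >= threshold_frac * (max - background), times pixel size.
    The default threshold is the full-width-at-half-maximum convention.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    sig = np.asarray(profile, dtype=float) - background
    peak = float(sig.max())
    if peak <= 0:
        raise ValueError("profile has no signal above background")
    above = sig >= threshold_frac * peak
    # longest run of True
    best = run = 0
    for v in above:
        run = run + 1 if v else 0
        best = max(best, run)
    return best * pixel_size


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------

def compare_groups(measurements: dict[str, np.ndarray]):
    """One-way ANOVA with Bonferroni-corrected pairwise comparisons.

    Returns ``(F, p, pairwise)`` where ``pairwise`` maps (group_a, group_b)
    -> Bonferroni-adjusted p-value (raw p times the number of pairs, capped
    at 1).  Identical zero-variance groups compare at p = 1.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in measurements.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 values")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p_overall = stats.f_oneway(*groups.values())
    if not np.isfinite(p_overall):
        f_stat, p_overall = 0.0, 1.0

    names = sorted(groups)
    pairs = list(combinations(names, 2))
    m = len(pairs)
    pairwise: dict[tuple[str, str], float] = {}
    for ga, gb in pairs:
        va, vb = groups[ga], groups[gb]
        if va.std() == 0 and vb.std() == 0:
            p = 1.0 if va.mean() == vb.mean() else 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p = stats.f_oneway(va, vb)
            if not np.isfinite(p):
                p = 1.0
        pairwise[(ga, gb)] = min(float(p) * m, 1.0)
    return float(f_stat), float(p_overall), pairwise
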