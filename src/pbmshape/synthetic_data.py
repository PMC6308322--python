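"""Seeded synthetic cohorts of segmented pBM curves with a known ICP effect.

The generator emulates the structure of a radial optic-nerve-head OCT study:
each subject contributes two eyes, each eye six B-scans at 30-degree angular
increments, and one lumbar-puncture opening pressure.  The ground-truth pBM
curve for a scan is a gently sloped resting profile plus a smooth
vitreous-ward bump at both margins whose amplitude grows linearly with ICP
above a reference pressure, with angle-specific gain (the nerve head is not
axially symmetric).  Two simulated raters re-trace each scan in pixel
coordinates with axial noise that is larger in the two central
(peripapillary) image eighths, where real raters disagree most.

All randomness is stratified per (subject, eye, angle) so a cohort is
bit-reproducible for a fixed seed regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association_stats import ICP_NORMAL_MAX, IcpRecord
from .curve_io import PbmCurve, RaterTrace, ScanMeta, mirror_x_px
from .errors import ConfigurationError, InputError

#: ICP above this pressure (cm H2O) deflects the pBM toward the vitreous.
REFERENCE_PRESSURE = ICP_NORMAL_MAX

#: Lateral extent of the raised-cosine deflection bump from each margin (μm).
BUMP_SPAN_UM = 1000.0

#: Knot spacing of the smooth ground-truth curve noise process (μm).
NOISE_KNOT_UM = 200.0

ANGLES = (0, 30, 60, 90, 120, 150)
EYES = ("OD", "OS")


def default_deflection_gain(base: float = 2.0, amplitude: float = 1.0) -> np.ndarray:
    """Smooth anisotropic gain profile over scan angle, maximal at 90 degrees.

    gain(theta) = base + amplitude * sin^2(theta), in μm per cm H2O above the
    reference pressure.
    """
    theta = np.deg2rad(ANGLES)
    return base + amplitude * np.sin(theta) ** 2


@dataclass(frozen=True)
class BaselineShape:
    """Resting pBM profile: opening half-width and a gentle outward tilt."""

    half_separation_um: float = 750.0
    slope_um_per_mm: float = -20.0  # y drift per mm moving away from the margin

    def __post_init__(self):
        if self.half_separation_um <= 0:
            raise ConfigurationError("half_separation_um must be positive")


@dataclass(frozen=True)
class SynthParams:
    n_subjects: int = 21
    icp_distribution: tuple = (
        "study_mixture",
        None,  # None -> default mixture parameters, see sample_icp
    )
    deflection_gain: tuple = tuple(default_deflection_gain())
    baseline_shape: BaselineShape = field(default_factory=BaselineShape)
    curve_noise_sd: float = 5.0  # μm, smooth noise of the true curve
    rater_noise_sd_outer: float = 0.59  # px, axial noise outside the center
    rater_noise_sd_central: float = 1.32  # px, axial noise in the central eighths
    lateral_scale: float = 6.0  # μm/px, device range 5.5-6.4
    axial_scale: float = 3.9  # μm/px
    width_px: int = 1024
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.lateral_scale <= 0 or self.axial_scale <= 0:
            raise ConfigurationError("scales must be positive")
        if len(self.deflection_gain) != 6:
            raise ConfigurationError("deflection_gain must have exactly 6 entries")
        if not (self.rater_noise_sd_central >= self.rater_noise_sd_outer >= 0):
            raise ConfigurationError(
                "need rater_noise_sd_central >= rater_noise_sd_outer >= 0"
            )
        if self.curve_noise_sd < 0:
            raise ConfigurationError("curve_noise_sd must be >= 0")
        name = self.icp_distribution[0]
        if name not in ("study_mixture", "normal", "uniform"):
            raise ConfigurationError(f"unknown ICP distribution {name!r}")


#: Default category mixture: 5/21 normal, 5/21 borderline, 11/21 elevated,
#: uniform within category ranges (cm H2O) — the study's category mix.
_DEFAULT_MIXTURE = {
    "weights": (5 / 21, 5 / 21, 11 / 21),
    "ranges": ((10.0, 20.0), (20.5, 24.5), (25.0, 50.0)),
}


def sample_icp(params: SynthParams, rng: np.random.Generator) -> float:
    name, dist_params = params.icp_distribution
    if name == "study_mixture":
        p = dist_params or _DEFAULT_MIXTURE
        k = rng.choice(3, p=np.asarray(p["weights"]) / np.sum(p["weights"]))
        lo, hi = p["ranges"][k]
        return float(rng.uniform(lo, hi))
    if name == "normal":
        p = dist_params or {"mean": 26.5, "sd": 12.4}
        if p["sd"] <= 0:
            raise ConfigurationError("normal ICP distribution needs sd > 0")
        return float(np.clip(rng.normal(p["mean"], p["sd"]), 1.0, None))
    if name == "uniform":
        p = dist_params or {"low": 10.0, "high": 45.0}
        return float(rng.uniform(p["low"], p["high"]))
    raise ConfigurationError(f"unknown ICP distribution {name!r}")


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in keys])


def _margin_px(params: SynthParams) -> tuple[int, int]:
    center_px = params.width_px / 2.0
    half_sep_px = params.baseline_shape.half_separation_um / params.lateral_scale
    left = int(np.floor(center_px - half_sep_px))
    right = params.width_px - 1 - left  # mirror-symmetric by construction
    if left < 8 or right > params.width_px - 9:
        raise ConfigurationError("opening half-separation leaves no branch support")
    return left, right


def deflection_amplitude(icp: float, angle_deg: int, params: SynthParams) -> float:
    """Peak vitreous-ward margin deflection in μm: gain * max(0, ICP - ref)."""
    idx = ANGLES.index(angle_deg) if angle_deg in ANGLES else -1
    if idx < 0:
        raise InputError(f"angle must be on the 30-degree grid, got {angle_deg}")
    return float(params.deflection_gain[idx]) * max(0.0, float(icp) - REFERENCE_PRESSURE)


def _profile_y(x_um: np.ndarray, margin_um: float, side: int,
               amplitude: float, shape: BaselineShape) -> np.ndarray:
    """Analytic truth profile: baseline tilt + raised-cosine bump at the margin.

    ``side`` is -1 for the left branch (outward = decreasing x), +1 for the
    right.  ``d`` is the outward distance from the margin.
    """
    d = (margin_um - x_um) if side < 0 else (x_um - margin_um)
    y = shape.slope_um_per_mm * d / 1000.0
    bump = np.where(
        np.abs(d) < BUMP_SPAN_UM,
        0.5 * amplitude * (1.0 + np.cos(np.pi * d / BUMP_SPAN_UM)),
        0.0,
    )
    return y + bump


def pbm_profile(
    icp: float,
    angle_deg: int,
    eye: str,
    params: SynthParams,
    scan_seed: int,
    subject_id: str = "truth",
) -> PbmCurve:
    """Ground-truth canonical pBM curve for one scan.

    The curve is sampled at every raster column, in canonical (OD-oriented,
    vitreous-positive) micron coordinates.  The true deflection amplitude is
    recorded on the curve for recovery tests.
    """
    if angle_deg not in ANGLES:
        raise InputError(f"angle must be on the 30-degree grid, got {angle_deg}")
    meta = ScanMeta(
        subject_id=subject_id,
        eye=eye,
        angle_deg=angle_deg,
        lateral_scale=params.lateral_scale,
        axial_scale=params.axial_scale,
        width_px=params.width_px,
    )
    amp = deflection_amplitude(icp, angle_deg, params)
    ml_px, mr_px = _margin_px(params)
    sc = params.lateral_scale
    x_left = np.arange(0, ml_px + 1, dtype=float) * sc
    x_right = np.arange(mr_px, params.width_px, dtype=float) * sc
    margin_l, margin_r = ml_px * sc, mr_px * sc
    y_left = _profile_y(x_left, margin_l, -1, amp, params.baseline_shape)
    y_right = _profile_y(x_right, margin_r, +1, amp, params.baseline_shape)
    if params.curve_noise_sd > 0:
        rng = _rng(params.seed, scan_seed, 0)
        knots = np.arange(0.0, params.width_px * sc + NOISE_KNOT_UM, NOISE_KNOT_UM)
        vals = rng.normal(0.0, params.curve_noise_sd, size=knots.size)
        y_left = y_left + np.interp(x_left, knots, vals)
        y_right = y_right + np.interp(x_right, knots, vals)
    return PbmCurve(
        branches=(
            np.column_stack([x_left, y_left]),
            np.column_stack([x_right, y_right]),
        ),
        margin_x_um=np.array([margin_l, margin_r]),
        meta=meta,
        true_amplitude_um=amp,
    )


def simulate_raters(
    truth: PbmCurve,
    meta: ScanMeta,
    params: SynthParams,
    seed: int,
) -> tuple[RaterTrace, RaterTrace]:
    """Two raters' pixel-space traces of one scan.

    The canonical truth is rasterized back to native pixel coordinates
    (mirrored for OS eyes), then independent axial noise is added per column:
    sd ``rater_noise_sd_central`` in the two central image eighths and
    ``rater_noise_sd_outer`` elsewhere.  Each rater's margin annotation is the
    true margin jittered laterally with the central sd and rounded to a
    column; the trace ends at the annotated margin.
    """
    w = meta.width_px
    sc_l, sc_a = meta.lateral_scale, meta.axial_scale
    # canonical truth sampled per column
    canon_x = [br[:, 0] / sc_l for br in truth.branches]  # px, canonical
    canon_y = [br[:, 1] / sc_a for br in truth.branches]
    m_canon = truth.margin_x_um / sc_l  # canonical margin columns
    lo_c, hi_c = 3.0 * w / 8.0, 5.0 * w / 8.0  # central eighths, native px

    traces = []
    for r in (0, 1):
        rng = _rng(params.seed, seed, 1 + r)
        jitter = rng.normal(0.0, params.rater_noise_sd_central, size=2)
        ml = int(np.clip(np.rint(m_canon[0] + jitter[0]), 2, (m_canon[0] + m_canon[1]) / 2 - 1))
        mr = int(np.clip(np.rint(m_canon[1] + jitter[1]), (m_canon[0] + m_canon[1]) / 2 + 1, w - 3))
        branches_canon = []
        for side, (mpx, (cx, cy)) in enumerate(zip((ml, mr), zip(canon_x, canon_y))):
            cols = np.arange(0, mpx + 1) if side == 0 else np.arange(mpx, w)
            y = np.interp(cols.astype(float), cx, cy)  # clamped at branch ends
            branches_canon.append((cols.astype(float), y))
        if meta.eye == "OS":  # back to native orientation
            (xl, yl), (xr, yr) = branches_canon
            branches_native = [
                (mirror_x_px(xr[::-1], w), yr[::-1]),
                (mirror_x_px(xl[::-1], w), yl[::-1]),
            ]
        else:
            branches_native = branches_canon
        out = []
        for x, y in branches_native:
            sd = np.where((x >= lo_c) & (x < hi_c),
                          params.rater_noise_sd_central, params.rater_noise_sd_outer)
            noise = rng.normal(0.0, 1.0, size=x.size) * sd
            out.append(np.column_stack([x, y + noise]))
        margins = np.array([out[0][-1, 0], out[1][0, 0]])
        traces.append(RaterTrace(rater_id=f"R{r + 1}", branches=tuple(out),
                                 margin_x_px=margins))
    return tuple(traces)


@dataclass
class ScanRecord:
    meta: ScanMeta
    truth: PbmCurve
    traces: tuple[RaterTrace, RaterTrace]
    icp: float


@dataclass
class SyntheticCohort:
    subjects: list[IcpRecord]
    scans: list[ScanRecord]
    params_used: SynthParams

    def truth_table(self) -> pd.DataFrame:
        """Ground-truth table: subject, eye, angle, ICP, true amplitude."""
        return pd.DataFrame(
            {
                "subject_id": [s.meta.subject_id for s in self.scans],
                "eye": [s.meta.eye for s in self.scans],
                "angle_deg": [s.meta.angle_deg for s in self.scans],
                "icp_cm_h2o": [s.icp for s in self.scans],
                "true_amplitude_um": [s.truth.true_amplitude_um for s in self.scans],
            }
        )

    def icp_by_subject(self) -> dict:
        return {r.subject_id: r.opening_pressure for r in self.subjects}


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Serialize a cohort to per-scan curve CSV + metadata JSON files.

    Layout: ``<outdir>/scans/<scan_id>.csv`` and ``.json`` plus
    ``<outdir>/truth.csv`` with the ground-truth amplitudes.
    """
    from pathlib import Path

    from .curve_io import write_traces

    outdir = Path(outdir)
    (outdir / "scans").mkdir(parents=True, exist_ok=True)
    for scan in cohort.scans:
        base = outdir / "scans" / scan.meta.scan_id
        write_traces(base.with_suffix(".csv"), base.with_suffix(".json"),
                     scan.meta, list(scan.traces), icp_cm_h2o=scan.icp)
    cohort.truth_table().to_csv(outdir / "truth.csv", index=False)


def read_cohort_files(indir) -> list[tuple[ScanMeta, list[RaterTrace], float]]:
    """Read every scan written by :func:`write_cohort` (sorted by scan id)."""
    from pathlib import Path

    from .curve_io import read_traces

    indir = Path(indir)
    out = []
    for meta_file in sorted((indir / "scans").glob("*.json")):
        curve_file = meta_file.with_suffix(".csv")
        meta, traces, icp = read_traces(curve_file, meta_file)
        out.append((meta, traces, icp))
    return out


def scan_key(subject_idx: int, eye: str, angle_deg: int) -> int:
    """Deterministic per-scan stream key, independent of generation order."""
    return (subject_idx * 2 + EYES.index(eye)) * 6 + ANGLES.index(angle_deg)


def simulate_cohort(params: SynthParams) -> SyntheticCohort:
    """Full synthetic cohort: n_subjects x 2 eyes x 6 angles, 2 raters per scan."""
    subjects = []
    scans = []
    for si in range(params.n_subjects):
        sid = f"S{si + 1:03d}"
        icp = sample_icp(params, _rng(params.seed, 10_000 + si))
        subjects.append(IcpRecord(subject_id=sid, opening_pressure=icp))
        for eye in EYES:
            for angle in ANGLES:
                key = scan_key(si, eye, angle)
                truth = pbm_profile(icp, angle, eye, params, key, subject_id=sid)
                traces = simulate_raters(truth, truth.meta, params, key)
                scans.append(ScanRecord(meta=truth.meta, truth=truth,
                                        traces=traces, icp=icp))
    return SyntheticCohort(subjects=subjects, scans=scans, params_used=params)
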