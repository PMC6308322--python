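"""Data model, I/O, canonicalization and inter-rater reliability for pBM curves.

A segmented peripapillary Bruch's membrane (pBM) trace consists of two
branches of ``(x, y)`` samples flanking the optic nerve head opening, with a
discontinuity underneath the nerve head.  Raters work in pixel coordinates on
the raw B-scan raster; all downstream analysis works on a canonical consensus
curve in microns.

Coordinate conventions
----------------------
* Pixel traces (:class:`RaterTrace`): x is the raster column (0-based), y is
  the axial position in pixels with **larger y pointing toward the vitreous**.
* Canonical curves (:class:`PbmCurve`): microns, right-eye (OD) orientation.
  Left-eye (OS) traces are mirrored about the vertical axis during
  canonicalization so temporal/nasal directions coincide across eyes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AlignmentError, ConfigurationError, FormatError, InputError

VALID_ANGLES = (0, 30, 60, 90, 120, 150)

#: Two central ("peripapillary") segments out of eight, by convention.
DEFAULT_N_SEGMENTS = 8
DEFAULT_THRESHOLD_PX = 3.0


def px_to_um(value_px: float | np.ndarray, scale_um_per_px: float) -> float | np.ndarray:
    """Convert a pixel quantity to microns with the given device scale."""
    if scale_um_per_px <= 0:
        raise ConfigurationError(f"scale must be positive, got {scale_um_per_px}")
    return value_px * scale_um_per_px


@dataclass(frozen=True)
class ScanMeta:
    """Identity and raster geometry of one radial B-scan."""

    subject_id: str
    eye: str  # "OD" | "OS"
    angle_deg: int  # one of VALID_ANGLES
    lateral_scale: float  # μm per pixel along x
    axial_scale: float  # μm per pixel along y
    width_px: int = 1024

    def __post_init__(self):
        if self.eye not in ("OD", "OS"):
            raise InputError(f"eye must be OD or OS, got {self.eye!r}")
        if self.angle_deg not in VALID_ANGLES:
            raise InputError(
                f"angle_deg must be one of {VALID_ANGLES}, got {self.angle_deg}"
            )
        if self.lateral_scale <= 0 or self.axial_scale <= 0:
            raise InputError("scales must be positive")
        if self.width_px < 2:
            raise InputError("width_px must be >= 2")

    @property
    def scan_id(self) -> str:
        return f"{self.subject_id}_{self.eye}_{self.angle_deg:03d}"

    @property
    def width_um(self) -> float:
        return self.width_px * self.lateral_scale

    @property
    def center_x_um(self) -> float:
        """Lateral midpoint of the scan (scans are centered on the nerve head)."""
        return self.width_um / 2.0


def _as_branch(arr) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
        raise InputError("a branch must be an (N>=2, 2) array of (x, y)")
    return a


@dataclass
class RaterTrace:
    """One rater's two-branch pBM segmentation in pixel coordinates.

    ``branches[0]`` is the left branch (smaller x), ``branches[1]`` the right.
    ``margin_x_px[i]`` is the rater-identified pBM opening edge of branch i and
    coincides with the inner endpoint of that branch (the rater stops
    segmenting at the margin).
    """

    rater_id: str
    branches: tuple[np.ndarray, np.ndarray]
    margin_x_px: np.ndarray  # shape (2,)

    def __post_init__(self):
        self.branches = (_as_branch(self.branches[0]), _as_branch(self.branches[1]))
        self.margin_x_px = np.asarray(self.margin_x_px, dtype=float)
        if self.margin_x_px.shape != (2,):
            raise InputError("margin_x_px must have exactly two entries")
        left, right = self.branches
        for name, br in (("left", left), ("right", right)):
            if np.any(np.diff(br[:, 0]) <= 0):
                raise FormatError(
                    f"rater {self.rater_id}: {name} branch x not strictly increasing"
                )
        if left[-1, 0] >= right[0, 0]:
            raise FormatError(
                f"rater {self.rater_id}: branch x-ranges overlap "
                "(no discontinuity under the optic nerve head)"
            )
        if not np.isclose(self.margin_x_px[0], left[-1, 0]):
            raise FormatError(
                f"rater {self.rater_id}: left margin not at inner end of branch"
            )
        if not np.isclose(self.margin_x_px[1], right[0, 0]):
            raise FormatError(
                f"rater {self.rater_id}: right margin not at inner end of branch"
            )


@dataclass
class PbmCurve:
    """Canonical consensus pBM curve in microns (OD orientation, vitreous-positive y)."""

    branches: tuple[np.ndarray, np.ndarray]
    margin_x_um: np.ndarray  # shape (2,)
    meta: ScanMeta
    true_amplitude_um: float | None = None  # ground truth, set by the simulator

    def __post_init__(self):
        self.branches = (_as_branch(self.branches[0]), _as_branch(self.branches[1]))
        self.margin_x_um = np.asarray(self.margin_x_um, dtype=float)
        for br in self.branches:
            if np.any(np.diff(br[:, 0]) <= 0):
                raise FormatError("curve branch x not strictly increasing")


@dataclass
class ReliabilityReport:
    """Segment-wise inter-rater disagreement for one scan."""

    n_segments: int
    threshold_px: float
    flagged: np.ndarray  # bool, (n_segments,)
    exceed_magnitudes_px: list  # list of arrays, one per segment
    summary: dict = field(default_factory=dict)


def mirror_x_px(x_px: np.ndarray, width_px: int) -> np.ndarray:
    """Mirror pixel x about the vertical image axis: x -> width_px - 1 - x."""
    return (width_px - 1) - np.asarray(x_px, dtype=float)


def _oriented_branches(trace: RaterTrace, meta: ScanMeta):
    """Return (left, right) branch arrays and margins in OD-oriented pixel x."""
    if meta.eye == "OD":
        return trace.branches, trace.margin_x_px.copy()
    left, right = trace.branches
    new_right = np.column_stack([mirror_x_px(left[::-1, 0], meta.width_px), left[::-1, 1]])
    new_left = np.column_stack([mirror_x_px(right[::-1, 0], meta.width_px), right[::-1, 1]])
    margins = np.array(
        [mirror_x_px(trace.margin_x_px[1], meta.width_px),
         mirror_x_px(trace.margin_x_px[0], meta.width_px)]
    )
    return (new_left, new_right), margins


def canonicalize(traces: list[RaterTrace], meta: ScanMeta) -> PbmCurve:
    """Build the consensus curve from exactly two raters' pixel traces.

    Left-eye traces are mirrored about the vertical axis, the two raters'
    curves are linearly interpolated onto the union x-grid of their overlap
    and averaged pointwise, margins are averaged, and everything is scaled to
    microns.
    """
    if len(traces) != 2:
        raise InputError(f"canonicalize requires exactly two raters, got {len(traces)}")
    (b0, m0) = _oriented_branches(traces[0], meta)
    (b1, m1) = _oriented_branches(traces[1], meta)

    branches_um = []
    for side, (br0, br1) in enumerate(zip(b0, b1)):
        if min(br0[-1, 0], br1[-1, 0]) <= max(br0[0, 0], br1[0, 0]):
            side_name = "left" if side == 0 else "right"
            raise AlignmentError(f"raters have empty x-overlap on the {side_name} branch")
        # The outer end is the raters' intersection; the inner (margin) end
        # extends to the union so the averaged margin always lies on the
        # consensus curve.  np.interp clamps the shorter rater over the
        # few-pixel sliver where only one rater segmented.
        if side == 0:
            lo, hi = max(br0[0, 0], br1[0, 0]), max(br0[-1, 0], br1[-1, 0])
        else:
            lo, hi = min(br0[0, 0], br1[0, 0]), min(br0[-1, 0], br1[-1, 0])
        grid = np.union1d(br0[:, 0], br1[:, 0])
        grid = grid[(grid >= lo) & (grid <= hi)]
        y0 = np.interp(grid, br0[:, 0], br0[:, 1])
        y1 = np.interp(grid, br1[:, 0], br1[:, 1])
        y = 0.5 * (y0 + y1)
        branches_um.append(
            np.column_stack([grid * meta.lateral_scale, y * meta.axial_scale])
        )
    margins_um = 0.5 * (m0 + m1) * meta.lateral_scale
    return PbmCurve(branches=tuple(branches_um), margin_x_um=margins_um, meta=meta)


def segment_edges(width_px: int, n_segments: int) -> np.ndarray:
    """Equal half-open segment boundaries over the full image width [0, width_px)."""
    if n_segments < 1:
        raise ConfigurationError("n_segments must be >= 1")
    return np.linspace(0.0, float(width_px), n_segments + 1)


def central_segment_indices(n_segments: int) -> tuple[int, int]:
    """Indices of the two central (peripapillary) segments."""
    return (n_segments // 2 - 1, n_segments // 2)


def reliability_report(
    traces: list[RaterTrace],
    meta: ScanMeta,
    n_segments: int = DEFAULT_N_SEGMENTS,
    threshold_px: float = DEFAULT_THRESHOLD_PX,
) -> ReliabilityReport:
    """Flag image segments whose raters disagree axially by >= threshold pixels.

    The full image width is split into ``n_segments`` equal half-open
    intervals; within each, |y1 - y2| is evaluated at every x sample shared by
    the two raters (native pixel coordinates; no mirroring is involved since
    both raters segment the same image).
    """
    if len(traces) != 2:
        raise InputError("reliability_report requires exactly two raters")
    if n_segments < 1:
        raise ConfigurationError("n_segments must be >= 1")
    t0, t1 = traces
    xs, diffs = [], []
    for br0, br1 in zip(t0.branches, t1.branches):
        common, i0, i1 = np.intersect1d(br0[:, 0], br1[:, 0], return_indices=True)
        xs.append(common)
        diffs.append(np.abs(br0[i0, 1] - br1[i1, 1]))
    x = np.concatenate(xs)
    d = np.concatenate(diffs)
    edges = segment_edges(meta.width_px, n_segments)
    seg = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_segments - 1)
    flagged = np.zeros(n_segments, dtype=bool)
    exceed = []
    for i in range(n_segments):
        mag = d[(seg == i) & (d >= threshold_px)]
        exceed.append(mag)
        flagged[i] = mag.size > 0
    c0, c1 = central_segment_indices(n_segments)
    central = np.zeros(n_segments, dtype=bool)
    central[[c0, c1]] = True
    all_exceed = np.concatenate(exceed) if exceed else np.array([])
    summary = {
        "prop_flagged": float(flagged.mean()),
        "prop_flagged_central": float(flagged[central].mean()),
        "prop_flagged_outer": float(flagged[~central].mean()),
        "mean_exceed_px": float(all_exceed.mean()) if all_exceed.size else np.nan,
        "max_exceed_px": float(all_exceed.max()) if all_exceed.size else np.nan,
    }
    return ReliabilityReport(
        n_segments=n_segments,
        threshold_px=threshold_px,
        flagged=flagged,
        exceed_magnitudes_px=exceed,
        summary=summary,
    )


def aggregate_reliability(reports: list[tuple[ScanMeta, ReliabilityReport]]) -> dict:
    """Cohort-level disagreement summary.

    Returns overall/central/outer flagged-segment proportions, mean and max
    exceedance magnitudes in pixels and microns, per-angle flagged
    proportions, and a one-way ANOVA (F, p) of per-scan flagged proportions
    across scan angles.
    """
    if not reports:
        raise InputError("aggregate_reliability requires a non-empty list")
    n_seg = reports[0][1].n_segments
    c0, c1 = central_segment_indices(n_seg)
    central = np.zeros(n_seg, dtype=bool)
    central[[c0, c1]] = True

    rows = []
    all_exceed_px, all_exceed_um = [], []
    for meta, rep in reports:
        if rep.n_segments != n_seg:
            raise InputError("all reports must use the same n_segments")
        ex = np.concatenate(rep.exceed_magnitudes_px) if rep.exceed_magnitudes_px else np.array([])
        all_exceed_px.append(ex)
        all_exceed_um.append(ex * meta.axial_scale)
        rows.append(
            {
                "scan_id": meta.scan_id,
                "angle_deg": meta.angle_deg,
                "prop_flagged": rep.flagged.mean(),
                "n_flagged_central": int(rep.flagged[central].sum()),
                "n_flagged_outer": int(rep.flagged[~central].sum()),
                "n_flagged": int(rep.flagged.sum()),
            }
        )
    df = pd.DataFrame(rows)
    ex_px = np.concatenate(all_exceed_px)
    ex_um = np.concatenate(all_exceed_um)
    n_scans = len(df)
    per_angle = df.groupby("angle_deg")["prop_flagged"].mean()

    groups = [g.to_numpy() for _, g in df.groupby("angle_deg")["prop_flagged"]]
    if len(groups) < 2 or np.ptp(np.concatenate(groups)) == 0:
        anova_f, anova_p, note = 0.0, 1.0, "no variation"
    elif np.ptp([g.mean() for g in groups]) == 0:
        anova_f, anova_p, note = 0.0, 1.0, "equal group means"
    else:
        anova_f, anova_p = sps.f_oneway(*groups)
        note = ""
    return {
        "n_scans": n_scans,
        "n_segments_total": n_scans * n_seg,
        "prop_flagged_overall": float(df["n_flagged"].sum() / (n_scans * n_seg)),
        "prop_flagged_central": float(df["n_flagged_central"].sum() / (n_scans * 2)),
        "prop_flagged_outer": float(df["n_flagged_outer"].sum() / (n_scans * (n_seg - 2))),
        "mean_exceed_px": float(ex_px.mean()) if ex_px.size else np.nan,
        "max_exceed_px": float(ex_px.max()) if ex_px.size else np.nan,
        "mean_exceed_um": float(ex_um.mean()) if ex_um.size else np.nan,
        "max_exceed_um": float(ex_um.max()) if ex_um.size else np.nan,
        "per_angle_prop_flagged": per_angle.to_dict(),
        "anova_f": float(anova_f),
        "anova_p": float(anova_p),
        "anova_note": note,
        "per_scan": df,
    }


# ---------------------------------------------------------------------------
# File formats
#
# Curve CSV: one row per sample with columns
#   scan_id, rater_id, branch (L|R), x_px, y_px, is_margin
# Metadata JSON: subject_id, eye, angle_deg, lateral_scale_um_per_px,
#   axial_scale_um_per_px, width_px, icp_cm_h2o (optional, may be null).
# ---------------------------------------------------------------------------

_META_KEYS = (
    "subject_id",
    "eye",
    "angle_deg",
    "lateral_scale_um_per_px",
    "axial_scale_um_per_px",
    "width_px",
)


def write_traces(
    curve_file,
    meta_file,
    meta: ScanMeta,
    traces: list[RaterTrace],
    icp_cm_h2o: float | None = None,
) -> None:
    rows = []
    for tr in traces:
        for bi, (br, bname) in enumerate(zip(tr.branches, ("L", "R"))):
            inner = len(br) - 1 if bi == 0 else 0
            for j, (x, y) in enumerate(br):
                rows.append(
                    {
                        "scan_id": meta.scan_id,
                        "rater_id": tr.rater_id,
                        "branch": bname,
                        "x_px": x,
                        "y_px": y,
                        "is_margin": int(j == inner),
                    }
                )
    pd.DataFrame(rows).to_csv(curve_file, index=False)
    payload = {
        "subject_id": meta.subject_id,
        "eye": meta.eye,
        "angle_deg": meta.angle_deg,
        "lateral_scale_um_per_px": meta.lateral_scale,
        "axial_scale_um_per_px": meta.axial_scale,
        "width_px": meta.width_px,
        "icp_cm_h2o": icp_cm_h2o,
    }
    Path(meta_file).write_text(json.dumps(payload, indent=1))


def read_traces(curve_file, meta_file):
    """Read one scan's traces; returns ``(meta, traces, icp_cm_h2o)``."""
    try:
        payload = json.loads(Path(meta_file).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"metadata file {meta_file}: invalid JSON ({e})") from e
    missing = [k for k in _META_KEYS if k not in payload]
    if missing:
        raise FormatError(f"metadata file {meta_file}: missing keys {missing}")
    meta = ScanMeta(
        subject_id=str(payload["subject_id"]),
        eye=str(payload["eye"]),
        angle_deg=int(payload["angle_deg"]),
        lateral_scale=float(payload["lateral_scale_um_per_px"]),
        axial_scale=float(payload["axial_scale_um_per_px"]),
        width_px=int(payload["width_px"]),
    )
    df = pd.read_csv(curve_file, float_precision="round_trip")
    required = {"scan_id", "rater_id", "branch", "x_px", "y_px", "is_margin"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"curve file {curve_file}: missing columns {sorted(required - set(df.columns))}"
        )
    traces = []
    for rater_id, sub in df.groupby("rater_id", sort=True):
        branches, margins = [], []
        for bname, bi in (("L", 0), ("R", 1)):
            bsub = sub[sub["branch"] == bname]
            if bsub.empty:
                raise FormatError(
                    f"curve file {curve_file}: rater {rater_id} missing branch {bname}"
                )
            br = bsub[["x_px", "y_px"]].to_numpy(dtype=float)
            if np.any(np.diff(br[:, 0]) <= 0):
                raise FormatError(
                    f"curve file {curve_file}: rater {rater_id} branch {bname} "
                    "x not strictly increasing"
                )
            m = bsub[bsub["is_margin"] == 1]
            if len(m) != 1:
                raise FormatError(
                    f"curve file {curve_file}: rater {rater_id} branch {bname} "
                    f"needs exactly one margin row, found {len(m)}"
                )
            branches.append(br)
            margins.append(float(m["x_px"].iloc[0]))
        traces.append(
            RaterTrace(rater_id=str(rater_id), branches=tuple(branches),
                       margin_x_px=np.array(margins))
        )
    icp = payload.get("icp_cm_h2o")
    return meta, traces, (None if icp is None else float(icp))


def write_curve(curve_file, curve: PbmCurve) -> None:
    """Serialize a canonical consensus curve (microns) to CSV."""
    rows = []
    for bi, (br, bname) in enumerate(zip(curve.branches, ("L", "R"))):
        inner = len(br) - 1 if bi == 0 else 0
        for j, (x, y) in enumerate(br):
            rows.append({"branch": bname, "x_um": x, "y_um": y, "is_margin": int(j == inner)})
    pd.DataFrame(rows).to_csv(curve_file, index=False)


def trace_equal(a: RaterTrace, b: RaterTrace) -> bool:
    return (
        a.rater_id == b.rater_id
        and all(np.array_equal(x, y) for x, y in zip(a.branches, b.branches))
        and np.array_equal(a.margin_x_px, b.margin_x_px)
    )
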