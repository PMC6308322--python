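"""Semi-landmark placement on canonical pBM curves.

Four strategies are supported, named by margin rule and landmark count:
``user-16``, ``user-14``, ``distance-16``, ``distance-14``.  Under the user
rule the innermost landmark of each side is the rater-identified pBM margin
(averaged across raters during canonicalization); under the distance rule it
sits a fixed distance (default 1,612 μm) from the optic nerve center on each
side.  Further landmarks step outward in fixed lateral increments (default
180 μm), y linearly interpolated from the curve; 14-landmark variants drop
the outermost point of each side.  Placement is deterministic and fails
atomically when a landmark leaves the curve support (the scan is then logged
as excluded for that strategy).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .curve_io import PbmCurve, ScanMeta
from .errors import ConfigurationError, PlacementError

DEFAULT_SPACING_UM = 180.0
DEFAULT_DISTANCE_UM = 1612.0


@dataclass(frozen=True)
class LandmarkStrategy:
    margin_rule: str  # "user" | "distance"
    n_total: int  # 14 or 16
    spacing_um: float = DEFAULT_SPACING_UM
    distance_um: float = DEFAULT_DISTANCE_UM

    def __post_init__(self):
        if self.margin_rule not in ("user", "distance"):
            raise ConfigurationError(f"margin_rule must be user|distance, got {self.margin_rule!r}")
        if self.n_total % 2 != 0 or self.n_total < 2:
            raise ConfigurationError("n_total must be a positive even count")
        if self.spacing_um <= 0:
            raise ConfigurationError("spacing_um must be positive")

    @property
    def name(self) -> str:
        return f"{self.margin_rule}-{self.n_total}"

    @property
    def per_side(self) -> int:
        return self.n_total // 2


#: The four standard strategies.
STRATEGIES = {
    s.name: s
    for s in (
        LandmarkStrategy("user", 16),
        LandmarkStrategy("user", 14),
        LandmarkStrategy("distance", 16),
        LandmarkStrategy("distance", 14),
    )
}


@dataclass
class LandmarkConfig:
    """Ordered semi-landmarks: left side inner-to-outer, then right side."""

    points: np.ndarray  # (n_total, 2) μm
    strategy: LandmarkStrategy
    meta: ScanMeta

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (self.strategy.n_total, 2):
            raise ConfigurationError(
                f"expected {self.strategy.n_total} points, got {self.points.shape}"
            )

    @property
    def left(self) -> np.ndarray:
        return self.points[: self.strategy.per_side]

    @property
    def right(self) -> np.ndarray:
        return self.points[self.strategy.per_side:]


def margins_distance(curve: PbmCurve, center_x_um: float, distance_um: float = DEFAULT_DISTANCE_UM):
    """Margin x-pair a fixed distance either side of the optic nerve center."""
    left_x = center_x_um - distance_um
    right_x = center_x_um + distance_um
    for side, x, br in (("left", left_x, curve.branches[0]), ("right", right_x, curve.branches[1])):
        if not (br[0, 0] <= x <= br[-1, 0]):
            raise PlacementError(
                f"{side} distance margin at x={x:.1f} μm outside branch support "
                f"[{br[0, 0]:.1f}, {br[-1, 0]:.1f}]",
                side=side,
                index=0,
            )
    return (left_x, right_x)


def place_semilandmarks(
    curve: PbmCurve,
    margins,
    strategy: LandmarkStrategy,
) -> LandmarkConfig:
    """Place ``n_total`` semi-landmarks stepping outward from the margins.

    Landmark k (k = 0 ... n_total/2 - 1) of each side sits at
    x = margin -/+ k * spacing_um moving away from the opening, with y
    linearly interpolated from the curve branch.  Raises
    :class:`PlacementError` (atomically) if any landmark leaves the branch
    support.
    """
    left_margin, right_margin = float(margins[0]), float(margins[1])
    pts = np.empty((strategy.n_total, 2))
    for side, (margin, br, sign) in enumerate(
        (
            (left_margin, curve.branches[0], -1.0),
            (right_margin, curve.branches[1], +1.0),
        )
    ):
        xs = margin + sign * strategy.spacing_um * np.arange(strategy.per_side)
        lo, hi = br[0, 0], br[-1, 0]
        bad = np.nonzero((xs < lo) | (xs > hi))[0]
        if bad.size:
            name = "left" if side == 0 else "right"
            raise PlacementError(
                f"landmark k={bad[0]} on {name} side at x={xs[bad[0]]:.1f} μm "
                f"outside branch support [{lo:.1f}, {hi:.1f}]",
                side=name,
                index=int(bad[0]),
            )
        ys = np.interp(xs, br[:, 0], br[:, 1])
        pts[side * strategy.per_side:(side + 1) * strategy.per_side] = np.column_stack([xs, ys])
    return LandmarkConfig(points=pts, strategy=strategy, meta=curve.meta)


def place_on_curve(curve: PbmCurve, strategy: LandmarkStrategy,
                   center_rule: str = "scan_midpoint") -> LandmarkConfig:
    """Apply a strategy's margin rule to one canonical curve and place landmarks.

    ``center_rule`` selects the optic nerve center for the distance rule:
    ``scan_midpoint`` (scans are centered on the nerve head) or
    ``margin_midpoint`` (midpoint of the rater-identified margins).
    """
    if strategy.margin_rule == "user":
        margins = (curve.margin_x_um[0], curve.margin_x_um[1])
    else:
        if center_rule == "scan_midpoint":
            center = curve.meta.center_x_um
        elif center_rule == "margin_midpoint":
            center = float(np.mean(curve.margin_x_um))
        else:
            raise ConfigurationError(f"unknown center_rule {center_rule!r}")
        margins = margins_distance(curve, center, strategy.distance_um)
    return place_semilandmarks(curve, margins, strategy)


def build_dataset(
    curves: list[PbmCurve],
    strategy: LandmarkStrategy,
    center_rule: str = "scan_midpoint",
):
    """Place landmarks on every curve; exclusions are logged, not raised.

    Returns ``(configs, exclusion_log)`` where the log is a DataFrame with
    columns scan_id, strategy, reason.
    """
    configs, excluded = [], []
    for curve in curves:
        try:
            configs.append(place_on_curve(curve, strategy, center_rule))
        except PlacementError as e:
            excluded.append(
                {"scan_id": curve.meta.scan_id, "strategy": strategy.name, "reason": str(e)}
            )
    log = pd.DataFrame(excluded, columns=["scan_id", "strategy", "reason"])
    return configs, log


def intersection_subset(config_sets: dict) -> set:
    """Scan ids placeable under every strategy in ``config_sets``."""
    ids = None
    for configs in config_sets.values():
        these = {c.meta.scan_id for c in configs}
        ids = these if ids is None else ids & these
    return ids or set()


# ---------------------------------------------------------------------------
# TPS and CSV export
# ---------------------------------------------------------------------------

def write_tps(path, configs: list[LandmarkConfig]) -> None:
    """Write configurations in TPS format (LM=, coordinate lines, ID=)."""
    lines = []
    for c in configs:
        lines.append(f"LM={c.strategy.n_total}")
        for x, y in c.points:
            lines.append(f"{x:.6f} {y:.6f}")
        lines.append(f"ID={c.meta.scan_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tps(path) -> list[tuple[str, np.ndarray]]:
    """Read a TPS file back as ``(scan_id, points)`` pairs."""
    out = []
    points, scan_id = [], None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.upper().startswith("LM="):
            points, scan_id = [], None
        elif line.upper().startswith("ID="):
            scan_id = line[3:]
            out.append((scan_id, np.array(points, dtype=float)))
        else:
            points.append([float(v) for v in line.split()])
    return out


def configs_to_frame(configs: list[LandmarkConfig]) -> pd.DataFrame:
    """Long-form table: scan_id, strategy, index, side, x_um, y_um."""
    rows = []
    for c in configs:
        half = c.strategy.per_side
        for i, (x, y) in enumerate(c.points):
            rows.append(
                {
                    "scan_id": c.meta.scan_id,
                    "strategy": c.strategy.name,
                    "index": i,
                    "side": "left" if i < half else "right",
                    "x_um": x,
                    "y_um": y,
                }
            )
    return pd.DataFrame(rows)
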