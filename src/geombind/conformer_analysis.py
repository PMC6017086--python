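"""Classification of ligand conformers from (ϕ1, ϕ2) dihedral time series.

A flexible minor-groove binder exchanges rapidly between a small number of
scaffold conformers distinguishable by two backbone torsions.  Frames are
assigned to a conformer when *both* torsions lie within a periodic
threshold (default 45°) of the conformer's center — an axis-aligned box on
the torus — with a ± sign symmetry applied to each torsion independently:
a center written ϕ1 ∼ ϕ2 ∼ ±90° matches either sign in either coordinate,
since the flat and perpendicular scaffold geometries are the same
conformer regardless of the individual torsion signs.  Everything else is
a transition frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, ContractError


def angular_distance(a: float, b: float) -> float:
    """Periodic distance between two angles in degrees, in [0, 180]."""
    d = abs((a - b + 180.0) % 360.0 - 180.0)
    return d


@dataclass
class DihedralSeries:
    """Ordered (ϕ1, ϕ2) frames in degrees, each in (−180, 180]."""

    frames: np.ndarray
    time_stride_ps: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, float))
        if self.frames.shape[0] < 1 or self.frames.shape[1] != 2:
            raise ContractError("series needs >= 1 frame of (phi1, phi2)")
        if np.any(self.frames <= -180.0) or np.any(self.frames > 180.0):
            raise ContractError("dihedrals must lie in (-180, 180]")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ConformerModel:
    """Named conformer centers on the torus plus the acceptance threshold.

    ``metric`` chooses the acceptance region: "box" (default; both
    coordinates within the threshold) or "euclidean" (periodic radial
    distance within the threshold).
    """

    modes: Sequence[tuple] = field(default_factory=list)  # (label, c1, c2)
    threshold: float = 45.0
    metric: str = "box"

    def __post_init__(self) -> None:
        labels = [m[0] for m in self.modes]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("mode labels must be unique")
        if not 0.0 < self.threshold < 90.0:
            raise ConfigurationError("threshold must be in (0, 90) degrees")
        if self.metric not in ("box", "euclidean"):
            raise ConfigurationError(f"unknown metric {self.metric!r}")


def _mode_distance(phi1: float, phi2: float, c1: float, c2: float) -> tuple:
    """Per-coordinate periodic distances to a center under the ± sign
    symmetry, applied to each torsion independently: a center written
    ϕ ∼ ±c matches both +c and −c in that coordinate.
    """
    d1 = min(angular_distance(phi1, c1), angular_distance(phi1, -c1))
    d2 = min(angular_distance(phi2, c2), angular_distance(phi2, -c2))
    return d1, d2


def classify_frame(phi1: float, phi2: float, model: ConformerModel) -> str:
    """Assign one frame to a conformer label or to "transition".

    A mode qualifies when both periodic coordinate distances (box metric)
    or the radial distance (euclidean metric) to the nearer sign image are
    within the threshold.  Among qualifying modes the nearest by
    max-coordinate distance wins; ties fall to declaration order.
    """
    best = None
    best_d = np.inf
    for label, c1, c2 in model.modes:
        d1, d2 = _mode_distance(phi1, phi2, c1, c2)
        if model.metric == "box":
            ok = d1 <= model.threshold and d2 <= model.threshold
            d = max(d1, d2)
        else:
            d = float(np.hypot(d1, d2))
            ok = d <= model.threshold
        if ok and d < best_d:
            best, best_d = label, d
    return best if best is not None else "transition"


def population_table(series: DihedralSeries, model: ConformerModel) -> dict:
    """Counts and fractions per conformer label plus "transition".

    Fractions are exact rationals (`fractions.Fraction`), so they sum to 1
    exactly; they compare and convert transparently to floats.
    """
    from fractions import Fraction

    if len(series) < 1:
        raise ContractError("empty series")
    labels = [m[0] for m in model.modes] + ["transition"]
    counts = {lab: 0 for lab in labels}
    for phi1, phi2 in series.frames:
        counts[classify_frame(phi1, phi2, model)] += 1
    n = len(series)
    return {
        lab: {"count": counts[lab], "fraction": Fraction(counts[lab], n)}
        for lab in labels
    }


def detect_modes(
    series: DihedralSeries,
    bin_width: float = 10.0,
    min_separation: float = 60.0,
    prominence: float = 3.0,
) -> ConformerModel:
    """Locate conformer centers from the 2-D periodic torsion histogram.

    Local maxima of the wrapped 2-D histogram exceeding ``prominence``
    times the mean occupied-bin count are collected, peaks closer than
    ``min_separation`` (per-coordinate periodic distance, including sign
    images) are merged into the stronger one, and centers are returned
    sorted by peak mass.
    """
    if len(series) < 100:
        raise ContractError("mode detection needs >= 100 frames")
    nb = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, nb + 1)
    h, _, _ = np.histogram2d(series.frames[:, 0], series.frames[:, 1], bins=[edges, edges])
    mean_occ = h[h > 0].mean()
    peaks = []
    for i in range(nb):
        for j in range(nb):
            v = h[i, j]
            if v <= 0:
                continue
            is_max = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    if h[(i + di) % nb, (j + dj) % nb] > v:
                        is_max = False
            if is_max and v >= prominence * mean_occ:
                c1 = -180.0 + (i + 0.5) * bin_width
                c2 = -180.0 + (j + 0.5) * bin_width
                peaks.append((v, c1, c2))
    if not peaks:
        raise ContractError(
            "no histogram peak above prominence; lower the prominence threshold"
        )
    peaks.sort(reverse=True)
    kept = []
    for v, c1, c2 in peaks:
        merged = False
        for kv, k1, k2 in kept:
            d1, d2 = _mode_distance(c1, c2, k1, k2)
            if max(d1, d2) < min_separation:
                merged = True
                break
        if not merged:
            kept.append((v, c1, c2))
    modes = [(f"mode{i + 1}", c1, c2) for i, (v, c1, c2) in enumerate(kept)]
    return ConformerModel(modes=modes)
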