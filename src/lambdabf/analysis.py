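"""Binding-mode trajectory analysis.

Interaction geometry series — centre-of-mass distances between a receptor
group and the ligand scaffold, hydrogen-bond-like atom distances — are
reduced to normalized distributions and occupancy fractions. Hydrogen
bonds are characterized by distance only (no angle criterion); the
default aromatic-stacking occupancy window is 3.3–4.4 Å and the default
hydrogen-bond window (0, 2.5] Å on the donor–acceptor distance proxy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

STACKING_WINDOW = (3.3, 4.4)
HBOND_WINDOW = (0.0, 2.5)


class DefinitionError(ValueError):
    pass


@dataclass
class InteractionDefinition:
    """A labelled pairwise interaction monitored along a trajectory."""

    label: str
    kind: str                       # "com_distance" | "atom_distance"
    group_a: np.ndarray
    group_b: np.ndarray
    window: tuple[float, float] = STACKING_WINDOW

    def __post_init__(self) -> None:
        if self.kind not in ("com_distance", "atom_distance"):
            raise DefinitionError("kind must be com_distance or atom_distance")
        self.group_a = np.asarray(self.group_a, dtype=int)
        self.group_b = np.asarray(self.group_b, dtype=int)
        if len(self.group_a) == 0 or len(self.group_b) == 0:
            raise DefinitionError("interaction groups must be non-empty")
        if set(self.group_a.tolist()) & set(self.group_b.tolist()):
            raise DefinitionError("interaction groups must be disjoint")
        if self.window[0] >= self.window[1]:
            raise DefinitionError("occupancy window min must be < max")


def com_distance_series(frames: np.ndarray, group_a, group_b,
                        masses) -> np.ndarray:
    """Per-frame mass-weighted COM distance (Å) between two atom groups."""
    frames = np.asarray(frames, dtype=float)
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if len(group_a) == 0 or len(group_b) == 0:
        raise DefinitionError("groups must be non-empty")
    masses = np.asarray(masses, dtype=float)
    wa = masses[group_a] / masses[group_a].sum()
    wb = masses[group_b] / masses[group_b].sum()
    ca = np.einsum("a,fad->fd", wa, frames[:, group_a])
    cb = np.einsum("b,fbd->fd", wb, frames[:, group_b])
    return np.linalg.norm(cb - ca, axis=1)


def normalized_histogram(series, bin_width: float = 0.1,
                         range_: tuple[float, float] | None = None):
    """Density curve of a distance series: (bin centers, density).

    The density integrates to one over the histogram range.
    """
    series = np.asarray(series, dtype=float)
    if len(series) == 0:
        raise ValueError("empty series")
    if len(series) < 100:
        warnings.warn(f"only {len(series)} samples; distribution estimate "
                      "will be noisy")
    if range_ is None:
        lo, hi = float(series.min()), float(series.max())
        if hi - lo < bin_width:
            lo -= bin_width / 2
            hi += bin_width / 2
    else:
        lo, hi = range_
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    hist, edges = np.histogram(series, bins=n_bins, range=(lo, lo + n_bins *
                                                           bin_width))
    centers = 0.5 * (edges[1:] + edges[:-1])
    density = hist / (hist.sum() * bin_width)
    return centers, density


def occupancy_fraction(series, window: tuple[float, float]) -> float:
    """Fraction of frames with the series value inside the closed window."""
    lo, hi = window
    if lo >= hi:
        raise ValueError("window min must be < max")
    series = np.asarray(series, dtype=float)
    return float(np.mean((series >= lo) & (series <= hi)))


def interaction_summary(frames: np.ndarray, masses,
                        definitions: list[InteractionDefinition],
                        bin_width: float = 0.1) -> list[dict]:
    """Per-interaction distribution mode and occupancy table."""
    rows = []
    for d in definitions:
        if d.kind == "com_distance":
            series = com_distance_series(frames, d.group_a, d.group_b, masses)
        else:
            series = np.linalg.norm(
                frames[:, int(d.group_b[0])] - frames[:, int(d.group_a[0])],
                axis=1)
        centers, density = normalized_histogram(series, bin_width=bin_width)
        rows.append({
            "label": d.label,
            "mode": float(centers[np.argmax(density)]),
            "occupancy": occupancy_fraction(series, d.window),
            "series": series,
            "centers": centers,
            "density": density,
        })
    return rows
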