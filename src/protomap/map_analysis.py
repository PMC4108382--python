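"""From spike logs to preference maps, selectivity indices and gradients.

Per-neuron firing rates across the eight motion directions are condensed by
the vector-average method: each direction angle theta contributes a vector of
length r(theta), and the resultant

    Vx = sum r(theta) cos(theta),   Vy = sum r(theta) sin(theta)

gives the preferred direction atan2(Vy, Vx) and the Selectivity Index
SI = |V| / sum r(theta), which is 0 for an unselective neuron and 1 for a
neuron responding to a single direction.  Orientation preference is the same
computation after averaging rates over opposite direction pairs and doubling
the angles (orientation is 180-degree periodic); the resulting angle is
halved back into [0, 180).

Map smoothness is quantified by the preference gradient: for every neuron
with a left and an upper neighbour, the circular angle differences dx and dy
(folded into [-180, 180]) give a gradient magnitude sqrt(dx^2 + dy^2); large
values mark fractures where preference jumps abruptly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DIRECTION_ORDER",
    "DIRECTION_ANGLES_DEG",
    "RateTable",
    "PreferenceMap",
    "GradientMap",
    "compute_rate_table",
    "preference_and_si",
    "preference_map",
    "circular_diff",
    "gradient_map",
    "tuning_curve",
    "render_maps",
]

#: Fixed direction order of rate-table columns and their angles (degrees,
#: mathematical convention: E = 0, N = 90).
DIRECTION_ORDER = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")
DIRECTION_ANGLES_DEG = np.array([0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0])


@dataclass
class RateTable:
    """Mean firing rate (Hz) per neuron x direction, averaged over instances."""

    rates: np.ndarray                 # (n_neurons, 8)
    directions: tuple = DIRECTION_ORDER
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.rates.ndim != 2 or self.rates.shape[1] != len(self.directions):
            raise ValueError("rates must be (n_neurons, n_directions)")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class PreferenceMap:
    """Per-neuron preferred angle and selectivity index."""

    mode: str                         # "direction" or "orientation"
    preferred_angle: np.ndarray       # degrees; NaN where undefined
    si: np.ndarray                    # in [0, 1]
    grid_shape: tuple[int, int] | None = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.preferred_angle)


@dataclass
class GradientMap:
    """Per-neuron preference-gradient magnitude (degrees)."""

    gradient: np.ndarray              # (rows, cols); NaN in first row/col
    mean_gradient: float


def compute_rate_table(
    spike_counts: dict[str, list[np.ndarray]],
    duration_s: float,
    grid_shape: tuple[int, int] | None = None,
) -> RateTable:
    """Average per-neuron spike counts into a rate table.

    ``spike_counts[direction]`` holds one per-neuron count vector per
    stimulus instance; rates are counts / duration averaged over instances.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    missing = [d for d in DIRECTION_ORDER if not spike_counts.get(d)]
    if missing:
        raise ValueError(f"missing directions: {missing}")
    cols = []
    for d in DIRECTION_ORDER:
        counts = np.asarray(spike_counts[d], dtype=np.float64)
        cols.append(counts.mean(axis=0) / duration_s)
    return RateTable(rates=np.column_stack(cols), grid_shape=grid_shape)


def preference_and_si(rates: np.ndarray, mode: str = "direction"):
    """Vector-average preferred angle and selectivity index.

    Accepts a single 8-vector or an (n, 8) array of non-negative rates bound
    to the angles of :data:`DIRECTION_ORDER`.  Returns (angle_deg, si);
    angles are in [0, 360) for direction mode, [0, 180) for orientation
    mode, and NaN (with si = 0) where all rates are zero.
    """
    r = np.atleast_2d(np.asarray(rates, dtype=np.float64))
    if r.shape[1] != 8:
        raise ValueError("expected 8 rates per neuron")
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    if mode == "direction":
        ang = np.radians(DIRECTION_ANGLES_DEG)
        vx = r @ np.cos(ang)
        vy = r @ np.sin(ang)
        total = r.sum(axis=1)
        theta = np.degrees(np.arctan2(vy, vx))
        theta = np.where(theta < 0, theta + 360.0, theta) % 360.0
    elif mode == "orientation":
        # average over opposite directions of motion, then double the angle
        r_axis = 0.5 * (r[:, :4] + r[:, 4:])
        ang2 = np.radians(2.0 * DIRECTION_ANGLES_DEG[:4])
        vx = r_axis @ np.cos(ang2)
        vy = r_axis @ np.sin(ang2)
        total = r_axis.sum(axis=1)
        theta = np.degrees(np.arctan2(vy, vx)) / 2.0
        theta = np.where(theta < 0, theta + 180.0, theta) % 180.0
    else:
        raise ValueError("mode must be 'direction' or 'orientation'")
    with np.errstate(invalid="ignore", divide="ignore"):
        si = np.hypot(vx, vy) / total
    si = np.where(total > 0, si, 0.0)
    si = np.clip(si, 0.0, 1.0)
    theta = np.where(total > 0, theta, np.nan)
    if np.asarray(rates).ndim == 1:
        return float(theta[0]), float(si[0])
    return theta, si


def preference_map(rate_table: RateTable, mode: str = "direction") -> PreferenceMap:
    """Preference map for every neuron of a rate table."""
    theta, si = preference_and_si(rate_table.rates, mode)
    return PreferenceMap(
        mode=mode, preferred_angle=theta, si=si, grid_shape=rate_table.grid_shape
    )


def circular_diff(a: np.ndarray, b: np.ndarray, period: float = 360.0) -> np.ndarray:
    """Signed angular difference a - b folded into [-period/2, period/2]."""
    d = (np.asarray(a) - np.asarray(b)) % period
    return np.where(d > period / 2, d - period, d)


def gradient_map(pref: PreferenceMap) -> GradientMap:
    """Local preference-gradient magnitude over the cortical grid.

    dx and dy are circular differences against the left and upper
    neighbours; the first row and column (no such neighbours) and any
    neuron whose own or neighbour preference is undefined are excluded
    from the mean.
    """
    if pref.grid_shape is None:
        raise ValueError("preference map has no grid shape")
    rows, cols = pref.grid_shape
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    period = 360.0 if pref.mode == "direction" else 180.0
    theta = pref.preferred_angle.reshape(rows, cols)
    grad = np.full((rows, cols), np.nan)
    dx = circular_diff(theta[1:, 1:], theta[1:, :-1], period)
    dy = circular_diff(theta[1:, 1:], theta[:-1, 1:], period)
    grad[1:, 1:] = np.hypot(dx, dy)
    mean = float(np.nanmean(grad[1:, 1:])) if np.any(~np.isnan(grad)) else float("nan")
    return GradientMap(gradient=grad, mean_gradient=mean)


def tuning_curve(rates: np.ndarray) -> np.ndarray:
    """Rates normalised to a peak of exactly 1 (undefined for all-zero)."""
    r = np.asarray(rates, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    m = r.max()
    if m <= 0:
        raise ValueError("tuning curve undefined for an all-zero rate vector")
    return r / m


def render_maps(
    pref: PreferenceMap,
    out_dir,
    prefix: str = "map",
    pref_or: PreferenceMap | None = None,
) -> list:
    """Write the preference map, SI histogram and (optionally) a DS-vs-OR
    scatter as PNG files; returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    rows, cols = pref.grid_shape
    period = 360.0 if pref.mode == "direction" else 180.0

    fig, ax = plt.subplots(figsize=(5, 4.2))
    img = pref.preferred_angle.reshape(rows, cols)
    im = ax.imshow(img, cmap="hsv", vmin=0, vmax=period, origin="lower")
    ax.set_title(f"{pref.mode} preference")
    fig.colorbar(im, ax=ax, label="preferred angle (deg)")
    p = out_dir / f"{prefix}_{pref.mode}_preference.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    si = pref.si
    ax.hist(si, bins=np.arange(0, 1.05, 0.05), color="steelblue", edgecolor="k")
    ax.set_xlabel("selectivity index")
    ax.set_ylabel("neurons")
    ax2 = ax.twinx()
    xs = np.sort(si)
    ax2.plot(xs, 100.0 * np.arange(1, len(xs) + 1) / len(xs), "r-")
    ax2.set_ylabel("cumulative %")
    p = out_dir / f"{prefix}_{pref.mode}_si_hist.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    if pref_or is not None:
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(pref.si, pref_or.si, s=4, alpha=0.4)
        ax.set_xlabel("direction SI")
        ax.set_ylabel("orientation SI")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        p = out_dir / f"{prefix}_ds_vs_or.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
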