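"""Construction of the three-layer network (Input -> LGN -> Cortex).

The architecture follows a Kohonen-style visual-map layout driven by an event
camera: a 128x128 input sheet relays events; a 32x32 LGN sheet down-samples it
through non-overlapping 4x4 connection fields; a 60x60 cortical sheet (80%
excitatory, 20% inhibitory neurons) receives overlapping afferent connection
fields from the LGN and is recurrently wired with a Mexican-hat profile:
short-range excitation with connection probability exp(-dist/sigma_e) cut off
beyond 5 grid units, and longer-range inhibition with probability
exp(-sigma_i/dist) inside an annulus of radii (5, 21].  Lateral synapses carry
distance-dependent conduction delays (1 grid unit = 1 ms, plus Gaussian
jitter), which is what lets moving stimuli interact with the lateral dynamics.

All wiring is probabilistic but replayable: a wiring seed fully determines the
synapse tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LayerGeometry",
    "NetworkGeometry",
    "WiringConfig",
    "SynapseTable",
    "Network",
    "excitatory_connection_prob",
    "inhibitory_connection_prob",
    "assign_cortex_labels",
    "build_input_to_lgn",
    "build_lgn_to_cortex",
    "build_lateral",
    "build_network",
    "save_network",
    "load_network",
]

#: Minimum synaptic delay, equal to the default simulation timestep (ms).
MIN_DELAY_MS = 0.1

CF_MODES = ("cf3", "cf5", "cf7", "random", "full")


@dataclass(frozen=True)
class LayerGeometry:
    """A rectangular sheet of neurons indexed row-major."""

    name: str
    rows: int
    cols: int

    @property
    def n(self) -> int:
        return self.rows * self.cols

    def positions(self) -> np.ndarray:
        """(n, 2) array of (row, col) positions."""
        r, c = np.divmod(np.arange(self.n), self.cols)
        return np.column_stack([r, c]).astype(np.float64)


@dataclass(frozen=True)
class NetworkGeometry:
    """The three sheets plus the inhibitory fraction of the cortex."""

    input: LayerGeometry = LayerGeometry("input", 128, 128)
    lgn: LayerGeometry = LayerGeometry("lgn", 32, 32)
    cortex: LayerGeometry = LayerGeometry("cortex", 60, 60)
    inhibitory_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.input.rows % self.lgn.rows or self.input.cols % self.lgn.cols:
            raise ValueError("input sheet must tile the LGN sheet exactly")
        if not 0.0 <= self.inhibitory_fraction <= 1.0:
            raise ValueError("inhibitory_fraction must be in [0, 1]")

    @property
    def relay_field(self) -> tuple[int, int]:
        """Rows/cols of input pixels relayed to one LGN neuron (4x4 default)."""
        return (self.input.rows // self.lgn.rows, self.input.cols // self.lgn.cols)


def smoke_geometry() -> NetworkGeometry:
    """A small geometry (64x64 -> 16x16 -> 12x12) for fast end-to-end tests."""
    return NetworkGeometry(
        input=LayerGeometry("input", 64, 64),
        lgn=LayerGeometry("lgn", 16, 16),
        cortex=LayerGeometry("cortex", 12, 12),
    )


@dataclass
class WiringConfig:
    """Parameters of the probabilistic wiring.

    sigma_exc/sigma_inh are the spreads of the lateral excitatory and
    inhibitory probability profiles; exc_cutoff and the inhibitory annulus
    (inh_inner, inh_outer] force probabilities to zero outside the stated
    ranges.  Setting ``inh_reduced_cutoff`` (e.g. 8) additionally zeroes
    inhibition beyond that distance — the reduced-inhibition manipulation.
    """

    cf_mode: str = "cf5"
    random_p: float = 0.2
    sigma_exc: float = 3.5
    sigma_inh: float = 8.0
    exc_cutoff: float = 5.0
    inh_inner: float = 5.0
    inh_outer: float = 21.0
    inh_reduced_cutoff: float | None = None
    afferent_weight_range: tuple[float, float] = (0.4, 0.5)
    lateral_exc_weight_range: tuple[float, float] = (0.3, 0.4)
    lateral_inh_weight_range: tuple[float, float] = (-0.4, -0.3)
    delay_noise_sd_ms: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cf_mode not in CF_MODES:
            raise ValueError(f"unknown cf_mode {self.cf_mode!r}; expected {CF_MODES}")
        if not 0.0 <= self.random_p <= 1.0:
            raise ValueError("random_p must be a probability")
        if min(self.sigma_exc, self.sigma_inh, self.exc_cutoff, self.inh_outer) <= 0:
            raise ValueError("sigmas and cutoffs must be positive")

    @property
    def cf_size(self) -> int | None:
        return int(self.cf_mode[2:]) if self.cf_mode.startswith("cf") else None


@dataclass
class SynapseTable:
    """Flat synapse arrays for one projection."""

    projection: str
    pre: np.ndarray    # presynaptic indices
    post: np.ndarray   # postsynaptic indices
    weight: np.ndarray
    delay_ms: np.ndarray

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        self.delay_ms = np.asarray(self.delay_ms, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.pre)


@dataclass
class Network:
    """A fully wired network instance plus its per-neuron cortical thresholds."""

    geometry: NetworkGeometry
    wiring: WiringConfig
    inhibitory: np.ndarray            # bool per cortical neuron
    v_thresh_cortex: np.ndarray       # mV per cortical neuron
    input_to_lgn: SynapseTable
    lgn_to_cortex: SynapseTable
    lateral: SynapseTable
    seed: int = 0


# --- connection probability profiles -----------------------------------------

def excitatory_connection_prob(dist, sigma: float = 3.5, cutoff: float = 5.0):
    """P(connect) = exp(-dist/sigma) for dist <= cutoff, else 0."""
    dist = np.asarray(dist, dtype=np.float64)
    if np.any(dist < 0):
        raise ValueError("distance must be non-negative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    p = np.where(dist <= cutoff, np.exp(-dist / sigma), 0.0)
    return float(p) if p.ndim == 0 else p


def inhibitory_connection_prob(dist, sigma: float = 8.0,
                               inner: float = 5.0, outer: float = 21.0):
    """P(connect) = exp(-sigma/dist) inside the annulus inner < dist <= outer.

    The probability *increases* with distance inside the annulus, producing
    the long-range inhibitory surround of the Mexican hat.
    """
    dist = np.asarray(dist, dtype=np.float64)
    if np.any(dist < 0):
        raise ValueError("distance must be non-negative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    with np.errstate(divide="ignore"):
        p = np.where(
            (dist > inner) & (dist <= outer),
            np.exp(-sigma / np.maximum(dist, 1e-300)),
            0.0,
        )
    return float(p) if p.ndim == 0 else p


# --- builders -----------------------------------------------------------------

def assign_cortex_labels(geometry: NetworkGeometry, rng: np.random.Generator) -> np.ndarray:
    """Randomly mark round(fraction * N_c) cortical neurons as inhibitory."""
    n = geometry.cortex.n
    n_inh = int(round(geometry.inhibitory_fraction * n))
    inhibitory = np.zeros(n, dtype=bool)
    inhibitory[rng.choice(n, size=n_inh, replace=False)] = True
    return inhibitory


def build_input_to_lgn(geometry: NetworkGeometry = NetworkGeometry()) -> SynapseTable:
    """Non-overlapping relay tiling: input pixel (x, y) -> LGN (x//4, y//4).

    Every LGN neuron pools a fixed block of input pixels with weight 1.0, so
    each LGN cell simply averages (and, with its refractory period, rate-
    limits) the activity of its tile.
    """
    gr, gc = geometry.relay_field
    rows = np.arange(geometry.input.n) // geometry.input.cols
    cols = np.arange(geometry.input.n) % geometry.input.cols
    lgn_idx = (rows // gr) * geometry.lgn.cols + (cols // gc)
    return SynapseTable(
        projection="input->lgn",
        pre=np.arange(geometry.input.n),
        post=lgn_idx,
        weight=np.ones(geometry.input.n),
        delay_ms=np.full(geometry.input.n, MIN_DELAY_MS),
    )


def _cf_centres(geometry: NetworkGeometry) -> np.ndarray:
    """Retinotopic centre of each cortical neuron on the LGN sheet.

    Cortical (r, c) on an R x C sheet maps linearly onto the LGN sheet so
    corners map to corners, then rounds to the nearest LGN cell.
    """
    ctx, lgn = geometry.cortex, geometry.lgn
    r = np.arange(ctx.n) // ctx.cols
    c = np.arange(ctx.n) % ctx.cols
    rr = np.rint(r * (lgn.rows - 1) / max(ctx.rows - 1, 1)).astype(np.int64)
    cc = np.rint(c * (lgn.cols - 1) / max(ctx.cols - 1, 1)).astype(np.int64)
    return np.column_stack([rr, cc])


def build_lgn_to_cortex(
    geometry: NetworkGeometry,
    cf_mode: str,
    rng: np.random.Generator,
    weight_range: tuple[float, float] = (0.4, 0.5),
    random_p: float = 0.2,
) -> SynapseTable:
    """Afferent projection under one of five connectivity regimes.

    cfK: each cortical neuron receives the K x K LGN block centred on its
    retinotopic position (clipped at the sheet border); random: each
    (LGN, cortex) pair connects independently with probability ``random_p``;
    full: all LGN neurons project to every cortical neuron.
    """
    if cf_mode not in CF_MODES:
        raise ValueError(f"unknown cf_mode {cf_mode!r}; expected {CF_MODES}")
    lgn, ctx = geometry.lgn, geometry.cortex
    if cf_mode == "full":
        pre = np.tile(np.arange(lgn.n), ctx.n)
        post = np.repeat(np.arange(ctx.n), lgn.n)
    elif cf_mode == "random":
        mask = rng.random((ctx.n, lgn.n)) < random_p
        post, pre = np.nonzero(mask)
    else:
        k = int(cf_mode[2:])
        half = k // 2
        centres = _cf_centres(geometry)
        pres, posts = [], []
        offs = np.arange(-half, half + 1)
        dr, dc = np.meshgrid(offs, offs, indexing="ij")
        dr, dc = dr.ravel(), dc.ravel()
        for j in range(ctx.n):
            rr = centres[j, 0] + dr
            cc = centres[j, 1] + dc
            ok = (rr >= 0) & (rr < lgn.rows) & (cc >= 0) & (cc < lgn.cols)
            src = rr[ok] * lgn.cols + cc[ok]
            pres.append(src)
            posts.append(np.full(len(src), j))
        pre = np.concatenate(pres)
        post = np.concatenate(posts)
    lo, hi = weight_range
    weight = rng.uniform(lo, hi, size=len(pre))
    return SynapseTable(
        projection="lgn->cortex",
        pre=pre,
        post=post,
        weight=weight,
        delay_ms=np.full(len(pre), MIN_DELAY_MS),
    )


def build_lateral(
    inhibitory: np.ndarray,
    cfg: WiringConfig,
    geometry: NetworkGeometry,
    rng: np.random.Generator,
) -> SynapseTable:
    """Mexican-hat recurrent wiring of the cortical sheet.

    The probability profile attaches to the *source* neuron's type:
    excitatory sources connect with exp(-d/sigma_e) up to the cutoff,
    inhibitory sources with exp(-sigma_i/d) inside the annulus.  One
    Bernoulli draw per ordered pair; no self-connections.  Delays are
    d + N(0, delay_noise_sd) ms (1 grid unit = 1 ms), clipped below at the
    minimum delay.
    """
    pos = geometry.cortex.positions()
    n = geometry.cortex.n
    dist = np.hypot(
        pos[:, None, 0] - pos[None, :, 0], pos[:, None, 1] - pos[None, :, 1]
    )

    p = np.empty_like(dist)
    exc = ~inhibitory
    p[exc] = excitatory_connection_prob(dist[exc], cfg.sigma_exc, cfg.exc_cutoff)
    p[inhibitory] = inhibitory_connection_prob(
        dist[inhibitory], cfg.sigma_inh, cfg.inh_inner, cfg.inh_outer
    )
    if cfg.inh_reduced_cutoff is not None:
        p[inhibitory] *= dist[inhibitory] <= cfg.inh_reduced_cutoff
    np.fill_diagonal(p, 0.0)

    mask = rng.random((n, n)) < p
    pre, post = np.nonzero(mask)
    d = dist[pre, post]

    weight = np.empty(len(pre))
    src_inh = inhibitory[pre]
    lo_e, hi_e = cfg.lateral_exc_weight_range
    lo_i, hi_i = cfg.lateral_inh_weight_range
    weight[~src_inh] = rng.uniform(lo_e, hi_e, size=(~src_inh).sum())
    weight[src_inh] = rng.uniform(lo_i, hi_i, size=src_inh.sum())

    delay = d + rng.normal(0.0, cfg.delay_noise_sd_ms, size=len(pre))
    delay = np.maximum(delay, MIN_DELAY_MS)
    return SynapseTable(
        projection="cortex->cortex", pre=pre, post=post, weight=weight, delay_ms=delay
    )


def build_network(
    wiring: WiringConfig,
    geometry: NetworkGeometry = NetworkGeometry(),
    seed: int | None = None,
    thresh_base_mv: float = 1.0,
    thresh_noise_range_mv: float = 0.3,
) -> Network:
    """Wire a complete network instance from one seed.

    Cortical thresholds are 1.0 mV plus truncated-Gaussian noise in
    [0, 0.3] mV (mean 0.15, sd 0.075), giving every neuron a slightly
    different excitability.
    """
    seed = wiring.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    inhibitory = assign_cortex_labels(geometry, rng)
    thresh = thresh_base_mv + _truncated_normal(
        rng,
        mean=thresh_noise_range_mv / 2.0,
        sd=thresh_noise_range_mv / 4.0,
        low=0.0,
        high=thresh_noise_range_mv,
        size=geometry.cortex.n,
    )
    return Network(
        geometry=geometry,
        wiring=wiring,
        inhibitory=inhibitory,
        v_thresh_cortex=thresh,
        input_to_lgn=build_input_to_lgn(geometry),
        lgn_to_cortex=build_lgn_to_cortex(
            geometry, wiring.cf_mode, rng,
            weight_range=wiring.afferent_weight_range, random_p=wiring.random_p,
        ),
        lateral=build_lateral(inhibitory, wiring, geometry, rng),
        seed=seed,
    )


def _truncated_normal(rng, mean, sd, low, high, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=bad.sum())
        bad = (out < low) | (out > high)
    return out


# --- persistence ---------------------------------------------------------------

def save_network(net: Network, path) -> None:
    """Write a network to an HDF5 container (auditable, resumable wiring)."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("geometry")
        for layer in (net.geometry.input, net.geometry.lgn, net.geometry.cortex):
            g.attrs[f"{layer.name}_rows"] = layer.rows
            g.attrs[f"{layer.name}_cols"] = layer.cols
        g.attrs["inhibitory_fraction"] = net.geometry.inhibitory_fraction
        w = f.create_group("wiring")
        for key, val in vars(net.wiring).items():
            if val is None:
                continue
            if isinstance(val, tuple):
                val = list(val)
            w.attrs[key] = val
        f.attrs["seed"] = net.seed
        f.create_dataset("inhibitory", data=net.inhibitory)
        f.create_dataset("v_thresh_cortex", data=net.v_thresh_cortex)
        for tab in (net.input_to_lgn, net.lgn_to_cortex, net.lateral):
            grp = f.create_group(tab.projection.replace("->", "_to_"))
            grp.create_dataset("pre", data=tab.pre)
            grp.create_dataset("post", data=tab.post)
            grp.create_dataset("weight", data=tab.weight)
            grp.create_dataset("delay_ms", data=tab.delay_ms)


def load_network(path) -> Network:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["geometry"].attrs
        geometry = NetworkGeometry(
            input=LayerGeometry("input", int(g["input_rows"]), int(g["input_cols"])),
            lgn=LayerGeometry("lgn", int(g["lgn_rows"]), int(g["lgn_cols"])),
            cortex=LayerGeometry("cortex", int(g["cortex_rows"]), int(g["cortex_cols"])),
            inhibitory_fraction=float(g["inhibitory_fraction"]),
        )
        wattrs = dict(f["wiring"].attrs)
        for key in ("afferent_weight_range", "lateral_exc_weight_range",
                    "lateral_inh_weight_range"):
            if key in wattrs:
                wattrs[key] = tuple(float(v) for v in wattrs[key])
        for key in ("cf_mode",):
            if key in wattrs:
                wattrs[key] = str(wattrs[key])
        for key in ("seed",):
            if key in wattrs:
                wattrs[key] = int(wattrs[key])
        wiring = WiringConfig(**wattrs)

        def table(name: str, projection: str) -> SynapseTable:
            grp = f[name]
            return SynapseTable(
                projection=projection,
                pre=grp["pre"][:],
                post=grp["post"][:],
                weight=grp["weight"][:],
                delay_ms=grp["delay_ms"][:],
            )

        return Network(
            geometry=geometry,
            wiring=wiring,
            inhibitory=f["inhibitory"][:].astype(bool),
            v_thresh_cortex=f["v_thresh_cortex"][:],
            input_to_lgn=table("input_to_lgn", "input->lgn"),
            lgn_to_cortex=table("lgn_to_cortex", "lgn->cortex"),
            lateral=table("cortex_to_cortex", "cortex->cortex"),
            seed=int(f.attrs["seed"]),
        )
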