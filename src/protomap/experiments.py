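"""End-to-end experiment protocol: variants x networks x stimuli -> report.

The protocol presents every network with repeated moving-bar sweeps in the
eight compass directions, averages firing rates over stimulus instances,
and derives direction/orientation preference maps, selectivity indices and
preference gradients.  Three manipulations are covered by named wiring
variants:

* afferent sweep — connection fields of 3x3, 5x5 (standard) and 7x7, plus
  unstructured regimes (random p = 0.2, full connectivity);
* reduced inhibition — lateral inhibitory connections forced to zero beyond
  8 grid units (with cf5 or full afferents).

Every random choice (wiring, thresholds, stimulus noise, background noise)
derives deterministically from one master seed, so any single presentation
is replayable in isolation.  Stimulus instances differ by Poisson seed and
bar lateral offset and are shared across networks and variants, mirroring a
fixed library of recorded sweeps.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .architecture import Network, NetworkGeometry, WiringConfig, build_network
from .dynamics import SimConfig, run_presentation
from .map_analysis import (
    DIRECTION_ORDER,
    GradientMap,
    PreferenceMap,
    RateTable,
    gradient_map,
    preference_map,
    render_maps,
)
from .stimulus import BarStimulusSpec, EventStream, generate_bar_events, instance_spec

__all__ = [
    "ExperimentPlan",
    "VariantResult",
    "standard_variants",
    "run_variant",
    "run_experiment",
    "compare_variants",
    "make_report",
]

log = logging.getLogger("protomap")


def standard_variants() -> dict[str, WiringConfig]:
    """The named wiring manipulations of the study."""
    return {
        "cf3": WiringConfig(cf_mode="cf3"),
        "cf5": WiringConfig(cf_mode="cf5"),
        "cf7": WiringConfig(cf_mode="cf7"),
        "random": WiringConfig(cf_mode="random"),
        "full": WiringConfig(cf_mode="full"),
        "cf5_reduced_inh": WiringConfig(cf_mode="cf5", inh_reduced_cutoff=8.0),
        "full_reduced_inh": WiringConfig(cf_mode="full", inh_reduced_cutoff=8.0),
    }


@dataclass
class ExperimentPlan:
    """Protocol description: which variants, how many networks and stimuli."""

    variants: dict[str, WiringConfig]
    n_networks: int = 5
    n_instances: int = 10
    geometry: NetworkGeometry = field(default_factory=NetworkGeometry)
    stimulus: BarStimulusSpec = field(default_factory=BarStimulusSpec)
    sim: SimConfig = field(default_factory=SimConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 1 or self.n_instances < 1:
            raise ValueError("need at least one network and one instance")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("variant labels must be unique")

    def derived_seed(self, *key) -> int:
        """Deterministic sub-seed for one (variant, network, trial, ...) slot."""
        ints = tuple(
            int.from_bytes(k.encode(), "little") if isinstance(k, str) else int(k)
            for k in key
        )
        return int(
            np.random.SeedSequence((self.master_seed,) + ints).generate_state(1)[0]
            % (2**31)
        )


@dataclass
class NetworkResult:
    rates: RateTable
    pref_direction: PreferenceMap
    pref_orientation: PreferenceMap
    gradient: GradientMap


@dataclass
class VariantResult:
    label: str
    networks: list[NetworkResult]

    @property
    def ds_si(self) -> np.ndarray:
        """Direction SI pooled over all neurons of all networks."""
        return np.concatenate([n.pref_direction.si for n in self.networks])

    @property
    def or_si(self) -> np.ndarray:
        return np.concatenate([n.pref_orientation.si for n in self.networks])

    @property
    def mean_ds_si(self) -> float:
        return float(self.ds_si.mean())

    @property
    def mean_or_si(self) -> float:
        return float(self.or_si.mean())

    @property
    def mean_gradient(self) -> float:
        return float(np.mean([n.gradient.mean_gradient for n in self.networks]))


def make_streams(plan: ExperimentPlan) -> dict[tuple[str, int], EventStream]:
    """The shared stimulus library: one stream per (direction, instance)."""
    streams = {}
    base = replace(plan.stimulus, sensor_shape=(
        plan.geometry.input.rows, plan.geometry.input.cols))
    for d in DIRECTION_ORDER:
        for m in range(plan.n_instances):
            seed = plan.derived_seed("stimulus", d, m)
            spec = instance_spec(replace(base, direction=d), m, seed)
            streams[(d, m)] = generate_bar_events(spec)
    return streams


def run_variant(
    label: str,
    wiring: WiringConfig,
    plan: ExperimentPlan,
    streams: dict[tuple[str, int], EventStream] | None = None,
) -> VariantResult:
    """Run the full protocol for one wiring variant."""
    if streams is None:
        streams = make_streams(plan)
    grid = (plan.geometry.cortex.rows, plan.geometry.cortex.cols)
    results = []
    try:
        for k in range(plan.n_networks):
            t0 = time.perf_counter()
            net = build_network(
                wiring, plan.geometry, seed=plan.derived_seed("wiring", label, k)
            )
            rates = np.zeros((plan.geometry.cortex.n, len(DIRECTION_ORDER)))
            for di, d in enumerate(DIRECTION_ORDER):
                for m in range(plan.n_instances):
                    stream = streams[(d, m)]
                    cfg = replace(
                        plan.sim, seed=plan.derived_seed("sim", label, k, d, m)
                    )
                    log_ = run_presentation(net, stream, cfg)
                    rates[:, di] += log_.cortex_counts() / (log_.duration_ms / 1e3)
            rates /= plan.n_instances
            table = RateTable(rates=rates, grid_shape=grid)
            pref_d = preference_map(table, "direction")
            pref_o = preference_map(table, "orientation")
            results.append(
                NetworkResult(
                    rates=table,
                    pref_direction=pref_d,
                    pref_orientation=pref_o,
                    gradient=gradient_map(pref_d),
                )
            )
            log.info(
                "variant %s network %d/%d done in %.1fs (mean DS SI %.3f)",
                label, k + 1, plan.n_networks, time.perf_counter() - t0,
                float(pref_d.si.mean()),
            )
    except Exception as exc:
        raise RuntimeError(f"variant {label!r} failed: {exc}") from exc
    return VariantResult(label=label, networks=results)


def run_experiment(plan: ExperimentPlan) -> dict[str, VariantResult]:
    """Run every variant of the plan against the shared stimulus library."""
    streams = make_streams(plan)
    return {
        label: run_variant(label, wiring, plan, streams)
        for label, wiring in plan.variants.items()
    }


def compare_variants(results: dict[str, VariantResult]) -> dict:
    """Omnibus Kruskal–Wallis plus pairwise Mann–Whitney tests on pooled
    per-neuron direction SI (standard SciPy routines)."""
    labels = list(results)
    if len(labels) < 2:
        raise ValueError("need at least two variants to compare")
    samples = [results[l].ds_si for l in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need at least two SI samples per variant")
    h, p = stats.kruskal(*samples)
    pairwise = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            u, pu = stats.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
            pairwise[f"{labels[i]} vs {labels[j]}"] = {"U": float(u), "p": float(pu)}
    return {"kruskal": {"H": float(h), "p": float(p)}, "pairwise": pairwise}


def make_report(
    results: dict[str, VariantResult],
    plan: ExperimentPlan,
    out_dir,
    comparisons: dict | None = None,
    figures: bool = True,
) -> None:
    """Write summary tables, per-network CSV archives, figures and provenance."""
    import pandas as pd

    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    if figures:
        (out / "figures").mkdir(exist_ok=True)

    si_rows, grad_rows = [], []
    for label, res in results.items():
        si_rows.append(
            {"variant": label, "mean_ds_si": res.mean_ds_si,
             "mean_or_si": res.mean_or_si}
        )
        grad_rows.append({"variant": label, "mean_gradient": res.mean_gradient})
        for k, nres in enumerate(res.networks):
            df = pd.DataFrame(nres.rates.rates, columns=list(DIRECTION_ORDER))
            df.insert(0, "neuron", np.arange(len(df)))
            df["ds_angle"] = nres.pref_direction.preferred_angle
            df["ds_si"] = nres.pref_direction.si
            df["or_angle"] = nres.pref_orientation.preferred_angle
            df["or_si"] = nres.pref_orientation.si
            df.to_csv(out / "tables" / f"{label}_net{k}_neurons.csv", index=False)
            if figures:
                render_maps(
                    nres.pref_direction,
                    out / "figures",
                    prefix=f"{label}_net{k}",
                    pref_or=nres.pref_orientation,
                )
    pd.DataFrame(si_rows).to_csv(out / "tables" / "si.csv", index=False)
    pd.DataFrame(grad_rows).to_csv(out / "tables" / "gradient.csv", index=False)

    prov = {
        "master_seed": plan.master_seed,
        "n_networks": plan.n_networks,
        "n_instances": plan.n_instances,
        "directions": list(DIRECTION_ORDER),
        "geometry": {
            "input": [plan.geometry.input.rows, plan.geometry.input.cols],
            "lgn": [plan.geometry.lgn.rows, plan.geometry.lgn.cols],
            "cortex": [plan.geometry.cortex.rows, plan.geometry.cortex.cols],
        },
        "stimulus": {k: v for k, v in asdict(plan.stimulus).items()},
        "sim": asdict(plan.sim),
        "variants": {k: {kk: vv for kk, vv in asdict(v).items()}
                     for k, v in plan.variants.items()},
    }
    if comparisons is not None:
        prov["rank_tests"] = comparisons
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
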