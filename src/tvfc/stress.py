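"""Randomized stress suite over the variability statistics.

Generates a batch of seeded synthetic ROI series spanning a range of
sizes and planted-dynamics amplitudes, computes every variability
statistic (regional, intra-network, inter-network) with the default
multi-scale window grid, and summarises the extremes.  Used to check
the theoretical bounds of the statistic (all defined values lie in
[0, 2]) on arbitrary inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynvar import TemporalVariabilityExtractor
from .parcellation import Parcellation
from .synthetic import SimulationSpec, simulate_subject

__all__ = ["StressResult", "run_stress_suite"]


@dataclass
class StressResult:
    max_value: float
    min_value: float
    n_inputs: int
    n_values: int
    all_in_bounds: bool


def _random_parcellation(rng: np.random.Generator, R: int) -> Parcellation:
    n_nets = int(rng.integers(2, min(6, R) + 1))
    # contiguous blocks guarantee every network is nonempty
    cuts = np.sort(rng.choice(np.arange(1, R), size=n_nets - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [R]])
    labels = tuple(f"roi_{i + 1:03d}" for i in range(R))
    nets = []
    for j in range(n_nets):
        nets += [f"net_{j + 1}"] * (bounds[j + 1] - bounds[j])
    return Parcellation(labels, tuple(nets))


def run_stress_suite(
    n_inputs: int = 50,
    seed: int = 0,
    max_rois: int = 20,
    max_volumes: int = 300,
) -> StressResult:
    """Run the bounds stress suite and return the observed extremes.

    Each input draws R in [5, max_rois], T in [120, max_volumes] (so
    the default 21..30-volume window grid always applies), a random
    network partition, and a modulation amplitude in [0, 0.9].
    """
    rng = np.random.default_rng(seed)
    vmax, vmin = -np.inf, np.inf
    n_values = 0
    in_bounds = True
    for i in range(n_inputs):
        R = int(rng.integers(5, max_rois + 1))
        T = int(rng.integers(120, max_volumes + 1))
        a = float(rng.uniform(0.0, 0.9))
        spec = SimulationSpec(
            n_rois=R,
            n_volumes=T,
            n_per_group=(1, 0, 0),
            group_amplitudes=(a, a, a),
            modulated_rois=tuple(range(max(2, R // 3))),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ts, _ = simulate_subject(spec, 0, subject_seed=i)
        parc = _random_parcellation(rng, R)
        ext = TemporalVariabilityExtractor(parc).fit([ts.data])
        values = ext.transform([ts.data])[0]
        defined = values[np.isfinite(values)]
        n_values += defined.size
        if defined.size:
            vmax = max(vmax, float(defined.max()))
            vmin = min(vmin, float(defined.min()))
            if defined.max() > 2.0 or defined.min() < 0.0:
                in_bounds = False
    return StressResult(vmax, vmin, n_inputs, n_values, in_bounds)
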