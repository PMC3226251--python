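"""Statistical calibration of the enrichment test on synthetic data.

Two replicated simulations characterise the distance-1 enrichment
p-value: its type-I error under the uniform null (``proximity_rho = 1``,
seeds drawn uniformly — the rejection rate at the 0.05 level should be
about 5%) and its power when proximity enrichment is planted
(``proximity_rho`` large, seeds = the essential genes).  Both share one
interactome and one distance cache across replicates; only the marker and
seed draws are redrawn.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np

from .neighborhood import DistanceProfiler, enrichment
from .synthetic_data import SyntheticConfig, gen_markers, gen_ppi


def _base(cfg: SyntheticConfig):
    ppi = gen_ppi(cfg.n_proteins, cfg.attach_m, cfg.rng_seed)
    return ppi, DistanceProfiler(ppi)


def type_i_error_rate(cfg: SyntheticConfig, n_replicates: int = 200,
                      n_random: int = 1000, alpha: float = 0.05,
                      distance: int = 1) -> float:
    """Fraction of null replicates with p(distance) < ``alpha``.

    Each replicate draws markers under the uniform null (rho = 1) and an
    independent uniform seed set of size ``cfg.n_essential``; anchors are
    then exchangeable with the random control, so the rejection rate
    estimates the test's size.
    """
    null_cfg = dataclasses.replace(cfg, proximity_rho=1.0)
    ppi, prof = _base(null_cfg)
    nodes = sorted(ppi.nodes)
    hits = 0
    for rep in range(n_replicates):
        rep_cfg = dataclasses.replace(null_cfg,
                                      rng_seed=null_cfg.rng_seed + 1000 + rep)
        markers = gen_markers(ppi, rep_cfg)
        rng = np.random.default_rng([int(rep_cfg.rng_seed), 3])
        seeds = rng.choice(nodes, size=cfg.n_essential, replace=False)
        res = enrichment(ppi, seeds, markers.bioassay_targets,
                         n_random=n_random, rng_seed=int(rep_cfg.rng_seed),
                         profiler=prof)
        if res.p_value.get(distance, 1.0) < alpha:
            hits += 1
    return hits / n_replicates


def detection_power(cfg: SyntheticConfig, n_replicates: int = 25,
                    n_random: int = 1000, alpha: float = 0.01,
                    distance: int = 1) -> float:
    """Fraction of planted replicates with p(distance) < ``alpha``.

    Each replicate redraws the marker sets at ``cfg.proximity_rho`` and
    runs the real analysis: seeds are the (degree-biased) essential genes,
    markers the planted bioassay targets.
    """
    ppi, prof = _base(cfg)
    hits = 0
    for rep in range(n_replicates):
        rep_cfg = dataclasses.replace(cfg, rng_seed=cfg.rng_seed + 2000 + rep)
        markers = gen_markers(ppi, rep_cfg)
        res = enrichment(ppi, markers.essential, markers.bioassay_targets,
                         n_random=n_random, rng_seed=int(rep_cfg.rng_seed),
                         profiler=prof)
        if res.p_value.get(distance, 1.0) < alpha:
            hits += 1
    return hits / n_replicates
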