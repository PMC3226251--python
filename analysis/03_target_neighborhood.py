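#!/usr/bin/env python
"""Where do bioassay targets sit in the interactome?

Reads the simulated interactome and marker sets (run 01 first) and asks
the two questions the prioritisation rests on: are bioassay targets
better connected than drug targets and random proteins (degree curves,
median-degree rank-sum test), and do they cluster around essential genes,
drug targets and disease genes beyond random expectation (per-distance
fraction profiles against a 1,000-draw randomised control)?"""

from pathlib import Path

import numpy as np

from assaynet import DistanceProfiler, degree_cdf, enrichment, io, map_symbols, ranksum

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "neighborhood"
N_RANDOM = 1000
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ppi = io.read_edges(BASE / "data" / "ppi_edges.tsv")
    sets = {}
    for name in ("essential", "drug_targets", "disease_genes",
                 "bioassay_targets"):
        mapped, unmapped = map_symbols(
            io.read_markers(BASE / "data" / f"markers_{name}.txt"), ppi)
        assert not unmapped, f"unmapped {name} symbols: {unmapped[:3]}"
        sets[name] = mapped

    rng = np.random.default_rng(SEED)
    nodes = sorted(ppi.nodes)
    reference = set(rng.choice(nodes, size=len(sets["bioassay_targets"]),
                               replace=False))

    rows = []
    groups = {"bioassay_targets": sets["bioassay_targets"],
              "drug_targets": sets["drug_targets"],
              "random_reference": reference}
    for name, members in groups.items():
        cdf = degree_cdf(ppi, members, range(1, 52))
        rows += [[name, k, v] for k, v in cdf.items()]
    io.write_table(rows, OUT / "degree_cdf.tsv",
                   columns=["group", "k", "pct_degree_ge_k"])

    deg = {n: ppi.degree(n) for n in nodes}
    bt = [deg[n] for n in sets["bioassay_targets"]]
    dt = [deg[n] for n in sets["drug_targets"]]
    p = ranksum(bt, dt)
    print(f"median degree: bioassay targets {np.median(bt):.0f} vs "
          f"drug targets {np.median(dt):.0f} (rank-sum P = {p:.3g})")

    prof = DistanceProfiler(ppi)
    rows = []
    for name in ("essential", "drug_targets", "disease_genes"):
        res = enrichment(ppi, sets[name], sets["bioassay_targets"],
                         n_random=N_RANDOM, rng_seed=SEED, profiler=prof)
        for d in res.distances:
            rows.append([name, d, res.mean_fraction[d],
                         res.random_mean_fraction[d], res.p_value[d]])
        f1, r1, p1 = (res.mean_fraction[1], res.random_mean_fraction[1],
                      res.p_value[1])
        print(f"around {name}: {100*f1:.2f}% of distance-1 proteins are "
              f"bioassay targets vs {100*r1:.2f}% around random proteins "
              f"(P = {p1:.3g})")
    io.write_table(rows, OUT / "enrichment.tsv",
                   columns=["anchor_set", "distance", "mean_fraction",
                            "random_mean_fraction", "p_value"])


if __name__ == "__main__":
    main()
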