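#!/usr/bin/env python
"""Generate the synthetic screening study: a preferential-attachment
interactome, marker sets with planted proximity enrichment, and a
clustered bioassay–compound activity table.  Writes the TSV inputs every
later analysis step consumes and reports the basic counts."""

from pathlib import Path

from assaynet import SyntheticConfig, gen_activity, gen_markers, gen_ppi, io, summarize, build_bipartite

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(rng_seed=seed)
    ppi = gen_ppi(cfg.n_proteins, cfg.attach_m, cfg.rng_seed)
    markers = gen_markers(ppi, cfg)
    table = gen_activity(cfg, markers)

    io.write_edges(ppi, OUT / "ppi_edges.tsv")
    for name, members in markers.as_dict().items():
        io.write_markers(members, OUT / f"markers_{name}.txt")
    io.write_activity(table, OUT / "activity.tsv", OUT / "assays.tsv")

    s = summarize(build_bipartite(table))
    print(f"interactome: {ppi.number_of_nodes()} proteins, "
          f"{ppi.number_of_edges()} interactions")
    print(f"markers: {len(markers.essential)} essential, "
          f"{len(markers.drug_targets)} drug targets, "
          f"{len(markers.disease_genes)} disease genes, "
          f"{len(markers.bioassay_targets)} bioassay targets "
          f"(proximity rho = {cfg.proximity_rho})")
    print(f"screen: {s.n_pairs} active pairs over {s.n_assays_active} assays "
          f"and {s.n_active_compounds} compounds "
          f"({s.mean_compounds_per_assay:.1f} compounds/assay, "
          f"{s.mean_assays_per_compound:.1f} assays/compound)")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
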