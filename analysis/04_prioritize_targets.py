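#!/usr/bin/env python
"""Rank bioassay targets as candidate drug targets.

For every bioassay target that is not already a drug target, computes the
characteristic (inverse-square-field) distance d̂ to the essential genes
and to the approved drug targets, then applies the binned ranking: bins
of width 0.5 on d̂_essential ascending, d̂_drug descending within a bin
(novelty first), candidates with fewer than 17 interaction partners
dropped.  Writes the full priority table and prints the top 10."""

from pathlib import Path

from assaynet import io, map_symbols, prioritize
from assaynet.druggability import score_targets

BASE = Path(__file__).resolve().parent.parent / "results"
MIN_DEGREE = 17


def main() -> None:
    ppi = io.read_edges(BASE / "data" / "ppi_edges.tsv")
    sets = {}
    for name in ("essential", "drug_targets", "bioassay_targets"):
        mapped, _ = map_symbols(
            io.read_markers(BASE / "data" / f"markers_{name}.txt"), ppi)
        sets[name] = mapped

    candidates = sets["bioassay_targets"] - sets["drug_targets"]
    rows = score_targets(ppi, candidates, sets["essential"],
                         sets["drug_targets"])
    ranked = prioritize(rows, bin_width=0.5, min_degree=MIN_DEGREE,
                        exclude=sets["drug_targets"])
    io.write_table(
        [[r.gene, f"{r.d_essential:.4f}", f"{r.d_drug:.4f}", r.degree,
          r.bin_index, r.rank] for r in ranked],
        BASE / "priorities.tsv",
        columns=["gene", "d_essential", "d_drug", "degree", "bin", "rank"])

    print(f"{len(candidates)} candidate targets, {len(ranked)} with degree "
          f">= {MIN_DEGREE} ranked; top 10:")
    print("rank\tgene\td_essential\td_drug\tdegree")
    for r in ranked[:10]:
        print(f"{r.rank}\t{r.gene}\t{r.d_essential:.4f}\t"
              f"{r.d_drug:.4f}\t{r.degree}")
    print(f"full table in {BASE / 'priorities.tsv'}")


if __name__ == "__main__":
    main()
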