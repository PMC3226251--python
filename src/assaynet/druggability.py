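"""Characteristic distance and binned druggability prioritisation.

Every member of a "charged" marker set (essential genes, or approved drug
targets) is viewed as a unit charge creating an inverse-square field; the
fields accumulate at a candidate protein.  With f_i the fraction of the
charged set at shortest-path distance d_i, the field strength at the
candidate is

    E = Σ_i f_i / d_i²

and the characteristic distance is d̂ = E^(−1/2): the distance at which a
single unit charge would produce the same field.  All charge on one shell
at distance k gives d̂ = k exactly; d̂ < 1 requires strong concentration
inside the first shell, which is why charged members of the set itself
land below 1.0 while unrelated proteins sit near or above it.

This formula is a reconstruction: it is the unique inverse-square field
summary consistent with the stated unit-charge analogy and the
single-shell behaviour, but the original presentation of the formula is
not available verbatim.

Prioritisation then bins candidates on d̂ to essential genes (ascending,
bin width 0.5), ranks within each bin by d̂ to drug targets *descending*
(farther from the existing target repertoire = more novel), and filters
out weakly connected candidates (degree < 17 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from .neighborhood import bfs_distances


@dataclass(frozen=True)
class DistanceProfile:
    """Fractions of a charged set per shortest-path shell around a target."""

    f: dict[int, float]
    charged_set_size: int
    reachable_fraction: float


@dataclass(frozen=True)
class PrioritizationRow:
    gene: str
    d_essential: float
    d_drug: float
    degree: int
    bin_index: int
    rank: int


def charge_profile(ppi: nx.Graph, target, charged: Iterable) -> DistanceProfile:
    """Distance distribution of ``charged`` members around ``target``.

    The target itself is excluded from both numerator and denominator.
    Unreachable charged members stay in the denominator (they contribute
    no field but still normalise the profile), so Σ f ≤ 1 with equality
    iff the whole charged set is reachable.
    """
    if target not in ppi:
        raise KeyError(f"target {target!r} not in the network")
    charged = set(charged) - {target}
    if not charged:
        raise ValueError("charged set is empty after excluding the target")
    dist = bfs_distances(ppi, target)
    shell: dict[int, int] = {}
    reachable = 0
    for s in charged:
        d = dist.get(s)
        if d is not None:
            shell[d] = shell.get(d, 0) + 1
            reachable += 1
    denom = len(charged)
    return DistanceProfile(
        f={d: c / denom for d, c in sorted(shell.items())},
        charged_set_size=denom,
        reachable_fraction=reachable / denom,
    )


def field_strength(profile: DistanceProfile) -> float:
    """E = Σ_i f(d_i) / d_i² — the accumulated inverse-square field."""
    return sum(frac / d**2 for d, frac in profile.f.items() if d >= 1)


def characteristic_distance(profile: DistanceProfile) -> float:
    """d̂ = E^(−1/2); +inf when nothing is reachable (zero field)."""
    e = field_strength(profile)
    if e == 0.0:
        return math.inf
    return e ** -0.5


def score_targets(ppi: nx.Graph, candidates: Iterable, essential: Iterable,
                  drug_targets: Iterable) -> list[tuple[str, float, float, int]]:
    """(gene, d̂ to essential genes, d̂ to drug targets, PPI degree) per
    candidate — the raw rows the prioritisation consumes."""
    essential = set(essential)
    drug_targets = set(drug_targets)
    rows = []
    for gene in sorted(set(candidates)):
        de = characteristic_distance(charge_profile(ppi, gene, essential))
        dd = characteristic_distance(charge_profile(ppi, gene, drug_targets))
        rows.append((gene, de, dd, ppi.degree(gene)))
    return rows


def prioritize(rows: Sequence[tuple[str, float, float, int]],
               bin_width: float = 0.5, min_degree: int = 17,
               exclude: Iterable = ()) -> list[PrioritizationRow]:
    """Binned ranking of candidate targets.

    1. drop genes in ``exclude`` (typically the approved drug targets);
    2. drop genes with network degree < ``min_degree`` (inclusive bound:
       degree == min_degree survives) and genes with no finite d̂ to the
       essential set;
    3. bin_index = floor(d_essential / bin_width); bins are left-closed
       right-open ([1.0,1.5), [1.5,2.0), ...) and traversed ascending;
    4. within a bin, sort by d_drug descending, ties broken by gene symbol
       ascending;
    5. ranks run 1..n over the concatenated bins.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    excluded = set(exclude)
    keyed = []
    for gene, de, dd, degree in rows:
        if gene in excluded or degree < min_degree or not math.isfinite(de):
            continue
        keyed.append((int(math.floor(de / bin_width)), -dd, gene, de, dd, degree))
    keyed.sort()
    return [
        PrioritizationRow(gene=g, d_essential=de, d_drug=dd, degree=deg,
                          bin_index=b, rank=i + 1)
        for i, (b, _, g, de, dd, deg) in enumerate(keyed)
    ]
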