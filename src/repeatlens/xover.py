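"""Unequal crossing-over between motif arrays: event model, Wright-Fisher
population simulation, and minimal-derivation search.

Mosaic repeat alleles (mixed CA18/CACA20/CGCA20 arrays with motif-boundary
block structure) are consistent with an origin by recombination between
misaligned arrays rather than by replication slippage.  This module makes
that hypothesis executable: a crossover event splices two parental arrays at
motif-granular breakpoints (the shared 10-nt motif head keeps register at
motif boundaries; sub-motif breakpoints would create units never observed),
conserving total motif count across the two products.  There is deliberately
no slippage / stepwise-mutation mode: the locus is transgenerationally
stable, unlike dynamic-mutation repeat disorders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError, ResourceError
from .motif_core import AlleleStructure, format_nomenclature

#: Viable product size range: observed alleles span 2-17 motifs; 20 gives
#: headroom without letting arrays run away.
VIABLE_RANGE = (2, 20)


@dataclass(frozen=True)
class CrossoverEvent:
    parent1: AlleleStructure
    parent2: AlleleStructure
    break1: int
    break2: int
    products: tuple[AlleleStructure, AlleleStructure]

    @property
    def unequal(self) -> bool:
        return self.break1 != self.break2


def unequal_crossover(
    p1: AlleleStructure, p2: AlleleStructure, break1: int, break2: int
) -> tuple[AlleleStructure, AlleleStructure]:
    """Splice two insertion-free arrays at motif indices ``break1``/``break2``.

    Products are ``p1[:break1] + p2[break2:]`` and ``p2[:break2] + p1[break1:]``;
    total motif count is conserved.  Breakpoint ``k`` means "between motif
    k-1 and motif k", so 0 and len(motifs) are valid (whole-array transfer).
    """
    if p1.has_insertions or p2.has_insertions:
        raise ParameterError("crossover parents must be insertion-free")
    if not (0 <= break1 <= p1.repeat_count):
        raise ParameterError(f"break1={break1} out of range 0..{p1.repeat_count}")
    if not (0 <= break2 <= p2.repeat_count):
        raise ParameterError(f"break2={break2} out of range 0..{p2.repeat_count}")
    q1 = AlleleStructure(p1.motifs[:break1] + p2.motifs[break2:])
    q2 = AlleleStructure(p2.motifs[:break2] + p1.motifs[break1:])
    return q1, q2


def _valid_breakpoints(
    n1: int, n2: int, viable: tuple[int, int] = VIABLE_RANGE
) -> list[tuple[int, int]]:
    """All misaligned (break1, break2) pairs whose products both fall in the
    viable size range."""
    lo, hi = viable
    out = []
    for b1 in range(n1 + 1):
        for b2 in range(n2 + 1):
            if b1 == b2:
                continue
            s1 = b1 + (n2 - b2)
            s2 = b2 + (n1 - b1)
            if lo <= s1 <= hi and lo <= s2 <= hi:
                out.append((b1, b2))
    return out


@dataclass
class PopulationTrajectory:
    """Per-generation allele pools of a Wright-Fisher simulation."""

    generations: list[list[AlleleStructure]]
    events: list[tuple[int, CrossoverEvent]]  # (generation, event)
    pop_size: int
    crossover_rate: float
    seed: int

    @property
    def n_generations(self) -> int:
        return len(self.generations) - 1

    def distinct_structures(self, generation: int = -1) -> int:
        return len({a.structure_key() for a in self.generations[generation]})

    def mean_repeat_count(self, generation: int = -1) -> float:
        pool = self.generations[generation]
        return sum(a.repeat_count for a in pool) / len(pool)


def evolve_population(
    initial_pool: Sequence[AlleleStructure],
    generations: int,
    crossover_rate: float,
    seed: int,
    pop_size: int | None = None,
    viable: tuple[int, int] = VIABLE_RANGE,
) -> PopulationTrajectory:
    """Wright-Fisher resampling of a diploid population of repeat alleles.

    The pool holds ``2 * pop_size`` alleles (consecutive pairs form
    individuals).  Each offspring allele is transmitted by a random parent;
    with probability ``crossover_rate`` the transmitted allele is one product
    of an unequal crossover between the parent's two homologs, with the
    breakpoint pair uniform over valid misalignments (products constrained to
    the viable size range).  Parents whose homologs admit no valid
    misalignment transmit a plain homolog.
    """
    if not initial_pool:
        raise ParameterError("initial pool must be non-empty")
    if not 0.0 <= crossover_rate <= 1.0:
        raise ParameterError("crossover_rate must be in [0, 1]")
    if pop_size is None:
        if len(initial_pool) % 2:
            raise ParameterError("initial pool must have even size (2 per individual)")
        pop_size = len(initial_pool) // 2
    if pop_size == 0:
        raise ParameterError("pop_size must be positive")
    rng = np.random.default_rng(seed)
    pool = list(initial_pool)
    if len(pool) != 2 * pop_size:
        pool = [pool[i] for i in rng.integers(0, len(pool), 2 * pop_size)]
    gens = [list(pool)]
    events: list[tuple[int, CrossoverEvent]] = []
    for g in range(1, generations + 1):
        new_pool: list[AlleleStructure] = []
        for _ in range(2 * pop_size):
            p = int(rng.integers(0, pop_size))
            h1, h2 = pool[2 * p], pool[2 * p + 1]
            transmitted = None
            if crossover_rate > 0 and rng.random() < crossover_rate:
                valid = _valid_breakpoints(h1.repeat_count, h2.repeat_count, viable)
                if valid:
                    b1, b2 = valid[int(rng.integers(0, len(valid)))]
                    products = unequal_crossover(h1, h2, b1, b2)
                    events.append((g, CrossoverEvent(h1, h2, b1, b2, products)))
                    transmitted = products[int(rng.integers(0, 2))]
            if transmitted is None:
                transmitted = h1 if rng.random() < 0.5 else h2
            new_pool.append(transmitted)
        pool = new_pool
        gens.append(list(pool))
    return PopulationTrajectory(
        generations=gens,
        events=events,
        pop_size=pop_size,
        crossover_rate=crossover_rate,
        seed=seed,
    )


@dataclass
class DerivationResult:
    min_events: int | None  # None => unreachable within max_events
    witness: list[CrossoverEvent] = field(default_factory=list)

    @property
    def reachable(self) -> bool:
        return self.min_events is not None


def derivation_distance(
    target: AlleleStructure,
    pool: Sequence[AlleleStructure],
    max_events: int = 3,
    node_budget: int = 500_000,
    viable: tuple[int, int] = VIABLE_RANGE,
) -> DerivationResult:
    """Minimal number of unequal-crossover events deriving ``target`` from
    ``pool``, with one witness event path.

    Exact search by total event cost: a product built from intermediates
    costing ``i`` and ``j`` events costs ``i + j + 1``.  Level ``c`` is the
    set of structures first reachable at cost ``c``; the search stops at
    ``max_events`` (the space is exponential) or when the node budget is
    exhausted.
    """
    if target.has_insertions:
        raise ParameterError("derivation search requires an insertion-free target")
    if max_events > 4:
        raise ParameterError("max_events is capped at 4 (exponential search)")
    tkey = target.structure_key()
    # best[key] = (cost, structure, witness_path)
    best: dict[tuple, tuple[int, AlleleStructure, list[CrossoverEvent]]] = {}
    levels: list[list[AlleleStructure]] = [[]]
    for a in pool:
        if a.has_insertions:
            continue
        k = a.structure_key()
        if k not in best:
            best[k] = (0, a, [])
            levels[0].append(a)
    if tkey in best:
        return DerivationResult(0, [])
    nodes = 0
    for cost in range(1, max_events + 1):
        level: list[AlleleStructure] = []
        # pairs of levels (i, j) with i + j + 1 == cost
        for i in range(0, cost):
            j = cost - 1 - i
            if j < i or j >= len(levels):
                continue
            for a in levels[i]:
                for b in levels[j]:
                    for b1, b2 in _valid_breakpoints(
                        a.repeat_count, b.repeat_count, viable
                    ):
                        nodes += 1
                        if nodes > node_budget:
                            raise ResourceError(
                                f"derivation search exceeded {node_budget} nodes "
                                f"(frontier {len(level)}) at cost {cost}"
                            )
                        products = unequal_crossover(a, b, b1, b2)
                        ev = CrossoverEvent(a, b, b1, b2, products)
                        for prod in products:
                            k = prod.structure_key()
                            if k in best:
                                continue
                            path = best[a.structure_key()][2] + best[b.structure_key()][2] + [ev]
                            best[k] = (cost, prod, path)
                            level.append(prod)
                            if k == tkey:
                                return DerivationResult(cost, path)
        levels.append(level)
    return DerivationResult(None, [])


def event_log_frame(trajectory: PopulationTrajectory):
    """Event log as a DataFrame of nomenclature strings (for TSV export)."""
    import pandas as pd

    rows = [
        {
            "generation": g,
            "parent1": format_nomenclature(ev.parent1),
            "parent2": format_nomenclature(ev.parent2),
            "break1": ev.break1,
            "break2": ev.break2,
            "product1": format_nomenclature(ev.products[0]),
            "product2": format_nomenclature(ev.products[1]),
        }
        for g, ev in trajectory.events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "generation", "parent1", "parent2", "break1", "break2", "product1", "product2",
        ],
    )
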