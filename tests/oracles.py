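"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's recursive scorer and scipy's test
machinery: module completion is scored by exhaustively expanding every OR
branch into explicit AND-combinations and taking, per step, the best
combination's structured fraction of present components; Mann-Whitney
p-values come from direct enumeration of the rank-subset null distribution.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from magfunc.kegg import And, Atom, ModuleDefinition, Optional, Or, Wildcard


# ---------------------------------------------------------------------------
# Module completion oracle
# ---------------------------------------------------------------------------

def _branch_expansions(node):
    """All OR-free trees reachable by resolving each OR to one branch.
    Optional components are dropped entirely (they carry no weight)."""
    if isinstance(node, (Atom, Wildcard)):
        return [node]
    if isinstance(node, Optional):
        return []
    if isinstance(node, Or):
        out = []
        for child in node.children:
            out.extend(_branch_expansions(child))
        return out
    if isinstance(node, And):
        child_lists = [lst for c in node.children
                       if (lst := _branch_expansions(c))]
        if not child_lists:
            return []
        out = []
        for combo in itertools.product(*child_lists):
            out.append(combo[0] if len(combo) == 1 else And(tuple(combo), op=node.op))
        return out
    raise TypeError(node)


def _structured_fraction(orfree, kos) -> float:
    """Fraction of required components present, weighting each AND child
    equally (nested groups count as one unit)."""
    if isinstance(orfree, Atom):
        return 1.0 if orfree.ko in kos else 0.0
    if isinstance(orfree, Wildcard):
        return 1.0
    if isinstance(orfree, And):
        return float(np.mean([_structured_fraction(c, kos)
                              for c in orfree.children]))
    raise TypeError(orfree)


def oracle_node_completeness(node, kos) -> float:
    expansions = _branch_expansions(node)
    if not expansions:
        return 0.0
    kos = frozenset(k.upper() for k in kos)
    return max(_structured_fraction(e, kos) for e in expansions)


def oracle_module_score(module: ModuleDefinition, kos) -> float:
    step_scores = []
    for step in module.steps:
        expansions = _branch_expansions(step)
        if not expansions:
            continue  # optional-only step: no weight
        kos_u = frozenset(k.upper() for k in kos)
        step_scores.append(max(_structured_fraction(e, kos_u)
                               for e in expansions))
    return float(np.mean(step_scores)) if step_scores else 0.0


# ---------------------------------------------------------------------------
# Mann-Whitney exact enumeration oracle
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _u_distribution(n_a: int, n_b: int):
    """Counts of the U statistic over all C(n_a+n_b, n_a) rank subsets."""
    n = n_a + n_b
    counts = np.zeros(n_a * n_b + 1, dtype=np.int64)
    offset = n_a * (n_a + 1) // 2
    for subset in itertools.combinations(range(1, n + 1), n_a):
        counts[sum(subset) - offset] += 1
    return counts


def oracle_exact_p(n_a: int, n_b: int, u: float) -> float:
    """Two-tailed exact p for an untied sample with statistic ``u``."""
    counts = _u_distribution(n_a, n_b)
    total = counts.sum()
    u_hi = max(u, n_a * n_b - u)
    u_lo = min(u, n_a * n_b - u)
    p = (counts[int(np.ceil(u_hi - 1e-9)):].sum()
         + counts[:int(np.floor(u_lo + 1e-9)) + 1].sum()) / total
    return float(min(p, 1.0))


def ranks_with_u(n_a: int, n_b: int, u: int):
    """An untied (a, b) instance realizing the given U statistic."""
    n = n_a + n_b
    ranks = list(range(1, n_a + 1))
    excess = u
    for i in range(n_a - 1, -1, -1):
        cap = n - (n_a - 1 - i)
        bump = min(excess, cap - ranks[i])
        ranks[i] += bump
        excess -= bump
    assert excess == 0, "U not realizable"
    a = [float(r) for r in ranks]
    b = [float(r) for r in range(1, n + 1) if r not in set(ranks)]
    return a, b
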