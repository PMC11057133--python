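"""Module novelty: how tumor-specific is a co-expression module?

The raw novelty of a tumor module is the minimum number N of reference
(normal-tissue) modules needed to jointly cover half of its genes; dividing
by the module size S gives the novelty score N/S.  A module fully preserved
from normal tissue has N = 1 and the minimal score for its size; a module
assembling genes scattered across many normal modules — or absent from them —
scores high.  Scores are binned into low/medium/high tertiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ModuleSet

LOW, MEDIUM, HIGH = "low", "medium", "high"


@dataclass(frozen=True)
class NoveltyResult:
    module: str
    size: int  # S
    raw_novelty: int  # N
    score: float  # N / S
    reached: bool  # 50% coverage achievable from the reference modules
    tertile: str = ""


def raw_novelty(
    target: Iterable[str],
    reference: ModuleSet,
    coverage: float = 0.5,
) -> tuple[int, bool]:
    """Minimum number of reference modules covering *coverage* of *target*.

    Reference modules are sorted by decreasing overlap with the target (ties:
    larger module first, then label) and accumulated until the covered gene
    count reaches ``coverage * |target|`` (non-strict).  Because reference
    modules are disjoint this greedy count is exactly the optimal N.  When
    coverage is unreachable (target genes missing from every reference
    module), N is the number of overlapping modules plus one and ``reached``
    is False, preserving the "more modules needed = more novel" ordering.
    """
    target = set(target)
    if not target:
        raise ValueError("target module must be non-empty")
    need = coverage * len(target)
    overlaps = sorted(
        (
            (len(target & genes), len(genes), label)
            for label, genes in reference.modules.items()
        ),
        key=lambda t: (-t[0], -t[1], t[2]),
    )
    covered = 0
    n_overlapping = sum(1 for o, _, _ in overlaps if o > 0)
    for n, (o, _, _) in enumerate(overlaps, start=1):
        if o == 0:
            break
        covered += o
        if covered >= need:
            return n, True
    return n_overlapping + 1, False


def novelty_score(n: int, s: int) -> float:
    """Novelty = raw novelty N over module size S."""
    if n < 1 or s < 1:
        raise ValueError("raw novelty and size must both be >= 1")
    return n / s


def classify_tertiles(scores: Sequence[tuple[str, float]]) -> dict[str, str]:
    """Bin (label, score) pairs into low/medium/high at the 1/3 and 2/3 quantiles.

    Quantiles use linear interpolation between order statistics; a score is
    low when <= q1, medium when <= q2, else high (so equal scores all fall in
    the low bin).
    """
    if not scores:
        raise ValueError("need at least one score")
    vals = np.array([s for _, s in scores], dtype=float)
    q1, q2 = np.quantile(vals, [1 / 3, 2 / 3])
    out = {}
    for label, s in scores:
        out[label] = LOW if s <= q1 else MEDIUM if s <= q2 else HIGH
    return out


def score_modules(
    target: ModuleSet,
    reference: ModuleSet,
    coverage: float = 0.5,
) -> list[NoveltyResult]:
    """Novelty of every module in *target* against *reference*, with tertiles.

    Tertile cutoffs are computed within this one comparison.  Grey pools are
    never part of the reference.
    """
    results = []
    for label, genes in target.modules.items():
        n, reached = raw_novelty(genes, reference, coverage)
        results.append(NoveltyResult(label, len(genes), n, novelty_score(n, len(genes)), reached))
    if results:
        tertiles = classify_tertiles([(r.module, r.score) for r in results])
        results = [
            NoveltyResult(r.module, r.size, r.raw_novelty, r.score, r.reached, tertiles[r.module])
            for r in results
        ]
    return results


def novelty_table(results: Sequence[NoveltyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": r.module,
                "size": r.size,
                "raw_novelty": r.raw_novelty,
                "score": r.score,
                "reached": r.reached,
                "tertile": r.tertile,
            }
            for r in results
        ]
    )


def max_overlap_profile(
    modset: ModuleSet, others: Mapping[str, ModuleSet]
) -> tuple[pd.DataFrame, pd.Series]:
    """Best percentage overlap of each module with each other cohort.

    Overlap of module A with module B is ``100 * |A & B| / |A|``; per cohort
    the maximum over that cohort's modules is recorded, then averaged over
    modules to one mean per cohort.
    """
    rows = {}
    for label, genes in modset.modules.items():
        row = {}
        for cohort, other in others.items():
            best = 0.0
            for b_genes in other.modules.values():
                best = max(best, 100.0 * len(genes & b_genes) / len(genes))
            row[cohort] = best
        rows[label] = row
    profile = pd.DataFrame.from_dict(rows, orient="index")
    means = profile.mean(axis=0) if len(profile) else pd.Series(dtype=float)
    return profile, means


def randomize_modules(
    modset: ModuleSet, n_iter: int = 1000, seed: int | None = None
) -> Iterator[ModuleSet]:
    """Yield random re-partitions of the assigned genes into same-size modules.

    Genes are shuffled uniformly and dealt back into modules of the original
    sizes, matching the null used to judge whether observed age compositions
    or overlaps exceed chance.  Reproducible given *seed*.
    """
    rng = np.random.default_rng(seed)
    labels = list(modset.modules)
    sizes = [len(modset.modules[lab]) for lab in labels]
    universe = np.array(sorted(modset.assigned_genes))
    for _ in range(n_iter):
        perm = rng.permutation(universe)
        modules: dict[str, set[str]] = {}
        start = 0
        for lab, size in zip(labels, sizes):
            modules[lab] = set(perm[start : start + size])
            start += size
        yield ModuleSet(modules, set(modset.grey), modset.provenance)
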