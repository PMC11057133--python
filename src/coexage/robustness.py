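"""Strongest-connection robustness filter for modules.

Keeps only the top half of each module's edge weights, then drops genes left
connected to fewer than half of the module's (original) genes.  Re-running
age enrichment and novelty on the surviving gene sets checks that module
classifications are not artifacts of weak edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FilteredModule:
    label: str
    original_size: int
    retained_genes: set[str]
    dropped_genes: set[str]
    retained_edges: pd.DataFrame  # columns gene_a, gene_b, weight
    empty: bool


def filter_strong_edges(module_net: pd.DataFrame, label: str = "") -> FilteredModule:
    """Drop edges below the module's median weight, then under-connected genes.

    The median is taken over the multiset of off-diagonal weights (each
    unordered pair once); edges strictly below it are removed, so ties at the
    median survive and with distinct weights exactly half the edges remain.
    A gene is kept when its retained-edge count reaches half of the ORIGINAL
    module size S (>= ceil(S/2)).  Deterministic; an empty outcome is flagged
    rather than raised.
    """
    s = module_net.shape[0]
    if module_net.shape[1] != s or s < 2:
        raise ValueError("need a square intra-module network of size >= 2")
    genes = list(module_net.index)
    w = module_net.to_numpy(dtype=float)
    iu = np.triu_indices(s, k=1)
    weights = w[iu]
    med = float(np.median(weights))

    keep = weights >= med
    a_idx, b_idx = iu[0][keep], iu[1][keep]
    degree = np.zeros(s, dtype=int)
    np.add.at(degree, a_idx, 1)
    np.add.at(degree, b_idx, 1)

    floor = int(np.ceil(s / 2))
    gene_keep = degree >= floor
    retained = {genes[i] for i in range(s) if gene_keep[i]}
    # edges between retained genes only
    edge_mask = gene_keep[a_idx] & gene_keep[b_idx]
    edges = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in a_idx[edge_mask]],
            "gene_b": [genes[i] for i in b_idx[edge_mask]],
            "weight": weights[keep][edge_mask],
        }
    )
    return FilteredModule(
        label=label,
        original_size=s,
        retained_genes=retained,
        dropped_genes=set(genes) - retained,
        retained_edges=edges,
        empty=len(retained) == 0,
    )
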