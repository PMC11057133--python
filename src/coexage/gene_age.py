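"""Evolutionary gene ages from phylostratigraphy.

Genes are placed on a 16-level phylostratigraphic scale: stratum 1 holds genes
with detectable orthologs across all organisms, stratum 16 genes specific to
humans.  Genes whose most distant orthologs lie in bacteria or single-celled
eukaryotes (strata 1-3) are classed as having unicellular (UC) origin; genes
with orthologs only in other multicellular species are multicellular (MC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

N_STRATA = 16
UC_MAX_STRATUM = 3

UC = "UC"
MC = "MC"
UNKNOWN = "unknown"


def age_class(stratum: int) -> str:
    """Map a phylostratum (1..16) to the UC/MC dichotomy.

    Strata 1-3 (orthologs in bacteria or single-celled eukaryotes) are UC;
    strata 4-16 (orthologs confined to multicellular species) are MC.
    """
    stratum = int(stratum)
    if not 1 <= stratum <= N_STRATA:
        raise ValueError(f"phylostratum must be in 1..{N_STRATA}, got {stratum}")
    return UC if stratum <= UC_MAX_STRATUM else MC


@dataclass(frozen=True)
class GeneAgeTable:
    """Phylostratum assignment per gene, with the derived UC/MC class.

    Gene identifiers are treated as opaque strings; no symbol/ID mapping is
    attempted.  Genes absent from the table are reported as ``unknown`` and
    must be excluded from age-enrichment counts.
    """

    strata: Mapping[str, int]
    _classes: Mapping[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        classes = {g: age_class(s) for g, s in self.strata.items()}
        object.__setattr__(self, "_classes", classes)

    def __len__(self) -> int:
        return len(self.strata)

    def __contains__(self, gene: str) -> bool:
        return gene in self.strata

    def age_of(self, gene: str) -> str:
        """UC/MC class of *gene*, or ``unknown`` when not in the table."""
        return self._classes.get(gene, UNKNOWN)

    @property
    def uc_genes(self) -> set[str]:
        return {g for g, c in self._classes.items() if c == UC}

    @property
    def mc_genes(self) -> set[str]:
        return {g for g, c in self._classes.items() if c == MC}

    def counts(self, genes: Iterable[str]) -> tuple[int, int]:
        """(UC, MC) counts among *genes*, ignoring unclassified genes."""
        uc = mc = 0
        for g in genes:
            c = self._classes.get(g)
            if c == UC:
                uc += 1
            elif c == MC:
                mc += 1
        return uc, mc

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.strata)
        return pd.DataFrame(
            {
                "gene": genes,
                "phylostratum": [self.strata[g] for g in genes],
                "age_class": [self._classes[g] for g in genes],
            }
        )


def load_phylostrata(path: str | Path) -> GeneAgeTable:
    """Read a two-column TSV (gene, phylostratum) into a :class:`GeneAgeTable`.

    Raises ``ValueError`` naming the offending row for out-of-range strata and
    for duplicated gene identifiers.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene, phylostratum)")
    genes = df.iloc[:, 0].astype(str)
    strata = pd.to_numeric(df.iloc[:, 1], errors="raise").astype(int)

    dups = genes[genes.duplicated()].unique()
    if len(dups):
        raise ValueError(f"{path}: duplicate gene id(s): {', '.join(dups[:5])}")
    bad = (strata < 1) | (strata > N_STRATA)
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"{path}: row {row + 2} ({genes.iloc[row]}): phylostratum "
            f"{strata.iloc[row]} outside 1..{N_STRATA}"
        )
    return GeneAgeTable(dict(zip(genes, strata)))


def write_phylostrata(table: GeneAgeTable, path: str | Path) -> None:
    """Write gene, phylostratum, and derived age_class as TSV."""
    table.to_frame().to_csv(path, sep="\t", index=False)
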