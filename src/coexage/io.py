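"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices are genes x samples TSV; the sample manifest, module
membership, mutation (MAF-like), segment (SEG-like), gene-coordinate
(BED-like), and driver tables are simple headered TSVs; gene sets use the
standard GMT layout (name, description, members, tab-separated).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .network import ExpressionMatrix, ModuleSet


def read_expression(path: str | Path, manifest: str | Path | None = None) -> ExpressionMatrix:
    sep = "," if str(path).endswith(".csv") else "\t"
    values = pd.read_csv(path, sep=sep, index_col=0)
    meta = read_manifest(manifest) if manifest is not None else None
    return ExpressionMatrix(values, meta)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_manifest(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str).set_index("sample")
    if "condition" not in meta.columns:
        raise ValueError(f"{path}: manifest needs a 'condition' column")
    return meta


def write_manifest(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_modules(path: str | Path, provenance: str = "") -> ModuleSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "module"} <= set(df.columns):
        raise ValueError(f"{path}: module table needs columns gene, module")
    return ModuleSet.from_membership(dict(zip(df["gene"], df["module"])), provenance)


def write_modules(modset: ModuleSet, path: str | Path) -> None:
    modset.to_frame(include_grey=True).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one gene set per line — name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: GMT line needs >= 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{line_no}: duplicate gene set {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_mutations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "patient", "consequence"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: mutation table needs columns {sorted(required)}")
    return df


def read_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"patient", "chrom", "start", "end", "state"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: segment table needs columns {sorted(required)}")
    return df


def read_gene_coords(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: gene coordinate table needs columns {sorted(required)}")
    return df


def read_drivers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "tumor_type"} <= set(df.columns):
        raise ValueError(f"{path}: driver table needs columns gene, tumor_type")
    return df


def write_cohort(cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write every table of a synthetic cohort in pipeline-ready formats."""
    from .gene_age import write_phylostrata

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "manifest": out / "manifest.tsv",
        "ages": out / "gene_ages.tsv",
        "mutations": out / "mutations.tsv",
        "segments": out / "cna_segments.tsv",
        "gene_coords": out / "gene_coords.tsv",
        "drivers": out / "drivers.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_manifest(cohort.expression.sample_meta, paths["manifest"])
    write_phylostrata(cohort.age_table, paths["ages"])
    cohort.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    cohort.cna_segments.to_csv(paths["segments"], sep="\t", index=False)
    cohort.gene_coords.to_csv(paths["gene_coords"], sep="\t", index=False)
    cohort.drivers.to_csv(paths["drivers"], sep="\t", index=False)
    return paths
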