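"""CSV schemas and validation for the package's tabular interchange formats.

All tables are plain UTF-8 CSVs with headers.  Enrichment values are
fractions in [0, 1] internally; the CLI offers a percent flag on
input/output.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "SchemaError",
    "ENRICHMENT_COLUMNS",
    "GENOTYPE_COLUMNS",
    "CD57_COLUMNS",
    "validate_enrichment",
    "read_enrichment",
    "write_enrichment",
    "read_genotypes",
    "write_genotypes",
]

ENRICHMENT_COLUMNS = ["individual_id", "compartment", "subset", "kir_class",
                      "time_days", "enrichment", "replicate"]
GENOTYPE_COLUMNS = ["individual_id", "kir2dl1", "kir2dl2", "kir2dl3",
                    "kir3dl1", "kir3dl2", "hla_alleles"]
CD57_COLUMNS = ["individual_id", "subset", "lineage", "fraction_cd57",
                "age", "cmv", "functional_count"]

COMPARTMENTS = {"saliva", "monocyte", "tcell"}
SUBSETS = {"Tcm", "Temra", "none"}
KIR_CLASSES = {"functional", "nonfunctional", "negative", "none"}


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


def validate_enrichment(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an enrichment time-series table, returning it unchanged."""
    missing = [c for c in ENRICHMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"enrichment table missing columns: {missing}")
    if df.empty:
        raise SchemaError("enrichment table is empty")
    bad = set(df["compartment"]) - COMPARTMENTS
    if bad:
        raise SchemaError(f"unknown compartments: {sorted(bad)}")
    bad = set(df["subset"]) - SUBSETS
    if bad:
        raise SchemaError(f"unknown subsets: {sorted(bad)}")
    bad = set(df["kir_class"]) - KIR_CLASSES
    if bad:
        raise SchemaError(f"unknown kir_class values: {sorted(bad)}")
    if (df["time_days"] < 0).any():
        raise SchemaError("negative time_days")
    if (df["enrichment"] < 0).any():
        raise SchemaError("negative enrichment")
    if (df["replicate"] < 1).any():
        raise SchemaError("replicate indices start at 1")
    non_t = df[df["compartment"] != "tcell"]
    if ((non_t["subset"] != "none") | (non_t["kir_class"] != "none")).any():
        raise SchemaError(
            "subset/kir_class must be 'none' outside the tcell compartment")
    return df


def read_enrichment(path: str | Path, percent: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path)
    if percent and "enrichment" in df.columns:
        df["enrichment"] = df["enrichment"] / 100.0
    return validate_enrichment(df)


def write_enrichment(df: pd.DataFrame, path: str | Path,
                     percent: bool = False) -> None:
    validate_enrichment(df)
    out = df.copy()
    if percent:
        out["enrichment"] = out["enrichment"] * 100.0
    out.to_csv(path, index=False)


def read_genotypes(path: str | Path):
    """Read a genotype CSV into a list of :class:`~ikirspan.genotype.Genotype`."""
    from .genotype import Genotype

    df = pd.read_csv(path)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"genotype table missing columns: {missing}")
    genotypes = []
    for _, row in df.iterrows():
        kir = {gene.upper()
               for gene in ("kir2dl1", "kir2dl2", "kir2dl3", "kir3dl1",
                            "kir3dl2")
               if int(row[gene]) == 1}
        alleles = tuple(a for a in str(row["hla_alleles"]).split(";") if a)
        genotypes.append(Genotype.make(str(row["individual_id"]), kir, alleles))
    return genotypes


def write_genotypes(genotypes, path: str | Path) -> None:
    rows = []
    for g in genotypes:
        rows.append({
            "individual_id": g.individual_id,
            **{gene.lower(): int(gene in g.kir_present)
               for gene in ("KIR2DL1", "KIR2DL2", "KIR2DL3", "KIR3DL1",
                            "KIR3DL2")},
            "hla_alleles": ";".join(g.hla_alleles),
        })
    pd.DataFrame(rows, columns=GENOTYPE_COLUMNS).to_csv(path, index=False)
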