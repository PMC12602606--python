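"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are plain TSV, UTF-8, no quoting. Genomic
coordinates are 1-based inclusive throughout (array-manifest
convention). Missing methylation values are encoded as ``NA``; counts
may not be missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PROMOTER_STATES = frozenset({"active_promoter", "weak_promoter"})
CHROMATIN_STATES = (
    "active_promoter",
    "weak_promoter",
    "enhancer",
    "lowly_methylated",
    "heterochromatin",
    "other",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# probe manifest


def validate_manifest(manifest: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    required = ["probe_id", "chrom", "pos", "state"]
    missing = [c for c in required if c not in manifest.columns]
    if missing:
        raise FormatError(f"manifest missing columns: {missing}")
    if "gene" not in manifest.columns:
        manifest = manifest.assign(gene=np.nan)
    dup = manifest["probe_id"].duplicated()
    if dup.any():
        raise FormatError(
            f"duplicate probe ids, e.g. {manifest.loc[dup, 'probe_id'].iloc[0]!r}"
        )
    if (manifest["pos"] < 1).any():
        bad = manifest.loc[manifest["pos"] < 1, "probe_id"].iloc[0]
        raise FormatError(f"probe {bad!r} has position < 1 (coordinates are 1-based)")
    is_prom = manifest["state"].isin(PROMOTER_STATES)
    has_gene = manifest["gene"].notna() & (manifest["gene"].astype(str) != "")
    if strict:
        bad = is_prom & ~has_gene
        if bad.any():
            raise FormatError(
                f"promoter probe without gene link: "
                f"{manifest.loc[bad, 'probe_id'].iloc[0]!r}"
            )
        bad = has_gene & ~is_prom
        if bad.any():
            raise FormatError(
                f"non-promoter probe with gene link: "
                f"{manifest.loc[bad, 'probe_id'].iloc[0]!r}"
            )
    return manifest


def read_manifest(path, strict: bool = True) -> pd.DataFrame:
    """Read a BED-like probe manifest TSV.

    Columns: probe_id, chrom, pos (1-based), state, gene (optional,
    required non-empty exactly for active/weak promoter probes).
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str,
                                            "state": str, "gene": str})
    df["pos"] = df["pos"].astype(int)
    return validate_manifest(df, strict=strict)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    out = manifest.copy()
    out["gene"] = out["gene"].fillna("")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# matrices


def read_matrix(path, kind: str, strict: bool = True) -> pd.DataFrame:
    """Read a features x samples TSV matrix.

    Parameters
    ----------
    path : path-like
        TSV with a header row of sample ids; first column holds feature
        ids.
    kind : {"beta", "counts", "expr"}
        ``beta`` values are validated to lie in [0, 1] (``NA`` allowed);
        ``counts`` must be non-negative integers with no missing
        entries; ``expr`` is any finite float matrix.
    strict : bool
        When False, out-of-range beta values are clipped with a warning
        instead of raising.
    """
    if kind not in {"beta", "counts", "expr"}:
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False)
    df.index = df.index.astype(str)
    dup = df.index.duplicated()
    if dup.any():
        raise FormatError(f"duplicate feature id {df.index[dup][0]!r}")
    dupc = df.columns.duplicated()
    if dupc.any():
        raise FormatError(f"duplicate sample id {df.columns[dupc][0]!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric entry in matrix: {exc}") from exc
    if kind == "beta":
        bad = (values < 0) | (values > 1)
        if np.nansum(bad):
            row = df.index[np.where(np.nan_to_num(bad))[0][0]]
            msg = f"beta value outside [0, 1] in row {row!r}"
            if strict:
                raise FormatError(msg)
            warnings.warn(msg + "; clipping")
            values = np.clip(values, 0.0, 1.0)
        return pd.DataFrame(values, index=df.index, columns=df.columns)
    if kind == "counts":
        if np.isnan(values).any():
            row = df.index[np.where(np.isnan(values).any(axis=1))[0][0]]
            raise FormatError(f"missing count in row {row!r}")
        if (values < 0).any():
            row = df.index[np.where((values < 0).any(axis=1))[0][0]]
            raise FormatError(f"negative count in row {row!r}")
        if not np.array_equal(values, np.round(values)):
            row = df.index[np.where((values != np.round(values)).any(axis=1))[0][0]]
            raise FormatError(f"fractional count in row {row!r}")
        return pd.DataFrame(values.astype(np.int64), index=df.index,
                            columns=df.columns)
    if not np.isfinite(values[~np.isnan(values)]).all():
        raise FormatError("non-finite expression value")
    return pd.DataFrame(values, index=df.index, columns=df.columns)


def write_matrix(matrix: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a matrix TSV; floats at stated precision, missing as NA."""
    if pd.api.types.is_integer_dtype(matrix.dtypes.iloc[0]):
        matrix.to_csv(path, sep="\t", na_rep="NA", lineterminator="\n")
    else:
        matrix.to_csv(path, sep="\t", na_rep="NA", float_format=float_format,
                      lineterminator="\n")


# ---------------------------------------------------------------------------
# sample sheet

SHEET_COLUMNS = [
    "sample_id", "batch", "epigenetic_subtype", "transcriptomic_subtype",
    "menin_lost", "daxx_atrx_lost", "grade", "alt_status", "cna_status",
    "functional_status", "tumor_size_cm", "dfs_time", "dfs_event",
]


def read_sample_sheet(path, strict: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("sample sheet missing sample_id column")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in sample sheet")
    if "dfs_event" in df.columns:
        ev = df["dfs_event"].dropna()
        if not ev.isin([0, 1]).all():
            raise FormatError("dfs_event must be 0/1")
    if strict and "tumor_size_cm" in df.columns:
        sz = pd.to_numeric(df["tumor_size_cm"], errors="coerce")
        if (sz.dropna() <= 0).any():
            raise FormatError("tumor_size_cm must be positive when present")
    for col in ("menin_lost", "daxx_atrx_lost"):
        if col in df.columns and df[col].dtype != bool:
            df[col] = df[col].map(
                {"True": True, "False": False, True: True, False: False, 1: True, 0: False}
            )
    return df.set_index("sample_id", drop=False)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets: ``sets[name] = (description, tuple of gene ids)``."""

    sets: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, name: str) -> tuple:
        return self.sets[name][1]

    def add(self, name: str, description: str, genes) -> None:
        genes = list(genes)
        seen, uniq = set(), []
        for g in genes:
            if g not in seen:
                seen.add(g)
                uniq.append(g)
        if len(uniq) < len(genes):
            warnings.warn(f"gene set {name!r}: duplicate members deduplicated")
        if not uniq:
            raise FormatError(f"gene set {name!r} is empty")
        self.sets[name] = (description, tuple(uniq))


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, member genes, tab-separated)."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            coll.add(fields[0], fields[1], [f for f in fields[2:] if f])
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, genes) in coll.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# sample alignment


def align_omics(beta: pd.DataFrame, counts: pd.DataFrame, sheet: pd.DataFrame):
    """Restrict the three tables to shared samples, identically ordered.

    Returns ``(beta, counts, sheet, dropped)`` where ``dropped`` maps
    table name to the sorted list of sample ids present only there.
    Mirrors the restriction to samples with both methylome and
    transcriptome data.
    """
    sets = {
        "beta": set(beta.columns),
        "counts": set(counts.columns),
        "sheet": set(sheet.index),
    }
    shared = sets["beta"] & sets["counts"] & sets["sheet"]
    if len(shared) < 2:
        raise ValueError(
            f"need >=2 shared samples across omics tables, got {len(shared)}"
        )
    # preserve the sample-sheet order for determinism
    order = [s for s in sheet.index if s in shared]
    dropped = {name: sorted(ids - shared) for name, ids in sets.items()}
    if any(dropped.values()):
        total = sum(len(v) for v in dropped.values())
        warnings.warn(f"align_omics dropped {total} table-specific samples")
    return beta[order], counts[order], sheet.loc[order], dropped
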