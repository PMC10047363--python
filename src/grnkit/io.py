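"""Tabular and genomic-interval formats used across the pipeline.

All files are UTF-8, tab-delimited, with ``.`` for missing values and ``#``
for comment lines. Genomic intervals follow the BED convention: 0-based,
half-open. Gene identifiers are opaque, case-sensitive strings; no symbol
normalization is attempted.

Every reader validates on construction — an invalid file never yields a
partially constructed object — and every reader is the left inverse of the
corresponding writer on valid objects (identifiers bit-identical, numeric
values to at least 6 decimals).
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "Network",
    "DifferentialTable",
    "AccessibilityTable",
    "TssTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_edge_list",
    "write_edge_list",
    "read_differential_table",
    "write_differential_table",
    "read_peak_table",
    "write_peak_table",
    "read_tss_table",
    "write_tss_table",
    "read_gene_sets",
    "write_gene_sets",
]

MISSING = "."
VALID_SIGNS = (-1, 0, 1)
VALID_PROVENANCE = frozenset({"inferred", "prior"})
VALID_CALLS = ("up", "down", "unchanged")

#: number of decimals guaranteed by the writers
FLOAT_DECIMALS = 6
_FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Raised when an input file violates a format or invariant contract."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

META_COLUMNS = ("timepoint", "condition", "replicate")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × samples expression values with per-sample design metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. All values
        must be finite.
    sample_meta
        DataFrame indexed by sample id with columns ``timepoint``,
        ``condition`` and ``replicate`` (integer ≥ 1). Every sample column of
        ``values`` must have a metadata row.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        values, meta = self.values, self.sample_meta
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        arr = values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if arr.size and not np.isfinite(arr).all():
            raise FormatError("expression values must be finite")
        missing = [s for s in values.columns if s not in meta.index]
        if missing:
            raise FormatError(f"samples missing from metadata: {missing}")
        for col in META_COLUMNS:
            if col not in meta.columns:
                raise FormatError(f"sample metadata lacks column {col!r}")
        if meta.index.duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        reps = meta.loc[list(values.columns), "replicate"]
        if (reps.astype(int) < 1).any():
            raise FormatError("replicate numbers must be ≥ 1")
        # keep metadata aligned to the matrix column order
        object.__setattr__(
            self, "sample_meta", meta.loc[list(values.columns)].copy()
        )

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a matrix restricted to ``sample_ids`` (order preserved)."""
        sample_ids = list(sample_ids)
        absent = [s for s in sample_ids if s not in self.values.columns]
        if absent:
            raise KeyError(f"unknown samples: {absent}")
        return ExpressionMatrix(
            self.values[sample_ids].copy(), self.sample_meta.loc[sample_ids].copy()
        )

    def samples_where(
        self, timepoint: str | None = None, condition: str | None = None
    ) -> list[str]:
        """Sample ids matching a (timepoint, condition) restriction."""
        meta = self.sample_meta
        mask = pd.Series(True, index=meta.index)
        if timepoint is not None:
            mask &= meta["timepoint"] == timepoint
        if condition is not None:
            mask &= meta["condition"] == condition
        return list(meta.index[mask])


def concat_expression(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate matrices over an identical gene index."""
    if not matrices:
        raise ValueError("no matrices to concatenate")
    genes = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != genes:
            raise FormatError("matrices have differing gene indices")
    values = pd.concat([m.values for m in matrices], axis=1)
    meta = pd.concat([m.sample_meta for m in matrices], axis=0)
    return ExpressionMatrix(values, meta)


def _non_comment_lines(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]


def read_expression_matrix(path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read a genes × samples TSV plus a sample-metadata TSV.

    The matrix file has a header row of sample ids with the gene-id column
    first; the metadata file is keyed by sample id with columns
    ``timepoint``, ``condition``, ``replicate``.
    """
    lines = _non_comment_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    raw = pd.read_csv(
        _io.StringIO("\n".join(lines)), sep="\t", index_col=0, dtype=str
    )
    raw.index = raw.index.astype(str)
    raw.columns = [str(c) for c in raw.columns]
    numeric = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric value in row {gene!r}, column {col!r}"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise FormatError(f"{path}: missing value in row {gene!r}, column {col!r}")
        numeric[col] = converted
    values = pd.DataFrame(numeric, index=raw.index)[raw.columns]
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, comment="#")
    meta.index = meta.index.astype(str)
    return ExpressionMatrix(values, meta)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    meta_path: str | Path,
    header_comment: str | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        matrix.values.to_csv(
            fh, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT,
            lineterminator="\n",
        )
    with open(meta_path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        matrix.sample_meta.to_csv(
            fh, sep="\t", index_label="sample_id", lineterminator="\n"
        )


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ("regulator", "target", "weight", "sign", "support", "provenance")


@dataclass(frozen=True)
class Network:
    """Directed, weighted, signed edge set with provenance and support.

    ``edges`` holds one row per (regulator, target) pair with columns
    ``regulator``, ``target``, ``weight`` (≥ 0 importance), ``sign``
    (+1 activation, −1 repression, 0 unknown), ``support`` (bootstrap
    fraction in [0, 1], NaN when not applicable), and ``provenance``
    (frozenset ⊆ {"inferred", "prior"}).

    ``extra_nodes`` carries nodes with no incident edges (pruning can leave
    isolated survivors).
    """

    edges: pd.DataFrame
    extra_nodes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        edges = self.edges.copy()
        if "regulator" not in edges.columns or "target" not in edges.columns:
            raise FormatError("edge table needs 'regulator' and 'target' columns")
        if "weight" not in edges.columns:
            edges["weight"] = 0.0
        if "sign" not in edges.columns:
            edges["sign"] = 0
        if "support" not in edges.columns:
            edges["support"] = np.nan
        if "provenance" not in edges.columns:
            edges["provenance"] = [frozenset() for _ in range(len(edges))]
        edges = edges[list(EDGE_COLUMNS)].reset_index(drop=True)
        edges["regulator"] = edges["regulator"].astype(str)
        edges["target"] = edges["target"].astype(str)
        edges["weight"] = edges["weight"].astype(float)
        edges["sign"] = edges["sign"].astype(int)
        edges["support"] = edges["support"].astype(float)
        if len(edges):
            if (edges["regulator"] == edges["target"]).any():
                bad = edges.loc[edges["regulator"] == edges["target"], "regulator"]
                raise FormatError(f"self-edges not allowed: {sorted(set(bad))}")
            if edges.duplicated(["regulator", "target"]).any():
                dup = edges.loc[
                    edges.duplicated(["regulator", "target"]), ["regulator", "target"]
                ]
                raise FormatError(
                    f"duplicate edges: {[tuple(r) for r in dup.to_numpy()][:5]}"
                )
            if not np.isfinite(edges["weight"]).all():
                raise FormatError("edge weights must be finite")
            if (edges["weight"] < 0).any():
                raise FormatError("edge weights must be ≥ 0")
            if not edges["sign"].isin(VALID_SIGNS).all():
                raise FormatError("edge signs must be in {-1, 0, 1}")
            sup = edges["support"].to_numpy()
            ok = np.isnan(sup) | ((sup >= 0) & (sup <= 1))
            if not ok.all():
                raise FormatError("edge support must lie in [0, 1]")
            for p in edges["provenance"]:
                if not isinstance(p, frozenset) or not p <= VALID_PROVENANCE:
                    raise FormatError(f"invalid provenance {p!r}")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "extra_nodes", tuple(str(n) for n in self.extra_nodes))

    @classmethod
    def from_records(
        cls, records: Iterable[Mapping], extra_nodes: Sequence[str] = ()
    ) -> "Network":
        rows = list(records)
        if rows:
            edges = pd.DataFrame(rows)
        else:
            edges = pd.DataFrame(
                {c: pd.Series(dtype=object) for c in ("regulator", "target")}
            )
        return cls(edges, tuple(extra_nodes))

    @classmethod
    def empty(cls) -> "Network":
        return cls.from_records([])

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_set(self) -> set[str]:
        return (
            set(self.edges["regulator"])
            | set(self.edges["target"])
            | set(self.extra_nodes)
        )

    def edge_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))

    def sign_map(self) -> dict[tuple[str, str], int]:
        return dict(
            zip(zip(self.edges["regulator"], self.edges["target"]), self.edges["sign"])
        )

    def sorted_edges(self) -> pd.DataFrame:
        return self.edges.sort_values(["regulator", "target"]).reset_index(drop=True)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.node_set()))
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.regulator, row.target, weight=row.weight, sign=row.sign
            )
        return g


_SIGN_TOKENS = {
    "+": 1, "-": -1, "+1": 1, "-1": -1, "0": 0, "1": 1,
}


def _parse_sign(token: str, path) -> int:
    token = str(token).strip()
    if token == MISSING:
        return 0
    if token not in _SIGN_TOKENS:
        raise FormatError(f"{path}: invalid sign {token!r}")
    return _SIGN_TOKENS[token]


def read_edge_list(path: str | Path) -> Network:
    """Read a regulator/target TSV edge list.

    Columns ``regulator`` and ``target`` are required; ``sign``, ``weight``,
    ``support`` and ``provenance`` are optional (defaults 0, 0, NaN, ∅).
    Duplicate (regulator, target) rows are a hard error — a curated prior
    with conflicting duplicate signs must be resolved upstream.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "regulator" not in df.columns or "target" not in df.columns:
        raise FormatError(f"{path}: needs 'regulator' and 'target' columns")
    records = []
    for row in df.itertuples(index=False):
        rec: dict = {"regulator": row.regulator, "target": row.target}
        rec["sign"] = _parse_sign(getattr(row, "sign", MISSING), path)
        weight = getattr(row, "weight", MISSING)
        rec["weight"] = 0.0 if str(weight) == MISSING else float(weight)
        support = getattr(row, "support", MISSING)
        rec["support"] = math.nan if str(support) == MISSING else float(support)
        prov = str(getattr(row, "provenance", MISSING))
        rec["provenance"] = (
            frozenset() if prov == MISSING else frozenset(prov.split(","))
        )
        records.append(rec)
    return Network.from_records(records)


def write_edge_list(
    network: Network, path: str | Path, header_comment: str | None = None
) -> None:
    df = network.sorted_edges().copy()
    df["sign"] = df["sign"].map(lambda s: f"{s:+d}" if s else "0")
    df["weight"] = df["weight"].map(lambda w: f"{w:.6f}")
    df["support"] = df["support"].map(
        lambda s: MISSING if pd.isna(s) else f"{s:.6f}"
    )
    df["provenance"] = df["provenance"].map(
        lambda p: ",".join(sorted(p)) if p else MISSING
    )
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# differential tables
# ---------------------------------------------------------------------------


def _de_call(log2fc: float, padj: float, alpha: float) -> str:
    if padj < alpha and log2fc > 0:
        return "up"
    if padj < alpha and log2fc < 0:
        return "down"
    return "unchanged"


@dataclass(frozen=True)
class DifferentialTable:
    """Per-gene log2 fold change, p, adjusted p, and a discrete call.

    The call is derived once, at construction, from ``padj`` and ``log2fc``
    at the significance level ``alpha`` carried in the table header:
    up iff padj < alpha and log2fc > 0; down iff padj < alpha and
    log2fc < 0; unchanged otherwise. Downstream consumers never
    re-threshold.
    """

    table: pd.DataFrame  # index gene_id; columns log2fc, pvalue, padj, call
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise FormatError(f"alpha must be in (0,1), got {self.alpha}")
        tbl = self.table.copy()
        for col in ("log2fc", "pvalue", "padj"):
            if col not in tbl.columns:
                raise FormatError(f"differential table lacks column {col!r}")
            tbl[col] = tbl[col].astype(float)
        if tbl.index.duplicated().any():
            raise FormatError("duplicate gene ids in differential table")
        for col in ("pvalue", "padj"):
            vals = tbl[col].to_numpy()
            if ((vals < 0) | (vals > 1)).any() or np.isnan(vals).any():
                raise FormatError(f"{col} values must lie in [0, 1]")
        if not np.isfinite(tbl["log2fc"]).all():
            raise FormatError("log2fc values must be finite")
        tbl["call"] = [
            _de_call(l, q, self.alpha) for l, q in zip(tbl["log2fc"], tbl["padj"])
        ]
        tbl.index = tbl.index.astype(str)
        object.__setattr__(self, "table", tbl)

    @classmethod
    def from_stats(
        cls,
        gene_ids: Sequence[str],
        log2fc: Sequence[float],
        pvalue: Sequence[float],
        padj: Sequence[float],
        alpha: float = 0.05,
    ) -> "DifferentialTable":
        tbl = pd.DataFrame(
            {"log2fc": log2fc, "pvalue": pvalue, "padj": padj},
            index=pd.Index([str(g) for g in gene_ids], name="gene_id"),
        )
        return cls(tbl, alpha)

    def calls(self) -> dict[str, str]:
        return dict(zip(self.table.index, self.table["call"]))

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index)


def read_differential_table(path: str | Path) -> DifferentialTable:
    """Read a differential table; ``alpha`` comes from a ``# alpha:`` header
    comment (default 0.05). The discrete call is recomputed at read time."""
    alpha = 0.05
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.startswith("alpha"):
                    alpha = float(stripped.split(":", 1)[1].strip())
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return DifferentialTable(df[["log2fc", "pvalue", "padj"]], alpha)


def write_differential_table(
    table: DifferentialTable, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f"# alpha: {table.alpha:g}\n")
        table.table.to_csv(
            fh, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT,
            lineterminator="\n",
        )


# ---------------------------------------------------------------------------
# accessibility peaks and TSS tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AccessibilityTable:
    """Differential accessibility peaks (BED-derived, 0-based half-open).

    Columns: ``peak_id``, ``chrom``, ``start``, ``end``, ``log2fc``, ``fdr``,
    and after promoter assignment ``assigned_gene`` (None when unassigned)
    and ``tss_distance`` (signed bp, negative = upstream of the TSS on the
    gene's strand).
    """

    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.peaks.copy().reset_index(drop=True)
        required = ("peak_id", "chrom", "start", "end", "log2fc", "fdr")
        for col in required:
            if col not in df.columns:
                raise FormatError(f"peak table lacks column {col!r}")
        if "assigned_gene" not in df.columns:
            df["assigned_gene"] = None
        if "tss_distance" not in df.columns:
            df["tss_distance"] = np.nan
        df["peak_id"] = df["peak_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["log2fc"] = df["log2fc"].astype(float)
        df["fdr"] = df["fdr"].astype(float)
        df["tss_distance"] = df["tss_distance"].astype(float)
        df["assigned_gene"] = [
            None if (g is None or (isinstance(g, float) and math.isnan(g)) or g == MISSING)
            else str(g)
            for g in df["assigned_gene"]
        ]
        df = df[
            [
                "peak_id", "chrom", "start", "end", "log2fc", "fdr",
                "assigned_gene", "tss_distance",
            ]
        ]
        if df["peak_id"].duplicated().any():
            raise FormatError("duplicate peak ids")
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "peak_id"].tolist()
            raise FormatError(f"peaks with start ≥ end: {bad}")
        if ((df["fdr"] < 0) | (df["fdr"] > 1)).any() or df["fdr"].isna().any():
            raise FormatError("peak fdr values must lie in [0, 1]")
        if not np.isfinite(df["log2fc"]).all():
            raise FormatError("peak log2fc values must be finite")
        object.__setattr__(self, "peaks", df)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def assigned(self) -> pd.DataFrame:
        return self.peaks[self.peaks["assigned_gene"].notna()]


@dataclass(frozen=True)
class TssTable:
    """One transcription start site per gene: chrom, strand, 0-based position."""

    table: pd.DataFrame  # index gene_id; columns chrom, strand, tss

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("chrom", "strand", "tss"):
            if col not in df.columns:
                raise FormatError(f"TSS table lacks column {col!r}")
        if df.index.duplicated().any():
            raise FormatError("duplicate gene ids in TSS table")
        if not df["strand"].isin(["+", "-"]).all():
            raise FormatError("TSS strand must be '+' or '-'")
        df.index = df.index.astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["tss"] = df["tss"].astype(int)
        object.__setattr__(self, "table", df)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index)


PEAK_COLUMNS = ("chrom", "start", "end", "peak_id", "log2fc", "fdr")


def read_peak_table(path: str | Path) -> AccessibilityTable:
    """Read a BED 3+3 dialect peak file (no header): chrom, start, end,
    peak_id, log2fc, fdr, with optional assigned_gene and tss_distance."""
    rows = []
    for i, line in enumerate(_non_comment_lines(path)):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) not in (6, 8):
            raise FormatError(f"{path}: line {i + 1} has {len(parts)} fields, need 6 or 8")
        rec = {
            "chrom": parts[0],
            "start": int(parts[1]),
            "end": int(parts[2]),
            "peak_id": parts[3],
            "log2fc": float(parts[4]),
            "fdr": float(parts[5]),
        }
        if len(parts) == 8:
            rec["assigned_gene"] = None if parts[6] == MISSING else parts[6]
            rec["tss_distance"] = math.nan if parts[7] == MISSING else float(parts[7])
        rows.append(rec)
    df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=list(PEAK_COLUMNS))
    return AccessibilityTable(df)


def write_peak_table(
    table: AccessibilityTable, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for row in table.peaks.itertuples(index=False):
            fields = [
                row.chrom, str(row.start), str(row.end), row.peak_id,
                _FLOAT_FMT % row.log2fc, _FLOAT_FMT % row.fdr,
            ]
            if row.assigned_gene is not None or not math.isnan(row.tss_distance):
                fields.append(MISSING if row.assigned_gene is None else row.assigned_gene)
                fields.append(
                    MISSING if math.isnan(row.tss_distance) else str(int(row.tss_distance))
                )
            fh.write("\t".join(fields) + "\n")


def read_tss_table(path: str | Path) -> TssTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return TssTable(df[["chrom", "strand", "tss"]])


def write_tss_table(
    table: TssTable, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.table.to_csv(fh, sep="\t", index_label="gene_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# gene sets (for over-representation analysis)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (set_id, gene) TSV into {set_id: members}."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "set_id" not in df.columns or "gene" not in df.columns:
        raise FormatError(f"{path}: needs 'set_id' and 'gene' columns")
    sets: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        sets.setdefault(row.set_id, set()).add(row.gene)
    return sets


def write_gene_sets(
    gene_sets: Mapping[str, Iterable[str]], path: str | Path,
    header_comment: str | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("set_id\tgene\n")
        for set_id in sorted(gene_sets):
            for gene in sorted(set(gene_sets[set_id])):
                fh.write(f"{set_id}\t{gene}\n")
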