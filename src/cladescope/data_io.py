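"""Readers and writers for the external table formats.

All tabular inputs are parsed into plain dataclasses or pandas frames:

* Orthogroup membership tables in the OrthoFinder ``Orthogroups.tsv``
  dialect (tab-separated, genes within a cell separated by ``", "``).
* Per-cluster marker tables in the Seurat ``FindAllMarkers`` dialect.
* Gene positions from GFF3 (``gene`` features, 1-based closed) or BED
  (0-based half-open); internally every interval is 0-based half-open.
* Gene-family count tables in the CAFE tab dialect, optionally carrying
  extra columns with precomputed ancestral counts for internal nodes.

Writers emit tab-separated text with a comment header carrying the tool
version and, when supplied, a config hash and seed, so outputs from
different runs are distinguishable.  Readers skip ``#`` comment lines, so
write -> read is the identity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .trees import SpeciesTree, read_tree_and_clades  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ["gene", "cluster", "avg_log2FC", "p_val_adj", "pct_in", "pct_out"]

#: default mapping from Seurat's FindAllMarkers output columns
SEURAT_COLUMN_MAP = {
    "gene": "gene",
    "cluster": "cluster",
    "avg_log2FC": "avg_log2FC",
    "p_val_adj": "p_val_adj",
    "pct.1": "pct_in",
    "pct.2": "pct_out",
}


class FormatError(ValueError):
    """Malformed input file."""


def _header_lines(meta: Optional[Mapping[str, str]] = None) -> str:
    parts = [f"tool=cladescope/{__version__}"]
    for key, value in (meta or {}).items():
        parts.append(f"{key}={value}")
    return "# " + " ".join(parts) + "\n"


# ---------------------------------------------------------------------------
# Orthogroup tables
# ---------------------------------------------------------------------------

@dataclass
class OrthogroupTable:
    """Orthogroup membership: orthogroup -> species -> gene list.

    ``species_order`` fixes the column order; gene lists may be empty.
    Every gene identifier belongs to at most one orthogroup.
    """

    og_ids: list[str]
    membership: dict[str, dict[str, list[str]]]
    species_order: list[str]

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        if len(set(self.og_ids)) != len(self.og_ids):
            dupes = sorted({o for o in self.og_ids if self.og_ids.count(o) > 1})
            raise FormatError(f"duplicate orthogroup ids: {dupes}")
        known = set(self.species_order)
        seen_genes: dict[str, str] = {}
        for og in self.og_ids:
            for sp, genes in self.membership[og].items():
                if sp not in known:
                    raise FormatError(
                        f"species {sp!r} in orthogroup {og} missing from header"
                    )
                for g in genes:
                    if g in seen_genes:
                        raise FormatError(
                            f"gene {g!r} appears in orthogroups "
                            f"{seen_genes[g]} and {og}"
                        )
                    seen_genes[g] = og

    def __len__(self) -> int:
        return len(self.og_ids)

    def genes_of(self, og_id: str, species: str) -> list[str]:
        return self.membership[og_id].get(species, [])

    def possessors(self, og_id: str) -> frozenset[str]:
        """Species with at least one gene in the orthogroup."""
        return frozenset(
            sp for sp, genes in self.membership[og_id].items() if genes
        )

    def n_genes(self, og_id: str) -> int:
        return sum(len(g) for g in self.membership[og_id].values())

    def species_genes(self, species: str) -> list[str]:
        """All genes of one species across every orthogroup, in table order."""
        out: list[str] = []
        for og in self.og_ids:
            out.extend(self.membership[og].get(species, []))
        return out

    def gene_to_og(self) -> dict[str, str]:
        mapping: dict[str, str] = {}
        for og in self.og_ids:
            for genes in self.membership[og].values():
                for g in genes:
                    mapping[g] = og
        return mapping

    def counts_frame(self) -> pd.DataFrame:
        """Gene counts as an orthogroup x species integer frame."""
        data = {
            sp: [len(self.membership[og].get(sp, ())) for og in self.og_ids]
            for sp in self.species_order
        }
        return pd.DataFrame(data, index=pd.Index(self.og_ids, name="og_id"))


def read_orthogroups(path, dialect: str = "orthofinder-tsv",
                     isoform_strip: Optional[str] = None) -> OrthogroupTable:
    """Parse an OrthoFinder-style ``Orthogroups.tsv`` file.

    ``isoform_strip`` is an optional regex removed from the end of every
    gene identifier (e.g. ``r"\\.t\\d+$"`` for transcript suffixes); off by
    default since splice-filtered proteomes already have one entry per
    gene.
    """
    if dialect != "orthofinder-tsv":
        raise ValueError(f"unknown orthogroup dialect {dialect!r}")
    strip_re = re.compile(isoform_strip) if isoform_strip else None
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    species = header[1:]
    og_ids: list[str] = []
    membership: dict[str, dict[str, list[str]]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        og = cells[0].strip()
        row: dict[str, list[str]] = {}
        for sp, cell in zip(species, cells[1:]):
            genes = [g.strip() for g in cell.split(",")] if cell.strip() else []
            if strip_re is not None:
                genes = [strip_re.sub("", g) for g in genes]
            row[sp] = [g for g in genes if g]
        membership[og] = row
        og_ids.append(og)
    return OrthogroupTable(og_ids=og_ids, membership=membership,
                           species_order=list(species))


def write_orthogroups(table: OrthogroupTable, path,
                      meta: Optional[Mapping[str, str]] = None) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(_header_lines(meta))
        fh.write("\t".join(["Orthogroup", *table.species_order]) + "\n")
        for og in table.og_ids:
            cells = [", ".join(table.membership[og].get(sp, []))
                     for sp in table.species_order]
            fh.write("\t".join([og, *cells]) + "\n")


# ---------------------------------------------------------------------------
# Marker tables
# ---------------------------------------------------------------------------

def read_markers(path, column_map: Optional[Mapping[str, str]] = None,
                 sep: Optional[str] = None) -> pd.DataFrame:
    """Read a per-cluster marker table (Seurat FindAllMarkers dialect).

    ``column_map`` maps input column names to the internal schema
    (:data:`MARKER_COLUMNS`); the default accepts Seurat's ``pct.1`` /
    ``pct.2`` names.  Rows with unparseable numerics are dropped with a
    logged count; duplicate (gene, cluster) pairs are a hard error.
    """
    column_map = dict(column_map or SEURAT_COLUMN_MAP)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    df = df.rename(columns=column_map)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    df = df[MARKER_COLUMNS].copy()
    n_in = len(df)
    for col in ("avg_log2FC", "p_val_adj", "pct_in", "pct_out"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["cluster"] = df["cluster"].astype(str)
    df = df.dropna()
    n_dropped = n_in - len(df)
    if n_dropped:
        logger.info("read_markers: dropped %d row(s) with unparseable numerics",
                    n_dropped)
    dup = df.duplicated(subset=["gene", "cluster"])
    if dup.any():
        pairs = df.loc[dup, ["gene", "cluster"]].itertuples(index=False)
        raise FormatError(
            "duplicate (gene, cluster) rows: "
            + ", ".join(f"({g}, {c})" for g, c in list(pairs)[:5])
        )
    bad = df[(df["p_val_adj"] < 0) | (df["p_val_adj"] > 1)
             | (df["pct_in"] < 0) | (df["pct_in"] > 1)
             | (df["pct_out"] < 0) | (df["pct_out"] > 1)]
    if len(bad):
        raise FormatError(f"{path}: p_val_adj/pct values outside [0, 1]")
    return df.reset_index(drop=True)


def write_markers(markers: pd.DataFrame, path,
                  meta: Optional[Mapping[str, str]] = None) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(_header_lines(meta))
        markers.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# Gene positions
# ---------------------------------------------------------------------------

POSITION_COLUMNS = ["species", "gene", "scaffold", "start", "end", "strand"]


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_positions(path, format: str, species: str) -> pd.DataFrame:
    """Read gene coordinates from GFF3 or BED into 0-based half-open form.

    GFF3 rows of type ``gene`` are used, identified by their ``ID``
    attribute; 1-based closed coordinates are shifted to 0-based half-open.
    BED (4+ columns, gene name in column 4) is taken as-is.  Rows whose
    interval is empty after conversion are rejected with a logged count.
    """
    rows: list[tuple] = []
    rejected = 0
    if format == "gff3":
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                cells = line.rstrip("\n").split("\t")
                if len(cells) < 9 or cells[2] != "gene":
                    continue
                attrs = _parse_gff_attributes(cells[8])
                gene = attrs.get("ID")
                if gene is None:
                    raise FormatError(f"{path}: gene feature without ID attribute")
                start = int(cells[3]) - 1
                end = int(cells[4])
                strand = cells[6] if cells[6] in "+-" else "."
                if start >= end:
                    rejected += 1
                    continue
                rows.append((species, gene, cells[0], start, end, strand))
    elif format == "bed":
        with open(path) as fh:
            for line in fh:
                if line.startswith(("#", "track", "browser")) or not line.strip():
                    continue
                cells = line.split()
                if len(cells) < 4:
                    raise FormatError(f"{path}: BED needs >= 4 columns")
                start, end = int(cells[1]), int(cells[2])
                strand = cells[5] if len(cells) > 5 and cells[5] in "+-" else "."
                if start >= end:
                    rejected += 1
                    continue
                rows.append((species, cells[3], cells[0], start, end, strand))
    else:
        raise ValueError(f"unknown gene-position format {format!r}")
    if rejected:
        logger.info("read_gene_positions: rejected %d empty interval(s)", rejected)
    df = pd.DataFrame(rows, columns=POSITION_COLUMNS)
    if df.duplicated(subset=["species", "gene"]).any():
        raise FormatError(f"{path}: duplicate (species, gene) entries")
    return df


def write_gene_positions_gff3(positions: pd.DataFrame, path,
                              meta: Optional[Mapping[str, str]] = None) -> None:
    """Export a position table as GFF3 (converting back to 1-based closed)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_header_lines(meta))
        for row in positions.itertuples(index=False):
            fh.write(
                f"{row.scaffold}\tcladescope\tgene\t{row.start + 1}\t{row.end}\t"
                f".\t{row.strand}\t.\tID={row.gene}\n"
            )


# ---------------------------------------------------------------------------
# Family count tables (CAFE dialect)
# ---------------------------------------------------------------------------

def read_family_counts(path, tree: Optional[SpeciesTree] = None,
                       dialect: str = "cafe-tab") -> pd.DataFrame:
    """Read a CAFE-style tab file of per-node gene-family counts.

    The first column is the family id (a leading CAFE ``Description``
    column, when present, is ignored); remaining columns are tree nodes —
    all leaves, plus optionally internal nodes carrying precomputed
    ancestral counts.  Counts must be nonnegative integers.
    """
    if dialect != "cafe-tab":
        raise ValueError(f"unknown family-count dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = list(df.columns)
    id_col = cols[0]
    if id_col.lower() in ("description", "desc") and len(cols) > 1:
        df = df.drop(columns=[id_col])
        cols = list(df.columns)
        id_col = cols[0]
    df = df.set_index(id_col)
    df.index.name = "family"
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any() or (numeric % 1 != 0).any() or (numeric < 0).any():
            bad = df[col][(pd.to_numeric(df[col], errors="coerce").isna())
                          | (numeric % 1 != 0) | (numeric < 0)]
            raise FormatError(
                f"{path}: column {col!r} has non-integer or negative "
                f"count(s), e.g. {bad.iloc[0]!r}"
            )
        df[col] = numeric.astype(int)
    if tree is not None:
        unknown = [c for c in df.columns if c not in tree]
        if unknown:
            raise FormatError(
                f"{path}: column(s) {unknown} match no tree node"
            )
        missing_leaves = [l for l in tree.leaf_names if l not in df.columns]
        if missing_leaves:
            raise FormatError(f"{path}: no counts for leaves {missing_leaves}")
    return df


def write_family_counts(counts: pd.DataFrame, path,
                        meta: Optional[Mapping[str, str]] = None) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(_header_lines(meta))
        counts.to_csv(fh, sep="\t", lineterminator="\n")


def write_table(df: pd.DataFrame, path, index: bool = False,
                meta: Optional[Mapping[str, str]] = None) -> None:
    """Write any result frame as commented-header TSV."""
    with open(path, "w", newline="\n") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g",
                  lineterminator="\n")
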