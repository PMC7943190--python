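"""Readers, writers and in-memory containers for every artifact the pipeline touches.

Formats are deliberately plain text: tab-separated expression and character
tables, Newick trees, GMT gene sets, one-identifier-per-line gene lists, and
tidy TSV result tables. No NEXUS, no Excel, no accession downloading.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CharacterMatrix",
    "Phylogeny",
    "GeneSetCollection",
    "AssayTable",
    "MISSING",
    "read_expression_table",
    "write_expression_table",
    "read_character_matrix",
    "write_character_matrix",
    "read_newick",
    "parse_newick",
    "write_newick",
    "read_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_assay_table",
    "write_assay_table",
]

#: Integer code used for the "?" (missing) character state.
MISSING: int = 2

_STATE_TO_CODE = {"0": 0, "1": 1, "?": MISSING}
_CODE_TO_STATE = {0: "0", 1: "1", MISSING: "?"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Expression matrices (TPM)
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance table in TPM with a sample -> species mapping.

    ``data`` is a float DataFrame (rows = genes, columns = samples); missing
    abundances are NaN. Every non-missing value must be >= 0, identifiers must
    be unique, and every sample must have a species label.
    """

    data: pd.DataFrame
    sample_species: dict[str, str]
    n_unparseable: int = 0

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample identifier: {dup!r}")
        missing_map = [s for s in self.data.columns if s not in self.sample_species]
        if missing_map:
            raise FormatError(
                f"samples absent from species map: {missing_map[:5]}"
            )
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FormatError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def species(self) -> list[str]:
        """Species labels in first-appearance (column) order."""
        seen: dict[str, None] = {}
        for s in self.data.columns:
            seen.setdefault(self.sample_species[s], None)
        return list(seen)


def read_expression_table(path: str | Path, species_map_path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression table (genes as rows, header of sample ids).

    Unparseable numeric cells become missing and are counted in
    ``n_unparseable`` (the load report). A duplicate gene identifier or a
    sample absent from the species map is a hard error.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    # cells that held a non-empty token but failed to parse (including "NA")
    nonempty = raw.apply(lambda col: col.str.strip() != "").to_numpy()
    unparseable = int((numeric.isna().to_numpy() & nonempty).sum())
    species_map = _read_species_map(species_map_path)
    return ExpressionMatrix(numeric, species_map, n_unparseable=unparseable)


def _read_species_map(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 'sample<TAB>species'")
        sample, species = parts
        if lineno == 1 and (sample.lower(), species.lower()) == ("sample", "species"):
            continue
        mapping[sample] = species
    return mapping


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def write_species_map(sample_species: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, species in sample_species.items():
            fh.write(f"{sample}\t{species}\n")


# ---------------------------------------------------------------------------
# Binary character matrices ({0, 1, ?})
# ---------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """Gene x taxon discrete character states, the unit of parsimony analysis.

    States are stored as an int8 code array (0 = absent, 1 = present,
    2 = missing "?"); ``genes`` and ``taxa`` give row/column labels.
    """

    genes: list[str]
    taxa: list[str]
    codes: np.ndarray  # (n_genes, n_taxa) int8 in {0, 1, MISSING}

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.genes), len(self.taxa)):
            raise FormatError("character matrix shape does not match labels")
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("taxon labels must be unique")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("gene identifiers must be unique")
        bad = ~np.isin(self.codes, (0, 1, MISSING))
        if bad.any():
            g, t = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid state {self.codes[g, t]} at gene {self.genes[g]!r}, taxon {self.taxa[t]!r}"
            )

    @classmethod
    def from_strings(
        cls, genes: Sequence[str], taxa: Sequence[str], rows: Sequence[Sequence[str]]
    ) -> "CharacterMatrix":
        codes = np.empty((len(genes), len(taxa)), dtype=np.int8)
        for i, row in enumerate(rows):
            for j, tok in enumerate(row):
                try:
                    codes[i, j] = _STATE_TO_CODE[tok]
                except KeyError:
                    raise FormatError(
                        f"invalid state token {tok!r} at row {i + 1}, column {j + 1}"
                    ) from None
        return cls(list(genes), list(taxa), codes)

    def character(self, gene: str) -> dict[str, str]:
        """One gene's states as a taxon -> {'0','1','?'} mapping."""
        i = self.genes.index(gene)
        return {t: _CODE_TO_STATE[int(c)] for t, c in zip(self.taxa, self.codes[i])}

    def to_frame(self) -> pd.DataFrame:
        sym = np.array(["0", "1", "?"], dtype=object)[self.codes]
        return pd.DataFrame(sym, index=self.genes, columns=self.taxa)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def read_character_matrix(path: str | Path, transposed: bool = False) -> CharacterMatrix:
    """Read a TSV character matrix (genes as rows, taxa as columns).

    ``transposed=True`` accepts the taxa-as-rows orientation. Any token
    outside {0, 1, ?} is a hard error reporting its row/column position.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty character matrix")
    header = lines[0].split("\t")
    cols = header[1:]
    row_labels: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise FormatError(f"{path}: line {lineno}: expected {len(header)} fields")
        row_labels.append(parts[0])
        for j, tok in enumerate(parts[1:], start=2):
            if tok not in _STATE_TO_CODE:
                raise FormatError(
                    f"{path}: invalid state {tok!r} at line {lineno}, column {j}"
                )
        rows.append(parts[1:])
    if transposed:
        mat = CharacterMatrix.from_strings(cols, row_labels, list(map(list, zip(*rows))))
    else:
        mat = CharacterMatrix.from_strings(row_labels, cols, rows)
    return mat


def write_character_matrix(matrix: CharacterMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Rooted trees
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted tree (polytomies permitted) with unique leaf labels.

    Wraps a :class:`dendropy.Tree` and pre-computes the indexed traversal
    structure (postorder node list, parent/child indices) used by the
    parsimony dynamic program. Trees are used exactly as rooted in the input;
    no rerooting is ever applied. Unary (single-child) nodes are collapsed at
    construction with a warning.
    """

    def __init__(self, tree: dendropy.Tree):
        n_before = sum(1 for _ in tree.preorder_node_iter())
        tree.suppress_unifurcations()
        if sum(1 for _ in tree.preorder_node_iter()) != n_before:
            warnings.warn("unary nodes collapsed", stacklevel=2)
        self._tree = tree
        self.postorder: list[dendropy.Node] = list(tree.postorder_node_iter())
        self.index: dict[int, int] = {id(n): i for i, n in enumerate(self.postorder)}
        self.parent: list[int | None] = [
            self.index[id(n.parent_node)] if n.parent_node is not None else None
            for n in self.postorder
        ]
        self.children: list[list[int]] = [
            [self.index[id(c)] for c in n.child_nodes()] for n in self.postorder
        ]
        self.is_leaf = np.array([n.is_leaf() for n in self.postorder])
        self.root_index = self.index[id(tree.seed_node)]
        self.labels: list[str] = []
        auto = 0
        seen_leaves: set[str] = set()
        for node in self.postorder:
            if node.is_leaf():
                label = node.taxon.label if node.taxon is not None else node.label
                if label is None:
                    raise FormatError("leaf without a label")
                if label in seen_leaves:
                    raise FormatError(f"duplicate leaf label: {label!r}")
                seen_leaves.add(label)
            else:
                label = node.label
                if not label:
                    auto += 1
                    label = f"_node{auto}"
                    node.label = label
            self.labels.append(label)
        self.leaf_index: dict[str, int] = {
            self.labels[i]: i for i in range(len(self.postorder)) if self.is_leaf[i]
        }

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in range(len(self.postorder)) if self.is_leaf[i]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_index)

    def edges(self) -> list[tuple[str, str]]:
        """All (parent label, child label) pairs, postorder by child."""
        return [
            (self.labels[self.parent[i]], self.labels[i])
            for i in range(len(self.postorder))
            if self.parent[i] is not None
        ]

    def mrca_index(self, taxa: Sequence[str]) -> int:
        unknown = [t for t in taxa if t not in self.leaf_index]
        if unknown:
            raise KeyError(f"taxa not in tree: {unknown}")
        node = self._tree.mrca(taxon_labels=list(taxa))
        return self.index[id(node)]

    def focal_edge(self, taxa: Sequence[str]) -> tuple[str, str]:
        """The edge subtending the MRCA of ``taxa`` (its stem branch).

        Raises if the MRCA is the root, which has no subtending edge.
        """
        child = self.mrca_index(taxa)
        if self.parent[child] is None:
            raise ValueError(
                "taxon set resolves to the root, which has no subtending edge"
            )
        return self.labels[self.parent[child]], self.labels[child]

    def as_newick(self, edge_lengths: Mapping[tuple[str, str], float] | None = None) -> str:
        tree = self._tree.clone(depth=1)
        if edge_lengths is not None:
            phy = Phylogeny(tree)
            for i, node in enumerate(phy.postorder):
                if phy.parent[i] is not None:
                    key = (phy.labels[phy.parent[i]], phy.labels[i])
                    node.edge.length = edge_lengths.get(key, 0)
        return tree.as_string(schema="newick", suppress_rooting=True).strip()


def parse_newick(newick: str) -> Phylogeny:
    """Parse a single rooted Newick string (quoted labels honored)."""
    depth = 0
    for offset, ch in enumerate(newick):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ')' at character offset {offset}")
    if depth != 0:
        raise FormatError(f"unbalanced '(' ({depth} unclosed) in newick string")
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        rooting="force-rooted",
    )
    return Phylogeny(tree)


def read_newick(path: str | Path) -> Phylogeny:
    return parse_newick(Path(path).read_text())


def write_newick(tree: Phylogeny, path: str | Path, **kwargs) -> None:
    Path(path).write_text(tree.as_newick(**kwargs) + "\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT) and gene lists
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, deduplicated gene tuple)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene<TAB>gene...``.

    Duplicate genes within a line are deduplicated with a warning; a line
    with fewer than three fields is a hard error naming the line.
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {lineno}: GMT line needs >= 3 fields")
        name, desc, genes = parts[0], parts[1], parts[2:]
        genes = [g for g in genes if g]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            warnings.warn(
                f"{path}: line {lineno}: {len(genes) - len(deduped)} duplicate "
                f"gene(s) removed from set {name!r}",
                stacklevel=2,
            )
        if name in sets:
            raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
        sets[name] = (desc, tuple(deduped))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        tok = line.strip()
        if tok and not tok.startswith("#"):
            out.append(tok)
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))


# ---------------------------------------------------------------------------
# Two-group assay tables
# ---------------------------------------------------------------------------


@dataclass
class AssayTable:
    """Replicate measurements for grouped assays with a declared scale.

    ``data`` has columns (group, replicate, value); ``scale`` is "raw" or
    "log". Each group needs at least two finite replicates.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        required = {"group", "replicate", "value"}
        if not required.issubset(self.data.columns):
            raise FormatError(f"assay table needs columns {sorted(required)}")
        if self.scale not in ("raw", "log"):
            raise FormatError(f"unknown scale tag {self.scale!r}")
        vals = self.data["value"].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise FormatError("assay values must be finite")
        counts = self.data.groupby("group").size()
        if (counts < 2).any():
            bad = counts[counts < 2].index[0]
            raise FormatError(f"group {bad!r} has fewer than 2 replicates")

    def group(self, label: str) -> np.ndarray:
        sel = self.data.loc[self.data["group"] == label, "value"]
        if sel.empty:
            raise KeyError(f"no group {label!r} in assay table")
        return sel.to_numpy(dtype=float)

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"]))


def read_assay_table(path: str | Path, scale: str | None = None) -> AssayTable:
    """Read a TSV with columns group/replicate/value.

    The scale tag may be given as a ``#scale=raw|log`` comment line in the
    file or via the ``scale`` argument (the argument wins).
    """
    file_scale = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#scale="):
            file_scale = line.split("=", 1)[1].strip()
        elif not line.startswith("#"):
            break
    df = pd.read_csv(path, sep="\t", comment="#")
    tag = scale or file_scale
    if tag is None:
        raise FormatError("assay table has no scale tag (#scale=raw|log) and none given")
    return AssayTable(df, tag)


def write_assay_table(table: AssayTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#scale={table.scale}\n")
        table.data.to_csv(fh, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    """Write a tidy result table as TSV (deterministic float formatting)."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def _isnan(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)
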