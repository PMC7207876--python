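"""Readers and writers for the plain-text formats the pipeline touches.

Assay matrices travel as GCT 1.3 (the LINCS distribution format for P100,
GCP and L1000), gene-set libraries as GMT, protein-protein interactions as
a three-column TSV in the STRING convention, and networks leave the
pipeline as SIF, GraphML or an edge TSV that Cytoscape can load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

#: Missing-value sentinels accepted in GCT bodies.  "-666" is the LINCS
#: convention; "NA" is the generic one.  Written files use "NA".
MISSING_SENTINELS = {"-666", "-666.0", "NA", "NaN", "nan", ""}

GCT_VERSION = "#1.3"

ANALYTE_TYPES = ("histone_mark", "phosphopeptide", "transcript")
LAYERS = ("drug", "histone", "phosphoprotein")

#: Prefix used to namespace node ids in network exports so that a drug and
#: a phosphoprotein sharing a symbol can never collide.
LAYER_PREFIX = {"drug": "drug:", "histone": "histone:", "phosphoprotein": "phospho:"}
_PREFIX_LAYER = {v: k for k, v in LAYER_PREFIX.items()}


class GctFormatError(ValueError):
    """Raised when a GCT file violates the 1.3 format contract."""


class PpiFormatError(ValueError):
    """Raised when a PPI edge table cannot be parsed."""


class GmtFormatError(ValueError):
    """Raised when a GMT gene-set file cannot be parsed."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class AnalyteMatrix:
    """An analyte x sample assay matrix with typed row/column metadata.

    ``values`` is float with NaN marking missing measurements.
    ``analyte_meta`` is indexed by analyte id and carries at least
    ``analyte_type`` (histone_mark | phosphopeptide | transcript) and
    optionally ``parent_gene``.  ``sample_meta`` is indexed by sample id and
    carries ``cell_line``, ``perturbagen``, ``dose``, ``timepoint_h``,
    ``replicate`` and ``is_control`` (vehicle/DMSO flag).
    """

    values: np.ndarray
    analyte_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_analytes, n_samples = self.values.shape
        if len(self.analyte_meta) != n_analytes:
            raise ValueError(
                f"analyte_meta has {len(self.analyte_meta)} rows for a "
                f"{n_analytes}-row matrix"
            )
        if len(self.sample_meta) != n_samples:
            raise ValueError(
                f"sample_meta has {len(self.sample_meta)} rows for a "
                f"{n_samples}-column matrix"
            )
        if self.analyte_meta.index.duplicated().any():
            dups = self.analyte_meta.index[self.analyte_meta.index.duplicated()]
            raise ValueError(f"duplicate analyte ids: {sorted(set(dups))}")
        if self.sample_meta.index.duplicated().any():
            dups = self.sample_meta.index[self.sample_meta.index.duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")

    # -- convenience views ---------------------------------------------------

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.analyte_meta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_meta.index)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean matrix, True where a measurement is missing."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.analyte_meta.index, columns=self.sample_meta.index
        )

    def select_samples(self, mask) -> "AnalyteMatrix":
        """Return a copy restricted to the samples where ``mask`` is True."""
        mask = np.asarray(mask)
        return AnalyteMatrix(
            self.values[:, mask].copy(),
            self.analyte_meta.copy(),
            self.sample_meta.loc[mask].copy(),
        )

    def copy(self) -> "AnalyteMatrix":
        return AnalyteMatrix(
            self.values.copy(), self.analyte_meta.copy(), self.sample_meta.copy()
        )


@dataclass
class PpiGraph:
    """Undirected protein-protein interaction graph.

    Edges are keyed by a sorted id pair and carry a STRING-style combined
    score in [0, 1000].  Self-loops are forbidden.
    """

    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), score in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if (a, b) != tuple(sorted((a, b))):
                raise ValueError(f"edge key {(a, b)} is not sorted")
            if not 0 <= score <= 1000:
                raise ValueError(f"score {score} for edge {(a, b)} outside [0, 1000]")

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def neighbors(self, protein: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == protein:
                out.add(b)
            elif b == protein:
                out.add(a)
        return out

    def has_edge(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.edges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), score in self.edges.items():
            g.add_edge(a, b, combined_score=score)
        return g

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class GeneSetLibrary:
    """A named collection of gene sets (GMT semantics)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")
            self.sets[term] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.sets[term]

    def terms(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# GCT 1.3
# ---------------------------------------------------------------------------


def _decode_cell(cell: str) -> float:
    if cell.strip() in MISSING_SENTINELS:
        return np.nan
    return float(cell)


def _coerce_meta_row(values: list[str]) -> list:
    """Best-effort typing for one column-metadata field across all samples."""
    lowered = [v.strip().lower() for v in values]
    if all(v in {"true", "false", "1", "0"} for v in lowered):
        # A field that is uniformly boolean-ish (is_control) becomes bool.
        if any(v in {"true", "false"} for v in lowered):
            return [v == "true" for v in lowered]
    try:
        nums = [float(v) for v in values]
    except ValueError:
        return values
    # keep integer-typed fields integral but never demote written floats
    if all("." not in v and "e" not in v.lower() for v in values):
        return [int(v) for v in nums]
    return nums


def read_gct(path: str | Path) -> AnalyteMatrix:
    """Read a GCT 1.3 file into an :class:`AnalyteMatrix`.

    Missing-value sentinels (``-666`` per the LINCS convention, or ``NA``)
    are decoded to NaN.  ``is_control`` column metadata written as
    true/false is restored to bool so that a write/read cycle is lossless.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("#"):
        raise GctFormatError(f"{path}: missing GCT version tag on line 1")
    if lines[0].strip() != GCT_VERSION:
        raise GctFormatError(
            f"{path}: unsupported GCT version {lines[0].strip()!r} (only {GCT_VERSION})"
        )
    dims = lines[1].split("\t") if "\t" in lines[1] else lines[1].split()
    if len(dims) != 4:
        raise GctFormatError(f"{path}: dimension line must have 4 fields, got {lines[1]!r}")
    try:
        nrows, ncols, nrowmeta, ncolmeta = (int(d) for d in dims)
    except ValueError as exc:
        raise GctFormatError(f"{path}: non-integer dimension line {lines[1]!r}") from exc

    header = lines[2].split("\t")
    expected_width = 1 + nrowmeta + ncols
    if len(header) != expected_width:
        raise GctFormatError(
            f"{path}: header line has {len(header)} fields, expected {expected_width}"
        )
    rowmeta_names = header[1 : 1 + nrowmeta]
    sample_ids = header[1 + nrowmeta :]

    colmeta: dict[str, list] = {}
    for i in range(ncolmeta):
        fields = lines[3 + i].split("\t")
        if len(fields) != expected_width:
            raise GctFormatError(
                f"{path}: column-metadata line {3 + i + 1} has {len(fields)} fields, "
                f"expected {expected_width}"
            )
        colmeta[fields[0]] = _coerce_meta_row(fields[1 + nrowmeta :])

    body = [ln for ln in lines[3 + ncolmeta :] if ln.strip()]
    if len(body) != nrows:
        raise GctFormatError(
            f"{path}: body has {len(body)} data rows but header declares {nrows}"
        )
    analyte_ids: list[str] = []
    rowmeta_rows: list[list[str]] = []
    values = np.empty((nrows, ncols))
    for r, ln in enumerate(body):
        fields = ln.split("\t")
        if len(fields) != expected_width:
            raise GctFormatError(
                f"{path}: data line {3 + ncolmeta + r + 1} has {len(fields)} fields, "
                f"expected {expected_width}"
            )
        analyte_ids.append(fields[0])
        rowmeta_rows.append(fields[1 : 1 + nrowmeta])
        try:
            values[r] = [_decode_cell(c) for c in fields[1 + nrowmeta :]]
        except ValueError as exc:
            raise GctFormatError(
                f"{path}: non-numeric value on data line {3 + ncolmeta + r + 1}: {exc}"
            ) from exc

    analyte_meta = pd.DataFrame(
        rowmeta_rows, columns=rowmeta_names, index=pd.Index(analyte_ids, name="id")
    )
    sample_meta = pd.DataFrame(colmeta, index=pd.Index(sample_ids, name="sample_id"))
    return AnalyteMatrix(values, analyte_meta, sample_meta)


def write_gct(m: AnalyteMatrix, path: str | Path) -> Path:
    """Write an :class:`AnalyteMatrix` as GCT 1.3; NaN becomes ``NA``."""
    path = Path(path)
    nrows, ncols = m.values.shape
    rowmeta_names = list(m.analyte_meta.columns)
    colmeta_names = list(m.sample_meta.columns)
    with open(path, "w") as fh:
        fh.write(GCT_VERSION + "\n")
        fh.write(f"{nrows}\t{ncols}\t{len(rowmeta_names)}\t{len(colmeta_names)}\n")
        fh.write("\t".join(["id", *rowmeta_names, *map(str, m.sample_ids)]) + "\n")
        for name in colmeta_names:
            cells = [_format_meta(v) for v in m.sample_meta[name]]
            fh.write("\t".join([name, *["NA"] * len(rowmeta_names), *cells]) + "\n")
        for r, aid in enumerate(m.analyte_ids):
            metas = [_format_meta(v) for v in m.analyte_meta.iloc[r]]
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in m.values[r]]
            fh.write("\t".join([str(aid), *metas, *cells]) + "\n")
    return path


def _format_meta(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


# ---------------------------------------------------------------------------
# PPI edge tables
# ---------------------------------------------------------------------------


def read_ppi_table(path: str | Path, min_confidence: float = 0.0) -> PpiGraph:
    """Read a STRING-style edge TSV (protein_a, protein_b, combined_score).

    Edges below ``min_confidence`` are dropped, unordered duplicates are
    collapsed keeping the maximum score, and self-loops are discarded.
    A header line is tolerated if its third field is non-numeric and named
    like a score column.
    """
    path = Path(path)
    edges: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            fields = ln.split("\t") if "\t" in ln else ln.split()
            if len(fields) < 3:
                raise PpiFormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, need >=3"
                )
            a, b, raw_score = fields[0], fields[1], fields[2]
            if lineno == 1 and raw_score.lower() in {"combined_score", "score"}:
                continue
            try:
                score = float(raw_score)
            except ValueError as exc:
                raise PpiFormatError(
                    f"{path}: non-numeric score {raw_score!r} on line {lineno}"
                ) from exc
            if a == b:
                continue
            if score < min_confidence:
                continue
            key = tuple(sorted((a, b)))
            edges[key] = max(score, edges.get(key, float("-inf")))
    if not edges:
        warnings.warn(
            f"{path}: no edges at min_confidence={min_confidence}", stacklevel=2
        )
    return PpiGraph(edges)


def write_ppi_table(ppi: PpiGraph, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tcombined_score\n")
        for (a, b), score in sorted(ppi.edges.items()):
            fh.write(f"{a}\t{b}\t{score:g}\n")
    return path


# ---------------------------------------------------------------------------
# GMT gene-set libraries
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a GMT file: term, description, then one gene symbol per field."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "need term, description and >=1 gene"
                )
            term = fields[0]
            if term in sets:
                raise GmtFormatError(f"{path}: duplicate term {term!r} on line {lineno}")
            genes = frozenset(g for g in fields[2:] if g.strip())
            if not genes:
                raise GmtFormatError(f"{path}: term {term!r} has no genes")
            sets[term] = genes
    return GeneSetLibrary(sets)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for term, genes in library.sets.items():
            fh.write("\t".join([term, "na", *sorted(genes)]) + "\n")
    return path


# ---------------------------------------------------------------------------
# Network exports
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def write_network(network, path: str | Path, format: str = "tsv") -> Path:
    """Export a tripartite network for Cytoscape.

    ``network`` is any object exposing ``nodes`` as an iterable of
    ``(id, layer, module)`` triples and ``edges`` as an iterable of
    ``(source, target, layer_pair, weight, sign)`` tuples (the
    :class:`~iphdnet.integrate.TripartiteNetwork` contract).  Node ids are
    namespaced by layer (``drug:``, ``histone:``, ``phospho:``) in every
    format.  The TSV format round-trips through :func:`read_network_tsv`.
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    path = Path(path)
    nodes = list(network.nodes)
    edges = list(network.edges)
    if format in ("sif", "graphml") and not edges:
        raise ValueError(f"cannot write an empty network as {format}")

    layer_of = {nid: layer for nid, layer, _module in nodes}

    def qual(nid: str) -> str:
        return LAYER_PREFIX[layer_of[nid]] + nid

    if format == "sif":
        with open(path, "w") as fh:
            for source, target, _pair, _weight, sign in sorted(edges):
                relation = "activates" if sign > 0 else "represses"
                fh.write(f"{qual(source)}\t{relation}\t{qual(target)}\n")
        return path

    if format == "graphml":
        g = nx.Graph()
        for nid, layer, module in nodes:
            g.add_node(qual(nid), layer=layer, module="" if module is None else module)
        for source, target, pair, weight, sign in edges:
            g.add_edge(
                qual(source), qual(target), layer_pair=pair, weight=float(weight),
                sign=int(sign),
            )
        nx.write_graphml(g, path)
        return path

    module_of = {nid: module for nid, _layer, module in nodes}
    with open(path, "w") as fh:
        fh.write(
            "source\tsource_layer\tsource_module\ttarget\ttarget_layer\t"
            "target_module\tlayer_pair\tweight\tsign\n"
        )
        for source, target, pair, weight, sign in sorted(edges):
            fh.write(
                "\t".join(
                    [
                        source,
                        layer_of[source],
                        _module_str(module_of[source]),
                        target,
                        layer_of[target],
                        _module_str(module_of[target]),
                        pair,
                        repr(float(weight)),
                        str(int(sign)),
                    ]
                )
                + "\n"
            )
        # isolated nodes are preserved as node-only records
        endpoint_ids = {s for s, *_ in edges} | {t for _s, t, *_ in edges}
        for nid, layer, module in sorted(nodes):
            if nid not in endpoint_ids:
                fh.write(f"{nid}\t{layer}\t{_module_str(module)}\t\t\t\t\t\t\n")
    return path


def _module_str(module) -> str:
    return "" if module is None else str(module)


def read_network_tsv(path: str | Path):
    """Read an edge TSV written by :func:`write_network` back into a
    :class:`~iphdnet.integrate.TripartiteNetwork` (lossless round trip)."""
    from .integrate import TripartiteNetwork  # local import to avoid a cycle

    path = Path(path)
    nodes: set[tuple[str, str, str | None]] = set()
    edges: set[tuple[str, str, str, float, int]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "source":
            raise ValueError(f"{path}: not a network edge TSV")
        for ln in fh:
            f = ln.rstrip("\n").split("\t")
            source, s_layer, s_mod, target, t_layer, t_mod, pair, weight, sign = f
            nodes.add((source, s_layer, s_mod or None))
            if target:  # edge record
                nodes.add((target, t_layer, t_mod or None))
                edges.add((source, target, pair, float(weight), int(sign)))
    return TripartiteNetwork(nodes=nodes, edges=edges)
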