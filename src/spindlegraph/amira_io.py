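"""Reading and writing AmiraMesh ASCII HxSpatialGraph files and analysis tables.

The spatial-graph dialect supported here is the one produced by filament
tracing in Amira / AmiraZIBEdition: an ASCII ``# AmiraMesh 3D ASCII`` header,
``define VERTEX/EDGE/POINT`` counts, a ``Parameters`` block whose
``ContentType`` is ``"HxSpatialGraph"``, data declarations of the form
``EDGE { int NumEdgePoints } @3`` and numeric payload blocks introduced by
``@k`` markers.  Binary AmiraMesh is rejected.

Per-edge integer fields other than ``EdgeConnectivity``/``NumEdgePoints`` are
exposed as labels (e.g. ``KMT``, ``KFiberID``).  Spindle pole coordinates may
be carried in the Parameters block as ``SpindlePole1``/``SpindlePole2``
(quoted ``"x y z"`` strings); this is how :mod:`spindlegraph.synthetic`
round-trips ground-truth poles.
"""

from __future__ import annotations

import io
import json
import math
import os
import re
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AmiraFormatError, AmiraStructureError

__all__ = [
    "SpatialGraph",
    "read_spatial_graph",
    "write_spatial_graph",
    "export_tables",
]

_HEADER_RE = re.compile(r"#\s*AmiraMesh(?:\s+3D)?\s+(ASCII|BINARY\S*)", re.IGNORECASE)
_DEFINE_RE = re.compile(r"^(?:define\s+|n)(\w+)\s+(\d+)\s*$")
_DECL_RE = re.compile(
    r"^(VERTEX|EDGE|POINT)\s*\{\s*(\w+)\s*(?:\[\s*(\d+)\s*\])?\s+(\w+)\s*\}\s*@(\d+)\s*$"
)
_MARKER_RE = re.compile(r"^@(\d+)\s*$")
_PARAM_KV_RE = re.compile(r"^\s*(\w+)\s+\"([^\"]*)\"\s*,?\s*$")

#: reserved per-edge fields that are structure, not labels
_STRUCTURAL_EDGE_FIELDS = {"EdgeConnectivity", "NumEdgePoints"}


@dataclass
class SpatialGraph:
    """Document-level representation of an HxSpatialGraph.

    Coordinates are kept exactly as read; unit handling and classification
    happen downstream in :mod:`spindlegraph.graph_model`.

    Attributes
    ----------
    vertices : (n_v, 3) float array
    edges : (n_e, 2) int array
        Vertex indices (0-based) of each edge.
    num_points : (n_e,) int array
        Number of interior+end points per edge; sums to ``len(points)``.
    points : (n_p, 3) float array
        Concatenated per-edge point runs, in edge order.
    edge_labels : mapping of field name to (n_e,) int array
    parameters : mapping of parameter name to string value
    """

    vertices: np.ndarray
    edges: np.ndarray
    num_points: np.ndarray
    points: np.ndarray
    edge_labels: dict[str, np.ndarray] = field(default_factory=dict)
    parameters: dict[str, str] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def point_offsets(self) -> np.ndarray:
        """Start offset of each edge's point run inside ``points``."""
        return np.concatenate([[0], np.cumsum(self.num_points)[:-1]]).astype(int)

    def edge_points(self, edge_index: int) -> np.ndarray:
        """The ordered (m, 3) point run of one edge (a view)."""
        off = self.point_offsets()[edge_index]
        return self.points[off : off + int(self.num_points[edge_index])]

    def pole_coordinates(self) -> tuple[np.ndarray | None, np.ndarray | None]:
        """Spindle poles from the Parameters block, if present."""
        poles = []
        for key in ("SpindlePole1", "SpindlePole2"):
            raw = self.parameters.get(key)
            poles.append(np.array([float(t) for t in raw.split()]) if raw else None)
        return poles[0], poles[1]

    def validate(self, endpoint_tol: float = 1e-4) -> None:
        """Check structural invariants; raise :class:`AmiraStructureError`.

        Endpoint/vertex coincidence beyond ``endpoint_tol`` is reported as a
        warning rather than an error: manually edited graphs in the wild
        occasionally violate it without harming downstream geometry.
        """
        total = int(self.num_points.sum()) if self.n_edges else 0
        if total != self.n_points:
            raise AmiraStructureError(
                f"sum of NumEdgePoints ({total}) does not match the POINT count "
                f"({self.n_points})"
            )
        if self.n_edges and (
            self.edges.min(initial=0) < 0 or self.edges.max(initial=-1) >= self.n_vertices
        ):
            raise AmiraStructureError(
                f"EdgeConnectivity references vertex indices outside [0, {self.n_vertices})"
            )
        if np.any(self.num_points < 2):
            bad = int(np.argmax(self.num_points < 2))
            raise AmiraStructureError(f"edge {bad} has fewer than 2 points")
        offsets = self.point_offsets()
        for i in range(self.n_edges):
            run = self.points[offsets[i] : offsets[i] + int(self.num_points[i])]
            v0 = self.vertices[self.edges[i, 0]]
            v1 = self.vertices[self.edges[i, 1]]
            if (
                np.linalg.norm(run[0] - v0) > endpoint_tol
                or np.linalg.norm(run[-1] - v1) > endpoint_tol
            ):
                warnings.warn(
                    f"edge {i}: point run endpoints deviate from vertex coordinates "
                    f"by more than {endpoint_tol}",
                    stacklevel=2,
                )


def _tokenize_blocks(lines: list[str], start: int) -> dict[int, list[str]]:
    """Collect numeric tokens of every ``@k`` data block."""
    blocks: dict[int, list[str]] = {}
    current: list[str] | None = None
    for raw in lines[start:]:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _MARKER_RE.match(line)
        if m:
            current = blocks.setdefault(int(m.group(1)), [])
            continue
        if current is not None:
            current.extend(line.split())
    return blocks


def _parse_parameters(lines: list[str], start: int) -> tuple[dict[str, str], int]:
    """Parse the (possibly nested) Parameters block starting at ``start``.

    Only top-level ``Key "value"`` pairs are retained; nested sub-blocks
    (label trees etc.) are skipped but brace-balanced.
    """
    params: dict[str, str] = {}
    depth = 0
    i = start
    while i < len(lines):
        line = lines[i]
        stripped = line.strip()
        if depth == 1:
            m = _PARAM_KV_RE.match(stripped)
            if m:
                params[m.group(1)] = m.group(2)
        depth += line.count("{") - line.count("}")
        i += 1
        if depth <= 0 and i > start:
            break
    if depth > 0:
        raise AmiraFormatError("unterminated Parameters block (unbalanced braces)")
    return params, i


def read_spatial_graph(source: str | os.PathLike | IO[str]) -> SpatialGraph:
    """Read an AmiraMesh ASCII HxSpatialGraph document.

    Parameters
    ----------
    source
        Path, or an open text stream, or the document text itself when it
        starts with the AmiraMesh header.

    Raises
    ------
    AmiraFormatError
        Malformed or binary header, missing ContentType, bad declarations.
    AmiraStructureError
        Declared counts inconsistent with the data payload.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = os.fspath(source) if isinstance(source, os.PathLike) else str(source)
        if s.lstrip().startswith("#") or "\n" in s:
            text = s
        else:
            with open(s, "r", encoding="utf-8") as fh:
                text = fh.read()

    lines = text.splitlines()
    if not lines:
        raise AmiraFormatError("empty input: expected an AmiraMesh ASCII header")
    header = _HEADER_RE.search(lines[0])
    if header is None:
        raise AmiraFormatError(
            f"not an AmiraMesh file: first line is {lines[0]!r} "
            "(expected '# AmiraMesh 3D ASCII ...')"
        )
    if header.group(1).upper() != "ASCII":
        raise AmiraFormatError(
            "binary AmiraMesh is not supported; export the spatial graph in "
            "ASCII format from Amira"
        )

    definitions: dict[str, int] = {}
    declarations: list[tuple[str, str, int, str, int]] = []
    parameters: dict[str, str] = {}
    data_start = len(lines)

    i = 1
    while i < len(lines):
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        if _MARKER_RE.match(line):
            data_start = i
            break
        m = _DEFINE_RE.match(line)
        if m:
            definitions[m.group(1)] = int(m.group(2))
            i += 1
            continue
        if line.startswith("Parameters"):
            parameters, i = _parse_parameters(lines, i)
            continue
        m = _DECL_RE.match(line)
        if m:
            section, kind, arity, name, marker = m.groups()
            declarations.append((section, kind, int(arity or 1), name, int(marker)))
            i += 1
            continue
        raise AmiraFormatError(f"unrecognized line {i + 1}: {lines[i]!r}")

    content = parameters.get("ContentType", "")
    if content != "HxSpatialGraph":
        raise AmiraFormatError(
            f"ContentType is {content!r}; expected \"HxSpatialGraph\" — is this a "
            "spatial graph export?"
        )

    n_v = definitions.get("VERTEX", 0)
    n_e = definitions.get("EDGE", 0)
    n_p = definitions.get("POINT", 0)

    blocks = _tokenize_blocks(lines, data_start)

    def block_array(marker: int, count: int, arity: int, dtype, what: str) -> np.ndarray:
        tokens = blocks.get(marker, [])
        expected = count * arity
        if len(tokens) != expected:
            raise AmiraStructureError(
                f"data block @{marker} ({what}) has {len(tokens)} values, "
                f"expected {expected}"
            )
        arr = np.array(tokens, dtype=dtype)
        return arr.reshape(count, arity) if arity > 1 else arr

    vertices = np.zeros((n_v, 3))
    edges = np.zeros((n_e, 2), dtype=int)
    num_points = np.zeros(n_e, dtype=int)
    points = np.zeros((n_p, 3))
    edge_labels: dict[str, np.ndarray] = {}

    for section, kind, arity, name, marker in declarations:
        count = definitions.get(section)
        if count is None:
            raise AmiraFormatError(f"declaration references undefined section {section!r}")
        dtype = float if kind.lower() == "float" else int
        arr = block_array(marker, count, arity, dtype, f"{section} {name}")
        if section == "VERTEX" and name == "VertexCoordinates":
            vertices = arr
        elif section == "EDGE" and name == "EdgeConnectivity":
            edges = arr.astype(int)
        elif section == "EDGE" and name == "NumEdgePoints":
            num_points = arr.astype(int)
        elif section == "POINT" and name == "EdgePointCoordinates":
            points = arr
        elif section == "EDGE" and name not in _STRUCTURAL_EDGE_FIELDS and arity == 1:
            edge_labels[name] = arr.astype(int)

    graph = SpatialGraph(
        vertices=vertices,
        edges=edges,
        num_points=num_points,
        points=points,
        edge_labels=edge_labels,
        parameters=parameters,
    )
    graph.validate()
    return graph


def _fmt(value: float) -> str:
    # repr gives the shortest decimal that round-trips the float exactly
    return repr(float(value))


def write_spatial_graph(graph: SpatialGraph, target: IO[str] | str | os.PathLike | None = None) -> str:
    """Serialize a :class:`SpatialGraph` as AmiraMesh 3D ASCII.

    Field order is deterministic: coordinates/connectivity first, then labels
    in sorted name order, so identical graphs serialize to identical bytes.
    Returns the document text; also writes it to ``target`` if given.
    """
    if graph.n_edges and np.any(graph.num_points < 2):
        bad = int(np.argmax(graph.num_points < 2))
        raise AmiraStructureError(f"refusing to write edge {bad} with fewer than 2 points")
    graph.validate()

    out = io.StringIO()
    out.write("# AmiraMesh 3D ASCII 2.0\n\n\n")
    out.write(f"define VERTEX {graph.n_vertices}\n")
    out.write(f"define EDGE {graph.n_edges}\n")
    out.write(f"define POINT {graph.n_points}\n\n")
    out.write("Parameters {\n")
    params = dict(graph.parameters)
    params.setdefault("ContentType", "HxSpatialGraph")
    keys = ["ContentType"] + sorted(k for k in params if k != "ContentType")
    for k in keys:
        out.write(f'    {k} "{params[k]}"\n')
    out.write("}\n\n")

    marker = 1
    decls: list[tuple[str, np.ndarray, bool]] = []

    def declare(section: str, kind: str, arity: int, name: str, data: np.ndarray, as_int: bool):
        nonlocal marker
        suffix = f"[{arity}]" if arity > 1 else ""
        out.write(f"{section} {{ {kind}{suffix} {name} }} @{marker}\n")
        decls.append((f"@{marker}", data, as_int))
        marker += 1

    declare("VERTEX", "float", 3, "VertexCoordinates", graph.vertices, False)
    declare("EDGE", "int", 2, "EdgeConnectivity", graph.edges, True)
    declare("EDGE", "int", 1, "NumEdgePoints", graph.num_points, True)
    declare("POINT", "float", 3, "EdgePointCoordinates", graph.points, False)
    for name in sorted(graph.edge_labels):
        declare("EDGE", "int", 1, name, graph.edge_labels[name], True)

    out.write("\n")
    for tag, data, as_int in decls:
        out.write(f"{tag}\n")
        arr = data.reshape(-1, 1) if data.ndim == 1 else data
        for row in arr:
            if as_int:
                out.write(" ".join(str(int(v)) for v in row))
            else:
                out.write(" ".join(_fmt(v) for v in row))
            out.write("\n")
        out.write("\n")

    text = out.getvalue()
    if target is not None:
        if hasattr(target, "write"):
            target.write(text)
        else:
            with open(target, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


def export_tables(
    tables: Iterable,
    directory: str | os.PathLike,
    format: str = "csv",
    precision: int = 6,
) -> list[str]:
    """Write analysis tables to ``directory`` (one file per analysis).

    Parameters
    ----------
    tables
        Iterable of :class:`spindlegraph.metrics.MetricTable` (anything with
        ``.name`` and ``.frame``).
    format
        ``"csv"`` (RFC-4180 quoting via pandas) or ``"xlsx"`` (one sheet per
        table, via openpyxl).
    precision
        Significant digits for floating values in CSV output.

    Returns the list of written file paths; a ``manifest.json`` describing
    them is written alongside.  Each table is written to a temporary file and
    renamed, so an I/O failure never leaves a partial table behind.
    """
    if format not in ("csv", "xlsx"):
        raise ValueError(f"unknown export format {format!r} (expected 'csv' or 'xlsx')")
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    written: list[str] = []
    manifest: list[dict] = []
    for table in tables:
        name = table.name
        frame: pd.DataFrame = table.frame
        path = os.path.join(directory, f"{name}.{format}")
        tmp = path + f".tmp.{format}"
        if format == "csv":
            frame.to_csv(tmp, index=False, float_format=f"%.{precision}g")
        else:
            with pd.ExcelWriter(tmp, engine="openpyxl") as writer:
                frame.to_excel(writer, sheet_name=name[:31], index=False)
        os.replace(tmp, path)
        written.append(path)
        manifest.append({"analysis": name, "file": os.path.basename(path), "rows": len(frame)})
    with open(os.path.join(directory, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump({"format": format, "tables": manifest}, fh, indent=2)
    return written
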