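"""Readers and writers for abundance tables, annotations, networks and reports.

This module is the single source of truth for on-disk formats:

* abundance tables — CSV, header row = sample ids, first column = feature ids,
  features as rows and samples as columns (fermentation-time order = column order);
* feature annotations — CSV with columns
  ``feature_id,role,species,genus,phylum,category``;
* truth-edge lists — CSV with columns ``microbe_id,volatile_id,sign``;
* association networks — GraphML or GEXF (both re-readable by standard graph tools);
* analysis reports — versioned JSON documents.

All numeric round trips are lossless to 1e-12; validation errors always name the
offending row or column.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

#: The closed vocabulary of volatile chemical classes.
CATEGORIES = frozenset(
    {
        "hydrocarbons",
        "esters",
        "ketones",
        "sulfides",
        "alcohols",
        "aldehydes",
        "aromatic compounds",
        "acids",
        "heterocyclic compounds",
    }
)

#: Tolerance on per-sample column sums for tables in ``relative`` mode.
RELATIVE_SUM_TOL = 1e-6

REPORT_SCHEMA_VERSION = 1


class AbundanceTable:
    """A nonnegative feature-by-sample matrix.

    Parameters
    ----------
    data:
        DataFrame with feature ids as the index and sample ids as columns.
        Sample column order is meaningful (fermentation-time order).
    mode:
        ``"raw"`` for arbitrary nonnegative intensities/areas, ``"relative"``
        for compositional data whose sample columns each sum to 1.
    """

    def __init__(self, data: pd.DataFrame, mode: str = "raw", *, validate: bool = True):
        if mode not in ("raw", "relative"):
            raise ConfigurationError(f"unknown table mode {mode!r}")
        self.data = data.astype(float)
        self.mode = mode
        if validate:
            self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative value at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        if self.mode == "relative":
            sums = vals.sum(axis=0)
            bad = np.abs(sums - 1.0) > RELATIVE_SUM_TOL
            if bad.any():
                j = int(np.argmax(bad))
                raise ValidationError(
                    f"sample column {cols[j]!r} sums to {sums[j]:.6g}, "
                    "expected 1 in relative mode"
                )

    # -- convenience --------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AbundanceTable({self.n_features} features x {self.n_samples} samples, "
            f"mode={self.mode!r})"
        )


@dataclasses.dataclass(frozen=True)
class FeatureAnnotation:
    """Maps a feature id to its role and taxonomic / chemical identity.

    Microbes carry species/genus/phylum; volatiles carry one of the nine
    chemical categories in :data:`CATEGORIES`.
    """

    feature_id: str
    role: str
    code: str | None = None
    species: str | None = None
    genus: str | None = None
    phylum: str | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("microbe", "volatile"):
            raise ValidationError(
                f"feature {self.feature_id!r}: unknown role {self.role!r}"
            )
        if self.role == "volatile":
            if not self.category:
                raise ValidationError(
                    f"volatile {self.feature_id!r} is missing its chemical category"
                )
            if self.category not in CATEGORIES:
                raise ValidationError(
                    f"volatile {self.feature_id!r}: unknown category "
                    f"{self.category!r} (closed vocabulary of 9 classes)"
                )


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

def read_abundance_table(path: str | Path, mode: str = "raw") -> AbundanceTable:
    """Read a feature-by-sample CSV and validate it.

    In ``relative`` mode columns are *validated* against the sum-to-1
    invariant, never silently renormalized.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValidationError(f"non-numeric sample columns: {non_numeric}")
    return AbundanceTable(df, mode=mode)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_ANNOT_COLUMNS = ["feature_id", "role", "species", "genus", "phylum", "category"]


def read_annotations(path: str | Path) -> list[FeatureAnnotation]:
    """Read a feature annotation CSV into validated annotation records."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("feature_id", "role") if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation file missing columns: {missing}")
    annots = []
    for _, row in df.iterrows():
        annots.append(
            FeatureAnnotation(
                feature_id=row["feature_id"],
                role=row["role"],
                code=row.get("code") or row["feature_id"],
                species=row.get("species") or None,
                genus=row.get("genus") or None,
                phylum=row.get("phylum") or None,
                category=row.get("category") or None,
            )
        )
    seen: set[str] = set()
    for a in annots:
        if a.feature_id in seen:
            raise ValidationError(f"duplicate annotation for feature {a.feature_id!r}")
        seen.add(a.feature_id)
    return annots


def write_annotations(annotations: Iterable[FeatureAnnotation], path: str | Path) -> None:
    rows = [
        {
            "feature_id": a.feature_id,
            "role": a.role,
            "code": a.code or a.feature_id,
            "species": a.species or "",
            "genus": a.genus or "",
            "phylum": a.phylum or "",
            "category": a.category or "",
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["feature_id", "role", "code", "species", "genus",
                                "phylum", "category"]).to_csv(path, index=False)


def annotation_index(annotations: Iterable[FeatureAnnotation]) -> dict[str, FeatureAnnotation]:
    return {a.feature_id: a for a in annotations}


# ---------------------------------------------------------------------------
# truth edges
# ---------------------------------------------------------------------------

def read_truth_edges(path: str | Path) -> set[tuple[str, str, int]]:
    df = pd.read_csv(path, dtype={"microbe_id": str, "volatile_id": str, "sign": int})
    need = ["microbe_id", "volatile_id", "sign"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValidationError(f"truth-edge file missing columns: {missing}")
    edges = set()
    for _, row in df.iterrows():
        sign = int(row["sign"])
        if sign not in (1, -1):
            raise ValidationError(
                f"edge ({row['microbe_id']}, {row['volatile_id']}): sign must be +1/-1"
            )
        edges.add((row["microbe_id"], row["volatile_id"], sign))
    return edges


def write_truth_edges(edges: Iterable[tuple[str, str, int]], path: str | Path) -> None:
    rows = sorted(edges)
    pd.DataFrame(rows, columns=["microbe_id", "volatile_id", "sign"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(network, path: str | Path, dialect: str = "graphml") -> None:
    """Serialize an association network for standard graph tooling (e.g. Gephi).

    Nodes carry role/category/phylum attributes, edges carry rho, p and sign.
    """
    graph = network.graph if hasattr(network, "graph") else network
    out = nx.Graph()
    for node, attrs in graph.nodes(data=True):
        clean = {k: v for k, v in attrs.items() if v is not None}
        out.add_node(node, **clean)
    for u, v, attrs in graph.edges(data=True):
        out.add_edge(u, v, **{k: v2 for k, v2 in attrs.items() if v2 is not None})
    if dialect == "graphml":
        nx.write_graphml(out, path)
    elif dialect == "gexf":
        nx.write_gexf(out, path)
    else:
        raise ConfigurationError(f"unknown network dialect {dialect!r}")


def read_network(path: str | Path, dialect: str = "graphml") -> nx.Graph:
    if dialect == "graphml":
        return nx.read_graphml(path)
    if dialect == "gexf":
        return nx.read_gexf(path)
    raise ConfigurationError(f"unknown network dialect {dialect!r}")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(results: dict, path: str | Path) -> None:
    """Write a schema-versioned, human-readable report document (JSON)."""
    doc = {"schema_version": REPORT_SCHEMA_VERSION, "sections": _jsonable(results)}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported report schema version {doc.get('schema_version')!r}"
        )
    return doc["sections"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
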