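"""Domain records and tab-separated readers/writers.

Every table the pipeline touches is UTF-8 TSV with a header row; gene sets
use the standard GMT layout.  Gene symbols are opaque, case-sensitive
strings — no alias resolution is attempted.  All readers preserve row
order and round-trip through the matching writer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ComponentRecord",
    "PathogenicGene",
    "GeneSetCollection",
    "SchemaError",
    "read_component_table",
    "write_component_table",
    "read_pathogenic_table",
    "write_pathogenic_table",
    "read_gmt",
    "write_gmt",
    "read_edges",
    "write_edges",
]

_GI_LEVELS = {"high", "low", "unknown"}
_HERG_LEVELS = {"high", "medium", "low", "unknown"}
_CARC_LEVELS = {"positive", "negative", "unknown"}


class SchemaError(ValueError):
    """A table violates the expected schema (missing column, bad value)."""


@dataclass(frozen=True)
class ComponentRecord:
    """One formula component with its ADME-relevant properties.

    Numeric properties (MW, H-bond donors/acceptors, rotatable bonds,
    logP, oral bioavailability) come from upstream predictors; the three
    categorical toxicity/absorption classes default to ``"unknown"`` when
    the source table lacks the column.
    """

    component_id: str
    name: str
    mw: float
    hdon: int
    hacc: int
    rbn: int
    logp: float
    ob: float
    herbs: frozenset[str] = frozenset()
    smiles: str | None = None
    gi_class: str = "unknown"
    herg_class: str = "unknown"
    carcinogenicity: str = "unknown"

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.component_id}: mw must be > 0, got {self.mw}")
        for attr in ("hdon", "hacc", "rbn"):
            val = getattr(self, attr)
            if not isinstance(val, int) or val < 0:
                raise ValueError(f"{self.component_id}: {attr} must be a non-negative integer, got {val!r}")
        if self.ob < 0:
            raise ValueError(f"{self.component_id}: ob must be >= 0, got {self.ob}")
        if self.gi_class not in _GI_LEVELS:
            raise ValueError(f"{self.component_id}: bad gi_class {self.gi_class!r}")
        if self.herg_class not in _HERG_LEVELS:
            raise ValueError(f"{self.component_id}: bad herg_class {self.herg_class!r}")
        if self.carcinogenicity not in _CARC_LEVELS:
            raise ValueError(f"{self.component_id}: bad carcinogenicity {self.carcinogenicity!r}")


@dataclass(frozen=True)
class PathogenicGene:
    """A disease gene with its literature-evidence count (NV >= 1)."""

    symbol: str
    nv: int

    def __post_init__(self) -> None:
        if self.nv < 1:
            raise ValueError(f"{self.symbol}: nv must be >= 1, got {self.nv}")


@dataclass
class GeneSetCollection:
    """Named collection of gene sets (e.g. pathways or GO terms).

    ``sets`` maps term id -> (description, frozenset of gene symbols).
    """

    name: str
    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, term: str) -> bool:
        return term in self.sets

    def genes(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)

    def terms_per_gene(self) -> dict[str, int]:
        """Number of terms each gene appears in (genes absent -> not listed)."""
        counts: dict[str, int] = {}
        for _, members in self.sets.values():
            for g in members:
                counts[g] = counts.get(g, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# component tables

_REQUIRED_COMPONENT_COLS = ("component_id", "mw", "hdon", "hacc", "rbn", "logp", "ob")
_CLASS_COLS = ("gi_class", "herg_class", "carcinogenicity")


def read_component_table(path: str | Path) -> list[ComponentRecord]:
    """Read a component property TSV into records, preserving row order.

    Required columns: component_id, mw, hdon, hacc, rbn, logp, ob.
    Optional: name, herbs (semicolon-separated codes), smiles, gi_class,
    herg_class, carcinogenicity.  Missing class columns become "unknown".
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in _REQUIRED_COMPONENT_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    dup = df["component_id"][df["component_id"].duplicated()].tolist()
    if dup:
        raise SchemaError(f"{path}: duplicated component_id(s): {sorted(set(dup))}")

    records: list[ComponentRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row = row._asdict()
        try:
            numeric = {
                "mw": float(row["mw"]),
                "logp": float(row["logp"]),
                "ob": float(row["ob"]),
                "hdon": int(float(row["hdon"])),
                "hacc": int(float(row["hacc"])),
                "rbn": int(float(row["rbn"])),
            }
        except ValueError as exc:
            raise SchemaError(f"{path}: line {i}: non-numeric property ({exc})") from exc
        herbs = frozenset(h for h in row.get("herbs", "").split(";") if h)
        classes = {c: (row.get(c) or "unknown") for c in _CLASS_COLS}
        records.append(
            ComponentRecord(
                component_id=row["component_id"],
                name=row.get("name", row["component_id"]) or row["component_id"],
                herbs=herbs,
                smiles=row.get("smiles") or None,
                **numeric,
                **classes,
            )
        )
    return records


def write_component_table(path: str | Path, records: Iterable[ComponentRecord]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "component_id": r.component_id,
                "name": r.name,
                "herbs": ";".join(sorted(r.herbs)),
                "smiles": r.smiles or "",
                "mw": r.mw,
                "hdon": r.hdon,
                "hacc": r.hacc,
                "rbn": r.rbn,
                "logp": r.logp,
                "ob": r.ob,
                "gi_class": r.gi_class,
                "herg_class": r.herg_class,
                "carcinogenicity": r.carcinogenicity,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pathogenic gene tables


def read_pathogenic_table(path: str | Path) -> list[PathogenicGene]:
    """Read (symbol, nv) rows; symbols must be unique, nv >= 1."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    for col in ("symbol", "nv"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column: {col}")
    dup = df["symbol"][df["symbol"].duplicated()].tolist()
    if dup:
        raise SchemaError(f"{path}: duplicated gene symbol(s): {sorted(set(dup))}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            nv = int(float(row.nv))
        except ValueError as exc:
            raise SchemaError(f"{path}: line {i}: non-numeric nv {row.nv!r}") from exc
        out.append(PathogenicGene(symbol=row.symbol, nv=nv))
    return out


def write_pathogenic_table(path: str | Path, genes: Iterable[PathogenicGene]) -> None:
    pd.DataFrame([{"symbol": g.symbol, "nv": g.nv} for g in genes]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: term <tab> description <tab> gene1 <tab> gene2 ...

    Duplicate genes within a line are dropped; duplicate term ids are an
    error.  Lines with fewer than three fields are malformed.
    """
    path = Path(path)
    coll = GeneSetCollection(name=name or path.stem)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            term, desc, *genes = fields
            if term in coll.sets:
                raise SchemaError(f"{path}: line {lineno}: duplicate term id {term!r}")
            members = frozenset(g for g in genes if g)
            if not members:
                raise SchemaError(f"{path}: line {lineno}: term {term!r} has no genes")
            coll.sets[term] = (desc, members)
    return coll


def write_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, (desc, members) in collection.sets.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# edge tables

_EDGE_COLS = ("source", "target", "etype", "weight")


def read_edges(path: str | Path, allow_self_loops: bool = False) -> pd.DataFrame:
    """Read an edge TSV into a canonical (source, target, etype, weight) frame.

    Two id columns minimum; a third column is the edge type, a fourth the
    non-negative weight (default 1.0).  Headerless SIF-style files are
    accepted when the first line does not start with 'source'.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
    has_header = first.split("\t")[0] in ("source", "src")
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        dtype=str,
        keep_default_na=False,
        comment="#",
    )
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: edge table needs at least two columns")
    df = df.iloc[:, :4]
    df.columns = _EDGE_COLS[: df.shape[1]]
    if "etype" not in df.columns:
        df["etype"] = ""
    if "weight" not in df.columns:
        df["weight"] = "1"
    try:
        df["weight"] = df["weight"].replace("", "1").astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric edge weight ({exc})") from exc
    if (df["weight"] < 0).any():
        bad = df.index[df["weight"] < 0][0] + (2 if has_header else 1)
        raise SchemaError(f"{path}: line {bad}: negative edge weight")
    if (df["source"] == "").any() or (df["target"] == "").any():
        bad = df.index[(df["source"] == "") | (df["target"] == "")][0] + (2 if has_header else 1)
        raise SchemaError(f"{path}: line {bad}: empty endpoint id")
    if not allow_self_loops:
        loops = df["source"] == df["target"]
        if loops.any():
            bad = df.index[loops][0] + (2 if has_header else 1)
            raise SchemaError(f"{path}: line {bad}: self-loop not permitted")
    return df.reset_index(drop=True)


def write_edges(path: str | Path, table: pd.DataFrame) -> None:
    df = table.copy()
    for col, default in (("etype", ""), ("weight", 1.0)):
        if col not in df.columns:
            df[col] = default
    df[list(_EDGE_COLS)].to_csv(path, sep="\t", index=False)


def dump_json(path: str | Path, obj: Mapping) -> None:
    """Serialize a result mapping to pretty, stable JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
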