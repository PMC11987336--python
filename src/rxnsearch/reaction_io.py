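"""Parsing, validation, decomposition and persistence of reaction records.

The interchange format is the three-part reaction SMILES
``reactants>reagents>products`` with "."-separated molecules per role.
Molecules are canonicalized on ingest (atom maps stripped) so equality
checks are notation independent. Raw records with several products are
decomposed into single-product records sharing the same reactants.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionError",
    "RawReaction",
    "ReactionRecord",
    "canonicalize_smiles",
    "parse_reaction",
    "decompose_multiproduct",
    "reaction_smiles",
    "read_dataset",
    "write_dataset",
]


class ReactionError(ValueError):
    """Raised for malformed reaction strings or invalid molecules."""


def canonicalize_smiles(smiles: str, strip_atom_maps: bool = True) -> str:
    """Return the canonical SMILES of a single molecule token.

    Atom-map numbers are stripped by default since the embedding method
    never uses them and patent-derived files frequently carry them.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ReactionError(f"unparsable molecule notation: {smiles!r}")
    if strip_atom_maps:
        for atom in mol.GetAtoms():
            atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


@dataclass
class RawReaction:
    """A reaction as written, possibly with several products."""

    products: list[str]
    reactants: list[str]
    reagents: list[str] = field(default_factory=list)
    attributes: dict[str, float] = field(default_factory=dict)
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.products:
            raise ReactionError("a reaction must have at least one product")


@dataclass
class ReactionRecord:
    """One single-product reaction with optional reagents and attributes."""

    record_id: str
    product: str
    reactants: list[str]
    reagents: list[str] = field(default_factory=list)
    attributes: dict[str, float] = field(default_factory=dict)
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if "." in self.product:
            raise ReactionError(
                f"record {self.record_id}: product must be a single connected "
                f"species, got {self.product!r}"
            )
        if not self.reactants:
            raise ReactionError(f"record {self.record_id}: reactants must be non-empty")
        for key, val in self.attributes.items():
            if not math.isfinite(float(val)):
                raise ReactionError(
                    f"record {self.record_id}: attribute {key!r} is not finite"
                )


def parse_reaction(line: str, attributes: dict[str, float] | None = None) -> RawReaction:
    """Parse a three-part reaction SMILES line into a :class:`RawReaction`."""
    parts = line.split(">")
    if len(parts) != 3:
        raise ReactionError(
            f"expected 'reactants>reagents>products' with two '>' separators, "
            f"got {line!r}"
        )
    reactant_part, reagent_part, product_part = (p.strip() for p in parts)
    if not product_part:
        raise ReactionError(f"reaction has no product: {line!r}")
    if not reactant_part:
        raise ReactionError(f"reaction has no reactants: {line!r}")

    def split_role(part: str) -> list[str]:
        return [canonicalize_smiles(tok) for tok in part.split(".") if tok]

    return RawReaction(
        products=split_role(product_part),
        reactants=split_role(reactant_part),
        reagents=split_role(reagent_part),
        attributes=dict(attributes or {}),
    )


def decompose_multiproduct(raw: RawReaction, parent_id: str = "rxn") -> list[ReactionRecord]:
    """Split a multi-product reaction into single-product records.

    Each output record keeps the full reactant/reagent/attribute payload.
    Duplicate products yield duplicate records (dedup is a user-level
    filter). Derived ids are deterministic: ``<parent>_p<index>`` when more
    than one product is present, the parent id unchanged otherwise.
    """
    records = []
    single = len(raw.products) == 1
    for i, product in enumerate(raw.products):
        records.append(
            ReactionRecord(
                record_id=parent_id if single else f"{parent_id}_p{i}",
                product=product,
                reactants=list(raw.reactants),
                reagents=list(raw.reagents),
                attributes=dict(raw.attributes),
                meta=dict(raw.meta),
            )
        )
    return records


def reaction_smiles(record: ReactionRecord) -> str:
    """Serialize a record back to 'reactants>reagents>product' notation."""
    return ">".join(
        [".".join(record.reactants), ".".join(record.reagents), record.product]
    )


_RESERVED_COLUMNS = {"id", "reaction"}


def _parse_row(
    reaction: str,
    row_id: str,
    attributes: dict[str, float],
    meta: dict[str, str],
) -> list[ReactionRecord]:
    raw = parse_reaction(reaction, attributes)
    raw.meta.update(meta)
    return decompose_multiproduct(raw, parent_id=row_id)


def read_dataset(
    path: str | Path,
    format: str | None = None,
    reaction_column: str = "reaction",
    attribute_columns: Sequence[str] | None = None,
    skip_bad_rows: bool = False,
) -> list[ReactionRecord]:
    """Load reaction records from CSV or JSONL.

    CSV rows need a reaction-SMILES column; all other columns except ``id``
    and ``meta_*`` are treated as numeric attributes unless
    ``attribute_columns`` narrows the schema. JSONL rows may carry either a
    ``reaction`` string or explicit product/reactants/reagents arrays.
    Failures are fail-fast by default; with ``skip_bad_rows`` offending rows
    are dropped with a logged warning naming the row number.
    """
    path = Path(path)
    fmt = format or ("jsonl" if path.suffix in {".jsonl", ".json"} else "csv")
    records: list[ReactionRecord] = []
    errors: list[str] = []

    def handle(row_no: int, fn):
        try:
            records.extend(fn())
        except (ReactionError, KeyError, TypeError) as exc:
            msg = f"row {row_no}: {exc}"
            if skip_bad_rows:
                logger.warning("skipping %s", msg)
            else:
                errors.append(msg)

    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            if reaction_column not in reader.fieldnames:
                raise ReactionError(
                    f"missing required column {reaction_column!r} in {path}"
                )
            attr_cols = (
                list(attribute_columns)
                if attribute_columns is not None
                else [
                    c
                    for c in reader.fieldnames
                    if c not in _RESERVED_COLUMNS
                    and c != reaction_column
                    and not c.startswith("meta_")
                ]
            )
            for row_no, row in enumerate(reader):
                def parse_csv_row(row=row, row_no=row_no):
                    attrs = {
                        c: float(row[c])
                        for c in attr_cols
                        if row.get(c) not in (None, "")
                    }
                    meta = {
                        c[len("meta_"):]: row[c]
                        for c in row
                        if c.startswith("meta_") and row[c] not in (None, "")
                    }
                    row_id = row.get("id") or f"row{row_no}"
                    return _parse_row(row[reaction_column], row_id, attrs, meta)

                handle(row_no, parse_csv_row)
    elif fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for row_no, line in enumerate(fh):
                if not line.strip():
                    continue

                def parse_json_row(line=line, row_no=row_no):
                    obj = json.loads(line)
                    attrs = {k: float(v) for k, v in obj.get("attributes", {}).items()}
                    meta = {str(k): str(v) for k, v in obj.get("meta", {}).items()}
                    row_id = str(obj.get("id", f"row{row_no}"))
                    if "reaction" in obj:
                        return _parse_row(obj["reaction"], row_id, attrs, meta)
                    raw = RawReaction(
                        products=[canonicalize_smiles(s) for s in obj["products"]],
                        reactants=[canonicalize_smiles(s) for s in obj["reactants"]],
                        reagents=[canonicalize_smiles(s) for s in obj.get("reagents", [])],
                        attributes=attrs,
                        meta=meta,
                    )
                    return decompose_multiproduct(raw, parent_id=row_id)

                handle(row_no, parse_json_row)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if errors:
        raise ReactionError(
            f"{len(errors)} bad row(s) in {path}: " + "; ".join(errors[:5])
        )
    return records


def write_dataset(
    records: Iterable[ReactionRecord], path: str | Path, format: str | None = None
) -> None:
    """Persist records to CSV or JSONL so that :func:`read_dataset` round-trips."""
    path = Path(path)
    fmt = format or ("jsonl" if path.suffix in {".jsonl", ".json"} else "csv")
    records = list(records)
    if fmt == "csv":
        attr_cols = sorted({k for r in records for k in r.attributes})
        meta_cols = sorted({k for r in records for k in r.meta})
        fields = ["id", "reaction"] + attr_cols + [f"meta_{k}" for k in meta_cols]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for r in records:
                row = {"id": r.record_id, "reaction": reaction_smiles(r)}
                row.update({k: repr(v) for k, v in r.attributes.items()})
                row.update({f"meta_{k}": v for k, v in r.meta.items()})
                writer.writerow(row)
    elif fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in records:
                fh.write(
                    json.dumps(
                        {
                            "id": r.record_id,
                            "products": [r.product],
                            "reactants": r.reactants,
                            "reagents": r.reagents,
                            "attributes": r.attributes,
                            "meta": r.meta,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown format {fmt!r}")
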