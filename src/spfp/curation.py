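"""Compound curation and activity-class assembly.

Activity classes are target-labeled sets of unique compounds with
numerically specified pIC50 values. The filters implemented here mirror
standard bioactivity-database hygiene: exact-relation measurements
against high-confidence direct targets, drug-like molecular weight,
potency inside the range the potency module can encode, removal of
records carrying inactivity/artifact annotations, and a PAINS
substructure screen.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

__all__ = [
    "CompoundRecord",
    "ActivityClass",
    "CurationRules",
    "CurationError",
    "filter_records",
    "deduplicate",
    "assemble_classes",
    "records_from_csv",
    "records_to_csv",
]

EXCLUDED_COMMENTS = frozenset(
    {
        "inactive",
        "not active",
        "inconclusive",
        "potential transcription error",
        "pan assay interference compounds",
    }
)


class CurationError(ValueError):
    """A record lacks a field required by an enabled curation rule."""


@dataclass
class CompoundRecord:
    """One measured compound-target data point."""

    compound_id: str
    smiles: str | None
    pIC50: float
    target_id: str
    mw: float | None = None
    relation: str = "="
    comment: str = ""
    confidence: int = 9
    fingerprint: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if not math.isfinite(self.pIC50):
            raise ValueError(f"pIC50 must be finite, got {self.pIC50}")


@dataclass
class CurationRules:
    """Thresholds and switches for :func:`filter_records`.

    Defaults are the standard curation values: relation '=', target
    confidence 9, MW < 1000 Da, pIC50 in [5, 11], annotation exclusion
    list, PAINS screen on. ``exclude_targets`` supports caller-supplied
    anti-target lists; ``extra_predicate`` is a hook for additional
    liability rules (record -> True to keep).
    """

    relation: str | None = "="
    confidence: int | None = 9
    max_mw: float | None = 1000.0
    min_pIC50: float | None = 5.0
    max_pIC50: float | None = 11.0
    excluded_comments: frozenset[str] = EXCLUDED_COMMENTS
    pains: bool = True
    exclude_targets: frozenset[str] = frozenset()
    extra_predicate: Callable[[CompoundRecord], bool] | None = None

    #: how to merge pIC50 values of duplicate (compound, target) pairs
    duplicate_policy: str = "mean"


_pains_catalog: FilterCatalog | None = None


def _get_pains_catalog() -> FilterCatalog:
    global _pains_catalog
    if _pains_catalog is None:
        params = FilterCatalogParams()
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
        _pains_catalog = FilterCatalog(params)
    return _pains_catalog


def _mol_of(rec: CompoundRecord) -> Chem.Mol:
    if rec.smiles is None:
        raise CurationError(
            f"record {rec.compound_id}: 'smiles' required for the enabled rule"
        )
    mol = Chem.MolFromSmiles(rec.smiles)
    if mol is None:
        raise CurationError(f"record {rec.compound_id}: unparseable SMILES {rec.smiles!r}")
    return mol


def filter_records(
    records: Sequence[CompoundRecord],
    rules: CurationRules | None = None,
) -> tuple[list[CompoundRecord], dict[str, int]]:
    """Apply the curation filters, preserving input order.

    Returns the retained records together with a per-rule rejection
    count (a record is charged to the first rule it violates, in the
    order: relation, confidence, mw, range, comment, target, pains,
    extra). Molecular weight is computed from the SMILES when absent.
    """
    rules = rules or CurationRules()
    kept: list[CompoundRecord] = []
    rejected: Counter[str] = Counter()

    for rec in records:
        if rules.relation is not None and rec.relation != rules.relation:
            rejected["relation"] += 1
            continue
        if rules.confidence is not None and rec.confidence != rules.confidence:
            rejected["confidence"] += 1
            continue
        if rules.max_mw is not None:
            mw = rec.mw
            if mw is None:
                mw = Descriptors.MolWt(_mol_of(rec))
                rec = replace(rec, mw=mw)
            if not mw < rules.max_mw:
                rejected["mw"] += 1
                continue
        if rules.min_pIC50 is not None and rec.pIC50 < rules.min_pIC50:
            rejected["range"] += 1
            continue
        if rules.max_pIC50 is not None and rec.pIC50 > rules.max_pIC50:
            rejected["range"] += 1
            continue
        if rec.comment and rec.comment.strip().lower() in rules.excluded_comments:
            rejected["comment"] += 1
            continue
        if rec.target_id in rules.exclude_targets:
            rejected["target"] += 1
            continue
        if rules.pains and _get_pains_catalog().HasMatch(_mol_of(rec)):
            rejected["pains"] += 1
            continue
        if rules.extra_predicate is not None and not rules.extra_predicate(rec):
            rejected["extra"] += 1
            continue
        kept.append(rec)

    return kept, dict(rejected)


_DUP_POLICIES = {
    "mean": np.mean,
    "median": np.median,
    "max": np.max,
}


def deduplicate(
    records: Sequence[CompoundRecord], policy: str = "mean"
) -> list[CompoundRecord]:
    """Collapse duplicate (compound_id, target_id) pairs to one record.

    Disagreeing pIC50 values are merged per ``policy`` (mean | median |
    max). The first occurrence supplies all other fields; first-seen
    order is preserved.
    """
    if policy not in _DUP_POLICIES:
        raise ValueError(f"unknown duplicate policy {policy!r}")
    merge = _DUP_POLICIES[policy]

    groups: dict[tuple[str, str], list[CompoundRecord]] = {}
    for rec in records:
        groups.setdefault((rec.compound_id, rec.target_id), []).append(rec)

    out = []
    for recs in groups.values():
        if len(recs) == 1:
            out.append(recs[0])
        else:
            out.append(replace(recs[0], pIC50=float(merge([r.pIC50 for r in recs]))))
    return out


@dataclass
class ActivityClass:
    """Curated compounds active against one target."""

    target_id: str
    records: list[CompoundRecord]
    target_name: str = ""

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate compound_id in class {self.target_id}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def potencies(self) -> np.ndarray:
        return np.array([r.pIC50 for r in self.records], dtype=float)

    @property
    def compound_ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def fingerprints(self) -> np.ndarray:
        """(n, 2048) binary structure-module matrix.

        Uses stored fingerprints when present, otherwise computes ECFP4
        from the SMILES.
        """
        from .encoding import structure_fingerprint

        rows = []
        for rec in self.records:
            if rec.fingerprint is not None:
                rows.append(np.asarray(rec.fingerprint, dtype=np.uint8))
            else:
                rows.append(structure_fingerprint(rec.smiles))
        return np.vstack(rows)

    def subset(self, indices: Iterable[int]) -> "ActivityClass":
        recs = [self.records[i] for i in indices]
        return ActivityClass(self.target_id, recs, self.target_name)


def assemble_classes(records: Sequence[CompoundRecord]) -> list[ActivityClass]:
    """Group filtered, deduplicated records into per-target classes.

    Classes are ordered by first appearance of the target; record
    totals are conserved.
    """
    by_target: dict[str, list[CompoundRecord]] = {}
    for rec in records:
        by_target.setdefault(rec.target_id, []).append(rec)
    return [ActivityClass(tid, recs) for tid, recs in by_target.items()]


def records_from_csv(path) -> list[CompoundRecord]:
    """Read compound records from CSV.

    Required columns: compound_id, smiles, pIC50, target_id. Optional:
    mw, relation, comment, confidence, fingerprint (hex-packed bits).
    """
    df = pd.read_csv(path, dtype={"compound_id": str, "target_id": str})
    missing = {"compound_id", "smiles", "pIC50", "target_id"} - set(df.columns)
    if missing:
        raise CurationError(f"CSV missing required columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        fp = None
        if hasattr(row, "fingerprint") and isinstance(row.fingerprint, str):
            raw = np.frombuffer(bytes.fromhex(row.fingerprint), dtype=np.uint8)
            fp = np.unpackbits(raw).astype(np.uint8)
        smiles = row.smiles if isinstance(row.smiles, str) else None
        records.append(
            CompoundRecord(
                compound_id=row.compound_id,
                smiles=smiles,
                pIC50=float(row.pIC50),
                target_id=row.target_id,
                mw=float(row.mw) if hasattr(row, "mw") and pd.notna(row.mw) else None,
                relation=getattr(row, "relation", "="),
                comment=str(getattr(row, "comment", "") or ""),
                confidence=int(getattr(row, "confidence", 9)),
                fingerprint=fp,
            )
        )
    return records


def records_to_csv(records: Sequence[CompoundRecord], path) -> None:
    rows = []
    for rec in records:
        fp_hex = None
        if rec.fingerprint is not None:
            fp_hex = np.packbits(np.asarray(rec.fingerprint, dtype=np.uint8)).tobytes().hex()
        rows.append(
            {
                "compound_id": rec.compound_id,
                "smiles": rec.smiles,
                "pIC50": rec.pIC50,
                "target_id": rec.target_id,
                "mw": rec.mw,
                "relation": rec.relation,
                "comment": rec.comment,
                "confidence": rec.confidence,
                "fingerprint": fp_hex,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
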