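"""ICD-9 / phecode / concept-string vocabularies.

ICD-9 billing codes attached to clinical visits are grouped into phecodes
(hierarchical phenotype groups, ~1,865 in the standard map) which serve as the
unit of association testing.  Each phecode also carries a set of exclusion
phecodes: control subjects carrying any of them are removed before matching,
so that near-miss presentations of the index disease do not contaminate the
control arm.  A second pair of tables links ICD-9 codes to UMLS concept
identifiers (CUIs) and CUIs to synonymous surface strings; the union of
strings under a phecode is what gets searched in the literature.

This module ships small toy versions of all three tables (``phedas.data``) so
the full pipeline runs without the licensed UMLS metathesaurus or the full
phecode map distribution; loaders accept any file in the same CSV dialects.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import VocabFormatError, VocabIntegrityError

__all__ = [
    "normalize_icd9",
    "PhecodeMap",
    "ConceptStrings",
    "load_phecode_map",
    "map_visits",
    "load_concept_tables",
    "expand_concept_strings",
    "toy_data_path",
]

# dotted canonical forms: numeric 1-3 digit root, V + 2 digits, E + 3 digits,
# each with an optional 1-2 digit decimal part
_ICD9_RE = re.compile(r"^(E\d{3}|V\d{2}|\d{1,3})(\.\d{1,2})?$")


def normalize_icd9(code: str) -> str:
    """Return the canonical dotted form of an ICD-9 code.

    Both dialects found in real extracts are accepted: dotted ("331.0") and
    dotless ("3310", dot implied after the third character, fourth for
    E-codes).  Normalization is idempotent.

    Raises
    ------
    VocabFormatError
        If the code cannot be interpreted as an ICD-9 code.
    """
    raw = str(code).strip().upper()
    if not raw:
        raise VocabFormatError("empty ICD-9 code")
    if "." not in raw:
        root_len = 4 if raw.startswith("E") else 3
        if len(raw) > root_len:
            raw = raw[:root_len] + "." + raw[root_len:]
    raw = raw.rstrip(".")
    if not _ICD9_RE.match(raw):
        raise VocabFormatError(f"malformed ICD-9 code: {code!r}")
    return raw


def _parse_exclude_range(spec: str) -> list[tuple[float, float]]:
    """Parse 'lo-hi[;lo-hi...]' phecode intervals into numeric ranges."""
    ranges = []
    for part in str(spec).replace(",", ";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo, hi = part.split("-", 1)
        else:
            lo = hi = part
        try:
            ranges.append((float(lo), float(hi)))
        except ValueError as exc:
            raise VocabFormatError(f"bad exclude_range field: {spec!r}") from exc
    return ranges


@dataclass
class PhecodeMap:
    """Many-to-one mapping of ICD-9 codes to phecodes with exclusion ranges.

    Attributes
    ----------
    code_to_phecode : dict
        Normalized ICD-9 code -> phecode string.
    labels : dict
        Phecode -> human-readable label.
    exclude_ranges : dict
        Phecode -> list of (lo, hi) numeric phecode intervals whose carriers
        must be dropped from the control pool.  Defaults to the degenerate
        range covering the phecode itself when a file provides none.
    problems : list
        Human-readable reports of malformed rows skipped during loading
        (never silently dropped).
    """

    code_to_phecode: dict[str, str] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)
    exclude_ranges: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    problems: list[str] = field(default_factory=list)

    @property
    def phecodes(self) -> set[str]:
        return set(self.code_to_phecode.values())

    def children(self, phecode: str) -> list[str]:
        """ICD-9 codes grouped under ``phecode``, sorted."""
        return sorted(c for c, p in self.code_to_phecode.items() if p == phecode)

    def exclusion_set(self, phecode: str, candidates: Iterable[str]) -> set[str]:
        """Phecodes among ``candidates`` excluded for ``phecode`` controls.

        Always contains ``phecode`` itself when present in candidates; the
        phecode itself is excluded even if no range was provided.
        """
        ranges = list(self.exclude_ranges.get(phecode, []))
        try:
            own = float(phecode)
            ranges.append((own, own))
        except ValueError:
            pass
        out = {phecode} & set(candidates)
        for cand in candidates:
            try:
                val = float(cand)
            except ValueError:
                continue
            if any(lo <= val <= hi for lo, hi in ranges):
                out.add(cand)
        return out

    def to_csv(self, path: str | Path) -> None:
        """Write the map back in the canonical CSV dialect (round-trips)."""
        rows = []
        for icd9 in sorted(self.code_to_phecode):
            phe = self.code_to_phecode[icd9]
            rng = ";".join(
                f"{lo:g}-{hi:g}" for lo, hi in self.exclude_ranges.get(phe, [])
            )
            rows.append(
                {
                    "icd9": icd9,
                    "phecode": phe,
                    "phecode_label": self.labels.get(phe, ""),
                    "exclude_range": rng,
                }
            )
        pd.DataFrame(rows, columns=["icd9", "phecode", "phecode_label", "exclude_range"]).to_csv(
            path, index=False
        )


@dataclass
class ConceptStrings:
    """Literature search strings for one phecode, via its ICD-9 codes' CUIs."""

    phecode: str
    concept_ids: set[str] = field(default_factory=set)
    strings: set[str] = field(default_factory=set)


def load_phecode_map(path: str | Path) -> PhecodeMap:
    """Load an ICD-9 -> phecode map from CSV.

    Required columns: ``icd9``, ``phecode``, ``phecode_label``; optional
    ``exclude_range`` holds dash-separated phecode intervals (semicolon
    separated when several).  Malformed rows are collected on
    ``PhecodeMap.problems`` and warned about, never silently dropped.

    Raises
    ------
    VocabFormatError
        Missing required columns.
    VocabIntegrityError
        The same ICD-9 code mapped to two different phecodes.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"icd9", "phecode", "phecode_label"}
    missing = required - set(df.columns)
    if missing:
        raise VocabFormatError(f"{path}: missing required columns {sorted(missing)}")

    pmap = PhecodeMap()
    for i, row in df.iterrows():
        try:
            icd9 = normalize_icd9(row["icd9"])
        except VocabFormatError as exc:
            pmap.problems.append(f"row {i}: {exc}")
            continue
        phe = str(row["phecode"]).strip()
        if not phe:
            pmap.problems.append(f"row {i}: empty phecode for {icd9}")
            continue
        prior = pmap.code_to_phecode.get(icd9)
        if prior is not None and prior != phe:
            raise VocabIntegrityError(
                f"{path}: ICD-9 {icd9} mapped to both {prior} and {phe}"
            )
        pmap.code_to_phecode[icd9] = phe
        if row["phecode_label"]:
            pmap.labels[phe] = row["phecode_label"]
        if "exclude_range" in df.columns and str(row["exclude_range"]).strip():
            pmap.exclude_ranges[phe] = _parse_exclude_range(row["exclude_range"])
    if pmap.problems:
        warnings.warn(
            f"{path}: skipped {len(pmap.problems)} malformed rows "
            f"(see PhecodeMap.problems)",
            stacklevel=2,
        )
    return pmap


def map_visits(
    visits: pd.DataFrame, pmap: PhecodeMap
) -> tuple[pd.DataFrame, int]:
    """Convert visit-level ICD-9 codes to phecodes.

    Parameters
    ----------
    visits : DataFrame
        Columns ``subject_id``, ``age_at_visit``, ``icd9``.
    pmap : PhecodeMap

    Returns
    -------
    (mapped, n_unmapped)
        ``mapped`` has columns ``subject_id``, ``age_at_visit``, ``phecode``,
        one row per input row whose (normalized) code is in the map;
        ``n_unmapped`` counts the rest, so mapped rows + unmapped = input rows.
    """
    if len(visits) == 0:
        return (
            pd.DataFrame(columns=["subject_id", "age_at_visit", "phecode"]),
            0,
        )
    codes = visits["icd9"].astype(str).map(
        lambda c: _normalize_or_none(c)
    )
    phecodes = codes.map(pmap.code_to_phecode)
    keep = phecodes.notna()
    mapped = visits.loc[keep, ["subject_id", "age_at_visit"]].copy()
    mapped["phecode"] = phecodes[keep]
    return mapped.reset_index(drop=True), int((~keep).sum())


def _normalize_or_none(code: str):
    try:
        return normalize_icd9(code)
    except VocabFormatError:
        return None


def load_concept_tables(
    icd9_cui_path: str | Path, cui_string_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the ICD-9->CUI and CUI->string tables (CSV, one row per link)."""
    icd9_cui = pd.read_csv(icd9_cui_path, dtype=str)
    cui_strings = pd.read_csv(cui_string_path, dtype=str)
    for df, req, path in (
        (icd9_cui, {"icd9", "cui"}, icd9_cui_path),
        (cui_strings, {"cui", "string"}, cui_string_path),
    ):
        missing = req - set(df.columns)
        if missing:
            raise VocabFormatError(f"{path}: missing required columns {sorted(missing)}")
    icd9_cui = icd9_cui.copy()
    icd9_cui["icd9"] = icd9_cui["icd9"].map(normalize_icd9)
    return icd9_cui, cui_strings


def expand_concept_strings(
    phecode: str,
    pmap: PhecodeMap,
    icd9_to_cui: pd.DataFrame,
    cui_to_strings: pd.DataFrame,
) -> ConceptStrings:
    """Collect every literature search string under a phecode.

    The phecode's ICD-9 children are mapped to their CUIs and all strings of
    those CUIs are pooled, lowercased and deduplicated.  A phecode with no
    ICD-9 children in the concept table yields an empty set with a warning.
    """
    children = set(pmap.children(phecode))
    cuis = set(
        icd9_to_cui.loc[icd9_to_cui["icd9"].isin(children), "cui"].dropna()
    )
    strings = {
        s.strip().lower()
        for s in cui_to_strings.loc[cui_to_strings["cui"].isin(cuis), "string"].dropna()
        if s.strip()
    }
    if not cuis:
        warnings.warn(
            f"phecode {phecode}: no concept identifiers found; empty string set",
            stacklevel=2,
        )
    return ConceptStrings(phecode=phecode, concept_ids=cuis, strings=strings)


def toy_data_path(name: str) -> Path:
    """Path to one of the bundled toy vocabulary/fixture CSVs."""
    return Path(resources.files("phedas.data") / name)
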