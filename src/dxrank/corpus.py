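"""Reading, cleaning and canonicalizing diagnosis corpora.

A corpus is one row per diagnosed case: a single disease label and an
ordered, comma-separated symptom string. Order matters downstream — the
first three symptoms are by convention the *main symptoms* and may receive
extra weight during scoring. Cleaning follows the conventions of clinical
free-text records: comma-only segmentation (both ASCII ``,`` and fullwidth
``，``), synonym normalization through a term lexicon, and exclusion of rows
carrying more than one diagnosis.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

__all__ = [
    "MedicalRecord",
    "TermLexicon",
    "Unmapped",
    "LexiconConflictError",
    "IngestReport",
    "segment_symptoms",
    "normalize_term",
    "load_lexicon",
    "load_records",
    "write_records",
]

_COMMA_RE = re.compile("[,，]")

#: Policies for symptom tokens that the lexicon does not know.
UNMAPPED_POLICIES = ("keep_raw", "drop_token", "drop_record")


def segment_symptoms(raw_text: str) -> list[str]:
    """Split a free-text symptom string into an ordered token list.

    Splits on ASCII and fullwidth commas only (no other punctuation),
    trims surrounding whitespace, drops empty tokens, and removes
    duplicates keeping the first occurrence, so the main-symptom
    positions of the input are preserved.
    """
    seen: set[str] = set()
    out: list[str] = []
    for tok in _COMMA_RE.split(raw_text or ""):
        tok = tok.strip()
        if tok and tok not in seen:
            seen.add(tok)
            out.append(tok)
    return out


@dataclass(frozen=True)
class Unmapped:
    """Marker for a token absent from the lexicon; carries the original text."""

    token: str


class LexiconConflictError(ValueError):
    """A surface term maps to two different canonical terms."""


def _fold(term: str) -> str:
    """Lookup key: trim, collapse internal whitespace, casefold."""
    return " ".join(term.split()).casefold()


class TermLexicon:
    """Synonym → canonical term mapping used to standardize symptom and
    disease names before counting.

    Canonical terms always map to themselves (idempotent closure), and no
    surface term may map to two different canonical terms. Lookup is exact
    after whitespace trimming and case folding — no fuzzy matching.
    """

    def __init__(
        self,
        entries: Mapping[str, str] | Iterable[tuple[str, str]] = (),
        categories: Mapping[str, str] | None = None,
    ) -> None:
        pairs = entries.items() if isinstance(entries, Mapping) else entries
        self._map: dict[str, str] = {}
        self._surface: dict[str, str] = {}  # folded key -> original surface, for errors
        for surface, canonical in pairs:
            self._add(surface, canonical)
            self._add(canonical, canonical)
        self.categories: dict[str, str] = dict(categories or {})

    def _add(self, surface: str, canonical: str) -> None:
        key = _fold(surface)
        prev = self._map.get(key)
        if prev is not None and prev != canonical:
            raise LexiconConflictError(
                f"surface term {self._surface[key]!r} maps to both "
                f"{prev!r} and {canonical!r}"
            )
        self._map[key] = canonical
        self._surface.setdefault(key, surface.strip())

    def canonical(self, token: str) -> Union[str, Unmapped]:
        hit = self._map.get(_fold(token))
        return hit if hit is not None else Unmapped(token)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, token: str) -> bool:
        return _fold(token) in self._map


def normalize_term(token: str, lexicon: TermLexicon) -> Union[str, Unmapped]:
    """Map a token to its canonical term, or an :class:`Unmapped` marker.

    Unmapped tokens are never silently dropped here — callers decide the
    policy and account for them.
    """
    return lexicon.canonical(token)


@dataclass(frozen=True)
class MedicalRecord:
    """One diagnosed case: a canonical disease label and an ordered,
    duplicate-free list of canonical symptom terms.

    Positions 1–3 of ``symptoms`` carry the main-symptom convention.
    """

    disease: str
    symptoms: tuple[str, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.symptoms:
            raise ValueError("record must have at least one symptom")
        if len(set(self.symptoms)) != len(self.symptoms):
            raise ValueError("record symptoms must be duplicate-free")


@dataclass
class IngestReport:
    """Accounting of what corpus loading kept and excluded.

    Invariant: ``n_rows - n_records`` equals the sum of the exclusion
    counters.
    """

    n_rows: int = 0
    n_records: int = 0
    n_multi_diagnosis: int = 0
    n_empty_symptoms: int = 0
    n_malformed: int = 0
    n_unmapped_dropped: int = 0
    unmapped_tokens: Counter = field(default_factory=Counter)

    @property
    def n_excluded(self) -> int:
        return (
            self.n_multi_diagnosis
            + self.n_empty_symptoms
            + self.n_malformed
            + self.n_unmapped_dropped
        )

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_records": self.n_records,
            "n_multi_diagnosis": self.n_multi_diagnosis,
            "n_empty_symptoms": self.n_empty_symptoms,
            "n_malformed": self.n_malformed,
            "n_unmapped_dropped": self.n_unmapped_dropped,
            "unmapped_tokens": dict(self.unmapped_tokens),
        }


def load_lexicon(path: str | Path) -> TermLexicon:
    """Load a term lexicon from a TSV with header columns ``surface``,
    ``canonical`` and optional ``category`` (tagging the canonical term).
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    categories: dict[str, str] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"surface", "canonical"} <= set(
            reader.fieldnames
        ):
            raise ValueError(
                f"{path}: lexicon needs 'surface' and 'canonical' columns"
            )
        for row in reader:
            surface = (row.get("surface") or "").strip()
            canonical = (row.get("canonical") or "").strip()
            if not surface or not canonical:
                continue
            pairs.append((surface, canonical))
            cat = (row.get("category") or "").strip()
            if cat:
                categories[canonical] = cat
    return TermLexicon(pairs, categories)


def _iter_rows(path: Path) -> Iterator[dict]:
    """Yield raw row dicts from TSV (header: disease/symptoms[/source_id])
    or JSON-lines files with the same keys."""
    with path.open(encoding="utf-8", newline="") as fh:
        first = fh.read(1)
        fh.seek(0)
        if path.suffix in {".jsonl", ".ndjson"} or first == "{":
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    yield json.loads(line)
                except json.JSONDecodeError:
                    yield {"__malformed__": line}
        else:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or not {"disease", "symptoms"} <= set(
                reader.fieldnames
            ):
                raise ValueError(
                    f"{path}: record file needs 'disease' and 'symptoms' columns"
                )
            yield from reader


def load_records(
    path: str | Path,
    lexicon: TermLexicon | None = None,
    policy: str = "keep_raw",
) -> tuple[list[MedicalRecord], IngestReport]:
    """Read, clean and canonicalize a diagnosis corpus.

    Rows whose diagnosis field contains more than one comma-separated
    disease are excluded (single-label corpus). Symptom strings are
    comma-segmented and normalized through the lexicon; the fate of tokens
    the lexicon does not know is set by ``policy``:

    ``keep_raw``
        the original token becomes a term as-is (default: the model is
        meant to accept natural-language symptom words);
    ``drop_token``
        the token is removed from the record;
    ``drop_record``
        the whole row is excluded.

    Unmapped tokens are counted in the report under every policy. Records
    left with zero symptoms are excluded. Returns the surviving records
    and an :class:`IngestReport`.
    """
    if policy not in UNMAPPED_POLICIES:
        raise ValueError(f"policy must be one of {UNMAPPED_POLICIES}")
    lexicon = lexicon if lexicon is not None else TermLexicon()
    path = Path(path)
    report = IngestReport()
    records: list[MedicalRecord] = []
    for rownum, row in enumerate(_iter_rows(path), start=1):
        report.n_rows += 1
        if "__malformed__" in row:
            report.n_malformed += 1
            continue
        disease_field = (row.get("disease") or "").strip()
        symptom_field = row.get("symptoms") or ""
        disease_tokens = segment_symptoms(disease_field)
        if not disease_tokens:
            report.n_malformed += 1
            continue
        if len(disease_tokens) > 1:
            report.n_multi_diagnosis += 1
            continue
        hit = normalize_term(disease_tokens[0], lexicon)
        disease = hit if isinstance(hit, str) else hit.token

        symptoms: list[str] = []
        seen: set[str] = set()
        drop_this_record = False
        for tok in segment_symptoms(symptom_field):
            norm = normalize_term(tok, lexicon)
            if isinstance(norm, Unmapped):
                report.unmapped_tokens[norm.token] += 1
                if policy == "drop_token":
                    continue
                if policy == "drop_record":
                    drop_this_record = True
                    break
                term = norm.token
            else:
                term = norm
            if term not in seen:
                seen.add(term)
                symptoms.append(term)
        if drop_this_record:
            report.n_unmapped_dropped += 1
            continue
        if not symptoms:
            report.n_empty_symptoms += 1
            continue
        source_id = str(row.get("source_id") or f"row{rownum}")
        records.append(MedicalRecord(disease, tuple(symptoms), source_id))
        report.n_records += 1
    return records, report


def write_records(path: str | Path, records: Sequence[MedicalRecord]) -> None:
    """Write records as the standard TSV (disease, comma-joined symptoms,
    source_id)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["disease", "symptoms", "source_id"])
        for r in records:
            writer.writerow([r.disease, ", ".join(r.symptoms), r.source_id])
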