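"""Longitudinal EHR cohort I/O: load, validate, filter, encode, split.

The interchange format is one patient per JSONL line::

    {"subject_id": "10001217",
     "visits": [{"hadm_id": "24597018",
                 "diagnoses": ["3240", ...],
                 "procedures": ["139", ...],
                 "medications": ["HydrALAzine", ...]}, ...]}

Codes are opaque strings; whether medications are ATC level-4 classes or
level-5 chemical subgroups is a cohort-level flag only.  Real extracts from
credentialed sources are converted to this format externally.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)


class CodeLevel(str, Enum):
    ATC04 = "ATC04"
    ATC05 = "ATC05"


class CohortError(ValueError):
    """Validation failure on a cohort or one of its records."""


@dataclass
class Visit:
    """One clinical visit: sets of diagnosis, procedure and medication codes.

    Diagnoses must be non-empty — a coded visit without any diagnosis carries
    no signal for the recommender and is rejected at load time.
    """

    subject_id: str
    visit_index: int
    diagnoses: frozenset[str]
    procedures: frozenset[str]
    medications: frozenset[str]
    hadm_id: str | None = None

    def __post_init__(self):
        if self.visit_index < 0:
            raise CohortError(f"negative visit_index for {self.subject_id}")
        if not self.diagnoses:
            raise CohortError(
                f"visit {self.visit_index} of subject {self.subject_id} "
                "has no diagnoses")


@dataclass
class Cohort:
    patients: list[tuple[str, list[Visit]]]
    level: CodeLevel = CodeLevel.ATC04

    def __post_init__(self):
        ids = [sid for sid, _ in self.patients]
        if len(set(ids)) != len(ids):
            dupes = [s for s, c in Counter(ids).items() if c > 1]
            raise CohortError(f"duplicate subject_ids: {dupes}")
        for sid, visits in self.patients:
            idxs = [v.visit_index for v in visits]
            if idxs != sorted(idxs) or len(set(idxs)) != len(idxs):
                raise CohortError(f"visit_index not strictly increasing for {sid}")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_visits(self) -> int:
        return sum(len(v) for _, v in self.patients)

    def __eq__(self, other):
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.level == other.level and self.patients == other.patients

    def all_codes(self, kind: str) -> Counter:
        """Occurrence counts (one per visit) of codes of `kind`."""
        c: Counter = Counter()
        for _, visits in self.patients:
            for v in visits:
                c.update(getattr(v, kind))
        return c


@dataclass
class Vocabulary:
    """Contiguous code↔index bijections for the three entity types."""

    diag_index: dict[str, int]
    proc_index: dict[str, int]
    med_index: dict[str, int]

    def __post_init__(self):
        for name in ("diag_index", "proc_index", "med_index"):
            idx = getattr(self, name)
            if sorted(idx.values()) != list(range(len(idx))):
                raise CohortError(f"{name} indices not contiguous from 0")

    @property
    def n_diag(self) -> int:
        return len(self.diag_index)

    @property
    def n_proc(self) -> int:
        return len(self.proc_index)

    @property
    def n_med(self) -> int:
        return len(self.med_index)

    def decode(self, kind: str, indices) -> set[str]:
        rev = {i: c for c, i in getattr(self, f"{kind}_index").items()}
        return {rev[i] for i in indices}


@dataclass
class MultiHotTriple:
    """Binary indicator vectors for one visit over the three vocabularies."""

    v_d: np.ndarray
    v_p: np.ndarray
    v_m: np.ndarray

    def active(self, kind: str) -> np.ndarray:
        return np.flatnonzero({"d": self.v_d, "p": self.v_p, "m": self.v_m}[kind])


def _parse_codes(raw, what: str, lineno: int) -> frozenset[str]:
    if not isinstance(raw, list) or any(not isinstance(c, str) or not c for c in raw):
        raise CohortError(f"line {lineno}: {what} must be a list of non-empty strings")
    if len(set(raw)) != len(raw):
        logger.warning("line %d: duplicate %s codes deduplicated", lineno, what)
    return frozenset(raw)


def load_cohort(path: str | Path, level: CodeLevel | str = CodeLevel.ATC04) -> Cohort:
    """Read a cohort from JSONL; validates per-record invariants."""
    level = CodeLevel(level)
    patients: list[tuple[str, list[Visit]]] = []
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise CohortError(f"line {lineno}: malformed JSON ({e})") from e
            sid = rec.get("subject_id")
            if not isinstance(sid, str) or not sid:
                raise CohortError(f"line {lineno}: missing subject_id")
            raw_visits = rec.get("visits")
            if not isinstance(raw_visits, list) or not raw_visits:
                raise CohortError(f"line {lineno}: patient {sid} has zero visits")
            visits = []
            for i, rv in enumerate(raw_visits):
                visits.append(Visit(
                    subject_id=sid,
                    visit_index=i,
                    diagnoses=_parse_codes(rv.get("diagnoses", []), "diagnosis", lineno),
                    procedures=_parse_codes(rv.get("procedures", []), "procedure", lineno),
                    medications=_parse_codes(rv.get("medications", []), "medication", lineno),
                    hadm_id=rv.get("hadm_id"),
                ))
            patients.append((sid, visits))
    if not patients:
        logger.warning("loaded empty cohort from %s", path)
    return Cohort(patients=patients, level=level)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sid, visits in cohort.patients:
            rec = {"subject_id": sid, "visits": [
                {"hadm_id": v.hadm_id,
                 "diagnoses": sorted(v.diagnoses),
                 "procedures": sorted(v.procedures),
                 "medications": sorted(v.medications)} for v in visits]}
            fh.write(json.dumps(rec) + "\n")


def filter_cohort(cohort: Cohort, min_visits: int = 2,
                  min_med_freq: int = 0) -> Cohort:
    """Drop rare medications, then short patients.

    The medication-frequency filter runs first: medications occurring fewer
    than `min_med_freq` times across the whole cohort are removed from every
    visit, and only then are patients with fewer than `min_visits` visits
    dropped.  The order is fixed so the operation is idempotent.
    """
    if min_visits < 1:
        raise ValueError("min_visits must be >= 1")
    if min_med_freq < 0:
        raise ValueError("min_med_freq must be >= 0")
    med_counts = cohort.all_codes("medications")
    keep = {c for c, n in med_counts.items() if n >= min_med_freq}
    patients = []
    for sid, visits in cohort.patients:
        if len(visits) < min_visits:
            continue
        new_visits = [
            Visit(subject_id=v.subject_id, visit_index=v.visit_index,
                  diagnoses=v.diagnoses, procedures=v.procedures,
                  medications=v.medications & keep, hadm_id=v.hadm_id)
            for v in visits]
        patients.append((sid, new_visits))
    if not patients:
        raise CohortError("cohort empty after filtering "
                          f"(min_visits={min_visits}, min_med_freq={min_med_freq})")
    return Cohort(patients=patients, level=cohort.level)


def build_vocabulary(cohort: Cohort) -> Vocabulary:
    """Index every distinct code; indices follow sorted code order."""
    if not cohort.patients:
        raise CohortError("cannot build a vocabulary from an empty cohort")
    kinds = {"diagnoses": set(), "procedures": set(), "medications": set()}
    for _, visits in cohort.patients:
        for v in visits:
            for kind in kinds:
                kinds[kind] |= getattr(v, kind)
    for kind, codes in kinds.items():
        if not codes:
            logger.warning("vocabulary has zero %s codes", kind)
    return Vocabulary(
        diag_index={c: i for i, c in enumerate(sorted(kinds["diagnoses"]))},
        proc_index={c: i for i, c in enumerate(sorted(kinds["procedures"]))},
        med_index={c: i for i, c in enumerate(sorted(kinds["medications"]))},
    )


def encode_visit(visit: Visit, vocab: Vocabulary) -> MultiHotTriple:
    """Multi-hot encode one visit against the vocabulary."""
    def enc(codes, index, n, what):
        v = np.zeros(n, dtype=np.int8)
        for c in codes:
            if c not in index:
                raise KeyError(f"unknown {what} code {c!r}")
            v[index[c]] = 1
        return v

    return MultiHotTriple(
        v_d=enc(visit.diagnoses, vocab.diag_index, vocab.n_diag, "diagnosis"),
        v_p=enc(visit.procedures, vocab.proc_index, vocab.n_proc, "procedure"),
        v_m=enc(visit.medications, vocab.med_index, vocab.n_med, "medication"),
    )


def encode_patient(visits: list[Visit], vocab: Vocabulary) -> list[MultiHotTriple]:
    return [encode_visit(v, vocab) for v in visits]


def split_cohort(cohort: Cohort, ratio: tuple[int, int, int] = (23, 16, 16),
                 seed: int = 0) -> tuple[Cohort, Cohort, Cohort]:
    """Patient-level train/validation/test partition.

    Sizes are proportional to `ratio` with the remainder assigned to the
    training part; deterministic for a fixed seed.
    """
    if any(r <= 0 for r in ratio):
        raise ValueError("ratio components must be positive")
    n = cohort.n_patients
    if n < 3:
        raise CohortError("need at least 3 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    total = sum(ratio)
    n_val = (n * ratio[1]) // total
    n_test = (n * ratio[2]) // total
    n_train = n - n_val - n_test
    parts = (order[:n_train], order[n_train:n_train + n_val],
             order[n_train + n_val:])
    return tuple(
        Cohort(patients=[cohort.patients[i] for i in sorted(part)],
               level=cohort.level)
        for part in parts)


def load_ddi_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read contraindicated medication pairs from a 2-column CSV
    (header ``code_a,code_b``)."""
    pairs = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if [h.strip().lower() for h in header[:2]] != ["code_a", "code_b"]:
            raise CohortError("DDI CSV must have header 'code_a,code_b'")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cols = [c.strip() for c in line.split(",")]
            if len(cols) < 2 or not cols[0] or not cols[1]:
                raise CohortError(f"DDI CSV line {lineno}: need two codes")
            pairs.append((cols[0], cols[1]))
    return pairs


def write_ddi_pairs(pairs: list[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("code_a,code_b\n")
        for a, b in pairs:
            fh.write(f"{a},{b}\n")
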