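"""Canonical permanent-dentition data model and surface-level record I/O.

The permanent dentition is represented in two-digit FDI notation: the first
digit is the quadrant (1 = upper right, 2 = upper left, 3 = lower left,
4 = lower right) and the second is the position within the quadrant (1 at the
midline through 8, the third molar).  All indices in this package are computed
over the 28 *index teeth* (positions 1-7 in every quadrant); third molars
(18, 28, 38, 48) are representable so that raw exports can be ingested, but
they never contribute to any phenotype.

Surfaces follow the DMFS convention: anterior teeth (incisors and canines,
positions 1-3) carry four scorable surfaces (mesial, distal, buccal/facial,
lingual/palatal); posterior teeth (premolars and molars, positions 4-7) add
the occlusal surface for five.  The index-surface universe therefore has
12 x 4 + 16 x 5 = 128 surfaces.

Surface caries status is harmonized at a moderate lesion threshold: when the
input carries ICDAS severity scores (integers 0-6), scores at or above the
threshold (default 3, visible enamel breakdown) are coded DECAYED and scores
below it SOUND.  A missing tooth is missing as a whole: MISSING_TOOTH applies
uniformly to every surface of the tooth.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical surface ordering used everywhere (occlusal first, then mesial,
#: distal, buccal, lingual).
SURFACE_ORDER: tuple[str, ...] = ("O", "M", "D", "B", "L")

#: The 28 index teeth in FDI notation, ascending numeric order.
INDEX_TEETH: tuple[int, ...] = tuple(
    sorted(q * 10 + p for q in (1, 2, 3, 4) for p in range(1, 8))
)

THIRD_MOLARS: frozenset[int] = frozenset({18, 28, 38, 48})

_VALID_FDI: frozenset[int] = frozenset(INDEX_TEETH) | THIRD_MOLARS

N_INDEX_TEETH = 28
N_INDEX_SURFACES = 128


class SurfaceStatus(str, enum.Enum):
    """Status of a single tooth surface after harmonization."""

    SOUND = "SOUND"
    DECAYED = "DECAYED"
    FILLED = "FILLED"
    MISSING_TOOTH = "MISSING"
    EXCLUDED = "EXCLUDED"

    @property
    def affected(self) -> bool:
        """True for statuses that count toward caries-experience indices."""
        return self in (
            SurfaceStatus.DECAYED,
            SurfaceStatus.FILLED,
            SurfaceStatus.MISSING_TOOTH,
        )


def quadrant(fdi: int) -> int:
    return fdi // 10


def position(fdi: int) -> int:
    return fdi % 10


def is_third_molar(fdi: int) -> bool:
    return fdi in THIRD_MOLARS


def is_index_tooth(fdi: int) -> bool:
    return fdi in _VALID_FDI and fdi not in THIRD_MOLARS


def is_anterior(fdi: int) -> bool:
    """Incisors and canines (positions 1-3): no occlusal surface."""
    return position(fdi) <= 3


def surfaces_for_tooth(fdi: int) -> tuple[str, ...]:
    """Scorable surfaces of a tooth in canonical order.

    Anterior teeth have {M, D, B, L}; posterior teeth add O.  Third molars
    follow the same convention but are never part of the index universe.
    """
    if fdi not in _VALID_FDI:
        raise ValueError(f"not a permanent-tooth FDI code: {fdi}")
    if is_anterior(fdi):
        return ("M", "D", "B", "L")
    return SURFACE_ORDER


def enumerate_index_surfaces() -> list[tuple[int, str]]:
    """All 128 index (tooth, surface) pairs, ordered by FDI code then O,M,D,B,L."""
    return [(t, s) for t in INDEX_TEETH for s in surfaces_for_tooth(t)]


_INDEX_SURFACES: tuple[tuple[int, str], ...] = tuple(enumerate_index_surfaces())
_INDEX_SURFACE_SET: frozenset[tuple[int, str]] = frozenset(_INDEX_SURFACES)


def universal_to_fdi(universal: int) -> int:
    """Map Universal (1-32) tooth numbering to FDI two-digit notation.

    Universal counts 1-16 across the maxilla from the upper-right third molar
    to the upper-left third molar, then 17-32 across the mandible from the
    lower-left third molar back to the lower-right third molar.
    """
    if not 1 <= universal <= 32:
        raise ValueError(f"Universal tooth number out of range: {universal}")
    if universal <= 8:
        return 10 + (9 - universal)
    if universal <= 16:
        return 20 + (universal - 8)
    if universal <= 24:
        return 30 + (25 - universal)
    return 40 + (universal - 24)


@dataclass
class SubjectRecord:
    """One person's surface-level odontogram plus basic demographics.

    ``surfaces`` maps every index (tooth, surface) pair to its status; after
    ingestion the map covers the full 128-surface universe.
    """

    subject_id: str
    age: float
    sex: str  # "female", "male", or "unknown"
    surfaces: dict[tuple[int, str], SurfaceStatus] = field(default_factory=dict)

    def status(self, fdi: int, surface: str) -> SurfaceStatus:
        return self.surfaces[(fdi, surface)]

    def tooth_statuses(self, fdi: int) -> list[SurfaceStatus]:
        return [self.surfaces[(fdi, s)] for s in surfaces_for_tooth(fdi)]

    def is_tooth_missing(self, fdi: int) -> bool:
        return all(s is SurfaceStatus.MISSING_TOOTH for s in self.tooth_statuses(fdi))


def make_uniform_record(
    subject_id: str,
    status: SurfaceStatus = SurfaceStatus.SOUND,
    age: float = 50.0,
    sex: str = "unknown",
) -> SubjectRecord:
    """A record with every index surface set to ``status`` (convenience)."""
    return SubjectRecord(
        subject_id=subject_id,
        age=age,
        sex=sex,
        surfaces={key: status for key in _INDEX_SURFACES},
    )


@dataclass(frozen=True)
class Violation:
    """One invariant violation found in a record or input row."""

    code: str
    subject_id: str
    tooth: int | None = None
    surface: str | None = None
    message: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"subject {self.subject_id}"
        if self.tooth is not None:
            where += f", tooth {self.tooth}"
        if self.surface is not None:
            where += f", surface {self.surface}"
        return f"[{self.code}] {where}: {self.message}"


class SurfaceDataError(ValueError):
    """Raised when an input file contains invalid surface-level data."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        lines = "\n".join(str(v) for v in violations[:50])
        more = "" if len(violations) <= 50 else f"\n... and {len(violations) - 50} more"
        super().__init__(f"{len(violations)} surface-data error(s):\n{lines}{more}")


def validate_subject_record(record: SubjectRecord) -> list[Violation]:
    """Check a record against the type invariants; violations are data, not exceptions."""
    out: list[Violation] = []
    sid = record.subject_id
    for key in record.surfaces:
        if key not in _INDEX_SURFACE_SET:
            out.append(
                Violation("unexpected_surface", sid, key[0], key[1],
                          "surface outside the 128-surface index universe")
            )
    covered = set(record.surfaces)
    for tooth, surf in _INDEX_SURFACES:
        if (tooth, surf) not in covered:
            out.append(
                Violation("uncovered_surface", sid, tooth, surf,
                          "index surface has no status")
            )
    for tooth in INDEX_TEETH:
        statuses = [
            record.surfaces[(tooth, s)]
            for s in surfaces_for_tooth(tooth)
            if (tooth, s) in record.surfaces
        ]
        n_missing = sum(s is SurfaceStatus.MISSING_TOOTH for s in statuses)
        if 0 < n_missing < len(statuses):
            out.append(
                Violation("partial_missing_tooth", sid, tooth, None,
                          "MISSING_TOOTH on some but not all surfaces")
            )
    if record.age < 0:
        out.append(Violation("negative_age", sid, message=f"age {record.age} < 0"))
    if record.sex not in ("female", "male", "unknown"):
        out.append(Violation("invalid_sex", sid, message=f"sex {record.sex!r}"))
    return out


_STATUS_TOKENS = {s.value: s for s in SurfaceStatus}
_STATUS_TOKENS["MISSING_TOOTH"] = SurfaceStatus.MISSING_TOOTH

CSV_COLUMNS = ["subject_id", "age", "sex", "tooth_fdi", "surface", "status"]


def _parse_status(
    raw: str, icdas_threshold: int
) -> SurfaceStatus | None:
    """Map a status token or ICDAS integer to a SurfaceStatus, or None if unparsable."""
    token = raw.strip().upper()
    if token in _STATUS_TOKENS:
        return _STATUS_TOKENS[token]
    try:
        icdas = int(token)
    except ValueError:
        return None
    if not 0 <= icdas <= 6:
        return None
    return SurfaceStatus.DECAYED if icdas >= icdas_threshold else SurfaceStatus.SOUND


def read_surface_csv(
    path,
    icdas_threshold: int = 3,
    unlisted_policy: str = "error",
    tooth_numbering: str = "fdi",
) -> list[SubjectRecord]:
    """Read a long-format surface CSV into fully populated subject records.

    Parameters
    ----------
    path
        CSV with header ``subject_id,age,sex,tooth_fdi,surface,status``;
        ``status`` is either a token (SOUND, DECAYED, FILLED, MISSING,
        EXCLUDED) or an integer ICDAS score 0-6.
    icdas_threshold
        ICDAS scores at or above this value are coded DECAYED, below SOUND.
    unlisted_policy
        What to do with index surfaces that have no row: ``"error"`` (default;
        forces cohorts to be explicit), ``"sound"`` (compact exports listing
        only affected surfaces), or ``"excluded"``.
    tooth_numbering
        ``"fdi"`` (default) or ``"universal"`` (1-32, converted on ingestion).

    Third-molar rows are accepted and dropped (a count is logged).  A MISSING
    status on any surface propagates to the whole tooth; a tooth with both
    MISSING and non-MISSING rows is reported as an error.
    """
    if unlisted_policy not in ("sound", "excluded", "error"):
        raise ValueError(f"unknown unlisted_policy: {unlisted_policy!r}")
    if tooth_numbering not in ("fdi", "universal"):
        raise ValueError(f"unknown tooth_numbering: {tooth_numbering!r}")

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SurfaceDataError(
            [Violation("missing_column", "<file>", message=f"missing column {c!r}")
             for c in missing_cols]
        )

    violations: list[Violation] = []
    # subject -> (tooth, surface) -> status; plus demographics
    per_subject: dict[str, dict[tuple[int, str], SurfaceStatus]] = {}
    demographics: dict[str, tuple[float, str]] = {}
    missing_teeth: dict[str, set[int]] = {}
    third_molar_rows = 0

    for row in df.itertuples(index=False):
        sid = str(row.subject_id)
        try:
            tooth = int(str(row.tooth_fdi).strip())
        except ValueError:
            violations.append(
                Violation("malformed_tooth", sid, None, None,
                          f"tooth code {row.tooth_fdi!r} is not an integer")
            )
            continue
        if tooth_numbering == "universal":
            try:
                tooth = universal_to_fdi(tooth)
            except ValueError:
                violations.append(
                    Violation("malformed_tooth", sid, tooth, None,
                              "Universal tooth number out of 1-32")
                )
                continue
        if tooth not in _VALID_FDI:
            violations.append(
                Violation("malformed_tooth", sid, tooth, None,
                          "not a permanent-tooth FDI code")
            )
            continue

        if sid not in demographics:
            try:
                age = float(row.age)
            except ValueError:
                violations.append(
                    Violation("malformed_age", sid, message=f"age {row.age!r}"))
                age = float("nan")
            sex = str(row.sex).strip().lower()
            if sex not in ("female", "male", "unknown"):
                sex = "unknown"
            demographics[sid] = (age, sex)
            per_subject[sid] = {}
            missing_teeth[sid] = set()

        if is_third_molar(tooth):
            third_molar_rows += 1
            continue

        surface = str(row.surface).strip().upper()
        if surface not in surfaces_for_tooth(tooth):
            violations.append(
                Violation("invalid_surface", sid, tooth, surface,
                          f"surface {surface!r} not valid for tooth {tooth}")
            )
            continue
        status = _parse_status(str(row.status), icdas_threshold)
        if status is None:
            violations.append(
                Violation("malformed_status", sid, tooth, surface,
                          f"status {row.status!r} is neither a token nor ICDAS 0-6")
            )
            continue

        key = (tooth, surface)
        prior = per_subject[sid].get(key)
        if prior is not None and prior is not status:
            violations.append(
                Violation("conflicting_status", sid, tooth, surface,
                          f"{prior.value} vs {status.value}")
            )
            continue
        per_subject[sid][key] = status
        if status is SurfaceStatus.MISSING_TOOTH:
            missing_teeth[sid].add(tooth)

    if third_molar_rows:
        logger.info("dropped %d third-molar row(s)", third_molar_rows)

    records: list[SubjectRecord] = []
    for sid, surfaces in per_subject.items():
        age, sex = demographics[sid]
        # propagate whole-tooth missingness; listed non-missing surfaces on a
        # missing tooth are contradictions
        for tooth in missing_teeth[sid]:
            for s in surfaces_for_tooth(tooth):
                prior = surfaces.get((tooth, s))
                if prior is not None and prior is not SurfaceStatus.MISSING_TOOTH:
                    violations.append(
                        Violation("partial_missing_tooth", sid, tooth, s,
                                  f"tooth marked MISSING but surface is {prior.value}")
                    )
                surfaces[(tooth, s)] = SurfaceStatus.MISSING_TOOTH
        # fill unlisted surfaces per policy
        for key in _INDEX_SURFACES:
            if key not in surfaces:
                if unlisted_policy == "sound":
                    surfaces[key] = SurfaceStatus.SOUND
                elif unlisted_policy == "excluded":
                    surfaces[key] = SurfaceStatus.EXCLUDED
                else:
                    violations.append(
                        Violation("uncovered_surface", sid, key[0], key[1],
                                  "no row for this index surface "
                                  "(unlisted_policy='error')")
                    )
        records.append(SubjectRecord(sid, age, sex, surfaces))

    if violations:
        raise SurfaceDataError(violations)
    return records


def write_surface_csv(records: list[SubjectRecord], path) -> None:
    """Write records in the long-format dialect, deterministic row order.

    Rows are ordered by subject id, then FDI code, then canonical surface
    order, so that read -> write -> read round-trips bit-exactly.
    """
    rows = []
    for rec in sorted(records, key=lambda r: r.subject_id):
        for tooth, surf in _INDEX_SURFACES:
            rows.append(
                (rec.subject_id, rec.age, rec.sex, tooth, surf,
                 rec.surfaces[(tooth, surf)].value)
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
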