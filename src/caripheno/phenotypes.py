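"""Tier-1 and tier-2 caries phenotypes: case status and the DMF index family.

Tier 1 is binary case status: any decayed, missing, or filled tooth or
surface (DMFT/DMFS > 0).  Tier 2 is the quantitative DMF family.  Teeth
missing due to *all* causes are counted in the M component, which turns DMFS
into a "tooth morbidity" index (written DM_T_FS at the surface level and
DM_T_FT at the tooth level): an edentulous person scores the maximum (128
surfaces / 28 teeth) on both.

Tooth-level classification follows the standard epidemiologic precedence
MISSING > DECAYED > FILLED, so a tooth with both decayed and filled surfaces
counts once, as decayed.  EXCLUDED surfaces contribute nothing and do not
shrink the fixed 128-surface / 28-tooth denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dentition import (
    INDEX_TEETH,
    N_INDEX_SURFACES,
    N_INDEX_TEETH,
    SubjectRecord,
    SurfaceStatus,
    surfaces_for_tooth,
)


@dataclass(frozen=True)
class IndexCounts:
    """Per-subject DMF component counts at surface and tooth level."""

    d_surfaces: int
    f_surfaces: int
    m_surfaces: int
    d_teeth: int
    f_teeth: int
    m_teeth: int

    @property
    def dmfs_morbidity(self) -> int:
        """Surface-level tooth-morbidity index (DM_T_FS), range 0-128."""
        return self.d_surfaces + self.f_surfaces + self.m_surfaces

    @property
    def dmft_morbidity(self) -> int:
        """Tooth-level tooth-morbidity index (DM_T_FT), range 0-28."""
        return self.d_teeth + self.f_teeth + self.m_teeth

    @property
    def n_teeth_present(self) -> int:
        return N_INDEX_TEETH - self.m_teeth

    @property
    def edentulous(self) -> bool:
        return self.m_teeth == N_INDEX_TEETH


def index_counts(record: SubjectRecord) -> IndexCounts:
    """Compute DMF surface and tooth counts for one validated record.

    A MISSING tooth contributes all of its 4 or 5 surfaces to m_surfaces and
    one to m_teeth.  Each tooth counts at most once toward the tooth-level
    index (precedence MISSING > DECAYED > FILLED).
    """
    d_s = f_s = m_s = d_t = f_t = m_t = 0
    for tooth in INDEX_TEETH:
        statuses = [record.surfaces[(tooth, s)] for s in surfaces_for_tooth(tooth)]
        if all(s is SurfaceStatus.MISSING_TOOTH for s in statuses):
            m_s += len(statuses)
            m_t += 1
            continue
        n_dec = sum(s is SurfaceStatus.DECAYED for s in statuses)
        n_fil = sum(s is SurfaceStatus.FILLED for s in statuses)
        d_s += n_dec
        f_s += n_fil
        if n_dec:
            d_t += 1
        elif n_fil:
            f_t += 1
    counts = IndexCounts(d_s, f_s, m_s, d_t, f_t, m_t)
    assert 0 <= counts.dmfs_morbidity <= N_INDEX_SURFACES
    return counts


def case_status(record: SubjectRecord, level: str = "surface") -> bool:
    """Binary caries case status: DMFS > 0 (surface) or DMFT > 0 (tooth).

    The two levels agree on every record (a positive surface count implies a
    positive tooth count and vice versa); both are exposed because cohorts
    report one or the other.
    """
    counts = index_counts(record)
    if level == "surface":
        return counts.dmfs_morbidity > 0
    if level == "tooth":
        return counts.dmft_morbidity > 0
    raise ValueError(f"unknown level: {level!r}")


PHENOTYPE_COLUMNS = [
    "subject_id", "age", "sex", "case_status", "dmft", "dmfs",
    "d_surf", "f_surf", "m_surf", "n_teeth", "edentulous",
]


def phenotype_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Per-subject phenotype table (one row per person, CLI output schema)."""
    rows = []
    for rec in records:
        c = index_counts(rec)
        rows.append(
            (rec.subject_id, rec.age, rec.sex, int(c.dmfs_morbidity > 0),
             c.dmft_morbidity, c.dmfs_morbidity, c.d_surfaces, c.f_surfaces,
             c.m_surfaces, c.n_teeth_present, int(c.edentulous))
        )
    return pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
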