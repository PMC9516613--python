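"""Tier-3 "precision" phenotypes: tooth-surface caries-cluster scores.

Tooth surfaces do not decay independently: occlusal pits and fissures of
molars are far more susceptible than, say, lower incisor surfaces.  A small
number of surface *clusters* with shared susceptibility capture this
structure, and a subject's score on a cluster is the proportion of its
surfaces that are affected (decayed, filled, or on a missing tooth):

    score_c = (# affected surfaces in cluster c) / |cluster c|

so each score lies in [0, 1] and the scores decompose the surface-level
morbidity index exactly: sum_c score_c * |cluster_c| = DM_T_FS.

The builtin default map partitions the 128 index surfaces into the five
classically named clusters (sizes 16, 24, 48, 16, 24):

1. molar pits and fissures
2. lower anterior teeth
3. molar smooth surfaces, premolar pits, and proximal surfaces
4. maxillary incisors
5. maxillary canines and premolar smooth surfaces

The exact assignment shipped here is a documented reconstruction from those
cluster names; any published mapping can be substituted via a 128-row config
file without code changes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dentition import (
    SubjectRecord,
    enumerate_index_surfaces,
    is_anterior,
    position,
    quadrant,
    surfaces_for_tooth,
)
from .phenotypes import index_counts

N_CLUSTERS = 5

DEFAULT_CLUSTER_LABELS: dict[int, str] = {
    1: "molar pits and fissures",
    2: "lower anterior teeth",
    3: "molar smooth surfaces, premolar pits, and proximal surfaces",
    4: "maxillary incisors",
    5: "maxillary canines and premolar smooth surfaces",
}


class ClusterMapError(ValueError):
    """Raised when a surface-to-cluster assignment is not a valid partition."""


@dataclass(frozen=True)
class ClusterMap:
    """A partition of the 128 index surfaces into named clusters."""

    name: str
    assignment: dict[tuple[int, str], int]
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        universe = enumerate_index_surfaces()
        errors = []
        seen = set(self.assignment)
        for key in universe:
            if key not in seen:
                errors.append(f"missing surface {key[0]}-{key[1]}")
        extra = seen - set(universe)
        for key in sorted(extra):
            errors.append(f"surface outside index universe: {key[0]}-{key[1]}")
        bad = {v for v in self.assignment.values() if not isinstance(v, int)}
        if bad:
            errors.append(f"non-integer cluster labels: {sorted(map(str, bad))}")
        if errors:
            raise ClusterMapError(f"invalid cluster map {self.name!r}: " + "; ".join(errors))
        for c in self.cluster_ids:
            if not self.members(c):
                raise ClusterMapError(f"cluster {c} is empty")

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def members(self, cluster: int) -> list[tuple[int, str]]:
        return [k for k in enumerate_index_surfaces() if self.assignment[k] == cluster]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for v in self.assignment.values():
            out[v] = out.get(v, 0) + 1
        return dict(sorted(out.items()))

    def label(self, cluster: int) -> str:
        return self.labels.get(cluster, f"cluster {cluster}")

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, s, self.assignment[(t, s)]) for t, s in enumerate_index_surfaces()]
        return pd.DataFrame(rows, columns=["tooth_fdi", "surface", "cluster"])


def default_cluster_map() -> ClusterMap:
    """The builtin five-cluster assignment reconstructed from the cluster names.

    Sizes are (16, 24, 48, 16, 24) for clusters 1-5.
    """
    assignment: dict[tuple[int, str], int] = {}
    for tooth, surf in enumerate_index_surfaces():
        q, p = quadrant(tooth), position(tooth)
        upper = q in (1, 2)
        if is_anterior(tooth):
            if not upper:
                c = 2  # lower incisors and canines
            elif p <= 2:
                c = 4  # maxillary incisors
            else:
                c = 5  # maxillary canines
        elif p in (4, 5):  # premolars
            c = 3 if surf in ("O", "M", "D") else 5
        else:  # molars (positions 6, 7)
            if surf == "O":
                c = 1
            elif surf in ("M", "D"):
                c = 3
            elif surf == "B":
                c = 3 if upper else 1
            else:  # lingual
                c = 1 if upper else 3
        assignment[(tooth, surf)] = c
    return ClusterMap("default", assignment, dict(DEFAULT_CLUSTER_LABELS))


def load_cluster_map(source: str | Path | None = None) -> ClusterMap:
    """Load a cluster map from CSV/JSON, or return the builtin default.

    CSV schema: ``tooth_fdi,surface,cluster`` with exactly one row per index
    surface.  JSON schema: ``{"name": ..., "labels": {...},
    "assignment": [[tooth, surface, cluster], ...]}``.  Non-partitions
    (duplicate or missing surfaces, empty clusters) are rejected.
    """
    if source is None or source == "default":
        return default_cluster_map()
    path = Path(source)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        triples = [(int(t), str(s).upper(), int(c)) for t, s, c in payload["assignment"]]
        name = payload.get("name", path.stem)
        labels = {int(k): str(v) for k, v in payload.get("labels", {}).items()}
    else:
        df = pd.read_csv(path)
        required = {"tooth_fdi", "surface", "cluster"}
        if not required.issubset(df.columns):
            raise ClusterMapError(
                f"cluster map {path} must have columns {sorted(required)}")
        triples = [
            (int(r.tooth_fdi), str(r.surface).upper(), int(r.cluster))
            for r in df.itertuples(index=False)
        ]
        name, labels = path.stem, {}
    assignment: dict[tuple[int, str], int] = {}
    for tooth, surf, cluster in triples:
        key = (tooth, surf)
        if key in assignment:
            raise ClusterMapError(f"duplicate surface {tooth}-{surf}")
        assignment[key] = cluster
    return ClusterMap(name, assignment, labels)


def score_subject(record: SubjectRecord, cluster_map: ClusterMap) -> np.ndarray:
    """Per-cluster proportion of affected surfaces, ordered by cluster id."""
    ids = cluster_map.cluster_ids
    affected = {c: 0 for c in ids}
    totals = cluster_map.sizes()
    for key, cluster in cluster_map.assignment.items():
        if record.surfaces[key].affected:
            affected[cluster] += 1
    return np.array([affected[c] / totals[c] for c in ids])


def score_frame(records: list[SubjectRecord], cluster_map: ClusterMap) -> pd.DataFrame:
    """Per-subject cluster scores (columns c1..c5 for the default map)."""
    ids = cluster_map.cluster_ids
    rows = [(rec.subject_id, *score_subject(rec, cluster_map)) for rec in records]
    return pd.DataFrame(rows, columns=["subject_id"] + [f"c{c}" for c in ids])


@dataclass(frozen=True)
class CohortClusterSummary:
    """Cohort-level roll-up mirroring a consortium summary-table row."""

    n: int
    age_mean: float
    age_sd: float
    pct_women: float
    pct_edentulous: float
    teeth_mean: float
    teeth_sd: float
    cases: int
    prevalence_pct: float
    dmft_mean: float
    dmft_sd: float
    dmfs_mean: float
    dmfs_sd: float
    cluster_means: tuple[float, ...]
    cluster_sds: tuple[float, ...]

    def to_row(self, cohort: str = "") -> dict:
        row = {
            "cohort": cohort, "n": self.n,
            "age_mean": self.age_mean, "age_sd": self.age_sd,
            "pct_women": self.pct_women, "pct_edentulous": self.pct_edentulous,
            "teeth_mean": self.teeth_mean, "teeth_sd": self.teeth_sd,
            "cases": self.cases, "prevalence_pct": self.prevalence_pct,
            "dmft_mean": self.dmft_mean, "dmft_sd": self.dmft_sd,
            "dmfs_mean": self.dmfs_mean, "dmfs_sd": self.dmfs_sd,
        }
        for i, (m, s) in enumerate(zip(self.cluster_means, self.cluster_sds), 1):
            row[f"c{i}_mean"], row[f"c{i}_sd"] = m, s
        return row


def summarize_cohort(
    records: list[SubjectRecord],
    cluster_map: ClusterMap,
    ddof: int = 0,
) -> CohortClusterSummary:
    """Summarize a cohort's demographics, DMF indices, and cluster scores.

    ``ddof=0`` (default) reports population SDs; pass ``ddof=1`` for sample
    SDs.  At cohort sample sizes the difference is negligible.
    """
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    n = len(records)
    ages = np.array([r.age for r in records], dtype=float)
    women = np.array([r.sex == "female" for r in records])
    counts = [index_counts(r) for r in records]
    dmft = np.array([c.dmft_morbidity for c in counts], dtype=float)
    dmfs = np.array([c.dmfs_morbidity for c in counts], dtype=float)
    teeth = np.array([c.n_teeth_present for c in counts], dtype=float)
    edent = np.array([c.edentulous for c in counts])
    cases = int((dmfs > 0).sum())
    scores = np.array([score_subject(r, cluster_map) for r in records])

    def sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=ddof)) if len(x) > ddof else math.nan

    return CohortClusterSummary(
        n=n,
        age_mean=float(ages.mean()), age_sd=sd(ages),
        pct_women=100.0 * float(women.mean()),
        pct_edentulous=100.0 * float(edent.mean()),
        teeth_mean=float(teeth.mean()), teeth_sd=sd(teeth),
        cases=cases, prevalence_pct=100.0 * cases / n,
        dmft_mean=float(dmft.mean()), dmft_sd=sd(dmft),
        dmfs_mean=float(dmfs.mean()), dmfs_sd=sd(dmfs),
        cluster_means=tuple(float(m) for m in scores.mean(axis=0)),
        cluster_sds=tuple(sd(scores[:, j]) for j in range(scores.shape[1])),
    )


# glyph per cluster id for the plain-text odontogram
_GLYPHS = "123456789"


def render_odontogram(cluster_map: ClusterMap) -> str:
    """Plain-text odontogram of a cluster map, one glyph per cluster.

    Maxillary arch on top (right to left quadrant 1 then quadrant 2),
    mandibular arch below; each tooth is a column of its surfaces in
    canonical order with '.' for absent occlusal surfaces on anteriors.
    """
    upper = [17, 16, 15, 14, 13, 12, 11, 21, 22, 23, 24, 25, 26, 27]
    lower = [47, 46, 45, 44, 43, 42, 41, 31, 32, 33, 34, 35, 36, 37]
    lines = []
    for arch in (upper, lower):
        lines.append("  ".join(f"{t:>2d}" for t in arch))
        for surf in ("O", "M", "D", "B", "L"):
            row = []
            for t in arch:
                if surf in surfaces_for_tooth(t):
                    row.append(f" {_GLYPHS[cluster_map.assignment[(t, surf)] - 1]}")
                else:
                    row.append(" .")
            lines.append("  ".join(row))
        lines.append("")
    legend = [f"{c}: {cluster_map.label(c)}" for c in cluster_map.cluster_ids]
    return "\n".join(lines + legend)
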