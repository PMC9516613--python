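"""Consortium cohort registry: load, validate, and roll up cohort metadata.

A registry row describes one contributing cohort: where it was conducted, how
many participants it contributes, which of the three phenotype tiers it can
support (binary prevalence, quantitative severity, surface-level patterns),
and — for cohorts with surface data — the printed summary statistics
(demographics, DMF indices, per-cluster means/SDs).

Two fixture registries are bundled: ``table1.csv`` (the 21-cohort consortium
overview) and ``table2.csv`` (the 8 cohorts contributing surface-level
cluster data, with full summary blocks).  Approximate sample sizes written
as ``~200000`` parse to the integer with an ``n_approximate`` flag; roll-ups
sum them at face value, which is how consortium total rows are printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

_CORE_COLUMNS = ["cohort", "region", "n", "prevalence", "severity", "patterns"]
_SUMMARY_COLUMNS = (
    ["age_mean", "age_sd", "pct_women", "pct_edentulous", "teeth_mean",
     "teeth_sd", "cases", "prevalence_pct", "dmft_mean", "dmft_sd",
     "dmfs_mean", "dmfs_sd"]
    + [f"c{i}_{stat}" for i in range(1, 6) for stat in ("mean", "sd")]
)
_KNOWN_COLUMNS = set(_CORE_COLUMNS) | set(_SUMMARY_COLUMNS) | {"notes"}

TIERS = ("prevalence", "severity", "patterns", "all")


class RegistryError(ValueError):
    """Raised for malformed registry files."""


@dataclass
class CohortRegistryEntry:
    """One cohort's metadata, tier availability, and optional summary block."""

    cohort: str
    region: str
    n: int
    n_approximate: bool = False
    has_prevalence: bool = False
    has_severity: bool = False
    has_patterns: bool = False
    cases: int | None = None
    notes: str = ""
    summary: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 0:
            raise RegistryError(f"{self.cohort}: negative n")
        if self.cases is not None and self.cases > self.n:
            raise RegistryError(f"{self.cohort}: cases {self.cases} > n {self.n}")

    def has_tier(self, tier: str) -> bool:
        if tier == "all":
            return True
        if tier not in TIERS:
            raise ValueError(f"unknown tier: {tier!r}")
        return getattr(self, f"has_{tier}")


def _parse_n(raw) -> tuple[int, bool]:
    text = str(raw).strip().replace(",", "")
    approx = text.startswith("~")
    if approx:
        text = text[1:]
    try:
        return int(text), approx
    except ValueError:
        raise RegistryError(f"non-numeric sample size: {raw!r}") from None


def _parse_flag(raw) -> bool:
    text = str(raw).strip().lower()
    return text in ("1", "true", "yes", "y", "x")


def load_registry(path: str | Path) -> list[CohortRegistryEntry]:
    """Load a cohort registry CSV into validated entries."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise RegistryError(f"registry {path} has no cohort rows")
    unknown = [c for c in df.columns if c not in _KNOWN_COLUMNS]
    if unknown:
        raise RegistryError(f"unknown registry column(s): {unknown}")
    missing = [c for c in _CORE_COLUMNS if c not in df.columns]
    if missing:
        raise RegistryError(f"registry missing column(s): {missing}")

    entries = []
    for _, row in df.iterrows():
        n, approx = _parse_n(row["n"])
        cases = None
        summary: dict[str, float] = {}
        for col in _SUMMARY_COLUMNS:
            if col not in df.columns:
                continue
            text = str(row[col]).strip()
            if not text:
                continue
            if col == "cases":
                cases = int(text.replace(",", ""))
            else:
                summary[col] = float(text)
        entries.append(
            CohortRegistryEntry(
                cohort=str(row["cohort"]),
                region=str(row["region"]),
                n=n,
                n_approximate=approx,
                has_prevalence=_parse_flag(row["prevalence"]),
                has_severity=_parse_flag(row["severity"]),
                has_patterns=_parse_flag(row["patterns"]),
                cases=cases,
                notes=str(row["notes"]) if "notes" in df.columns else "",
                summary=summary,
            )
        )
    return entries


def total_n(entries: list[CohortRegistryEntry], tier: str = "all") -> int:
    """Sum of cohort sample sizes over cohorts contributing the given tier."""
    return sum(e.n for e in entries if e.has_tier(tier))


def pooled_caries_free(
    entries: list[CohortRegistryEntry],
) -> tuple[int, float]:
    """Pooled count and percent of caries-free participants across cohorts.

    Caries-free participants are those without any caries experience
    (n minus the binary case count); every entry must carry a case count.
    """
    for e in entries:
        if e.cases is None:
            raise RegistryError(f"{e.cohort}: no case count in registry")
    total = sum(e.n for e in entries)
    free = sum(e.n - e.cases for e in entries)
    return free, 100.0 * free / total


def coverage_fraction(current_n: int, target_n: int) -> float:
    """Percent of a target sample size achieved so far."""
    if target_n <= 0:
        raise ValueError("target_n must be positive")
    return 100.0 * current_n / target_n


def table1_path() -> Path:
    """Bundled 21-cohort consortium overview registry."""
    return Path(str(resources.files("caripheno.data") / "table1.csv"))


def table2_path() -> Path:
    """Bundled 8-cohort surface-level (cluster) registry with summary blocks."""
    return Path(str(resources.files("caripheno.data") / "table2.csv"))
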