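"""Synthetic surface-level cohorts with known ground truth.

The generator emulates the statistical structure that the downstream
analyses assume, so every pipeline stage can be tested against a known
truth:

* **Cluster-specific susceptibility** — each surface's affection probability
  depends on the cluster it belongs to through a per-cluster baseline
  log-odds ``a_c``.
* **Age dependence** — a shared log-odds slope ``b`` per year of age.
* **Person-level frailty** — a normal random intercept ``u_i`` shared by all
  of a person's surfaces (and their tooth-loss process), inducing the
  within-mouth correlation that makes caries counts overdispersed.
* **Cluster-level frailty** (optional, default off) — an additional random
  intercept per person *per cluster*.  A purely shared frailty correlates
  all surfaces equally and therefore carries no information about which
  surfaces belong together; cluster-level frailty is what makes the
  generating partition recoverable by correlation-based clustering, and is
  the "strong separation" dial used in derivation tests.
* **All-cause tooth loss** — each tooth is missing with probability
  ``logistic(m0 + m1 * age + u_i)``; a missing tooth sets all its surfaces
  to MISSING, feeding the tooth-morbidity encoding of the M component.

Affected surfaces split 50/50 between DECAYED and FILLED; the DMF indices
treat the two identically, so the split only exercises status bookkeeping.

Model for surface s of subject i (given the tooth is present):

    P(affected) = logistic(a_{c(s)} + b * age_i + u_i + v_{i,c(s)})

with u_i ~ N(0, frailty_sd^2) and v_ic ~ N(0, cluster_frailty_sd^2).

Identical parameters (including the seed) reproduce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .clusters import ClusterMap, default_cluster_map
from .dentition import (
    INDEX_TEETH,
    SubjectRecord,
    SurfaceStatus,
    enumerate_index_surfaces,
)

#: Default per-cluster baseline log-odds, parametrized so that at the default
#: age slope a 50-year-old's per-surface affection probabilities are
#: (0.60, 0.05, 0.40, 0.20, 0.25) for clusters 1-5 — the susceptibility
#: ordering (molars highest, lower anteriors lowest) seen across cohorts.
_DEFAULT_P50 = (0.60, 0.05, 0.40, 0.20, 0.25)
_DEFAULT_AGE_SLOPE = 0.03
DEFAULT_CLUSTER_LOGITS: tuple[float, ...] = tuple(
    float(logit(p) - _DEFAULT_AGE_SLOPE * 50.0) for p in _DEFAULT_P50
)


@dataclass
class SyntheticCohortParams:
    """Generating parameters for one synthetic cohort."""

    n: int = 500
    age_mean: float = 55.0
    age_sd: float = 12.0
    age_range: tuple[float, float] = (18.0, 100.0)
    pct_female: float = 55.0
    cluster_logits: tuple[float, ...] = DEFAULT_CLUSTER_LOGITS
    age_slope: float = _DEFAULT_AGE_SLOPE
    frailty_sd: float = 1.0
    cluster_frailty_sd: float = 0.0
    tooth_loss: tuple[float, float] = (-4.5, 0.04)  # (m0, m1) log-odds
    generating_map: ClusterMap | None = None
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.frailty_sd < 0 or self.cluster_frailty_sd < 0:
            raise ValueError("frailty SDs must be nonnegative")
        if not 0 <= self.pct_female <= 100:
            raise ValueError("pct_female must be in [0, 100]")
        if self.generating_map is None:
            self.generating_map = default_cluster_map()
        ids = self.generating_map.cluster_ids
        if len(self.cluster_logits) != len(ids):
            raise ValueError(
                f"need {len(ids)} cluster logits, got {len(self.cluster_logits)}")

    def truth(self) -> dict:
        """Ground-truth record echoing all generating parameters."""
        out = asdict(self)
        out["generating_map"] = self.generating_map.name
        return out


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Truncated-normal draws by resampling (cheap at these truncation levels)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(
    params: SyntheticCohortParams,
) -> tuple[list[SubjectRecord], dict]:
    """Generate one cohort of surface-level records plus its ground truth."""
    rng = np.random.default_rng(params.seed)
    cmap = params.generating_map
    universe = enumerate_index_surfaces()
    ids = cmap.cluster_ids
    cluster_index = {c: j for j, c in enumerate(ids)}
    surf_cluster = np.array([cluster_index[cmap.assignment[key]] for key in universe])
    surf_tooth = np.array([INDEX_TEETH.index(t) for t, _ in universe])
    logits = np.asarray(params.cluster_logits, dtype=float)
    m0, m1 = params.tooth_loss

    ages = _truncated_normal(
        rng, params.age_mean, params.age_sd, *params.age_range, params.n
    )
    female = rng.random(params.n) < params.pct_female / 100.0
    frailty = rng.normal(0.0, params.frailty_sd, params.n)

    records = []
    for i in range(params.n):
        u = frailty[i]
        v = rng.normal(0.0, params.cluster_frailty_sd, len(ids))
        p_miss = expit(m0 + m1 * ages[i] + u)
        tooth_missing = rng.random(len(INDEX_TEETH)) < p_miss
        p_surf = expit(logits[surf_cluster] + params.age_slope * ages[i] + u
                       + v[surf_cluster])
        affected = rng.random(len(universe)) < p_surf
        filled = rng.random(len(universe)) < 0.5  # D/F split among affected

        surfaces = {}
        for j, key in enumerate(universe):
            if tooth_missing[surf_tooth[j]]:
                surfaces[key] = SurfaceStatus.MISSING_TOOTH
            elif affected[j]:
                surfaces[key] = (
                    SurfaceStatus.FILLED if filled[j] else SurfaceStatus.DECAYED
                )
            else:
                surfaces[key] = SurfaceStatus.SOUND
        records.append(
            SubjectRecord(
                subject_id=f"{params.name}_{i:05d}",
                age=float(ages[i]),
                sex="female" if female[i] else "male",
                surfaces=surfaces,
            )
        )
    return records, params.truth()


def generate_consortium(
    cohort_params: list[SyntheticCohortParams],
    master_seed: int | None = None,
) -> list[tuple[list[SubjectRecord], dict]]:
    """Generate independent cohorts.

    With ``master_seed`` given, each cohort's seed is derived
    deterministically from it (overriding the per-cohort seeds); otherwise
    the per-cohort seeds are used as-is.
    """
    if not cohort_params:
        raise ValueError("empty cohort parameter list")
    if master_seed is not None:
        child_seeds = np.random.SeedSequence(master_seed).generate_state(
            len(cohort_params)
        )
        cohort_params = [
            replace(p, seed=int(s) & 0x7FFFFFFF)
            for p, s in zip(cohort_params, child_seeds)
        ]
    return [generate_cohort(p) for p in cohort_params]


def consortium_age_spread(
    n_cohorts: int = 8,
    age_range: tuple[float, float] = (23.0, 74.0),
    cohort_n: int = 300,
    master_seed: int = 0,
    **overrides,
) -> list[SyntheticCohortParams]:
    """Parameter list for a consortium whose cohort mean ages span a range.

    Mirrors the span of mean ages seen across contributing cohorts (early
    twenties to mid seventies); used by the recovery-chain tests and the
    pipeline demo.
    """
    means = np.linspace(age_range[0], age_range[1], n_cohorts)
    return [
        SyntheticCohortParams(
            n=cohort_n,
            age_mean=float(m),
            age_sd=3.0,
            name=f"cohort{j+1}",
            seed=master_seed + j,
            **overrides,
        )
        for j, m in enumerate(means)
    ]
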