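"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from bkarisk import (
    Comorbidity,
    Mobilization,
    PatientRecord,
    CohortTable,
    paper_like_config,
)

_CONDITIONS = tuple(Comorbidity)
_MOBILIZATION = (Mobilization.EARLY, Mobilization.LATE, Mobilization.BEDRIDDEN)
_BAND_AGES = (40, 70, 85)  # one representative age per band


def record_with_score(
    score: int,
    patient_id: str = "P",
    died_within_1yr: bool = False,
    days_to_death: int | None = None,
    katz_components=None,
    **outcomes,
) -> PatientRecord:
    """Build a valid record whose total risk score equals ``score`` (0–12)."""
    assert 0 <= score <= 12
    n_comorb = min(score, 6)
    rest = score - n_comorb
    mob_pts = min(rest, 2)
    rest -= mob_pts
    age_pts = min(rest, 2)
    rest -= age_pts
    assert rest <= 2
    return PatientRecord(
        patient_id=patient_id,
        age_years=_BAND_AGES[age_pts],
        comorbidities=frozenset(_CONDITIONS[:n_comorb]),
        mobilization=_MOBILIZATION[mob_pts],
        hypoxia=rest >= 1,
        metabolic_disorder=rest >= 2,
        died_within_1yr=died_within_1yr,
        days_to_death=days_to_death,
        katz_components=katz_components,
        **outcomes,
    )


def cohort_from_scores(spec_rows) -> CohortTable:
    """Cohort from (score, died, days_to_death, katz_components) tuples."""
    records = []
    for i, (score, died, days, katz) in enumerate(spec_rows):
        records.append(
            record_with_score(
                score,
                patient_id=f"P{i:03d}",
                died_within_1yr=died,
                days_to_death=days,
                katz_components=katz,
            )
        )
    return CohortTable(tuple(records))


# ---------------------------------------------------------------------------
# independent oracles (never share code with the implementation under test)


def mw_u_pairwise(a, b) -> float:
    """U for group a by direct pairwise counting (ties count one half)."""
    return sum(
        1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
    )


def mw_exact_p_bruteforce(a, b) -> float:
    """Two-sided exact p by enumerating every group labeling."""
    pooled = list(a) + list(b)
    n1 = len(a)
    idx = range(len(pooled))
    center = n1 * len(b) / 2.0
    observed = abs(mw_u_pairwise(a, b) - center)
    extreme = total = 0
    for combo in itertools.combinations(idx, n1):
        chosen = set(combo)
        ga = [pooled[i] for i in chosen]
        gb = [pooled[i] for i in idx if i not in chosen]
        total += 1
        if abs(mw_u_pairwise(ga, gb) - center) >= observed - 1e-9:
            extreme += 1
    return extreme / total


def auc_pair_counting(scores, labels) -> float:
    """AUC as (concordant + half-tied) / (n_pos * n_neg), by explicit loops."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


def spearman_r_oracle(x, y) -> float:
    """Pearson correlation of midranks via scipy ranking + numpy."""
    from scipy.stats import rankdata

    return float(np.corrcoef(rankdata(x), rankdata(y))[0, 1])


# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def paper_cfg():
    return paper_like_config(seed=0)


@pytest.fixture(scope="session")
def paper_cohort(paper_cfg):
    from bkarisk import simulate_cohort

    return simulate_cohort(paper_cfg)
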