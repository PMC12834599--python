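"""Synthetic study cohorts with site/family clustering.

The cohort emulates the cluster structure of a multi-site developmental
imaging study: subjects are nested in families, families in acquisition
sites.  Predictors of interest are a rare binary exposure (stimulant taken on
the day of scanning, prevalence ~5.8%) and an ordinal sleep-duration scale
(1 = <5 h ... 5 = >9 h).  Nuisance covariates follow plausible marginals:
age in months, sex, mean framewise displacement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["gen_cohort", "validate_cohort", "DEFAULT_SLEEP_PROBS"]

# Ordinal sleep-duration categories 1..5; mass concentrated at 7-9 h as in
# school-age children.
DEFAULT_SLEEP_PROBS: tuple[float, ...] = (0.03, 0.12, 0.35, 0.35, 0.15)

REQUIRED_COLUMNS = ("subject_id", "site_id", "family_id", "stimulant", "sleep")


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the cohort invariants; raise ``ValueError`` on violation."""
    for col in REQUIRED_COLUMNS:
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing required column {col!r}")
    fam_sites = cohort.groupby("family_id")["site_id"].nunique()
    if (fam_sites > 1).any():
        bad = fam_sites[fam_sites > 1].index.tolist()
        raise ValueError(f"families straddle sites: {bad}")
    if not cohort["stimulant"].isin([0, 1]).all():
        raise ValueError("stimulant must be coded 0/1")
    if not cohort["sleep"].isin([1, 2, 3, 4, 5]).all():
        raise ValueError("sleep must be an ordinal code in 1..5")


def gen_cohort(
    n_subjects: int,
    n_sites: int = 21,
    mean_family_size: float = 1.15,
    prevalence_stim: float = 0.058,
    sleep_probs: tuple[float, ...] = DEFAULT_SLEEP_PROBS,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a subjects-by-covariates table with nested cluster labels.

    Families are built by partitioning each site's subjects into runs whose
    sizes are ``1 + Poisson(mean_family_size - 1)`` (most families are
    singletons, some are sibling pairs/triples), so family ids never straddle
    sites by construction.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    if n_sites > n_subjects:
        raise ValueError(f"n_sites={n_sites} exceeds n_subjects={n_subjects}")
    if not 0.0 <= prevalence_stim <= 1.0:
        raise ValueError("prevalence_stim must be in [0, 1]")
    if mean_family_size < 1.0:
        raise ValueError("mean_family_size must be >= 1")
    sleep_probs = np.asarray(sleep_probs, dtype=float)
    if sleep_probs.min() < 0 or not np.isclose(sleep_probs.sum(), 1.0):
        raise ValueError("sleep_probs must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    # sites roughly balanced
    site = np.sort(rng.integers(0, n_sites, size=n_subjects))
    # guarantee every site appears
    site[:n_sites] = np.arange(n_sites)
    site = np.sort(site)

    family = np.empty(n_subjects, dtype=np.int64)
    next_family = 0
    for s in range(n_sites):
        idx = np.flatnonzero(site == s)
        pos = 0
        while pos < len(idx):
            size = 1 + rng.poisson(mean_family_size - 1.0)
            size = min(size, len(idx) - pos)
            family[idx[pos : pos + size]] = next_family
            next_family += 1
            pos += size

    stim = rng.random(n_subjects) < prevalence_stim
    sleep = rng.choice(np.arange(1, 6), size=n_subjects, p=sleep_probs)
    age_months = rng.uniform(108, 132, size=n_subjects)  # 9-11 y
    sex = rng.integers(0, 2, size=n_subjects)
    fd_mean = np.exp(rng.normal(np.log(0.12), 0.35, size=n_subjects))

    cohort = pd.DataFrame(
        {
            "subject_id": [f"sub-{k:05d}" for k in range(n_subjects)],
            "site_id": site,
            "family_id": family,
            "stimulant": stim.astype(int),
            "sleep": sleep.astype(int),
            "age_months": age_months,
            "sex": sex,
            "fd_mean": fd_mean,
        }
    )
    validate_cohort(cohort)
    return cohort
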