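"""Synthetic participant cohorts with correlated questionnaire responses.

Each family (dyad) carries one latent factor; every instrument's latent
score loads on it with weight sqrt(rho), so any two instrument totals
correlate at approximately ``latent_correlation``.  Children of the same
family share the parent/carer id and the parent-completed instruments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .. import questionnaires
from ..errors import ConfigError

__all__ = ["CohortSimConfig", "generate_cohort", "CHILD_INSTRUMENTS", "PARENT_INSTRUMENTS"]

CHILD_INSTRUMENTS = ("child_22",)
PARENT_INSTRUMENTS = ("dsr", "dsr_parent_ext", "tdds")

_ITEM_NOISE_SD = 0.25  # per-item noise on the latent scale, before discretisation


@dataclass
class CohortSimConfig:
    n_participants: int
    age_range_months: tuple[int, int] = (60, 167)
    sibling_fraction: float = 0.0
    latent_correlation: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be at least 1")
        if not (0.0 <= self.sibling_fraction <= 1.0):
            raise ConfigError("sibling_fraction must lie in [0, 1]")
        if self.sibling_fraction > 0 and self.n_participants < 2:
            raise ConfigError("sibling_fraction > 0 requires at least 2 participants")
        if not (-1.0 <= self.latent_correlation <= 1.0):
            raise ConfigError("latent_correlation must lie in [-1, 1]")
        if self.latent_correlation < 0.0:
            # The shared-factor construction cannot realise a common negative
            # correlation across more than two instruments.
            raise ConfigError("latent_correlation < 0 is not supported by the shared-factor model")
        if not (0 <= self.age_range_months[0] < self.age_range_months[1]):
            raise ConfigError("age_range_months must be an increasing non-negative pair")


def _draw_items(latent: np.ndarray, spec: questionnaires.InstrumentSpec, rng: np.random.Generator) -> np.ndarray:
    """Map per-respondent latent scores to integer item responses.

    Each item adds independent noise to the latent, then the Gaussian CDF
    maps it onto the response range; discretisation keeps responses in
    range without truncation pile-up at the extremes.
    """
    k = spec.n_items
    z = latent[:, None] + rng.normal(0.0, _ITEM_NOISE_SD, size=(len(latent), k))
    u = norm.cdf(z / np.sqrt(1.0 + _ITEM_NOISE_SD**2))
    n_levels = spec.response_max - spec.response_min + 1
    return np.minimum((u * n_levels).astype(int), n_levels - 1) + spec.response_min


def generate_cohort(
    cfg: CohortSimConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Generate a cohort table and per-instrument response tables.

    Returns ``(cohort, responses)``.  ``cohort`` has one row per child
    with ids, demographics, placeholder ``avoidance_score`` /
    ``gastric_index`` columns (NaN until the pipelines fill them), and
    scored questionnaire totals and subscales (columns
    ``<instrument>_total``, ``<instrument>_<subscale>``).  ``responses``
    maps instrument name to its raw item table, keyed by the respondent id
    (child id for the child instrument, parent id otherwise).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants

    # Family structure: sibling_fraction of children join an existing family.
    n_siblings = int(round(cfg.sibling_fraction * n))
    n_founders = max(1, n - n_siblings)
    parent_ids = [f"P{i + 1:03d}" for i in range(n_founders)]
    assignment = list(parent_ids)
    while len(assignment) < n:
        assignment.append(parent_ids[rng.integers(0, n_founders)])

    participant_ids = [f"C{i + 1:03d}" for i in range(n)]
    ages = rng.integers(cfg.age_range_months[0], cfg.age_range_months[1] + 1, size=n)
    sexes = rng.choice(["f", "m"], size=n)

    cohort = pd.DataFrame(
        {
            "participant_id": participant_ids,
            "parent_id": assignment,
            "age_months": ages,
            "sex": sexes,
            "avoidance_score": np.nan,
            "gastric_index": np.nan,
        }
    )

    rho = cfg.latent_correlation
    family_latent = {pid: rng.standard_normal() for pid in parent_ids}
    instruments = {name: questionnaires.load_instrument(name) for name in CHILD_INSTRUMENTS + PARENT_INSTRUMENTS}

    def scale_latent(shared: np.ndarray) -> np.ndarray:
        unique = rng.standard_normal(len(shared))
        return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * unique

    responses: dict[str, pd.DataFrame] = {}
    child_shared = np.array([family_latent[p] for p in assignment])
    for name in CHILD_INSTRUMENTS:
        spec = instruments[name]
        items = _draw_items(scale_latent(child_shared), spec, rng)
        responses[name] = pd.DataFrame(
            np.column_stack([participant_ids, items]),
            columns=["participant_id"] + spec.item_columns,
        ).astype({c: int for c in spec.item_columns})

    parent_shared = np.array([family_latent[p] for p in parent_ids])
    for name in PARENT_INSTRUMENTS:
        spec = instruments[name]
        items = _draw_items(scale_latent(parent_shared), spec, rng)
        responses[name] = pd.DataFrame(
            np.column_stack([parent_ids, items]),
            columns=["participant_id"] + spec.item_columns,
        ).astype({c: int for c in spec.item_columns})

    # Score and merge totals/subscales into the cohort table.
    for name, table in responses.items():
        spec = instruments[name]
        scored = questionnaires.score(table, spec)
        scored = scored.drop(columns=["n_missing"]).rename(
            columns={c: (f"{name}_{c}" if c != "participant_id" else c) for c in scored.columns}
        )
        if name in CHILD_INSTRUMENTS:
            cohort = cohort.merge(scored, on="participant_id", how="left")
        else:
            scored = scored.rename(columns={"participant_id": "parent_id"})
            cohort = cohort.merge(scored, on="parent_id", how="left")
    return cohort, responses
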