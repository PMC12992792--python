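"""Replication scoring and interaction calling for matrix Y2H screens.

The scoring scheme turns stamped colony observations into a per-pair
replication score in [0, 8]:

1. colony sizes are discretized to growth scores 0 (no growth), 1
   (background colony) or 3 (fully grown spot);
2. for each bait x prey configuration and biological replicate, the
   score is the fraction of technical positions at growth score 3
   (max 1 per configuration per biological replicate);
3. a configuration contributes only if every biological replicate in
   which it was tested showed the interaction (ratio > 0); its
   contribution is then the highest per-replicate ratio;
4. contributions of the up-to-eight configurations of a protein pair
   are summed, so a pair positive in all configurations and in the
   technical replicates of at least one biological replicate scores 8.

Interactions are called at a replication-score threshold (default 0.75,
inclusive). Auto-active baits (growth on selective medium without any
prey) and sticky preys (positive with more than half of all baits) are
flagged and excluded before scoring.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .screen_design import ScreenDesign

logger = logging.getLogger(__name__)

__all__ = [
    "GROWTH_SCORES",
    "DEFAULT_SIZE_THRESHOLDS",
    "DEFAULT_CALL_THRESHOLD",
    "discretize_colony",
    "flag_auto_active_baits",
    "flag_auto_active_preys",
    "score_configuration",
    "combine_bio_replicates",
    "pair_replication_score",
    "call_interactions",
    "score_screen",
]

GROWTH_SCORES = (0, 1, 3)
#: normalized colony-size cutoffs on a 0-1 scale: below t_low -> 0,
#: [t_low, t_high) -> 1, >= t_high -> 3
DEFAULT_SIZE_THRESHOLDS = (0.25, 0.6)
DEFAULT_CALL_THRESHOLD = 0.75


def discretize_colony(size, thresholds: tuple[float, float] = DEFAULT_SIZE_THRESHOLDS):
    """Discretize colony size(s) to growth scores 0/1/3.

    ``size`` may be a scalar or array-like; sizes must be >= 0 and
    ``thresholds = (t_low, t_high)`` strictly increasing. The upper
    boundary is inclusive: ``size == t_high`` scores 3.
    """
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ValueError(f"thresholds must increase: {thresholds}")
    arr = np.asarray(size, dtype=float)
    if (arr < 0).any():
        raise ValueError("colony sizes must be non-negative")
    out = np.where(arr >= t_high, 3, np.where(arr >= t_low, 1, 0))
    if np.isscalar(size) or arr.ndim == 0:
        return int(out)
    return out


def _ensure_growth_scores(
    observations: pd.DataFrame,
    thresholds: tuple[float, float] = DEFAULT_SIZE_THRESHOLDS,
) -> pd.DataFrame:
    """Return observations with a validated ``growth_score`` column."""
    obs = observations.copy()
    if "growth_score" not in obs.columns:
        if "size" not in obs.columns:
            raise ValueError("observations need a growth_score or size column")
        obs["growth_score"] = discretize_colony(obs["size"].to_numpy(), thresholds)
    bad = ~obs["growth_score"].isin(GROWTH_SCORES)
    if bad.any():
        raise ValueError(
            f"growth_score values outside {GROWTH_SCORES}: "
            f"{sorted(obs.loc[bad, 'growth_score'].unique())}"
        )
    return obs


def flag_auto_active_baits(
    no_prey_controls: pd.DataFrame,
    min_fraction: float | None = None,
    thresholds: tuple[float, float] = DEFAULT_SIZE_THRESHOLDS,
) -> set[str]:
    """Flag bait constructs growing on selective medium without mating.

    ``no_prey_controls`` holds one row per stamped control position with
    columns ``bait_id`` and ``growth_score`` (or ``size``). A bait is
    flagged when the fraction of its control positions at growth score 3
    exceeds ``min_fraction``; the default (None) flags on any score-3
    position.
    """
    if len(no_prey_controls) == 0:
        warnings.warn("empty auto-activity control set; no baits flagged")
        return set()
    obs = _ensure_growth_scores(no_prey_controls, thresholds)
    frac = obs.assign(hit=obs["growth_score"] == 3).groupby("bait_id")["hit"].mean()
    if min_fraction is None:
        flagged = frac[frac > 0]
    else:
        flagged = frac[frac >= min_fraction]
    return set(flagged.index)


def flag_auto_active_preys(
    observations: pd.DataFrame,
    min_fraction: float = 0.5,
    exclude_baits: Iterable[str] = (),
    thresholds: tuple[float, float] = DEFAULT_SIZE_THRESHOLDS,
    min_baits: int = 8,
) -> set[str]:
    """Flag prey constructs growing with more than ``min_fraction`` of baits.

    Positivity is evaluated per (bait construct, prey construct): any
    position at growth score 3 in any replicate counts the bait as grown
    with. Baits in ``exclude_baits`` (e.g. auto-active baits) are ignored.
    Stickiness means growth with *many independent* baits, so preys
    tested against fewer than ``min_baits`` distinct baits are never
    flagged (a genuine interaction in a small screen is not auto-activity).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    obs = _ensure_growth_scores(observations, thresholds)
    obs = obs[~obs["bait_id"].isin(set(exclude_baits))]
    if len(obs) == 0:
        return set()
    per_combo = (
        obs.assign(hit=obs["growth_score"] == 3)
        .groupby(["prey_id", "bait_id"])["hit"]
        .any()
    )
    grouped = per_combo.groupby("prey_id")
    frac = grouped.mean()
    n_baits = grouped.size()
    return set(frac[(frac > min_fraction) & (n_baits >= min_baits)].index)


def score_configuration(observations: pd.DataFrame) -> float:
    """Ratio of score-3 positions for one configuration x biological replicate."""
    if len(observations) == 0:
        raise ValueError("no observations for configuration")
    keys = observations[["bait_id", "prey_id", "bio_rep"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("observations span multiple configurations/replicates")
    obs = _ensure_growth_scores(observations)
    return float((obs["growth_score"] == 3).mean())


def combine_bio_replicates(
    ratios: Sequence[float], gate: str = "all_positive"
) -> float:
    """Collapse per-biological-replicate ratios into one contribution.

    ``all_positive`` (default): the configuration contributes its highest
    per-replicate ratio only if every tested biological replicate showed
    the interaction (ratio > 0); ``majority``: more than half must.
    A configuration tested in a single replicate passes the gate vacuously.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("need at least one biological replicate")
    positive = [r > 0 for r in ratios]
    if gate == "all_positive":
        passed = all(positive)
    elif gate == "majority":
        passed = sum(positive) > len(positive) / 2
    else:
        raise ValueError(f"unknown gate {gate!r}")
    return float(max(ratios)) if passed else 0.0


def pair_replication_score(contributions: dict[tuple[str, str], float]) -> float:
    """Sum configuration contributions into the pair replication score."""
    if len(set(contributions)) != len(contributions):
        raise ValueError("duplicate configuration keys")
    score = float(sum(contributions.values()))
    if not 0 <= score <= 8 + 1e-12:
        raise ValueError(f"pair score {score} outside [0, 8]")
    return score


def _pair_columns(scores: pd.DataFrame, design: ScreenDesign | None) -> pd.DataFrame:
    """Annotate per-config rows with canonical pair keys and scope."""
    def parse(cid: str) -> tuple[str, str]:
        label = cid.split("|", 1)[0]
        gene, species = label.rsplit("_", 1)
        return gene, species

    bait = scores["bait_id"].map(parse)
    prey = scores["prey_id"].map(parse)
    a = [min(x, y) for x, y in zip(bait, prey)]
    b = [max(x, y) for x, y in zip(bait, prey)]
    scores = scores.assign(
        gene_a=[t[0] for t in a],
        species_a=[t[1] for t in a],
        gene_b=[t[0] for t in b],
        species_b=[t[1] for t in b],
    )
    scores["scope"] = np.where(
        scores["species_a"] == scores["species_b"], "intra", "inter"
    )
    return scores


def call_interactions(
    pair_scores: pd.DataFrame, threshold: float = DEFAULT_CALL_THRESHOLD
) -> pd.DataFrame:
    """Threshold pair scores into interaction calls (inclusive >=)."""
    if not 0 < threshold <= 8:
        raise ValueError(f"threshold must be in (0, 8], got {threshold}")
    calls = pair_scores.copy()
    calls["positive"] = calls["score"] >= threshold
    calls["threshold"] = threshold
    return calls


def score_screen(
    observations: pd.DataFrame,
    design: ScreenDesign | None = None,
    no_prey_controls: pd.DataFrame | None = None,
    threshold: float = DEFAULT_CALL_THRESHOLD,
    size_thresholds: tuple[float, float] = DEFAULT_SIZE_THRESHOLDS,
    gate: str = "all_positive",
    prey_min_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """End-to-end scoring of a screen's colony observations.

    Parameters
    ----------
    observations
        One row per stamped position: ``bait_id``, ``prey_id``,
        ``bio_rep``, ``position`` and ``growth_score`` (or ``size``).
    no_prey_controls
        Optional mating-free selection observations (``bait_id``,
        ``position``, ``growth_score``/``size``) for bait auto-activity QC.

    Returns
    -------
    (calls, config_audit, qc)
        ``calls``: one row per protein pair (gene/species columns, scope,
        score, n_configs, positive). ``config_audit``: per-configuration
        contributions. ``qc``: flagged auto-active constructs.
    """
    obs = _ensure_growth_scores(observations, size_thresholds)
    dup = obs.duplicated(["bait_id", "prey_id", "bio_rep", "position"])
    if dup.any():
        raise ValueError("duplicate (configuration, bio_rep, position) rows")

    auto_baits: set[str] = set()
    if no_prey_controls is not None:
        auto_baits = flag_auto_active_baits(no_prey_controls, thresholds=size_thresholds)
    auto_preys = flag_auto_active_preys(
        obs, min_fraction=prey_min_fraction, exclude_baits=auto_baits,
        thresholds=size_thresholds,
    )
    n_before = len(obs)
    obs = obs[~obs["bait_id"].isin(auto_baits) & ~obs["prey_id"].isin(auto_preys)]
    logger.info(
        "auto-activity QC: %d baits, %d preys flagged; %d of %d observations kept",
        len(auto_baits), len(auto_preys), len(obs), n_before,
    )

    per_rep = (
        obs.assign(hit=obs["growth_score"] == 3)
        .groupby(["bait_id", "prey_id", "bio_rep"])
        .agg(ratio=("hit", "mean"), n_positions=("hit", "size"))
        .reset_index()
    )
    per_config = (
        per_rep.groupby(["bait_id", "prey_id"])
        .agg(
            contribution=("ratio", lambda r: combine_bio_replicates(list(r), gate)),
            n_bio_reps=("ratio", "size"),
            max_ratio=("ratio", "max"),
        )
        .reset_index()
    )
    per_config = _pair_columns(per_config, design)

    group_cols = ["gene_a", "species_a", "gene_b", "species_b", "scope"]
    pair_scores = (
        per_config.groupby(group_cols)
        .agg(score=("contribution", "sum"), n_configs=("contribution", "size"))
        .reset_index()
    )
    calls = call_interactions(pair_scores, threshold)
    qc = {
        "auto_active_baits": sorted(auto_baits),
        "auto_active_preys": sorted(auto_preys),
        "n_observations_used": int(len(obs)),
        "n_observations_total": int(n_before),
    }
    return calls, per_config, qc
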