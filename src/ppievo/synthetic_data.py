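"""Ground-truth generators for all three data modalities.

Every analysis stage of the package can be exercised without any
external download: these generators emulate

* plate-format Y2H colony growth for a configurable true-interaction
  network, including tag-orientation-specific false negatives,
  auto-active bait/prey constructs, 2-3 biological x 3-4 technical
  replicates, and bimodal colony-size noise;
* cross-species call matrices with planted evolutionary-trajectory
  labels (conserved / coevolving / species-restricted / not detected);
* pairwise codon alignments diverged under a specified omega via a
  mutation-acceptance scheme;
* co-IP/MS protein-group intensity tables with bait-specific planted
  enrichment, a GFP reference group, and intensity-dependent
  missingness.

All generators are pure functions of (config, seed): identical inputs
give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molevo_dnds import BASES, CodonAlignment, _code
from .network_evolution import CrossSpeciesMatrix
from .screen_design import (
    Configuration,
    ProteinPair,
    ScreenDesign,
    build_roster,
    default_design_config,
    enumerate_configurations,
    enumerate_pairs,
)

__all__ = [
    "Y2HSimConfig",
    "TrajectorySimConfig",
    "CodonSimConfig",
    "CoipSimConfig",
    "simulate_y2h",
    "simulate_trajectory_matrices",
    "simulate_codon_pair",
    "simulate_coip",
]


# ---------------------------------------------------------------------------
# Y2H screen simulator
# ---------------------------------------------------------------------------

@dataclass
class Y2HSimConfig:
    """Conditions for one simulated matrix screen.

    Defaults emulate the study conditions: the full five-species
    x 11-gene roster, 10 auto-active bait and 2 auto-active prey
    constructs, baits screened in 2 or 3 biological replicates, preys
    stamped in 3 or 4 technical replicates, and 8-fold construct
    testing in which individual configurations of a true pair may be
    undetectable (tag interference).
    """

    design: ScreenDesign | None = None
    n_true_pairs: int = 60
    detection_prob: float = 0.85  # per-position full-growth prob, detectable config
    config_detect_prob: float = 0.75  # prob a configuration of a true pair works
    false_positive_rate: float = 0.01  # per-position spurious full-growth prob
    # mating-free plates lack prey-dependent reporter activation; spurious
    # full growth there reflects true auto-activity, so the default is 0
    control_false_positive_rate: float = 0.0
    n_auto_baits: int = 10
    n_auto_preys: int = 2
    auto_growth_prob: float = 0.95
    sticky_growth_prob: float = 0.8
    bio_rep_choices: tuple[int, ...] = (2, 3)
    tech_rep_choices: tuple[int, ...] = (3, 4)
    n_control_positions: int = 4
    # colony-size modes on a normalized 0-1 scale (beta parameters)
    neg_mode: tuple[float, float] = (2.0, 18.0)  # mean 0.1
    pos_mode: tuple[float, float] = (8.0, 2.0)  # mean 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detection_prob", "config_detect_prob", "false_positive_rate",
                     "auto_growth_prob", "sticky_growth_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(b not in (2, 3) for b in self.bio_rep_choices):
            raise ValueError("biological replicates must be 2 or 3")
        if any(t not in (3, 4) for t in self.tech_rep_choices):
            raise ValueError("technical replicates must be 3 or 4")


def simulate_y2h(
    config: Y2HSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a full matrix screen.

    Returns ``(observations, no_prey_controls, truth)``. Observations
    carry one row per stamped position (bait_id, prey_id, bio_rep,
    position, size); controls are mating-free selection plates for bait
    auto-activity QC. ``truth`` holds the planted pairs with
    per-configuration detectability, the auto-active construct ids and
    the config used.
    """
    design = config.design or build_roster(default_design_config())
    rng = np.random.default_rng(config.seed)

    baits = sorted(
        c.construct_id for c in design.constructs if c.role == "bait"
    )
    preys = sorted(
        c.construct_id for c in design.constructs if c.role == "prey"
    )
    auto_baits = sorted(rng.choice(baits, size=config.n_auto_baits, replace=False))
    auto_preys = sorted(rng.choice(preys, size=config.n_auto_preys, replace=False))

    pairs = enumerate_pairs(design)
    idx = rng.choice(len(pairs), size=config.n_true_pairs, replace=False)
    true_pairs: list[ProteinPair] = [pairs[i] for i in sorted(idx)]

    # per-configuration detectability of true pairs (tag interference)
    detect: dict[tuple[str, str], float] = {}
    truth_rows = []
    for pair in true_pairs:
        configs = enumerate_configurations(pair, design)
        detectable = rng.random(len(configs)) < config.config_detect_prob
        n_det_qc = 0
        for cfg, det in zip(configs, detectable):
            key = (cfg.bait.construct_id, cfg.prey.construct_id)
            detect[key] = config.detection_prob if det else 0.0
            if det and key[0] not in auto_baits and key[1] not in auto_preys:
                n_det_qc += 1
        truth_rows.append(
            {
                "gene_a": pair.a.gene,
                "species_a": pair.a.species,
                "gene_b": pair.b.gene,
                "species_b": pair.b.species,
                "scope": pair.scope,
                "n_configs": len(configs),
                "n_detectable": int(detectable.sum()),
                "n_detectable_after_qc": n_det_qc,
            }
        )
    truth_pairs = pd.DataFrame(truth_rows)

    bio_reps = {
        b: int(rng.choice(config.bio_rep_choices)) for b in baits
    }
    tech_reps = {
        p: int(rng.choice(config.tech_rep_choices)) for p in preys
    }

    combos = pd.MultiIndex.from_product(
        [baits, preys], names=["bait_id", "prey_id"]
    ).to_frame(index=False)
    combos["n_bio"] = combos["bait_id"].map(bio_reps)
    combos["n_tech"] = combos["prey_id"].map(tech_reps)
    p_signal = np.full(len(combos), config.false_positive_rate)
    keys = list(zip(combos["bait_id"], combos["prey_id"]))
    p_true = np.array([detect.get(k, 0.0) for k in keys])
    p_signal = np.maximum(p_signal, p_true)
    p_signal = np.where(
        combos["prey_id"].isin(auto_preys), config.sticky_growth_prob, p_signal
    )
    p_signal = np.where(
        combos["bait_id"].isin(auto_baits), config.auto_growth_prob, p_signal
    )
    combos["p_signal"] = p_signal

    n_rows = combos["n_bio"] * combos["n_tech"]
    obs = combos.loc[combos.index.repeat(n_rows)].reset_index(drop=True)
    within = obs.groupby(["bait_id", "prey_id"]).cumcount()
    obs["bio_rep"] = within // obs["n_tech"] + 1
    obs["position"] = within % obs["n_tech"] + 1
    signal = rng.random(len(obs)) < obs["p_signal"].to_numpy()
    a_neg, b_neg = config.neg_mode
    a_pos, b_pos = config.pos_mode
    size = np.where(
        signal,
        rng.beta(a_pos, b_pos, size=len(obs)),
        rng.beta(a_neg, b_neg, size=len(obs)),
    )
    obs["size"] = size
    observations = obs[["bait_id", "prey_id", "bio_rep", "position", "size"]]

    ctrl = pd.MultiIndex.from_product(
        [baits, range(1, config.n_control_positions + 1)],
        names=["bait_id", "position"],
    ).to_frame(index=False)
    p_ctrl = np.where(
        ctrl["bait_id"].isin(auto_baits),
        config.auto_growth_prob,
        config.control_false_positive_rate,
    )
    ctrl_signal = rng.random(len(ctrl)) < p_ctrl
    ctrl["size"] = np.where(
        ctrl_signal,
        rng.beta(a_pos, b_pos, size=len(ctrl)),
        rng.beta(a_neg, b_neg, size=len(ctrl)),
    )

    truth = {
        "true_pairs": truth_pairs,
        "auto_active_baits": list(auto_baits),
        "auto_active_preys": list(auto_preys),
        "detectability": detect,
        "config": config,
    }
    return observations, ctrl, truth


# ---------------------------------------------------------------------------
# Trajectory-matrix simulator
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySimConfig:
    """Generative models for planted trajectory labels.

    ``flip_noise`` is signal dropout: each planted-positive cell is
    flipped to negative with this probability, reflecting the
    false-negative-dominated noise of Y2H screens after auto-activity
    QC. Spurious positives are controlled separately by
    ``false_positive_rate`` (default 0). The coevolution model makes a
    cell positive with logistic probability in the species divergence
    (midpoint in My); the default midpoint keeps inter-species signal
    essentially confined to the closest species pair.
    """

    n_pairs: int = 200
    label_mix: dict[str, float] = field(
        default_factory=lambda: {
            "conserved": 0.25,
            "coevolving": 0.25,
            "species_restricted": 0.25,
            "not_detected": 0.25,
        }
    )
    flip_noise: float = 0.1
    false_positive_rate: float = 0.0
    coevolve_midpoint_my: float = 9.0
    coevolve_scale_my: float = 0.75
    restricted_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.label_mix.values()) or not self.label_mix:
            raise ValueError("label mix weights must be non-negative and non-empty")
        if sum(self.label_mix.values()) <= 0:
            raise ValueError("label mix weights must sum to > 0")


def _planted_prob(
    label: str,
    dist: np.ndarray,
    cfg: TrajectorySimConfig,
    rng: np.random.Generator,
    n_species: int,
) -> np.ndarray:
    """Per-cell planted-positive probability matrix for one gene pair."""
    if label == "conserved":
        return np.ones_like(dist)
    if label == "coevolving":
        return 1.0 / (
            1.0 + np.exp((dist - cfg.coevolve_midpoint_my) / cfg.coevolve_scale_my)
        )
    if label == "species_restricted":
        k = int(rng.integers(1, 3))  # restricted to 1 or 2 species
        rows = rng.choice(n_species, size=k, replace=False)
        prob = np.zeros_like(dist)
        axis_is_rows = bool(rng.random() < 0.5)
        if axis_is_rows:
            prob[rows, :] = cfg.restricted_rate
        else:
            prob[:, rows] = cfg.restricted_rate
        return prob
    if label == "not_detected":
        return np.zeros_like(dist)
    raise ValueError(f"unknown label {label!r}")


def simulate_trajectory_matrices(
    design: ScreenDesign,
    config: TrajectorySimConfig = TrajectorySimConfig(),
) -> tuple[list[CrossSpeciesMatrix], list[str]]:
    """Simulate cross-species call matrices with planted labels.

    Each simulated gene pair is heterotypic with both genes present in
    all species of ``design``, giving a full S x S call matrix. Returns
    the matrices and the planted label list (same order).
    """
    rng = np.random.default_rng(config.seed)
    species = design.species_ids
    dist = design.divergence_my.loc[species, species].to_numpy()
    labels_avail = sorted(config.label_mix)
    weights = np.array([config.label_mix[l] for l in labels_avail], dtype=float)
    weights /= weights.sum()

    matrices: list[CrossSpeciesMatrix] = []
    labels: list[str] = []
    for i in range(config.n_pairs):
        label = labels_avail[int(rng.choice(len(labels_avail), p=weights))]
        prob = _planted_prob(label, dist, config, rng, len(species))
        planted = rng.random(dist.shape) < prob
        detected = planted & (rng.random(dist.shape) >= config.flip_noise)
        if config.false_positive_rate > 0:
            fp = (~planted) & (rng.random(dist.shape) < config.false_positive_rate)
            detected |= fp
        values = pd.DataFrame(
            detected.astype(float), index=species, columns=species
        )
        matrices.append(CrossSpeciesMatrix(f"simA{i:04d}", f"simB{i:04d}", values))
        labels.append(label)
    return matrices, labels


# ---------------------------------------------------------------------------
# Codon-pair simulator
# ---------------------------------------------------------------------------

@dataclass
class CodonSimConfig:
    """Mutation-acceptance codon simulator settings.

    ``divergence`` is the expected number of substitution attempts per
    codon between the two sequences (split evenly over the two lineages
    descending from a common ancestor). ``omega`` scales the relative
    acceptance of nonsynonymous vs synonymous attempts; stop-creating
    attempts are always rejected. ``ts_weight`` up-weights transitions
    relative to transversions when drawing the mutant base (1 = no bias).
    """

    n_codons: int = 3000
    omega: float = 1.0
    divergence: float = 0.2
    ts_weight: float = 1.0
    table_id: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")


_TRANSITions = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _evolve_lineage(
    codons: list[str],
    n_attempts: int,
    cfg: CodonSimConfig,
    rng: np.random.Generator,
    code: dict[str, str],
) -> tuple[list[str], int, int]:
    """Apply substitution attempts to one lineage; returns counts (syn, nonsyn)."""
    seq = list(codons)
    n_syn = n_nonsyn = 0
    p_syn = 1.0 / max(1.0, cfg.omega)
    p_nonsyn = cfg.omega / max(1.0, cfg.omega)
    for _ in range(n_attempts):
        i = int(rng.integers(len(seq)))
        pos = int(rng.integers(3))
        current = seq[i]
        base = current[pos]
        alts = [b for b in BASES if b != base]
        w = np.array(
            [cfg.ts_weight if _TRANSITions[base] == b else 1.0 for b in alts]
        )
        new_base = alts[int(rng.choice(3, p=w / w.sum()))]
        mutant = current[:pos] + new_base + current[pos + 1 :]
        if code[mutant] == "*":
            continue  # stop-creating attempts are rejected
        if code[mutant] == code[current]:
            accept = rng.random() < p_syn
            if accept:
                n_syn += 1
        else:
            accept = rng.random() < p_nonsyn
            if accept:
                n_nonsyn += 1
        if accept:
            seq[i] = mutant
    return seq, n_syn, n_nonsyn


def simulate_codon_pair(config: CodonSimConfig) -> tuple[CodonAlignment, dict]:
    """Simulate an ancestor and two descendant coding sequences.

    Returns the pairwise alignment of the two descendants plus a truth
    log with the realized synonymous/nonsynonymous substitution counts
    per lineage.
    """
    rng = np.random.default_rng(config.seed)
    code = _code(config.table_id)
    sense = sorted(c for c, aa in code.items() if aa != "*")
    ancestor = [sense[i] for i in rng.integers(len(sense), size=config.n_codons)]

    per_lineage = config.divergence / 2.0 * config.n_codons
    truth = {"omega": config.omega, "divergence": config.divergence, "lineages": []}
    descendants = []
    for _ in range(2):
        n_attempts = int(rng.poisson(per_lineage))
        seq, n_syn, n_nonsyn = _evolve_lineage(ancestor, n_attempts, config, rng, code)
        descendants.append(seq)
        truth["lineages"].append(
            {"n_attempts": n_attempts, "n_syn": n_syn, "n_nonsyn": n_nonsyn}
        )
    aln = CodonAlignment(descendants[0], descendants[1], table_id=config.table_id)
    return aln, truth


# ---------------------------------------------------------------------------
# co-IP/MS intensity simulator
# ---------------------------------------------------------------------------

@dataclass
class CoipSimConfig:
    """Label-free co-IP intensity matrix with planted enrichment.

    Defaults emulate the study's acquisition layout: four biological
    replicates, each in two technical replicates, per sample group, with
    a tagged-GFP control group serving as both the differential-
    enrichment control and the reference for relative ratios.
    """

    n_proteins: int = 400
    baits: tuple[str, ...] = ("baitA", "baitB")
    reference: str = "GFP"
    n_enriched: int = 15
    fold: float = 8.0
    baseline_mean: float = 20.0  # log2 units
    baseline_sd: float = 1.5
    cv: float = 0.1  # biological coefficient of variation (linear scale)
    tech_sd: float = 0.05  # extra log2 noise per technical replicate
    missingness: float = 0.1  # dropout prob at the baseline mean intensity
    missing_steepness: float = 0.5
    n_bio_reps: int = 4
    n_tech_reps: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold effects must be > 0")
        if not 0 <= self.missingness <= 1:
            raise ValueError("missingness must be in [0, 1]")
        if self.n_enriched > self.n_proteins:
            raise ValueError("enriched set larger than protein universe")


def simulate_coip(config: CoipSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a protein-group intensity table.

    Returns ``(intensities, meta, truth)``: linear-scale intensities
    (protein groups x samples, NaN = not detected), sample metadata
    (sample, group, bio_rep, tech_rep) and the planted enriched sets per
    bait. The reference protein group (named after ``config.reference``)
    is made highly abundant in every group so relative ratios are always
    computable.
    """
    rng = np.random.default_rng(config.seed)
    proteins = [f"PG{i:04d}" for i in range(config.n_proteins)]
    proteins[0] = config.reference
    base = rng.normal(config.baseline_mean, config.baseline_sd, config.n_proteins)
    base[0] = config.baseline_mean + 4  # tagged bait/reference is abundant

    groups = [config.reference] + list(config.baits)
    enriched: dict[str, list[str]] = {}
    candidates = np.arange(1, config.n_proteins)
    for bait in config.baits:
        chosen = rng.choice(candidates, size=config.n_enriched, replace=False)
        enriched[bait] = [proteins[i] for i in sorted(chosen)]

    bio_sd = np.log2(1.0 + config.cv)  # approx log2-sd for a linear-scale CV
    columns = {}
    meta_rows = []
    for group in groups:
        effect = np.zeros(config.n_proteins)
        if group in enriched:
            rows = [proteins.index(p) for p in enriched[group]]
            effect[rows] = np.log2(config.fold)
        for b in range(1, config.n_bio_reps + 1):
            bio = base + effect + rng.normal(0, bio_sd, config.n_proteins)
            for t in range(1, config.n_tech_reps + 1):
                sample = f"{group}_b{b}_t{t}"
                log2i = bio + rng.normal(0, config.tech_sd, config.n_proteins)
                if config.missingness >= 1.0:
                    keep = np.zeros(config.n_proteins, dtype=bool)
                elif config.missingness <= 0.0:
                    keep = np.ones(config.n_proteins, dtype=bool)
                else:
                    # logistic dropout in log-intensity, anchored so that a
                    # protein at the baseline mean drops out with prob `missingness`
                    anchor = config.baseline_mean - np.log(
                        1.0 / config.missingness - 1.0
                    ) / config.missing_steepness
                    p_miss = 1.0 / (
                        1.0 + np.exp(config.missing_steepness * (log2i - anchor))
                    )
                    keep = rng.random(config.n_proteins) >= p_miss
                col = np.where(keep, np.exp2(log2i), np.nan)
                columns[sample] = col
                meta_rows.append(
                    {"sample": sample, "group": group, "bio_rep": b, "tech_rep": t}
                )
    intensities = pd.DataFrame(columns, index=proteins)
    meta = pd.DataFrame(meta_rows)
    truth = {"enriched": enriched, "fold": config.fold, "config": config}
    return intensities, meta, truth
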