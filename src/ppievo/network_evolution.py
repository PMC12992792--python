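"""Evolutionary-trajectory analysis of cross-species interaction calls.

For each ortholog gene pair (geneA, geneB) the interaction calls are
assembled into a species x species matrix (rows: species contributing the
geneA ortholog; columns: species contributing the geneB ortholog). Cells
are positive (1), negative (0) or untested/absent (NaN). Each testable
cell belongs to an evolutionary-distance group given by the divergence
time of the two source species (intra-species = 0 My), and the fraction
of positive calls per distance group summarizes how the interaction
behaves across evolutionary time.

A rule-based classifier turns the per-distance profile into one of five
trajectory labels, evaluated in precedence order:

``not_detected``
    no positive cell anywhere.
``conserved``
    fraction >= theta_c in every tested distance group, i.e. the
    interaction is detected across all tested divergences.
``coevolving``
    strong intra-species signal (intra fraction >= theta_c), fractions
    non-increasing with distance (tolerance ``mono_tol``), and nearly no
    signal in the largest tested distance group (fraction <= theta_f) —
    the pattern expected when compensatory interface evolution preserves
    the interaction only between coevolved (same or closely related
    species) partners.
``species_restricted``
    positives exist but are confined, for at least one of the two genes,
    to orthologs from at most ``k_restrict`` species — network rewiring
    restricted to a lineage.
``sporadic``
    anything else.

The thresholds are explicit parameters of this formalization; the labels
themselves follow the conserved / coevolving / species-restricted
taxonomy used for cross-species Y2H data.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen_design import ProteinEntry, ProteinPair, ScreenDesign

__all__ = [
    "TrajectoryParams",
    "CrossSpeciesMatrix",
    "build_matrix",
    "fraction_by_distance",
    "classify_trajectory",
    "network_summary",
    "intra_species_edges",
]

LABELS = ("conserved", "coevolving", "species_restricted", "sporadic", "not_detected")


@dataclass(frozen=True)
class TrajectoryParams:
    """Classifier thresholds.

    theta_c: minimum fraction for a group to count as robustly detected.
    theta_f: maximum far-distance fraction compatible with coevolution.
    mono_tol: allowed increase between successive distance groups while
        still counting the profile as non-increasing.
    k_restrict: maximum number of species supporting a gene's positives
        for the pattern to count as species-restricted.
    """

    theta_c: float = 0.5
    theta_f: float = 0.25
    mono_tol: float = 0.1
    k_restrict: int = 2

    def __post_init__(self) -> None:
        for name in ("theta_c", "theta_f", "mono_tol"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.k_restrict < 1:
            raise ValueError("k_restrict must be >= 1")


@dataclass
class CrossSpeciesMatrix:
    """Call matrix for one gene pair: rows geneA species, cols geneB species."""

    gene_a: str
    gene_b: str
    values: pd.DataFrame  # 1.0 positive, 0.0 negative, NaN untested/absent

    @property
    def homotypic_genes(self) -> bool:
        return self.gene_a == self.gene_b

    def positive_species(self) -> tuple[set[str], set[str]]:
        """Species whose orthologs of geneA / geneB appear in a positive cell."""
        pos = self.values == 1.0
        sp_a = set(self.values.index[pos.any(axis=1)])
        sp_b = set(self.values.columns[pos.any(axis=0)])
        return sp_a, sp_b


def build_matrix(
    calls: pd.DataFrame, gene_a: str, gene_b: str, design: ScreenDesign
) -> CrossSpeciesMatrix:
    """Assemble the cross-species call matrix for one gene pair.

    ``calls`` is the per-pair call table (columns gene_a, species_a,
    gene_b, species_b, positive). Species lacking a gene are absent
    (NaN); tested combinations missing from ``calls`` are untested (NaN).
    For geneA == geneB the matrix is symmetrized by OR, since the pair
    (ortholog from species X, ortholog from species Y) is unordered.
    """
    for g in (gene_a, gene_b):
        if g not in design.genes:
            raise ValueError(f"gene {g!r} not in roster")
    gene_a, gene_b = sorted((gene_a, gene_b))
    sp = design.species_ids
    rows = [s for s in sp if design.has_protein(gene_a, s)]
    cols = [s for s in sp if design.has_protein(gene_b, s)]
    mat = pd.DataFrame(np.nan, index=rows, columns=cols)

    lookup: dict[tuple[str, str, str, str], bool] = {}
    sub = calls[
        ((calls["gene_a"] == gene_a) & (calls["gene_b"] == gene_b))
        | ((calls["gene_a"] == gene_b) & (calls["gene_b"] == gene_a))
    ]
    for row in sub.itertuples():
        # canonicalize row orientation: callers may supply either order
        p = ProteinPair(
            ProteinEntry(row.gene_a, row.species_a),
            ProteinEntry(row.gene_b, row.species_b),
        )
        key = (p.a.gene, p.a.species, p.b.gene, p.b.species)
        lookup[key] = lookup.get(key, False) or bool(row.positive)
    for sa in rows:
        for sb in cols:
            pair = ProteinPair(ProteinEntry(gene_a, sa), ProteinEntry(gene_b, sb))
            key = (pair.a.gene, pair.a.species, pair.b.gene, pair.b.species)
            if key in lookup:
                mat.loc[sa, sb] = float(lookup[key])
    if gene_a == gene_b:
        arr = mat.to_numpy()
        with np.errstate(invalid="ignore"):
            sym = np.fmax(arr, arr.T)  # OR over orientations, NaN-aware
        mat = pd.DataFrame(sym, index=rows, columns=cols)
    return CrossSpeciesMatrix(gene_a, gene_b, mat)


def _iter_cells(matrix: CrossSpeciesMatrix):
    """Yield (species_a, species_b, value) over distinct tests.

    For a homotypic gene pair only unordered species combinations are
    yielded (the symmetrized matrix would otherwise double-count).
    """
    vals = matrix.values
    for i, sa in enumerate(vals.index):
        for j, sb in enumerate(vals.columns):
            if matrix.homotypic_genes and j < i:
                continue
            yield sa, sb, vals.iloc[i, j]


def fraction_by_distance(
    matrix: CrossSpeciesMatrix,
    divergence: pd.DataFrame,
    bins: list[float] | None = None,
) -> pd.DataFrame:
    """Fraction of positive calls per evolutionary-distance group.

    Each testable cell is assigned the divergence time (My) of its two
    source species (0 for intra-species). By default every distinct
    divergence value forms its own group; ``bins`` may give custom bin
    edges instead. Untested/absent cells never enter denominators.

    Returns a DataFrame with columns ``distance``, ``n_tested``,
    ``n_positive``, ``fraction``, sorted by distance.
    """
    records = []
    for sa, sb, v in _iter_cells(matrix):
        if sa not in divergence.index or sb not in divergence.index:
            raise ValueError(f"species {sa}/{sb} missing from divergence matrix")
        if np.isnan(v):
            continue
        records.append((float(divergence.loc[sa, sb]), v))
    if not records:
        return pd.DataFrame(columns=["distance", "n_tested", "n_positive", "fraction"])
    df = pd.DataFrame(records, columns=["distance", "value"])
    if bins is not None:
        df["distance"] = pd.cut(df["distance"], bins=bins, include_lowest=True).map(
            lambda iv: iv.mid
        ).astype(float)
    prof = (
        df.groupby("distance")["value"]
        .agg(n_tested="size", n_positive="sum")
        .reset_index()
    )
    prof["n_positive"] = prof["n_positive"].astype(int)
    prof["fraction"] = prof["n_positive"] / prof["n_tested"]
    return prof.sort_values("distance").reset_index(drop=True)


def _within_monotone_band(fractions: np.ndarray, tol: float) -> bool:
    """True when the sequence is within ``tol`` of a non-increasing one.

    The closest non-increasing sequence (least squares, unweighted) is
    found by pool-adjacent-violators; the check passes when the largest
    deviation from that fit is at most ``tol``. A sup-norm band is more
    stable than checking successive differences when adjacent distance
    groups hold very different numbers of tested cells (an intra group
    of 5 cells next to a 2-cell nearest-neighbor group).
    """
    # non-increasing PAVA: pool adjacent blocks whenever a later block
    # exceeds an earlier one
    blocks = [[float(f), 1] for f in fractions]  # [mean, count]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] < blocks[i + 1][0]:
            m = (blocks[i][0] * blocks[i][1] + blocks[i + 1][0] * blocks[i + 1][1]) / (
                blocks[i][1] + blocks[i + 1][1]
            )
            blocks[i] = [m, blocks[i][1] + blocks[i + 1][1]]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    fit = np.concatenate([[m] * n for m, n in blocks])
    return bool(np.max(np.abs(fractions - fit)) <= tol + 1e-9)


def classify_trajectory(
    profile: pd.DataFrame,
    matrix: CrossSpeciesMatrix,
    params: TrajectoryParams = TrajectoryParams(),
) -> dict:
    """Assign a trajectory label to one gene pair.

    Returns a dict with ``label``, the per-group fractions and the
    species support sets backing the decision.
    """
    tested = profile[profile["n_tested"] > 0]
    if len(tested) == 0:
        raise ValueError("profile has no tested distance group")
    fractions = dict(zip(tested["distance"], tested["fraction"]))
    sp_a, sp_b = matrix.positive_species()
    n_positive = int(tested["n_positive"].sum())

    label = "sporadic"
    if n_positive == 0:
        label = "not_detected"
    elif (tested["fraction"] >= params.theta_c).all():
        label = "conserved"
    else:
        frac_seq = tested.sort_values("distance")["fraction"].to_numpy()
        non_increasing = _within_monotone_band(frac_seq, params.mono_tol)
        intra = fractions.get(0.0)
        far = frac_seq[-1]
        if (
            intra is not None
            and intra >= params.theta_c
            and non_increasing
            and far <= params.theta_f
        ):
            label = "coevolving"
        elif min(len(sp_a), len(sp_b)) <= params.k_restrict:
            label = "species_restricted"
    return {
        "label": label,
        "fractions": fractions,
        "n_positive": n_positive,
        "species_support_a": sorted(sp_a),
        "species_support_b": sorted(sp_b),
    }


def network_summary(
    calls: pd.DataFrame,
    design: ScreenDesign,
    params: TrajectoryParams = TrajectoryParams(),
) -> pd.DataFrame:
    """Per-gene-pair trajectory table over the whole roster.

    One row per unordered gene-level pair (homotypic included); for the
    default 11-gene roster that is 66 rows. Fractions are serialized as a
    JSON column keyed by distance.
    """
    rows = []
    for ga, gb in itertools.combinations_with_replacement(sorted(design.genes), 2):
        matrix = build_matrix(calls, ga, gb, design)
        profile = fraction_by_distance(matrix, design.divergence_my)
        if len(profile) == 0 or profile["n_tested"].sum() == 0:
            result = {"label": "not_detected", "fractions": {}, "n_positive": 0}
        else:
            result = classify_trajectory(profile, matrix, params)
        rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "label": result["label"],
                "n_positive": result["n_positive"],
                "fractions": json.dumps(
                    {str(k): v for k, v in sorted(result["fractions"].items())}
                ),
            }
        )
    return pd.DataFrame(rows)


def intra_species_edges(calls: pd.DataFrame) -> pd.DataFrame:
    """Edge list of positive intra-species interactions, one row per species edge."""
    pos = calls[(calls["positive"]) & (calls["scope"] == "intra")]
    return pos[["species_a", "gene_a", "gene_b", "score"]].rename(
        columns={"species_a": "species"}
    ).reset_index(drop=True)
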