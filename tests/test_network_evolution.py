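"""Cross-species matrices, distance profiles and trajectory labels."""

import numpy as np
import pandas as pd
import pytest

from ppievo import (
    CrossSpeciesMatrix,
    TrajectoryParams,
    TrajectorySimConfig,
    build_matrix,
    classify_trajectory,
    fraction_by_distance,
    network_summary,
    simulate_trajectory_matrices,
)
from ppievo.network_evolution import intra_species_edges


def _calls(rows):
    df = pd.DataFrame(
        rows, columns=["gene_a", "species_a", "gene_b", "species_b", "positive"]
    )
    df["score"] = np.where(df["positive"], 8.0, 0.0)
    df["scope"] = np.where(df["species_a"] == df["species_b"], "intra", "inter")
    return df


SPECIES = ["Dmel", "Dsim", "Dere", "Dper", "Dvir"]


def _full_matrix(design, gene_a, gene_b, positive_cells):
    rows = []
    for sa in SPECIES:
        for sb in SPECIES:
            if not design.has_protein(gene_a, sa) or not design.has_protein(gene_b, sb):
                continue
            rows.append([gene_a, sa, gene_b, sb, (sa, sb) in positive_cells])
    return _calls(rows)


class TestBuildMatrix:
    def test_gene_absence_masks_cells(self, paper_design):
        calls = _full_matrix(paper_design, "Kipf", "Rhi", set())
        m = build_matrix(calls, "Kipf", "Rhi", paper_design)
        assert m.values.shape == (3, 5)
        assert int(m.values.notna().sum().sum()) == 15

    def test_all_negative_matrix(self, paper_design):
        calls = _full_matrix(paper_design, "Del", "Rhi", set())
        m = build_matrix(calls, "Del", "Rhi", paper_design)
        assert (m.values == 0).all().all()

    def test_homotypic_symmetrized_by_or(self, paper_design):
        calls = _calls([["CtBP", "Dmel", "CtBP", "Dsim", True]])
        m = build_matrix(calls, "CtBP", "CtBP", paper_design)
        assert m.values.loc["Dmel", "Dsim"] == 1.0
        assert m.values.loc["Dsim", "Dmel"] == 1.0

    def test_unknown_gene_rejected(self, paper_design):
        with pytest.raises(ValueError, match="not in roster"):
            build_matrix(_calls([]), "nope", "Rhi", paper_design)


class TestFractionByDistance:
    def test_all_positive_gives_unit_fractions(self, paper_design):
        cells = {(a, b) for a in SPECIES for b in SPECIES}
        calls = _full_matrix(paper_design, "Del", "Cuff", cells)
        m = build_matrix(calls, "Del", "Cuff", paper_design)
        prof = fraction_by_distance(m, paper_design.divergence_my)
        assert (prof["fraction"] == 1.0).all()
        assert prof["n_tested"].sum() == 25

    def test_random_matrix_matches_cell_tally(self, paper_design):
        rng = np.random.default_rng(42)
        for _ in range(10):
            vals = rng.choice([0.0, 1.0, np.nan], size=(5, 5))
            m = CrossSpeciesMatrix(
                "gX", "gY", pd.DataFrame(vals, index=SPECIES, columns=SPECIES)
            )
            prof = fraction_by_distance(m, paper_design.divergence_my)
            # brute-force tally per distance over all 25 cells
            tally: dict[float, list[int]] = {}
            for sa in SPECIES:
                for sb in SPECIES:
                    v = m.values.loc[sa, sb]
                    if np.isnan(v):
                        continue
                    d = float(paper_design.divergence_my.loc[sa, sb])
                    tally.setdefault(d, [0, 0])
                    tally[d][0] += 1
                    tally[d][1] += int(v)
            for row in prof.itertuples():
                assert tally[row.distance] == [row.n_tested, row.n_positive]
            assert prof["n_tested"].sum() == sum(v[0] for v in tally.values())

    def test_missing_species_in_divergence_rejected(self, paper_design):
        m = CrossSpeciesMatrix(
            "gX", "gY", pd.DataFrame([[1.0]], index=["??"], columns=["??"])
        )
        with pytest.raises(ValueError, match="missing from divergence"):
            fraction_by_distance(m, paper_design.divergence_my)


class TestClassify:
    def _label(self, design, cells):
        calls = _full_matrix(design, "Del", "Cuff", cells)
        m = build_matrix(calls, "Cuff", "Del", design)
        prof = fraction_by_distance(m, design.divergence_my)
        return classify_trajectory(prof, m)["label"]

    def test_positives_at_all_distances_is_conserved(self, paper_design):
        cells = {(a, b) for a in SPECIES for b in SPECIES}
        assert self._label(paper_design, cells) == "conserved"

    def test_intra_and_near_only_is_coevolving(self, paper_design):
        near = {("Dmel", "Dsim"), ("Dsim", "Dmel")}
        cells = {(s, s) for s in SPECIES} | near
        assert self._label(paper_design, cells) == "coevolving"

    def test_single_row_is_species_restricted(self, paper_design):
        # one species' ortholog of one gene interacts with several partners
        cells = {("Dper", b) for b in SPECIES}
        assert self._label(paper_design, cells) == "species_restricted"

    def test_no_positives_is_not_detected(self, paper_design):
        assert self._label(paper_design, set()) == "not_detected"

    def test_label_invariant_under_species_relabeling(self, paper_design):
        cells = {(s, s) for s in SPECIES} | {("Dmel", "Dsim"), ("Dsim", "Dmel")}
        base = self._label(paper_design, cells)
        # swap the two 5-My species everywhere; divergences are preserved
        swap = {"Dmel": "Dsim", "Dsim": "Dmel"}
        swapped = {(swap.get(a, a), swap.get(b, b)) for a, b in cells}
        assert self._label(paper_design, swapped) == base

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TrajectoryParams(theta_c=1.5)
        with pytest.raises(ValueError):
            TrajectoryParams(k_restrict=0)

    def test_single_species_design_reaches_only_two_labels(self):
        from ppievo import build_roster

        d = build_roster({"species": ["S1"], "genes": ["g1", "g2"]})
        for positive in (True, False):
            calls = _calls([["g1", "S1", "g2", "S1", positive]])
            m = build_matrix(calls, "g1", "g2", d)
            prof = fraction_by_distance(m, d.divergence_my)
            label = classify_trajectory(prof, m)["label"]
            assert label == ("conserved" if positive else "not_detected")


class TestPlantedRecovery:
    def test_zero_noise_recovers_all_labels(self, paper_design):
        cfg = TrajectorySimConfig(n_pairs=100, flip_noise=0.0, seed=3)
        mats, labels = simulate_trajectory_matrices(paper_design, cfg)
        for m, lab in zip(mats, labels):
            prof = fraction_by_distance(m, paper_design.divergence_my)
            assert classify_trajectory(prof, m)["label"] == lab

    def test_all_not_detected_mix(self, paper_design):
        cfg = TrajectorySimConfig(
            n_pairs=20, label_mix={"not_detected": 1.0}, seed=0
        )
        mats, labels = simulate_trajectory_matrices(paper_design, cfg)
        for m in mats:
            prof = fraction_by_distance(m, paper_design.divergence_my)
            assert classify_trajectory(prof, m)["label"] == "not_detected"

    def test_noisy_recovery_above_ninety_percent(self, paper_design):
        cfg = TrajectorySimConfig(n_pairs=200, flip_noise=0.1, seed=11)
        mats, labels = simulate_trajectory_matrices(paper_design, cfg)
        correct = sum(
            classify_trajectory(
                fraction_by_distance(m, paper_design.divergence_my), m
            )["label"] == lab
            for m, lab in zip(mats, labels)
        )
        assert correct / len(labels) >= 0.9


class TestNetworkSummary:
    def test_default_roster_has_66_gene_pairs(self, paper_design):
        calls = _calls([])
        summary = network_summary(calls, paper_design)
        assert len(summary) == 66
        assert (summary["label"] == "not_detected").all()

    def test_intra_edges_export(self, paper_design):
        calls = _calls(
            [["Del", "Dmel", "Rhi", "Dmel", True],
             ["Del", "Dmel", "Rhi", "Dsim", True]]
        )
        edges = intra_species_edges(calls)
        assert len(edges) == 1
        assert edges["species"].iloc[0] == "Dmel"
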