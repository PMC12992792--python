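"""Intensity preprocessing, GFP ratios, differential enrichment, Tukey fences."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppievo import (
    CoipSimConfig,
    differential_enrichment,
    gfp_relative,
    preprocess,
    simulate_coip,
    tukey_fences,
)


def _table(values, groups, n_tech=2):
    """Build (intensities, meta) from a protein x (group, bio_rep) array."""
    cols, meta = {}, []
    for g in groups:
        for b in range(1, values[g].shape[1] + 1):
            for t in range(1, n_tech + 1):
                sample = f"{g}_b{b}_t{t}"
                cols[sample] = values[g][:, b - 1]
                meta.append({"sample": sample, "group": g, "bio_rep": b,
                             "tech_rep": t})
    proteins = [f"P{i}" for i in range(next(iter(values.values())).shape[0])]
    return pd.DataFrame(cols, index=proteins), pd.DataFrame(meta)


class TestPreprocess:
    def test_tech_rep_filter_drops_half_detected(self):
        intens, meta = _table({"g": np.array([[8.0], [8.0]])}, ["g"])
        intens.loc["P0", "g_b1_t2"] = np.nan  # detected in one tech rep only
        out = preprocess(intens, meta)
        assert np.isnan(out.loc["P0", ("g", 1)])
        assert not np.isnan(out.loc["P1", ("g", 1)])

    def test_median_centering_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        raw = np.exp2(rng.normal(10, 1, size=(5, 1)))
        intens, meta = _table({"g": raw}, ["g"], n_tech=1)
        out = preprocess(intens, meta)
        log = np.log2(raw[:, 0])
        expected = log - np.median(log)
        np.testing.assert_allclose(out[("g", 1)].to_numpy(), expected)

    def test_idempotent_on_centered_log_data(self):
        rng = np.random.default_rng(1)
        intens, meta = _table(
            {"g": rng.normal(0, 1, size=(9, 3))}, ["g"], n_tech=1
        )
        centered = intens.sub(intens.median(axis=0), axis=1)
        once = preprocess(centered, meta, already_log=True)
        flat = once.copy()
        flat.columns = [f"g_b{b}_t1" for (_, b) in once.columns]
        meta2 = pd.DataFrame(
            [{"sample": c, "group": "g", "bio_rep": i + 1, "tech_rep": 1}
             for i, c in enumerate(flat.columns)]
        )
        twice = preprocess(flat, meta2, already_log=True)
        np.testing.assert_allclose(
            once.to_numpy(), twice.to_numpy(), atol=1e-9
        )

    def test_all_missing_protein_removed(self):
        intens, meta = _table({"g": np.array([[8.0], [np.nan]])}, ["g"])
        out = preprocess(intens, meta)
        assert list(out.index) == ["P0"]

    def test_metadata_must_cover_samples(self):
        intens, meta = _table({"g": np.array([[8.0]])}, ["g"])
        with pytest.raises(ValueError, match="without metadata"):
            preprocess(intens, meta.iloc[:1])


class TestGfpRelative:
    def test_reference_ratio_zero_and_fourfold_is_two(self):
        base = np.full((3, 2), 10.0)
        base[1] += 2.0  # 4x the reference
        intens, meta = _table({"g": np.exp2(base)}, ["g"])
        out = preprocess(intens, meta)
        out.index = ["GFP", "quad", "other"]
        ratios = gfp_relative(out, "GFP")
        by = ratios.groupby("protein_group")["log2_ratio"].mean()
        assert by["GFP"] == pytest.approx(0.0, abs=1e-9)
        assert by["quad"] == pytest.approx(2.0, abs=1e-9)

    def test_missing_reference_rejected(self):
        intens, meta = _table({"g": np.array([[8.0]])}, ["g"])
        out = preprocess(intens, meta)
        with pytest.raises(ValueError, match="reference"):
            gfp_relative(out, "nope")


def brute_force_bh(pvals):
    """Textbook Benjamini-Hochberg: adj_i = min_{j>=i} (m * p_(j) / j), capped."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adj[i] = running
    return adj


class TestDifferentialEnrichment:
    def _processed(self, bait, ctrl):
        intens, meta = _table(
            {"bait": np.exp2(bait), "ctrl": np.exp2(ctrl)}, ["bait", "ctrl"]
        )
        return preprocess(intens, meta, normalization="median")

    def test_identical_groups_not_hit(self):
        vals = np.tile(np.arange(5, 10, dtype=float)[:, None], (1, 4))
        out = differential_enrichment(self._processed(vals, vals), "bait", "ctrl")
        assert not out["hit"].any()
        assert (out["log2fc"] == 0).all()

    def test_planted_eightfold_is_hit(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(10, 0.05, size=(20, 4))
        bait = ctrl + rng.normal(0, 0.05, size=(20, 4))
        bait[0] += 3.0  # 8-fold
        out = differential_enrichment(self._processed(bait, ctrl), "bait", "ctrl")
        out = out.set_index("protein_group")
        assert bool(out.loc["P0", "hit"])
        assert int(out["hit"].sum()) == 1

    def test_insufficient_replicates_untestable(self):
        bait = np.full((2, 4), 10.0)
        ctrl = np.full((2, 4), 8.0)
        ctrl[0, 1:] = np.nan
        out = differential_enrichment(
            self._processed(bait, ctrl), "bait", "ctrl"
        ).set_index("protein_group")
        assert out.loc["P0", "status"] == "untestable"
        assert not bool(out.loc["P0", "hit"])
        assert out.loc["P1", "status"] == "tested"

    @given(
        st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=50)
    )
    @settings(max_examples=50, deadline=None)
    def test_bh_matches_brute_force(self, pvals):
        from statsmodels.stats.multitest import multipletests

        pvals = np.array(pvals)
        adj = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, brute_force_bh(pvals), rtol=1e-10)
        # adjusted p monotone in raw p
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_bh_equal_spacing_example(self):
        adj = brute_force_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])


class TestTukeyFences:
    def test_outlier_flagged(self):
        lo, hi, out = tukey_fences(list(range(1, 10)) + [100])
        q1, q3 = np.quantile(np.array(list(range(1, 10)) + [100]), [0.25, 0.75])
        assert lo == pytest.approx(q1 - 1.5 * (q3 - q1))
        assert hi == pytest.approx(q3 + 1.5 * (q3 - q1))
        assert list(out) == [100.0]

    def test_symmetric_data_no_outliers(self):
        _, _, out = tukey_fences(np.linspace(-1, 1, 20))
        assert out.size == 0

    def test_constant_data_collapsed_fences(self):
        lo, hi, out = tukey_fences([5.0] * 6)
        assert lo == hi == 5.0
        assert out.size == 0

    def test_too_few_values(self):
        with pytest.raises(ValueError, match=">= 4"):
            tukey_fences([1.0, 2.0, 3.0])


def test_plots_render_to_files(tmp_path):
    from ppievo.coip_enrichment import ratio_boxplot, volcano_plot

    intens, meta, _ = simulate_coip(CoipSimConfig(seed=0, n_proteins=60,
                                                  missingness=0.0))
    proc = preprocess(intens, meta)
    enr = differential_enrichment(proc, "baitA", "GFP")
    volcano_plot(enr, tmp_path / "volcano.png", title="baitA vs GFP")
    ratios = gfp_relative(proc, "GFP")
    some = list(ratios["protein_group"].unique()[:3])
    ratio_boxplot(ratios, some, tmp_path / "box.png")
    assert (tmp_path / "volcano.png").stat().st_size > 0
    assert (tmp_path / "box.png").stat().st_size > 0


class TestSimulatedRecovery:
    def test_planted_hits_recovered_exactly_low_noise(self):
        intens, meta, truth = simulate_coip(CoipSimConfig(seed=0, missingness=0.0))
        proc = preprocess(intens, meta)
        for bait in ("baitA", "baitB"):
            enr = differential_enrichment(proc, bait, "GFP")
            hits = set(enr.loc[enr["hit"] & (enr["direction"] == "enriched"),
                               "protein_group"])
            assert hits == set(truth["enriched"][bait])

    def test_null_screens_control_false_positives(self):
        total_hits = 0
        for seed in range(20):
            intens, meta, _ = simulate_coip(
                CoipSimConfig(seed=seed, n_enriched=0, missingness=0.0,
                              n_proteins=150)
            )
            proc = preprocess(intens, meta)
            enr = differential_enrichment(proc, "baitA", "GFP")
            total_hits += int(enr["hit"].sum())
        # nominal FDR at the -log10 adj p > 2 cutoff is 1%
        assert total_hits / (20 * 150) <= 0.01

    def test_full_missingness_degenerates_cleanly(self):
        intens, meta, _ = simulate_coip(
            CoipSimConfig(seed=1, missingness=1.0, n_proteins=30)
        )
        proc = preprocess(intens, meta)
        assert len(proc) == 0
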