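"""Microbiome stage: prevalence filtering, absolute-abundance scaling,
genus aggregation, and permutation differential abundance."""

import numpy as np
import pandas as pd
import pytest

from antwound.microbiome import (
    absolute_abundance,
    aggregate_genus,
    community_permanova,
    genus_differential_abundance,
    parse_genus,
    prevalence_filter,
)
from antwound.synthgen import MicrobiomeParams, gen_asv_counts


def _table(counts, samples=None, asvs=None):
    counts = np.asarray(counts)
    samples = samples or [f"s{i}" for i in range(counts.shape[1])]
    asvs = asvs or [f"ASV{i}" for i in range(counts.shape[0])]
    return pd.DataFrame(counts, index=asvs, columns=samples)


class TestPrevalenceFilter:
    def test_boundary_one_percent_in_five_samples_retained(self):
        """An ASV at exactly 1% in exactly 5 samples passes the inclusive
        rule."""
        n_samples = 8
        counts = np.full((2, n_samples), 0)
        counts[0] = 990
        counts[1, :5] = 10  # exactly 1% where present
        t = _table(counts)
        kept = prevalence_filter(t, min_rel=0.01, min_samples=5)
        assert "ASV1" in kept.index

    def test_below_threshold_removed(self):
        counts = np.full((2, 10), 0)
        counts[0] = 991
        counts[1] = 9  # 0.9% everywhere
        kept = prevalence_filter(_table(counts))
        assert "ASV1" not in kept.index
        assert list(kept.columns) == list(_table(counts).columns)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 200, size=(20, 12))
        t = _table(counts)
        kept = prevalence_filter(t, 0.05, 3)
        rel = counts / counts.sum(axis=0)
        expected = [
            f"ASV{i}" for i in range(20) if (rel[i] >= 0.05).sum() >= 3
        ]
        assert list(kept.index) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        t = _table(rng.integers(0, 50, size=(15, 8)))
        once = prevalence_filter(t, 0.02, 4)
        twice = prevalence_filter(once, 0.02, 4)
        pd.testing.assert_frame_equal(once, twice)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5])
    def test_rejects_bad_threshold(self, bad):
        with pytest.raises(ValueError):
            prevalence_filter(_table([[1]]), min_rel=bad)


class TestAbsoluteAbundance:
    def test_half_half_scaling(self):
        t = _table([[5], [5]])
        out = absolute_abundance(t, {"s0": 1000.0})
        np.testing.assert_allclose(out["s0"], [500, 500])

    def test_columns_sum_to_totals(self):
        rng = np.random.default_rng(2)
        t = _table(rng.integers(1, 100, size=(6, 4)))
        totals = {f"s{i}": float(10 ** (3 + i)) for i in range(4)}
        out = absolute_abundance(t, totals)
        for s, tot in totals.items():
            assert out[s].sum() == pytest.approx(tot, rel=1e-9)

    def test_three_by_three_hand_example(self):
        t = _table([[1, 0, 2], [1, 1, 2], [2, 3, 4]])
        out = absolute_abundance(t, {"s0": 400.0, "s1": 100.0, "s2": 80.0})
        np.testing.assert_allclose(out["s0"], [100, 100, 200])
        np.testing.assert_allclose(out["s1"], [0, 25, 75])
        np.testing.assert_allclose(out["s2"], [20, 20, 40])


class TestAggregateGenus:
    def test_same_genus_summed(self):
        t = _table([[10.0], [5.0]])
        tax = {"ASV0": "g__Pseudomonas", "ASV1": "g__Pseudomonas"}
        out = aggregate_genus(t, tax)
        assert out.loc["Pseudomonas", "s0"] == 15.0

    def test_singleton_passthrough_and_mass_conserved(self):
        rng = np.random.default_rng(3)
        t = _table(rng.random((5, 3)) * 100)
        tax = {f"ASV{i}": f"d__B;g__G{i % 2}" for i in range(5)}
        out = aggregate_genus(t, tax)
        np.testing.assert_allclose(out.sum(axis=0), t.sum(axis=0))

    def test_lineage_parsing(self):
        assert parse_genus("d__Bacteria;f__X;g__Klebsiella") == "Klebsiella"
        assert parse_genus("Serratia") == "Serratia"
        assert parse_genus("d__Bacteria;g__") == "unclassified"
        assert parse_genus(None) == "unclassified"

    def test_paper_shape_fixture(self):
        """The default synthetic layout mirrors the study: 18 ASVs in 11
        genera across 40 samples."""
        table, tax, meta, totals = gen_asv_counts(seed=0)
        assert table.shape == (18, 40)
        genera = {parse_genus(tax[a]) for a in table.index}
        assert len(genera) == 11


class TestDifferentialAbundance:
    def _null_params(self):
        return MicrobiomeParams(
            perturbed={}, total_fold={2.0: 1.0, 11.0: 1.0}, n_per_cell=10
        )

    def test_identical_groups_all_p_one(self):
        genus = pd.DataFrame(
            np.tile([[10.0], [20.0]], (1, 8)),
            index=["A", "B"],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = pd.Series(["x"] * 4 + ["y"] * 4, index=genus.columns)
        with pytest.warns(UserWarning):
            res = genus_differential_abundance(genus, groups, n_perm=200, seed=0)
        assert (res["p_holm"] == 1.0).all()

    def test_no_perturbation_type_i_controlled(self):
        """Null generator configuration (no genus shift, flat totals): the
        Holm-corrected family stays clean in most replicate datasets."""
        clean = 0
        for seed in range(21, 31):
            table, tax, meta, totals = gen_asv_counts(self._null_params(), seed=seed)
            genus = aggregate_genus(absolute_abundance(table, totals), tax)
            res = genus_differential_abundance(
                genus, meta["treatment"], meta["timepoint_h"], n_perm=1000, seed=seed
            )
            if (res["p_holm"] >= 0.05).all():
                clean += 1
        # Holm keeps the familywise error at 5% per timepoint family, so
        # most replicate datasets should show no rejection at all
        assert clean >= 7

    def test_shifted_genus_attains_smallest_p(self):
        """On a genus copy-number table with a single 100-fold shifted
        genus at n=10/group, that genus is detected after Holm and attains
        the smallest raw p."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            genera = [f"G{i}" for i in range(11)]
            vals = rng.lognormal(np.log(1000.0), 0.5, size=(11, 20))
            vals[4, 10:] *= 100.0  # the bloom
            genus = pd.DataFrame(vals, index=genera, columns=[f"s{i}" for i in range(20)])
            groups = pd.Series(["sterile"] * 10 + ["infected"] * 10, index=genus.columns)
            res = genus_differential_abundance(genus, groups, n_perm=2000, seed=seed)
            res = res.set_index("genus")
            if res.loc["G4", "p_holm"] < 0.05 and res["p_raw"].idxmin() == "G4":
                hits += 1
        assert hits >= 5

    def test_default_generator_pseudomonas_detected(self):
        """With the default perturbation (Pseudomonas bloom plus the
        10x/100x total-load shifts) the Pseudomonas genus is significant
        at the late timepoint with the infected-up direction."""
        table, tax, meta, totals = gen_asv_counts(seed=17)
        genus = aggregate_genus(absolute_abundance(table, totals), tax)
        res = genus_differential_abundance(
            genus, meta["treatment"], meta["timepoint_h"], n_perm=2000, seed=2
        )
        late = res[res["timepoint"] == 11.0].set_index("genus")
        assert late.loc["Pseudomonas", "p_holm"] < 0.05
        assert late.loc["Pseudomonas", "direction"] == "infected>sterile"

    def test_small_case_matches_exhaustive_oracle(self):
        from antwound.statcore import permutation_t_test

        genus = pd.DataFrame(
            [[1.0, 2.0, 3.0, 10.0, 12.0, 11.0]],
            index=["G"],
            columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=genus.columns)
        res = genus_differential_abundance(genus, groups, n_perm=10_000, seed=0)
        exact = permutation_t_test(
            genus.iloc[0, :3], genus.iloc[0, 3:], exhaustive=True
        ).p_value
        assert abs(res["p_raw"].iloc[0] - exact) < 0.02


class TestCommunityPermanova:
    def test_treatment_separation_detected(self):
        table, tax, meta, totals = gen_asv_counts(seed=12)
        res = community_permanova(
            absolute_abundance(table, totals), meta["treatment"], n_perm=199, seed=0
        )
        assert res.p_value < 0.05
        assert 0 < res.r_squared <= 1
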