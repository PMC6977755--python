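"""Richness, rarefaction (vs exhaustive oracle), and PCA ordination."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import beequant as bq
from beequant.community import group_summary
from beequant.exceptions import UndefinedStatisticError
from beequant.simulate import CALIBRATOR_TAXON


def toy_counts(rows, columns=None):
    columns = columns or [f"t{j}" for j in range(len(rows[0]))]
    return pd.DataFrame(
        rows, index=[f"s{i}" for i in range(len(rows))], columns=columns
    )


class TestRichness:
    def test_counts_present_taxa(self):
        table = toy_counts([[3, 0], [1, 2]])
        assert bq.sample_richness(table).tolist() == [1, 2]

    def test_failed_sample_has_zero_richness(self):
        table = toy_counts([[0, 0, 0], [1, 1, 1]])
        assert bq.sample_richness(table).tolist() == [0, 3]

    def test_presence_based(self):
        table = toy_counts([[3, 0], [1, 2]])
        assert bq.sample_richness(table * 10).tolist() == bq.sample_richness(
            table
        ).tolist()

    def test_read_count_table_excludes_calibrator(self):
        counts = toy_counts([[5, 0], [2, 2]])
        tallies = pd.DataFrame(
            {"unassigned": [0, 0], "ambiguous": [0, 0], "calibrator": [100, 100]},
            index=counts.index,
        )
        rct = bq.ReadCountTable(counts=counts, tallies=tallies)
        assert bq.sample_richness(rct).tolist() == [1, 2]


class TestRichnessCorrelation:
    def test_identical_vectors(self):
        assert bq.richness_correlation([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_reversed_linear(self):
        assert bq.richness_correlation([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_five_point_hand_computation(self):
        x = np.array([3.0, 7, 2, 9, 5])
        y = np.array([1.0, 6, 2, 7, 6])
        # direct covariance / variance arithmetic oracle
        r_hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert bq.richness_correlation(x, y) == pytest.approx(r_hand)

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedStatisticError):
            bq.richness_correlation([1, 1, 1], [1, 2, 3])

    def test_too_short_raises(self):
        with pytest.raises(UndefinedStatisticError):
            bq.richness_correlation([1, 2], [1, 2])

    def test_noiseless_pipeline_richness_matches_morphology(self):
        # error-free, dropout-free reads: molecular richness equals
        # morphological richness sample by sample, so r = 1
        taxa = [f"t{j}" for j in range(10)] + [CALIBRATOR_TAXON]
        refdb = bq.generate_reference_db(
            11, length=200, min_divergence=10, seed=20, taxon_ids=taxa
        )
        profiles = [bq.TaxonProfile(t, 1.0 + 0.3 * j, 1.2) for j, t in enumerate(taxa[:-1])]
        profiles.append(bq.TaxonProfile(CALIBRATOR_TAXON, 2.0, 0.0))
        design = bq.StudyDesign(
            management_types=("CRP", "NPAM"), locations=("A", "B"),
            sampling_dates=3, traps_per_site=2,
        )
        table = bq.generate_specimen_table(design, profiles[:-1], seed=21)
        batches = bq.simulate_reads(
            table, profiles, refdb, reads_per_sample=5_000,
            per_base_error=0.0, calibrator_count=2, seed=21,
        )
        rct = bq.process_batches(
            batches, refdb, mode="community", calibrator_taxon=CALIBRATOR_TAXON
        )
        morph = bq.sample_richness(table)
        mol = bq.sample_richness(rct)
        assert (morph[mol.index] == mol).all()
        assert bq.richness_correlation(morph[mol.index], mol) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def toy_incidence():
    presence = toy_counts(
        [
            [1, 1, 0, 0, 0, 1],
            [1, 0, 1, 0, 0, 0],
            [0, 1, 1, 1, 0, 0],
            [1, 0, 0, 0, 1, 0],
            [1, 1, 0, 0, 0, 0],
        ]
    )
    return bq.IncidenceMatrix.from_counts(presence)


class TestRarefaction:
    def exhaustive_expected_richness(self, presence: np.ndarray, t: int) -> float:
        T = presence.shape[0]
        vals = [
            (presence[list(subset)].sum(axis=0) > 0).sum()
            for subset in itertools.combinations(range(T), t)
        ]
        return float(np.mean(vals))

    def test_summary_quantities(self, toy_incidence):
        inc = toy_incidence
        assert inc.T == 5 and inc.S_obs == 6
        assert inc.incidence_freq.tolist() == [4, 3, 2, 1, 1, 1]
        assert inc.Q1 == 3 and inc.Q2 == 1

    def test_endpoint_equals_observed_richness(self, toy_incidence):
        curve = bq.rarefaction_curve(toy_incidence, [toy_incidence.T])
        assert curve["expected_richness"].iloc[0] == pytest.approx(6.0)

    def test_single_unit_equals_mean_richness(self, toy_incidence):
        curve = bq.rarefaction_curve(toy_incidence, [1])
        mean_richness = toy_incidence.presence.sum(axis=1).mean()
        assert curve["expected_richness"].iloc[0] == pytest.approx(mean_richness)

    def test_interpolation_matches_exhaustive_subsets(self, toy_incidence):
        presence = toy_incidence.presence.to_numpy()
        curve = bq.rarefaction_curve(toy_incidence, [1, 2, 3, 4, 5])
        for _, row in curve.iterrows():
            oracle = self.exhaustive_expected_richness(presence, int(row["t"]))
            assert row["expected_richness"] == pytest.approx(oracle)

    @given(data=st.data())
    def test_oracle_equivalence_on_random_matrices(self, data):
        T = data.draw(st.integers(min_value=2, max_value=8))
        S = data.draw(st.integers(min_value=1, max_value=6))
        bits = data.draw(
            st.lists(
                st.lists(st.integers(min_value=0, max_value=1), min_size=S, max_size=S),
                min_size=T, max_size=T,
            )
        )
        presence = np.array(bits)
        if presence.sum() == 0:
            presence[0, 0] = 1
        inc = bq.IncidenceMatrix.from_counts(toy_counts(presence.tolist()))
        curve = bq.rarefaction_curve(inc, list(range(1, T + 1)))
        for _, row in curve.iterrows():
            oracle = self.exhaustive_expected_richness(presence, int(row["t"]))
            assert row["expected_richness"] == pytest.approx(oracle)

    def test_monotone_including_extrapolation(self, toy_incidence):
        curve = bq.rarefaction_curve(toy_incidence, list(range(1, 16)))
        vals = curve["expected_richness"].to_numpy()
        assert np.all(np.diff(vals) >= -1e-12)
        assert (curve["method"] == "extrapolated").sum() == 10

    def test_extrapolation_approaches_chao2_asymptote(self, toy_incidence):
        inc = toy_incidence
        q0 = (inc.T - 1) / inc.T * inc.Q1**2 / (2 * inc.Q2)
        curve = bq.rarefaction_curve(inc, [inc.T + 1000])
        assert curve["expected_richness"].iloc[0] == pytest.approx(
            inc.S_obs + q0, rel=1e-6
        )

    def test_no_doubletons_substitution(self):
        presence = toy_counts([[1, 1, 0], [0, 1, 0], [0, 1, 1]])
        inc = bq.IncidenceMatrix.from_counts(presence)
        assert inc.Q2 == 0 and inc.Q1 == 2
        q0 = (inc.T - 1) / inc.T * inc.Q1 * (inc.Q1 - 1) / 2
        curve = bq.rarefaction_curve(inc, [inc.T + 500])
        assert curve["expected_richness"].iloc[0] == pytest.approx(
            inc.S_obs + q0, rel=1e-6
        )

    def test_invalid_t_raises(self, toy_incidence):
        with pytest.raises(ValueError):
            bq.rarefaction_curve(toy_incidence, [0])


class TestOrdination:
    def test_variance_conservation_and_orthogonality(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 30, size=(12, 6)),
            index=[f"s{i}" for i in range(12)],
            columns=[f"t{j}" for j in range(6)],
        )
        res = bq.pca_ordination(counts)
        x = counts.to_numpy(dtype=float)
        x = x / x.sum(axis=1, keepdims=True)
        total_var = x.var(axis=0, ddof=1).sum()
        assert res.explained_variance.sum() == pytest.approx(total_var)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)
        scores = res.scores.to_numpy()
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_two_taxon_closed_form(self):
        # rows already sum to 1; centred columns are (-0.3, 0, 0.3) and its
        # negative, so the 2x2 covariance has eigenvalues (0.18, 0) and PC1
        # scores are +-0.3*sqrt(2)
        counts = toy_counts([[0.2, 0.8], [0.5, 0.5], [0.8, 0.2]])
        res = bq.pca_ordination(counts)
        assert res.explained_variance == pytest.approx([0.18, 0.0], abs=1e-12)
        pc1 = res.scores["PC1"].to_numpy()
        expected = np.array([-0.3 * np.sqrt(2), 0.0, 0.3 * np.sqrt(2)])
        assert np.abs(pc1) == pytest.approx(np.abs(expected))

    def test_hulls_are_convex_subsets_of_scores(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 20, size=(10, 4)),
            index=[f"s{i}" for i in range(10)],
            columns=list("abcd"),
        )
        groups = {s: ("g1" if i < 5 else "g2") for i, s in enumerate(counts.index)}
        res = bq.pca_ordination(counts, groups)
        for label, verts in res.hulls.items():
            pts = res.scores.loc[
                [s for s in counts.index if groups[s] == label], ["PC1", "PC2"]
            ].to_numpy()
            for v in verts:
                assert any(np.allclose(v, p) for p in pts)

    def test_degenerate_group_returns_points(self):
        counts = toy_counts([[1, 2], [2, 1], [3, 3], [1, 1]])
        groups = {"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2"}
        res = bq.pca_ordination(counts, groups)
        assert len(res.hulls["g1"]) <= 2

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            bq.pca_ordination(toy_counts([[1, 2]]))

    def test_locations_separate_more_than_managements(self):
        # distinct taxon pools per location, shared across managements:
        # ordination spreads locations apart while managements overlap
        design = bq.StudyDesign(sampling_dates=6, traps_per_site=5)
        profiles = [
            p for p in bq.default_profiles(num_taxa=40, seed=3)
            if p.taxon_id != CALIBRATOR_TAXON
        ]
        table = bq.generate_specimen_table(design, profiles, seed=4)
        res = bq.pca_ordination(table)
        meta = pd.DataFrame(
            [bq.simulate.parse_sample_id(s) for s in table.index],
            index=table.index, columns=["management", "location", "date"],
        )
        pcs = res.scores[["PC1", "PC2"]]
        loc_dists, mgmt_dists = [], []
        for loc in design.locations:
            sub = pcs[meta["location"] == loc]
            crp = sub[meta.loc[sub.index, "management"] == "CRP"].mean()
            npam = sub[meta.loc[sub.index, "management"] == "NPAM"].mean()
            mgmt_dists.append(np.linalg.norm(crp - npam))
        centroids = {
            loc: pcs[meta["location"] == loc].mean() for loc in design.locations
        }
        for a, b in itertools.combinations(design.locations, 2):
            loc_dists.append(np.linalg.norm(centroids[a] - centroids[b]))
        assert np.mean(loc_dists) > np.mean(mgmt_dists)


class TestGroupSummary:
    def test_mean_and_ci_per_cell(self):
        design = bq.StudyDesign(sampling_dates=5, traps_per_site=2)
        values = pd.Series(
            np.arange(design.n_community_pools, dtype=float),
            index=design.sample_ids(),
        )
        out = group_summary(values)
        assert len(out) == 8  # 4 locations x 2 managements
        assert (out["n"] == 5).all()
        row = out.iloc[0]
        assert row["ci_low"] <= row["mean"] <= row["ci_high"]
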