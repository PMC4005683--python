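"""Scaling, probe-affinity correction, probe selection and the gene index."""

import numpy as np
import pandas as pd
import pytest

from splicearray import (
    SimulationParams,
    correct_probe_effects,
    gene_expression_index,
    generate_design,
    preprocess,
    scale_arrays,
    select_probes,
    simulate_experiment,
)

from conftest import matrix_for


class TestScaleArrays:
    def test_untrimmed_mean_scaling_hand_computed(self, tiny_design):
        # column mean 30, target 100 -> factor 10/3 applied to every value
        col = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        values = np.tile(np.r_[col, col, 20.0, 40.0][:, None], (1, 6))
        mat = matrix_for(tiny_design, values)
        scaled = scale_arrays(mat, target=100.0, trim=0.0)
        np.testing.assert_allclose(
            scaled.values.iloc[:5, 0], [100 / 3, 200 / 3, 100.0, 400 / 3, 500 / 3]
        )
        assert scaled.state == "scaled"

    def test_column_already_at_target_unchanged(self, tiny_design):
        values = np.full((12, 6), 500.0)
        scaled = scale_arrays(matrix_for(tiny_design, values), target=500.0)
        np.testing.assert_allclose(scaled.values.to_numpy(), values)

    def test_per_sample_rescaling_is_absorbed(self, tiny_design):
        rng = np.random.default_rng(0)
        values = rng.lognormal(5, 1, size=(12, 6))
        doubled = values.copy()
        doubled[:, 2] *= 2.0  # one array scanned at twice the gain
        a = scale_arrays(matrix_for(tiny_design, values))
        b = scale_arrays(matrix_for(tiny_design, doubled))
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_all_zero_column_cannot_scale(self, tiny_design):
        values = np.full((12, 6), 100.0)
        values[:, 0] = 0.0
        with pytest.raises(ValueError, match="cannot scale"):
            scale_arrays(matrix_for(tiny_design, values))


class TestCorrectProbeEffects:
    def test_probe_at_twice_gene_median_corrected_onto_median(self, tiny_design):
        values = np.full((12, 6), 200.0)
        values[0, :] = 400.0  # probe 0 always exactly 2x its gene median
        mat = matrix_for(tiny_design, values)
        mat.state = "scaled"
        corrected = correct_probe_effects(mat, tiny_design)
        np.testing.assert_allclose(corrected.values.iloc[0], 200.0)
        assert corrected.state == "background_corrected"

    def test_identical_probes_unchanged(self, tiny_design):
        values = np.full((12, 6), 321.0)
        mat = matrix_for(tiny_design, values)
        mat.state = "scaled"
        corrected = correct_probe_effects(mat, tiny_design)
        np.testing.assert_allclose(corrected.values.to_numpy(), values)

    def test_matches_brute_force_median_residual_oracle(self):
        params = SimulationParams(seed=21, n_genes=15)
        design = generate_design(params)
        mat, _ = simulate_experiment(design, params)
        mat.state = "scaled"
        corrected = correct_probe_effects(mat, design)

        # oracle: per probe, affinity = median_s(log2 x_ps - log2 const_median_gene_s)
        frame = design.probe_frame().set_index("probe_id")
        log2x = np.log2(mat.values)
        expected = {}
        for probe in mat.values.index:
            gene = frame.loc[probe, "gene_id"]
            members = frame.index[
                (frame["gene_id"] == gene) & (frame["group"] == "constitutive")
            ]
            med = log2x.loc[members].median(axis=0)
            affinity = float(np.median(log2x.loc[probe] - med))
            expected[probe] = mat.values.loc[probe] / 2**affinity
        oracle = pd.DataFrame(expected).T.loc[mat.values.index]
        np.testing.assert_allclose(corrected.values.to_numpy(), oracle.to_numpy())

    def test_median_probe_signal_preserved_for_symmetric_affinities(self, tiny_design):
        # affinities symmetric around 0 -> per-sample gene median unchanged
        base = np.full((12, 6), 100.0)
        base[0, :] *= 4.0
        base[1, :] /= 4.0
        mat = matrix_for(tiny_design, base)
        mat.state = "scaled"
        corrected = correct_probe_effects(mat, tiny_design)
        np.testing.assert_allclose(
            np.median(corrected.values.to_numpy(), axis=0),
            np.median(base, axis=0),
        )


class TestSelectProbes:
    def _corrected(self, design, values):
        mat = matrix_for(design, values)
        mat.state = "background_corrected"
        return mat

    def test_proportional_probes_all_kept(self, tiny_design):
        rng = np.random.default_rng(1)
        profile = rng.lognormal(6, 0.5, size=6)
        values = np.outer(np.ones(12), profile) * rng.uniform(0.5, 2.0, size=(12, 1))
        mask = select_probes(self._corrected(tiny_design, values), tiny_design, min_keep=1)
        const = [p for p in tiny_design.probe_ids if p.startswith("psC")]
        assert mask.loc[const].all()

    def test_anticorrelated_probe_dropped(self, tiny_design):
        profile = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        values = np.outer(np.ones(12), 100 * profile)
        values[8, :] = 100 * profile[::-1]  # psC1_p1 exactly anticorrelated, r = -1
        mask = select_probes(self._corrected(tiny_design, values), tiny_design, min_keep=1)
        assert not mask.loc["psC1_p1"]
        assert mask.loc[["psC1_p2", "psC2_p1", "psC2_p2"]].all()

    def test_event_probes_never_selected(self, tiny_design):
        values = np.full((12, 6), 100.0)
        mask = select_probes(self._corrected(tiny_design, values), tiny_design)
        event_probes = [p for p in tiny_design.probe_ids if not p.startswith("psC")]
        assert not mask.loc[event_probes].any()

    def test_min_keep_fallback_keeps_flat_probes(self, tiny_design):
        # zero-variance profiles get r := 0 < r_min, but min_keep rescues them
        values = np.full((12, 6), 100.0)
        mask = select_probes(self._corrected(tiny_design, values), tiny_design, min_keep=3)
        const = [p for p in tiny_design.probe_ids if p.startswith("psC")]
        assert mask.loc[const].all()


class TestGeneIndex:
    def test_index_is_mean_of_selected_probes(self, tiny_design):
        values = np.full((12, 6), 100.0)
        values[8, :] = 400.0  # psC1_p1
        values[9, :] = 600.0  # psC1_p2
        mat = matrix_for(tiny_design, values)
        mat.state = "background_corrected"
        mask = pd.Series(False, index=tiny_design.probe_ids)
        mask.loc[["psC1_p1", "psC1_p2"]] = True
        index = gene_expression_index(mat, mask, tiny_design)
        np.testing.assert_allclose(index.loc["gA"], 500.0)

    def test_single_probe_index_equals_probe(self, tiny_design):
        values = np.full((12, 6), 123.0)
        mat = matrix_for(tiny_design, values)
        mat.state = "background_corrected"
        mask = pd.Series(False, index=tiny_design.probe_ids)
        mask.loc["psC2_p1"] = True
        index = gene_expression_index(mat, mask, tiny_design)
        np.testing.assert_allclose(index.loc["gA"], 123.0)

    def test_index_matches_brute_force_means(self):
        params = SimulationParams(seed=22, n_genes=12)
        design = generate_design(params)
        mat, _ = simulate_experiment(design, params)
        corrected, mask, index = preprocess(mat, design)
        frame = design.probe_frame().set_index("probe_id")
        for gene in index.index:
            sel = [
                p for p in mask[mask].index
                if frame.loc[p, "gene_id"] == gene
            ]
            np.testing.assert_allclose(
                index.loc[gene].to_numpy(), corrected.values.loc[sel].mean(axis=0).to_numpy()
            )

    def test_noise_free_index_recovers_true_expression(self):
        # sd_noise=0, sd_affinity=0: index(g, s) == E_gene exactly
        params = SimulationParams(
            seed=23, n_genes=8, sd_noise=0.0, sd_affinity=0.0, fraction_unexpressed=0.0
        )
        design = generate_design(params)
        mat, truth = simulate_experiment(design, params)
        mat.state = "scaled"  # already on a common scale by construction
        corrected = correct_probe_effects(mat, design)
        mask = select_probes(corrected, design)
        index = gene_expression_index(corrected, mask, design)
        expected = truth.genes.set_index("gene_id")["expr_control"]
        np.testing.assert_allclose(
            index["control_1"].to_numpy(), expected.loc[index.index].to_numpy(), rtol=1e-10
        )
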