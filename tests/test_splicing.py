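"""Splicing index, Fisher combination, probeset stats and event calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from splicearray import (
    SimulationParams,
    call_event,
    call_events,
    fisher_combine,
    generate_design,
    preprocess,
    probe_pvalues,
    probeset_stats,
    simulate_experiment,
    splicing_index,
    summarize_events,
)

from conftest import matrix_for


def _si(design, values):
    mat = matrix_for(design, values)
    mat.state = "background_corrected"
    # use constitutive probes directly as the gene index
    const = [p for p in design.probe_ids if p.startswith("psC")]
    index = mat.values.loc[const].mean(axis=0).to_frame().T
    index.index = pd.Index(["gA"], name="gene_id")
    return splicing_index(mat, index, design), mat


class TestSplicingIndex:
    def test_probe_tracking_gene_has_zero_si(self, tiny_design):
        values = np.full((12, 6), 200.0)
        si, _ = _si(tiny_design, values)
        np.testing.assert_allclose(si.si.to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(si.delta_si.to_numpy(), 0.0, atol=1e-12)

    def test_ratio_doubling_in_treated_gives_delta_one(self, tiny_design):
        values = np.full((12, 6), 200.0)
        values[0, 3:] = 400.0  # psE_p1 doubles relative to its gene in treated
        si, _ = _si(tiny_design, values)
        # the index moved too (psE is not constitutive so index is unchanged)
        assert si.delta_si.loc["psE_p1"] == pytest.approx(1.0, abs=1e-12)
        assert si.delta_si.loc["psB_p1"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_definition(self):
        params = SimulationParams(seed=31, n_genes=10)
        design = generate_design(params)
        mat, _ = simulate_experiment(design, params)
        corrected, _, index = preprocess(mat, design)
        si = splicing_index(corrected, index, design)
        frame = design.probe_frame().set_index("probe_id")
        ctrl = corrected.samples("control")
        trt = corrected.samples("treated")
        for probe in corrected.values.index[::17]:
            gene = frame.loc[probe, "gene_id"]
            expect = np.log2(corrected.values.loc[probe] / index.loc[gene])
            np.testing.assert_allclose(si.si.loc[probe], expect, atol=1e-12)
            np.testing.assert_allclose(
                si.delta_si.loc[probe],
                expect[trt].mean() - expect[ctrl].mean(),
                atol=1e-12,
            )

    def test_label_swap_negates_delta_but_keeps_calls(self):
        params = SimulationParams(
            seed=33, n_genes=60, fraction_regulated_splicing=0.3, delta_psi=0.4
        )
        design = generate_design(params)
        mat, _ = simulate_experiment(design, params)

        def run(mat):
            corrected, _, index = preprocess(mat, design)
            si = splicing_index(corrected, index, design)
            p = probe_pvalues(si, corrected)
            stats = probeset_stats(si, p, design)
            return si, stats, call_events(stats, design)

        si_f, stats_f, ev_f = run(mat)
        swapped = mat.with_values(mat.values, state="raw")
        swapped.condition_map = {
            s: ("treated" if c == "control" else "control")
            for s, c in mat.condition_map.items()
        }
        si_r, stats_r, ev_r = run(swapped)
        np.testing.assert_allclose(si_r.delta_si, -si_f.delta_si, atol=1e-10)
        np.testing.assert_allclose(stats_r["fisher_p"], stats_f["fisher_p"], atol=1e-10)
        assert (stats_r["direction"] == -stats_f["direction"]).all()
        pd.testing.assert_series_equal(ev_r["called"], ev_f["called"])
        assert (ev_r.loc[ev_r["called"], "direction"]
                == -ev_f.loc[ev_f["called"], "direction"]).all()


class TestFisherCombine:
    def test_k1_is_identity_over_grid(self):
        for p in np.logspace(-12, 0, 40):
            assert fisher_combine([p]) == pytest.approx(p, abs=1e-12, rel=1e-9)

    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_two_equal_p_closed_form(self):
        # k=2: combined p = e^(-x/2) (1 + x/2) with x = -2 ln(0.0025)
        x = -2 * math.log(0.05 * 0.05)
        expect = math.exp(-x / 2) * (1 + x / 2)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(expect, rel=1e-12)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(0.017479, abs=5e-7)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            fisher_combine([])

    @given(st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_combined_p_is_valid_probability(self, ps):
        assert 0.0 <= fisher_combine(ps) <= 1.0

    def test_underflow_clipped(self):
        assert fisher_combine([0.0, 0.5]) >= 0.0


def _stats_row(ps, group, p, dsi, alpha=0.01):
    return {
        "probeset_id": ps, "gene_id": "gA", "event_id": "ev1",
        "event_type": "cassette", "group": group, "k": 3,
        "fisher_p": p, "delta_si": dsi, "direction": int(np.sign(dsi)),
        "significant": p <= alpha,
    }


class TestCallEvent:
    def test_cassette_exclusion_plus_one_inclusion_called(self):
        members = pd.DataFrame([
            _stats_row("psE", "exclusion", 0.005, +1.0),
            _stats_row("psB", "inclusion", 0.004, -0.8),
            _stats_row("psJ5", "inclusion", 0.2, -0.1),
            _stats_row("psJ3", "inclusion", 0.2, -0.1),
        ])
        call = call_event(members)
        assert call.called and call.direction == -1  # inclusion down in treated
        assert (call.n_sig_excl, call.n_sig_incl) == (1, 1)

    def test_same_sign_inclusion_blocks_call(self):
        members = pd.DataFrame([
            _stats_row("psE", "exclusion", 0.005, +1.0),
            _stats_row("psB", "inclusion", 0.004, +0.8),  # same sign as exclusion
            _stats_row("psJ5", "inclusion", 0.2, -0.1),
            _stats_row("psJ3", "inclusion", 0.2, -0.1),
        ])
        assert not call_event(members).called

    def test_nothing_significant_not_called(self):
        members = pd.DataFrame([
            _stats_row("psE", "exclusion", 0.5, +1.0),
            _stats_row("psB", "inclusion", 0.5, -0.8),
        ])
        assert not call_event(members).called

    def test_exclusion_side_required(self):
        members = pd.DataFrame([
            _stats_row("psE", "exclusion", 0.5, +1.0),
            _stats_row("psB", "inclusion", 0.001, -0.8),
        ])
        assert not call_event(members).called

    def test_one_third_rule_uses_ceiling(self):
        # 4 inclusion probesets: ceil(4/3) = 2 significant required
        members = pd.DataFrame(
            [_stats_row("psE", "exclusion", 0.001, +1.0)]
            + [_stats_row(f"i{k}", "inclusion", 0.001 if k < 1 else 0.9, -0.5)
               for k in range(4)]
        )
        assert not call_event(members).called
        members.loc[2, "fisher_p"] = 0.001
        members.loc[2, "significant"] = True
        assert call_event(members).called

    def test_indeterminate_exclusion_consensus_not_called(self):
        members = pd.DataFrame([
            _stats_row("e1", "exclusion", 0.001, +1.0),
            _stats_row("e2", "exclusion", 0.001, -1.0),  # consensus sums to 0
            _stats_row("e3", "exclusion", 0.9, 0.0),
            _stats_row("i1", "inclusion", 0.001, -0.5),
        ])
        assert not call_event(members).called

    def test_calling_monotone_in_alpha(self):
        params = SimulationParams(
            seed=35, n_genes=120, fraction_regulated_splicing=0.3, delta_psi=0.4
        )
        design = generate_design(params)
        mat, _ = simulate_experiment(design, params)
        corrected, _, index = preprocess(mat, design)
        si = splicing_index(corrected, index, design)
        p = probe_pvalues(si, corrected)
        called = {}
        for alpha in (0.05, 0.01, 0.001):
            stats = probeset_stats(si, p, design, alpha_ps=alpha)
            ev = call_events(stats, design, alpha_ps=alpha)
            called[alpha] = set(ev.loc[ev["called"], "event_id"])
        assert called[0.001] <= called[0.01] <= called[0.05]


class TestProbesetStats:
    def test_single_probe_probeset_keeps_its_p(self, tiny_design):
        rng = np.random.default_rng(0)
        values = 200 * 2 ** rng.normal(0, 0.2, size=(12, 6))
        si, mat = _si(tiny_design, values)
        probe_p = probe_pvalues(si)
        stats = probeset_stats(si, probe_p, tiny_design)
        # each probeset here has 2 probes; check Fisher against a direct oracle
        for row in stats.itertuples():
            member_p = probe_p[[f"{row.probeset_id}_p1", f"{row.probeset_id}_p2"]]
            x = -2 * np.log(member_p).sum()
            expect = math.exp(-x / 2) * (1 + x / 2)  # chi2 sf, 4 df
            assert row.fisher_p == pytest.approx(expect, rel=1e-10)

    def test_all_p_one_gives_fisher_one(self, tiny_design):
        values = np.full((12, 6), 200.0)
        si, _ = _si(tiny_design, values)
        probe_p = pd.Series(1.0, index=si.si.index)
        stats = probeset_stats(si, probe_p, tiny_design)
        assert np.allclose(stats["fisher_p"], 1.0)
        assert not stats["significant"].any()


class TestSummarize:
    def test_counts_by_category(self):
        ev = pd.DataFrame({
            "event_type": ["cassette", "cassette", "mutually_exclusive", "alt5"],
            "called": [True, True, True, False],
        })
        s = summarize_events(ev).set_index("category")["n_called"]
        assert (s["cassette"], s["mutually_exclusive"], s["alt_ss"], s["total"]) == (2, 1, 0, 3)

    def test_empty(self):
        s = summarize_events(pd.DataFrame())
        assert (s["n_called"] == 0).all()
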