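"""Three-node motif model: integration, invariants, exemplars."""

import numpy as np
import pytest

from primescreen.features import classify_mechanism, evaluate_priming
from primescreen.protocols import StimulusProtocol, standard_protocols
from primescreen.synth import generate_trinode_exemplars
from primescreen.trinode import (
    CANONICAL_TOPOLOGIES,
    MetropolisConfig,
    TriNodeParams,
    TriNodeTopology,
    hill,
    simulate_trinode,
    simulate_trinode_rk4,
    steady_state,
    _Evaluator,
)

PROTOCOLS = standard_protocols(0.03, 1.0, 50.0, 50.0)


@pytest.fixture(scope="module")
def exemplars():
    return generate_trinode_exemplars()


class TestHill:
    def test_half_saturation_and_origin(self):
        for K in (0.01, 0.5, 2.0):
            for n in (1, 2, 3.0):
                assert hill(K, K, n) == pytest.approx(0.5)
                assert hill(0.0, K, n) == 0.0

    def test_monotone_and_bounded(self):
        u = np.linspace(0, 5, 200)
        h = hill(u, 0.4, 3)
        assert np.all(np.diff(h) >= 0)
        assert np.all((h >= 0) & (h < 1))


class TestTopology:
    def test_requires_stimulus_edges(self):
        with pytest.raises(ValueError, match="S->x1 and S->x2"):
            TriNodeTopology.from_dict({("S", "x1"): 1, ("x1", "x3"): 1})

    def test_requires_convergence_on_readout(self):
        with pytest.raises(ValueError, match="x3"):
            TriNodeTopology.from_dict({("S", "x1"): 1, ("S", "x2"): 1})

    def test_stimulus_has_no_incoming_edges(self):
        with pytest.raises(ValueError, match="no incoming"):
            TriNodeTopology.from_dict(
                {("S", "x1"): 1, ("S", "x2"): 1, ("x1", "x3"): 1,
                 ("x1", "S"): 1}
            )


class TestSimulation:
    def test_zero_stimulus_steady_state_is_flat(self, exemplars):
        topo, params = exemplars["PS"]
        tc = simulate_trinode(topo, params, PROTOCOLS["untreated"])
        for name in tc.names:
            traj = tc[name]
            assert np.all(np.abs(traj - traj[0]) < 1e-5)

    def test_trajectories_stay_in_unit_box(self, exemplars):
        for topo, params in exemplars.values():
            tc = simulate_trinode(topo, params, PROTOCOLS["LD_HD"])
            assert tc.values.min() >= 0.0
            assert tc.values.max() <= 1.0

    def test_box_invariance_from_random_parameters(self, rng):
        """The RHS keeps the state in [0,1]^3 even for random kinetics."""
        topo = CANONICAL_TOPOLOGIES["SD"]
        for _ in range(5):
            params = TriNodeParams(
                k=rng.uniform(0.05, 4.0, 3),
                gamma=rng.uniform(0.005, 1.5, 3),
                w={e: rng.uniform(0.3, 5.0) for e, _ in topo.edges},
                K={e: rng.uniform(0.01, 2.0) for e, _ in topo.edges},
            )
            tc = simulate_trinode(topo, params, PROTOCOLS["LD_HD"])
            assert tc.values.min() >= -1e-9
            assert tc.values.max() <= 1.0 + 1e-9

    def test_adaptive_agrees_with_fixed_step_rk4_reference(self, exemplars):
        """Integration oracle: sup-norm agreement within 1e-4."""
        for name, (topo, params) in exemplars.items():
            adaptive = simulate_trinode(
                topo, params, PROTOCOLS["LD_HD"], n_points_per_segment=50,
                rtol=1e-9, atol=1e-11,
            )
            reference = simulate_trinode_rk4(
                topo, params, PROTOCOLS["LD_HD"], h=0.005
            )
            for var in ("x1", "x2", "x3"):
                ref = np.interp(adaptive.times, reference.times, reference[var])
                err = np.abs(adaptive[var] - ref).max()
                assert err < 1e-4, f"{name}/{var}: sup-norm {err:.2e}"

    def test_steady_state_has_small_rhs(self, exemplars):
        from primescreen.trinode import _compiled_rhs

        topo, params = exemplars["SD"]
        x = steady_state(topo, params, 0.0)
        assert np.linalg.norm(_compiled_rhs(topo, params)(x, 0.0)) < 1e-7


class TestExemplars:
    def test_each_exemplar_is_primed_and_classifies_to_its_label(
        self, exemplars
    ):
        cfg = MetropolisConfig(seed=0)
        ev = _Evaluator(cfg)
        for name, (topo, params) in exemplars.items():
            score, tcs = ev.full_score(topo, params)
            feats = ev.features(tcs)
            assert evaluate_priming(feats)["primed"], name
            assert classify_mechanism(
                feats, graph=topo.to_signed_graph()
            ).label == name

    def test_ld_pretreatment_advances_the_slow_activator(self, exemplars):
        """PS/AI signature: the LD-inducible pathway reaches its working
        level earlier (relative to HD onset) in the primed arm."""
        for name in ("PS", "AI"):
            topo, params = exemplars[name]
            hd = simulate_trinode(topo, params, PROTOCOLS["HD"])
            ldhd = simulate_trinode(topo, params, PROTOCOLS["LD_HD"])
            level = 0.5 * hd.max_in("x2", 50.0, 100.0)
            t_hd = _first_crossing(hd, "x2", level, 50.0)
            t_ldhd = _first_crossing(ldhd, "x2", level, 50.0)
            assert t_ldhd < t_hd, name

    def test_ld_pretreatment_delays_the_suppressor(self, exemplars):
        """SD signature: the suppressor, pre-lowered by LD, reaches its
        inhibiting level later after HD onset in the primed arm."""
        topo, params = exemplars["SD"]
        hd = simulate_trinode(topo, params, PROTOCOLS["HD"])
        ldhd = simulate_trinode(topo, params, PROTOCOLS["LD_HD"])
        level = 0.9 * hd.max_in("x1", 50.0, 100.0)
        t_hd = _first_crossing(hd, "x1", level, 50.0)
        t_ldhd = _first_crossing(ldhd, "x1", level, 50.0)
        assert t_ldhd > t_hd


def _first_crossing(tc, var, level, t_start):
    mask = tc.times >= t_start
    t, v = tc.times[mask], tc[var][mask]
    above = np.nonzero(v >= level)[0]
    return t[above[0]] if above.size else np.inf


class TestSearchMachinery:
    def test_same_seed_reproduces_record_list(self):
        from primescreen.trinode import metropolis_search

        cfg = MetropolisConfig(
            seed=3, total_budget=900, chain_budget=450, stage1_iters=60,
            stage2_iters=150, nm_maxfev=80, nm_rounds=1, walk_iters=30,
            n_chains=2,
        )
        prior = [CANONICAL_TOPOLOGIES["PS"]]
        r1 = metropolis_search(cfg, prior)
        r2 = metropolis_search(cfg, prior)
        assert len(r1) == len(r2)
        for a, b in zip(r1, r2):
            assert np.allclose(a.params.k, b.params.k)
            assert a.label.label == b.label.label

    def test_swap_regulators_is_an_exact_relabeling(self, exemplars):
        from primescreen.trinode import _swap_x1_x2

        topo, params = exemplars["SD"]
        topo2, params2 = _swap_x1_x2(topo, params)
        tc = simulate_trinode(topo, params, PROTOCOLS["LD_HD"])
        tc2 = simulate_trinode(topo2, params2, PROTOCOLS["LD_HD"])
        assert np.allclose(tc["x1"], tc2["x2"], atol=1e-9)
        assert np.allclose(tc["x2"], tc2["x1"], atol=1e-9)
        assert np.allclose(tc["x3"], tc2["x3"], atol=1e-9)


class TestSummaries:
    def test_summarize_regions_rows_match_labels(self, exemplars):
        from primescreen.trinode import (
            PrimedNetworkRecord, summarize_regions,
        )

        cfg = MetropolisConfig(seed=0)
        ev = _Evaluator(cfg)
        records = []
        for name, (topo, params) in exemplars.items():
            _, tcs = ev.full_score(topo, params)
            feats = ev.features(tcs)
            records.append(
                PrimedNetworkRecord(
                    topo, params, feats,
                    classify_mechanism(feats, graph=topo.to_signed_graph()),
                )
            )
        table, hists = summarize_regions(records)
        assert set(table["label"]) == {"PS", "AI", "SD"}
        sd_rows = table[table.label == "SD"]
        assert (sd_rows["dss_x1_ld"] < -0.1).all()
        ps_rows = table[table.label == "PS"]
        assert (ps_rows["dmax_diff_x2"] > 0.1).all()
        ai_rows = table[table.label == "AI"]
        assert (ai_rows["dmax_diff_x2"].abs() <= 0.1).all()
        assert "PS" in hists and "dmax_diff_x2" in hists["PS"]
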