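"""Single-isotherm and global least-squares inference."""

import numpy as np
import pytest

from allofit.binding import BindingModel, SiteClass
from allofit.experiment import (
    make_synthetic_panel,
    myristate_binding_model,
    myristate_titration_config,
    simulate_isotherm,
    zinc_binding_model,
    zinc_titration_config,
)
from allofit.fitting import (
    ParameterSpec,
    fit_global,
    fit_single_isotherm,
    occupancy_vs_condition,
)
from conftest import TRUTH


def start_model():
    """Deliberately displaced starting model for the two-class Zn fits."""
    return BindingModel([SiteClass(1.3, 8e4, -7e3), SiteClass(1.6, 8e3, -2e4)])


class TestSingleFit:
    def test_noiseless_round_trip(self, noiseless_isotherm):
        res = fit_single_isotherm(noiseless_isotherm, start_model(), n_starts=1)
        assert res.converged
        for name, truth in TRUTH.items():
            assert res.params[name].value == pytest.approx(truth, rel=1e-6)

    def test_site_absent_gives_zero_stoichiometry(self):
        # generator lacks the high-affinity class; fitting with K1/dH1
        # fixed at "wild-type" values and N free must drive N1 to ~0,
        # the signature of a knocked-out high-affinity site
        truth_model = BindingModel([SiteClass(2.0, TRUTH["k2"], TRUTH["dh2"])])
        iso = simulate_isotherm(truth_model, zinc_titration_config())
        specs = [
            ParameterSpec("k1", TRUTH["k1"], fixed=True),
            ParameterSpec("dh1", TRUTH["dh1"], fixed=True),
            ParameterSpec("n1", 1.0, lower=0.0, upper=3.0),
            ParameterSpec("n2", 2.0, lower=0.0, upper=5.0),
        ]
        res = fit_single_isotherm(iso, zinc_binding_model(), specs, n_starts=4)
        assert res.converged
        assert abs(res.params["n1"].value) < 0.02
        assert res.params["n2"].value == pytest.approx(2.0, abs=0.05)

    def test_attenuated_sites_drop_proportionally(self):
        # both classes attenuated in the generator; with all K/dH fixed
        # the fitted stoichiometries track the attenuation factors
        truth_model = BindingModel(
            [
                SiteClass(0.5, TRUTH["k1"], TRUTH["dh1"]),
                SiteClass(0.7, TRUTH["k2"], TRUTH["dh2"]),
            ]
        )
        iso = simulate_isotherm(truth_model, zinc_titration_config())
        specs = [
            ParameterSpec("k1", TRUTH["k1"], fixed=True),
            ParameterSpec("dh1", TRUTH["dh1"], fixed=True),
            ParameterSpec("k2", TRUTH["k2"], fixed=True),
            ParameterSpec("dh2", TRUTH["dh2"], fixed=True),
            ParameterSpec("n1", 1.0, lower=0.0, upper=3.0),
            ParameterSpec("n2", 2.0, lower=0.0, upper=5.0),
        ]
        res = fit_single_isotherm(iso, zinc_binding_model(), specs, n_starts=1)
        assert res.params["n1"].value == pytest.approx(0.5, abs=0.01)
        assert res.params["n2"].value == pytest.approx(0.7, abs=0.01)

    def test_myristate_three_class_fixed_stoichiometries(self):
        # three sets of sites with N fixed to 2/1/4; K and dH free
        model = myristate_binding_model()
        cfg = myristate_titration_config()
        iso = make_synthetic_panel(
            31, [1.0], noise_sd=None, model=model, config=cfg
        )[0]
        start = BindingModel(
            [
                SiteClass(2.0, 5e6, -1.5e4),
                SiteClass(1.0, 1e5, -1e4),
                SiteClass(4.0, 1e4, -5e3),
            ]
        )
        specs = [
            ParameterSpec("n1", 2.0, fixed=True),
            ParameterSpec("n2", 1.0, fixed=True),
            ParameterSpec("n3", 4.0, fixed=True),
        ]
        res = fit_single_isotherm(iso, start, specs, n_starts=4, seed=3)
        assert res.converged
        # 1% heat noise: K recovered within its noise-scaled confidence
        # interval (the adjacent classes overlap, so the intervals are wide)
        for name, truth in [("k1", 1.76e6), ("k2", 3.91e5), ("k3", 3.11e4)]:
            p = res.params[name]
            assert p.stderr is not None
            assert abs(p.value - truth) < 2.5 * p.stderr

    def test_myristate_three_class_noiseless_round_trip(self):
        iso = simulate_isotherm(myristate_binding_model(), myristate_titration_config())
        start = BindingModel(
            [
                SiteClass(2.0, 5e6, -1.5e4),
                SiteClass(1.0, 1e5, -1e4),
                SiteClass(4.0, 1e4, -5e3),
            ]
        )
        specs = [
            ParameterSpec("n1", 2.0, fixed=True),
            ParameterSpec("n2", 1.0, fixed=True),
            ParameterSpec("n3", 4.0, fixed=True),
        ]
        res = fit_single_isotherm(iso, start, specs, n_starts=4, seed=0)
        for name, truth in [("k1", 1.76e6), ("k2", 3.91e5), ("k3", 3.11e4)]:
            assert res.params[name].value == pytest.approx(truth, rel=1e-6)

    def test_fixed_parameters_do_not_move(self, noiseless_isotherm):
        specs = [ParameterSpec("k1", 1.23e5, fixed=True)]
        res = fit_single_isotherm(
            noiseless_isotherm, start_model(), specs, n_starts=1
        )
        assert res.params["k1"].value == pytest.approx(1.23e5, rel=1e-12)

    def test_all_fixed_rejected(self, noiseless_isotherm, zinc_model):
        specs = [
            ParameterSpec(name, TRUTH[name], fixed=True) for name in TRUTH
        ]
        with pytest.raises(ValueError, match="free"):
            fit_single_isotherm(noiseless_isotherm, zinc_model, specs)

    def test_fixing_at_optimum_leaves_chi2(self, noiseless_isotherm):
        free = fit_single_isotherm(noiseless_isotherm, start_model(), n_starts=1)
        specs = [ParameterSpec("k1", free.params["k1"].value, fixed=True)]
        fixed = fit_single_isotherm(
            noiseless_isotherm, free.model, specs, n_starts=1
        )
        assert fixed.chi2 <= free.chi2 + 1e-14

    def test_log_and_linear_k_agree(self, noiseless_isotherm):
        a = fit_single_isotherm(noiseless_isotherm, start_model(), n_starts=1)
        b = fit_single_isotherm(
            noiseless_isotherm, start_model(), n_starts=1, log_k=False
        )
        for name in ("k1", "k2", "dh1", "n1"):
            assert a.params[name].value == pytest.approx(
                b.params[name].value, rel=1e-4
            )

    def test_identifiability_guard_flags_close_affinities(self):
        # two classes with K within a factor of 2 are barely separable;
        # the fit must report the near-degeneracy, not hide it
        close = BindingModel(
            [SiteClass(1.0, 2.0e5, -1.2e4), SiteClass(1.0, 1.2e5, -2.2e4)]
        )
        iso = make_synthetic_panel(9, [1.0], model=close)[0]
        start = BindingModel(
            [SiteClass(1.0, 3e5, -1e4), SiteClass(1.0, 1e5, -2e4)]
        )
        res = fit_single_isotherm(iso, start, n_starts=1)
        assert any("correlation" in f for f in res.flags)

    def test_exclude_first_drops_one_observation(self, noiseless_isotherm):
        res = fit_single_isotherm(
            noiseless_isotherm, start_model(), n_starts=1, exclude_first=True
        )
        assert res.n_obs == len(noiseless_isotherm) - 1

    def test_recovery_unbiased_at_one_percent_noise(self):
        # the field's standard strategy (stoichiometries fixed) on a
        # small replicate study; the 200-replicate bias check runs in
        # the acceptance suite
        specs = [
            ParameterSpec("n1", 1.0, fixed=True),
            ParameterSpec("n2", 2.0, fixed=True),
        ]
        start = BindingModel([SiteClass(1.0, 8e4, -7e3), SiteClass(2.0, 8e3, -2e4)])
        k1s = []
        for seed in range(50):
            iso = make_synthetic_panel(seed, [1.0])[0]
            res = fit_single_isotherm(iso, start, specs, n_starts=1)
            if res.converged:
                k1s.append(res.params["k1"].value)
        assert np.median(k1s) == pytest.approx(TRUTH["k1"], rel=0.02)


class TestBootstrap:
    def test_bootstrap_errors_match_jacobian_scale(self):
        from allofit.fitting import bootstrap_standard_errors

        specs = [
            ParameterSpec("n1", 1.0, fixed=True),
            ParameterSpec("n2", 2.0, fixed=True),
        ]
        start = BindingModel([SiteClass(1.0, 8e4, -7e3), SiteClass(2.0, 8e3, -2e4)])
        iso = make_synthetic_panel(11, [1.0])[0]
        base = fit_single_isotherm(iso, start, specs, n_starts=1)
        boot = bootstrap_standard_errors(
            iso, start, specs, n_boot=30, seed=1, n_starts=1
        )
        # same order of magnitude as the Jacobian-based error for K1
        jac_se = base.params["k1"].stderr
        assert 0.2 * jac_se < boot["k1"] < 5.0 * jac_se
        # seeded determinism
        boot2 = bootstrap_standard_errors(
            iso, start, specs, n_boot=30, seed=1, n_starts=1
        )
        assert boot == boot2


def make_panel(seed=42, noise_sd=None):
    theta_wt = list(np.linspace(1.0, 0.1, 6))
    theta_ko = [1.0] * 6
    meta = [{"condition": "WT", "fa_mol_eq": i} for i in range(6)] + [
        {"condition": "FA2-KO", "fa_mol_eq": i} for i in range(6)
    ]
    panel = make_synthetic_panel(
        seed, theta_wt + theta_ko, noise_sd=noise_sd, metadata=meta
    )
    return panel, theta_wt + theta_ko, meta


GLOBAL_SPECS = [
    ParameterSpec("n1", 1.0, fixed=True),
    ParameterSpec("n2", 2.0, fixed=True),
]


def global_start():
    return BindingModel([SiteClass(1.0, 1e5, -8e3), SiteClass(2.0, 1e4, -2e4)])


class TestGlobalFit:
    def test_recovers_theta_and_shared_k(self):
        panel, truth_theta, meta = make_panel()
        res = fit_global(panel, global_start(), GLOBAL_SPECS)
        assert res.converged
        fitted = [t.value for t in res.occupancy]
        assert np.max(np.abs(np.array(fitted) - np.array(truth_theta))) < 0.05
        assert res.shared["k1"].value == pytest.approx(2.9e5, rel=0.10)
        # arm separation: WT monotone trend down, KO all near 1
        assert all(t > 0.9 for t in fitted[6:])

    def test_shared_parameter_exact_across_isotherms(self):
        panel, _, _ = make_panel()
        res = fit_global(panel, global_start(), GLOBAL_SPECS)
        k1_values = {r.params["k1"].value for r in res.per_isotherm}
        assert len(k1_values) == 1

    def test_single_isotherm_panel_matches_single_fit(self, noiseless_isotherm):
        specs = GLOBAL_SPECS + [
            ParameterSpec("k2", TRUTH["k2"], fixed=True),
            ParameterSpec("dh2", TRUTH["dh2"], fixed=True),
        ]
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = fit_global(
                [noiseless_isotherm], global_start(), specs, theta0=0.8
            )
        # theta plays the role of N1: a noiseless occupancy-1 isotherm
        # must return theta = 1 and the generating K1/dH1
        assert res.occupancy[0].value == pytest.approx(1.0, abs=1e-6)
        assert res.shared["k1"].value == pytest.approx(TRUTH["k1"], rel=1e-5)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            fit_global([], global_start(), GLOBAL_SPECS)


@pytest.fixture(scope="module")
def fit():
    panel, truth, meta = make_panel()
    res = fit_global(panel, global_start(), GLOBAL_SPECS)
    return res, meta


class TestOccupancyTable:
    def test_table_rows_and_sorting(self, fit):
        res, meta = fit
        table = occupancy_vs_condition(res, meta, key="condition", sort_key="fa_mol_eq")
        assert len(table) == 12
        assert set(table["condition"]) == {"WT", "FA2-KO"}
        assert list(table["fa_mol_eq"]) == sorted(table["fa_mol_eq"])

    def test_wild_type_arm_monotone_non_increasing(self, fit):
        res, meta = fit
        table = occupancy_vs_condition(res, meta, key="condition", sort_key="fa_mol_eq")
        wt = table[table["condition"] == "WT"].sort_values("fa_mol_eq")
        # fitted occupancy tracks the descending generator schedule
        assert np.all(np.diff(wt["theta"]) < 0.05)
        assert wt["theta"].iloc[0] > 0.9
        assert wt["theta"].iloc[-1] < 0.2

    def test_missing_metadata_key(self, fit):
        res, meta = fit
        with pytest.raises(KeyError):
            occupancy_vs_condition(res, meta, key="nonexistent")

    def test_theta_errors_shrink_with_noise(self):
        ses = []
        ref = simulate_isotherm(zinc_binding_model(), zinc_titration_config())
        peak = np.max(np.abs(ref.heats))
        for frac in (0.02, 0.005):
            panel, _, meta = make_panel(seed=5, noise_sd=frac * peak)
            res = fit_global(panel, global_start(), GLOBAL_SPECS)
            ses.append(np.mean([t.stderr for t in res.occupancy]))
        assert ses[1] < ses[0]
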