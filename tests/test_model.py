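"""The additive-stability logistic model, its initialization, fit and errors."""

import itertools
import math

import numpy as np
import pytest

from gmma.genotype import ProteinVariant, Substitution, substitution_stats
from gmma.model import (
    DESTABILIZING,
    FATAL,
    NEUTRAL,
    STABILIZING,
    UNKNOWN,
    FitSettings,
    GmmaFitResult,
    GmmaParameters,
    burden_curve,
    categorize,
    category_counts,
    global_fit,
    mean_field_init,
    p_active,
    reliability_filter,
    sigmoid_activity,
    standard_uncertainties,
    variant_dG,
)

S1 = Substitution(48, "A", "V")
S2 = Substitution(49, "L", "P")
S3 = Substitution(50, "G", "R")


def V(subs, active=None) -> ProteinVariant:
    return ProteinVariant(substitutions=tuple(sorted(subs, key=lambda s: s.residue)),
                          active=active)


def params(dG_ref=-27.9, RT=2.52, **ddg) -> GmmaParameters:
    named = {"S1": S1, "S2": S2, "S3": S3}
    return GmmaParameters(dG_ref=dG_ref, ddG={named[k]: v for k, v in ddg.items()}, RT=RT)


class TestVariantDG:
    def test_empty_variant_is_reference(self):
        assert variant_dG(params(), V([])) == pytest.approx(-27.9)

    def test_additive_sum(self):
        assert variant_dG(params(S1=5.0), V([S1])) == pytest.approx(-22.9)

    def test_order_invariant(self):
        p = params(S1=1.0, S2=-2.0, S3=0.5)
        assert variant_dG(p, V([S1, S2, S3])) == pytest.approx(
            variant_dG(p, V([S3, S1, S2]))
        )

    def test_unknown_substitution_raises(self):
        with pytest.raises(KeyError):
            variant_dG(params(), V([S1]))


class TestPActive:
    def test_midpoint(self):
        assert p_active(params(dG_ref=0.0), V([])) == pytest.approx(0.5)

    def test_reference_stability_is_almost_surely_active(self):
        # 1/(1+exp(-27.9/2.52)) evaluated independently
        expected = 1.0 / (1.0 + math.exp(-27.9 / 2.52))
        assert expected == pytest.approx(0.9999845, abs=1e-6)
        assert p_active(params(), V([])) == pytest.approx(expected, rel=1e-12)

    def test_sigmoid_symmetry(self):
        lo = p_active(params(dG_ref=27.9), V([]))
        hi = p_active(params(dG_ref=-27.9), V([]))
        assert lo == pytest.approx(1.5539e-5, rel=1e-3)
        assert lo + hi == pytest.approx(1.0, abs=1e-12)

    def test_overflow_guarded(self):
        # extreme energies evaluate without overflow and saturate the link
        assert 0.0 <= p_active(params(dG_ref=1e6), V([])) < 1e-100
        assert 1.0 - 1e-15 <= p_active(params(dG_ref=-1e6), V([])) <= 1.0

    def test_destabilizing_substitution_decreases_p(self):
        p = params(dG_ref=-5.0, S1=3.0)
        assert p_active(p, V([S1])) < p_active(p, V([]))

    def test_scale_covariance(self):
        # only dG/RT is identified: rescaling all energies and RT together
        # leaves every activity probability unchanged
        base = params(dG_ref=-7.0, S1=2.0, S2=-1.5)
        scaled = GmmaParameters(dG_ref=base.dG_ref * 3.7,
                                ddG={s: v * 3.7 for s, v in base.ddG.items()},
                                RT=base.RT * 3.7)
        for variant in (V([]), V([S1]), V([S1, S2])):
            assert p_active(base, variant) == pytest.approx(
                p_active(scaled, variant), rel=1e-12
            )


class TestBurdenCurve:
    def test_all_active(self):
        curve = burden_curve([V([], True), V([S1], True), V([S1, S2], True)])
        assert (curve["fraction_active"] == 1.0).all()

    def test_fractions(self):
        variants = [V([S1, S2], True)] * 3 + [V([S1, S3], False)]
        curve = burden_curve(variants)
        assert curve.loc[2, "fraction_active"] == pytest.approx(0.75)
        assert curve.loc[2, "n_variants"] == 4

    def test_matches_group_by_oracle(self, small_screen):
        variants, _, _ = small_screen
        curve = burden_curve(variants)
        for n in curve.index:
            group = [v for v in variants if v.n_sub == n]
            assert curve.loc[n, "n_variants"] == len(group)
            assert curve.loc[n, "fraction_active"] == pytest.approx(
                sum(v.active for v in group) / len(group)
            )


def mixed_toy():
    """Replicated observations with conflicting labels: the least-squares
    optimum is interior, so grid search can locate it."""
    return (
        [V([], True)] * 4 + [V([], False)]
        + [V([S1], True)] * 2 + [V([S1], False)] * 3
        + [V([S2], True)] + [V([S2], False)] * 4
        + [V([S1, S2], False)] * 3 + [V([S1, S2], True)]
    )


def rss_of(variants, dG_ref, ddg_map, RT=2.52):
    total = 0.0
    for v in variants:
        dG = dG_ref + sum(ddg_map[s] for s in v.substitutions)
        total += (float(v.active) - sigmoid_activity(dG, RT)) ** 2
    return total


class TestMeanFieldInit:
    def test_all_active_degenerate_clamps(self):
        settings = FitSettings()
        variants = [V([S1], True), V([S2], True), V([S1, S2], True)]
        init = mean_field_init(variants, settings=settings)
        assert init.ddG[S1] == settings.ddg_bounds[0]
        assert init.ddG[S2] == settings.ddg_bounds[0]
        # reference driven deep into the fully-stable (flat) regime
        assert init.dG_ref <= -20
        assert sigmoid_activity(init.dG_ref, init.RT) > 1 - 1e-3

    def test_one_sided_substitution_clamped_up(self):
        settings = FitSettings()
        variants = (
            [V([S1], True), V([S1], False)] * 3
            + [V([S2], False), V([S1, S2], False)] * 2
        )
        init = mean_field_init(variants, settings=settings)
        assert init.ddG[S2] == settings.ddg_bounds[1]

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            mean_field_init([])

    def test_per_substitution_step_matches_grid_oracle(self):
        # each ddG_s must minimize its own 1-D objective: compare against a
        # dense 0.01 kJ/mol grid of that same objective
        rng = np.random.default_rng(4)
        variants = []
        for subs in ([S1], [S2], [S3], [S1, S2], [S2, S3], [S1, S3], [S1, S2, S3]):
            for _ in range(3):
                variants.append(V(subs, bool(rng.integers(0, 2))))
        init = mean_field_init(variants)
        RT = init.RT

        curve = burden_curve(variants)
        # recover the background parameters the same way step (a) defines them
        from scipy.optimize import least_squares

        n = curve.index.to_numpy(dtype=float)
        frac = curve["fraction_active"].to_numpy()
        w = np.sqrt(curve["n_variants"].to_numpy(dtype=float))
        fit = least_squares(
            lambda th: w * (frac - sigmoid_activity(th[0] + n * th[1], RT)),
            x0=np.array([-5.0, 1.0]), bounds=([-60.0, -10.0], [60.0, 40.0]),
        )
        d0, m = fit.x

        grid = np.arange(-40.0, 40.0, 0.01)
        for s in (S1, S2, S3):
            group = [v for v in variants if s in v.substitutions]
            y = np.array([float(v.active) for v in group])
            background = d0 + (np.array([v.n_sub for v in group]) - 1.0) * m
            losses = np.array([
                np.sum((y - sigmoid_activity(background + g, RT)) ** 2) for g in grid
            ])
            best = grid[int(np.argmin(losses))]
            assert abs(init.ddG[s] - best) < 0.05


class TestGlobalFit:
    def test_two_parameter_toy_matches_dense_grid(self):
        variants = mixed_toy()
        dG_ref = -1.0
        settings = FitSettings(dg_ref_bounds=(dG_ref, dG_ref))  # pin the reference
        init = GmmaParameters(dG_ref=dG_ref, ddG={S1: 0.0, S2: 0.0})
        fit = global_fit(variants, init, settings)

        grid = np.arange(-12.0, 12.0, 0.05)
        best, best_rss = None, np.inf
        for a in grid:
            for b in grid:
                rss = rss_of(variants, dG_ref, {S1: a, S2: b})
                if rss < best_rss:
                    best, best_rss = (a, b), rss
        assert fit.parameters.dG_ref == dG_ref
        assert abs(fit.parameters.ddG[S1] - best[0]) < 0.05
        assert abs(fit.parameters.ddG[S2] - best[1]) < 0.05
        assert fit.rss <= best_rss + 1e-6

    def test_three_free_parameters_beat_refined_grid(self):
        variants = mixed_toy()
        init = mean_field_init(variants)
        fit = global_fit(variants, init)

        # coarse-to-fine grid over (dG_ref, ddG1, ddG2), independent of LM
        lo, hi, step = -12.0, 12.0, 0.4
        centre = (0.0, 0.0, 0.0)
        for _ in range(6):
            axes = [np.arange(c - 3 * step, c + 3 * step + 1e-9, step) for c in centre]
            best, best_rss = centre, np.inf
            for d0, a, b in itertools.product(*axes):
                rss = rss_of(variants, d0, {S1: a, S2: b})
                if rss < best_rss:
                    best, best_rss = (d0, a, b), rss
            centre, step = best, step / 3.0
        assert fit.rss <= best_rss + 1e-6

    def test_rss_never_exceeds_init(self, small_screen):
        variants, _, _ = small_screen
        dataset = [v for v in variants if not v.has_nonsense]
        init = mean_field_init(dataset)
        init_rss = rss_of(dataset, init.dG_ref, init.ddG, init.RT)
        fit = global_fit(dataset, init, FitSettings(max_iterations=30))
        assert fit.rss <= init_rss + 1e-9

    def test_noiseless_truth_is_a_fixed_point(self):
        # threshold labels from strongly saturated true energies: the truth
        # is a (numerically) zero-residual point, so the fit must stay put
        truth = GmmaParameters(dG_ref=-40.0, ddG={S1: 120.0, S2: -40.0}, RT=2.52)
        variants = [
            V([], True), V([S1], False), V([S2], True), V([S1, S2], False),
        ]  # signs of dG: -40, +80, -80, +40
        settings = FitSettings(ddg_bounds=(-200.0, 200.0), dg_ref_bounds=(-200.0, 200.0))
        fit = global_fit(variants, truth, settings)
        assert fit.rss < 1e-10
        assert fit.converged and fit.iterations == 0
        assert fit.parameters.dG_ref == pytest.approx(truth.dG_ref, abs=1e-3)
        for s in (S1, S2):
            assert fit.parameters.ddG[s] == pytest.approx(truth.ddG[s], abs=1e-3)

    def test_non_convergence_is_flagged_not_raised(self):
        variants = mixed_toy()
        fit = global_fit(variants, mean_field_init(variants),
                         FitSettings(max_iterations=1))
        assert fit.converged is False

    def test_missing_init_entry_raises(self):
        with pytest.raises(KeyError):
            global_fit([V([S1], True)], GmmaParameters(dG_ref=0.0, ddG={}))


class TestStandardUncertainties:
    def test_matches_finite_difference_jacobian(self):
        # oracle: numerical Jacobian of the residual vector -> same covariance
        variants = mixed_toy()
        init = mean_field_init(variants)
        fit = global_fit(variants, init)
        fit = standard_uncertainties(fit, variants)

        subs = sorted({s for v in variants for s in v.substitutions},
                      key=lambda s: (s.residue, s.mut_aa))
        x0 = np.array([fit.parameters.dG_ref] + [fit.parameters.ddG[s] for s in subs])

        def residuals(x):
            ddg = dict(zip(subs, x[1:]))
            return np.array([
                float(v.active) - sigmoid_activity(
                    x[0] + sum(ddg[s] for s in v.substitutions), 2.52)
                for v in variants
            ])

        eps = 1e-6
        J = np.column_stack([
            (residuals(x0 + eps * np.eye(len(x0))[j]) - residuals(x0 - eps * np.eye(len(x0))[j]))
            / (2 * eps)
            for j in range(len(x0))
        ])
        dof = len(variants) - len(x0)
        cov = (fit.rss / dof) * np.linalg.pinv(J.T @ J, hermitian=True)
        su_oracle = np.sqrt(cov.diagonal())
        assert fit.su_dG_ref == pytest.approx(su_oracle[0], rel=0.01)
        for j, s in enumerate(subs):
            assert fit.su[s] == pytest.approx(su_oracle[j + 1], rel=0.01)

    def test_duplicated_dataset_shrinks_su_by_sqrt2(self):
        variants = mixed_toy()
        fit1 = standard_uncertainties(
            global_fit(variants, mean_field_init(variants)), variants
        )
        doubled = variants + variants
        fit2 = standard_uncertainties(
            global_fit(doubled, mean_field_init(doubled)), doubled
        )
        n, p = len(variants), 3
        # exact dof-corrected expectation; -> 1/sqrt(2) as n grows
        expected = math.sqrt((2 * fit1.rss / (2 * n - p)) / (fit1.rss / (n - p)) / 2)
        for s in (S1, S2):
            assert fit2.su[s] / fit1.su[s] == pytest.approx(expected, rel=0.02)
        assert expected == pytest.approx(1 / math.sqrt(2), rel=0.06)

    def test_hanging_substitution_gets_capped_sentinel(self):
        settings = FitSettings()
        variants = mixed_toy() + [V([S3], True)]   # S3 seen exactly once
        fit = global_fit(variants, mean_field_init(variants), settings)
        fit = standard_uncertainties(fit, variants, settings)
        assert fit.su[S3] == settings.su_cap
        assert fit.su[S1] < settings.su_cap

    def test_underdetermined_raises(self):
        variants = [V([S1], True), V([S2], False)]
        fit = global_fit(variants, mean_field_init(variants))
        with pytest.raises(ValueError):
            standard_uncertainties(fit, variants)


def make_fit(ddg_su: dict, dG_ref=-27.9) -> GmmaFitResult:
    fit = GmmaFitResult(
        parameters=GmmaParameters(dG_ref=dG_ref, ddG={s: v for s, (v, _) in ddg_su.items()})
    )
    fit.su = {s: su for s, (_, su) in ddg_su.items()}
    return fit


def fake_stats(n_by_sub: dict):
    from gmma.genotype import SubstitutionStats

    return {s: SubstitutionStats(n_variants=n, n_active=n // 2, n_inactive=n - n // 2)
            for s, n in n_by_sub.items()}


class TestReliabilityFilter:
    @pytest.mark.parametrize(
        "n, su, reliable",
        [(41, 5.0, True), (39, 1.0, False), (100, 6.31, False), (40, 6.3, True)],
    )
    def test_rules(self, n, su, reliable):
        fit = make_fit({S1: (-2.0, su)})
        got = reliability_filter(fit, fake_stats({S1: n}))
        assert (S1 in got) is reliable


class TestCategorize:
    @pytest.mark.parametrize(
        "ddg, su, reliable, expected",
        [
            (-3.0, 1.0, True, STABILIZING),
            (+0.5, 1.0, True, NEUTRAL),
            (+5.0, 1.0, True, DESTABILIZING),
            (+30.0, 50.0, False, DESTABILIZING),   # beyond -dG_ref despite noise
            (+5.0, 50.0, False, UNKNOWN),
        ],
    )
    def test_rules(self, ddg, su, reliable, expected):
        fit = make_fit({S1: (ddg, su)})
        rel = {S1} if reliable else set()
        category = categorize(fit, rel, fake_stats({S1: 50}))
        assert category[S1] == expected

    def test_fatal_class_and_conservation(self):
        fit = make_fit({S1: (-3.0, 1.0), S2: (2.0, 10.0)})
        category = categorize(fit, {S1}, fake_stats({S1: 50, S2: 50}),
                              fatal={S3}, all_substitutions={S1, S2, S3})
        assert category[S3] == FATAL
        counts = category_counts(category)
        assert sum(counts.values()) == 3
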