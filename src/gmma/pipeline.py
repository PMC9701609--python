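"""End-to-end orchestration: labelled variants -> fitted, categorized effects.

Chains the exclusion rules, connectivity check, mean-field initialization,
global fit, uncertainty estimation, reliability filtering and categorization
into one call, and provides the seeded simulate->screen->fit chain used for
parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import simulate as sim
from .genotype import (
    ConnectivityReport,
    ProteinVariant,
    Substitution,
    SubstitutionStats,
    connectivity,
    detect_fatal,
    exclude_variants,
    substitution_stats,
)
from .model import (
    DEFAULT_RT,
    FitSettings,
    GmmaFitResult,
    categorize,
    global_fit,
    mean_field_init,
    reliability_filter,
    standard_uncertainties,
)


@dataclass(frozen=True)
class GmmaConfig:
    """Knobs of the full analysis, with the screen's defaults."""

    RT: float = DEFAULT_RT
    fatal_min_obs: int = 20
    reliability_min_variants: int = 40
    reliability_max_su: float = 6.3
    settings: FitSettings = field(default_factory=FitSettings)


@dataclass
class GmmaAnalysis:
    """Everything the pipeline produced, for reporting and tests."""

    fit: GmmaFitResult
    stats: dict[Substitution, SubstitutionStats]
    stats_fit: dict[Substitution, SubstitutionStats]
    fatal: set[Substitution]
    reliable: set[Substitution]
    connectivity: ConnectivityReport
    n_variants_total: int
    n_variants_fit: int
    n_excluded_nonsense: int
    n_excluded_fatal: int


def run_gmma(variants: list[ProteinVariant], config: GmmaConfig | None = None) -> GmmaAnalysis:
    """Run the full analysis on labelled protein variants.

    Nonsense-carrying variants and variants containing irreversibly fatal
    substitutions are excluded from fitting; the remaining connected dataset
    is fit globally from the mean-field start, uncertainties are propagated
    from the curvature at the optimum, and every substitution (including
    excluded ones) receives a category.
    """
    config = config or GmmaConfig()
    stats_all = substitution_stats(variants)

    non_nonsense = [v for v in variants if not v.has_nonsense]
    fatal = detect_fatal(substitution_stats(non_nonsense), min_obs=config.fatal_min_obs)
    dataset, excluded = exclude_variants(variants, fatal)
    n_nonsense = sum(1 for v in excluded if v.has_nonsense)

    stats_fit = substitution_stats(dataset)
    report = connectivity(dataset)

    init = mean_field_init(dataset, RT=config.RT, settings=config.settings)
    fit = global_fit(dataset, init, settings=config.settings)
    fit = standard_uncertainties(fit, dataset, settings=config.settings)
    reliable = reliability_filter(fit, stats_fit,
                                  min_variants=config.reliability_min_variants,
                                  max_su=config.reliability_max_su)
    categorize(fit, reliable, stats_fit, fatal=fatal,
               all_substitutions=set(stats_all) | set(fit.parameters.ddG))

    return GmmaAnalysis(
        fit=fit,
        stats=stats_all,
        stats_fit=stats_fit,
        fatal=fatal,
        reliable=reliable,
        connectivity=report,
        n_variants_total=len(variants),
        n_variants_fit=len(dataset),
        n_excluded_nonsense=n_nonsense,
        n_excluded_fatal=len(excluded) - n_nonsense,
    )


def simulate_dataset(seed: int, n_transformants: int = 15_000,
                     doping_rate: float = 0.10,
                     selection_model: str = "bernoulli",
                     label_noise: float = 0.0,
                     mixture: sim.MixtureSpec | None = None,
                     dG_ref_true: float = -25.0) -> tuple[
    list[ProteinVariant], sim.SyntheticTruth, "sim.ReferenceTemplate"
]:
    """Seeded simulate->screen->label chain (the read-free path).

    Returns labelled protein variants, the ground truth, and the template.
    """
    rng = np.random.default_rng(seed)
    template = sim.default_template()
    spec = sim.DopingSpec(rate=doping_rate)
    library = sim.generate_library(template, spec, n_transformants, rng)
    universe = sim.substitution_universe(template)
    truth = sim.draw_truth(universe, rng, mixture=mixture, dG_ref_true=dG_ref_true,
                           label_noise=label_noise, seed=seed)
    activity = sim.simulate_screen(library, truth, template, rng,
                                   model=selection_model)
    variants = sim.labelled_variants_from_screen(library, activity, template)
    return variants, truth, template
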