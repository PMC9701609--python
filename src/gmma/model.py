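"""The binary GMMA model: additive stability with a sigmoidal link.

Each variant's folding free energy is the reference stability plus the sum of
its substitutions' effects,

    dG(v) = dG_ref + sum_{s in v} ddG_s            [kJ/mol]

and the probability of the active (complementing) phenotype follows a logistic
link on the stability scale,

    p_active(v) = 1 / (1 + exp(dG(v) / RT)).

Stable variants (dG < 0) are almost surely active; the link scale RT pins the
kJ/mol unit, since a binary readout only identifies dG up to a positive factor.
All parameters are estimated jointly by damped (Levenberg-Marquardt) least
squares of the binary labels against p_active, seeded by a mean-field
initialization that treats co-occurring substitutions as an average background.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import least_squares, minimize_scalar

from .genotype import ProteinVariant, Substitution, SubstitutionStats
from .template import AMINO_ACIDS, ReferenceTemplate

#: Thermal energy k_B*T at the 30 degC screening temperature, kJ/mol.
DEFAULT_RT = 2.52

#: Sentinel categories.
STABILIZING, NEUTRAL, DESTABILIZING, UNKNOWN, FATAL = (
    "stabilizing", "neutral", "destabilizing", "unknown", "fatal"
)


@dataclass
class GmmaParameters:
    """Model parameters: reference stability, per-substitution effects, link scale.

    Negative values are stable/stabilizing (kJ/mol). ``RT`` is a fixed
    constant of the link, not a fitted quantity.
    """

    dG_ref: float
    ddG: dict[Substitution, float]
    RT: float = DEFAULT_RT

    def __post_init__(self) -> None:
        if self.RT <= 0:
            raise ValueError("RT must be positive")


@dataclass(frozen=True)
class FitSettings:
    """Levenberg-Marquardt and bounds settings for the global fit."""

    max_iterations: int = 500
    step_tol: float = 1e-8
    rss_tol: float = 1e-12
    rss_floor: float = 1e-12    # absolute: below this the fit is already exact
    damping_init: float = 1e-3
    damping_up: float = 10.0
    damping_down: float = 0.1
    ddg_bounds: tuple[float, float] = (-40.0, 40.0)
    dg_ref_bounds: tuple[float, float] = (-60.0, 60.0)
    su_cap: float = 100.0

    def __post_init__(self) -> None:
        if self.step_tol <= 0 or self.rss_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class GmmaFitResult:
    """Converged parameters with uncertainties, categories and diagnostics."""

    parameters: GmmaParameters
    su: dict[Substitution, float] = field(default_factory=dict)
    su_dG_ref: float = float("nan")
    category: dict[Substitution, str] = field(default_factory=dict)
    rss: float = float("nan")
    iterations: int = 0
    converged: bool = False
    n_variants: int = 0
    n_parameters: int = 0

    @property
    def degrees_of_freedom(self) -> int:
        return self.n_variants - self.n_parameters

    @property
    def residual_variance(self) -> float:
        if self.degrees_of_freedom <= 0:
            return float("nan")
        return self.rss / self.degrees_of_freedom


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def variant_dG(params: GmmaParameters, variant: ProteinVariant) -> float:
    """Additive stability of a variant: dG_ref plus its substitutions' effects."""
    try:
        return params.dG_ref + sum(params.ddG[s] for s in variant.substitutions)
    except KeyError as exc:
        raise KeyError(f"unknown substitution {exc.args[0]}") from exc


def sigmoid_activity(dG: np.ndarray | float, RT: float) -> np.ndarray | float:
    """p_active = 1/(1 + exp(dG/RT)), exponent clamped against overflow."""
    z = np.clip(np.asarray(dG, dtype=float) / RT, -500.0, 500.0)
    p = 1.0 / (1.0 + np.exp(z))
    return float(p) if np.isscalar(dG) else p


def p_active(params: GmmaParameters, variant: ProteinVariant) -> float:
    """Probability that a variant complements growth (is folded/active)."""
    return float(sigmoid_activity(variant_dG(params, variant), params.RT))


def burden_curve(variants: Iterable[ProteinVariant]) -> pd.DataFrame:
    """Fraction of active variants per substitution burden.

    Returns a frame indexed by ``n_sub`` with columns ``n_variants``,
    ``n_active``, ``fraction_active``. The survival-vs-burden curve probes the
    inactivation transition and feeds the mean-field initialization.
    """
    rows: dict[int, list[int]] = {}
    for v in variants:
        if v.active is None:
            raise ValueError("variants must be labelled")
        n, a = rows.setdefault(v.n_sub, [0, 0])
        rows[v.n_sub] = [n + 1, a + int(v.active)]
    df = pd.DataFrame(
        [(k, n, a, a / n) for k, (n, a) in sorted(rows.items())],
        columns=["n_sub", "n_variants", "n_active", "fraction_active"],
    ).set_index("n_sub")
    return df


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _design(variants: Sequence[ProteinVariant], subs: Sequence[Substitution]) -> tuple[
    sp.csr_matrix, np.ndarray
]:
    """Sparse incidence matrix (column 0 = dG_ref, then one column per
    substitution) and the binary label vector."""
    index = {s: j + 1 for j, s in enumerate(subs)}
    rows, cols = [], []
    y = np.empty(len(variants))
    for i, v in enumerate(variants):
        if v.active is None:
            raise ValueError("variants must be labelled")
        y[i] = float(v.active)
        rows.append(i)
        cols.append(0)
        for s in v.substitutions:
            rows.append(i)
            cols.append(index[s])
    data = np.ones(len(rows))
    A = sp.csr_matrix((data, (rows, cols)), shape=(len(variants), len(subs) + 1))
    return A, y


def _dataset_substitutions(variants: Sequence[ProteinVariant]) -> list[Substitution]:
    subs = {s for v in variants for s in v.substitutions}
    return sorted(subs, key=lambda s: (s.residue, s.mut_aa))


# ---------------------------------------------------------------------------
# mean-field initialization
# ---------------------------------------------------------------------------

def mean_field_init(variants: Sequence[ProteinVariant], RT: float = DEFAULT_RT,
                    settings: FitSettings | None = None) -> GmmaParameters:
    """Initial estimates treating co-occurring substitutions as a mean background.

    Two steps: (a) fit a two-parameter burden model — reference stability and
    a mean per-substitution effect ``m`` — to the survival-vs-burden curve by
    weighted least squares; (b) for each substitution, minimize over a single
    scalar ddG the squared residuals of its containing variants, with every
    co-occurring substitution contributing the background mean ``m``.
    Substitutions seen only in active (only inactive) variants are clamped to
    the lower (upper) ddG bound — the data only bound their effect.
    """
    settings = settings or FitSettings()
    variants = list(variants)
    if not variants:
        raise ValueError("empty dataset")
    lo, hi = settings.ddg_bounds

    curve = burden_curve(variants)
    n = curve.index.to_numpy(dtype=float)
    frac = curve["fraction_active"].to_numpy()
    w = np.sqrt(curve["n_variants"].to_numpy(dtype=float))

    def burden_residuals(theta: np.ndarray) -> np.ndarray:
        d0, m = theta
        return w * (frac - sigmoid_activity(d0 + n * m, RT))

    fit = least_squares(
        burden_residuals,
        x0=np.array([-5.0, 1.0]),
        bounds=([settings.dg_ref_bounds[0], -10.0], [settings.dg_ref_bounds[1], hi]),
    )
    d0, m = fit.x

    by_sub: dict[Substitution, list[tuple[float, int]]] = {}
    for v in variants:
        for s in v.substitutions:
            by_sub.setdefault(s, []).append((float(v.active), v.n_sub))

    ddG: dict[Substitution, float] = {}
    for s, obs in by_sub.items():
        y = np.array([o[0] for o in obs])
        background = d0 + (np.array([o[1] for o in obs], dtype=float) - 1.0) * m
        if y.all():
            ddG[s] = lo
            continue
        if not y.any():
            ddG[s] = hi
            continue

        def objective(x: float) -> float:
            return float(np.sum((y - sigmoid_activity(background + x, RT)) ** 2))

        res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-4})
        ddG[s] = float(res.x)

    return GmmaParameters(dG_ref=float(d0), ddG=ddG, RT=RT)


# ---------------------------------------------------------------------------
# global Levenberg-Marquardt fit
# ---------------------------------------------------------------------------

def _pack(params: GmmaParameters, subs: Sequence[Substitution]) -> np.ndarray:
    x = np.empty(len(subs) + 1)
    x[0] = params.dG_ref
    for j, s in enumerate(subs):
        x[j + 1] = params.ddG[s]
    return x


def _clip(x: np.ndarray, settings: FitSettings) -> np.ndarray:
    out = x.copy()
    out[0] = np.clip(out[0], *settings.dg_ref_bounds)
    out[1:] = np.clip(out[1:], *settings.ddg_bounds)
    return out


def global_fit(variants: Sequence[ProteinVariant], init: GmmaParameters,
               settings: FitSettings | None = None) -> GmmaFitResult:
    """Joint least-squares fit of dG_ref and all ddG to the binary labels.

    Minimizes ``sum_v (y_v - p_active(v))^2`` by Levenberg-Marquardt damping:
    the normal equations are solved with a multiplicative damping of the
    diagonal, the damping factor shrinking on accepted (improving) steps and
    growing on rejected ones. The residual Jacobian is analytic and sparse
    (``d r_v / d theta_j = p_v (1 - p_v) / RT`` for every parameter touching
    variant v), so the full-library fit stays cheap. Parameters are kept
    inside their bounds by projection. The returned RSS never exceeds the
    initial one; non-convergence is flagged, not raised.
    """
    settings = settings or FitSettings()
    variants = list(variants)
    subs = _dataset_substitutions(variants)
    missing = [s for s in subs if s not in init.ddG]
    if missing:
        raise KeyError(f"init lacks ddG for {len(missing)} substitutions, e.g. {missing[0]}")
    A, y = _design(variants, subs)
    RT = init.RT
    x = _clip(_pack(init, subs), settings)

    def residuals(x: np.ndarray) -> np.ndarray:
        return y - sigmoid_activity(A @ x, RT)

    r = residuals(x)
    rss = float(r @ r)
    lam = settings.damping_init
    converged = False
    iterations = 0

    # parameters pinned by equal bounds are frozen out of the solve
    free = np.ones(x.size, dtype=bool)
    free[0] = settings.dg_ref_bounds[0] != settings.dg_ref_bounds[1]
    free[1:] = settings.ddg_bounds[0] != settings.ddg_bounds[1]

    if rss < settings.rss_floor:
        converged = True

    for iterations in range(1, (0 if converged else settings.max_iterations) + 1):
        p = sigmoid_activity(A @ x, RT)
        w = p * (1.0 - p) / RT
        J = A.multiply(w[:, None]).tocsr()            # J = diag(w) A
        g = np.asarray(J.T @ r).ravel()[free]         # gradient/2 of RSS
        JtJ = (J.T @ J).toarray()[np.ix_(free, free)]
        diag = np.maximum(JtJ.diagonal(), 1e-12)

        accepted = False
        for _ in range(50):
            M = JtJ + lam * np.diag(diag)
            try:
                step = np.linalg.solve(M, -g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(M, -g, rcond=None)[0]
            x_new = x.copy()
            x_new[free] += step
            x_new = _clip(x_new, settings)
            r_new = residuals(x_new)
            rss_new = float(r_new @ r_new)
            if rss_new <= rss:
                accepted = True
                break
            lam *= settings.damping_up
        if not accepted:
            converged = True          # no improving direction: local optimum
            break
        step_norm = float(np.linalg.norm(x_new - x))
        drop = rss - rss_new
        x, r, rss = x_new, r_new, rss_new
        lam = max(lam * settings.damping_down, 1e-12)
        if (step_norm < settings.step_tol or rss < settings.rss_floor
                or drop < settings.rss_tol * max(rss, 1.0)):
            converged = True
            break

    ddG = {s: float(x[j + 1]) for j, s in enumerate(subs)}
    params = GmmaParameters(dG_ref=float(x[0]), ddG=ddG, RT=RT)
    return GmmaFitResult(
        parameters=params,
        rss=rss,
        iterations=iterations,
        converged=converged,
        n_variants=len(variants),
        n_parameters=len(subs) + 1,
    )


# ---------------------------------------------------------------------------
# uncertainties, reliability, categories
# ---------------------------------------------------------------------------

def standard_uncertainties(fit: GmmaFitResult, variants: Sequence[ProteinVariant],
                           settings: FitSettings | None = None) -> GmmaFitResult:
    """Standard uncertainties from the curvature of the objective at the optimum.

    ``su_i = sqrt(sigma^2 [(J^T J)^+]_ii)`` with ``sigma^2 = RSS / (n - p)``.
    The pseudo-inverse handles the singular directions left by hanging
    substitutions, whose su is reported as the capped sentinel. Updates and
    returns the fit result in place.
    """
    settings = settings or FitSettings()
    variants = list(variants)
    subs = _dataset_substitutions(variants)
    A, y = _design(variants, subs)
    params = fit.parameters
    x = _pack(params, subs)
    dof = len(variants) - (len(subs) + 1)
    if dof <= 0:
        raise ValueError("underdetermined: degrees of freedom <= 0")

    p = sigmoid_activity(A @ x, params.RT)
    w = p * (1.0 - p) / params.RT
    J = A.multiply(w[:, None]).tocsr()
    JtJ = (J.T @ J).toarray()
    sigma2 = fit.rss / dof
    cov = sigma2 * np.linalg.pinv(JtJ, hermitian=True)
    su = np.sqrt(np.maximum(cov.diagonal(), 0.0))
    su = np.minimum(su, settings.su_cap)
    # parameters with (numerically) no curvature are unidentifiable
    su[np.asarray(JtJ.diagonal() < 1e-10)] = settings.su_cap

    fit.su_dG_ref = float(su[0])
    fit.su = {s: float(su[j + 1]) for j, s in enumerate(subs)}
    return fit


def reliability_filter(fit: GmmaFitResult, stats: Mapping[Substitution, SubstitutionStats],
                       min_variants: int = 40, max_su: float = 6.3) -> set[Substitution]:
    """Substitutions with a trustworthy effect estimate: observed in at least
    ``min_variants`` variants and fitted with su no worse than ``max_su`` kJ/mol."""
    return {
        s for s, su in fit.su.items()
        if su <= max_su and s in stats and stats[s].n_variants >= min_variants
    }


def categorize(fit: GmmaFitResult, reliable: set[Substitution],
               stats: Mapping[Substitution, SubstitutionStats],
               fatal: set[Substitution] = frozenset(),
               all_substitutions: Iterable[Substitution] | None = None,
               su_factor: float = 1.0) -> dict[Substitution, str]:
    """Assign each substitution a category.

    Fatal substitutions are their own class. A reliable effect is stabilizing
    when ``ddG + su_factor*su < 0``, destabilizing when ``ddG - su_factor*su > 0``,
    neutral otherwise. A non-reliable effect estimated to destabilize more
    than the reference is stable enough evidence to call destabilizing; all
    remaining non-reliable effects are unknown. The map covers every
    substitution in ``all_substitutions`` (default: fitted plus fatal).
    Updates ``fit.category`` and returns it.
    """
    params = fit.parameters
    universe = set(all_substitutions) if all_substitutions is not None else (
        set(fit.parameters.ddG) | set(fatal)
    )
    category: dict[Substitution, str] = {}
    for s in universe:
        if s in fatal:
            category[s] = FATAL
            continue
        ddg = params.ddG.get(s)
        if ddg is None:
            category[s] = UNKNOWN
            continue
        if s in reliable:
            su = fit.su.get(s, float("inf"))
            if ddg + su_factor * su < 0:
                category[s] = STABILIZING
            elif ddg - su_factor * su > 0:
                category[s] = DESTABILIZING
            else:
                category[s] = NEUTRAL
        elif ddg > -params.dG_ref:
            category[s] = DESTABILIZING
        else:
            category[s] = UNKNOWN
    fit.category = category
    return category


def category_counts(category: Mapping[Substitution, str]) -> dict[str, int]:
    counts = {c: 0 for c in (STABILIZING, NEUTRAL, DESTABILIZING, UNKNOWN, FATAL)}
    for c in category.values():
        counts[c] += 1
    return counts


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def fit_to_frame(fit: GmmaFitResult, stats: Mapping[Substitution, SubstitutionStats]) -> pd.DataFrame:
    """Tabulate the fit: one row per substitution with effect, uncertainty,
    occurrence counts, category and stabilizing rank (1 = most stabilizing)."""
    subs = sorted(fit.parameters.ddG, key=lambda s: (fit.parameters.ddG[s], str(s)))
    rank = {s: i + 1 for i, s in enumerate(subs)}
    rows = []
    for s in sorted(fit.parameters.ddG, key=lambda s: (s.residue, s.mut_aa)):
        st = stats.get(s)
        rows.append({
            "substitution": str(s),
            "ddG_kJmol": fit.parameters.ddG[s],
            "su_kJmol": fit.su.get(s, float("nan")),
            "n_variants": st.n_variants if st else 0,
            "n_active": st.n_active if st else 0,
            "category": fit.category.get(s, UNKNOWN),
            "rank": rank[s],
        })
    return pd.DataFrame(rows)


def heatmap_frame(fit: GmmaFitResult, template: ReferenceTemplate) -> pd.DataFrame:
    """Residue x amino-acid matrix of fitted effects (kJ/mol).

    Wild-type cells carry the sentinel ``WT``; substitutions observed but
    without a robust estimate carry ``unknown``; substitutions absent from the
    library are empty strings.
    """
    residues = [template.residue_number(i) for i in range(template.n_codons)]
    data = {}
    for residue in residues:
        wt = template.reference_aa(residue)
        col = {}
        for aa in AMINO_ACIDS:
            if aa == wt:
                col[aa] = "WT"
                continue
            sub = Substitution(residue=residue, wt_aa=wt, mut_aa=aa)
            if sub not in fit.category:
                col[aa] = ""
            elif fit.category[sub] in (UNKNOWN, FATAL) and sub not in fit.parameters.ddG:
                col[aa] = fit.category[sub]
            elif fit.category[sub] == UNKNOWN:
                col[aa] = "unknown"
            else:
                col[aa] = f"{fit.parameters.ddG[sub]:.2f}"
        data[residue] = col
    return pd.DataFrame(data, index=list(AMINO_ACIDS))
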