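"""Synthetic doped-oligo libraries with known stability ground truth.

Emulates the statistical structure of a doped-oligonucleotide deep mutational
scan read out through a binary folding screen: two mutagenesis windows doped
at ~10% per base around a fixed cloning cassette, multi-substitution variants
(on the order of nine amino acid changes each), a mostly-destabilizing
ground-truth effect distribution with rare stabilizing outliers, nonsense
mutations, sigmoidal survival in total stability, and sequencing reads with
per-base errors that create spurious low-count genotypes.

Everything is deterministic under a fixed seed so the whole
simulate -> call -> label -> fit chain can be replayed.
"""

from __future__ import annotations

import itertools
import json
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .genotype import ProteinVariant, Substitution, SubstitutionStats, translate_variant
from .model import DEFAULT_RT, GmmaFitResult, GmmaParameters, sigmoid_activity
from .read_processing import ChangeSet, DnaVariant
from .template import GENETIC_CODE, ReferenceTemplate

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

#: Fixed seed for the synthetic reference template (a property of the
#: construct, not of any one simulation run).
_TEMPLATE_SEED = 202207

#: Geometry of the default construct: 50 codons (residues 48-97) flanked by
#: 10 bases each side; a 10-base cloning cassette inside the window is never
#: doped, leaving 71 + 69 = 140 dopable bases in two blocks.
_N_CODONS = 50
_USER_SITE_WINDOW_OFFSETS = range(71, 81)


def default_template() -> ReferenceTemplate:
    """The synthetic reference amplicon used throughout the package.

    A fixed random (stop-free) 50-codon window with 10-base flanks, mirroring
    the geometry of a doped two-oligo construct; the sequence itself is
    synthetic, not any natural gene.
    """
    rng = np.random.default_rng(_TEMPLATE_SEED)
    codons = [c for c, aa in GENETIC_CODE.items() if aa != "*"]
    window = "".join(rng.choice(codons) for _ in range(_N_CODONS))
    flank5 = "".join(rng.choice(list("ACGT")) for _ in range(10))
    flank3 = "".join(rng.choice(list("ACGT")) for _ in range(10))
    start = 10
    end = start + 3 * _N_CODONS
    undoped = {start + o for o in _USER_SITE_WINDOW_OFFSETS}
    return ReferenceTemplate(
        dna_sequence=flank5 + window + flank3,
        window=(start, end),
        doped_positions=frozenset(set(range(start, end)) - undoped),
        protein_offset=48,
        frame=0,
    )


@dataclass(frozen=True)
class DopingSpec:
    """Per-position doping: each eligible base is replaced with probability
    ``rate``, uniformly among the three non-reference bases."""

    rate: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("doping rate must be in [0, 1]")


@dataclass(frozen=True)
class MixtureSpec:
    """Ground-truth ddG mixture (kJ/mol): weights and normal components for
    destabilizing, neutral and stabilizing substitution classes."""

    weights: tuple[float, float, float] = (0.80, 0.15, 0.05)
    means: tuple[float, float, float] = (4.0, 0.0, -2.5)
    sds: tuple[float, float, float] = (2.0, 0.5, 1.0)

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    @property
    def mean(self) -> float:
        return float(sum(w * m for w, m in zip(self.weights, self.means)))


@dataclass(frozen=True)
class LibrarySpec:
    """Scale of the simulated experiment."""

    n_transformants: int = 15_000
    depth_input: int = 100_000
    depth_selected: int = 100_000
    read_error_rate: float = 0.001
    selection_model: str = "bernoulli"    # bernoulli | threshold
    label_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n_transformants < 1 or self.depth_input < 1 or self.depth_selected < 1:
            raise ValueError("library sizes and depths must be positive")
        if self.selection_model not in ("bernoulli", "threshold"):
            raise ValueError("selection_model must be 'bernoulli' or 'threshold'")


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of a simulated screen, recorded for replay."""

    dG_ref_true: float
    RT: float
    ddG_true: dict[Substitution, float]
    label_noise: float = 0.0
    seed: int | None = None

    def as_parameters(self) -> GmmaParameters:
        return GmmaParameters(dG_ref=self.dG_ref_true, ddG=dict(self.ddG_true), RT=self.RT)


# ---------------------------------------------------------------------------
# doping and library generation
# ---------------------------------------------------------------------------

def _seq_to_idx(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX[b] for b in seq], dtype=np.uint8)


def _idx_to_seq(idx: np.ndarray) -> str:
    return _BASES[idx].tobytes().decode()


def sample_doped_sequence(template: ReferenceTemplate, spec: DopingSpec,
                          rng: np.random.Generator) -> str:
    """One doped molecule: each doped position independently mutated with
    probability ``spec.rate``, uniformly among the 3 alternatives."""
    idx = _seq_to_idx(template.dna_sequence)
    doped = np.fromiter(sorted(template.doped_positions), dtype=np.int64)
    hit = rng.random(doped.size) < spec.rate
    offsets = rng.integers(1, 4, size=doped.size).astype(np.uint8)
    idx[doped[hit]] = (idx[doped[hit]] + offsets[hit]) % 4
    return _idx_to_seq(idx)


def generate_library(template: ReferenceTemplate, spec: DopingSpec,
                     n_transformants: int, rng: np.random.Generator) -> dict[ChangeSet, int]:
    """Dope ``n_transformants`` independent molecules and deduplicate.

    Returns unique DNA genotypes (as canonical change sets) with their
    multiplicities in the transformed library.
    """
    doped = np.fromiter(sorted(template.doped_positions), dtype=np.int64)
    ref_idx = _seq_to_idx(template.dna_sequence)[doped]
    ref_bases = [template.dna_sequence[p] for p in doped]
    hits = rng.random((n_transformants, doped.size)) < spec.rate
    offsets = rng.integers(1, 4, size=(n_transformants, doped.size), dtype=np.int64)

    library: dict[ChangeSet, int] = {}
    bases = "ACGT"
    for row in range(n_transformants):
        cols = np.nonzero(hits[row])[0]
        changes = tuple(
            (int(doped[c]), ref_bases[c], bases[(int(ref_idx[c]) + int(offsets[row, c])) % 4])
            for c in cols
        )
        library[changes] = library.get(changes, 0) + 1
    return library


def library_report(library: Mapping[ChangeSet, int], template: ReferenceTemplate) -> dict:
    """Unique-variant count and amino acid burden distribution of a library."""
    burdens = []
    n_nonsense = 0
    for changes, mult in library.items():
        pv = translate_variant(DnaVariant(base_changes=changes), template)
        burdens.extend([pv.n_sub] * mult)
        n_nonsense += mult * int(pv.has_nonsense)
    burdens = np.asarray(burdens)
    return {
        "n_transformants": int(burdens.size),
        "n_unique_genotypes": len(library),
        "mean_aa_burden": float(burdens.mean()),
        "sd_aa_burden": float(burdens.std()),
        "fraction_nonsense": n_nonsense / burdens.size,
    }


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def substitution_universe(template: ReferenceTemplate) -> set[Substitution]:
    """All amino acid substitutions reachable by doping.

    Enumerates, per codon, every combination of alternative bases at that
    codon's doped positions (covering multi-base codon changes), and collects
    the non-synonymous, non-stop outcomes.
    """
    universe: set[Substitution] = set()
    for ci in range(template.n_codons):
        a, b = template.codon_interval(ci)
        ref_codon = template.reference_codon(ci)
        wt = GENETIC_CODE[ref_codon]
        doped_offsets = [p - a for p in range(a, b) if p in template.doped_positions]
        if not doped_offsets:
            continue
        choices = [
            [c for c in "ACGT"] if o in doped_offsets else [ref_codon[o]]
            for o in range(3)
        ]
        for combo in itertools.product(*choices):
            aa = GENETIC_CODE["".join(combo)]
            if aa not in ("*", wt):
                universe.add(Substitution(residue=template.residue_number(ci),
                                          wt_aa=wt, mut_aa=aa))
    return universe


def draw_truth(universe: Iterable[Substitution], rng: np.random.Generator,
               mixture: MixtureSpec | None = None, dG_ref_true: float = -25.0,
               RT: float = DEFAULT_RT, label_noise: float = 0.0,
               seed: int | None = None) -> SyntheticTruth:
    """Draw a ground-truth ddG for every reachable substitution.

    Effects come from a three-component normal mixture: mostly destabilizing,
    some neutral, rarely stabilizing — the regime protein substitutions
    occupy. Deterministic given the generator state.
    """
    mixture = mixture or MixtureSpec()
    subs = sorted(universe, key=lambda s: (s.residue, s.mut_aa))
    comp = rng.choice(3, size=len(subs), p=mixture.weights)
    values = rng.normal(np.take(mixture.means, comp), np.take(mixture.sds, comp))
    return SyntheticTruth(
        dG_ref_true=dG_ref_true,
        RT=RT,
        ddG_true={s: float(v) for s, v in zip(subs, values)},
        label_noise=label_noise,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

def simulate_screen(library: Mapping[ChangeSet, int], truth: SyntheticTruth,
                    template: ReferenceTemplate, rng: np.random.Generator,
                    model: str = "bernoulli", label_noise: float | None = None) -> dict[
    ChangeSet, bool
]:
    """Binary growth outcome for every genotype in the library.

    ``bernoulli``: each clone survives with probability
    ``p_active = 1/(1+exp(dG_true/RT))``, then the label is flipped with the
    label-noise rate. ``threshold``: survival iff ``dG_true < 0``. Nonsense
    genotypes are inactive regardless (the truncated fusion cannot fold).
    """
    eps = truth.label_noise if label_noise is None else label_noise
    activity: dict[ChangeSet, bool] = {}
    for changes in library:
        pv = translate_variant(DnaVariant(base_changes=changes), template)
        if pv.has_nonsense:
            activity[changes] = False
            continue
        dG = truth.dG_ref_true + sum(truth.ddG_true[s] for s in pv.substitutions)
        if model == "threshold":
            active = dG < 0.0
        elif model == "bernoulli":
            active = bool(rng.random() < sigmoid_activity(dG, truth.RT))
        else:
            raise ValueError(f"unknown selection model {model!r}")
        if eps > 0.0 and rng.random() < eps:
            active = not active
        activity[changes] = active
    return activity


def labelled_variants_from_screen(library: Mapping[ChangeSet, int],
                                  activity: Mapping[ChangeSet, bool],
                                  template: ReferenceTemplate) -> list[ProteinVariant]:
    """Aggregate a screened library directly to labelled protein variants.

    The read-free path: counts are library multiplicities; a protein variant
    is active when any of its DNA genotypes survived (matching the
    any-count-above-cutoff rule of the sequencing path).
    """
    acc: dict[tuple, list] = {}
    for changes, mult in library.items():
        pv = translate_variant(DnaVariant(base_changes=changes), template)
        key = (pv.substitutions, pv.has_nonsense)
        entry = acc.setdefault(key, [0, 0, False])
        entry[0] += mult
        if activity[changes]:
            entry[1] += mult
            entry[2] = True
    return [
        ProteinVariant(substitutions=subs, has_nonsense=nonsense, count_input=ci,
                       count_selected=cs, active=act)
        for (subs, nonsense), (ci, cs, act) in acc.items()
    ]


# ---------------------------------------------------------------------------
# sequencing reads
# ---------------------------------------------------------------------------

def simulate_reads(library: Mapping[ChangeSet, int], activity: Mapping[ChangeSet, bool],
                   template: ReferenceTemplate, spec: LibrarySpec,
                   rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Merged-read pools for the input and the selected library.

    Input reads sample genotypes proportional to their multiplicity; selected
    reads only from genotypes whose clone survived. Every read carries
    independent per-base errors (window and flanks alike) at
    ``spec.read_error_rate``, the mechanism that creates spurious low-count
    genotypes for the cutoff machinery to remove.
    """
    genotypes = list(library)
    seqs = np.stack([
        _seq_to_idx(_apply_changes_str(template, changes)) for changes in genotypes
    ])
    mult = np.array([library[g] for g in genotypes], dtype=float)

    def emit(weights: np.ndarray, depth: int) -> list[str]:
        total = weights.sum()
        if total <= 0:
            return []
        draws = rng.choice(len(genotypes), size=depth, p=weights / total)
        reads = seqs[draws].copy()
        if spec.read_error_rate > 0:
            errors = rng.random(reads.shape) < spec.read_error_rate
            shifts = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
            reads[errors] = (reads[errors] + shifts[errors]) % 4
        return [_idx_to_seq(row) for row in reads]

    input_reads = emit(mult, spec.depth_input)
    selected_weights = mult * np.array([activity[g] for g in genotypes], dtype=float)
    selected_reads = emit(selected_weights, spec.depth_selected)
    return input_reads, selected_reads


def _apply_changes_str(template: ReferenceTemplate, changes: ChangeSet) -> str:
    seq = list(template.dna_sequence)
    for pos, _, alt in changes:
        seq[pos] = alt
    return "".join(seq)


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

def recovery_report(truth: SyntheticTruth, fit: GmmaFitResult,
                    stats: Mapping[Substitution, SubstitutionStats],
                    min_variants: int = 40, top_true: int = 5,
                    top_fitted: int = 15) -> dict:
    """Compare fitted effects with the ground truth.

    Metrics are computed over substitutions with a fitted effect that were
    observed in at least ``min_variants`` variants: Pearson r, RMSE, sign
    accuracy, and how many of the ``top_true`` most stabilizing true effects
    rank inside the fitted ``top_fitted``.
    """
    fitted = fit.parameters.ddG
    comparable = [
        s for s in fitted
        if s in truth.ddG_true and s in stats and stats[s].n_variants >= min_variants
    ]
    if not comparable:
        raise ValueError("no_comparable_substitutions")
    t = np.array([truth.ddG_true[s] for s in comparable])
    f = np.array([fitted[s] for s in comparable])
    r = float(pearsonr(t, f).statistic) if len(comparable) > 1 else float("nan")

    # ranking is meaningful only among well-observed effects (the method
    # itself only ranks substitutions passing the reliability filter)
    true_top = sorted(comparable, key=lambda s: truth.ddG_true[s])[:top_true]
    fitted_top = set(sorted(comparable, key=lambda s: fitted[s])[:top_fitted])
    overlap = sum(1 for s in true_top if s in fitted_top)

    return {
        "n_compared": len(comparable),
        "pearson_r": r,
        "rmse_kJmol": float(np.sqrt(np.mean((t - f) ** 2))),
        "sign_accuracy": float(np.mean(np.sign(t) == np.sign(f))),
        "true_top_k": [str(s) for s in true_top],
        "top_overlap": overlap,
        "dG_ref_true": truth.dG_ref_true,
        "dG_ref_fitted": fit.parameters.dG_ref,
    }


# ---------------------------------------------------------------------------
# truth I/O
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(((str(s), v) for s, v in truth.ddG_true.items())),
        columns=["substitution", "ddG_true"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path, dG_ref_true: float = -25.0,
               RT: float = DEFAULT_RT) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t")
    ddG = {Substitution.from_string(s): float(v)
           for s, v in zip(df["substitution"], df["ddG_true"])}
    return SyntheticTruth(dG_ref_true=dG_ref_true, RT=RT, ddG_true=ddG)
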