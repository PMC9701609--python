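"""Protein-level genotypes: translation, aggregation, activity labels, exclusions.

DNA genotypes are translated codon-wise to sets of amino acid substitutions,
aggregated (synonymous DNA routes merge), and labelled active/inactive from the
selected/input pool counts. The module also implements the screen's exclusion
rules — variants absent from the input pool, nonsense-carrying variants,
irreversibly fatal substitutions — and the substitution co-occurrence network
whose connectivity a global fit requires.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import pandas as pd

from .read_processing import ChangeSet, DnaVariant
from .template import AMINO_ACIDS, GENETIC_CODE, ReferenceTemplate


class FrameViolation(ValueError):
    """A base change falls outside a complete window codon."""


@dataclass(frozen=True, order=True)
class Substitution:
    """One amino acid substitution, e.g. E54Y.

    ``residue`` is the 1-based protein position; a stop codon is not a
    Substitution (it sets the variant's nonsense flag instead).
    """

    residue: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError("wt_aa and mut_aa must differ")
        if self.mut_aa not in AMINO_ACIDS or self.wt_aa not in AMINO_ACIDS:
            raise ValueError(f"invalid amino acid in {self.wt_aa}{self.residue}{self.mut_aa}")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.residue}{self.mut_aa}"

    @classmethod
    def from_string(cls, text: str) -> "Substitution":
        return cls(residue=int(text[1:-1]), wt_aa=text[0], mut_aa=text[-1])


@dataclass(frozen=True)
class ProteinVariant:
    """A protein variant: sorted substitution set, nonsense flag, pool counts,
    and a binary activity label (``None`` until :func:`assign_activity`)."""

    substitutions: tuple[Substitution, ...]
    has_nonsense: bool = False
    count_input: int = 0
    count_selected: int = 0
    active: bool | None = None

    def __post_init__(self) -> None:
        residues = [s.residue for s in self.substitutions]
        if residues != sorted(set(residues)):
            raise ValueError("substitutions must be sorted by residue and unique per residue")

    @property
    def n_sub(self) -> int:
        return len(self.substitutions)

    def __str__(self) -> str:
        return variant_to_string(self.substitutions)


def variant_to_string(substitutions: Sequence[Substitution]) -> str:
    """Canonical variant string: colon-joined tokens sorted by residue; ``WT``."""
    if not substitutions:
        return "WT"
    return ":".join(str(s) for s in sorted(substitutions, key=lambda s: s.residue))


def variant_from_string(text: str) -> tuple[Substitution, ...]:
    if text == "WT":
        return ()
    return tuple(sorted((Substitution.from_string(t) for t in text.split(":")),
                        key=lambda s: s.residue))


@dataclass(frozen=True)
class SubstitutionStats:
    """Occurrence tallies for one substitution over labelled variants."""

    n_variants: int
    n_active: int
    n_inactive: int

    @property
    def hanging(self) -> bool:
        return self.n_variants == 1


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def translate_variant(dna: DnaVariant, template: ReferenceTemplate) -> ProteinVariant:
    """Translate a DNA genotype to its protein variant.

    Changed codons are translated with the standard genetic code; multiple
    base changes in one codon yield at most one Substitution from the combined
    mutant codon. Stop codons set ``has_nonsense`` and contribute no
    Substitution. Counts are copied; the activity label stays unset.
    """
    by_codon: dict[int, list[tuple[int, str, str]]] = defaultdict(list)
    for pos, ref, alt in dna.base_changes:
        try:
            idx = template.codon_index_of(pos)
        except ValueError as exc:
            raise FrameViolation(str(exc)) from exc
        by_codon[idx].append((pos, ref, alt))

    substitutions: list[Substitution] = []
    has_nonsense = False
    for idx, changes in by_codon.items():
        a, _ = template.codon_interval(idx)
        codon = list(template.reference_codon(idx))
        for pos, ref, alt in changes:
            if codon[pos - a] != ref:
                raise ValueError(f"reference base mismatch at {pos}")
            codon[pos - a] = alt
        mut_aa = GENETIC_CODE["".join(codon)]
        wt_aa = GENETIC_CODE[template.reference_codon(idx)]
        if mut_aa == "*":
            has_nonsense = True
        elif mut_aa != wt_aa:
            substitutions.append(
                Substitution(residue=template.residue_number(idx), wt_aa=wt_aa, mut_aa=mut_aa)
            )
    return ProteinVariant(
        substitutions=tuple(sorted(substitutions, key=lambda s: s.residue)),
        has_nonsense=has_nonsense,
        count_input=dna.count_input,
        count_selected=dna.count_selected,
    )


def aggregate_to_protein(input_counts: Mapping[ChangeSet, int],
                         selected_counts: Mapping[ChangeSet, int],
                         template: ReferenceTemplate) -> list[ProteinVariant]:
    """Aggregate per-pool DNA genotype counts to protein variants.

    DNA genotypes with identical (substitution set, nonsense flag) merge and
    their counts sum per pool; synonymous-only genotypes merge into the
    wild-type protein variant.
    """
    acc: dict[tuple[tuple[Substitution, ...], bool], list[int]] = defaultdict(lambda: [0, 0])
    for pool_idx, table in enumerate((input_counts, selected_counts)):
        for changes, count in table.items():
            pv = translate_variant(DnaVariant(base_changes=tuple(sorted(changes))), template)
            acc[(pv.substitutions, pv.has_nonsense)][pool_idx] += count
    return [
        ProteinVariant(substitutions=subs, has_nonsense=nonsense,
                       count_input=ci, count_selected=cs)
        for (subs, nonsense), (ci, cs) in acc.items()
    ]


# ---------------------------------------------------------------------------
# activity labels
# ---------------------------------------------------------------------------

def assign_activity(variants: Iterable[ProteinVariant], cutoff_input: int,
                    cutoff_selected: int, strict: bool = False) -> tuple[
    list[ProteinVariant], list[ProteinVariant]
]:
    """Label variants active/inactive from per-pool counts; no pseudo-counts.

    A variant is active when its selected-pool count clears the selected
    cutoff, inactive when it is observed in the input pool but not active.
    Active variants absent from the input pool are discarded (they cannot be
    interpreted, having no input representation). Variants below both cutoffs
    are dropped as unobserved.

    ``strict`` switches the comparison from ``count >= cutoff`` (the cutoff is
    the smallest kept count, the default) to ``count > cutoff``.

    Returns ``(labelled, discarded)`` where discarded holds the
    input-absent-but-selected variants.
    """
    def clears(count: int, cutoff: int) -> bool:
        return count > cutoff if strict else count >= cutoff

    labelled: list[ProteinVariant] = []
    discarded: list[ProteinVariant] = []
    for v in variants:
        in_input = clears(v.count_input, cutoff_input)
        in_selected = clears(v.count_selected, cutoff_selected)
        if in_selected and not in_input:
            discarded.append(replace(v, active=True))
        elif in_selected:
            labelled.append(replace(v, active=True))
        elif in_input:
            labelled.append(replace(v, active=False))
        # below both cutoffs: unobserved, dropped
    return labelled, discarded


# ---------------------------------------------------------------------------
# substitution statistics and exclusion rules
# ---------------------------------------------------------------------------

def substitution_stats(variants: Iterable[ProteinVariant]) -> dict[Substitution, SubstitutionStats]:
    """Per-substitution occurrence/activity tallies over labelled variants."""
    n_var: Counter[Substitution] = Counter()
    n_act: Counter[Substitution] = Counter()
    for v in variants:
        if v.active is None:
            raise ValueError("variants must be labelled before computing stats")
        for s in v.substitutions:
            n_var[s] += 1
            if v.active:
                n_act[s] += 1
    return {
        s: SubstitutionStats(n_variants=n, n_active=n_act[s], n_inactive=n - n_act[s])
        for s, n in n_var.items()
    }


def count_one_sided(stats: Mapping[Substitution, SubstitutionStats]) -> int:
    """Number of substitutions observed only in active or only in inactive
    variants (their effect is only bounded, not located, by the data)."""
    return sum(1 for st in stats.values() if st.n_active == 0 or st.n_inactive == 0)


def detect_fatal(stats: Mapping[Substitution, SubstitutionStats],
                 min_obs: int = 20) -> set[Substitution]:
    """Irreversibly fatal substitutions: never seen active despite >= min_obs
    observations. A single active variant rescues a substitution."""
    return {
        s for s, st in stats.items()
        if st.n_variants >= min_obs and st.n_active == 0
    }


def exclude_variants(variants: Iterable[ProteinVariant],
                     fatal: set[Substitution] = frozenset()) -> tuple[
    list[ProteinVariant], list[ProteinVariant]
]:
    """Split variants into (fit dataset, excluded): nonsense-carrying variants
    and variants containing a fatal substitution are excluded from fitting."""
    kept, excluded = [], []
    for v in variants:
        if v.has_nonsense or any(s in fatal for s in v.substitutions):
            excluded.append(v)
        else:
            kept.append(v)
    return kept, excluded


# ---------------------------------------------------------------------------
# co-occurrence network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnectivityReport:
    components: tuple[frozenset[Substitution], ...]
    hanging: frozenset[Substitution]

    @property
    def connected(self) -> bool:
        return len(self.components) <= 1


def connectivity(variants: Iterable[ProteinVariant]) -> ConnectivityReport:
    """Components of the substitution co-occurrence graph.

    Substitutions are nodes; two are joined when they co-occur in at least one
    variant. Only a connected network lets the global fit propagate stability
    information between substitutions; hanging substitutions (seen in exactly
    one variant) are listed because the fit cannot constrain them.
    """
    graph = nx.Graph()
    occurrences: Counter[Substitution] = Counter()
    for v in variants:
        subs = v.substitutions
        graph.add_nodes_from(subs)
        occurrences.update(subs)
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                graph.add_edge(subs[i], subs[j])
    components = tuple(
        frozenset(c) for c in sorted(nx.connected_components(graph), key=len, reverse=True)
    )
    hanging = frozenset(s for s, n in occurrences.items() if n == 1)
    return ConnectivityReport(components=components, hanging=hanging)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def variants_to_frame(variants: Iterable[ProteinVariant]) -> pd.DataFrame:
    rows = [
        {
            "variant": str(v),
            "has_nonsense": v.has_nonsense,
            "count_input": v.count_input,
            "count_selected": v.count_selected,
            "active": "" if v.active is None else int(v.active),
        }
        for v in variants
    ]
    return pd.DataFrame(rows, columns=["variant", "has_nonsense", "count_input",
                                       "count_selected", "active"])


def write_variants(variants: Iterable[ProteinVariant], path: str | Path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_variants(path: str | Path) -> list[ProteinVariant]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"variant": str, "active": str})
    out = []
    for row in df.itertuples(index=False):
        active = None if row.active == "" else bool(int(row.active))
        out.append(ProteinVariant(
            substitutions=variant_from_string(row.variant),
            has_nonsense=bool(row.has_nonsense) if not isinstance(row.has_nonsense, str)
            else row.has_nonsense.lower() == "true",
            count_input=int(row.count_input),
            count_selected=int(row.count_selected),
            active=active,
        ))
    return out
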