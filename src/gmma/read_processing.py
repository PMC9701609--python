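"""Amplicon read processing: validation, mutation calling, counting, noise cutoff.

Merged amplicon reads are validated against the reference template, compressed
to lists of base changes inside the mutated window, and tallied into genotype
count tables per sequencing pool. Mismatches in the two 10-base flanks never
enter a genotype; they estimate the per-base sequencing-error rate, from which
a per-pool read-count cutoff is derived to remove spurious low-count genotypes.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import poisson

from .template import DNA_ALPHABET, ReferenceTemplate

#: One base change: (0-based position, reference base, observed base).
BaseChange = tuple[int, str, str]
#: A genotype as a canonical (sorted) tuple of base changes; () is wild type.
ChangeSet = tuple[BaseChange, ...]


@dataclass(frozen=True)
class DnaVariant:
    """A DNA genotype with per-pool read counts."""

    base_changes: ChangeSet
    count_input: int = 0
    count_selected: int = 0

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.base_changes]
        if positions != sorted(set(positions)):
            raise ValueError("base_changes must be sorted with unique positions")
        if self.count_input < 0 or self.count_selected < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class FlankStats:
    """Sequencing-error evidence from the 2 x 10 bp flanking regions."""

    n_reads: int
    n_flank_mismatch_bases: int
    flank_bases_per_read: int = 20

    @property
    def per_base_rate(self) -> float:
        if self.n_reads == 0:
            return 0.0
        return self.n_flank_mismatch_bases / (self.flank_bases_per_read * self.n_reads)


@dataclass(frozen=True)
class CutoffConfig:
    """Policy for the noise cutoff.

    ``max_expected_spurious`` is the tolerated expected number of distinct
    error-derived genotypes at or above the cutoff; ``fixed`` overrides the
    model-based rule with an explicit per-pool cutoff.
    """

    max_expected_spurious: float = 0.5
    fixed: int | None = None
    max_cutoff: int = 1000


# ---------------------------------------------------------------------------
# validation and mutation calling
# ---------------------------------------------------------------------------

def validate_amplicon(seq: str, template: ReferenceTemplate) -> tuple[bool, str | None]:
    """Accept or reject a merged read against the template.

    Returns ``(True, None)`` on acceptance, else ``(False, reason)`` with
    reason in ``{"length_mismatch", "ambiguous_base"}``. Lowercase input is
    case-folded, not an error.
    """
    seq = seq.upper()
    if len(seq) != len(template.dna_sequence):
        return False, "length_mismatch"
    if not set(seq) <= DNA_ALPHABET:
        return False, "ambiguous_base"
    return True, None


def call_base_changes(seq: str, template: ReferenceTemplate) -> tuple[ChangeSet, int]:
    """Compress an accepted read to its window base changes.

    Returns the sorted change set inside the window and, separately, the
    number of mismatching bases inside the two flanks. Flank mismatches never
    become part of a genotype.
    """
    seq = seq.upper()
    if len(seq) != len(template.dna_sequence):
        raise ValueError("sequence length does not match template; validate first")
    ref = template.dna_sequence
    start, end = template.window
    changes = tuple(
        (i, ref[i], seq[i]) for i in range(start, end) if seq[i] != ref[i]
    )
    flank_mismatches = sum(
        1
        for a, b in template.flanks
        for i in range(a, b)
        if seq[i] != ref[i]
    )
    return changes, flank_mismatches


def apply_changes(changes: Iterable[BaseChange], template: ReferenceTemplate) -> str:
    """Reconstruct the full amplicon sequence carrying the given changes."""
    seq = list(template.dna_sequence)
    for pos, ref, alt in changes:
        if seq[pos] != ref:
            raise ValueError(f"reference base mismatch at {pos}: {seq[pos]} != {ref}")
        seq[pos] = alt
    return "".join(seq)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_genotypes(observations: Iterable[ChangeSet]) -> dict[ChangeSet, int]:
    """Tally identical change sets into a genotype count table.

    Keys are canonical sorted change sets; the empty tuple is the wild type.
    The counts sum to the number of observations.
    """
    return dict(Counter(tuple(sorted(obs)) for obs in observations))


def process_pool(reads: Iterable[str], template: ReferenceTemplate) -> tuple[
    dict[ChangeSet, int], FlankStats, dict[str, int]
]:
    """Full path for one pool: validate, call, count, flank statistics.

    Returns ``(count_table, flank_stats, rejection_log)`` where the rejection
    log maps reason -> number of rejected reads.
    """
    rejected: Counter[str] = Counter()
    observations: list[ChangeSet] = []
    n_flank = 0
    for read in reads:
        ok, reason = validate_amplicon(read, template)
        if not ok:
            rejected[reason] += 1
            continue
        changes, flank = call_base_changes(read, template)
        observations.append(changes)
        n_flank += flank
    stats = FlankStats(
        n_reads=len(observations),
        n_flank_mismatch_bases=n_flank,
        flank_bases_per_read=2 * template.flank_length,
    )
    return count_genotypes(observations), stats, dict(rejected)


# ---------------------------------------------------------------------------
# noise cutoff
# ---------------------------------------------------------------------------

def expected_spurious_at(count_table: dict[ChangeSet, int], per_read_error_prob: float,
                         cutoff: int) -> float:
    """Expected number of distinct error-derived genotypes with >= cutoff reads.

    Each true genotype with R reads emits erroneous reads at rate
    ``per_read_error_prob * R``; treating the most populous error class of each
    parent as a Poisson count with that mean gives a conservative bound on how
    many spurious genotypes survive a given cutoff.
    """
    if per_read_error_prob <= 0.0:
        return 0.0
    return float(
        sum(
            poisson.sf(cutoff - 1, per_read_error_prob * reads)
            for reads in count_table.values()
            if reads > 0
        )
    )


def choose_count_cutoff(count_table: dict[ChangeSet, int], flank_stats: FlankStats,
                        template: ReferenceTemplate,
                        config: CutoffConfig | None = None) -> int:
    """Choose the per-pool read-count cutoff from the flank error rate.

    The per-read probability of at least one erroneous window base is
    ``q = 1 - (1 - per_base_rate) ** window_length``. The cutoff is the
    smallest ``c`` such that the expected number of spurious genotypes
    reaching ``c`` reads (see :func:`expected_spurious_at`) falls below
    ``config.max_expected_spurious``. Genotypes with count < cutoff are
    treated as sequencing noise.
    """
    config = config or CutoffConfig()
    if config.fixed is not None:
        if config.fixed < 1:
            raise ValueError("fixed cutoff must be >= 1")
        return config.fixed
    if flank_stats.n_reads == 0 or not count_table:
        return 1
    window_len = template.window[1] - template.window[0]
    q = 1.0 - (1.0 - flank_stats.per_base_rate) ** window_len
    for c in range(1, config.max_cutoff + 1):
        if expected_spurious_at(count_table, q, c) < config.max_expected_spurious:
            return c
    return config.max_cutoff


def apply_cutoff(count_table: dict[ChangeSet, int], cutoff: int) -> dict[ChangeSet, int]:
    """Drop genotypes whose read count falls below the cutoff."""
    return {g: n for g, n in count_table.items() if n >= cutoff}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def dna_genotype_to_string(changes: ChangeSet) -> str:
    """Canonical DNA genotype string: semicolon-joined ``<ref><pos1><alt>`` tokens.

    Positions are 1-based in the string dialect; ``WT`` denotes no changes.
    """
    if not changes:
        return "WT"
    return ";".join(f"{ref}{pos + 1}{alt}" for pos, ref, alt in changes)


def dna_genotype_from_string(text: str) -> ChangeSet:
    if text == "WT":
        return ()
    changes = []
    for token in text.split(";"):
        ref, alt = token[0], token[-1]
        pos = int(token[1:-1]) - 1
        changes.append((pos, ref, alt))
    return tuple(sorted(changes))


def write_count_table(count_table: dict[ChangeSet, int], path: str | Path) -> None:
    """Write a genotype count table as TSV with columns ``genotype``, ``count``."""
    rows = sorted(count_table.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(
        {"genotype": [dna_genotype_to_string(g) for g, _ in rows],
         "count": [n for _, n in rows]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> dict[ChangeSet, int]:
    df = pd.read_csv(path, sep="\t", dtype={"genotype": str, "count": int})
    return {dna_genotype_from_string(g): int(n) for g, n in zip(df["genotype"], df["count"])}


def read_pool_file(path: str | Path) -> list[str]:
    """Read merged amplicon sequences: FASTA if the file starts with '>', else
    one sequence per line."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    return [line.strip() for line in text.splitlines() if line.strip()]
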