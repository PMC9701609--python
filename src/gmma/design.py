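"""Multi-mutant design: rank stabilizing substitutions and combine them.

Reliable substitutions are ranked by fitted effect (most stabilizing first);
a combinable set keeps at most one substitution per residue; the expected
stability of the combined multi-mutant assumes perfect additivity.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genotype import Substitution, SubstitutionStats
from .model import GmmaFitResult, GmmaParameters


@dataclass(frozen=True)
class RankedSubstitution:
    substitution: Substitution
    ddG: float
    su: float
    n_variants: int
    rank: int


@dataclass(frozen=True)
class MultiMutantDesign:
    """A combinable substitution set with its additive stability prediction."""

    name: str
    substitutions: tuple[Substitution, ...]
    predicted_dG: float
    predicted_ddG: float


def rank_reliable(fit: GmmaFitResult, reliable: set[Substitution],
                  stats: Mapping[Substitution, SubstitutionStats]) -> list[RankedSubstitution]:
    """Rank reliable substitutions by ddG ascending (rank 1 = most stabilizing).

    Ties break toward smaller uncertainty, then more supporting variants,
    then the canonical substitution string.
    """
    entries = [
        (fit.parameters.ddG[s], fit.su.get(s, float("inf")),
         -(stats[s].n_variants if s in stats else 0), str(s), s)
        for s in reliable
    ]
    entries.sort()
    return [
        RankedSubstitution(substitution=s, ddG=ddg, su=su, n_variants=-neg_n, rank=i + 1)
        for i, (ddg, su, neg_n, _, s) in enumerate(entries)
    ]


def select_combination(ranked: Sequence[RankedSubstitution], top_k: int,
                       name: str | None = None,
                       params: GmmaParameters | None = None) -> MultiMutantDesign:
    """Scan the top_k ranked substitutions, keeping the first at each residue.

    Later (worse-ranked) substitutions at an occupied residue are discarded,
    so the design holds at most one substitution per position. With fitted
    parameters supplied, the additive prediction is filled in (else dG_ref is
    taken as 0 and only the summed ddG is meaningful).
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    chosen: dict[int, RankedSubstitution] = {}
    for entry in ranked[:top_k]:
        chosen.setdefault(entry.substitution.residue, entry)
    members = tuple(e.substitution for e in sorted(chosen.values(), key=lambda e: e.rank))
    ddg_sum = sum(e.ddG for e in chosen.values())
    dg_ref = params.dG_ref if params is not None else 0.0
    return MultiMutantDesign(
        name=name or f"MM{len(members)}",
        substitutions=members,
        predicted_dG=dg_ref + ddg_sum,
        predicted_ddG=ddg_sum,
    )


def predict_additive(params: GmmaParameters, substitutions: Sequence[Substitution]) -> tuple[
    float, float, dict[Substitution, float]
]:
    """Expected stability of a multi-mutant under perfect additivity.

    Returns ``(predicted_dG, predicted_ddG, per-member contributions)``.
    Duplicate residues are a position clash: a protein cannot carry two
    substitutions at one site.
    """
    residues = [s.residue for s in substitutions]
    if len(residues) != len(set(residues)):
        raise ValueError("position_clash: duplicate residue in design")
    contributions = {s: params.ddG[s] for s in substitutions}
    ddg = sum(contributions.values())
    return params.dG_ref + ddg, ddg, contributions


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def ranked_to_frame(ranked: Sequence[RankedSubstitution]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"rank": e.rank, "substitution": str(e.substitution), "ddG_kJmol": e.ddG,
             "su_kJmol": e.su, "n_variants": e.n_variants}
            for e in ranked
        ]
    )


def design_report(design: MultiMutantDesign, params: GmmaParameters) -> dict:
    dg, ddg, contributions = predict_additive(params, design.substitutions)
    return {
        "name": design.name,
        "substitutions": [str(s) for s in design.substitutions],
        "contributions_kJmol": {str(s): v for s, v in contributions.items()},
        "predicted_dG_kJmol": dg,
        "predicted_ddG_kJmol": ddg,
        "dG_ref_kJmol": params.dG_ref,
    }


def write_design_report(design: MultiMutantDesign, params: GmmaParameters,
                        path: str | Path) -> None:
    Path(path).write_text(json.dumps(design_report(design, params), indent=2) + "\n")
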