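"""Function annotation post-processing.

Applies the COG hit-acceptance rule to alignment hit tables (domain coverage
>= 0.5 and e-value <= 0.01, otherwise category S), reduces naive
function-to-pathway maps to a parsimonious minimal pathway set, and builds
COG-category relative-abundance profiles from quantified spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN_CATEGORY = "S"
EXACT_SOLVER_LIMIT = 20


@dataclass(frozen=True)
class CogHit:
    query: str
    cog_id: str
    categories: str
    domain_coverage: float
    e_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.domain_coverage <= 1:
            raise ValueError(f"domain coverage out of [0,1]: {self.domain_coverage}")
        if self.e_value < 0:
            raise ValueError("e-value must be >= 0")


@dataclass(frozen=True)
class CogAssignment:
    query: str
    cog_ids: frozenset[str]
    categories: str  # concatenated single-letter categories


def hits_from_table(df: pd.DataFrame) -> list[CogHit]:
    return [
        CogHit(
            query=str(row["query"]),
            cog_id=str(row["subject_id"]),
            categories=str(row.get("categories", "") or ""),
            domain_coverage=float(row["domain_coverage"]),
            e_value=float(row["evalue"]),
        )
        for _, row in df.iterrows()
    ]


def filter_cog_hits(
    hits: Iterable[CogHit],
    all_proteins: Iterable[str] | None = None,
    min_coverage: float = 0.5,
    max_evalue: float = 0.01,
) -> dict[str, CogAssignment]:
    """COG assignment rule: coverage >= 0.5 of the domain and e <= 0.01.

    Proteins named in ``all_proteins`` (or seen in the hit table) with no
    surviving hit fall back to the unknown-function category S.
    """
    surviving: dict[str, set[CogHit]] = {}
    seen: set[str] = set()
    for hit in hits:
        seen.add(hit.query)
        if hit.domain_coverage >= min_coverage and hit.e_value <= max_evalue:
            surviving.setdefault(hit.query, set()).add(hit)

    universe = set(all_proteins) if all_proteins is not None else seen
    assignments: dict[str, CogAssignment] = {}
    for protein in sorted(universe | seen):
        kept = surviving.get(protein)
        if kept:
            letters = sorted({c for h in kept for c in h.categories if c.strip()})
            assignments[protein] = CogAssignment(
                query=protein,
                cog_ids=frozenset(h.cog_id for h in kept),
                categories="".join(letters) or UNKNOWN_CATEGORY,
            )
        else:
            assignments[protein] = CogAssignment(
                query=protein, cog_ids=frozenset(), categories=UNKNOWN_CATEGORY
            )
    return assignments


# ---------------------------------------------------------------------------
# Parsimonious pathway minimization
# ---------------------------------------------------------------------------

def _greedy_cover(functions: set[str], pathway_map: Mapping[str, set[str]]) -> set[str]:
    remaining = set(functions)
    chosen: set[str] = set()
    while remaining:
        best = max(sorted(pathway_map), key=lambda p: len(pathway_map[p] & remaining))
        gain = pathway_map[best] & remaining
        if not gain:
            break
        chosen.add(best)
        remaining -= gain
    return chosen


def minimize_pathways(
    functions: Iterable[str],
    pathway_map: Mapping[str, Iterable[str]],
    exact_limit: int = EXACT_SOLVER_LIMIT,
) -> tuple[set[str], set[str]]:
    """Minimum set of pathways whose union covers every coverable function.

    Exact minimum-cardinality set cover (subset enumeration by size) when at
    most ``exact_limit`` candidate pathways are relevant; greedy set cover
    beyond that, with a warning. Returns (chosen pathways, unexplained
    functions).
    """
    functions = set(functions)
    full_map = {p: set(fs) for p, fs in pathway_map.items()}
    candidates = {p: fs & functions for p, fs in full_map.items() if fs & functions}
    coverable = set().union(*candidates.values()) if candidates else set()
    unexplained = functions - coverable
    if not candidates:
        return set(), unexplained

    names = sorted(candidates)
    if len(names) > exact_limit:
        logger.warning(
            "minimize_pathways: %d candidate pathways > %d; using greedy set cover",
            len(names), exact_limit,
        )
        return _greedy_cover(coverable, candidates), unexplained

    for size in range(1, len(names) + 1):
        best: tuple[str, ...] | None = None
        for combo in combinations(names, size):
            union = set().union(*(candidates[p] for p in combo))
            if union >= coverable:
                best = combo
                break
        if best is not None:
            return set(best), unexplained
    return set(names), unexplained  # unreachable: all candidates always cover


def read_pathway_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (pathway_id, function_id) -> pathway map."""
    mapping: dict[str, set[str]] = {}
    with Path(path).open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path} line {lineno}: expected 2 columns")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping


# ---------------------------------------------------------------------------
# COG category profiles
# ---------------------------------------------------------------------------

def cog_category_profile(
    protein_spectra: Mapping[str, float],
    assignments: Mapping[str, CogAssignment],
) -> pd.Series:
    """Relative abundance of COG category letters for one genome.

    Spectra of a protein are split equally over its category letters;
    unassigned proteins count toward S. The result sums to 1.
    """
    totals: dict[str, float] = {}
    grand = 0.0
    for protein, spectra in protein_spectra.items():
        if spectra <= 0:
            continue
        assignment = assignments.get(protein)
        letters = assignment.categories if assignment else UNKNOWN_CATEGORY
        share = spectra / len(letters)
        for letter in letters:
            totals[letter] = totals.get(letter, 0.0) + share
        grand += spectra
    if grand == 0:
        raise ValueError("no expressed proteins: cannot build a category profile")
    return pd.Series({k: v / grand for k, v in sorted(totals.items())}, name="relative_abundance")
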