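"""Host-phenotype specificity (HPS) of protein expression.

HPS is the Shannon entropy of a protein's phenotype expression proportions
taken in log base N, where N is the number of phenotypes the protein is
expressed in: ``-sum_j p_j * log_N(p_j)``. 0 means expression concentrated
in a single phenotype; 1 means a uniform spread over all N phenotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .io_formats import SampleManifest


@dataclass(frozen=True)
class PhenotypeProfile:
    """Proportions of a protein's (normalized) expression per phenotype.

    Only phenotypes with nonzero expression are retained; proportions sum
    to one.
    """

    protein_id: str
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.proportions):
            raise ValueError("proportions must be strictly positive (drop zero phenotypes first)")
        if self.proportions and abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")

    @property
    def n_phenotypes(self) -> int:
        return len(self.proportions)


def compute_hps(profile: PhenotypeProfile) -> float:
    """Entropy-based specificity in [0, 1]. N = 1 yields 0 by convention."""
    n = profile.n_phenotypes
    if n == 0:
        raise ValueError(f"protein {profile.protein_id}: expressed in zero phenotypes")
    if n == 1:
        return 0.0
    log_n = math.log(n)
    h = -sum(p * math.log(p) / log_n for p in profile.proportions)
    return min(max(h, 0.0), 1.0)


def profile_from_counts(
    protein_id: str,
    counts_by_phenotype: dict[str, float],
    min_expression: float = 0.0,
    full_vocabulary: list[str] | None = None,
) -> PhenotypeProfile:
    """Build a profile from per-phenotype summed (normalized) counts.

    Phenotypes at or below ``min_expression`` are excluded before N is fixed.
    When ``full_vocabulary`` is given, N is forced to the vocabulary size by
    keeping zero-phenotypes out of the proportions but using base
    ``len(full_vocabulary)`` downstream — see :func:`hps_table`.
    """
    expressed = {ph: v for ph, v in counts_by_phenotype.items() if v > min_expression}
    total = sum(expressed.values())
    if total <= 0:
        raise ValueError(f"protein {protein_id}: no expression above threshold")
    props = tuple(expressed[ph] / total for ph in sorted(expressed))
    return PhenotypeProfile(protein_id=protein_id, proportions=props)


def hps_table(
    normalized_counts: pd.DataFrame,
    manifest: SampleManifest,
    min_expression: float = 0.0,
    n_from_vocabulary: bool = False,
) -> pd.DataFrame:
    """HPS for every protein row of a (normalized) counts matrix.

    Returns a frame with columns protein_id, n_phenotypes, hps. With
    ``n_from_vocabulary`` the entropy base is the full phenotype vocabulary
    size rather than each protein's support size.
    """
    phenotype_of = {s: manifest.phenotype_of(s) for s in normalized_counts.columns}
    groups = normalized_counts.T.groupby(pd.Series(phenotype_of)).sum().T
    vocab_n = len(manifest.vocabulary)

    rows = []
    for protein_id, series in groups.iterrows():
        by_pheno = {ph: v for ph, v in series.items() if v > min_expression}
        if not by_pheno:
            continue
        profile = profile_from_counts(protein_id, by_pheno, min_expression=0.0)
        if n_from_vocabulary and vocab_n >= 2:
            log_n = math.log(vocab_n)
            value = -sum(p * math.log(p) / log_n for p in profile.proportions)
            value = float(min(max(value, 0.0), 1.0))
        else:
            value = compute_hps(profile)
        rows.append({"protein_id": protein_id, "n_phenotypes": profile.n_phenotypes, "hps": value})
    return pd.DataFrame(rows, columns=["protein_id", "n_phenotypes", "hps"])


def genome_hps_summary(table: pd.DataFrame, protein_to_genome: dict[str, str]) -> pd.DataFrame:
    """Boxplot-ready per-genome mean/median HPS summary."""
    table = table.assign(genome_id=table["protein_id"].map(protein_to_genome))
    grouped = table.groupby("genome_id")["hps"]
    return pd.DataFrame(
        {
            "mean_hps": grouped.mean(),
            "median_hps": grouped.median(),
            "n_proteins": grouped.size(),
        }
    ).reset_index()
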