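"""Amino-acid-scale properties, composition statistics, and class comparisons.

Ten literature property scales (polarity, hydrophobicity, average area
buried, fraction of buried residues, bulkiness, molar refractivity,
recognition factors, molecular weight, transmembrane tendency, and HPLC
retention) are packaged as a TSV and exposed as :class:`AAScale` objects.
On top of them sit the per-residue property profiles used throughout the
pipeline, N-glycosylation sequon counting (N-X-S/T with X != P), and the
statistical machinery for comparing enriched vs depleted fragment classes:
two-sided Mann-Whitney tests, Benjamini-Hochberg correction, and the
one-sided Fisher exact test for signal-peptide enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
SCALE_NAMES = (
    "polarity",
    "hydrophobicity",
    "area_buried",
    "buried_residues",
    "bulkiness",
    "molar_refractivity",
    "recognition_factors",
    "molecular_weight",
    "transmembrane_tendency",
    "hplc_retention",
)

__all__ = [
    "STANDARD_AA",
    "SCALE_NAMES",
    "AAScale",
    "CompositionStats",
    "load_scales",
    "load_aux_scales",
    "property_profile",
    "count_sequons",
    "composition_stats",
    "compare_classes",
    "adjust_bh",
    "apply_bh_policy",
    "fisher_secretory_enrichment",
]


@dataclass(frozen=True)
class AAScale:
    """A named per-residue property scale with its literature citation key."""

    name: str
    values: Mapping[str, float]
    citation: str = ""
    _mean: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        if set(self.values) != set(STANDARD_AA):
            raise ValueError(
                f"scale {self.name!r} must define exactly the 20 standard residues"
            )
        object.__setattr__(
            self, "_mean", float(np.mean([self.values[a] for a in STANDARD_AA]))
        )

    @property
    def mean(self) -> float:
        """Unweighted mean over the 20 standard residues (unknown-residue fill)."""
        return self._mean

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def as_array(self) -> np.ndarray:
        """Values in the fixed alphabetical residue order of ``STANDARD_AA``."""
        return np.array([self.values[a] for a in STANDARD_AA])


def _read_scale_tsv(filename: str) -> pd.DataFrame:
    with resources.files("secscreen.data").joinpath(filename).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", index_col="residue")


_CITATIONS = {
    "polarity": "Zimmerman-1968",
    "hydrophobicity": "Kyte-Doolittle-1982",
    "area_buried": "Rose-1985",
    "buried_residues": "Chothia-1976",
    "bulkiness": "Zimmerman-1968",
    "molar_refractivity": "Jones-1975",
    "recognition_factors": "Fraga-1982",
    "molecular_weight": "residue-formula-weight",
    "transmembrane_tendency": "Zhao-London-2006",
    "hplc_retention": "Meek-1980",
    "helix_propensity": "Chou-Fasman-1978",
    "flexibility": "Bhaskaran-Ponnuswamy-1988",
}


def load_scales() -> dict[str, AAScale]:
    """The ten packaged property scales, keyed by name."""
    table = _read_scale_tsv("aa_scales.tsv")
    return {
        name: AAScale(name, table[name].to_dict(), _CITATIONS[name])
        for name in SCALE_NAMES
    }


def load_aux_scales() -> dict[str, AAScale]:
    """Auxiliary scales (helix propensity, flexibility) for the simulator."""
    table = _read_scale_tsv("aux_scales.tsv")
    return {
        name: AAScale(name, table[name].to_dict(), _CITATIONS[name])
        for name in table.columns
    }


def property_profile(peptide: str, scale: AAScale) -> np.ndarray:
    """Per-residue property track: ``track[i] = scale[peptide[i]]``.

    Residues outside the 20-letter alphabet (e.g. X, U) map to the scale
    mean, with a warning.
    """
    track = np.empty(len(peptide))
    unknown = []
    for i, aa in enumerate(peptide):
        try:
            track[i] = scale.values[aa]
        except KeyError:
            track[i] = scale.mean
            unknown.append(aa)
    if unknown:
        warnings.warn(
            f"unknown residues {sorted(set(unknown))} mapped to the "
            f"{scale.name!r} scale mean",
            stacklevel=2,
        )
    return track


def count_sequons(peptide: str) -> int:
    """Number of N-glycosylation sequons N-X-S/T with X != P.

    Overlapping sequons are all counted; the window must fit, so the final
    two positions cannot start a sequon.
    """
    return sum(
        1
        for i in range(len(peptide) - 2)
        if peptide[i] == "N"
        and peptide[i + 1] != "P"
        and peptide[i + 2] in ("S", "T")
    )


@dataclass(frozen=True)
class CompositionStats:
    """Summary composition of one peptide."""

    length: int
    frac_de: float       # fraction of D + E (negatively charged)
    frac_pro: float      # fraction of prolines
    mean_hydrophobicity: float
    cys_count: int
    cys_parity_even: bool
    sequon_count: int


def composition_stats(
    peptide: str, hydrophobicity: AAScale | None = None
) -> CompositionStats:
    """Composition summary used in the class-comparison analyses."""
    if hydrophobicity is None:
        hydrophobicity = load_scales()["hydrophobicity"]
    n = len(peptide)
    if n == 0:
        raise ValueError("empty peptide")
    n_de = sum(1 for aa in peptide if aa in "DE")
    n_p = peptide.count("P")
    n_c = peptide.count("C")
    return CompositionStats(
        length=n,
        frac_de=n_de / n,
        frac_pro=n_p / n,
        mean_hydrophobicity=float(property_profile(peptide, hydrophobicity).mean()),
        cys_count=n_c,
        cys_parity_even=(n_c % 2 == 0),
        sequon_count=count_sequons(peptide),
    )


def compare_classes(
    values_enriched: Sequence[float], values_depleted: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two fragment classes.

    Returns ``(U, p)``.  The exact null distribution is used for small,
    tie-free samples and the tie-corrected normal approximation otherwise
    (scipy's automatic method selection).
    """
    x = np.asarray(values_enriched, dtype=float)
    y = np.asarray(values_depleted, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_bh_policy(
    pvalues: Sequence[float], min_comparisons: int = 10
) -> np.ndarray:
    """BH correction applied only when the comparison count exceeds the policy
    threshold (default: correct only for more than 10 comparisons)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size > min_comparisons:
        return adjust_bh(p)
    return p.copy()


def fisher_secretory_enrichment(
    k_sp: int, k_nosp: int, bg_sp: int, bg_nosp: int
) -> float:
    """One-sided Fisher exact test for signal-peptide enrichment.

    Tests whether the secretable protein set (``k_sp`` with a signal peptide,
    ``k_nosp`` without) is enriched for signal-peptide proteins relative to
    the background proteome (``bg_sp`` / ``bg_nosp``); returns the upper-tail
    p-value P(X >= k_sp).
    """
    for v in (k_sp, k_nosp, bg_sp, bg_nosp):
        if v < 0:
            raise ValueError("counts must be non-negative")
    table = [[k_sp, k_nosp], [bg_sp, bg_nosp]]
    return float(stats.fisher_exact(table, alternative="greater")[1])
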