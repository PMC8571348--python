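"""Library-design calculations for fragment surface-display screens.

Covers the arithmetic a screen designer needs before any sequencing data
exists: how many distinct clones a transformation yields, how likely the
rarest fragment is to be sampled into a library of a given size, and how the
observed double-positive (displaying) cell fraction translates into the
fraction of in-frame fragments that are displayed.

The diversity estimate assumes equally probable variants: transforming ``T``
clones drawn from ``D_max`` possible variants leaves an expected

    D = D_max * (1 - exp(-T / D_max))

distinct variants in the library.  The sampling-probability model treats
fragment relative abundances as log-uniform over a configurable dynamic
range (transcript abundances in human cell lines span roughly four orders of
magnitude), optionally compressed by a normalization step, and asks for the
probability that the *least* abundant fragment is seen at least once among
Poisson-sampled clones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiversityInput",
    "SamplingModel",
    "estimate_diversity",
    "sampling_probability",
    "sampling_curve",
    "displayed_fraction",
    "transformation_efficiency",
]


@dataclass(frozen=True)
class DiversityInput:
    """Transformation outcome used for a diversity estimate.

    Parameters
    ----------
    transformants : float
        Number of transformant clones obtained (``T``); must be >= 0.
    max_diversity : float
        Maximal achievable diversity ``D_max`` (distinct variants, given an
        infinite number of transformants); must be > 0.
    """

    transformants: float
    max_diversity: float

    def __post_init__(self) -> None:
        if self.max_diversity <= 0:
            raise ValueError("max_diversity must be positive")
        if self.transformants < 0:
            raise ValueError("transformants must be non-negative")


@dataclass(frozen=True)
class SamplingModel:
    """Abundance model behind the fragment-sampling probability curve.

    Parameters
    ----------
    n_distinct : int
        Number of distinct fragments at the chosen resolution (>= 1).
    dynamic_range_log10 : float
        Span of fragment relative abundances, in log10 units (>= 0).
    normalization_factor : float
        Fold-compression of the abundance range achieved by normalization
        (>= 1; 1 means no normalization).
    library_size : float
        Number of clones sampled into the library (>= 0).
    """

    n_distinct: int
    dynamic_range_log10: float
    normalization_factor: float = 1.0
    library_size: float = 0.0

    def __post_init__(self) -> None:
        if self.n_distinct < 1:
            raise ValueError("n_distinct must be >= 1")
        if self.dynamic_range_log10 < 0:
            raise ValueError("dynamic_range_log10 must be >= 0")
        if self.normalization_factor < 1:
            raise ValueError("normalization_factor must be >= 1")
        if self.library_size < 0:
            raise ValueError("library_size must be >= 0")


def estimate_diversity(inp: DiversityInput) -> float:
    """Expected number of distinct clones, assuming equally probable variants.

    Returns ``D = D_max * (1 - exp(-T / D_max))``, which is bounded by both
    ``T`` and ``D_max`` and increases monotonically (and concavely) in ``T``.
    """
    t, dmax = inp.transformants, inp.max_diversity
    return dmax * (-math.expm1(-t / dmax))


def _normalized_abundances(m: SamplingModel) -> np.ndarray:
    """Relative fragment abundances after normalization (sums to 1)."""
    span = max(m.dynamic_range_log10 - math.log10(m.normalization_factor), 0.0)
    if m.n_distinct == 1:
        return np.ones(1)
    # log-uniform grid: log10-abundances evenly spaced over the residual span
    weights = 10.0 ** np.linspace(0.0, span, m.n_distinct)
    return weights / weights.sum()


def sampling_probability(m: SamplingModel) -> float:
    """Probability that the rarest fragment is sampled at least once.

    Fragment relative abundances are modelled as log-uniform over
    ``dynamic_range_log10`` decades, compressed by the normalization factor
    (floored at a flat distribution).  Clone counts are Poisson, so the
    rarest fragment (relative abundance ``p_min``) is captured with
    probability ``1 - exp(-library_size * p_min)``.
    """
    p_min = _normalized_abundances(m).min()
    return -math.expm1(-m.library_size * p_min)


def sampling_curve(m: SamplingModel, library_sizes: np.ndarray) -> np.ndarray:
    """Vectorized :func:`sampling_probability` over a grid of library sizes."""
    p_min = _normalized_abundances(m).min()
    return -np.expm1(-np.asarray(library_sizes, dtype=float) * p_min)


def displayed_fraction(
    double_positive_pct: float, frame_factor: float
) -> float:
    """Scale the double-positive cell percentage to in-frame fragments.

    Random-primed cloning puts a fragment in frame with both fusion partners
    with probability 1/9, so a ``frame_factor`` of 9 converts the observed
    percentage of displaying (double-positive) cells into the percentage of
    in-frame fragments that are detectably displayed.  The result is capped
    at 100%; a pre-cap value above 100 raises a warning.
    """
    if not 0 <= double_positive_pct <= 100:
        raise ValueError("double_positive_pct must be in [0, 100]")
    if frame_factor <= 0:
        raise ValueError("frame_factor must be positive")
    value = double_positive_pct * frame_factor
    if value > 100:
        warnings.warn(
            "displayed fraction exceeds 100% before capping", stacklevel=2
        )
        value = 100.0
    return value


def transformation_efficiency(
    cfu: float, ug_dna: float, growth_factor: float = 1.0
) -> float:
    """Colony-forming units per microgram DNA, corrected for recovery growth.

    Cells divide during the post-electroporation recovery; dividing the
    plated CFU count by the fold-growth during recovery recovers the number
    of original transformation events.
    """
    if ug_dna <= 0:
        raise ValueError("ug_dna must be positive")
    if growth_factor < 1:
        raise ValueError("growth_factor must be >= 1")
    if cfu < 0:
        raise ValueError("cfu must be non-negative")
    return (cfu / growth_factor) / ug_dna


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
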