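"""FPTM and E-factor enrichment statistics with replicate-consistency classes.

The screen's per-fragment statistic is the enrichment factor

    E_r = log2( FPTM_sorted,r / FPTM_unsorted,merged )

where FPTM is the fragment count per ten million read pairs and the merged
unsorted sample (replicate unsorted counts summed, then normalized) serves
as the common denominator.  Fragments detected in all replicates are
classified by consistency of E across replicates at thresholds +1/-1
(a minimal two-fold increase/decrease): ``enriched`` (all E >= +1, the
secretable proxy), ``depleted`` (all E <= -1), ``uncertain`` (all but one
replicate consistent, the odd one strictly between the thresholds) or
``inconsistent``.  Fragments consistent in exactly two replicates feed the
independent validation sets A (third replicate between the thresholds) and
B (third replicate beyond the opposite threshold).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

TEN_MILLION = 1e7

CLASS_ENRICHED = "enriched"
CLASS_DEPLETED = "depleted"
CLASS_UNCERTAIN = "uncertain"
CLASS_INCONSISTENT = "inconsistent"
CLASS_UNDETECTED = "undetected"

__all__ = [
    "ClassifierConfig",
    "sample_layout",
    "compute_fptm",
    "merge_unsorted",
    "compute_efactor",
    "flag_in_frame",
    "enrich",
    "classify",
    "stratify_independent_sets",
    "concordance",
    "coverage_fraction",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and rules for consistency classification."""

    upper: float = 1.0
    lower: float = -1.0
    detection_rule: str = "per_replicate"  # or "merged_unsorted"
    per_replicate_denominator: bool = False  # sensitivity option

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError("upper threshold must exceed lower threshold")
        if self.detection_rule not in ("per_replicate", "merged_unsorted"):
            raise ValueError(f"unknown detection rule {self.detection_rule!r}")


_SAMPLE_RE = re.compile(r"^rep(\d+)_(unsorted|sorted)$")


def sample_layout(counts: pd.DataFrame) -> tuple[list[int], dict[tuple[int, str], str]]:
    """Parse ``rep{r}_{pool}`` columns; returns replicate ids and column map."""
    layout: dict[tuple[int, str], str] = {}
    reps = set()
    for col in counts.columns:
        m = _SAMPLE_RE.match(col)
        if not m:
            raise ValueError(f"unrecognized sample column {col!r}")
        r = int(m.group(1))
        layout[(r, m.group(2))] = col
        reps.add(r)
    return sorted(reps), layout


def compute_fptm(counts: pd.DataFrame) -> pd.DataFrame:
    """Fragment count Per Ten Million read pairs, per sample column.

    Every output column sums to 1e7 (up to floating tolerance).
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total count: {bad}")
    return counts / totals * TEN_MILLION


def merge_unsorted(counts: pd.DataFrame) -> pd.Series:
    """FPTM over the merged (summed) replicate unsorted samples."""
    _, layout = sample_layout(counts)
    unsorted_cols = [col for (r, pool), col in layout.items() if pool == "unsorted"]
    if not unsorted_cols:
        raise ValueError("no unsorted samples present")
    merged = counts[unsorted_cols].sum(axis=1)
    total = merged.sum()
    if total <= 0:
        raise ValueError("merged unsorted sample has zero total count")
    return merged / total * TEN_MILLION


def compute_efactor(fptm_sorted, fptm_unsorted):
    """E = log2(FPTM_sorted / FPTM_unsorted) as an extended real.

    sorted == 0 gives -inf, unsorted == 0 (with sorted > 0) gives +inf, and
    both zero gives NaN (the fragment is undetected, flagged rather than
    dropped).  Accepts scalars or aligned arrays/Series.
    """
    s = np.asarray(fptm_sorted, dtype=float)
    u = np.asarray(fptm_unsorted, dtype=float)
    if (s < 0).any() or (u < 0).any():
        raise ValueError("FPTM values must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.log2(s / u)
    e = np.where((s == 0) & (u == 0), np.nan, e)
    if np.ndim(fptm_sorted) == 0 and np.ndim(fptm_unsorted) == 0:
        return float(e)
    if isinstance(fptm_sorted, pd.Series):
        return pd.Series(e, index=fptm_sorted.index)
    return e


def flag_in_frame(
    start: int, end: int, cds_start: int, cds_end: int
) -> tuple[bool, bool]:
    """(N-terminal, C-terminal) frame flags for a fragment on its transcript.

    A fragment is in frame with the upstream fusion partner when its start
    lies inside the CDS on a codon boundary, and with the downstream partner
    when its length is a multiple of three.  A fragment starting outside the
    CDS is out of frame on both ends.
    """
    if start < 0 or end <= start:
        raise ValueError("need 0 <= start < end")
    if not (cds_start <= start < cds_end):
        return False, False
    return (start - cds_start) % 3 == 0, (end - start) % 3 == 0


def enrich(
    counts: pd.DataFrame,
    in_frame: pd.Series | None = None,
    cfg: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Full per-fragment enrichment table.

    Returns a DataFrame indexed by fragment key with per-sample FPTM, the
    merged unsorted FPTM, per-replicate E factors, detection flags and the
    consistency class.  ``in_frame`` (boolean Series aligned to the index)
    is carried through for the concordance denominator.
    """
    cfg = cfg or ClassifierConfig()
    reps, layout = sample_layout(counts)
    fptm = compute_fptm(counts)
    merged = merge_unsorted(counts)

    out = pd.DataFrame(index=counts.index.copy())
    for r in reps:
        out[f"fptm_unsorted_{r}"] = fptm[layout[(r, "unsorted")]]
        out[f"fptm_sorted_{r}"] = fptm[layout[(r, "sorted")]]
    out["fptm_unsorted_merged"] = merged
    for r in reps:
        denom = (
            out[f"fptm_unsorted_{r}"] if cfg.per_replicate_denominator else merged
        )
        out[f"E_{r}"] = compute_efactor(out[f"fptm_sorted_{r}"], denom)
    for r in reps:
        if cfg.detection_rule == "per_replicate":
            det = (counts[layout[(r, "sorted")]] > 0) | (
                counts[layout[(r, "unsorted")]] > 0
            )
        else:
            det = (counts[layout[(r, "sorted")]] > 0) | (
                merged > 0
            )
        out[f"detected_{r}"] = det
    out["in_frame"] = (
        in_frame.reindex(counts.index).fillna(False).astype(bool)
        if in_frame is not None
        else True
    )
    out["class"] = classify(out, cfg)
    return out


def _e_matrix(records: pd.DataFrame) -> np.ndarray:
    e_cols = sorted(
        (c for c in records.columns if re.match(r"^E_\d+$", c)),
        key=lambda c: int(c.split("_")[1]),
    )
    return records[e_cols].to_numpy(dtype=float)


def _detected_all(records: pd.DataFrame) -> np.ndarray:
    det_cols = [c for c in records.columns if c.startswith("detected_")]
    if not det_cols:
        return np.ones(len(records), dtype=bool)
    return records[det_cols].to_numpy(dtype=bool).all(axis=1)


def classify(records: pd.DataFrame, cfg: ClassifierConfig | None = None) -> pd.Series:
    """Consistency class per fragment from its per-replicate E factors.

    Only fragments detected in every replicate are classified; the rest are
    ``undetected``.  Thresholds are inclusive: E exactly at +1 counts as the
    minimal two-fold increase.
    """
    cfg = cfg or ClassifierConfig()
    e = _e_matrix(records)
    n_rep = e.shape[1]
    detected = _detected_all(records)

    with np.errstate(invalid="ignore"):
        ge = (e >= cfg.upper).sum(axis=1)
        le = (e <= cfg.lower).sum(axis=1)
        mid = ((e > cfg.lower) & (e < cfg.upper)).sum(axis=1)

    labels = np.full(len(records), CLASS_INCONSISTENT, dtype=object)
    labels[(ge == n_rep - 1) & (mid == 1)] = CLASS_UNCERTAIN
    labels[(le == n_rep - 1) & (mid == 1)] = CLASS_UNCERTAIN
    labels[ge == n_rep] = CLASS_ENRICHED
    labels[le == n_rep] = CLASS_DEPLETED
    labels[~detected] = CLASS_UNDETECTED
    return pd.Series(labels, index=records.index, name="class")


def stratify_independent_sets(
    records: pd.DataFrame, cfg: ClassifierConfig | None = None
) -> pd.DataFrame:
    """Independent validation sets from two-of-three-consistent fragments.

    Among detected fragments consistent in exactly two replicates, set A
    holds those whose third replicate lies strictly between the thresholds
    and set B those whose third replicate crosses the opposite threshold.
    Returns a DataFrame with columns ``independent_set`` ("A"/"B") and
    ``label`` (1 for the enriched side, 0 for the depleted side), indexed by
    the member fragments only.
    """
    cfg = cfg or ClassifierConfig()
    e = _e_matrix(records)
    n_rep = e.shape[1]
    detected = _detected_all(records)
    with np.errstate(invalid="ignore"):
        ge = (e >= cfg.upper).sum(axis=1)
        le = (e <= cfg.lower).sum(axis=1)
        mid = ((e > cfg.lower) & (e < cfg.upper)).sum(axis=1)

    a_enr = detected & (ge == n_rep - 1) & (mid == 1)
    a_dep = detected & (le == n_rep - 1) & (mid == 1)
    b_enr = detected & (ge == n_rep - 1) & (le == 1)
    b_dep = detected & (le == n_rep - 1) & (ge == 1)

    rows = []
    for mask, set_name, label in (
        (a_enr, "A", 1),
        (a_dep, "A", 0),
        (b_enr, "B", 1),
        (b_dep, "B", 0),
    ):
        for key in records.index[mask]:
            rows.append((key, set_name, label))
    out = pd.DataFrame(
        rows, columns=["fragment_key", "independent_set", "label"]
    ).set_index("fragment_key")
    return out


def concordance(records: pd.DataFrame) -> float:
    """Percent of commonly detected in-frame fragments classified consistently.

    ``(n_enriched + n_depleted) / n_commonly_detected_in_frame * 100``.
    """
    mask = records["in_frame"].astype(bool) & (records["class"] != CLASS_UNDETECTED)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no commonly detected in-frame fragments")
    consistent = records.loc[mask, "class"].isin([CLASS_ENRICHED, CLASS_DEPLETED])
    return float(consistent.sum()) / n * 100.0


def coverage_fraction(
    fragments: pd.DataFrame,
    transcript_lengths: dict[str, int],
    min_reads: int = 3,
) -> float:
    """Percent of transcriptome bases covered by well-supported fragments.

    ``fragments`` needs columns ``transcript_id``, ``start``, ``end`` and
    ``count``; a base is covered when at least one overlapping fragment has
    ``count >= min_reads``.
    """
    total = sum(transcript_lengths.values())
    if total <= 0:
        raise ValueError("empty transcriptome")
    covered = 0
    good = fragments[fragments["count"] >= min_reads]
    for tid, grp in good.groupby("transcript_id"):
        tlen = transcript_lengths[tid]
        delta = np.zeros(tlen + 1, dtype=np.int64)
        starts = np.clip(grp["start"].to_numpy(), 0, tlen)
        ends = np.clip(grp["end"].to_numpy(), 0, tlen)
        np.add.at(delta, starts, 1)
        np.add.at(delta, ends, -1)
        covered += int((np.cumsum(delta[:-1]) > 0).sum())
    return covered / total * 100.0
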