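"""Residue-level consolidation of overlapping fragment calls.

Overlapping fragments of one protein can disagree about secretability, so
fragment-level classes are collapsed to residues: a residue keeps the label
``secreted`` or ``depleted`` only when every covering fragment agrees, is
``ambiguous`` when covered by both classes, and ``uncovered`` otherwise.
Maximal runs of identically labelled unambiguous residues become
*consolidated fragments*, carrying per-residue property profiles averaged
over the contributing fragments.  Independently, fragment peptides can be
clustered into representatives by full containment: a shorter sequence
joins the first longer representative that contains it verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABEL_SECRETED = "secreted"
LABEL_DEPLETED = "depleted"
LABEL_AMBIGUOUS = "ambiguous"
LABEL_UNCOVERED = "uncovered"

__all__ = [
    "FilteredFragment",
    "ResidueLabelTrack",
    "ConsolidatedFragment",
    "RepresentativeCluster",
    "filter_for_consolidation",
    "build_residue_track",
    "build_consolidated",
    "cluster_representatives",
]


@dataclass(frozen=True)
class FilteredFragment:
    """A fragment that passed the consolidation filter, with its protein offset."""

    key: str
    protein_id: str
    peptide: str
    offset: int  # 0-based aa offset of the peptide within the protein
    label: str  # secreted / depleted
    multiple_matches: bool = False


@dataclass
class ResidueLabelTrack:
    """Per-residue consensus labels for one protein."""

    protein_id: str
    labels: np.ndarray  # array of label strings, length = protein length
    support: np.ndarray  # number of covering fragments per residue


@dataclass(frozen=True)
class ConsolidatedFragment:
    """A maximal run of identically labelled, unambiguous residues."""

    protein_id: str
    start: int  # 0-based half-open aa coordinates on the protein
    end: int
    label: str
    profile: np.ndarray | None = None  # condensed per-residue property values

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepresentativeCluster:
    """A representative peptide and the member keys it fully contains."""

    representative: str
    members: list[str] = field(default_factory=list)


_CLASS_TO_LABEL = {"enriched": LABEL_SECRETED, "depleted": LABEL_DEPLETED}


def filter_for_consolidation(
    fragments: list[tuple[str, str, str, str]],
    proteins: dict[str, str],
    min_length: int = 30,
) -> list[FilteredFragment]:
    """Keep fragments matching their protein verbatim and longer than 30 aa.

    ``fragments`` holds ``(key, protein_id, peptide, class)`` tuples where
    class is ``enriched`` or ``depleted``.  The length filter is strict
    (a 31-aa peptide passes, a 30-aa one does not).  A peptide matching at
    several offsets is assigned the first occurrence and flagged.
    """
    kept: list[FilteredFragment] = []
    for key, protein_id, peptide, cls in fragments:
        if cls not in _CLASS_TO_LABEL:
            raise ValueError(f"fragment {key!r} has non-consolidatable class {cls!r}")
        if len(peptide) <= min_length:
            continue
        protein = proteins.get(protein_id)
        if protein is None:
            continue
        offset = protein.find(peptide)
        if offset < 0:
            continue
        multiple = protein.find(peptide, offset + 1) >= 0
        kept.append(
            FilteredFragment(
                key=key,
                protein_id=protein_id,
                peptide=peptide,
                offset=offset,
                label=_CLASS_TO_LABEL[cls],
                multiple_matches=multiple,
            )
        )
    return kept


def build_residue_track(
    fragments: list[FilteredFragment], protein_length: int, protein_id: str
) -> ResidueLabelTrack:
    """Consensus residue labels from the covering fragments of one protein."""
    sec = np.zeros(protein_length, dtype=np.int64)
    dep = np.zeros(protein_length, dtype=np.int64)
    for f in fragments:
        if f.protein_id != protein_id:
            continue
        lo, hi = f.offset, min(f.offset + len(f.peptide), protein_length)
        (sec if f.label == LABEL_SECRETED else dep)[lo:hi] += 1
    labels = np.full(protein_length, LABEL_UNCOVERED, dtype=object)
    labels[(sec > 0) & (dep == 0)] = LABEL_SECRETED
    labels[(dep > 0) & (sec == 0)] = LABEL_DEPLETED
    labels[(sec > 0) & (dep > 0)] = LABEL_AMBIGUOUS
    return ResidueLabelTrack(protein_id, labels, sec + dep)


def build_consolidated(
    track: ResidueLabelTrack,
    fragments: list[FilteredFragment] | None = None,
    profiles: dict[str, np.ndarray] | None = None,
) -> list[ConsolidatedFragment]:
    """Maximal same-label runs of unambiguous residues, with condensed profiles.

    ``profiles`` maps fragment key to that fragment's per-residue property
    track; the consolidated profile at each residue is the unweighted mean
    over the fragments covering it.
    """
    n = len(track.labels)
    mean_profile = None
    if profiles is not None and fragments is not None:
        acc = np.zeros(n)
        cnt = np.zeros(n)
        for f in fragments:
            if f.protein_id != track.protein_id or f.key not in profiles:
                continue
            prof = np.asarray(profiles[f.key], dtype=float)
            lo = f.offset
            hi = min(lo + len(prof), n)
            acc[lo:hi] += prof[: hi - lo]
            cnt[lo:hi] += 1
        with np.errstate(invalid="ignore"):
            mean_profile = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)

    out: list[ConsolidatedFragment] = []
    i = 0
    while i < n:
        label = track.labels[i]
        if label not in (LABEL_SECRETED, LABEL_DEPLETED):
            i += 1
            continue
        j = i
        while j < n and track.labels[j] == label:
            j += 1
        out.append(
            ConsolidatedFragment(
                protein_id=track.protein_id,
                start=i,
                end=j,
                label=label,
                profile=None if mean_profile is None else mean_profile[i:j].copy(),
            )
        )
        i = j
    return out


def cluster_representatives(
    peptides: dict[str, str]
) -> list[RepresentativeCluster]:
    """Greedy longest-first containment clustering at 100% identity.

    Sequences are visited longest first (ties broken by key for
    determinism); each joins the first existing representative containing it
    as an exact substring, otherwise it founds a new cluster.  Repeating the
    procedure on the representatives yields singletons (idempotence).
    """
    clusters: list[RepresentativeCluster] = []
    for key in sorted(peptides, key=lambda k: (-len(peptides[k]), k)):
        seq = peptides[key]
        for cl in clusters:
            if seq in cl.representative:
                cl.members.append(key)
                break
        else:
            clusters.append(RepresentativeCluster(representative=seq, members=[key]))
    return clusters
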