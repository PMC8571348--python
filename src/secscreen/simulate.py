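"""Fully synthetic surface-display secretability screen.

Emulates the data-generating process of a sorted-pool fragment screen so the
whole downstream pipeline is testable without any sequencing download:

* a transcriptome of random-codon CDSs whose relative abundances are
  log-uniform over a configurable dynamic range (human cell-line transcript
  abundances span roughly four orders of magnitude);
* random-primed fragments placed uniformly along each transcript, with the
  1/9 dual-frame probability arising naturally from uniform start positions
  and a smooth length distribution (both coordinates mod 3 are uniform);
* a planted, sequence-dependent secretability signal: a logistic model on
  peptide composition that favours negatively charged residues, prolines and
  backbone flexibility and disfavours hydrophobicity and helix propensity —
  the direction of the biophysical differences a real screen shows;
* three replicate sorted/unsorted count samples, multinomial per sample,
  with sorted-pool abundances biased by each fragment's display probability.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .biophys import AAScale, load_aux_scales, load_scales

__all__ = [
    "Transcript",
    "Fragment",
    "PlantedEffect",
    "SimulationConfig",
    "SyntheticScreen",
    "generate_transcriptome",
    "simulate_fragmentation",
    "plant_secretability",
    "simulate_screen_counts",
    "simulate_screen",
    "write_fixture",
    "read_fixture",
    "fragment_key",
]

# 61 sense codons of the standard code, fixed order
_BASES = "TCAG"
_ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [c for c in _ALL_CODONS if c not in _STOP_CODONS]


@dataclass(frozen=True)
class Transcript:
    """A synthetic mRNA: one CDS (optionally flanked by UTRs) plus a stop codon."""

    id: str
    sequence: str
    cds_start: int
    cds_end: int  # 0-based half-open, multiple of 3 long, stop-free
    abundance: float
    gene_id: str
    protein: str


@dataclass(frozen=True)
class Fragment:
    """A fragment species identified by (transcript, start, end), 0-based half-open."""

    transcript_id: str
    start: int
    end: int
    gene_id: str
    in_frame_n: bool
    in_frame_c: bool
    peptide: str | None  # defined only for dual-in-frame, stop-free fragments

    @property
    def key(self) -> str:
        return fragment_key(self.transcript_id, self.start, self.end)

    @property
    def dual_in_frame(self) -> bool:
        return self.in_frame_n and self.in_frame_c


def fragment_key(transcript_id: str, start: int, end: int) -> str:
    return f"{transcript_id}:{start}-{end}"


def parse_fragment_key(key: str) -> tuple[str, int, int]:
    tid, coords = key.rsplit(":", 1)
    start, end = coords.split("-")
    return tid, int(start), int(end)


@dataclass(frozen=True)
class PlantedEffect:
    """Logistic coefficients of the planted secretability signal.

    Features are peptide-composition z-scores (relative to the background
    amino-acid frequencies implied by uniform sense-codon usage), so the
    coefficients are in comparable units.  Positive weights on the fraction
    of D/E, the fraction of prolines and mean flexibility, and negative
    weights on mean hydrophobicity and helix propensity, plant the signal in
    the direction real screens show.
    """

    intercept: float = -6.0
    frac_de: float = 4.0
    frac_pro: float = 2.0
    hydrophobicity: float = -4.0
    helix: float = -2.0
    flexibility: float = 2.0

    @classmethod
    def null(cls) -> "PlantedEffect":
        """No signal: every in-frame fragment displays with probability 1/2."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic screen (defaults = default screen)."""

    seed: int
    n_genes: int = 400
    cds_len_mean: float = 1200.0   # nt
    cds_len_sd: float = 300.0
    cds_len_min: int = 300
    cds_len_max: int = 2400
    utr5_len: int = 0
    utr3_len: int = 0
    abundance_log10_range: float = 4.0
    fragments_per_transcript: int = 250
    frag_len_mean: float = 240.0   # nt -> 50-100 aa coding median
    frag_len_sd: float = 60.0
    frag_len_min: int = 90
    frag_len_max: int = 450
    n_replicates: int = 3
    depth_unsorted: int = 4_000_000
    depth_sorted: int = 4_000_000
    effect: PlantedEffect = field(default_factory=PlantedEffect)
    overdispersion: float | None = None  # Dirichlet concentration scale; None = pure multinomial

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "n_genes",
            "fragments_per_transcript",
            "n_replicates",
            "depth_unsorted",
            "depth_sorted",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.abundance_log10_range < 0:
            raise ValueError("abundance_log10_range must be >= 0")


@dataclass
class SyntheticScreen:
    """Bundle of everything one simulated screen produces."""

    config: SimulationConfig
    transcripts: list[Transcript]
    fragments: list[Fragment]
    truth: pd.DataFrame       # index fragment key; display_probability, secretable
    counts: pd.DataFrame      # index fragment key; rep{r}_{unsorted|sorted} columns


def _draw_truncated_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    """Rejection-sampled truncated-normal integer lengths (no boundary atoms)."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(rng.normal(mean, sd, size=2 * (n - filled))).astype(np.int64)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def generate_transcriptome(cfg: SimulationConfig) -> list[Transcript]:
    """Random-codon transcripts with log-uniform relative abundances."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    # log10-abundances uniform over the configured range, then renormalized
    log_abund = rng.uniform(0.0, cfg.abundance_log10_range, size=n)
    weights = 10.0 ** log_abund
    weights /= weights.sum()

    cds_lens = _draw_truncated_lengths(
        rng, n, cfg.cds_len_mean, cfg.cds_len_sd, cfg.cds_len_min, cfg.cds_len_max
    )
    cds_lens -= cds_lens % 3

    sense = np.array(SENSE_CODONS)
    stops = np.array(sorted(_STOP_CODONS))
    bases = np.array(list("ACGT"))
    transcripts = []
    for i in range(n):
        n_codons = cds_lens[i] // 3
        codons = sense[rng.integers(0, len(sense), size=n_codons)]
        cds = "".join(codons)
        stop = stops[rng.integers(0, 3)]
        utr5 = "".join(bases[rng.integers(0, 4, size=cfg.utr5_len)])
        utr3 = "".join(bases[rng.integers(0, 4, size=cfg.utr3_len)])
        seq = utr5 + cds + stop + utr3
        cds_start = len(utr5)
        cds_end = cds_start + len(cds)
        protein = str(Seq(cds).translate())
        transcripts.append(
            Transcript(
                id=f"T{i:05d}",
                sequence=seq,
                cds_start=cds_start,
                cds_end=cds_end,
                abundance=float(weights[i]),
                gene_id=f"G{i:05d}",
                protein=protein,
            )
        )
    return transcripts


def _frame_flags(
    start: int, end: int, cds_start: int, cds_end: int
) -> tuple[bool, bool]:
    in_n = cds_start <= start < cds_end and (start - cds_start) % 3 == 0
    in_c = (end - start) % 3 == 0
    return in_n, in_c


def simulate_fragmentation(
    transcripts: list[Transcript], cfg: SimulationConfig
) -> tuple[list[Fragment], pd.DataFrame]:
    """Place random-primed fragments and return species plus a truth skeleton.

    Starts are uniform along the transcript; lengths follow the configured
    truncated-normal distribution; a fragment that would extend past the
    transcript end is truncated to it.  Fragment species (identical
    coordinates) are deduplicated.  Peptides are translated for fragments in
    frame with both fusion partners whose frame contains no stop codon.
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    seen: dict[str, Fragment] = {}
    for tr in transcripts:
        tlen = len(tr.sequence)
        lens = _draw_truncated_lengths(
            rng,
            cfg.fragments_per_transcript,
            cfg.frag_len_mean,
            cfg.frag_len_sd,
            cfg.frag_len_min,
            cfg.frag_len_max,
        )
        lens = np.minimum(lens, tlen)
        # both fragmentation breakpoints lie on the transcript: the start is
        # uniform over the placements where the fragment fits
        starts = rng.integers(0, tlen - lens + 1)
        ends = np.minimum(starts + lens, tlen)
        for start, end in zip(starts.tolist(), ends.tolist()):
            key = fragment_key(tr.id, start, end)
            if key in seen:
                continue
            in_n, in_c = _frame_flags(start, end, tr.cds_start, tr.cds_end)
            peptide = None
            if in_n and in_c and end <= tr.cds_end:
                a0 = (start - tr.cds_start) // 3
                peptide = tr.protein[a0 : a0 + (end - start) // 3]
                if "*" in peptide:  # cannot happen for an internal CDS window
                    peptide = None
            seen[key] = Fragment(
                transcript_id=tr.id,
                start=start,
                end=end,
                gene_id=tr.gene_id,
                in_frame_n=in_n,
                in_frame_c=in_c,
                peptide=peptide,
            )
    fragments = list(seen.values())
    truth = pd.DataFrame(
        {
            "display_probability": np.nan,
            "secretable": False,
        },
        index=pd.Index([f.key for f in fragments], name="fragment_key"),
    )
    return fragments, truth


# -- planted signal ---------------------------------------------------------

def _codon_background_frequencies() -> dict[str, float]:
    """Amino-acid frequencies implied by uniform usage of the 61 sense codons."""
    counts: dict[str, int] = {}
    for codon in SENSE_CODONS:
        aa = str(Seq(codon).translate())
        counts[aa] = counts.get(aa, 0) + 1
    return {aa: c / len(SENSE_CODONS) for aa, c in counts.items()}


def _scale_background(scale: AAScale) -> tuple[float, float]:
    """Mean and per-residue SD of a scale under the codon background."""
    freqs = _codon_background_frequencies()
    mu = sum(freqs[aa] * scale.values[aa] for aa in freqs)
    var = sum(freqs[aa] * (scale.values[aa] - mu) ** 2 for aa in freqs)
    return mu, float(np.sqrt(var))


def peptide_signal_features(
    peptides: list[str],
    hydrophobicity: AAScale,
    helix: AAScale,
    flexibility: AAScale,
) -> np.ndarray:
    """Z-scored composition features (n_peptides x 5) for the planted signal.

    Columns: D/E fraction, proline fraction, mean hydrophobicity, mean helix
    propensity, mean flexibility; each standardized by its codon-background
    mean and standard error at the peptide's length.
    """
    freqs = _codon_background_frequencies()
    p_de = freqs["D"] + freqs["E"]
    p_pro = freqs["P"]
    backgrounds = [_scale_background(s) for s in (hydrophobicity, helix, flexibility)]
    out = np.empty((len(peptides), 5))
    for i, pep in enumerate(peptides):
        n = len(pep)
        root_n = np.sqrt(n)
        f_de = sum(1 for aa in pep if aa in "DE") / n
        f_p = pep.count("P") / n
        out[i, 0] = (f_de - p_de) / (np.sqrt(p_de * (1 - p_de)) / root_n)
        out[i, 1] = (f_p - p_pro) / (np.sqrt(p_pro * (1 - p_pro)) / root_n)
        for j, scale in enumerate((hydrophobicity, helix, flexibility)):
            mu, sd = backgrounds[j]
            mean_val = float(np.mean([scale.values.get(aa, scale.mean) for aa in pep]))
            out[i, 2 + j] = (mean_val - mu) / (sd / root_n)
    return out


def plant_secretability(
    fragments: list[Fragment], cfg: SimulationConfig
) -> pd.DataFrame:
    """Assign each fragment a display probability from the planted logistic model.

    Out-of-frame fragments (and in-frame fragments whose reading frame hits a
    stop codon, which lose the C-terminal tag) get probability 0.
    """
    eff = cfg.effect
    keys = [f.key for f in fragments]
    probs = np.zeros(len(fragments))
    idx = [i for i, f in enumerate(fragments) if f.peptide]
    if idx:
        scales = load_scales()
        aux = load_aux_scales()
        feats = peptide_signal_features(
            [fragments[i].peptide for i in idx],
            scales["hydrophobicity"],
            aux["helix_propensity"],
            aux["flexibility"],
        )
        beta = np.array(
            [eff.frac_de, eff.frac_pro, eff.hydrophobicity, eff.helix, eff.flexibility]
        )
        logit = eff.intercept + feats @ beta
        probs[idx] = 1.0 / (1.0 + np.exp(-logit))
    truth = pd.DataFrame(
        {"display_probability": probs},
        index=pd.Index(keys, name="fragment_key"),
    )
    truth["secretable"] = truth["display_probability"] >= 0.5
    return truth


def simulate_screen_counts(
    fragments: list[Fragment],
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    transcripts: list[Transcript] | None = None,
    abundances: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Three-replicate sorted/unsorted multinomial count table.

    Unsorted sample weights are proportional to transcript abundance; sorted
    weights additionally multiply in each fragment's display probability.
    With ``cfg.overdispersion`` set, per-replicate proportions are drawn from
    a Dirichlet around the expected proportions before the multinomial draw.
    """
    if abundances is None:
        if transcripts is None:
            raise ValueError("provide either transcripts or abundances")
        abundances = {t.id: t.abundance for t in transcripts}
    keys = [f.key for f in fragments]
    missing = set(keys) - set(truth.index)
    if missing:
        raise ValueError(f"truth table missing {len(missing)} fragments")
    w = np.array([abundances[f.transcript_id] for f in fragments], dtype=float)
    disp = truth.loc[keys, "display_probability"].to_numpy(dtype=float)
    w_sorted = w * disp
    if w_sorted.sum() <= 0:
        raise ValueError("sorted pool has zero total weight (nothing displays)")
    p_unsorted = w / w.sum()
    p_sorted = w_sorted / w_sorted.sum()

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    data = {}
    for r in range(1, cfg.n_replicates + 1):
        for pool, p, depth in (
            ("unsorted", p_unsorted, cfg.depth_unsorted),
            ("sorted", p_sorted, cfg.depth_sorted),
        ):
            prep = p
            if cfg.overdispersion is not None:
                conc = np.where(p > 0, p * cfg.overdispersion, 0.0)
                prep = np.zeros_like(p)
                pos = conc > 0
                prep[pos] = rng.dirichlet(conc[pos])
            data[f"rep{r}_{pool}"] = rng.multinomial(depth, prep)
    counts = pd.DataFrame(data, index=pd.Index(keys, name="fragment_key"))
    return counts


def simulate_screen(cfg: SimulationConfig) -> SyntheticScreen:
    """End-to-end simulation: transcriptome -> fragments -> truth -> counts."""
    transcripts = generate_transcriptome(cfg)
    fragments, _ = simulate_fragmentation(transcripts, cfg)
    truth = plant_secretability(fragments, cfg)
    counts = simulate_screen_counts(fragments, truth, cfg, transcripts=transcripts)
    return SyntheticScreen(cfg, transcripts, fragments, truth, counts)


# -- fixture I/O ------------------------------------------------------------

def write_fixture(screen: SyntheticScreen, outdir: str | Path) -> dict[str, Path]:
    """Write the screen as plain-text files that round-trip via :func:`read_fixture`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptides": outdir / "peptides.fasta",
        "fragments": outdir / "fragments.tsv",
        "counts": outdir / "counts.tsv",
        "truth": outdir / "truth.tsv",
        "transcripts": outdir / "transcripts.tsv",
        "config": outdir / "config.json",
    }
    records = [
        SeqRecord(Seq(f.peptide), id=f.key, description=f.gene_id)
        for f in screen.fragments
        if f.peptide
    ]
    SeqIO.write(records, paths["peptides"], "fasta")

    frag_df = pd.DataFrame(
        {
            "fragment_key": [f.key for f in screen.fragments],
            "transcript_id": [f.transcript_id for f in screen.fragments],
            "gene_id": [f.gene_id for f in screen.fragments],
            "start": [f.start for f in screen.fragments],
            "end": [f.end for f in screen.fragments],
            "in_frame_n": [int(f.in_frame_n) for f in screen.fragments],
            "in_frame_c": [int(f.in_frame_c) for f in screen.fragments],
            "peptide": [f.peptide or "" for f in screen.fragments],
        }
    )
    frag_df.to_csv(paths["fragments"], sep="\t", index=False)
    screen.counts.to_csv(paths["counts"], sep="\t")
    screen.truth.to_csv(paths["truth"], sep="\t", float_format="%.17g")
    tr_df = pd.DataFrame(
        {
            "id": [t.id for t in screen.transcripts],
            "gene_id": [t.gene_id for t in screen.transcripts],
            "cds_start": [t.cds_start for t in screen.transcripts],
            "cds_end": [t.cds_end for t in screen.transcripts],
            "abundance": [t.abundance for t in screen.transcripts],
            "sequence": [t.sequence for t in screen.transcripts],
            "protein": [t.protein for t in screen.transcripts],
        }
    )
    tr_df.to_csv(paths["transcripts"], sep="\t", index=False, float_format="%.17g")
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(screen.config), fh, indent=2)
    return paths


def read_fixture(outdir: str | Path) -> SyntheticScreen:
    """Read a fixture written by :func:`write_fixture`."""
    outdir = Path(outdir)
    with open(outdir / "config.json") as fh:
        raw = json.load(fh)
    raw["effect"] = PlantedEffect(**raw["effect"])
    cfg = SimulationConfig(**raw)
    tr_df = pd.read_csv(
        outdir / "transcripts.tsv", sep="\t", float_precision="round_trip"
    )
    transcripts = [
        Transcript(
            id=row.id,
            sequence=row.sequence,
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            abundance=float(row.abundance),
            gene_id=row.gene_id,
            protein=row.protein,
        )
        for row in tr_df.itertuples()
    ]
    frag_df = pd.read_csv(
        outdir / "fragments.tsv", sep="\t", keep_default_na=False
    )
    fragments = [
        Fragment(
            transcript_id=row.transcript_id,
            start=int(row.start),
            end=int(row.end),
            gene_id=row.gene_id,
            in_frame_n=bool(row.in_frame_n),
            in_frame_c=bool(row.in_frame_c),
            peptide=row.peptide or None,
        )
        for row in frag_df.itertuples()
    ]
    truth = pd.read_csv(
        outdir / "truth.tsv", sep="\t", index_col="fragment_key",
        float_precision="round_trip",
    )
    counts = pd.read_csv(outdir / "counts.tsv", sep="\t", index_col="fragment_key")
    return SyntheticScreen(cfg, transcripts, fragments, truth, counts)
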