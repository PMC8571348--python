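"""End-to-end orchestration: simulate -> enrich -> consolidate -> features ->
classifiers -> attribution -> report.

Every stage reads and writes plain-text files under one run directory, keeps
an explicit seed, and records a manifest of SHA-256 hashes of its inputs and
outputs, so a rerun with the same configuration reproduces the run
bit-for-bit and any divergence is attributable to a specific stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biophys, consolidate as cons, enrichment as enr
from .features import (
    MIN_PEPTIDE_LENGTH,
    SecretabilityDataset,
    auroc,
    build_dataset,
    make_folds,
)
from .gb import GBTrainConfig, fit_full, predict_scales, run_gb_cv
from .nn import (
    CNNConfig,
    aggregate_attributions,
    attribute_many,
    ensemble_average,
    normalize_contributions,
    train_cnn,
)
from .nn.model import train_single
from .simulate import (
    PlantedEffect,
    SimulationConfig,
    simulate_screen,
    write_fixture,
)

logger = logging.getLogger("secscreen")

STAGES = (
    "simulate",
    "enrich",
    "consolidate",
    "features",
    "gb",
    "cnn",
    "attribute",
    "report",
)

__all__ = ["RunConfig", "run_pipeline", "make_report", "STAGES"]


@dataclass
class RunConfig:
    """Serializable configuration of one full pipeline run."""

    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    simulation: SimulationConfig | None = None
    upper_threshold: float = 1.0
    lower_threshold: float = -1.0
    min_peptide_length: int = MIN_PEPTIDE_LENGTH
    consolidation_min_length: int = 30
    consolidation_profile_scale: str = "hydrophobicity"
    coverage_min_reads: int = 3
    n_folds: int = 10
    gb: GBTrainConfig | None = None
    cnn: CNNConfig | None = None
    eval_independent_sets: bool = True
    n_attribution_sequences: int = 40

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        if self.gb is None:
            self.gb = GBTrainConfig(seed=self.seed)
        if self.cnn is None:
            self.cnn = CNNConfig(seed=self.seed)

    # -- JSON round trip -----------------------------------------------------

    def to_json(self) -> str:
        raw = dataclasses.asdict(self)
        return json.dumps(raw, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        if raw.get("simulation") is not None:
            sim = dict(raw["simulation"])
            sim["effect"] = PlantedEffect(**sim["effect"])
            raw["simulation"] = SimulationConfig(**sim)
        if raw.get("gb") is not None:
            raw["gb"] = GBTrainConfig(**raw["gb"])
        if raw.get("cnn") is not None:
            cnn = dict(raw["cnn"])
            for key in ("n_filters", "kernel_sizes"):
                if key in cnn:
                    cnn[key] = tuple(cnn[key])
            raw["cnn"] = CNNConfig(**cnn)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(
    stage_dir: Path, inputs: list[Path], outputs: list[Path], seed: int
) -> None:
    manifest = {
        "seed": seed,
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
    }
    (stage_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )


def _classifier_cfg(cfg: RunConfig) -> enr.ClassifierConfig:
    return enr.ClassifierConfig(upper=cfg.upper_threshold, lower=cfg.lower_threshold)


# -- stages ------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, run_dir: Path) -> None:
    out = run_dir / "simulate"
    logger.info("simulate: seed=%s", cfg.simulation.seed)
    screen = simulate_screen(cfg.simulation)
    paths = write_fixture(screen, out)
    _write_manifest(out, [], list(paths.values()), cfg.simulation.seed)


def _load_fixture_frames(run_dir: Path):
    sim = run_dir / "simulate"
    frags = pd.read_csv(sim / "fragments.tsv", sep="\t", keep_default_na=False)
    counts = pd.read_csv(sim / "counts.tsv", sep="\t", index_col="fragment_key")
    transcripts = pd.read_csv(sim / "transcripts.tsv", sep="\t")
    return frags, counts, transcripts


def stage_enrich(cfg: RunConfig, run_dir: Path) -> None:
    out = run_dir / "enrich"
    out.mkdir(parents=True, exist_ok=True)
    frags, counts, transcripts = _load_fixture_frames(run_dir)
    in_frame = pd.Series(
        (frags["in_frame_n"].astype(bool) & frags["in_frame_c"].astype(bool)).values,
        index=frags["fragment_key"].values,
    )
    records = enr.enrich(counts, in_frame=in_frame, cfg=_classifier_cfg(cfg))
    records.to_csv(out / "enrichment.tsv", sep="\t")

    classified = records[records["in_frame"] & (records["class"] != enr.CLASS_UNDETECTED)]
    fractions = (
        classified["class"].value_counts(normalize=True) * 100
    ).to_dict()
    unsorted_cols = [c for c in counts.columns if c.endswith("_unsorted")]
    cov_df = frags[["fragment_key", "transcript_id", "start", "end"]].copy()
    cov_df["count"] = counts[unsorted_cols].sum(axis=1).reindex(
        frags["fragment_key"]
    ).to_numpy()
    tlens = dict(
        zip(transcripts["id"], transcripts["sequence"].str.len())
    )
    summary = {
        "n_fragments": int(len(records)),
        "n_commonly_detected_in_frame": int(len(classified)),
        "class_fractions_pct": {k: float(v) for k, v in sorted(fractions.items())},
        "concordance_pct": enr.concordance(records),
        "coverage_pct": enr.coverage_fraction(
            cov_df, tlens, min_reads=cfg.coverage_min_reads
        ),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    sim = run_dir / "simulate"
    _write_manifest(
        out,
        [sim / "counts.tsv", sim / "fragments.tsv"],
        [out / "enrichment.tsv", out / "summary.json"],
        cfg.seed,
    )


def _load_records(run_dir: Path) -> pd.DataFrame:
    return pd.read_csv(
        run_dir / "enrich" / "enrichment.tsv", sep="\t", index_col="fragment_key"
    )


def _peptide_maps(frags: pd.DataFrame) -> tuple[dict[str, str], dict[str, str]]:
    peptides = {
        row.fragment_key: row.peptide
        for row in frags.itertuples()
        if row.peptide
    }
    genes = dict(zip(frags["fragment_key"], frags["gene_id"]))
    return peptides, genes


def stage_consolidate(cfg: RunConfig, run_dir: Path) -> None:
    out = run_dir / "consolidate"
    out.mkdir(parents=True, exist_ok=True)
    frags, _, transcripts = _load_fixture_frames(run_dir)
    records = _load_records(run_dir)
    peptides, genes = _peptide_maps(frags)
    proteins = dict(zip(transcripts["gene_id"], transcripts["protein"]))

    classed = records.loc[records["class"].isin(["enriched", "depleted"]), "class"]
    inputs = [
        (key, genes[key], peptides[key], cls)
        for key, cls in classed.items()
        if key in peptides
    ]
    filtered = cons.filter_for_consolidation(
        inputs, proteins, min_length=cfg.consolidation_min_length
    )
    scale = biophys.load_scales()[cfg.consolidation_profile_scale]
    profiles = {
        f.key: biophys.property_profile(f.peptide, scale) for f in filtered
    }
    rows = []
    by_protein: dict[str, list[cons.FilteredFragment]] = {}
    for f in filtered:
        by_protein.setdefault(f.protein_id, []).append(f)
    for pid, frs in sorted(by_protein.items()):
        track = cons.build_residue_track(frs, len(proteins[pid]), pid)
        for cf in cons.build_consolidated(track, frs, profiles):
            rows.append(
                {
                    "protein_id": cf.protein_id,
                    "start": cf.start,
                    "end": cf.end,
                    "label": cf.label,
                    "mean_profile": float(np.nanmean(cf.profile)),
                }
            )
    pd.DataFrame(
        rows, columns=["protein_id", "start", "end", "label", "mean_profile"]
    ).to_csv(out / "consolidated.tsv", sep="\t", index=False)

    clusters = cons.cluster_representatives(
        {f.key: f.peptide for f in filtered}
    )
    cl_rows = [
        {
            "cluster": i,
            "representative": cl.representative,
            "n_members": len(cl.members),
            "members": ",".join(cl.members),
        }
        for i, cl in enumerate(clusters)
    ]
    pd.DataFrame(
        cl_rows, columns=["cluster", "representative", "n_members", "members"]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    _write_manifest(
        out,
        [run_dir / "enrich" / "enrichment.tsv"],
        [out / "consolidated.tsv", out / "clusters.tsv"],
        cfg.seed,
    )


def stage_features(cfg: RunConfig, run_dir: Path) -> None:
    """Composition statistics per class plus Mann-Whitney/BH comparisons."""
    out = run_dir / "features"
    out.mkdir(parents=True, exist_ok=True)
    frags, _, _ = _load_fixture_frames(run_dir)
    records = _load_records(run_dir)
    peptides, _ = _peptide_maps(frags)
    hydro = biophys.load_scales()["hydrophobicity"]

    stats_rows = []
    for key, cls in records["class"].items():
        if cls not in ("enriched", "depleted") or key not in peptides:
            continue
        st = biophys.composition_stats(peptides[key], hydro)
        stats_rows.append(
            {
                "fragment_key": key,
                "class": cls,
                "length": st.length,
                "frac_de": st.frac_de,
                "frac_pro": st.frac_pro,
                "mean_hydrophobicity": st.mean_hydrophobicity,
                "cys_count": st.cys_count,
                "sequon_count": st.sequon_count,
            }
        )
    stats = pd.DataFrame(stats_rows)
    stats.to_csv(out / "class_stats.tsv", sep="\t", index=False)

    tests = []
    if not stats.empty:
        enriched = stats[stats["class"] == "enriched"]
        depleted = stats[stats["class"] == "depleted"]
        if len(enriched) and len(depleted):
            for col in (
                "length",
                "frac_de",
                "frac_pro",
                "mean_hydrophobicity",
                "cys_count",
                "sequon_count",
            ):
                u, p = biophys.compare_classes(enriched[col], depleted[col])
                tests.append(
                    {
                        "feature": col,
                        "median_enriched": float(enriched[col].median()),
                        "median_depleted": float(depleted[col].median()),
                        "U": u,
                        "p": p,
                    }
                )
    test_df = pd.DataFrame(
        tests, columns=["feature", "median_enriched", "median_depleted", "U", "p"]
    )
    if len(test_df):
        test_df["p_adj"] = biophys.adjust_bh(test_df["p"].to_numpy())
    test_df.to_csv(out / "feature_tests.tsv", sep="\t", index=False)
    _write_manifest(
        out,
        [run_dir / "enrich" / "enrichment.tsv"],
        [out / "class_stats.tsv", out / "feature_tests.tsv"],
        cfg.seed,
    )


def _dataset_from_run(cfg: RunConfig, run_dir: Path) -> SecretabilityDataset:
    frags, _, _ = _load_fixture_frames(run_dir)
    records = _load_records(run_dir)
    peptides, genes = _peptide_maps(frags)
    return build_dataset(
        records, peptides, genes, min_length=cfg.min_peptide_length
    )


def _independent_sets(cfg: RunConfig, run_dir: Path) -> pd.DataFrame:
    records = _load_records(run_dir)
    return enr.stratify_independent_sets(records, _classifier_cfg(cfg))


def stage_gb(cfg: RunConfig, run_dir: Path) -> None:
    out = run_dir / "gb"
    out.mkdir(parents=True, exist_ok=True)
    dataset = _dataset_from_run(cfg, run_dir)
    folds = make_folds(dataset, k=cfg.n_folds, seed=cfg.seed)
    scale_res, ens, score = run_gb_cv(dataset, folds, cfg=cfg.gb)
    oof = scale_res.oof.copy()
    oof["ensemble_prob"] = ens.prob
    oof["label"] = dataset.labels
    oof["fold"] = folds.record_fold
    oof.to_csv(out / "oof.tsv", sep="\t")

    metrics = {
        "auroc_cv": score,
        "n_records": len(dataset),
        "n_positive": dataset.n_positive,
        "per_scale_auroc": {
            name: auroc(dataset.labels, scale_res.oof[name].to_numpy())
            for name in scale_res.oof.columns
        },
    }
    if cfg.eval_independent_sets:
        frags, _, _ = _load_fixture_frames(run_dir)
        peptides, _ = _peptide_maps(frags)
        fit_full(dataset, scale_res, ens, cfg=cfg.gb)
        sets = _independent_sets(cfg, run_dir)
        for set_name in ("A", "B"):
            sub = sets[sets["independent_set"] == set_name]
            keys = [
                k
                for k in sub.index
                if k in peptides and len(peptides[k]) >= cfg.min_peptide_length
            ]
            labels = sub.loc[keys, "label"].to_numpy()
            if len(set(labels.tolist())) < 2:
                metrics[f"auroc_set_{set_name}"] = None
                continue
            probs = predict_scales(scale_res, ens, [peptides[k] for k in keys])
            metrics[f"auroc_set_{set_name}"] = auroc(labels, probs)
            pd.DataFrame(
                {"fragment_key": keys, "label": labels, "prob": probs}
            ).to_csv(out / f"set_{set_name}.tsv", sep="\t", index=False)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    _write_manifest(
        out,
        [run_dir / "enrich" / "enrichment.tsv"],
        [out / "oof.tsv", out / "metrics.json"],
        cfg.seed,
    )


def stage_cnn(cfg: RunConfig, run_dir: Path) -> None:
    out = run_dir / "cnn"
    out.mkdir(parents=True, exist_ok=True)
    dataset = _dataset_from_run(cfg, run_dir)
    folds = make_folds(dataset, k=cfg.n_folds, seed=cfg.seed)
    models, oof = train_cnn(dataset, folds, cfg.cnn)
    frame = oof.to_frame()
    frame["label"] = dataset.labels
    frame["fold"] = folds.record_fold

    metrics = {
        "auroc_cv": auroc(dataset.labels, oof.to_numpy()),
        "n_records": len(dataset),
    }
    gb_oof_path = run_dir / "gb" / "oof.tsv"
    if gb_oof_path.exists():
        gb_oof = pd.read_csv(gb_oof_path, sep="\t", index_col="fragment_key")
        joint = ensemble_average(
            gb_oof["ensemble_prob"].reindex(oof.index), oof
        )
        frame["gb_cnn_average"] = joint
        metrics["auroc_gb_cnn_average"] = auroc(dataset.labels, joint.to_numpy())
    frame.to_csv(out / "oof.tsv", sep="\t")

    if cfg.eval_independent_sets:
        frags, _, _ = _load_fixture_frames(run_dir)
        peptides, _ = _peptide_maps(frags)
        full_model = train_single(dataset.peptides, dataset.labels, cfg.cnn)
        sets = _independent_sets(cfg, run_dir)
        for set_name in ("A", "B"):
            sub = sets[sets["independent_set"] == set_name]
            keys = [
                k
                for k in sub.index
                if k in peptides and len(peptides[k]) >= cfg.min_peptide_length
            ]
            labels = sub.loc[keys, "label"].to_numpy()
            if len(set(labels.tolist())) < 2:
                metrics[f"auroc_set_{set_name}"] = None
                continue
            probs = full_model.predict_proba([peptides[k] for k in keys])
            metrics[f"auroc_set_{set_name}"] = auroc(labels, probs)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    _write_manifest(
        out,
        [run_dir / "enrich" / "enrichment.tsv"],
        [out / "oof.tsv", out / "metrics.json"],
        cfg.seed,
    )


def stage_attribute(cfg: RunConfig, run_dir: Path) -> None:
    out = run_dir / "attribution"
    out.mkdir(parents=True, exist_ok=True)
    dataset = _dataset_from_run(cfg, run_dir)
    folds = make_folds(dataset, k=cfg.n_folds, seed=cfg.seed)
    # one fold model is enough for aggregate attribution patterns; attribute
    # its own held-out (test-fold) sequences
    fold = 0
    te = folds.test_indices(fold)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    pick = rng.choice(
        te, size=min(cfg.n_attribution_sequences, te.size), replace=False
    )
    from dataclasses import replace as dc_replace

    model = train_single(
        [dataset.peptides[i] for i in folds.train_indices(fold)],
        dataset.labels[folds.train_indices(fold)],
        dc_replace(cfg.cnn, seed=cfg.cnn.seed * 1000 + fold),
    )
    maps = attribute_many(
        model, {dataset.keys[i]: dataset.peptides[i] for i in sorted(pick)}
    )
    maps = normalize_contributions(maps)

    rows = []
    for mp in maps:
        for i, (aa, c) in enumerate(zip(mp.peptide, mp.contributions)):
            rows.append((mp.key, i, aa, c))
    pd.DataFrame(
        rows, columns=["fragment_key", "position", "residue", "contribution"]
    ).to_csv(out / "maps.tsv", sep="\t", index=False)
    aggregate_attributions(maps, "per_aa").to_csv(out / "per_aa.tsv", sep="\t")
    aggregate_attributions(maps, "per_region20").to_csv(
        out / "per_region20.tsv", sep="\t"
    )
    residuals = {
        "max_completeness_residual": max(
            mp.completeness_residual for mp in maps
        ),
        "n_sequences": len(maps),
    }
    (out / "metrics.json").write_text(json.dumps(residuals, indent=2, sort_keys=True))
    _write_manifest(
        out,
        [run_dir / "enrich" / "enrichment.tsv"],
        [out / "maps.tsv", out / "per_aa.tsv", out / "per_region20.tsv"],
        cfg.seed,
    )


def make_report(run_dir: Path) -> dict:
    """Aggregate stage outputs into report/summary.json and an AUROC table."""
    run_dir = Path(run_dir)
    out = run_dir / "report"
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    enrich_summary = run_dir / "enrich" / "summary.json"
    if enrich_summary.exists():
        summary["enrichment"] = json.loads(enrich_summary.read_text())
    tests = run_dir / "features" / "feature_tests.tsv"
    if tests.exists():
        summary["feature_tests"] = pd.read_csv(tests, sep="\t").to_dict("records")
    auroc_rows = []
    for stage, model_name in (("gb", "gradient_boosting"), ("cnn", "cnn")):
        metrics_path = run_dir / stage / "metrics.json"
        if metrics_path.exists():
            metrics = json.loads(metrics_path.read_text())
            summary[stage] = metrics
            auroc_rows.append(
                {
                    "model": model_name,
                    "auroc_cv": metrics.get("auroc_cv"),
                    "auroc_set_A": metrics.get("auroc_set_A"),
                    "auroc_set_B": metrics.get("auroc_set_B"),
                }
            )
    if "cnn" in summary and "auroc_gb_cnn_average" in summary["cnn"]:
        auroc_rows.append(
            {
                "model": "gb_cnn_average",
                "auroc_cv": summary["cnn"]["auroc_gb_cnn_average"],
                "auroc_set_A": None,
                "auroc_set_B": None,
            }
        )
    attribution_metrics = run_dir / "attribution" / "metrics.json"
    if attribution_metrics.exists():
        summary["attribution"] = json.loads(attribution_metrics.read_text())
        per_aa = run_dir / "attribution" / "per_aa.tsv"
        if per_aa.exists():
            summary["attribution"]["per_aa"] = (
                pd.read_csv(per_aa, sep="\t").to_dict("records")
            )
    pd.DataFrame(
        auroc_rows, columns=["model", "auroc_cv", "auroc_set_A", "auroc_set_B"]
    ).to_csv(out / "auroc_table.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    # global manifest over every file of the run
    manifest = {}
    for path in sorted(run_dir.rglob("*")):
        if path.is_file() and path.name != "run_manifest.json":
            manifest[str(path.relative_to(run_dir))] = _sha256(path)
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return summary


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "enrich": stage_enrich,
    "consolidate": stage_consolidate,
    "features": stage_features,
    "gb": stage_gb,
    "cnn": stage_cnn,
    "attribute": stage_attribute,
}


def run_pipeline(cfg: RunConfig, run_dir: str | Path) -> Path:
    """Execute the enabled stages in order; abort with the stage name on error."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(cfg.to_json())
    for stage in STAGES:
        if not cfg.stages.get(stage, True):
            logger.info("stage %s: skipped", stage)
            continue
        logger.info("stage %s: start", stage)
        try:
            if stage == "report":
                make_report(run_dir)
            else:
                _STAGE_FUNCS[stage](cfg, run_dir)
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s: done", stage)
    return run_dir
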