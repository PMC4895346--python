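"""End-to-end orchestration of the occupancy-prediction workflows.

Two workflows mirror the two kinds of binding-site lists: ``predicted``
(PWM genome scan, then tag-support filtering) and ``peaks`` (externally
called peak lists reduced to centers, annotated with the best PWM match
near each center).  Both continue identically: feature annotation
(tag-count coverage, footprint shape probability, sequence-intrinsic
features, numeric-track averages), normalization, optional strong/weak
labeling, model training and feature importance.  A JSON manifest records
seeds, input checksums and stage order so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from . import models as tmodels
from .footprint import extract_profiles, partition_profiles
from .pwm import (best_match_in_window, filter_sites_by_tag_support,
                  log_odds_from_probabilities, scan_sequence,
                  score_threshold_from_pvalue)
from .seqfeat import annotate_sequence_features
from .tracks import (average_track, count_tags, estimate_fragment_shift,
                     snp_density_track)

#: window presets (bases) per data type, matching the study design
WINDOW_TF = 100
WINDOW_DNASE = 250
WINDOW_HISTONE = 500
WINDOW_CONSERVATION = 50
WINDOW_SNP = 10
WINDOW_NUCLEOSOME = 10


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class TrackSpec:
    """One input track: path, label, counting window, shift policy."""

    path: str
    name: str
    halfwidth: int = WINDOW_TF
    shift: object = 0            # int, or "auto" for cross-correlation

    @classmethod
    def parse(cls, text: str) -> "TrackSpec":
        """Parse ``path:name:halfwidth[:shift|auto]`` CLI syntax."""
        parts = text.split(":")
        if len(parts) < 2:
            raise ValueError("track spec needs at least path:name")
        path, name = parts[0], parts[1]
        halfwidth = int(parts[2]) if len(parts) > 2 else WINDOW_TF
        shift = parts[3] if len(parts) > 3 else 0
        if shift != "auto":
            shift = int(shift)
        return cls(path, name, halfwidth, shift)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    workflow: str                       # predicted | peaks
    fasta: str
    outdir: str
    pfm: str | None = None
    sites: str | None = None            # BED/peak file (peaks workflow)
    peak_dialect: str = "narrowPeak"
    pvalue: float = 1e-4
    chip: TrackSpec | None = None       # target ChIP track
    extra_tags: list = field(default_factory=list)
    dnase: TrackSpec | None = None
    numeric_tracks: list = field(default_factory=list)
    snps: str | None = None
    include_footprint: bool = True
    include_seq_features: bool = True
    include_kmers: bool = False
    task: str = "regress"               # regress | classify
    method: str = "svm-radial"
    fraction: float = 0.2
    min_tag_count: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("chip", "dnase"):
            if isinstance(raw.get(key), dict):
                raw[key] = TrackSpec(**raw[key])
        for key in ("extra_tags", "numeric_tracks"):
            raw[key] = [TrackSpec(**t) if isinstance(t, dict) else t
                        for t in raw.get(key, [])]
        return cls(**raw)

    def validate(self):
        if self.workflow not in ("predicted", "peaks"):
            raise ValueError(f"unknown workflow {self.workflow!r}")
        if self.workflow == "predicted" and self.pfm is None:
            raise ValueError("predicted workflow requires a PFM")
        if self.workflow == "peaks" and self.sites is None:
            raise ValueError("peaks workflow requires a peak file")
        if self.chip is None:
            raise ValueError("a target ChIP track is required")


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _resolve_shift(track, spec: TrackSpec) -> int:
    if spec.shift == "auto":
        return estimate_fragment_shift(track)
    return int(spec.shift)


def run_pipeline(config: RunConfig):
    """Execute a configured run; returns (FeatureTable, ModelReport, manifest).

    Stages run in a fixed order; any failure aborts with a stage-tagged
    :class:`PipelineError` and leaves partial outputs under a ``failed/``
    marker in the output directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seed = {s: int(rng.integers(0, 2 ** 31))
                  for s in ("scan", "footprint", "model", "importance")}
    manifest = {"workflow": config.workflow, "seed": config.seed,
                "stage_seeds": stage_seed, "stages": [], "inputs": {}}
    for label, path in [("fasta", config.fasta), ("pfm", config.pfm),
                        ("sites", config.sites), ("snps", config.snps)]:
        if path:
            manifest["inputs"][label] = {"path": str(path),
                                         "sha256": _checksum(path)}

    stage = "acquire-sites"
    try:
        genome = tio.read_fasta(config.fasta)
        pwm = None
        if config.pfm:
            pwm = log_odds_from_probabilities(tio.read_jaspar_pfm(config.pfm))
        if config.workflow == "predicted":
            threshold = score_threshold_from_pvalue(pwm, config.pvalue)
            parts = [scan_sequence(seq, pwm, threshold, chrom=chrom,
                                   id_prefix=f"{pwm.name}_{chrom}")
                     for chrom, seq in genome.items()]
            import pandas as pd
            frame = pd.concat([p.frame for p in parts], ignore_index=True)
            sites = tio.SiteList(frame)
            manifest["pwm_threshold"] = threshold
        else:
            sites = tio.read_peaks(config.sites, dialect=config.peak_dialect)
        if len(sites) == 0:
            raise PipelineError(stage, "no sites acquired")
        manifest["stages"].append({"stage": stage, "n_sites": len(sites)})

        stage = "load-tracks"
        chip_track = tio.read_tag_track(config.chip.path, config.chip.name)
        extra_tracks = [(spec, tio.read_tag_track(spec.path, spec.name))
                        for spec in config.extra_tags]
        dnase_track = (tio.read_tag_track(config.dnase.path,
                                          config.dnase.name)
                       if config.dnase else None)
        numeric = [(spec, tio.read_bedgraph(spec.path, spec.name))
                   for spec in config.numeric_tracks]

        stage = "filter-sites"
        if config.workflow == "predicted":
            support = [chip_track] + [t for _, t in extra_tracks]
            sites = filter_sites_by_tag_support(
                sites, support, min_count=config.min_tag_count,
                halfwidth=WINDOW_TF)
            if len(sites) == 0:
                raise PipelineError(stage, "no sites with tag support")
        manifest["stages"].append({"stage": stage, "n_sites": len(sites)})

        stage = "annotate"
        import pandas as pd
        features = pd.DataFrame(index=sites.frame["id"])
        chip_shift = _resolve_shift(chip_track, config.chip)
        features["target"] = count_tags(chip_track, sites,
                                        halfwidth=config.chip.halfwidth,
                                        shift=chip_shift)
        manifest["chip_shift"] = chip_shift
        if pwm is not None and config.workflow == "peaks":
            scores = [best_match_in_window(genome[s.chrom], pwm, s.center,
                                           halfwidth=WINDOW_TF)[0]
                      for s in sites]
            features["pwm_score"] = scores
        elif pwm is not None:
            features["pwm_score"] = sites.frame["score"].to_numpy()
        for spec, track in extra_tracks:
            shift = _resolve_shift(track, spec)
            features[spec.name] = count_tags(track, sites,
                                             halfwidth=spec.halfwidth,
                                             shift=shift)
        if dnase_track is not None:
            features["dnase_count"] = count_tags(
                dnase_track, sites, halfwidth=config.dnase.halfwidth or
                WINDOW_DNASE, shift=0)
            if config.include_footprint:
                profiles = extract_profiles(dnase_track, sites)
                part = partition_profiles(profiles,
                                          seed=stage_seed["footprint"])
                features["dgf_shape_p"] = part.p
        for spec, track in numeric:
            features[spec.name] = average_track(track, sites,
                                                halfwidth=spec.halfwidth)
        if config.snps:
            snps = tio.read_snp_bed(config.snps)
            features["snp_density"] = average_track(
                snp_density_track(snps), sites, halfwidth=WINDOW_SNP)
        if config.include_seq_features:
            seqfeat = annotate_sequence_features(
                genome, sites, halfwidth=WINDOW_TF,
                include_kmers=config.include_kmers)
            features = features.join(seqfeat)
        table = tmodels.FeatureTable(features)
        manifest["stages"].append({"stage": stage,
                                   "n_features": len(table.feature_names)})

        stage = "normalize"
        table = tmodels.normalize(table)

        stage = "model"
        if config.task == "classify":
            labels, subset = tmodels.label_strong_weak(table,
                                                       config.fraction)
            report = tmodels.train_classifier(subset, labels,
                                              method=config.method,
                                              seed=stage_seed["model"])
            imp_table, imp_labels = subset, labels
        else:
            report = tmodels.train_regressor(table, method=config.method,
                                             seed=stage_seed["model"])
            imp_table, imp_labels = table, None

        stage = "importance"
        report.importance = tmodels.feature_importance(
            report, imp_table, imp_labels, seed=stage_seed["importance"])
        manifest["stages"].append({"stage": stage, "done": True})

    except PipelineError:
        _mark_failed(outdir, stage)
        raise
    except Exception as exc:
        _mark_failed(outdir, stage)
        raise PipelineError(stage, str(exc)) from exc

    stage = "write-outputs"
    table.to_tsv(outdir / "feature_table.tsv")
    with open(outdir / "model_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    report.importance.rename_axis("feature").to_csv(
        outdir / "importance.tsv", sep="\t")
    manifest["metric"] = {"name": report.metric_name,
                          "cv": report.cv_metric,
                          "holdout": report.holdout_metric}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return table, report, manifest


def feature_table_from_bundle(bundle, include_footprint: bool = True,
                              include_seq_features: bool = True,
                              chip_shift: object = "auto",
                              seed: int = 0):
    """Annotate a simulated bundle in memory with the standard feature set.

    Runs the same feature operations as the file-based pipeline — windowed
    tag counts (target and DNase), footprint shape probability, histone /
    conservation / SNP track averages, G+C and structural scores — directly
    on the bundle's objects.  The PWM score feature is the planted
    instance's score carried on the site list.
    """
    import pandas as pd

    sites = bundle.sites
    features = pd.DataFrame(index=sites.frame["id"])
    shift = (estimate_fragment_shift(bundle.chip) if chip_shift == "auto"
             else int(chip_shift))
    features["target"] = count_tags(bundle.chip, sites, halfwidth=WINDOW_TF,
                                    shift=shift)
    features["pwm_score"] = sites.frame["score"].to_numpy()
    features["dnase_count"] = count_tags(bundle.dnase, sites,
                                         halfwidth=WINDOW_DNASE)
    if include_footprint:
        profiles = extract_profiles(bundle.dnase, sites)
        features["dgf_shape_p"] = partition_profiles(profiles, seed=seed).p
    for mark, track in bundle.histone_tracks.items():
        features[mark] = average_track(track, sites,
                                       halfwidth=WINDOW_HISTONE)
    features["conservation"] = average_track(bundle.conservation, sites,
                                             halfwidth=WINDOW_CONSERVATION)
    features["snp_density"] = average_track(snp_density_track(bundle.snps),
                                            sites, halfwidth=WINDOW_SNP)
    if include_seq_features:
        from .models import FeatureTable
        from .seqfeat import annotate_sequence_features
        seqfeat = annotate_sequence_features(bundle.seq_by_chrom, sites,
                                             halfwidth=WINDOW_TF)
        features = features.join(seqfeat)
    from .models import FeatureTable
    return FeatureTable(features)


def _mark_failed(outdir: Path, stage: str):
    failed = outdir / "failed"
    failed.mkdir(exist_ok=True)
    (failed / "STAGE").write_text(stage + "\n")
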