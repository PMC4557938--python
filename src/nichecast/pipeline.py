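"""End-to-end orchestration: profiles -> networks -> scoring -> SVM reports.

A run consumes a cohort (real flat files or a generated synthetic bundle)
and produces, for each requested feature type x niche combination, the
leave-one-out SVM report, plus a cross-type F-score summary, per-type
high-weight overlap tables, and a machine-readable manifest recording the
configuration hash, seed, selected cost parameters and output digests.

The four feature types mirror the four computational model outputs:

- ``enzyme_profile``   — raw EC function counts,
- ``metabolome``       — PRMT scores against the full EIN,
- ``secondary_metabolome`` — PRMT scores against the EIN restricted to a
  secondary-metabolism enzyme set,
- ``transportome``     — PRTT scores through the transporter-ligand matrix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import networks, scoring, synthetic
from .errors import NichecastError
from .learn import SVMConfig, loov_ovr_svm, niche_overlap
from .networks import build_ein, load_transportome, read_reactions, subset_network
from .profiles import read_profile_matrix
from .synthetic import SyntheticSpec, PlantedSignal, read_labels

log = logging.getLogger(__name__)

FEATURE_TYPES = ("enzyme_profile", "metabolome", "secondary_metabolome", "transportome")


@dataclass
class RunConfig:
    """Full-pipeline configuration; see docs/methods.md for the YAML schema."""

    output_dir: str = "nichecast_run"
    # explicit input files (all five needed unless `synthetic` is set)
    reactions: str | None = None
    transportome: str | None = None
    enzyme_profiles: str | None = None
    transporter_profiles: str | None = None
    labels: str | None = None
    secondary_functions: str | None = None  # one enzyme function id per line
    synthetic: SyntheticSpec | None = None
    feature_types: tuple[str, ...] = FEATURE_TYPES
    pseudocount: float = 1.0
    normalize_ein: str = "none"
    svm: SVMConfig = field(default_factory=SVMConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.feature_types) - set(FEATURE_TYPES)
        if unknown:
            raise NichecastError(f"unknown feature type(s): {sorted(unknown)}")
        # the top-level seed is the single source of randomness for a run
        self.svm = dataclasses.replace(self.svm, seed=self.seed)
        if self.synthetic is not None:
            self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        synth = raw.pop("synthetic", None)
        if synth is not None:
            planted = synth.pop("planted", None)
            if planted is not None:
                synth["planted"] = tuple(PlantedSignal(**p) for p in planted)
            for key in ("niches",):
                if key in synth:
                    synth[key] = tuple(synth[key])
            synth = SyntheticSpec(**synth)
        svm = raw.pop("svm", None)
        svm = SVMConfig(**svm) if isinstance(svm, dict) else (svm or SVMConfig())
        if "feature_types" in raw:
            raw["feature_types"] = tuple(raw["feature_types"])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise NichecastError(f"unknown config key(s): {sorted(unknown)}")
        return cls(synthetic=synth, svm=svm, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    """In-memory view of one pipeline run."""

    f_scores: pd.DataFrame  # niches x feature types
    reports: dict[str, object]  # feature type -> NichePredictionReport
    feature_tables: dict[str, pd.DataFrame]
    output_dir: Path
    manifest: dict


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        bundle = synthetic.generate(config.synthetic)
        return (bundle.reactions, bundle.transportome, bundle.enzyme_profiles,
                bundle.transporter_profiles, bundle.labels, bundle.secondary_functions)
    required = {
        "reactions": config.reactions,
        "transportome": config.transportome,
        "enzyme_profiles": config.enzyme_profiles,
        "transporter_profiles": config.transporter_profiles,
        "labels": config.labels,
    }
    missing = [k for k, v in required.items() if v is None]
    if missing:
        raise NichecastError(f"config missing input path(s): {missing} "
                             "(set them, or provide a `synthetic` block)")
    for k, v in required.items():
        if not Path(v).exists():
            raise NichecastError(f"{k} file not found: {v}")
    reactions = read_reactions(config.reactions)
    transportome = load_transportome(config.transportome)
    enz = read_profile_matrix(config.enzyme_profiles)
    tra = read_profile_matrix(config.transporter_profiles)
    labels = read_labels(config.labels)
    if config.secondary_functions:
        secondary = {line.strip() for line in Path(config.secondary_functions).read_text().splitlines()
                     if line.strip()}
    else:
        secondary = set()
    return reactions, transportome, enz, tra, labels, secondary


def build_feature_tables(
    reactions, transportome, enzyme_profiles, transporter_profiles,
    secondary_functions, pseudocount: float = 1.0, normalize_ein: str = "none",
    feature_types=FEATURE_TYPES,
) -> dict[str, pd.DataFrame]:
    """Compute the per-type genomes x features tables fed to the SVMs."""
    tables: dict[str, pd.DataFrame] = {}
    if "enzyme_profile" in feature_types:
        tables["enzyme_profile"] = enzyme_profiles.astype(float)
    if "metabolome" in feature_types or "secondary_metabolome" in feature_types:
        ein = build_ein(reactions, normalize=normalize_ein)
        if "metabolome" in feature_types:
            tables["metabolome"] = scoring.score(ein, enzyme_profiles,
                                                 pseudocount=pseudocount).data
        if "secondary_metabolome" in feature_types:
            if not secondary_functions:
                raise NichecastError("secondary_metabolome requested but no secondary "
                                     "enzyme function set provided")
            sub = subset_network(reactions, secondary_functions)
            if not sub:
                raise NichecastError("secondary enzyme set matches no reactions")
            sec_ein = build_ein(sub, normalize=normalize_ein)
            tables["secondary_metabolome"] = scoring.score(
                sec_ein, enzyme_profiles, pseudocount=pseudocount,
                kind="prmt_secondary").data
    if "transportome" in feature_types:
        tables["transportome"] = scoring.score(transportome, transporter_profiles,
                                               pseudocount=pseudocount).data
    return tables


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full factorial (feature type x niche) study and write outputs."""
    t0 = time.monotonic()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    reactions, transportome, enz, tra, labels, secondary = _load_inputs(config)
    for name, prof in (("enzyme", enz), ("transporter", tra)):
        extra = labels.index.difference(prof.index).tolist()
        missing = prof.index.difference(labels.index).tolist()
        if extra or missing:
            raise NichecastError(
                f"genome ids of labels and {name} profiles disagree; "
                f"in labels only: {extra}; in profiles only: {missing}")
    labels = labels.loc[enz.index]  # one canonical genome order
    tra = tra.loc[enz.index]
    log.info("inputs: %d genomes, %d enzyme functions, %d transporters, "
             "%d reactions, %d niches", enz.shape[0], enz.shape[1], tra.shape[1],
             len(reactions), labels.shape[1])

    tables = build_feature_tables(reactions, transportome, enz, tra, secondary,
                                  config.pseudocount, config.normalize_ein,
                                  config.feature_types)

    reports: dict[str, object] = {}
    fscore_rows: dict[str, pd.Series] = {}
    written: list[Path] = []
    for ftype, table in tables.items():
        t1 = time.monotonic()
        report = loov_ovr_svm(table, labels, config.svm)
        reports[ftype] = report
        fscore_rows[ftype] = report.f_scores()
        tdir = outdir / ftype
        tdir.mkdir(exist_ok=True)
        for niche, nr in report.per_niche.items():
            p = tdir / f"predictions_{niche}.tsv"
            nr.predictions.to_csv(p, sep="\t")
            written.append(p)
            w = pd.DataFrame({"weight": nr.weights, "high_weight": nr.high_weight.astype(int)})
            w.index.name = "feature"
            p = tdir / f"weights_{niche}.tsv"
            w.to_csv(p, sep="\t")
            written.append(p)
        hw_sets = {niche: set(nr.high_weight[nr.high_weight].index)
                   for niche, nr in report.per_niche.items()}
        if len(hw_sets) >= 2:
            p = tdir / "high_weight_overlap.tsv"
            niche_overlap(hw_sets).to_csv(p, sep="\t", index=False)
            written.append(p)
        log.info("feature type %s: %d features after filter input, %d niches, %.1fs",
                 ftype, table.shape[1], len(report.per_niche), time.monotonic() - t1)

    f_scores = pd.DataFrame(fscore_rows)
    f_scores.index.name = "niche"
    p = outdir / "f_scores.tsv"
    f_scores.to_csv(p, sep="\t")
    written.append(p)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "c_selected": {ft: {n: r.c_final for n, r in rep.per_niche.items()}
                       for ft, rep in reports.items()},
        "skipped_niches": {ft: rep.skipped for ft, rep in reports.items()},
        "runtime_seconds": round(time.monotonic() - t0, 2),
        "files": {str(p.relative_to(outdir)): hashlib.sha256(p.read_bytes()).hexdigest()
                  for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    log.info("run complete in %.1fs -> %s", time.monotonic() - t0, outdir)
    return RunResult(f_scores, reports, tables, outdir, manifest)
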