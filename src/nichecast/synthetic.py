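"""Synthetic study generator: reaction networks, transporter repertoires,
genome count profiles and non-exclusive niche labels with planted signal.

Every pipeline stage can be exercised without external databases by drawing
a cohort that shares the statistical shape of real genome-annotation data:
per-genome gene-family counts are overdispersed (negative binomial), the
transporter-ligand matrix is sparse and binary, reaction networks are
random sparse bipartite maps from enzyme functions to metabolites, and
niche labels are independent Bernoulli per niche (so a genome can occupy
several niches at once, or none).

Discriminative signal is *planted*: for each niche, a chosen set of
features (transporter or enzyme functions) gets an additive count shift in
the genomes positive for that niche. The planted features and labels are
recorded in a ground-truth manifest so recovery can be measured. All
randomness flows from the single ``seed``; the same seed reproduces every
component bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NichecastError
from .networks import InteractionMatrix, Reaction, write_matrix, write_reactions
from .profiles import write_profile_matrix

log = logging.getLogger(__name__)

DEFAULT_NICHES = ("biocontrol", "biofilm", "plant_pathogen", "plant_growth")


@dataclass(frozen=True)
class PlantedSignal:
    """A niche's discriminative signal: which features shift, and by how much."""

    niche: str
    kind: str = "transporter"  # 'enzyme' or 'transporter'
    n_features: int = 5
    effect_size: float = 4.0  # additive count shift in niche-positive genomes
    features: tuple[str, ...] | None = None  # explicit ids; auto-assigned when None

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise NichecastError("effect_size must be >= 0")
        if self.kind not in ("enzyme", "transporter"):
            raise NichecastError(f"unknown planted feature kind {self.kind!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Dimensions and distributions of a synthetic cohort.

    Defaults describe the reference study conditions used throughout the
    test-suite: 60 genomes, negative-binomial baseline counts (mean 1.5,
    dispersion 2 — overdispersed, with a realistic zero fraction), four
    non-exclusive niches at prevalence 0.4, and per niche five planted
    transporter features shifted by 4 counts in positives.
    """

    n_genomes: int = 60
    n_enzyme_functions: int = 120
    n_transporters: int = 60
    n_metabolites: int = 90
    n_ligands: int = 40
    mean_reactions_per_function: float = 2.0
    mean_ligands_per_transporter: float = 2.0
    count_mean: float = 1.5
    count_dispersion: float = 2.0
    niches: tuple[str, ...] = DEFAULT_NICHES
    planted: tuple[PlantedSignal, ...] | None = None  # None -> default per-niche signal
    label_prevalence: float = 0.4
    secondary_fraction: float = 0.3  # enzyme functions assigned to the 'secondary' pathway set
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genomes", "n_enzyme_functions", "n_transporters",
                     "n_metabolites", "n_ligands"):
            if getattr(self, name) < 1:
                raise NichecastError(f"{name} must be >= 1")
        if not (0 < self.label_prevalence < 1):
            raise NichecastError("label_prevalence must lie in (0, 1)")
        if self.count_mean <= 0 or self.count_dispersion <= 0:
            raise NichecastError("count_mean and count_dispersion must be positive")

    def resolved_planted(self) -> tuple[PlantedSignal, ...]:
        if self.planted is not None:
            return self.planted
        return tuple(PlantedSignal(niche=n) for n in self.niches)


@dataclass
class SyntheticBundle:
    """Everything one run of the pipeline consumes, plus the ground truth."""

    reactions: list[Reaction]
    transportome: InteractionMatrix
    enzyme_profiles: pd.DataFrame
    transporter_profiles: pd.DataFrame
    labels: pd.DataFrame
    secondary_functions: set[str]
    ground_truth: dict


def _enzyme_ids(n: int) -> list[str]:
    # EC-shaped four-field ids, unique via the serial last field
    return [f"{1 + i % 7}.{1 + (i // 7) % 9}.{1 + (i // 63) % 9}.{i + 1}" for i in range(n)]


def _transporter_ids(n: int) -> list[str]:
    return [f"K{10000 + i:05d}" for i in range(n)]


def _negative_binomial(rng: np.random.Generator, mean: float, dispersion: float,
                       size: tuple[int, int]) -> np.ndarray:
    # NB parameterised by mean and dispersion (shape) k: p = k / (k + mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _draw_labels(rng: np.random.Generator, spec: SyntheticSpec) -> pd.DataFrame:
    lab = rng.random((spec.n_genomes, len(spec.niches))) < spec.label_prevalence
    # guarantee >=2 positives and >=2 negatives per niche so OVR SVMs are trainable
    for j in range(lab.shape[1]):
        while lab[:, j].sum() < 2:
            lab[rng.integers(spec.n_genomes), j] = True
        while (~lab[:, j]).sum() < 2:
            lab[rng.integers(spec.n_genomes), j] = False
    genomes = [f"G{i:03d}" for i in range(spec.n_genomes)]
    return pd.DataFrame(lab, index=pd.Index(genomes, name="genome"), columns=list(spec.niches))


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Draw a full synthetic cohort from the spec's single seed."""
    rng = np.random.default_rng(spec.seed)
    enzymes = _enzyme_ids(spec.n_enzyme_functions)
    transporters = _transporter_ids(spec.n_transporters)
    metabolites = [f"C{i:05d}" for i in range(spec.n_metabolites)]
    ligands = [f"C{80000 + i:05d}" for i in range(spec.n_ligands)]

    labels = _draw_labels(rng, spec)
    genomes = labels.index

    enzyme_counts = _negative_binomial(
        rng, spec.count_mean, spec.count_dispersion, (spec.n_genomes, spec.n_enzyme_functions))
    transporter_counts = _negative_binomial(
        rng, spec.count_mean, spec.count_dispersion, (spec.n_genomes, spec.n_transporters))
    enzyme_profiles = pd.DataFrame(enzyme_counts, index=genomes.copy(), columns=enzymes)
    transporter_profiles = pd.DataFrame(transporter_counts, index=genomes.copy(),
                                        columns=transporters)

    # plant the per-niche signal: additive shift in niche-positive genomes
    planted = spec.resolved_planted()
    cursors = {"enzyme": 0, "transporter": 0}
    namespaces = {"enzyme": enzymes, "transporter": transporters}
    matrices = {"enzyme": enzyme_profiles, "transporter": transporter_profiles}
    truth_planted: dict[str, dict] = {}
    for sig in planted:
        if sig.niche not in labels.columns:
            raise NichecastError(f"planted niche {sig.niche!r} not among niches {list(labels.columns)}")
        ns = namespaces[sig.kind]
        if sig.features is not None:
            feats = list(sig.features)
            outside = [f for f in feats if f not in ns]
            if outside:
                raise NichecastError(f"planted feature(s) outside the {sig.kind} namespace: {outside}")
        else:
            start = cursors[sig.kind]
            if start + sig.n_features > len(ns):
                raise NichecastError(
                    f"not enough {sig.kind} functions to plant {sig.n_features} more features")
            feats = ns[start:start + sig.n_features]
            cursors[sig.kind] = start + sig.n_features
        shift = int(round(sig.effect_size))
        pos = labels[sig.niche].to_numpy()
        matrices[sig.kind].loc[pos, feats] += shift
        truth_planted[sig.niche] = {"kind": sig.kind, "features": list(feats),
                                    "effect_size": sig.effect_size}

    # random sparse reaction network: each enzyme function performs >=1 reactions
    reactions: list[Reaction] = []
    rid = 0
    for func in enzymes:
        k = max(1, int(rng.poisson(spec.mean_reactions_per_function)))
        for _ in range(k):
            n_sub = int(1 + rng.integers(0, 2))
            n_prod = int(1 + rng.integers(0, 2))
            picks = rng.choice(spec.n_metabolites, size=n_sub + n_prod, replace=False)
            subs = frozenset(metabolites[i] for i in picks[:n_sub])
            prods = frozenset(metabolites[i] for i in picks[n_sub:])
            reactions.append(Reaction(f"R{rid:05d}", func, subs, prods,
                                      reversible=bool(rng.random() < 0.2)))
            rid += 1

    # binary transporter-ligand specificity matrix, >=1 ligand per transporter
    T = np.zeros((spec.n_ligands, spec.n_transporters), dtype=float)
    for j in range(spec.n_transporters):
        k = min(spec.n_ligands, max(1, int(rng.poisson(spec.mean_ligands_per_transporter))))
        T[rng.choice(spec.n_ligands, size=k, replace=False), j] = 1.0
    transportome = InteractionMatrix(
        pd.DataFrame(T, index=pd.Index(ligands, name="compound"), columns=transporters),
        mode="transportome",
    )

    n_secondary = max(1, int(round(spec.secondary_fraction * spec.n_enzyme_functions)))
    secondary = set(np.array(enzymes)[rng.choice(spec.n_enzyme_functions, size=n_secondary,
                                                 replace=False)])

    ground_truth = {
        "seed": spec.seed,
        "spec": {k: v for k, v in asdict(spec).items() if k != "planted"},
        "planted": truth_planted,
        "labels": {g: [n for n in labels.columns if labels.at[g, n]] for g in labels.index},
        "secondary_functions": sorted(secondary),
    }
    return SyntheticBundle(reactions, transportome, enzyme_profiles, transporter_profiles,
                           labels, secondary, ground_truth)


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    out = labels.astype(int).copy()
    out.index.name = out.index.name or "genome"
    out.to_csv(path, sep="\t")


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = ~df.isin([0, 1]).all(axis=None)
    if bad:
        raise NichecastError(f"labels in {path} must be 0/1")
    return df.astype(bool)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every component in the flat-text dialects the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reactions": outdir / "reactions.tsv",
        "transportome": outdir / "transportome.txt",
        "enzyme_profiles": outdir / "enzyme_profiles.tsv",
        "transporter_profiles": outdir / "transporter_profiles.tsv",
        "labels": outdir / "labels.tsv",
        "secondary_functions": outdir / "secondary_functions.txt",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_reactions(bundle.reactions, paths["reactions"])
    write_matrix(bundle.transportome, paths["transportome"])
    write_profile_matrix(bundle.enzyme_profiles, paths["enzyme_profiles"])
    write_profile_matrix(bundle.transporter_profiles, paths["transporter_profiles"])
    write_labels(bundle.labels, paths["labels"])
    paths["secondary_functions"].write_text(
        "\n".join(sorted(bundle.secondary_functions)) + "\n")
    paths["ground_truth"].write_text(json.dumps(bundle.ground_truth, indent=2) + "\n")
    return paths


# ---------------------------------------------------------------------------
# worked example: a hand-sized membrane-plus-metabolism toy network

@dataclass
class WorkedExample:
    """Tiny fixed network: 3 transporters, 4 enzyme steps, 6 compounds.

    Extracellular ligands A, B, C cross the membrane via transporters t1
    (A and B), t2 (C) and t3 (B and C); inside the cell the enzyme chain
    e1..e4 runs A -> D -> E -> F -> B (with e3 also consuming C). Two genome
    profiles are included: ``toy_base`` with every function in single copy
    and ``toy_t1dup`` identical except for a duplicated t1, whose relative
    transport capacity therefore rises for exactly ligands A and B.
    """

    reactions: list[Reaction]
    transportome: InteractionMatrix
    enzyme_profiles: pd.DataFrame
    transporter_profiles: pd.DataFrame


def generate_worked_example() -> WorkedExample:
    reactions = [
        Reaction("R_e1", "e1", frozenset({"A"}), frozenset({"D"})),
        Reaction("R_e2", "e2", frozenset({"D"}), frozenset({"E"})),
        Reaction("R_e3", "e3", frozenset({"E", "C"}), frozenset({"F"})),
        Reaction("R_e4", "e4", frozenset({"F"}), frozenset({"B"})),
    ]
    T = pd.DataFrame(
        [[1.0, 0.0, 0.0],   # A: only t1
         [1.0, 0.0, 1.0],   # B: t1 and t3
         [0.0, 1.0, 1.0]],  # C: t2 and t3
        index=pd.Index(["A", "B", "C"], name="compound"),
        columns=["t1", "t2", "t3"],
    )
    transporters = pd.DataFrame(
        [[1, 1, 1], [2, 1, 1]],
        index=pd.Index(["toy_base", "toy_t1dup"], name="genome"),
        columns=["t1", "t2", "t3"],
    )
    enzymes = pd.DataFrame(
        [[1, 1, 1, 1], [1, 1, 1, 1]],
        index=pd.Index(["toy_base", "toy_t1dup"], name="genome"),
        columns=["e1", "e2", "e3", "e4"],
    )
    return WorkedExample(reactions, InteractionMatrix(T, mode="transportome"),
                         enzymes, transporters)


def write_worked_example(outdir: str | Path) -> dict[str, Path]:
    ex = generate_worked_example()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reactions": outdir / "toy_reactions.tsv",
        "transportome": outdir / "toy_transportome.txt",
        "enzyme_profiles": outdir / "toy_enzyme_profiles.tsv",
        "transporter_profiles": outdir / "toy_transporter_profiles.tsv",
    }
    write_reactions(ex.reactions, paths["reactions"])
    write_matrix(ex.transportome, paths["transportome"])
    write_profile_matrix(ex.enzyme_profiles, paths["enzyme_profiles"])
    write_profile_matrix(ex.transporter_profiles, paths["transporter_profiles"])
    return paths
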