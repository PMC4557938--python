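"""Relative metabolic-turnover and transmembrane-transport scoring.

Predicted Relative Metabolic Turnover (PRMT) compares the metabolic
capacity encoded by genome *x* against a reference genome *y*:

    PRMT = M (e_x - e_y)

where **M** is the metabolite x enzyme-function interaction matrix and
e_x, e_y are the log2-transformed enzyme function count vectors. A positive
score for a compound means genome *x* has an increased relative capacity to
synthesize it compared with the reference; a negative score, an increased
relative capacity to consume it. Scores are relative capacities only —
they are not reaction rates, fluxes or concentrations.

Predicted Relative Transmembrane Transport (PRTT) is the exact special case
obtained by substituting the binary transporter-ligand matrix **T** and the
transporter (KO) count vectors:

    PRTT = T (k_x - k_y)

with positive scores meaning increased relative transport capacity for a
ligand. The reference genome is by default the per-function arithmetic mean
of the *raw* counts over all genomes in the study (log-transformed after
averaging, not the mean of logs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NichecastError
from .networks import InteractionMatrix

log = logging.getLogger(__name__)

SCORE_KINDS = ("prmt", "prmt_secondary", "prtt")


@dataclass
class ScoreTable:
    """Genomes x compounds matrix of PRMT or PRTT scores."""

    data: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in SCORE_KINDS:
            raise NichecastError(f"unknown score kind {self.kind!r}; expected one of {SCORE_KINDS}")
        if not np.isfinite(self.data.values).all():
            raise NichecastError("score table contains non-finite values")


def average_reference(matrix: pd.DataFrame) -> pd.Series:
    """Per-function arithmetic mean of raw counts across genomes.

    This is the 'average genome' used as the fixed reference *y*, mirroring
    how relative-turnover scores are normalized against a cohort average.
    """
    if matrix.shape[0] == 0:
        raise NichecastError("cannot average an empty profile matrix")
    return matrix.mean(axis=0)


def log_transform(counts: np.ndarray | pd.Series, pseudocount: float = 1.0) -> np.ndarray:
    """log2(count + pseudocount); the default pseudocount 1 maps absent functions to 0."""
    arr = np.asarray(counts, dtype=float)
    if pseudocount < 0:
        raise NichecastError(f"pseudocount must be non-negative, got {pseudocount}")
    if (arr < 0).any():
        raise NichecastError("negative counts cannot be log-transformed")
    shifted = arr + pseudocount
    if (shifted == 0).any():
        raise NichecastError("count + pseudocount = 0 encountered; log2 undefined "
                             "(use a positive pseudocount)")
    return np.log2(shifted)


def _align_functions(matrix: InteractionMatrix, profiles: pd.DataFrame) -> pd.DataFrame:
    """Reindex profiles onto the matrix's function columns, zero-filling absentees."""
    for name, idx in (("profile genome", profiles.index), ("profile function", profiles.columns)):
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise NichecastError(f"duplicate {name} ids: {dups}")
    cols = matrix.data.columns
    missing = cols.difference(profiles.columns)
    if len(missing):
        log.warning("%d function(s) in the interaction matrix absent from all genomes; "
                    "treated as count 0 (e.g. %s)", len(missing), list(missing[:5]))
    return profiles.reindex(columns=cols, fill_value=0)


def score(
    matrix: InteractionMatrix,
    profiles: pd.DataFrame,
    reference: pd.Series | None = None,
    pseudocount: float = 1.0,
    kind: str | None = None,
) -> ScoreTable:
    """Score every genome against the reference through an interaction matrix.

    Row *g* of the result is ``M . (log2(counts_g + pc) - log2(reference + pc))``
    over the matrix's compound rows. Functions present in the matrix but
    absent from the profiles (or the reference) are treated as count 0.

    Parameters
    ----------
    matrix:
        EIN (``mode="ein"``) or transporter-ligand (``mode="transportome"``).
    profiles:
        Genomes x functions raw count matrix.
    reference:
        Per-function raw mean counts; computed from ``profiles`` via
        :func:`average_reference` when omitted.
    kind:
        Override the score kind label (e.g. ``"prmt_secondary"`` for a
        pathway-restricted EIN); defaults from the matrix mode.
    """
    aligned = _align_functions(matrix, profiles)
    if reference is None:
        reference = average_reference(profiles)
    ref = reference.reindex(matrix.data.columns, fill_value=0.0)
    delta = log_transform(aligned.values, pseudocount) - log_transform(ref.values, pseudocount)
    scores = delta @ matrix.data.values.T
    if kind is None:
        kind = "prmt" if matrix.mode == "ein" else "prtt"
    table = pd.DataFrame(scores, index=profiles.index.copy(), columns=matrix.data.index.copy())
    table.index.name = "genome"
    return ScoreTable(table, kind)


def score_pair(
    matrix: InteractionMatrix,
    profiles: pd.DataFrame,
    x: str,
    y: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Score a single genome *x* directly against another genome *y*.

    Antisymmetric by construction: ``score_pair(m, p, x, y) == -score_pair(m, p, y, x)``.
    """
    for g in (x, y):
        if g not in profiles.index:
            raise NichecastError(f"genome {g!r} not in profile matrix")
    table = score(matrix, profiles.loc[[x]], reference=profiles.loc[y], pseudocount=pseudocount)
    return table.data.iloc[0]


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write scores as wide TSV (genomes x compounds)."""
    out = table.data.copy()
    out.index.name = out.index.name or "genome"
    out.to_csv(path, sep="\t")


def read_score_table(path: str | Path, kind: str) -> ScoreTable:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ScoreTable(df, kind)
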