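"""Interaction matrices: the Enzyme Interaction Network and the transportome.

The Enzyme Interaction Network (EIN) is a metabolite x enzyme-function
matrix **M** recording which functions can produce (+) or consume (-) which
metabolites, with no stoichiometry, flux or mass balance: the entry for
metabolite *i* and function *j* is the sum over that function's reactions of
+1 per appearance of *i* as product and -1 per appearance as substrate. A
metabolite on both sides of the same reaction (a currency-style passthrough)
therefore nets to zero.

The transportome analogue is a binary ligand x transporter-function matrix
**T**: 1 where a transporter annotation moves a ligand across the membrane,
0 otherwise. Both matrices plug into the same scoring machinery
(:mod:`nichecast.scoring`).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import NichecastError

log = logging.getLogger(__name__)

MODES = ("ein", "transportome")


@dataclass(frozen=True)
class Reaction:
    """One directed metabolic transformation carried out by an enzyme function."""

    reaction_id: str
    enzyme_function: str
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrates", frozenset(self.substrates))
        object.__setattr__(self, "products", frozenset(self.products))
        if not self.substrates and not self.products:
            raise NichecastError(f"reaction {self.reaction_id} references no metabolites")


@dataclass
class InteractionMatrix:
    """Compound x function matrix: signed EIN or binary transporter-ligand map."""

    data: pd.DataFrame  # rows: metabolites/ligands, cols: functions
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise NichecastError(f"unknown matrix mode {self.mode!r}; expected one of {MODES}")
        self.validate()

    def validate(self) -> None:
        df = self.data
        for axis, name in ((df.index, "row"), (df.columns, "column")):
            if axis.duplicated().any():
                dups = axis[axis.duplicated()].unique().tolist()
                raise NichecastError(f"duplicate {name} ids: {dups}")
        if not np.isfinite(df.values).all():
            raise NichecastError("non-finite values in interaction matrix")
        if self.mode == "transportome":
            bad = ~np.isin(df.values, (0, 1))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise NichecastError(
                    f"transportome matrix must be binary; found {df.iat[i, j]!r} at "
                    f"row {df.index[i]!r}, column {df.columns[j]!r}"
                )
        zero_cols = df.columns[(df != 0).sum(axis=0) == 0].tolist()
        if zero_cols:
            log.warning("interaction matrix has %d all-zero column(s), e.g. %s",
                        len(zero_cols), zero_cols[:5])

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def function_ids(self) -> list[str]:
        return list(self.data.columns)


def build_ein(
    reactions: Sequence[Reaction],
    normalize: str = "none",
    reversible_mode: str = "forward",
) -> InteractionMatrix:
    """Build the EIN matrix **M** from a reaction list.

    Parameters
    ----------
    reactions:
        Directed transformations, each tied to one enzyme function.
    normalize:
        ``"none"`` keeps raw signed counts; ``"per_function"`` divides each
        column by its number of nonzero entries, so promiscuous functions do
        not dominate purely by touching many compounds.
    reversible_mode:
        ``"forward"`` counts every reaction once in its annotated direction;
        ``"both"`` additionally adds the mirrored direction for reactions
        flagged reversible (whose own substrate/product contributions then
        cancel).
    """
    if not reactions:
        raise NichecastError("cannot build an EIN from an empty reaction list")
    if normalize not in ("none", "per_function"):
        raise NichecastError(f"unknown normalize mode {normalize!r}")
    if reversible_mode not in ("forward", "both"):
        raise NichecastError(f"unknown reversible mode {reversible_mode!r}")

    entries: Counter[tuple[str, str]] = Counter()
    metabolites: set[str] = set()
    functions: set[str] = set()
    for rxn in reactions:
        metabolites |= rxn.substrates | rxn.products
        functions.add(rxn.enzyme_function)
        contrib: Counter[str] = Counter()
        for p in rxn.products:
            contrib[p] += 1
        for s in rxn.substrates:
            contrib[s] -= 1
        if rxn.reversible and reversible_mode == "both":
            for p in rxn.products:
                contrib[p] -= 1
            for s in rxn.substrates:
                contrib[s] += 1
        for met, v in contrib.items():
            entries[(met, rxn.enzyme_function)] += v

    rows = sorted(metabolites)
    cols = sorted(functions)
    M = pd.DataFrame(0, index=pd.Index(rows, name="compound"), columns=cols, dtype=float)
    for (met, func), v in entries.items():
        M.at[met, func] = float(v)
    if normalize == "per_function":
        nonzero = (M != 0).sum(axis=0).replace(0, 1)
        M = M / nonzero
    return InteractionMatrix(M, mode="ein")


def subset_network(reactions: Iterable[Reaction], allowed_functions: set[str]) -> list[Reaction]:
    """Keep only reactions of the given enzyme functions.

    Restricting to a pathway-defined enzyme set (e.g. secondary-metabolite
    biosynthesis) and rebuilding the EIN yields the corresponding restricted
    metabolic model.
    """
    out = [r for r in reactions if r.enzyme_function in allowed_functions]
    if not out:
        log.warning("subset_network: no reactions left after restricting to %d function(s)",
                    len(allowed_functions))
    return out


# ---------------------------------------------------------------------------
# flat-file dialects

def write_reactions(reactions: Sequence[Reaction], path: str | Path) -> None:
    """Write reactions as TSV: reaction_id, function, substrates, products, reversible.

    Metabolite sets are ';'-joined in sorted order; reversible is 0/1.
    """
    rows = [
        {
            "reaction_id": r.reaction_id,
            "enzyme_function": r.enzyme_function,
            "substrates": ";".join(sorted(r.substrates)),
            "products": ";".join(sorted(r.products)),
            "reversible": int(r.reversible),
        }
        for r in reactions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reactions(path: str | Path) -> list[Reaction]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"reaction_id", "enzyme_function", "substrates", "products", "reversible"}
    missing = required - set(df.columns)
    if missing:
        raise NichecastError(f"reaction table {path} missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        subs = frozenset(s for s in row["substrates"].split(";") if s)
        prods = frozenset(s for s in row["products"].split(";") if s)
        out.append(Reaction(row["reaction_id"], row["enzyme_function"], subs, prods,
                            bool(int(row["reversible"]))))
    return out


def write_matrix(matrix: InteractionMatrix, path: str | Path) -> None:
    """Write an interaction matrix in the tab-separated header-row+column dialect."""
    out = matrix.data.copy()
    out.index.name = out.index.name or "compound"
    if matrix.mode == "transportome":
        out = out.astype(int)
    out.to_csv(path, sep="\t")


def _load_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise NichecastError(f"non-numeric cell in matrix {path}: {exc}") from None
    return df


def load_transportome(path: str | Path) -> InteractionMatrix:
    """Load and validate a binary transporter-ligand matrix (ligands x transporters)."""
    return InteractionMatrix(_load_matrix(path), mode="transportome")


def load_ein(path: str | Path) -> InteractionMatrix:
    """Load a signed metabolite x enzyme-function matrix."""
    return InteractionMatrix(_load_matrix(path), mode="ein")
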