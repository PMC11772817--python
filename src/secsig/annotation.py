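"""Secretome membership and IFN-regulation lookup.

The secretome filter emulates flat membership in the Gene Ontology
"extracellular region" term (GO:0005576).  IFN regulation is looked up in a
local snapshot of an Interferome-style table: one record per (gene, IFN type,
direction) with an experimental fold change.  A gene counts as IFN-regulated
when at least one record meets the fold-change threshold (default 1.5, the
conventional Interferome query setting).  The live database is never queried;
its curated content is version-dependent, so a local table keeps analyses
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError

#: default Interferome fold-change threshold
DEFAULT_TAU_IFN = 1.5

IFN_TYPES = ("I", "II", "III")
DIRECTIONS = ("up", "down")

INTERFEROME_COLUMNS = ["gene", "ifn_type", "fold_change", "direction"]


@dataclass
class AnnotationDB:
    """Secretome membership set plus an IFN-regulation record table.

    ``interferome`` columns: gene, ifn_type in {I, II, III}, fold_change > 0,
    direction in {up, down}.  A gene may carry several records.
    """

    secretome: frozenset[str]
    interferome: pd.DataFrame

    def __post_init__(self) -> None:
        self.secretome = frozenset(self.secretome)
        missing = set(INTERFEROME_COLUMNS) - set(self.interferome.columns)
        if missing:
            raise ConfigurationError(f"interferome table missing columns: {sorted(missing)}")
        bad_type = ~self.interferome["ifn_type"].isin(IFN_TYPES)
        if bad_type.any():
            raise ConfigurationError("interferome ifn_type must be one of I, II, III")
        if (self.interferome["fold_change"] <= 0).any():
            raise ConfigurationError("interferome fold_change must be > 0")
        if (~self.interferome["direction"].isin(DIRECTIONS)).any():
            raise ConfigurationError("interferome direction must be 'up' or 'down'")


@dataclass(frozen=True)
class IFNQueryResult:
    gene: str
    is_ifn_regulated: bool
    types: frozenset[str]
    directions: dict[str, frozenset[str]]  # type -> directions observed


def annotate_secretome(genes, db: AnnotationDB) -> pd.Series:
    """Boolean membership per gene; genes absent from the DB are False."""
    genes = list(genes)
    return pd.Series([g in db.secretome for g in genes], index=genes, dtype=bool)


def query_interferome(
    gene: str, db: AnnotationDB, tau_ifn: float = DEFAULT_TAU_IFN
) -> IFNQueryResult:
    """Aggregate all records for ``gene`` with fold_change >= ``tau_ifn``."""
    if tau_ifn <= 0:
        raise ConfigurationError("tau_ifn must be > 0")
    rec = db.interferome
    hit = rec[(rec["gene"] == gene) & (rec["fold_change"] >= tau_ifn)]
    directions = {
        t: frozenset(hit.loc[hit["ifn_type"] == t, "direction"])
        for t in IFN_TYPES
        if (hit["ifn_type"] == t).any()
    }
    return IFNQueryResult(
        gene=gene,
        is_ifn_regulated=len(hit) > 0,
        types=frozenset(directions),
        directions=directions,
    )


def _ifn_table(db: AnnotationDB, tau_ifn: float) -> pd.DataFrame:
    rec = db.interferome
    return rec[rec["fold_change"] >= tau_ifn]


def is_ifn_regulated(
    genes, db: AnnotationDB, tau_ifn: float = DEFAULT_TAU_IFN, direction: str | None = None
) -> pd.Series:
    """Vectorized IFN-regulation lookup, optionally restricted to a direction."""
    hit = _ifn_table(db, tau_ifn)
    if direction is not None:
        hit = hit[hit["direction"] == direction]
    regulated = set(hit["gene"])
    genes = list(genes)
    return pd.Series([g in regulated for g in genes], index=genes, dtype=bool)


def summarize_ifn_regulation(
    de: pd.DataFrame,
    db: AnnotationDB,
    tau_ifn: float = DEFAULT_TAU_IFN,
    counting_mode: str = "any",
    direction_match: bool = True,
) -> dict:
    """Summary of IFN regulation among the differential genes.

    Returns a dict with the fraction of up- and down-regulated DE genes that
    are IFN-regulated, plus the per-type share of all IFN-regulated DE genes.
    With ``direction_match`` (default) an up-DE gene only counts as
    IFN-regulated if it carries an "up" record at threshold, mirroring how
    up- and down-regulated genes are summarized separately; set it False to
    accept any record direction.  ``counting_mode`` "any" counts a gene
    toward every IFN type it carries; "exclusive" only counts genes with a
    single type.  A direction with no DE genes yields fraction ``None``.
    """
    if counting_mode not in ("any", "exclusive"):
        raise ConfigurationError("counting_mode must be 'any' or 'exclusive'")
    if de.empty:
        raise ConfigurationError("differential table is empty")

    de_genes = de[de["passes_de"]]
    up_genes = list(de_genes.index[de_genes["log2fc"] > 0])
    down_genes = list(de_genes.index[de_genes["log2fc"] < 0])

    def _fraction(genes: list[str], de_direction: str) -> float | None:
        if not genes:
            return None
        want = de_direction if direction_match else None
        flags = is_ifn_regulated(genes, db, tau_ifn, direction=want)
        return float(flags.mean())

    # per-type shares over all IFN-regulated DE genes (either direction)
    all_de = up_genes + down_genes
    type_of: dict[str, frozenset[str]] = {}
    for g in all_de:
        q = query_interferome(g, db, tau_ifn)
        if q.is_ifn_regulated:
            type_of[g] = q.types
    n_reg = len(type_of)
    shares: dict[str, float] = {}
    for t in IFN_TYPES:
        if counting_mode == "any":
            n_t = sum(1 for types in type_of.values() if t in types)
        else:
            n_t = sum(1 for types in type_of.values() if types == frozenset({t}))
        shares[t] = n_t / n_reg if n_reg else 0.0

    return {
        "up_fraction": _fraction(up_genes, "up"),
        "down_fraction": _fraction(down_genes, "down"),
        "type_shares": shares,
        "n_ifn_regulated_de": n_reg,
        "counting_mode": counting_mode,
        "direction_match": direction_match,
        "tau_ifn": tau_ifn,
    }
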