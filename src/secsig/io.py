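"""Plain-text readers and writers for the pipeline's file formats.

All tabular artifacts are TSV/CSV with headers; gene sets use the GMT
convention (name, description, then genes, tab-separated) and ranked lists
the two-column RNK convention.  No binary intermediates are produced.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotation import INTERFEROME_COLUMNS, AnnotationDB
from .errors import ConfigurationError
from .expression import CountMatrix, RankedList
from .proteomics import ARRAY_COLUMNS, ArrayExperiment
from .qpcr import CTTable

# ---------------------------------------------------------------------------
# counts + sample table


def write_counts(m: CountMatrix, counts_path, samples_path) -> None:
    m.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    table = pd.DataFrame(
        {
            "sample": m.sample_ids,
            "condition": [m.condition_of[s] for s in m.sample_ids],
            "replicate": [s.rsplit("_", 1)[-1] for s in m.sample_ids],
        }
    )
    table.to_csv(samples_path, sep="\t", index=False)


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    condition_of = pd.Series(
        samples["condition"].values, index=samples["sample"].values, name="condition"
    )
    return CountMatrix(counts=counts, condition_of=condition_of)


# ---------------------------------------------------------------------------
# annotation database


def write_annotation(db: AnnotationDB, secretome_path, interferome_path) -> None:
    Path(secretome_path).write_text("\n".join(sorted(db.secretome)) + "\n")
    db.interferome.to_csv(interferome_path, sep="\t", index=False)


def read_annotation(secretome_path, interferome_path) -> AnnotationDB:
    secretome = frozenset(
        line.strip()
        for line in Path(secretome_path).read_text().splitlines()
        if line.strip()
    )
    interferome = pd.read_csv(interferome_path, sep="\t")
    missing = set(INTERFEROME_COLUMNS) - set(interferome.columns)
    if missing:
        raise ConfigurationError(f"interferome file missing columns: {sorted(missing)}")
    return AnnotationDB(secretome=secretome, interferome=interferome)


# ---------------------------------------------------------------------------
# cytokine array


def write_array(x: ArrayExperiment, path) -> None:
    x.spots[ARRAY_COLUMNS].to_csv(path, index=False)


def read_array(path, saturation_ceiling: float = 65535.0) -> ArrayExperiment:
    spots = pd.read_csv(path, keep_default_na=False)
    return ArrayExperiment(spots=spots, saturation_ceiling=saturation_ceiling)


# ---------------------------------------------------------------------------
# qPCR CT table


def write_ct_table(t: CTTable, ct_path, samples_path) -> None:
    t.records.to_csv(ct_path, sep="\t", index=False)
    table = pd.DataFrame(
        {
            "sample": t.samples,
            "condition": [t.condition_of[s] for s in t.samples],
        }
    )
    table.to_csv(samples_path, sep="\t", index=False)


def read_ct_table(ct_path, samples_path, housekeeping_genes=("Gapdh", "Actb")) -> CTTable:
    records = pd.read_csv(ct_path, sep="\t")
    samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    condition_of = pd.Series(
        samples["condition"].values, index=samples["sample"].values, name="condition"
    )
    return CTTable(
        records=records,
        housekeeping_genes=tuple(housekeeping_genes),
        condition_of=condition_of,
    )


# ---------------------------------------------------------------------------
# gene sets (GMT) and ranked lists (RNK)


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ConfigurationError(f"malformed GMT line: {line!r}")
        name, _desc, *genes = fields
        if name in out:
            raise ConfigurationError(f"duplicate gene set name {name!r} in GMT")
        out[name] = [g for g in genes if g]
    return out


def write_rnk(r: RankedList, path) -> None:
    with open(path, "w") as fh:
        for gene, metric in zip(r.genes, r.metrics):
            fh.write(f"{gene}\t{metric:.10g}\n")


def read_rnk(path) -> RankedList:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "metric"])
    return RankedList(genes=list(df["gene"].astype(str)), metrics=df["metric"].to_numpy())
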