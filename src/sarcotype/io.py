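"""File formats: TSV expression matrices, clinical CSV, GMT gene sets.

Matrices are written genes-in-rows with a header row of sample ids; gzip is
handled transparently by pandas via the file extension. Floats are written
with 10 significant digits so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .preprocess import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


class FormatError(ValueError):
    pass


def read_counts_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df)


def write_counts_tsv(counts: CountMatrix, path) -> None:
    counts.values.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_normalized(norm: NormalizedMatrix, logexpr_path, weights_path) -> None:
    write_matrix_tsv(norm.logexpr, logexpr_path)
    write_matrix_tsv(norm.weights, weights_path)


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise FormatError("clinical table must have a sample_id column")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in clinical table")
    return df.set_index("sample_id")


def write_clinical_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, float_format=FLOAT_FORMAT)


def check_sample_join(expr_samples, clinical_samples) -> None:
    """Expression/clinical sample ids must match exactly; offenders listed."""
    e, c = set(expr_samples), set(clinical_samples)
    if e != c:
        only_e = sorted(e - c)
        only_c = sorted(c - e)
        raise FormatError(
            f"sample_id mismatch between expression and clinical tables; "
            f"expression-only: {only_e[:10]}, clinical-only: {only_c[:10]}"
        )


def read_gmt(path) -> dict:
    """Read a GMT file into name -> gene set (order not preserved).

    Lines are tab-separated: name, description, genes... Duplicate set names
    and gene-less lines are errors; duplicated genes within a set are
    deduplicated with a warning.
    """
    sets = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                raise FormatError(f"{path}:{ln}: gene set line with no genes")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{ln}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g.strip()]
            uniq = set(genes)
            if len(uniq) < len(genes):
                logger.warning(
                    "set %s has duplicated gene ids; deduplicated", name
                )
            sets[name] = frozenset(uniq)
    if not sets:
        raise FormatError(f"{path}: no gene sets")
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = sorted(sets[name])
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
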