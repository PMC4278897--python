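"""Reading, writing and validating FPKM expression tables.

An expression matrix is a pandas DataFrame with gene identifiers as the
index (one row per gene) and sample identifiers as columns; every value is
a finite, non-negative FPKM. A sample annotation is a DataFrame indexed by
sample id with columns ``tissue``, ``donor``, ``compartment`` and ``lane``.
A tissue profile is the replicate-averaged matrix: one column per tissue,
each entry the arithmetic mean FPKM over that tissue's samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COMPARTMENTS = ("whole", "islet", "exocrine")

ANNOTATION_COLUMNS = ("tissue", "donor", "compartment", "lane")


class FormatError(ValueError):
    """An input table violates the expression-matrix or annotation format."""


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants and return the matrix.

    Raises
    ------
    FormatError
        If gene or sample ids are duplicated, or any value is negative,
        non-numeric or non-finite.
    """
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][0]
        raise FormatError(f"duplicate gene id: {dup!r}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id: {dup!r}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        coerced = matrix.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & matrix.notna()
        if bad.to_numpy().any():
            gene, sample = _first_true(bad)
            raise FormatError(
                f"non-numeric value at gene {gene!r}, sample {sample!r}"
            )
        values = coerced.to_numpy()
        matrix = coerced
    if np.isnan(values).any():
        gene, sample = _first_true(pd.DataFrame(
            np.isnan(values), index=matrix.index, columns=matrix.columns))
        raise FormatError(f"missing value at gene {gene!r}, sample {sample!r}")
    if not np.isfinite(values).all():
        gene, sample = _first_true(pd.DataFrame(
            ~np.isfinite(values), index=matrix.index, columns=matrix.columns))
        raise FormatError(f"non-finite value at gene {gene!r}, sample {sample!r}")
    if (values < 0).any():
        gene, sample = _first_true(matrix < 0)
        raise FormatError(f"negative FPKM at gene {gene!r}, sample {sample!r}")
    return matrix


def _first_true(mask: pd.DataFrame) -> tuple[str, str]:
    rows, cols = np.nonzero(mask.to_numpy())
    return str(mask.index[rows[0]]), str(mask.columns[cols[0]])


def read_fpkm_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a genes-by-samples FPKM table (first column gene ids, header row
    sample ids) into a validated DataFrame, preserving input gene order."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    seen: set[str] = set()
    for sample in header[1:]:
        if sample in seen:
            raise FormatError(f"duplicate sample id: {sample!r}")
        seen.add(sample)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.index.name = None
    raw.columns = raw.columns.astype(str)
    try:
        matrix = raw.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        matrix = raw  # validate_matrix locates the offending cell
    return validate_matrix(matrix.astype(float) if matrix is not raw else raw)


def write_fpkm_table(matrix: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a validated FPKM matrix as TSV with full float precision."""
    validate_matrix(matrix)
    matrix.to_csv(path, sep=sep, index_label="gene", float_format="%.17g")


def read_annotation(path, sep: str = "\t") -> pd.DataFrame:
    """Read a sample-annotation table (sample_id, tissue, donor, compartment,
    lane) into a DataFrame indexed by sample id; lane may be empty."""
    ann = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "sample_id" not in ann.columns:
        raise FormatError("annotation must have a 'sample_id' column")
    ann = ann.set_index("sample_id")
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            if col == "lane":
                ann["lane"] = ""
            else:
                raise FormatError(f"annotation missing column {col!r}")
    return validate_annotation(ann[list(ANNOTATION_COLUMNS)])


def write_annotation(annotation: pd.DataFrame, path, sep: str = "\t") -> None:
    annotation.to_csv(path, sep=sep, index_label="sample_id")


def validate_annotation(
    annotation: pd.DataFrame, matrix: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Check annotation invariants; if a matrix is given, require exactly one
    annotation row for each of its samples."""
    if annotation.index.has_duplicates:
        dup = annotation.index[annotation.index.duplicated()][0]
        raise FormatError(f"duplicate annotation for sample {dup!r}")
    if (annotation["tissue"].astype(str).str.len() == 0).any():
        bad = annotation.index[annotation["tissue"].astype(str).str.len() == 0][0]
        raise FormatError(f"empty tissue label for sample {bad!r}")
    bad_comp = ~annotation["compartment"].isin(COMPARTMENTS)
    if bad_comp.any():
        sample = annotation.index[bad_comp][0]
        raise FormatError(
            f"sample {sample!r} has compartment "
            f"{annotation.loc[sample, 'compartment']!r}; "
            f"expected one of {COMPARTMENTS}"
        )
    if matrix is not None:
        missing = matrix.columns.difference(annotation.index)
        if len(missing) > 0:
            raise FormatError(f"sample without annotation: {missing[0]!r}")
    return annotation


def average_replicates(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    compartment_filter: str = "all",
) -> pd.DataFrame:
    """Average replicate samples into a gene x tissue profile.

    Each tissue column is the unweighted arithmetic mean FPKM over the
    tissue's samples, computed on the linear FPKM scale.

    Parameters
    ----------
    matrix
        Validated genes-by-samples FPKM matrix.
    annotation
        Sample annotation covering every matrix column.
    compartment_filter
        ``"all"`` keeps every sample; otherwise only samples whose
        ``compartment`` equals the given value contribute.
    """
    validate_annotation(annotation, matrix)
    samples = list(matrix.columns)
    if compartment_filter != "all":
        if compartment_filter not in COMPARTMENTS:
            raise FormatError(
                f"unknown compartment filter {compartment_filter!r}")
        keep = annotation.loc[samples, "compartment"] == compartment_filter
        samples = [s for s, k in zip(samples, keep) if k]
    if not samples:
        raise FormatError("no samples left after compartment selection")
    tissues = annotation.loc[samples, "tissue"]
    profile = matrix[samples].T.groupby(tissues.to_numpy()).mean().T
    profile = profile[sorted(profile.columns)]
    profile.columns.name = None
    return profile


def log2_pseudo(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(FPKM + 1); the +1 pseudo-count maps zeros to zero."""
    validate_matrix(matrix)
    return np.log2(matrix + 1.0)
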