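"""Readers and writers for genotype matrices, phenotypes, subgroup lists
and LOOCV reports.

Supported genotype dialects
---------------------------
``csv`` / ``tsv``
    Header row of marker ids; first column the individual id; every cell
    an allele dosage in {0, 1, 2}. This is also the format the writers
    emit, so simulate -> write -> read round-trips bit-exactly.
``plink-raw``
    The whitespace-delimited dosage text produced by ``plink --recode A``:
    six leading pedigree columns (FID IID PAT MAT SEX PHENOTYPE) followed
    by one dosage column per marker. The IID column is used as the
    individual id.

Validation is strict: a missing value, a non-{0,1,2} entry or a duplicate
id is a parse error that names the offending line. Phenotypes are joined
to genotypes by individual id; the genotype file owns the ordering.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .loocv import LoocvResult
from .types import GenotypeMatrix, PhenotypeVector

__all__ = [
    "read_genotypes",
    "read_phenotypes",
    "read_subgroup",
    "write_genotypes",
    "write_phenotypes",
    "write_result",
]

log = logging.getLogger("gblupcv")

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix == ".raw":
        return "plink-raw"
    raise DataError(
        f"cannot infer genotype dialect from {path.name!r}; pass dialect explicitly"
    )


def _validate_dosages(values: pd.DataFrame, path, header_rows: int) -> np.ndarray:
    raw = values.to_numpy()
    numeric = pd.to_numeric(pd.Series(raw.ravel()), errors="coerce")
    arr = numeric.to_numpy(dtype=float).reshape(raw.shape)
    bad = ~np.isin(arr, (0.0, 1.0, 2.0)) | ~np.isfinite(arr)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise DataError(
            f"{path}: line {i + 1 + header_rows}, marker {values.columns[j]!r}: "
            f"invalid dosage {values.iat[i, j]!r} (must be 0, 1 or 2; no missing values)"
        )
    return arr


def read_genotypes(path, dialect: str = "auto") -> GenotypeMatrix:
    """Load an n x p dosage matrix from CSV/TSV or PLINK RAW text."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"genotype file not found: {path}")
    if dialect == "auto":
        dialect = _infer_dialect(path)
    if dialect not in ("csv", "tsv", "plink-raw"):
        raise DataError(f"unknown genotype dialect {dialect!r}")
    try:
        if dialect == "plink-raw":
            df = pd.read_csv(path, sep=r"\s+", dtype=str)
        else:
            df = pd.read_csv(path, sep="," if dialect == "csv" else "\t",
                             dtype=str, index_col=0)
    except pd.errors.EmptyDataError as err:
        raise DataError(f"{path}: empty genotype file") from err
    if dialect == "plink-raw":
        missing = [c for c in _PLINK_META if c not in df.columns]
        if missing:
            raise DataError(f"{path}: not PLINK RAW — missing columns {missing}")
        ids = df["IID"].astype(str).tolist()
        body = df.drop(columns=_PLINK_META)
    else:
        ids = [str(x) for x in df.index]
        body = df
    if body.shape[1] == 0 or body.shape[0] == 0:
        raise DataError(f"{path}: no marker columns / no individuals found")
    dupes = sorted({x for x in ids if ids.count(x) > 1})
    if dupes:
        raise DataError(f"{path}: duplicate individual ids {dupes}")
    arr = _validate_dosages(body, path, header_rows=1)
    g = GenotypeMatrix(arr, ids, [str(c) for c in body.columns])
    log.info("read %d individuals x %d markers from %s (%s)",
             g.n_individuals, g.n_markers, path, dialect)
    return g


def read_phenotypes(path, g: GenotypeMatrix) -> PhenotypeVector:
    """Load a two-column (id, value) file and align it to ``g`` by id join.

    The delimiter (tab, comma or whitespace) and an optional header row are
    detected automatically. Row order in the file is irrelevant; the
    genotype matrix dictates the output order. Unknown or missing ids are
    errors that list the offenders.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"phenotype file not found: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    except pd.errors.EmptyDataError as err:
        raise DataError(f"{path}: empty phenotype file") from err
    if df.shape[1] != 2:
        raise DataError(f"{path}: expected 2 columns (id, value), found {df.shape[1]}")
    # header row: second field not parseable as a number
    if pd.to_numeric(df.iloc[0, 1:2], errors="coerce").isna().all():
        df = df.iloc[1:]
    def _to_float(s):
        try:
            return float(s)
        except (TypeError, ValueError):
            return np.nan

    # Python's float() is correctly rounded, so repr-written values
    # round-trip bit-exactly
    vals = df[1].map(_to_float)
    if vals.isna().any():
        bad = df[0][vals.isna()].tolist()
        raise DataError(f"{path}: non-numeric phenotype for ids {bad}")
    mapping = dict(zip(df[0].astype(str), vals.astype(float)))
    if len(mapping) != len(df):
        dupes = sorted({x for x in df[0].astype(str) if (df[0] == x).sum() > 1})
        raise DataError(f"{path}: duplicate phenotype ids {dupes}")
    unknown = sorted(set(mapping) - set(g.individual_ids))
    absent = [i for i in g.individual_ids if i not in mapping]
    if unknown or absent:
        parts = []
        if unknown:
            parts.append(f"phenotypes for unknown individuals {unknown[:10]}")
        if absent:
            parts.append(f"no phenotype for genotyped individuals {absent[:10]}")
        raise DataError(f"{path}: id mismatch — " + "; ".join(parts))
    values = np.array([mapping[i] for i in g.individual_ids])
    log.info("read %d phenotypes from %s", values.size, path)
    return PhenotypeVector(values, g.individual_ids)


def read_subgroup(path, g: GenotypeMatrix) -> np.ndarray:
    """Load a one-id-per-line subgroup file; return integer row indices."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"subgroup file not found: {path}")
    wanted = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    pos = {ind: i for i, ind in enumerate(g.individual_ids)}
    unknown = [w for w in wanted if w not in pos]
    if unknown:
        raise DataError(f"{path}: subgroup ids not in genotype file: {unknown[:10]}")
    return np.array([pos[w] for w in wanted], dtype=int)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write dosages as CSV (id column + marker-id header), integer cells."""
    path = Path(path)
    df = pd.DataFrame(g.dosages.astype(int), index=g.individual_ids, columns=g.marker_ids)
    df.to_csv(path, index_label="id")
    log.info("wrote %d x %d genotype matrix to %s", *g.shape, path)


def write_phenotypes(y: PhenotypeVector, path) -> None:
    """Write phenotypes as a two-column TSV with full float precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id\tvalue\n")
        for ind, v in zip(y.individual_ids, y.values):
            fh.write(f"{ind}\t{float(v)!r}\n")
    log.info("wrote %d phenotypes to %s", len(y), path)


def write_result(result: LoocvResult, y: PhenotypeVector, path) -> None:
    """Write the per-individual LOOCV report as TSV plus a sidecar summary.

    Columns: id, y, y_hat, e_hat, leverage, pev, reliability; columns a
    strategy does not produce are left blank. PRESS and accuracy go to
    ``<path>.summary`` as key=value lines and to the log. Residuals are
    written with ``repr`` so a round-trip read is bit-exact.
    """
    path = Path(path)
    n = len(y)
    lev = result.leverage.values if result.leverage is not None else [None] * n
    pev = result.pev if result.pev is not None else [None] * n
    rel = result.reliability if result.reliability is not None else [None] * n

    def fmt(x):
        return "" if x is None or (isinstance(x, float) and np.isnan(x)) else repr(float(x))

    with open(path, "w") as fh:
        fh.write("id\ty\ty_hat\te_hat\tleverage\tpev\treliability\n")
        for i, ind in enumerate(y.individual_ids):
            fh.write("\t".join([
                ind, fmt(y.values[i]), fmt(result.predictions[i]),
                fmt(result.residuals[i]), fmt(lev[i]), fmt(pev[i]), fmt(rel[i]),
            ]) + "\n")

    acc = "NA" if np.isnan(result.accuracy) else repr(result.accuracy)
    if acc == "NA":
        log.warning("accuracy undefined for the requested mask; reporting NA")
    summary = path.with_name(path.name + ".summary")
    with open(summary, "w") as fh:
        fh.write(f"strategy={result.strategy}\n")
        fh.write(f"n={n}\n")
        fh.write(f"n_in_mask={int(result.subgroup_mask.sum())}\n")
        fh.write(f"press={result.press!r}\n")
        fh.write(f"accuracy={acc}\n")
    log.info("strategy=%s PRESS=%.6g accuracy=%s -> %s",
             result.strategy, result.press, acc, path)
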