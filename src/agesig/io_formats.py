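"""Readers and writers for the external formats the pipeline touches.

Conventions
-----------
* Count matrices are ``pandas.DataFrame`` (features x samples, non-negative
  integers); sample metadata is a DataFrame indexed by ``sample_id`` with
  columns ``strain``, ``tissue``, ``age_months``, ``sex``.
* All genomic coordinates are 0-based half-open. TSS positions are single
  0-based coordinates.
* BED score column carries footprint purity as an integer in [0, 1000]
  (BED caps score at 1000); purity = score / 1000.
* Readers reject malformed records instead of silently coercing them.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from agesig.errors import ValidationError

SAMPLE_COLUMNS = ["strain", "tissue", "age_months", "sex"]

PEAK_COLUMNS = ["chrom", "start", "end", "name", "support"]
FOOTPRINT_COLUMNS = ["chrom", "start", "end", "tf", "purity", "strand"]


# ---------------------------------------------------------------------------
# counts + sample metadata


def validate_counts(counts: pd.DataFrame, samples: pd.DataFrame | None = None) -> None:
    """Check count-matrix invariants; raise :class:`ValidationError` on failure."""
    if counts.index.duplicated().any():
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids: {dupes[:5]}")
    if counts.columns.duplicated().any():
        dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.isfinite(values).all() or not (values == np.floor(values)).all():
            bad = np.argwhere(~(np.isfinite(values) & (values == np.floor(values))))
            g, s = bad[0]
            raise ValidationError(
                f"non-integer count for feature {counts.index[g]!r} "
                f"in sample {counts.columns[s]!r}"
            )
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative count for feature {counts.index[g]!r} in sample {counts.columns[s]!r}"
        )
    if samples is not None:
        validate_samples(samples)
        missing = counts.columns.difference(samples.index)
        if len(missing):
            raise ValidationError(
                f"samples present in counts but missing from metadata: {sorted(missing)}"
            )
        extra = samples.index.difference(counts.columns)
        if len(extra):
            raise ValidationError(
                f"samples present in metadata but missing from counts: {sorted(extra)}"
            )


def validate_samples(samples: pd.DataFrame) -> None:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample table missing required columns: {missing}")
    if samples.index.duplicated().any():
        dupes = samples.index[samples.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dupes[:5]}")
    ages = pd.to_numeric(samples["age_months"], errors="coerce")
    if ages.isna().any() or (ages <= 0).any():
        bad = samples.index[ages.isna() | (ages <= 0)].tolist()
        raise ValidationError(f"non-positive or non-numeric age_months for: {bad[:5]}")


def read_counts(counts_path, samples_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a counts TSV (feature x sample) and its sample-metadata TSV.

    Returns ``(counts, samples)`` with counts as int64 and samples indexed by
    ``sample_id``, validated against each other.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    validate_counts(counts, samples)
    counts = counts.astype(np.int64)
    # align metadata row order to the count columns
    samples = samples.loc[counts.columns]
    return counts, samples


def write_counts(counts: pd.DataFrame, samples: pd.DataFrame, counts_path, samples_path) -> None:
    validate_counts(counts, samples)
    counts.to_csv(counts_path, sep="\t", index_label="feature")
    samples.to_csv(samples_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> member...

    Member order within a set is preserved for reporting; duplicate members
    within a line are stored once. An empty file yields an empty collection.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen = set()
            for m in fields[2:]:
                if m and m not in seen:
                    members.append(m)
                    seen.add(m)
            if not members:
                raise ValidationError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# BED intervals


def _check_interval(chrom, start, end, lineno, path):
    if end <= start:
        raise ValidationError(f"{path}: line {lineno}: end <= start ({chrom}:{start}-{end})")
    if start < 0:
        raise ValidationError(f"{path}: line {lineno}: negative start")


def read_bed(path, kind: str = "peaks") -> pd.DataFrame:
    """Read BED intervals (0-based half-open).

    ``kind='peaks'`` expects BED3+ and returns columns
    ``chrom, start, end, name, support`` (support parsed from the score column
    when present, else 1). ``kind='footprints'`` expects BED6 with
    name = TF identity and score = purity x 1000, returning
    ``chrom, start, end, tf, purity, strand``.
    """
    if kind not in ("peaks", "footprints"):
        raise ValueError(f"unknown kind: {kind!r}")
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if kind == "peaks":
                if len(fields) < 3:
                    raise ValidationError(f"{path}: line {lineno}: BED3+ requires >= 3 fields")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                _check_interval(chrom, start, end, lineno, path)
                name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
                support = int(float(fields[4])) if len(fields) > 4 else 1
                rows.append((chrom, start, end, name, support))
            else:
                if len(fields) < 6:
                    raise ValidationError(f"{path}: line {lineno}: footprint BED requires 6 fields")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                _check_interval(chrom, start, end, lineno, path)
                tf = fields[3]
                score = float(fields[4])
                if not 0 <= score <= 1000:
                    raise ValidationError(f"{path}: line {lineno}: score outside [0, 1000]")
                strand = fields[5]
                if strand not in ("+", "-", "."):
                    raise ValidationError(f"{path}: line {lineno}: unknown strand {strand!r}")
                rows.append((chrom, start, end, tf, score / 1000.0, strand))
    columns = PEAK_COLUMNS if kind == "peaks" else FOOTPRINT_COLUMNS
    return pd.DataFrame(rows, columns=columns)


def write_bed(intervals: pd.DataFrame, path, kind: str = "peaks") -> None:
    """Write intervals back to BED (inverse of :func:`read_bed`)."""
    with open(path, "w") as fh:
        if kind == "peaks":
            for row in intervals.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{row.support}\n")
        elif kind == "footprints":
            for row in intervals.itertuples(index=False):
                score = int(round(row.purity * 1000))
                strand = getattr(row, "strand", ".")
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.tf}\t{score}\t{strand}\n")
        else:
            raise ValueError(f"unknown kind: {kind!r}")


# ---------------------------------------------------------------------------
# TSS tables


def read_tss(path) -> pd.DataFrame:
    """Read a TSS table TSV: gene, chrom, pos (0-based), strand."""
    tss = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    required = ["gene", "chrom", "pos", "strand"]
    missing = [c for c in required if c not in tss.columns]
    if missing:
        raise ValidationError(f"{path}: TSS table missing columns {missing}")
    if tss["gene"].duplicated().any():
        dupes = tss.loc[tss["gene"].duplicated(), "gene"].tolist()
        raise ValidationError(f"{path}: duplicate gene entries: {dupes[:5]}")
    if (tss["pos"] < 0).any():
        raise ValidationError(f"{path}: negative TSS positions")
    bad = ~tss["strand"].isin(["+", "-"])
    if bad.any():
        raise ValidationError(f"{path}: unknown strand values {tss.loc[bad, 'strand'].unique()}")
    return tss.set_index("gene")


def write_tss(tss: pd.DataFrame, path) -> None:
    tss.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# YAML config


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: top-level config must be a mapping")
    return cfg


def write_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)
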