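"""Count-table I/O, depth normalisation, rank aggregation and composition summaries.

The universal currency of the pipeline is the *count table*: a
:class:`pandas.DataFrame` of non-negative integer abundances with taxa as
rows and samples as columns.  Sample metadata is a DataFrame indexed by
sample id with ``habitat``, ``mode`` and ``replicate`` columns; taxonomy is
a DataFrame indexed by taxon id with one column per rank (at least
``phylum`` and ``genus``).

All files are plain tab-separated UTF-8 text, "." decimal, no quoting; the
canonical orientation is taxa-rows x sample-columns.  Lines starting with
``#`` (e.g. the header comment of a BIOM TSV export) are skipped on read.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

#: closed vocabulary of sampling environments, in canonical (tie-break) order
HABITATS = ("water", "sediment", "intestine")
#: breeding modes: crayfish monoculture ponds vs rice-crayfish co-culture fields
MODES = ("MC", "RC")


class TableFormatError(ValueError):
    """Raised when a tabular input violates the count-table contract."""


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the count-table invariants and return the table as int64.

    Raises :class:`TableFormatError` listing the offending ids/cells when
    ids are duplicated or entries are negative or non-integer.
    """
    dup_taxa = table.index[table.index.duplicated()].unique().tolist()
    if dup_taxa:
        raise TableFormatError(f"duplicate taxon ids: {dup_taxa}")
    dup_samples = table.columns[table.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise TableFormatError(f"duplicate sample ids: {dup_samples}")

    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        numeric = table.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & table.notna()
        if bad.to_numpy().any():
            cells = [
                (t, s) for t in table.index for s in table.columns if bad.at[t, s]
            ]
            raise TableFormatError(f"malformed numeric cells at {cells[:10]}")
        values = numeric.to_numpy()
        table = numeric
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise TableFormatError(
            f"missing value at ({table.index[r]}, {table.columns[c]})"
        )
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise TableFormatError(
            f"negative count at ({table.index[r]}, {table.columns[c]})"
        )
    if not np.allclose(values, np.round(values)):
        r, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise TableFormatError(
            f"non-integer count at ({table.index[r]}, {table.columns[c]})"
        )
    out = table.astype(np.int64)
    out.index.name = table.index.name or "taxon_id"
    return out


def validate_sample_info(info: pd.DataFrame, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check metadata invariants (closed vocabularies, coverage of samples)."""
    for col in ("habitat", "mode"):
        if col not in info.columns:
            raise TableFormatError(f"sample metadata lacks required column '{col}'")
    bad_hab = sorted(set(info["habitat"]) - set(HABITATS))
    if bad_hab:
        raise TableFormatError(f"unknown habitat labels: {bad_hab}")
    bad_mode = sorted(set(info["mode"]) - set(MODES))
    if bad_mode:
        raise TableFormatError(f"unknown mode labels: {bad_mode}")
    if info.index.duplicated().any():
        dups = info.index[info.index.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate sample ids in metadata: {dups}")
    if table is not None:
        missing = sorted(set(table.columns) - set(info.index))
        if missing:
            raise TableFormatError(f"samples without metadata: {missing}")
    return info


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_count_table(path) -> pd.DataFrame:
    """Read a taxa x samples TSV count table (first column = taxon ids)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise TableFormatError(f"{path}: empty table")
    header = lines[0].rstrip("\n").split("\t")[1:]
    dup = sorted({s for s in header if header.count(s) > 1})
    if dup:
        raise TableFormatError(f"{path}: duplicated sample column(s) {dup}")
    from io import StringIO

    raw = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0, dtype=str)
    return validate_count_table(raw)


def write_count_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_sample_info(path) -> pd.DataFrame:
    info = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    info["replicate"] = info["replicate"].astype(int)
    return validate_sample_info(info)


def write_sample_info(info: pd.DataFrame, path) -> None:
    info.to_csv(path, sep="\t")


def read_taxonomy(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    tax.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# depth normalisation
# ---------------------------------------------------------------------------

def rarefy(table: pd.DataFrame, depth: int | str = "min", seed: int | None = None) -> pd.DataFrame:
    """Subsample every sample without replacement to a common depth.

    ``depth="min"`` resolves to the smallest per-sample total ("normalised
    according to the least sequence number").  Each sample is drawn once
    from its reads via the multivariate hypergeometric distribution, so no
    taxon count can exceed its original value and every column sums exactly
    to ``depth``.  Deterministic under a fixed ``seed``.
    """
    totals = table.sum(axis=0)
    if isinstance(depth, str):
        if depth != "min":
            raise ValueError(f"depth must be an integer or 'min', got {depth!r}")
        depth = int(totals.min())
    depth = int(depth)
    too_shallow = totals.index[totals < depth].tolist()
    if too_shallow:
        raise ValueError(
            f"rarefaction depth {depth} exceeds total reads of sample(s) {too_shallow}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty(table.shape, dtype=np.int64)
    counts = table.to_numpy()
    for j in range(table.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions; every column sums to 1."""
    totals = table.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    return table / totals


# ---------------------------------------------------------------------------
# taxonomy aggregation & composition summaries
# ---------------------------------------------------------------------------

def aggregate_rank(table: pd.DataFrame, tax: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Collapse taxa to a taxonomic rank; column sums are conserved exactly."""
    if rank not in tax.columns:
        raise ValueError(f"rank {rank!r} not in taxonomy (have {list(tax.columns)})")
    missing = sorted(set(table.index) - set(tax.index))
    if missing:
        raise ValueError(f"taxa without lineage: {missing[:10]}")
    names = tax.loc[table.index, rank].fillna("unclassified")
    out = table.groupby(names.to_numpy()).sum()
    out.index.name = rank
    return out


def bin_others(rel: pd.DataFrame, threshold: float = 0.01, label: str = "others") -> pd.DataFrame:
    """Merge taxa whose dataset-wide mean relative abundance is < threshold.

    The merged row is appended last under ``label``; column sums are
    preserved.  ``threshold=0`` is the identity (no row is ever below it).
    """
    means = rel.mean(axis=1)
    low = means < threshold
    if not low.any():
        return rel.copy()
    kept = rel.loc[~low]
    others = rel.loc[low].sum(axis=0).to_frame(label).T
    others.index.name = rel.index.name
    return pd.concat([kept, others])


def habitat_distribution(
    table: pd.DataFrame, info: pd.DataFrame, taxon: str
) -> dict[str, float]:
    """Share of a taxon's total reads found in each habitat, as percentages.

    Percentages are rounded to 2 decimals (round-half-even) and sum to 100
    within rounding.
    """
    if taxon not in table.index:
        raise KeyError(f"taxon {taxon!r} not in table")
    row = table.loc[taxon]
    total = row.sum()
    if total == 0:
        raise ValueError(f"taxon {taxon!r} has zero total reads")
    out = {}
    for hab in HABITATS:
        samples = info.index[info["habitat"] == hab]
        out[hab] = float(np.round(100.0 * row[samples].sum() / total, 2))
    return out


def top_n_taxa(table: pd.DataFrame, n: int) -> list[str]:
    """The n taxa with the largest total counts; ties broken by taxon id."""
    if n > len(table.index):
        raise ValueError(f"n={n} exceeds number of taxa ({len(table.index)})")
    totals = table.sum(axis=1)
    order = sorted(table.index, key=lambda t: (-totals[t], t))
    return order[:n]


def log10_abundance(rel: pd.DataFrame, floor: float = 1e-6) -> pd.DataFrame:
    """log10-transformed relative abundance (heatmap export); zeros floored."""
    return np.log10(rel.clip(lower=floor))
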