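"""Readers and writers for the exchange formats, and the in-memory data model.

Formats handled here:

* expression matrices — TSV, genes in rows (first column = gene identifier,
  header row = sample identifiers), log-scale intensities;
* outcome tables — two-column TSV ``sample_id<TAB>good|bad`` (no header);
* gene-set collections — GMT, one set per line
  (``name<TAB>description<TAB>gene1<TAB>gene2...``), with an optional
  ``BP:``/``CC:``/``MF:`` category tag leading the description field;
* drug-screen activity tables — delimited text in the DTP "Standard Agent"
  layout (columns NSC, LCONC, PANEL, CELL, NLOGGI50, Compound, CAS).

Lines starting with ``#`` are treated as comments in the TSV formats so that
pipeline outputs may carry provenance headers.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OUTCOME_GOOD = "good"
OUTCOME_BAD = "bad"
_CATEGORIES = ("BP", "CC", "MF", "custom")


class FormatError(ValueError):
    """A file violated the contract of its format."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class ExpressionCohort:
    """A genes x samples log-expression matrix with optional outcome labels.

    Parameters
    ----------
    cohort_id : str
        Free-text label for the cohort (e.g. a GEO accession).
    values : pandas.DataFrame
        Numeric matrix, index = gene identifiers, columns = sample
        identifiers, values log-scale intensities.
    outcome : pandas.Series or None
        Per-sample label, ``"good"`` or ``"bad"``; index must equal the
        sample identifiers.  ``None`` for unlabelled panels such as a
        cell-line baseline profile.
    """

    cohort_id: str
    values: pd.DataFrame
    outcome: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(
                f"cohort {self.cohort_id!r}: duplicate gene identifiers {list(dups)[:5]}"
            )
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(
                f"cohort {self.cohort_id!r}: duplicate sample identifiers {list(dups)[:5]}"
            )
        if self.values.isna().all(axis=1).any():
            bad = self.values.index[self.values.isna().all(axis=1)]
            raise FormatError(
                f"cohort {self.cohort_id!r}: entirely missing gene rows {list(bad)[:5]}"
            )
        if self.outcome is not None:
            missing = [s for s in self.values.columns if s not in self.outcome.index]
            if missing:
                raise FormatError(
                    f"cohort {self.cohort_id!r}: sample {missing[0]!r} has no outcome label"
                )
            self.outcome = self.outcome.reindex(self.values.columns)
            bad_labels = set(self.outcome.unique()) - {OUTCOME_GOOD, OUTCOME_BAD}
            if bad_labels:
                raise FormatError(
                    f"cohort {self.cohort_id!r}: invalid outcome labels {sorted(bad_labels)}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with a category tag (BP, CC, MF or custom)."""

    name: str
    category: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(f"unknown gene-set category {self.category!r}")
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered mapping of set name -> :class:`GeneSet`."""

    sets: dict[str, GeneSet] = field(default_factory=dict)
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise FormatError(f"duplicate gene-set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set


@dataclass(frozen=True)
class DrugActivityRecord:
    """One row of a DTP-style drug screen table.

    ``nloggi50`` is −log10 of the GI50 (the concentration causing 50% growth
    inhibition); higher values mean a more potent compound.
    """

    nsc: str
    cell: str
    nloggi50: float
    lconc: float | None = None
    panel: str = ""
    compound: str = ""
    cas: str = ""

    def __post_init__(self) -> None:
        if not self.nsc:
            raise ValueError("drug activity record with empty NSC identifier")
        if not self.cell:
            raise ValueError("drug activity record with empty cell-line identifier")
        if not math.isfinite(self.nloggi50):
            raise ValueError(
                f"non-finite NLOGGI50 for drug {self.nsc!r} / cell {self.cell!r}"
            )


# ---------------------------------------------------------------------------
# expression + outcome
# ---------------------------------------------------------------------------


def _read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_expression(path, outcome_path=None, cohort_id: str | None = None) -> ExpressionCohort:
    """Read an expression TSV (plus optional outcome TSV) into a cohort.

    Duplicate gene identifiers are collapsed by keeping the row with the
    highest mean value (the usual probe-to-gene reduction).  Rows and columns
    keep file order.
    """
    # round_trip parsing keeps written float64 values bit-exact on re-read
    values = _read_table(path, index_col=0, float_precision="round_trip")
    values.index = values.index.astype(str)
    for col in values.columns:
        if values[col].dtype == object:
            parsed = pd.to_numeric(values[col], errors="coerce")
            bad = parsed.isna() & values[col].notna()
            if bad.any():
                g = values.index[bad.to_numpy()][0]
                raise FormatError(
                    f"{path}: non-numeric value {values.loc[g, col]!r} "
                    f"at gene {g!r}, sample {col!r}"
                )
            values[col] = parsed
    values = values.astype(float)

    if values.index.has_duplicates:
        n_before = len(values)
        means = values.mean(axis=1).to_numpy()
        keep = np.ones(len(values), dtype=bool)
        for gene, idx in values.groupby(level=0, sort=False).indices.items():
            if len(idx) > 1:
                best = idx[int(np.argmax(means[idx]))]
                for i in idx:
                    keep[i] = i == best
        values = values.iloc[keep]
        logger.info(
            "%s: collapsed %d duplicate gene rows by highest mean", path, n_before - len(values)
        )

    outcome = None
    if outcome_path is not None:
        outcome = read_outcome(outcome_path)
    return ExpressionCohort(
        cohort_id=cohort_id or str(path), values=values, outcome=outcome
    )


def read_outcome(path) -> pd.Series:
    """Read a two-column ``sample<TAB>good|bad`` file."""
    df = _read_table(path, header=None, names=["sample", "outcome"], dtype=str)
    if df["outcome"].isna().any():
        raise FormatError(f"{path}: outcome file rows must have two columns")
    ser = pd.Series(df["outcome"].to_numpy(), index=df["sample"].to_numpy())
    if ser.index.has_duplicates:
        dup = ser.index[ser.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample {dup!r} in outcome file")
    bad = set(ser.unique()) - {OUTCOME_GOOD, OUTCOME_BAD}
    if bad:
        raise FormatError(f"{path}: invalid outcome labels {sorted(bad)}")
    return ser


def write_expression(cohort_or_frame, path, header_lines=None) -> None:
    """Write a genes x samples matrix as TSV (optionally with '#' header lines)."""
    values = (
        cohort_or_frame.values
        if isinstance(cohort_or_frame, ExpressionCohort)
        else cohort_or_frame
    )
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        values.to_csv(fh, sep="\t", index_label="gene", lineterminator="\n")


def write_outcome(outcome: pd.Series, path) -> None:
    with open(path, "w") as fh:
        for sample, label in outcome.items():
            fh.write(f"{sample}\t{label}\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path, source: str | None = None) -> GeneSetCollection:
    """Parse a GMT file; a leading ``BP:``/``CC:``/``MF:`` tag on the
    description field sets the category, otherwise ``custom``."""
    collection = GeneSetCollection(source=source or str(path))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            category = "custom"
            for tag in ("BP", "CC", "MF"):
                if desc.startswith(tag + ":"):
                    category = tag
                    break
            members = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} is empty")
            if name in collection:
                raise FormatError(f"{path}: line {lineno}: duplicate gene-set name {name!r}")
            collection.add(GeneSet(name=name, category=category, members=members))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection to GMT; categories are encoded as description tags
    so that read_gmt(write_gmt(c)) == c."""
    with open(path, "w") as fh:
        for gs in collection:
            desc = f"{gs.category}:{gs.name}" if gs.category != "custom" else "na"
            fh.write("\t".join([gs.name, desc, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# drug screen table
# ---------------------------------------------------------------------------

_MANDATORY = ("NSC", "CELL", "NLOGGI50")
_OPTIONAL = ("LCONC", "PANEL", "Compound", "CAS")


def read_drug_table(path) -> list[DrugActivityRecord]:
    """Read a DTP "Standard Agent"-layout activity table.

    The delimiter (tab or comma) is sniffed from the header line.  Rows whose
    NLOGGI50 is missing or non-finite are dropped; the drop count is logged.
    """
    with open(path) as fh:
        header = fh.readline()
    delim = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delim, comment="#", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    for col in _MANDATORY:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")

    def _exact_float(s):  # bit-exact round-trip, unlike the csv fast path
        try:
            return float(s)
        except (TypeError, ValueError):
            return float("nan")

    activity = df["NLOGGI50"].map(_exact_float)
    ok = np.isfinite(activity.to_numpy(dtype=float, na_value=np.nan))
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with missing/non-finite NLOGGI50", path, n_dropped)

    records: list[DrugActivityRecord] = []
    for i in np.nonzero(ok)[0]:
        row = df.iloc[int(i)]
        lconc = None
        if "LCONC" in df.columns and pd.notna(row.get("LCONC")):
            lconc = float(row["LCONC"])
        records.append(
            DrugActivityRecord(
                nsc=str(row["NSC"]).strip(),
                cell=str(row["CELL"]).strip(),
                nloggi50=float(activity.iloc[int(i)]),
                lconc=lconc,
                panel=str(row["PANEL"]).strip() if "PANEL" in df.columns and pd.notna(row.get("PANEL")) else "",
                compound=str(row["Compound"]).strip() if "Compound" in df.columns and pd.notna(row.get("Compound")) else "",
                cas=str(row["CAS"]).strip() if "CAS" in df.columns and pd.notna(row.get("CAS")) else "",
            )
        )
    return records


def write_drug_table(records: list[DrugActivityRecord], path) -> None:
    """Write records in the Standard Agent column layout (TSV)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["NSC", "LCONC", "PANEL", "CELL", "NLOGGI50", "Compound", "CAS"])
        for r in records:
            writer.writerow(
                [
                    r.nsc,
                    "" if r.lconc is None else repr(r.lconc),
                    r.panel,
                    r.cell,
                    repr(r.nloggi50),
                    r.compound,
                    r.cas,
                ]
            )
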